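"""Intragenic (intra-protein) domain-duplication detection.

A duplicated domain shows up as an off-diagonal local self-alignment: a
stretch near the N-terminus that aligns, with positive score, to a disjoint
stretch nearer the C-terminus of the same protein.  Hits are found by
Smith–Waterman restricted to the strict upper triangle of the self-comparison
matrix (which excludes the trivial self-diagonal), required to have
non-overlapping query/subject spans, attributed to exons through the
per-exon peptide segmentation, and assessed for significance by a
residue-shuffling permutation test (composition-preserving, seeded).

Splice-phase signatures provide the complementary, sequence-free line of
evidence: exons created by an intragenic duplication carry their junction
phases with them, so the duplicated block's phase subsequence appears twice.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .gene_models import GeneModel, GeneModelError, compute_splice_phases
from .pairwise_align import (
    AlignmentParams,
    AlignmentResult,
    best_self_local_score,
    local_align,
    self_local_align,
)
from .sequence_core import PepSequence


@dataclass(frozen=True)
class ExonSegment:
    """The peptide fragment encoded by one exon's coding interval.

    Codons spanning a splice junction are assigned to the exon contributing
    at least 2 of the 3 nucleotides, so the segments tile the protein
    exactly once."""

    exon_ordinal: int
    peptide: PepSequence
    ref_residue_span: tuple[int, int]  # 1-based inclusive on the full protein


@dataclass(frozen=True)
class DuplicationHit:
    """One off-diagonal self-alignment segment pair.

    ``query_span`` is strictly N-terminal of and non-overlapping with
    ``subject_span``.  ``empirical_p`` is the fraction of shuffled-protein
    best off-diagonal scores at least as high as the observed one (with the
    +1 correction, so it lies in (0, 1])."""

    query_span: tuple[int, int]
    subject_span: tuple[int, int]
    alignment: AlignmentResult
    identity_pct: float
    empirical_p: float
    query_exons: tuple[int, ...] = ()
    subject_exons: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        qs, qe = self.query_span
        ss, se = self.subject_span
        if not (qs <= qe < ss <= se):
            raise ValueError(
                f"query span {self.query_span} must lie strictly N-terminal of "
                f"subject span {self.subject_span}"
            )
        if not 0 < self.empirical_p <= 1:
            raise ValueError(f"empirical_p must be in (0, 1], got {self.empirical_p}")


@dataclass(frozen=True)
class PhaseSignature:
    """Ordered junction end-phases of a gene's coding junctions."""

    gene_id: str
    phases: tuple[int, ...]


# ---------------------------------------------------------------------------
# per-exon peptide segmentation
# ---------------------------------------------------------------------------


def split_by_exon(protein: PepSequence, model: GeneModel) -> list[ExonSegment]:
    """Cut the protein into the peptide segments encoded by each coding exon.

    ``protein`` must be the conceptual translation of the model's CDS (stop
    codon excluded); the total coding length must equal 3*(len+1) (with a
    stop codon) or 3*len.  Junction-spanning codons go to the exon providing
    >= 2 of the 3 nucleotides."""
    total = model.total_coding_length
    n = len(protein)
    if total not in (3 * n, 3 * (n + 1)):
        raise GeneModelError(
            f"protein length {n} inconsistent with total coding length {total}"
        )
    # nucleotides of residue r (1-based): CDS positions 3r-2 .. 3r
    counts: dict[int, dict[int, int]] = {}
    cum = 0
    for e in model.exons:
        if e.coding_start is None:
            continue
        lo, hi = cum + 1, cum + e.coding_length  # 1-based CDS interval
        first_res = (lo + 2) // 3
        last_res = min((hi + 2) // 3, n)
        for r in range(first_res, last_res + 1):
            r_lo, r_hi = 3 * r - 2, 3 * r
            ov = min(hi, r_hi) - max(lo, r_lo) + 1
            if ov > 0:
                counts.setdefault(r, {})[e.index] = ov
        cum += e.coding_length
    owner = {r: max(d.items(), key=lambda kv: (kv[1], -kv[0]))[0] for r, d in counts.items()}
    segments: list[ExonSegment] = []
    start = 1
    for r in range(2, n + 2):
        if r == n + 1 or owner[r] != owner[start]:
            seg = protein.residues[start - 1 : r - 1]
            segments.append(
                ExonSegment(
                    owner[start],
                    PepSequence(f"{model.gene_id}_exon{owner[start]}", seg),
                    (start, r - 1),
                )
            )
            if r == n + 1:
                break
            start = r
    return segments


# ---------------------------------------------------------------------------
# self-comparison
# ---------------------------------------------------------------------------


def permutation_pvalue(
    observed: float,
    null_scores: np.ndarray,
    randomized: bool = False,
    rng: np.random.Generator | None = None,
) -> float:
    """Empirical p-value of an observed statistic against permutation nulls.

    The default is the standard conservative estimator
    ``(1 + #{null >= obs}) / (n + 1)`` (always in (0, 1]).  Because
    alignment scores are discrete, ties make this estimator stochastically
    larger than uniform; ``randomized=True`` breaks ties uniformly at
    random, which is exactly uniform under the null and is what
    distributional calibration checks should use."""
    null_scores = np.asarray(null_scores)
    n = len(null_scores)
    if not randomized:
        return (1 + int((null_scores >= observed).sum())) / (n + 1)
    rng = rng or np.random.default_rng()
    greater = int((null_scores > observed).sum())
    ties = int((null_scores == observed).sum())
    return (greater + rng.random() * (1 + ties)) / (n + 1)


def _split_resolved_hit(residues: str, params: AlignmentParams, lo: int, hi: int,
                        min_len: int):
    """Fallback when the best upper-triangle path has overlapping spans:
    scan split points c and take the best local alignment between the
    N-terminal part (up to c) and the C-terminal part (from c)."""
    best = None
    for c in range(max(min_len, lo), min(len(residues) - min_len, hi) + 1):
        aln = local_align(residues[:c], residues[c:], params)
        if aln.n_columns == 0:
            continue
        if best is None or aln.score > best[0].score:
            best = (aln, c)
    if best is None:
        return None
    aln, c = best
    return AlignmentResult(
        aln.aligned_a, aln.aligned_b, aln.score,
        aln.a_start, aln.a_end, aln.b_start + c, aln.b_end + c,
        len(residues), len(residues), "local", params,
    )


def self_compare(
    protein: PepSequence,
    params: AlignmentParams | None = None,
    min_len: int = 20,
    n_permutations: int = 1000,
    seed: int = 0,
    max_hits: int = 3,
) -> list[DuplicationHit]:
    """Find duplicated segments within one protein.

    Hits are harvested iteratively: the best strict-upper-triangle local
    self-alignment is extracted, its residues are excluded, and the search
    repeats (up to ``max_hits``); hits whose aligned query stretch is
    shorter than ``min_len`` residues are discarded.  Each hit's
    ``empirical_p`` compares its score against the best off-diagonal scores
    of ``n_permutations`` residue-shuffled versions of the protein
    (seed-reproducible; the null distribution is computed once, which is
    conservative for secondary hits)."""
    params = params or AlignmentParams.protein(mode="local")
    n = len(protein)
    if n < 2 * min_len:
        warnings.warn(
            f"protein of length {n} too short for self-comparison at min_len={min_len}",
            stacklevel=2,
        )
        return []
    residues = protein.residues
    rng = np.random.default_rng(seed)
    null_scores = np.empty(n_permutations)
    arr = np.frombuffer(residues.encode(), dtype=np.uint8)
    for k in range(n_permutations):
        shuffled = rng.permutation(arr).tobytes().decode()
        null_scores[k] = best_self_local_score(shuffled, params)
    row_block = np.zeros(n, dtype=np.uint8)
    col_block = np.zeros(n, dtype=np.uint8)
    hits: list[DuplicationHit] = []
    for _ in range(max_hits):
        aln = self_local_align(residues, params, diag_min=1,
                               row_block=row_block, col_block=col_block)
        if aln.n_columns == 0:
            break
        if aln.a_end >= aln.b_start:  # overlapping spans: resolve by split scan
            resolved = _split_resolved_hit(residues, params, aln.b_start, aln.a_end,
                                           min_len)
            if resolved is None:
                break
            aln = resolved
        q_res = sum(1 for c in aln.aligned_a if c != "-")
        if q_res < min_len:
            break
        p = permutation_pvalue(aln.score, null_scores)
        aligned_pairs = sum(
            1 for ca, cb in zip(aln.aligned_a, aln.aligned_b)
            if ca != "-" and cb != "-"
        )
        ident = sum(
            1 for ca, cb in zip(aln.aligned_a, aln.aligned_b)
            if ca != "-" and ca == cb
        )
        hits.append(
            DuplicationHit(
                query_span=(aln.a_start, aln.a_end),
                subject_span=(aln.b_start, aln.b_end),
                alignment=aln,
                # identity over aligned residue pairs (gap columns excluded):
                # a duplication bridged by an indel can still be 100% identical
                identity_pct=100.0 * ident / aligned_pairs,
                empirical_p=p,
            )
        )
        row_block[aln.a_start - 1 : aln.a_end] = 1
        col_block[aln.b_start - 1 : aln.b_end] = 1
        # a span claimed as query must not reappear as subject and vice versa
        col_block[aln.a_start - 1 : aln.a_end] = 1
        row_block[aln.b_start - 1 : aln.b_end] = 1
    return hits


# ---------------------------------------------------------------------------
# exon attribution
# ---------------------------------------------------------------------------


def map_exon_homology(
    hits: Sequence[DuplicationHit],
    model: GeneModel,
    protein: PepSequence,
    min_columns: int = 4,
) -> tuple[list[DuplicationHit], pd.DataFrame]:
    """Attribute each hit's aligned columns to exons on both sides.

    Returns the hits annotated with their exon ordinal sets, plus a tidy
    table with one row per (hit, query exon, subject exon) combination, the
    number of aligned residue pairs supporting it, and their summed
    substitution score.  An exon enters a hit's attribution set when at
    least ``min_columns`` aligned (non-gap) residue pairs fall in it AND
    those columns score positively in total — this keeps out exons that are
    merely crossed by the path (gap-bridged linker exons, or short
    chance stretches aligned because they were cheaper than a longer gap)."""
    from .pairwise_align import _score_matrix

    segments = split_by_exon(protein, model)
    exon_of = np.empty(len(protein) + 1, dtype=np.int64)
    for seg in segments:
        lo, hi = seg.ref_residue_span
        exon_of[lo : hi + 1] = seg.exon_ordinal
    rows = []
    annotated: list[DuplicationHit] = []
    for h_idx, hit in enumerate(hits):
        alpha, S = _score_matrix(hit.alignment.params)
        pair_counts: dict[tuple[int, int], int] = {}
        pair_scores: dict[tuple[int, int], float] = {}
        for qpos, spos in hit.alignment.column_map:
            if qpos is None or spos is None:
                continue
            key = (int(exon_of[qpos]), int(exon_of[spos]))
            pair_counts[key] = pair_counts.get(key, 0) + 1
            col = S[alpha.index(protein.residues[qpos - 1]),
                    alpha.index(protein.residues[spos - 1])]
            pair_scores[key] = pair_scores.get(key, 0.0) + float(col)
        q_stats: dict[int, tuple[int, float]] = {}
        s_stats: dict[int, tuple[int, float]] = {}
        for (qe, se), c in pair_counts.items():
            sc = pair_scores[(qe, se)]
            qc, qs = q_stats.get(qe, (0, 0.0))
            q_stats[qe] = (qc + c, qs + sc)
            scnt, sscore = s_stats.get(se, (0, 0.0))
            s_stats[se] = (scnt + c, sscore + sc)
            rows.append(
                {"hit": h_idx, "query_exon": qe, "subject_exon": se,
                 "n_aligned_columns": c, "column_score": sc}
            )
        # an exon's aligned columns must be self-supporting: they have to
        # outscore the two gap openings that excising them would cost,
        # otherwise they are just a cheaper-than-gap crossing
        support = 2 * hit.alignment.params.gap_open
        q_exons = tuple(sorted(e for e, (c, sc) in q_stats.items()
                               if c >= min_columns and sc > support))
        s_exons = tuple(sorted(e for e, (c, sc) in s_stats.items()
                               if c >= min_columns and sc > support))
        annotated.append(replace(hit, query_exons=q_exons, subject_exons=s_exons))
    table = pd.DataFrame(rows, columns=["hit", "query_exon", "subject_exon",
                                        "n_aligned_columns", "column_score"])
    if not table.empty:
        table = table.sort_values(["hit", "query_exon", "subject_exon"]).reset_index(drop=True)
    return annotated, table


def exon_correspondence(table: pd.DataFrame, min_columns: int = 4,
                        min_score: float = 22.0) -> dict[int, tuple[int, ...]]:
    """Collapse the attribution table to query-exon -> subject-exon sets
    (same homology filter as the per-hit attribution: enough aligned
    columns, summed substitution score above the cost of excising the
    segment — two gap openings under the default protein scoring)."""
    out: dict[int, tuple[int, ...]] = {}
    if table.empty:
        return out
    keep = table[(table.n_aligned_columns >= min_columns) & (table.column_score > min_score)]
    for q, sub in keep.groupby("query_exon"):
        out[int(q)] = tuple(sorted(int(x) for x in sub.subject_exon.unique()))
    return out


# ---------------------------------------------------------------------------
# splice-phase signatures
# ---------------------------------------------------------------------------


def phase_signature(model: GeneModel) -> PhaseSignature:
    phases = tuple(p.end_phase_upstream for p in compute_splice_phases(model))
    return PhaseSignature(model.gene_id, phases)


def _lcs(a: Sequence[int], b: Sequence[int]) -> list[tuple[int, int]]:
    """Longest common subsequence; returns matched index pairs."""
    n, m = len(a), len(b)
    L = np.zeros((n + 1, m + 1), dtype=np.int64)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            if a[i - 1] == b[j - 1]:
                L[i, j] = L[i - 1, j - 1] + 1
            else:
                L[i, j] = max(L[i - 1, j], L[i, j - 1])
    pairs = []
    i, j = n, m
    while i > 0 and j > 0:
        if a[i - 1] == b[j - 1] and L[i, j] == L[i - 1, j - 1] + 1:
            pairs.append((i - 1, j - 1))
            i, j = i - 1, j - 1
        elif L[i - 1, j] >= L[i, j - 1]:
            i -= 1
        else:
            j -= 1
    return pairs[::-1]


def phase_signature_compare(models: Sequence[GeneModel]) -> pd.DataFrame:
    """Pairwise agreement of coding-junction phase signatures.

    For each pair of models the longest common subsequence of junction
    end-phases is computed; the aligned listing pairs up the matched
    junctions.  Models without coding junctions are skipped with a warning.
    """
    if len(models) < 2:
        raise GeneModelError("need at least two models to compare phase signatures")
    sigs = []
    for m in models:
        sig = phase_signature(m)
        if not sig.phases:
            warnings.warn(f"{m.gene_id}: no coding junctions; skipped", stacklevel=2)
            continue
        sigs.append(sig)
    rows = []
    for i in range(len(sigs)):
        for j in range(i + 1, len(sigs)):
            a, b = sigs[i], sigs[j]
            pairs = _lcs(a.phases, b.phases)
            listing = "; ".join(
                f"{a.gene_id}[{ia + 1}]={a.phases[ia]}~{b.gene_id}[{ib + 1}]={b.phases[ib]}"
                for ia, ib in pairs
            )
            rows.append(
                {
                    "gene_a": a.gene_id,
                    "gene_b": b.gene_id,
                    "n_junctions_a": len(a.phases),
                    "n_junctions_b": len(b.phases),
                    "lcs_length": len(pairs),
                    "agreement_a": len(pairs) / len(a.phases),
                    "agreement_b": len(pairs) / len(b.phases),
                    "aligned_phases": listing,
                }
            )
    return pd.DataFrame(rows)
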