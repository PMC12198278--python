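"""Gene architecture: exons, coding segments, splicing phases, transcript
assembly, and the local-synteny check.

Splicing-phase convention
-------------------------
The *end phase* of an exon is the cumulative coding length through that exon
modulo 3.  End phase 0 means the last nucleotide of the exon is position 3
of a codon (the junction falls between complete codons); end phase 1 means
one nucleotide of the interrupted codon lies upstream, and so on.  The GFF3
``phase`` column instead counts nucleotides to the next codon start; it
equals ``(3 - start_phase) % 3`` and both values are reported in tabular
output to avoid confusion.

All genomic coordinates are 1-based inclusive.  Exon ordinals are 1-based in
transcription order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, Sequence

import gffutils
import numpy as np
import pandas as pd

from .sequence_core import NucSequence, reverse_complement


class GeneModelError(ValueError):
    """Raised for inconsistent gene architecture."""


@dataclass(frozen=True)
class Exon:
    """One exon: 1-based ordinal in transcription order, genomic interval,
    and an optional protein-coding sub-interval (absent for fully
    untranslated exons)."""

    index: int
    genomic_start: int
    genomic_end: int
    coding_start: int | None = None
    coding_end: int | None = None

    def __post_init__(self) -> None:
        if self.genomic_start > self.genomic_end:
            raise GeneModelError(
                f"exon {self.index}: genomic_start > genomic_end "
                f"({self.genomic_start} > {self.genomic_end})"
            )
        if (self.coding_start is None) != (self.coding_end is None):
            raise GeneModelError(f"exon {self.index}: half-specified coding interval")
        if self.coding_start is not None:
            if not (self.genomic_start <= self.coding_start <= self.coding_end
                    <= self.genomic_end):
                raise GeneModelError(
                    f"exon {self.index}: coding interval outside the exon"
                )

    @property
    def length(self) -> int:
        return self.genomic_end - self.genomic_start + 1

    @property
    def coding_length(self) -> int:
        if self.coding_start is None:
            return 0
        return self.coding_end - self.coding_start + 1


@dataclass(frozen=True)
class GeneModel:
    """Exon/CDS architecture of one gene on one sequence.

    ``exons`` are ordered in transcription direction (for the minus strand
    that means descending genomic coordinates) and must not overlap.
    """

    gene_id: str
    seq_id: str
    strand: Literal["+", "-"]
    exons: tuple[Exon, ...]
    start_codon_exon: int

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise GeneModelError(f"bad strand {self.strand!r}")
        exons = tuple(self.exons)
        object.__setattr__(self, "exons", exons)
        for k, e in enumerate(exons, start=1):
            if e.index != k:
                raise GeneModelError(f"exon ordinals must be 1..n in order, got {e.index} at {k}")
        ivs = [(e.genomic_start, e.genomic_end) for e in exons]
        genomic_order = sorted(ivs)
        for (s1, e1), (s2, e2) in zip(genomic_order, genomic_order[1:]):
            if s2 <= e1:
                raise GeneModelError("exons overlap")
        if self.strand == "+" and ivs != genomic_order:
            raise GeneModelError("plus-strand exons must ascend in genomic coordinates")
        if self.strand == "-" and ivs != genomic_order[::-1]:
            raise GeneModelError("minus-strand exons must descend in genomic coordinates")
        total_coding = sum(e.coding_length for e in exons)
        if any(e.coding_start is not None for e in exons) and total_coding < 3:
            raise GeneModelError("total coding length must be >= 3 when coding segments exist")
        coding_exons = [e.index for e in exons if e.coding_start is not None]
        if coding_exons and self.start_codon_exon != coding_exons[0]:
            raise GeneModelError(
                f"start_codon_exon {self.start_codon_exon} is not the first coding exon "
                f"({coding_exons[0]})"
            )

    @property
    def coding_exons(self) -> list[Exon]:
        return [e for e in self.exons if e.coding_start is not None]

    @property
    def total_coding_length(self) -> int:
        return sum(e.coding_length for e in self.exons)

    def exon(self, ordinal: int) -> Exon:
        if not 1 <= ordinal <= len(self.exons):
            raise GeneModelError(f"no exon {ordinal} in {self.gene_id}")
        return self.exons[ordinal - 1]


@dataclass(frozen=True)
class JunctionPhase:
    """Splicing phases at the junction between two adjacent exons."""

    junction: tuple[int, int]
    end_phase_upstream: int
    start_phase_downstream: int

    def __post_init__(self) -> None:
        for p in (self.end_phase_upstream, self.start_phase_downstream):
            if p not in (0, 1, 2):
                raise GeneModelError(f"phase must be 0, 1 or 2, got {p}")


def compute_splice_phases(model: GeneModel) -> list[JunctionPhase]:
    """Phases of every coding-relevant junction (between the first and the
    last coding exon), computed as cumulative coding length mod 3 from the
    annotated start codon.

    For an unbroken reading frame the downstream start phase equals the
    upstream end phase at every junction.
    """
    coding = model.coding_exons
    if not coding:
        raise GeneModelError(f"{model.gene_id}: model has no coding segments")
    first, last = coding[0].index, coding[-1].index
    cum = 0
    cum_through = {}
    for e in model.exons:
        cum += e.coding_length
        cum_through[e.index] = cum
    out = []
    for i in range(first, last):
        end_phase = cum_through[i] % 3
        start_phase = cum_through[i] % 3  # identical for a contiguous frame
        out.append(JunctionPhase((i, i + 1), end_phase, start_phase))
    return out


def exon_end_phase(model: GeneModel, ordinal: int) -> int:
    """Cumulative coding length through ``ordinal`` mod 3."""
    cum = sum(e.coding_length for e in model.exons if e.index <= ordinal)
    return cum % 3


def exon_start_phase(model: GeneModel, ordinal: int) -> int:
    """Cumulative coding length before ``ordinal`` mod 3."""
    cum = sum(e.coding_length for e in model.exons if e.index < ordinal)
    return cum % 3


def phases_to_table(phases: Sequence[JunctionPhase]) -> pd.DataFrame:
    """Tabular phase report; also carries the GFF3-style phase of the
    downstream exon ((3 - start_phase) % 3)."""
    return pd.DataFrame(
        {
            "junction": [f"{a}-{b}" for (a, b) in (p.junction for p in phases)],
            "end_phase_upstream": [p.end_phase_upstream for p in phases],
            "start_phase_downstream": [p.start_phase_downstream for p in phases],
            "gff3_phase_downstream": [(3 - p.start_phase_downstream) % 3 for p in phases],
        }
    )


# ---------------------------------------------------------------------------
# GFF3 I/O
# ---------------------------------------------------------------------------


def parse_gff3_gene(path: str | Path, gene_id: str) -> GeneModel:
    """Read one gene's exon/CDS architecture from a GFF3 file.

    exon and CDS features must share a transcript parent (an mRNA feature,
    or the gene itself).  The GFF3 ``phase`` column, when present, is
    validated against the recomputed phases (mismatch is a warning, the
    recomputed value wins).  A CDS feature outside every exon is an error.
    """
    db = gffutils.create_db(
        str(path), ":memory:", keep_order=True, merge_strategy="create_unique",
        force=True,
    )
    try:
        gene = db[gene_id]
    except gffutils.FeatureNotFoundError as exc:
        raise GeneModelError(f"gene {gene_id!r} not found in {path}") from exc
    mrnas = list(db.children(gene, featuretype="mRNA"))
    parent = mrnas[0] if mrnas else gene
    exon_feats = sorted(db.children(parent, featuretype="exon"), key=lambda f: f.start)
    cds_feats = sorted(db.children(parent, featuretype="CDS"), key=lambda f: f.start)
    if not exon_feats:
        raise GeneModelError(f"gene {gene_id!r} has no exon features")
    strand = gene.strand if gene.strand in ("+", "-") else "+"
    if strand == "-":
        exon_feats = exon_feats[::-1]
    exons: list[Exon] = []
    for k, ef in enumerate(exon_feats, start=1):
        inside = [c for c in cds_feats if c.start >= ef.start and c.end <= ef.end]
        if len(inside) > 1:
            raise GeneModelError(f"exon {k} of {gene_id!r} contains multiple CDS features")
        cs, ce = (inside[0].start, inside[0].end) if inside else (None, None)
        exons.append(Exon(k, ef.start, ef.end, cs, ce))
    covered = sum(1 for e in exons if e.coding_start is not None)
    if covered != len(cds_feats):
        raise GeneModelError(f"{gene_id!r}: CDS feature outside any exon")
    coding = [e for e in exons if e.coding_start is not None]
    if not coding:
        raise GeneModelError(f"{gene_id!r}: no CDS features")
    model = GeneModel(gene_id, gene.seqid, strand, tuple(exons), coding[0].index)
    _validate_gff3_phases(model, cds_feats, strand)
    return model


def _validate_gff3_phases(model: GeneModel, cds_feats, strand: str) -> None:
    feats = cds_feats if strand == "+" else cds_feats[::-1]  # transcription order
    cum = 0
    for f, exon in zip(feats, model.coding_exons):
        expected = (3 - cum % 3) % 3
        if f.frame not in (".", "", None):
            got = int(f.frame)
            if got != expected:
                warnings.warn(
                    f"{model.gene_id}: GFF3 phase {got} for CDS at {f.start}-{f.end} "
                    f"disagrees with recomputed phase {expected}; using recomputed",
                    stacklevel=3,
                )
        cum += exon.coding_length


def write_gff3(model: GeneModel, path: str | Path, source: str = "pseudocasp") -> None:
    """Write the gene model as GFF3 (gene, mRNA, exon and CDS features,
    with the GFF3-convention phase column on CDS)."""
    gstart = min(e.genomic_start for e in model.exons)
    gend = max(e.genomic_end for e in model.exons)
    rows = [
        (model.seq_id, source, "gene", gstart, gend, ".", model.strand, ".",
         f"ID={model.gene_id}"),
        (model.seq_id, source, "mRNA", gstart, gend, ".", model.strand, ".",
         f"ID={model.gene_id}.t1;Parent={model.gene_id}"),
    ]
    cum = 0
    cds_rows = []
    for e in model.exons:
        rows.append(
            (model.seq_id, source, "exon", e.genomic_start, e.genomic_end, ".",
             model.strand, ".", f"ID={model.gene_id}.exon{e.index};Parent={model.gene_id}.t1")
        )
        if e.coding_start is not None:
            phase = (3 - cum % 3) % 3
            cds_rows.append(
                (model.seq_id, source, "CDS", e.coding_start, e.coding_end, ".",
                 model.strand, str(phase),
                 f"ID={model.gene_id}.cds{e.index};Parent={model.gene_id}.t1")
            )
            cum += e.coding_length
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for row in rows + cds_rows:
            fh.write("\t".join(str(x) for x in row) + "\n")


# ---------------------------------------------------------------------------
# transcript assembly
# ---------------------------------------------------------------------------


def build_transcript(
    model: GeneModel,
    seq: NucSequence,
    included_exons: Iterable[int] | None = None,
) -> tuple[NucSequence, np.ndarray]:
    """Splice a transcript from the included exons (default: all).

    Returns the spliced sequence (reverse-complemented for the minus strand)
    and a per-base coordinate map: ``map[t]`` is the 1-based genomic position
    of transcript base ``t`` (0-based).
    """
    if seq.id != model.seq_id:
        raise GeneModelError(
            f"sequence id {seq.id!r} does not match model seq_id {model.seq_id!r}"
        )
    if included_exons is None:
        included = [e.index for e in model.exons]
    else:
        included = sorted(set(included_exons))
        bad = [k for k in included if not 1 <= k <= len(model.exons)]
        if bad:
            raise GeneModelError(f"no such exon(s): {bad}")
        if not included:
            raise GeneModelError("empty exon inclusion set")
    parts: list[str] = []
    maps: list[np.ndarray] = []
    for e in model.exons:  # transcription order
        if e.index not in included:
            continue
        segment = seq.residues[e.genomic_start - 1 : e.genomic_end]
        positions = np.arange(e.genomic_start, e.genomic_end + 1, dtype=np.int64)
        if model.strand == "-":
            segment = reverse_complement(segment)
            positions = positions[::-1]
        parts.append(segment)
        maps.append(positions)
    name = model.gene_id + (
        "" if len(included) == len(model.exons)
        else "_skip" + "_".join(str(k) for k in sorted(set(range(1, len(model.exons) + 1)) - set(included)))
    )
    return NucSequence(name, "".join(parts)), np.concatenate(maps)


def extract_cds(
    model: GeneModel,
    seq: NucSequence,
    included_exons: Iterable[int] | None = None,
) -> tuple[NucSequence, np.ndarray, np.ndarray]:
    """Concatenate the coding segments of the included exons.

    Returns the CDS sequence, the per-base 1-based genomic coordinate map,
    and the per-base exon ordinal."""
    if included_exons is None:
        included = {e.index for e in model.exons}
    else:
        included = set(included_exons)
    parts: list[str] = []
    maps: list[np.ndarray] = []
    ords: list[np.ndarray] = []
    for e in model.exons:
        if e.index not in included or e.coding_start is None:
            continue
        segment = seq.residues[e.coding_start - 1 : e.coding_end]
        positions = np.arange(e.coding_start, e.coding_end + 1, dtype=np.int64)
        if model.strand == "-":
            segment = reverse_complement(segment)
            positions = positions[::-1]
        parts.append(segment)
        maps.append(positions)
        ords.append(np.full(len(segment), e.index, dtype=np.int64))
    if not parts:
        raise GeneModelError("no coding segments among the included exons")
    return (
        NucSequence(model.gene_id + "_cds", "".join(parts)),
        np.concatenate(maps),
        np.concatenate(ords),
    )


# ---------------------------------------------------------------------------
# local synteny
# ---------------------------------------------------------------------------


def check_flanking_synteny(
    locus: Sequence[tuple[str, int]],
    target: str,
    expected_neighbor: str,
    side: Literal["5prime", "3prime"],
    target_strand: Literal["+", "-"] = "+",
) -> bool:
    """True iff the nearest annotated neighbor of ``target`` on the stated
    side (in the target's transcription orientation) is
    ``expected_neighbor``.

    ``locus`` is an ordered list of (gene_id, start) annotations on one
    sequence.  Raises if the target is absent or has no neighbor on that
    side."""
    if side not in ("5prime", "3prime"):
        raise ValueError(f"side must be '5prime' or '3prime', got {side!r}")
    entries = sorted(locus, key=lambda t: t[1])
    idx = [k for k, (g, _) in enumerate(entries) if g == target]
    if not idx:
        raise GeneModelError(f"target gene {target!r} not in locus list")
    k = idx[0]
    if len(entries) == 1:
        raise GeneModelError(
            f"target {target!r} has no neighbor in the locus list"
        )
    upstream_left = (target_strand == "+") == (side == "5prime")
    nk = k - 1 if upstream_left else k + 1
    if nk < 0 or nk >= len(entries):
        return False  # genes exist, but none on the requested side
    return entries[nk][0] == expected_neighbor
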