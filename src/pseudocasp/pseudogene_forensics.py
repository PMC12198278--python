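"""Pseudogene forensics: frameshift propagation, premature-stop location,
exon-skip rescue evaluation, rescue-ORF mapping, catalytic-dyad checks and
gene-status classification.

The analyses compare a query gene (possibly disabled) against an intact
ortholog.  Indel events are called from a global alignment of the intact
ortholog CDS (the reference coordinate system) against the query CDS; the
pre-lesion reading frame of the query is recovered from those events, which
is what lets splicing phases and rescue frames be expressed in the
conserved (ortholog) frame even though the query's own reading is broken.

Counting conventions
--------------------
* ``codons_downstream_to_stop`` counts complete triplets strictly after the
  codon disrupted by the causal event, with the stop triplet counted as the
  terminating ordinal (a stop in the 6th triplet after the deletion gives
  6).
* Truncated-protein lengths are measured from the annotated initiator
  methionine, with Met counted as residue 1 and the stop excluded.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Literal, Sequence


from .gene_models import GeneModel, JunctionPhase, extract_cds
from .pairwise_align import (
    AlignmentParams,
    IndelEvent,
    call_indels,
    global_align,
    local_align,
    percent_identity,
)
from .sequence_core import NucSequence, PepSequence, translate_cds

logger = logging.getLogger("pseudocasp")


class ForensicsError(ValueError):
    """Raised for inconsistent forensic inputs."""


@dataclass(frozen=True)
class PtcReport:
    """Location and consequence of a premature termination codon.

    ``causal_event`` is the first frame-shifting indel, or ``None`` when the
    premature stop arises from a substitution."""

    causal_event: IndelEvent | None
    codons_downstream_to_stop: int
    truncated_peptide: PepSequence
    truncated_length: int

    def __post_init__(self) -> None:
        if self.codons_downstream_to_stop < 0:
            raise ForensicsError("codons_downstream_to_stop must be non-negative")
        if "*" in self.truncated_peptide.residues:
            raise ForensicsError("truncated peptide must not contain internal stops")
        if self.truncated_length != len(self.truncated_peptide):
            raise ForensicsError("truncated_length inconsistent with peptide")


@dataclass(frozen=True)
class SkipVerdict:
    """Outcome of skipping one exon: does it remove the lesion, and does it
    restore the reading frame?"""

    skipped_exon: int
    removes_lesion: bool
    frame_restored: bool
    explanation: JunctionPhase


@dataclass(frozen=True)
class RescueOrf:
    """An ORF starting at an internal ATG in frame with the ortholog-defined
    downstream frame, mapped onto the intact ortholog protein."""

    start_codon_exon: int
    orf_peptide: PepSequence
    ref_start_residue: int
    ref_end_residue: int

    def __post_init__(self) -> None:
        if not self.orf_peptide.residues.startswith("M"):
            raise ForensicsError("rescue ORF must begin with methionine")
        if self.ref_start_residue > self.ref_end_residue:
            raise ForensicsError("ref_start must be <= ref_end")


@dataclass(frozen=True)
class DyadReport:
    """Positions of the catalytic histidine and cysteine on the query, or
    absent where the aligned residue is not conserved."""

    his_pos: int | None
    cys_pos: int | None

    @property
    def intact(self) -> bool:
        return self.his_pos is not None and self.cys_pos is not None


@dataclass(frozen=True)
class GeneStatus:
    """Classification verdict with the list of rules that fired."""

    verdict: Literal["intact", "pseudogene", "truncated_coding"]
    evidence: tuple[str, ...]


# ---------------------------------------------------------------------------
# event coordinate mapping
# ---------------------------------------------------------------------------


def events_on_query(events: Sequence[IndelEvent]) -> list[tuple[IndelEvent, int]]:
    """Map each event's reference position into query-CDS coordinates.

    The query equals the reference with the events applied in order, so a
    reference position p corresponds to query position p + net(insertions -
    deletions applied upstream).  Returns (event, query_pos) pairs in
    reference order, where ``query_pos`` is the 1-based query position after
    which the event occurs."""
    out = []
    offset = 0
    for ev in sorted(events, key=lambda e: e.ref_pos):
        out.append((ev, ev.ref_pos + offset))
        offset += ev.length if ev.kind == "insertion" else -ev.length
    return out


def _query_exon_cds_spans(model: GeneModel) -> dict[int, tuple[int, int]]:
    """Half-open 1-based CDS-coordinate span [lo, hi) of each coding exon."""
    spans = {}
    cum = 0
    for e in model.exons:
        if e.coding_start is not None:
            spans[e.index] = (cum, cum + e.coding_length)
            cum += e.coding_length
    return spans


def _assign_events_to_exons(
    model: GeneModel, events: Sequence[IndelEvent]
) -> dict[int, list[tuple[IndelEvent, int]]]:
    spans = _query_exon_cds_spans(model)
    assigned: dict[int, list[tuple[IndelEvent, int]]] = {k: [] for k in spans}
    for ev, qpos in events_on_query(events):
        home = None
        for k, (lo, hi) in spans.items():
            if lo <= qpos < hi:
                home = k
                break
        if home is None:  # event beyond the last coding base
            home = max(spans)
        assigned[home].append((ev, qpos))
    return assigned


def corrected_coding_lengths(
    model: GeneModel, events: Sequence[IndelEvent]
) -> dict[int, int]:
    """Pre-lesion (ortholog-frame) coding length of each coding exon:
    the query length plus deleted bases minus inserted bases."""
    assigned = _assign_events_to_exons(model, events)
    out = {}
    for e in model.exons:
        if e.coding_start is None:
            continue
        delta = 0
        for ev, _ in assigned.get(e.index, []):
            delta += ev.length if ev.kind == "deletion" else -ev.length
        out[e.index] = e.coding_length + delta
    return out


# ---------------------------------------------------------------------------
# premature termination codon
# ---------------------------------------------------------------------------


def locate_ptc(
    query_model: GeneModel,
    query_seq: NucSequence,
    events: Sequence[IndelEvent],
) -> PtcReport:
    """Locate the premature termination codon caused by the given lesions.

    The query transcript is assembled from all exons and translated from the
    annotated start codon; the first stop after the first frame-shifting
    event is the PTC.  ``codons_downstream_to_stop`` counts triplets
    strictly after the codon disrupted by the event, stop inclusive.
    Raises :class:`ForensicsError` when there is no frame-shifting event and
    no premature stop ("no lesion to locate")."""
    cds, gmap, _ = extract_cds(query_model, query_seq)
    outcome = translate_cds(cds, 0, to_first_stop=True)
    last_coding = query_model.coding_exons[-1]
    annotated_end = (last_coding.coding_end if query_model.strand == "+"
                     else last_coding.coding_start)
    premature = True
    if outcome.stop_found:
        stop_end = int(gmap[3 * (outcome.stop_codon_index + 1) - 1])
        premature = stop_end != annotated_end
    fs = [ev for ev in events if ev.frame_shift != 0]
    if not fs:
        if outcome.stop_found and premature:
            return PtcReport(
                causal_event=None,
                codons_downstream_to_stop=0,
                truncated_peptide=outcome.peptide,
                truncated_length=len(outcome.peptide),
            )
        raise ForensicsError("no lesion to locate: no frameshift and no premature stop")
    if not outcome.stop_found:
        raise ForensicsError(
            "frameshifting event present but no stop codon downstream"
        )
    if not premature:
        raise ForensicsError(
            "frameshifting events compensate: translation reaches the "
            "annotated terminal stop (no premature stop to locate)"
        )
    first_fs_qpos = None
    for ev, qpos in events_on_query(events):
        if ev.frame_shift != 0:
            first_fs_qpos = (ev, qpos)
            break
    causal, q_d = first_fs_qpos
    stop_ordinal = outcome.stop_codon_index + 1  # 1-based codon ordinal
    disrupted = (q_d + 2) // 3  # codon containing the last pre-lesion base
    if stop_ordinal <= disrupted:
        # a premature stop upstream of the frameshift (stop substitution)
        return PtcReport(None, 0, outcome.peptide, len(outcome.peptide))
    return PtcReport(
        causal_event=causal,
        codons_downstream_to_stop=stop_ordinal - disrupted,
        truncated_peptide=outcome.peptide,
        truncated_length=len(outcome.peptide),
    )


# ---------------------------------------------------------------------------
# exon skipping
# ---------------------------------------------------------------------------


def evaluate_exon_skip(
    model: GeneModel,
    skipped_exon: int,
    events: Sequence[IndelEvent],
    query_seq: NucSequence | None = None,
) -> SkipVerdict:
    """Does skipping ``skipped_exon`` remove the lesion(s), and does it
    restore the reading frame?

    Phases are computed from the pre-lesion (ortholog-frame) coding lengths,
    i.e. the query lengths corrected by the called indels, so that the
    junction formed by the skip is judged in the conserved frame.  When
    ``query_seq`` is given the verdict is cross-validated by conceptual
    translation of the skip isoform (disagreement warns; the phase verdict
    stands)."""
    exon = model.exon(skipped_exon)
    if skipped_exon == model.start_codon_exon:
        raise ForensicsError("cannot evaluate skipping of the start-codon exon")
    if exon.coding_start is None:
        raise ForensicsError(f"exon {skipped_exon} is not coding")
    if skipped_exon in (1, len(model.exons)):
        raise ForensicsError(f"exon {skipped_exon} is not internal")
    corrected = corrected_coding_lengths(model, events)
    assigned = _assign_events_to_exons(model, events)
    fs_inside = [ev for ev, _ in assigned.get(skipped_exon, []) if ev.frame_shift != 0]
    fs_total = [ev for ev in events if ev.frame_shift != 0]
    removes = len(fs_inside) == len(fs_total) and len(fs_total) > 0
    cum_before = 0
    for e in model.exons:
        if e.index >= skipped_exon:
            break
        cum_before += corrected.get(e.index, 0)
    end_phase_up = cum_before % 3
    start_phase_down = (cum_before + corrected[skipped_exon]) % 3
    no_fs_outside = len(fs_inside) == len(fs_total)
    frame_restored = (end_phase_up == start_phase_down) and no_fs_outside
    upstream = skipped_exon - 1
    downstream = skipped_exon + 1
    verdict = SkipVerdict(
        skipped_exon=skipped_exon,
        removes_lesion=removes,
        frame_restored=frame_restored,
        explanation=JunctionPhase((upstream, downstream), end_phase_up, start_phase_down),
    )
    if query_seq is not None:
        oracle = skip_translation_restores(model, query_seq, (skipped_exon,))
        if oracle != frame_restored:
            warnings.warn(
                f"skip verdict for exon {skipped_exon} ({frame_restored}) disagrees "
                f"with the translation oracle ({oracle}); a substitution lesion or "
                f"in-frame stop may be present",
                stacklevel=2,
            )
    return verdict


def skip_translation_restores(
    model: GeneModel, seq: NucSequence, skipped: Sequence[int]
) -> bool:
    """Translation oracle: True iff conceptual translation of the isoform
    lacking ``skipped`` reaches the gene's annotated terminal stop codon."""
    included = [e.index for e in model.exons if e.index not in set(skipped)]
    cds, gmap, _ = extract_cds(model, seq, included)
    outcome = translate_cds(cds, 0, to_first_stop=True)
    if not outcome.stop_found:
        return False
    stop_end_t = 3 * (outcome.stop_codon_index + 1) - 1  # 0-based CDS index
    stop_end_genomic = int(gmap[stop_end_t])
    last_coding = model.coding_exons[-1]
    annotated_end = (
        last_coding.coding_end if model.strand == "+" else last_coding.coding_start
    )
    return stop_end_genomic == annotated_end


def evaluate_multi_exon_skip(
    model: GeneModel,
    skipped_exons: Sequence[int],
    events: Sequence[IndelEvent],
) -> SkipVerdict:
    """Frame arithmetic for skipping several exons at once (the single-exon
    case is the mode analysed by default; this enumeration is opt-in)."""
    skipped = sorted(set(skipped_exons))
    if model.start_codon_exon in skipped:
        raise ForensicsError("cannot skip the start-codon exon")
    corrected = corrected_coding_lengths(model, events)
    assigned = _assign_events_to_exons(model, events)
    fs_total = [ev for ev in events if ev.frame_shift != 0]
    fs_inside = [
        ev for k in skipped for ev, _ in assigned.get(k, []) if ev.frame_shift != 0
    ]
    removed_len = sum(corrected.get(k, 0) for k in skipped)
    no_fs_outside = len(fs_inside) == len(fs_total)
    removes = no_fs_outside and len(fs_total) > 0
    frame_restored = removed_len % 3 == 0 and no_fs_outside
    first, last = skipped[0], skipped[-1]
    cum_before = sum(
        corrected.get(e.index, 0) for e in model.exons if e.index < first
    )
    return SkipVerdict(
        skipped_exon=first,
        removes_lesion=removes,
        frame_restored=frame_restored,
        explanation=JunctionPhase(
            (first - 1, last + 1), cum_before % 3, (cum_before + removed_len) % 3
        ),
    )


# ---------------------------------------------------------------------------
# rescue ORF
# ---------------------------------------------------------------------------


def find_rescue_orf(
    query_model: GeneModel,
    query_seq: NucSequence,
    reference_protein: PepSequence,
    params: AlignmentParams | None = None,
) -> RescueOrf | None:
    """Earliest ATG, 3' of the premature stop, in frame with the
    ortholog-defined downstream frame; its ORF is translated to the next
    stop and mapped onto the reference protein.

    For an intact gene (translation from the annotated start reaches the
    terminal stop) the annotated CDS itself is returned with
    ``ref_start_residue`` from the alignment (1 for a same-length ortholog).
    Returns ``None`` when no in-frame ATG exists."""
    params = params or AlignmentParams.protein(mode="local")
    cds, _, eords = extract_cds(query_model, query_seq)
    outcome = translate_cds(cds, 0, to_first_stop=True)
    n_codons = len(cds) // 3
    if outcome.stop_found and outcome.stop_codon_index + 1 == n_codons:
        # intact: the annotated CDS is its own (trivial) rescue ORF
        aln = local_align(outcome.peptide, reference_protein, params)
        return RescueOrf(
            start_codon_exon=query_model.start_codon_exon,
            orf_peptide=outcome.peptide,
            ref_start_residue=aln.b_start,
            ref_end_residue=aln.b_end,
        )
    barrier = 3 * (outcome.stop_codon_index + 1) if outcome.stop_found else 0
    frame = _ortholog_frame(cds.residues, barrier, reference_protein, params)
    pos = None
    for p in range(barrier + ((frame - barrier) % 3), len(cds) - 2, 3):
        if cds.residues[p : p + 3] == "ATG":
            pos = p
            break
    if pos is None:
        return None
    orf = translate_cds(cds.residues[pos:], 0, to_first_stop=True,
                        peptide_id=query_seq.id + "_rescue")
    if len(orf.peptide) == 0:
        return None
    aln = local_align(orf.peptide, reference_protein, params)
    if aln.n_columns == 0:
        return None
    return RescueOrf(
        start_codon_exon=int(eords[pos]),
        orf_peptide=orf.peptide,
        ref_start_residue=aln.b_start,
        ref_end_residue=aln.b_end,
    )


def _ortholog_frame(
    cds: str, barrier: int, reference_protein: PepSequence, params: AlignmentParams
) -> int:
    """Determine the downstream reading frame consistent with the ortholog:
    the frame whose conceptual translation of the post-stop region aligns
    best to the reference protein.  Returns the frame as a CDS-coordinate
    residue class (0-2)."""
    tail = cds[barrier:]
    best_frame, best_score = barrier % 3, -1.0
    for f in range(3):
        if len(tail) - f < 3:
            continue
        pep = translate_cds(tail, f, to_first_stop=False).peptide
        residues = pep.residues.replace("*", "X")
        if not residues:
            continue
        aln = local_align(PepSequence("frame", residues), reference_protein, params)
        if aln.score > best_score:
            best_score = aln.score
            best_frame = (barrier + f) % 3
    return best_frame


# ---------------------------------------------------------------------------
# catalytic dyad
# ---------------------------------------------------------------------------


def check_catalytic_dyad(
    protein: PepSequence,
    reference: PepSequence,
    ref_his: int,
    ref_cys: int,
    params: AlignmentParams | None = None,
) -> DyadReport:
    """Alignment-anchored dyad check: the reference His/Cys positions are
    mapped through a global protein alignment; a position is reported only
    when the aligned query residue is H (respectively C)."""
    for name, p in (("ref_his", ref_his), ("ref_cys", ref_cys)):
        if not 1 <= p <= len(reference):
            raise ForensicsError(
                f"{name}={p} outside reference protein of length {len(reference)}"
            )
    params = params or AlignmentParams.protein()
    aln = global_align(reference, protein, params)
    his_pos = cys_pos = None
    for a_pos, b_pos in aln.column_map:
        if a_pos == ref_his and b_pos is not None:
            if protein.residues[b_pos - 1] == "H":
                his_pos = b_pos
        if a_pos == ref_cys and b_pos is not None:
            if protein.residues[b_pos - 1] == "C":
                cys_pos = b_pos
    return DyadReport(his_pos, cys_pos)


def repair_to_reference_frame(
    query_cds: NucSequence, events: Sequence[IndelEvent]
) -> NucSequence:
    """Undo the called indels on the query CDS so that it regains the
    reference (pre-lesion) frame: deleted stretches are re-inserted as N
    runs, inserted stretches removed.  Used to recover a full-length
    conceptual translation (with X at repaired codons) for the dyad check
    on frameshifted genes."""
    s = query_cds.residues
    parts: list[str] = []
    prev = 0
    for ev, qpos in events_on_query(events):
        parts.append(s[prev:qpos])
        if ev.kind == "deletion":
            parts.append("N" * ev.length)
            prev = qpos
        else:
            prev = qpos + ev.length
    parts.append(s[prev:])
    return NucSequence(query_cds.id + "_repaired", "".join(parts))


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------


def classify_gene_status(
    ptc: PtcReport | None,
    skips: Sequence[SkipVerdict],
    rescue: RescueOrf | None,
    dyad: DyadReport,
    domain_window: tuple[int, int],
    reference_length: int | None = None,
) -> GeneStatus:
    """Combine the forensic reports into a verdict.

    * ``intact``: no premature stop and the dyad is conserved.
    * ``pseudogene``: a premature stop that no single-exon skip repairs and
      that no rescue ORF predating the catalytic domain window can bypass,
      or loss of the catalytic dyad.
    * ``truncated_coding``: everything else (e.g. a premature stop that an
      in-frame skip removes, or a rescue ORF covering the whole domain).
    """
    lo, hi = domain_window
    if lo > hi or lo < 1:
        raise ForensicsError(f"bad catalytic-domain window {domain_window}")
    if ptc is not None and reference_length is not None:
        if ptc.truncated_length >= reference_length:
            raise ForensicsError(
                "contradictory inputs: truncated peptide not shorter than the reference"
            )
    evidence: list[str] = []
    if ptc is not None:
        if ptc.causal_event is not None:
            evidence.append(
                f"frameshift ({ptc.causal_event.kind} of {ptc.causal_event.length} nt "
                f"after reference position {ptc.causal_event.ref_pos}) with premature "
                f"stop {ptc.codons_downstream_to_stop} triplets downstream; "
                f"truncated product of {ptc.truncated_length} aa"
            )
        else:
            evidence.append(
                f"premature stop by substitution; truncated product of "
                f"{ptc.truncated_length} aa"
            )
    # a skip only rescues the product if it restores the frame AND removes
    # the lesion (a frame-neutral skip elsewhere leaves the lesion in place)
    any_skip_restores = any(s.frame_restored and s.removes_lesion for s in skips)
    if ptc is not None and skips:
        if any_skip_restores:
            ok = [s.skipped_exon for s in skips
                  if s.frame_restored and s.removes_lesion]
            evidence.append(f"exon skip(s) {ok} remove the lesion and restore "
                            f"the reading frame")
        else:
            evidence.append(
                "no single-exon skip restores the reading frame: "
                + "; ".join(
                    f"skip exon {s.skipped_exon} joins end phase "
                    f"{s.explanation.end_phase_upstream} to start phase "
                    f"{s.explanation.start_phase_downstream}"
                    for s in skips
                    if s.removes_lesion
                )
            )
    rescue_in_domain = rescue is not None and rescue.ref_start_residue > lo
    if rescue is None:
        if ptc is not None:
            evidence.append("no rescue ORF in frame with the downstream domain")
    elif rescue_in_domain and ptc is not None:
        evidence.append(
            f"rescue ORF starts at reference residue {rescue.ref_start_residue}, "
            f"inside the catalytic domain ({lo}-{hi}): incomplete domain"
        )
    if not dyad.intact:
        missing = [n for n, v in (("His", dyad.his_pos), ("Cys", dyad.cys_pos)) if v is None]
        evidence.append(f"catalytic dyad lost ({'/'.join(missing)} not conserved)")
    pseudogene = (
        ptc is not None
        and not any_skip_restores
        and (rescue is None or rescue_in_domain)
    ) or not dyad.intact
    if ptc is None and dyad.intact:
        verdict = "intact"
        evidence.append("no premature stop; catalytic dyad conserved")
    elif pseudogene:
        verdict = "pseudogene"
    else:
        verdict = "truncated_coding"
    return GeneStatus(verdict, tuple(evidence))


# ---------------------------------------------------------------------------
# end-to-end pipeline
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ForensicsReport:
    """Everything the pipeline computed for one query gene."""

    gene_id: str
    percent_identity_cds: float
    events: tuple[IndelEvent, ...]
    ptc: PtcReport | None
    skips: tuple[SkipVerdict, ...]
    rescue: RescueOrf | None
    dyad: DyadReport
    status: GeneStatus

    def to_dict(self) -> dict:
        return {
            "gene_id": self.gene_id,
            "percent_identity_cds": self.percent_identity_cds,
            "events": [
                {
                    "kind": e.kind,
                    "ref_pos": e.ref_pos,
                    "length": e.length,
                    "frame_shift": e.frame_shift,
                }
                for e in self.events
            ],
            "ptc": None
            if self.ptc is None
            else {
                "codons_downstream_to_stop": self.ptc.codons_downstream_to_stop,
                "truncated_length": self.ptc.truncated_length,
                "truncated_peptide": self.ptc.truncated_peptide.residues,
                "causal_event_ref_pos": None
                if self.ptc.causal_event is None
                else self.ptc.causal_event.ref_pos,
            },
            "skips": [
                {
                    "skipped_exon": s.skipped_exon,
                    "removes_lesion": s.removes_lesion,
                    "frame_restored": s.frame_restored,
                    "end_phase_upstream": s.explanation.end_phase_upstream,
                    "start_phase_downstream": s.explanation.start_phase_downstream,
                }
                for s in self.skips
            ],
            "rescue": None
            if self.rescue is None
            else {
                "start_codon_exon": self.rescue.start_codon_exon,
                "orf_length": len(self.rescue.orf_peptide),
                "ref_start_residue": self.rescue.ref_start_residue,
                "ref_end_residue": self.rescue.ref_end_residue,
            },
            "dyad": {
                "his_pos": self.dyad.his_pos,
                "cys_pos": self.dyad.cys_pos,
                "intact": self.dyad.intact,
            },
            "status": {
                "verdict": self.status.verdict,
                "evidence": list(self.status.evidence),
            },
        }

    def summary(self) -> str:
        lines = [f"gene {self.gene_id}: {self.status.verdict.upper()}"]
        lines.append(f"  CDS identity to ortholog: {self.percent_identity_cds:.2f}%")
        for e in self.events:
            lines.append(
                f"  {e.kind} of {e.length} nt after reference position {e.ref_pos}"
                f" (frame shift {e.frame_shift})"
            )
        for item in self.status.evidence:
            lines.append(f"  - {item}")
        return "\n".join(lines)


def run_forensics(
    query_model: GeneModel,
    query_seq: NucSequence,
    ortholog_cds: NucSequence,
    ortholog_protein: PepSequence,
    ref_his: int,
    ref_cys: int,
    domain_window: tuple[int, int],
    nuc_params: AlignmentParams | None = None,
    enumerate_multi_skips: bool = False,
) -> ForensicsReport:
    """The full forensic chain for one query gene against an intact ortholog.

    Aligns the query CDS to the ortholog CDS, calls indels (reference =
    ortholog), locates the premature stop, evaluates every internal
    single-exon skip, searches for a rescue ORF, checks the catalytic dyad
    on the frame-corrected conceptual translation, and classifies the gene.
    """
    nuc_params = nuc_params or AlignmentParams.nucleotide()
    query_cds, _, _ = extract_cds(query_model, query_seq)
    aln = global_align(ortholog_cds, query_cds, nuc_params)
    identity = percent_identity(aln)
    events = tuple(call_indels(aln, reference="a"))
    try:
        ptc = locate_ptc(query_model, query_seq, events)
    except ForensicsError:
        ptc = None
    skips: list[SkipVerdict] = []
    if ptc is not None:
        n = len(query_model.exons)
        for e in query_model.coding_exons:
            if e.index in (1, n) or e.index == query_model.start_codon_exon:
                continue
            skips.append(
                evaluate_exon_skip(query_model, e.index, events, query_seq)
            )
        if enumerate_multi_skips:
            cands = [
                e.index
                for e in query_model.coding_exons
                if e.index not in (1, n) and e.index != query_model.start_codon_exon
            ]
            for i, a in enumerate(cands):
                for b in cands[i + 1 :]:
                    skips.append(
                        evaluate_multi_exon_skip(query_model, (a, b), events)
                    )
    rescue = find_rescue_orf(query_model, query_seq, ortholog_protein)
    if any(ev.frame_shift != 0 for ev in events):
        repaired = repair_to_reference_frame(query_cds, events)
    else:
        repaired = query_cds
    pep = translate_cds(repaired, 0, to_first_stop=False).peptide
    query_protein = PepSequence(pep.id, pep.residues.replace("*", "X"))
    dyad = check_catalytic_dyad(query_protein, ortholog_protein, ref_his, ref_cys)
    status = classify_gene_status(
        ptc, skips, rescue, dyad, domain_window, reference_length=len(ortholog_protein)
    )
    return ForensicsReport(
        gene_id=query_model.gene_id,
        percent_identity_cds=identity,
        events=events,
        ptc=ptc,
        skips=tuple(skips),
        rescue=rescue,
        dyad=dyad,
        status=status,
    )
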