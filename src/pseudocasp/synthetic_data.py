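"""Generator for caspase-16-like loci with known ground truth.

The generator builds an ancestral caspase-1-like gene (8 exons: one
untranslated leader, two prodomain/CARD exons, two large-subunit exons, one
inter-subunit linker exon, two small-subunit exons) and derives from it an
11-exon caspase-16-like gene by intragenic exon duplication: the large- and
small-subunit exons are copied 5'-ward to form a new prodomain (a degenerate
second copy of the catalytic domain), and the linker exon is duplicated in
place.  The catalytic His/Cys dyad sits in fixed pentapeptide contexts in
the large-subunit exons and, at nonzero copy divergence, is knocked out in
the prodomain copy.  Splice phases travel with the duplicated exons, so the
copied block's phase subsequence appears twice in the derived gene.

Default exon coding lengths (nt, stop codon included in the last exon):

====  =====================  ======
exon  role                   coding
====  =====================  ======
1     untranslated leader    0
2     prodomain (large-1')   198
3     prodomain (large-2')   130
4     prodomain (small-1')   127
5     prodomain (small-2')   133
6     large subunit 1        198
7     large subunit 2        130
8     linker                 36
9     linker (copy)          36
10    small subunit 1        127
11    small subunit 2 + stop 136
====  =====================  ======

Exon 2 therefore ends in splicing phase 0 and exon 4 begins in splicing
phase 1 (198 ≡ 0, 198+130 ≡ 1 mod 3), the asymmetry that makes skipping
exon 3 fail to restore the reading frame.  At nonzero copy divergence the
generator additionally primes the canonical frameshift window in exon 3:
deleting the nucleotide after coding position 100 of exon 3 places the
first out-of-frame stop exactly in the 6th triplet after the disrupted
codon (truncating the product to 105 residues), and plants the only
downstream in-frame ATG in exon 7 — reproducing, with known truth, the
lesion anatomy of the human gene.  Coding sequence is drawn uniformly from
the 61 sense codons; noncoding sequence is sampled at a configurable GC
content.  Everything is deterministic under the seed (regeneration is
byte-identical).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Literal, Sequence

import numpy as np

from .gene_models import Exon, GeneModel, write_gff3
from .pairwise_align import IndelEvent
from .sequence_core import (
    CODON_TABLE,
    NucSequence,
    PepSequence,
    STOP_CODONS,
    translate_cds,
    write_fasta,
)

SENSE_CODONS: tuple[str, ...] = tuple(sorted(CODON_TABLE))  # 61 codons
#: deterministic codon choice per amino acid (used for fixed motifs)
FIXED_CODON: dict[str, str] = {}
for _c in SENSE_CODONS:
    FIXED_CODON.setdefault(CODON_TABLE[_c], _c)

HIS_MOTIF = "GSHGI"  # catalytic histidine context (H at centre)
CYS_MOTIF = "QACRG"  # catalytic cysteine context (C at centre)


class GeneratorError(ValueError):
    """Raised for out-of-range generator parameters or lesion specs."""


@dataclass(frozen=True)
class GeneratorParams:
    """Tunable locus layout.  Defaults give the 11-exon layout above."""

    card_exon: int = 135          # each of the two ancestral prodomain exons
    large1: int = 198             # must be 0 mod 3 (phase-0 end of exon 2)
    large2: int = 130             # must be 1 mod 3 (phase-1 start of exon 4)
    linker: int = 36              # must be 0 mod 3
    small1: int = 127
    small2: int = 133             # sans stop; small1+small2 must be 2 mod 3
    utr5_exon: int = 150
    utr5_head: int = 24
    utr3_tail: int = 90
    flank: int = 60
    intron_min: int = 80
    intron_max: int = 200
    duplicate_divergence: float = 0.40  # residue-substitution fraction in copies
    gc_noncoding: float = 0.45

    def __post_init__(self) -> None:
        if not 0.0 <= self.duplicate_divergence <= 0.60:
            raise GeneratorError("duplicate_divergence must be within 0-0.6")
        if not 0.2 <= self.gc_noncoding <= 0.8:
            raise GeneratorError("gc_noncoding must be within 0.2-0.8")
        if self.large1 % 3 != 0 or self.linker % 3 != 0:
            raise GeneratorError("large1 and linker lengths must be multiples of 3")
        if self.large2 % 3 != 1:
            raise GeneratorError("large2 length must be 1 mod 3 (phase-1 junction)")
        if (self.small1 + self.small2) % 3 != 2:
            raise GeneratorError("small1+small2 must be 2 mod 3 (in-frame layout)")
        if (2 * self.card_exon) % 3 != 0:
            raise GeneratorError("ancestral prodomain must keep the frame (0 mod 3)")
        if self.intron_min < 20 or self.intron_max < self.intron_min:
            raise GeneratorError("bad intron length range")


@dataclass
class Lesion:
    """One injected lesion, positioned within an exon's coding segment
    (1-based, transcription order)."""

    kind: Literal["deletion", "insertion", "substitution", "dyad_knockout"]
    exon: int = 0
    position: int = 0
    length: int = 1
    replacement: str = ""


@dataclass
class TruthManifest:
    """Ground truth for one generated locus (and its lesion scenario).

    Replaying :func:`generate_caspase16_like_locus` with the recorded seed
    and parameters regenerates byte-identical sequences."""

    seed: int
    params: GeneratorParams
    ancestral_model: GeneModel
    derived_model: GeneModel
    ancestral_locus: NucSequence
    duplication_plan: list[tuple[tuple[int, ...], tuple[int, ...]]]
    dyad: tuple[int, int]                    # His/Cys residues, derived protein
    derived_protein: PepSequence
    lesions: list[Lesion] = field(default_factory=list)
    scenario: str | None = None
    expected_status: str | None = None
    expected: dict = field(default_factory=dict)

    def to_json(self) -> str:
        def model_d(m: GeneModel) -> dict:
            return {
                "gene_id": m.gene_id,
                "seq_id": m.seq_id,
                "strand": m.strand,
                "start_codon_exon": m.start_codon_exon,
                "exons": [
                    [e.index, e.genomic_start, e.genomic_end, e.coding_start, e.coding_end]
                    for e in m.exons
                ],
            }

        return json.dumps(
            {
                "seed": self.seed,
                "params": asdict(self.params),
                "ancestral_model": model_d(self.ancestral_model),
                "derived_model": model_d(self.derived_model),
                "ancestral_locus": self.ancestral_locus.residues,
                "duplication_plan": [[list(s), list(c)] for s, c in self.duplication_plan],
                "dyad": list(self.dyad),
                "derived_protein": self.derived_protein.residues,
                "lesions": [asdict(l) for l in self.lesions],
                "scenario": self.scenario,
                "expected_status": self.expected_status,
                "expected": self.expected,
            },
            indent=2,
        )


# ---------------------------------------------------------------------------
# low-level sequence sampling
# ---------------------------------------------------------------------------


def random_nuc_sequence(length: int, gc: float = 0.5,
                        seed: int | np.random.Generator = 0,
                        seq_id: str = "random") -> NucSequence:
    """A random nucleotide sequence at the given GC content."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    bases = rng.choice(np.array(list("ACGT")), size=length, p=p)
    return NucSequence(seq_id, "".join(bases))


def _random_sense_codons(rng: np.random.Generator, n: int) -> list[str]:
    idx = rng.integers(0, len(SENSE_CODONS), size=n)
    return [SENSE_CODONS[i] for i in idx]


def _random_sense_codon_other_aa(rng: np.random.Generator, aa: str) -> str:
    while True:
        c = SENSE_CODONS[int(rng.integers(0, len(SENSE_CODONS)))]
        if CODON_TABLE[c] != aa:
            return c


def _set_codon(cds: list[str], codon_1based: int, triplet: str) -> None:
    cds[codon_1based - 1] = triplet


def _codons_to_str(cds: list[str]) -> str:
    return "".join(cds)


def _has_inframe_stop(cds: str) -> bool:
    return any(cds[i : i + 3] in STOP_CODONS for i in range(0, len(cds) - 2, 3))


# ---------------------------------------------------------------------------
# ancestral CDS and the duplication plan
# ---------------------------------------------------------------------------


def _ancestral_offsets(p: GeneratorParams) -> dict[str, tuple[int, int]]:
    """0-based half-open block offsets within the ancestral CDS (sans stop)."""
    card = 2 * p.card_exon
    out = {}
    pos = 0
    for name, ln in [("card", card), ("large1", p.large1), ("large2", p.large2),
                     ("linker", p.linker), ("small1", p.small1), ("small2", p.small2)]:
        out[name] = (pos, pos + ln)
        pos += ln
    out["total"] = (0, pos)
    return out


def _sample_ancestral_cds(rng: np.random.Generator, p: GeneratorParams) -> str:
    """Ancestral CDS (sans stop): uniform sense codons with the start codons,
    dyad motifs and block-boundary bases pinned.  Resampled until neither
    the ancestral frame nor the duplicated (derived) frame contains an
    in-frame stop (the chimeric codons at block joins are the only risk)."""
    off = _ancestral_offsets(p)
    n_codons = off["total"][1] // 3
    card_codons = 2 * p.card_exon // 3
    his_anc = card_codons + 31   # codon ordinal of the catalytic His
    cys_anc = card_codons + 90   # codon ordinal of the catalytic Cys
    for _ in range(100):
        codons = _random_sense_codons(rng, n_codons)
        _set_codon(codons, 1, "ATG")                   # ancestral initiator
        _set_codon(codons, card_codons + 1, "ATG")     # large-subunit start (copied
        for k, aa in enumerate(HIS_MOTIF):             # as the derived initiator)
            _set_codon(codons, his_anc - 2 + k, FIXED_CODON[aa])
        for k, aa in enumerate(CYS_MOTIF):
            _set_codon(codons, cys_anc - 2 + k, FIXED_CODON[aa])
        chars = list(_codons_to_str(codons))
        # pin the bases flanking the linker to the bases flanking its
        # absence in the prodomain copy, so that at zero copy divergence the
        # prodomain translates identically to the catalytic domain around
        # the linker gap (the chimeric codons at the joins then coincide)
        chars[off["linker"][0]] = "G"     # linker first == small1 first
        chars[off["small1"][0]] = "G"
        chars[off["large2"][1] - 1] = "G"  # large2 last == linker last
        chars[off["linker"][1] - 1] = "G"
        anc = "".join(chars)
        if _has_inframe_stop(anc):
            continue
        if not _has_inframe_stop(_derived_cds_from_ancestral(anc, p)):
            return anc
    raise GeneratorError("could not sample a stop-free ancestral CDS")


def _derived_cds_from_ancestral(anc: str, p: GeneratorParams) -> str:
    """Apply the duplication plan: prodomain = copy of large+small blocks,
    linker duplicated in place.  Returns the derived CDS sans stop."""
    off = _ancestral_offsets(p)
    large = anc[off["large1"][0] : off["large2"][1]]
    linker = anc[off["linker"][0] : off["linker"][1]]
    small = anc[off["small1"][0] : off["small2"][1]]
    prodomain = large + small
    return prodomain + large + linker + linker + small


def _derived_layout(p: GeneratorParams) -> list[int]:
    """Coding lengths of derived exons 2..11 (stop codon in the last)."""
    return [p.large1, p.large2, p.small1, p.small2,
            p.large1, p.large2, p.linker, p.linker,
            p.small1, p.small2 + 3]


def _ancestral_layout(p: GeneratorParams) -> list[int]:
    return [p.card_exon, p.card_exon, p.large1, p.large2, p.linker,
            p.small1, p.small2 + 3]


def _get_codon(chars: list[str], c: int) -> str:
    return "".join(chars[3 * c - 3 : 3 * c])


def _set_chars_codon(chars: list[str], c: int, triplet: str) -> None:
    chars[3 * c - 3 : 3 * c] = list(triplet)


def _diverge_codons(chars: list[str], codon_ordinals: Sequence[int], frac: float,
                    rng: np.random.Generator) -> None:
    """Substitute ``frac`` of the given codons with sense codons encoding a
    different residue (composition of the rest untouched)."""
    k = int(round(frac * len(codon_ordinals)))
    if k == 0:
        return
    chosen = rng.choice(np.asarray(codon_ordinals), size=k, replace=False)
    for c in sorted(int(x) for x in chosen):
        aa = CODON_TABLE[_get_codon(chars, c)]
        _set_chars_codon(chars, c, _random_sense_codon_other_aa(rng, aa))


def _prime_frameshift_window(chars: list[str], p: GeneratorParams) -> dict:
    """Engineer exon 3's canonical lesion window: deleting the base after
    coding position 100 of exon 3 must meet its first out-of-frame stop in
    the 6th downstream triplet.  All edits keep the in-frame reading
    stop-free (stops never contain C, so forcing a middle base to C is
    always safe)."""
    exon3_cds_start = p.large1  # 0-based CDS offset of exon 3
    d = exon3_cds_start + 100   # 1-based CDS position after which the base is deleted
    # shifted triplets after the disrupted codon (1-based CDS coordinates)
    t0 = (d, d + 2, d + 3)      # chimeric codon at the deletion point
    shifted = [(d + 4 + 3 * k, d + 5 + 3 * k, d + 6 + 3 * k) for k in range(6)]
    stop_triplet = shifted[5]
    for idx, pos in enumerate(stop_triplet):
        chars[pos - 1] = "TAA"[idx]
    for trip in [t0] + shifted[:5]:
        s = "".join(chars[q - 1] for q in trip)
        if s in STOP_CODONS:
            chars[trip[1] - 1] = "C"
    # the deleted base must differ from its left neighbour so that the
    # left-aligned indel call has the single canonical coordinate d
    if chars[d] == chars[d - 1]:
        chars[d] = "C" if chars[d - 1] != "C" else "G"
    return {"deleted_base_exon": 3, "deleted_base_position": 101,
            "disrupted_codon": (d + 2) // 3,
            "expected_stop_triplets_downstream": 6}


def _plant_rescue_atg(chars: list[str], p: GeneratorParams) -> dict:
    """Remove every in-frame ATG between the primed stop and exon 7, then
    plant a single ATG at a fixed codon inside exon 7 (the only potential
    start codon in frame with the catalytic domain)."""
    pro_codons = (p.large1 + p.large2 + p.small1 + p.small2) // 3
    exon7_first_codon = pro_codons + p.large1 // 3 + 1
    plant = exon7_first_codon + 7
    stop_end = p.large1 + 100 + 21          # last base of the primed stop triplet
    boundary_codon = (stop_end + 2) // 3    # overlaps the stop: edit only its tail
    if _get_codon(chars, boundary_codon) == "ATG":
        _set_chars_codon(chars, boundary_codon, "ATC")
    for c in range(boundary_codon + 1, plant):
        if _get_codon(chars, c) == "ATG":
            _set_chars_codon(chars, c, "CTG")
    _set_chars_codon(chars, plant, "ATG")
    return {"rescue_atg_codon": plant, "rescue_exon": 7}


# ---------------------------------------------------------------------------
# genomic assembly
# ---------------------------------------------------------------------------


def _assemble_locus(gene_id: str, seq_id: str, cds: str,
                    coding_lengths: Sequence[int], rng: np.random.Generator,
                    p: GeneratorParams) -> tuple[NucSequence, GeneModel]:
    """Wrap the CDS into exons (leader exon, 5'UTR head, 3'UTR tail),
    introns (GT..AG) and flanks; returns the genomic sequence and model."""
    slices = []
    pos = 0
    for ln in coding_lengths:
        slices.append(cds[pos : pos + ln])
        pos += ln
    assert pos == len(cds)
    pieces: list[str] = []
    exons: list[Exon] = []
    cursor = 0

    def noncoding(n: int) -> str:
        return random_nuc_sequence(n, p.gc_noncoding, rng).residues

    def intron() -> str:
        n = int(rng.integers(p.intron_min, p.intron_max + 1))
        return "GT" + noncoding(n - 4) + "AG"

    pieces.append(noncoding(p.flank))
    cursor += p.flank
    n_exons = len(coding_lengths) + 1
    for k in range(1, n_exons + 1):
        if k > 1:
            iv = intron()
            pieces.append(iv)
            cursor += len(iv)
        if k == 1:
            seg, head, tail = "", 0, p.utr5_exon
        elif k == 2:
            seg, head, tail = slices[0], p.utr5_head, 0
        elif k == n_exons:
            seg, head, tail = slices[-1], 0, p.utr3_tail
        else:
            seg, head, tail = slices[k - 2], 0, 0
        utr_head = noncoding(head)
        utr_tail = noncoding(tail)
        gstart = cursor + 1
        pieces.append(utr_head + seg + utr_tail)
        cursor += head + len(seg) + tail
        gend = cursor
        if seg:
            cstart = gstart + head
            cend = cstart + len(seg) - 1
        else:
            cstart = cend = None
        exons.append(Exon(k, gstart, gend, cstart, cend))
    pieces.append(noncoding(p.flank))
    genome = NucSequence(seq_id, "".join(pieces))
    coding = [e for e in exons if e.coding_start is not None]
    model = GeneModel(gene_id, seq_id, "+", tuple(exons), coding[0].index)
    return genome, model


DUPLICATION_PLAN: list[tuple[tuple[int, ...], tuple[int, ...]]] = [
    ((6, 7), (2, 3)),     # large-subunit exons -> prodomain exons 2-3
    ((10, 11), (4, 5)),   # small-subunit exons -> prodomain exons 4-5
    ((8,), (9,)),         # linker exon duplicated in place
]


def generate_caspase16_like_locus(
    seed: int,
    params: GeneratorParams | None = None,
) -> tuple[NucSequence, GeneModel, TruthManifest]:
    """Generate a caspase-16-like locus with known truth.

    Returns the derived (11-exon) genomic sequence, its gene model, and the
    truth manifest (which also carries the ancestral 8-exon gene for
    phase-signature comparisons).  At ``duplicate_divergence`` 0 the
    prodomain is an exact copy of the catalytic domain; at nonzero
    divergence the copy is degenerate, its dyad is knocked out, and the
    canonical exon-3 lesion window / exon-7 rescue ATG are engineered in.
    """
    p = params or GeneratorParams()
    rng = np.random.default_rng(seed)
    anc = _sample_ancestral_cds(rng, p)
    anc_cds = anc + "TAA"
    derived = _derived_cds_from_ancestral(anc, p)
    chars = list(derived)
    pro_codons = (p.large1 + p.large2 + p.small1 + p.small2) // 3
    _set_chars_codon(chars, 1, "ATG")  # the copied block gained the initiator
    expected: dict = {}
    if p.duplicate_divergence > 0:
        eligible_pro = list(range(2, pro_codons + 1))
        _diverge_codons(chars, eligible_pro, p.duplicate_divergence, rng)
        # knock the dyad out of the prodomain copy
        card_codons = 2 * p.card_exon // 3
        his_copy = 31   # = his_anc - card_codons
        cys_copy = 90
        _set_chars_codon(chars, his_copy, "AAC")
        _set_chars_codon(chars, cys_copy, "TCC")
        # linker copy: complete codons inside exon 9
        linker2_start = pro_codons * 3 + p.large1 + p.large2 + p.linker  # 0-based
        first_full = (linker2_start + 3) // 3 + 1 if linker2_start % 3 else linker2_start // 3 + 1
        last_full = (linker2_start + p.linker) // 3
        _diverge_codons(chars, list(range(first_full, last_full + 1)),
                        p.duplicate_divergence, rng)
        expected.update(_prime_frameshift_window(chars, p))
        expected.update(_plant_rescue_atg(chars, p))
    derived_cds = "".join(chars) + anc_cds[-3:]
    if _has_inframe_stop(derived_cds[:-3]):
        raise GeneratorError("internal stop after divergence engineering (bug)")
    anc_genome, anc_model = _assemble_locus(
        "CASP1LIKE", "anc_locus", anc_cds, _ancestral_layout(p), rng, p
    )
    der_genome, der_model = _assemble_locus(
        "CASP16LIKE", "derived_locus", derived_cds, _derived_layout(p), rng, p
    )
    protein = translate_cds(derived_cds, 0, to_first_stop=True,
                            peptide_id="CASP16LIKE_protein").peptide
    dyad = (pro_codons + 31, pro_codons + 90)
    assert protein.residues[dyad[0] - 1] == "H" and protein.residues[dyad[1] - 1] == "C"
    expected["domain_window"] = [pro_codons + 1, len(protein)]
    manifest = TruthManifest(
        seed=seed,
        params=p,
        ancestral_model=anc_model,
        derived_model=der_model,
        ancestral_locus=anc_genome,
        duplication_plan=list(DUPLICATION_PLAN),
        dyad=dyad,
        derived_protein=protein,
        expected=expected,
    )
    return der_genome, der_model, manifest


# ---------------------------------------------------------------------------
# lesion injection
# ---------------------------------------------------------------------------

SCENARIOS = (
    "human-casp16p",
    "in-frame-deletion",
    "dyad-knockout",
    "stop-substitution",
    "compensated-double-indel",
)


def _exon_cds_offset(model: GeneModel, exon: int) -> int:
    """CDS nucleotides upstream of the given exon (0-based offset)."""
    off = 0
    for e in model.exons:
        if e.index >= exon:
            break
        off += e.coding_length
    return off


def _named_scenario(name: str, seq: NucSequence, model: GeneModel,
                    manifest: TruthManifest) -> list[Lesion]:
    if name == "human-casp16p":
        pos = manifest.expected.get("deleted_base_position", 101)
        return [Lesion("deletion", exon=3, position=pos, length=1)]
    if name == "in-frame-deletion":
        return [Lesion("deletion", exon=3, position=60, length=3)]
    if name == "dyad-knockout":
        return [Lesion("dyad_knockout")]
    if name == "stop-substitution":
        return [Lesion("substitution", exon=7, position=7, length=3, replacement="TAA")]
    if name == "compensated-double-indel":
        from .gene_models import extract_cds

        cds, _, _ = extract_cds(model, seq)
        base = _exon_cds_offset(model, 3)
        for k in range(26):
            sd = base + 30 + k          # first deleted base, 1-based CDS
            si = base + 45 + k          # insertion after this CDS position
            trial = cds.residues[: sd - 1] + cds.residues[sd:si] + "G" + cds.residues[si:]
            out = translate_cds(trial, 0, to_first_stop=True)
            if out.stop_found and 3 * (out.stop_codon_index + 1) == len(trial):
                return [
                    Lesion("deletion", exon=3, position=30 + k, length=1),
                    Lesion("insertion", exon=3, position=45 + k, length=1,
                           replacement="G"),
                ]
        raise GeneratorError("no stop-free compensated indel placement found")
    raise GeneratorError(f"unknown scenario {name!r}; choose from {SCENARIOS}")


def _resolve_lesion(model: GeneModel, manifest: TruthManifest,
                    lesion: Lesion) -> Lesion:
    """Turn a dyad_knockout into a concrete substitution at the manifest's
    cysteine codon (middle base -> C, Cys -> Ser)."""
    if lesion.kind != "dyad_knockout":
        return lesion
    cys = manifest.dyad[1]
    cds_pos = 3 * cys - 1  # middle base of the Cys codon, 1-based CDS
    for e in model.exons:
        if e.coding_start is None:
            continue
        off = _exon_cds_offset(model, e.index)
        if off < cds_pos <= off + e.coding_length:
            return Lesion("substitution", exon=e.index, position=cds_pos - off,
                          length=1, replacement="C")
    raise GeneratorError("dyad codon outside every coding interval")


def _validate_lesion(model: GeneModel, lesion: Lesion) -> None:
    exon = model.exon(lesion.exon)
    if exon.coding_start is None:
        raise GeneratorError(f"exon {lesion.exon} has no coding segment")
    clen = exon.coding_length
    if lesion.kind in ("deletion", "substitution"):
        lo, hi = lesion.position, lesion.position + lesion.length - 1
    else:  # insertion after `position`
        lo = hi = lesion.position
    if lo < 1 or hi > clen:
        raise GeneratorError(
            f"lesion {lesion.kind} at exon {lesion.exon}:{lesion.position} "
            f"outside the coding interval"
        )
    if lesion.kind in ("deletion", "insertion") and hi > clen - 10:
        raise GeneratorError(
            "indel lesions within the last 10 coding nt of an exon are rejected "
            "(splice-site ambiguity is out of modelled scope)"
        )


def _apply_lesion(seq: str, model: GeneModel, lesion: Lesion) -> tuple[str, GeneModel]:
    if model.strand != "+":
        raise GeneratorError(
            "lesions are expressed in plus-strand coordinates; apply them "
            "before reflecting the locus with flip_locus"
        )
    exon = model.exon(lesion.exon)
    g = exon.coding_start + lesion.position - 1  # 1-based genomic
    if lesion.kind == "substitution":
        repl = lesion.replacement or "A" * lesion.length
        if len(repl) != lesion.length:
            raise GeneratorError("substitution replacement length mismatch")
        new_seq = seq[: g - 1] + repl + seq[g - 1 + lesion.length :]
        return new_seq, model
    if lesion.kind == "deletion":
        new_seq = seq[: g - 1] + seq[g - 1 + lesion.length :]
        delta, first_after = -lesion.length, g + lesion.length
    else:
        ins = lesion.replacement or "G" * lesion.length
        if len(ins) != lesion.length:
            raise GeneratorError("insertion content length mismatch")
        new_seq = seq[:g] + ins + seq[g:]
        delta, first_after = lesion.length, g + 1
    exons = []
    for e in model.exons:
        gs, ge, cs, ce = e.genomic_start, e.genomic_end, e.coding_start, e.coding_end
        if ge < g:
            pass
        elif gs >= first_after if lesion.kind == "deletion" else gs > g:
            gs, ge = gs + delta, ge + delta
            if cs is not None:
                cs, ce = cs + delta, ce + delta
        else:  # the lesion's exon (indel strictly inside its coding interval)
            ge += delta
            ce += delta
        exons.append(Exon(e.index, gs, ge, cs, ce))
    return new_seq, GeneModel(model.gene_id, model.seq_id, model.strand,
                              tuple(exons), model.start_codon_exon)


def inject_lesions(
    seq: NucSequence,
    model: GeneModel,
    manifest: TruthManifest,
    scenario: str | Sequence[Lesion],
) -> tuple[NucSequence, GeneModel, TruthManifest]:
    """Apply a lesion scenario (a name from :data:`SCENARIOS` or an explicit
    lesion list) and record the expected downstream consequences — net frame
    shift, first out-of-frame stop, skip-rescue and rescue-ORF outcomes,
    expected classification — in the manifest by direct simulation."""
    if isinstance(scenario, str):
        lesions = _named_scenario(scenario, seq, model, manifest)
        scen_name = scenario
    else:
        lesions = list(scenario)
        scen_name = None
    resolved = [_resolve_lesion(model, manifest, l) for l in lesions]
    for l in resolved:
        _validate_lesion(model, l)
    # apply in descending genomic order so positions stay valid
    order = sorted(
        range(len(resolved)),
        key=lambda i: model.exon(resolved[i].exon).coding_start + resolved[i].position,
        reverse=True,
    )
    new_seq_str, new_model = seq.residues, model
    for i in order:
        new_seq_str, new_model = _apply_lesion(new_seq_str, new_model, resolved[i])
    new_seq = NucSequence(seq.id, new_seq_str, seq.description)
    expected = dict(manifest.expected)
    status = _simulate_truth(new_seq, new_model, model, manifest, resolved, expected)
    new_manifest = replace(
        manifest,
        lesions=list(manifest.lesions) + resolved,
        scenario=scen_name if scen_name is not None else manifest.scenario,
        expected_status=status,
        expected=expected,
    )
    return new_seq, new_model, new_manifest


def _simulate_truth(new_seq: NucSequence, new_model: GeneModel,
                    old_model: GeneModel, manifest: TruthManifest,
                    lesions: Sequence[Lesion], expected: dict) -> str:
    """Direct-simulation oracle for the expected classification: conceptual
    translation of the lesioned gene and its skip isoforms, ATG scanning in
    the terminal-stop frame, and untouched-dyad bookkeeping.  Independent of
    the alignment/event-calling pipeline."""
    from .gene_models import extract_cds
    from .pseudogene_forensics import skip_translation_restores

    cds, gmap, eords = extract_cds(new_model, new_seq)
    out = translate_cds(cds, 0, to_first_stop=True)
    last_coding = new_model.coding_exons[-1]
    annotated_end = (last_coding.coding_end if new_model.strand == "+"
                     else last_coding.coding_start)
    premature = True
    if out.stop_found:
        stop_end_gen = int(gmap[3 * (out.stop_codon_index + 1) - 1])
        premature = stop_end_gen != annotated_end
    indels = [l for l in lesions if l.kind in ("deletion", "insertion")]
    net_shift = sum(
        (l.length if l.kind == "insertion" else -l.length) for l in indels
    ) % 3
    expected["net_frame_shift"] = net_shift
    # dyad: intact unless a lesion touched the dyad codons
    his, cys = manifest.dyad
    dyad_ok = True
    for l in lesions:
        off = _exon_cds_offset(old_model, l.exon)
        lo = off + l.position
        hi = lo + (l.length - 1 if l.kind in ("deletion", "substitution") else 0)
        for c in (his, cys):
            if lo <= 3 * c and hi >= 3 * c - 2:
                dyad_ok = False
    expected["dyad_intact"] = dyad_ok
    skip_works = False
    skip_results = {}
    if premature:
        n = len(new_model.exons)
        for e in new_model.coding_exons:
            if e.index in (1, n) or e.index == new_model.start_codon_exon:
                continue
            ok = skip_translation_restores(new_model, new_seq, (e.index,))
            skip_results[e.index] = ok
            skip_works = skip_works or ok
        expected["skip_restores"] = skip_results
        if out.stop_found:
            expected["truncated_length"] = len(out.peptide)
        if len(indels) == 1 and net_shift != 0 and out.stop_found:
            l = indels[0]
            q_d = _exon_cds_offset(old_model, l.exon) + l.position - 1
            if l.kind == "insertion":
                q_d = _exon_cds_offset(old_model, l.exon) + l.position
            disrupted = (q_d + 2) // 3
            expected["codons_downstream_to_stop"] = (
                out.stop_codon_index + 1 - disrupted
            )
    # rescue ORF: earliest ATG after the stop whose reading reaches the
    # annotated terminal stop codon (frame filter implied by the position)
    rescue = None
    if premature and out.stop_found:
        barrier = 3 * (out.stop_codon_index + 1)
        deltas = []
        for l in indels:
            s = _exon_cds_offset(old_model, l.exon) + l.position
            deltas.append((s, l.length if l.kind == "deletion" else -l.length, l.kind))
        for p0 in range(barrier, len(cds) - 2):
            if cds.residues[p0 : p0 + 3] != "ATG":
                continue
            o = translate_cds(cds.residues[p0:], 0, to_first_stop=True)
            if not o.stop_found:
                continue
            if int(gmap[p0 + 3 * (o.stop_codon_index + 1) - 1]) != annotated_end:
                continue
            p_orig = p0
            for s, d, kind in deltas:
                if kind == "deletion" and p0 >= s - 1:
                    p_orig += d
                elif kind == "insertion" and p0 >= s:
                    p_orig += d
            rescue = {
                "cds_pos": p0 + 1,
                "exon": int(eords[p0]),
                "ref_start_residue": p_orig // 3 + 1,
                "orf_length": len(o.peptide),
            }
            break
        expected["rescue"] = rescue
    domain_lo = expected.get("domain_window", [0, 0])[0]
    if not premature and dyad_ok:
        return "intact"
    if (
        premature
        and not skip_works
        and (rescue is None or rescue["ref_start_residue"] > domain_lo)
    ) or not dyad_ok:
        return "pseudogene"
    return "truncated_coding"


# ---------------------------------------------------------------------------
# ortholog divergence
# ---------------------------------------------------------------------------

_OTHER_BASES = {"A": "CGT", "C": "AGT", "G": "ACT", "T": "ACG", "N": "ACG"}


def diverge_orthologs(
    seq: NucSequence,
    p_sub: float,
    p_indel: float = 0.0,
    seed: int = 0,
    protect: Sequence[tuple[int, int]] = (),
) -> tuple[NucSequence, list[IndelEvent], float]:
    """Simulate an ortholog by per-site substitution and indel mutation.

    Substitutions replace a site with one of the three other bases (so the
    expected identity of a substitution-only run is 100*(1 - p_sub)).
    Indels draw lengths 1-3, are kept non-overlapping (a short spacing is
    enforced so every event has a well-defined coordinate) and are recorded
    left-aligned on the original sequence — the same normalization the
    indel caller uses.  ``protect`` intervals (1-based, e.g. dyad codons)
    are never mutated.  Returns (mutated sequence, truth events, expected
    percent identity)."""
    from .pairwise_align import _left_align_deletion, _left_align_insertion

    if not 0.0 <= p_sub <= 0.3:
        raise GeneratorError("p_sub must be within 0-0.3")
    if not 0.0 <= p_indel <= 0.05:
        raise GeneratorError("p_indel must be within 0-0.05")
    rng = np.random.default_rng(seed)
    ref = seq.residues
    n = len(ref)
    protected = np.zeros(n, dtype=bool)
    for lo, hi in protect:
        protected[max(lo - 1, 0) : hi] = True
    sub_r = rng.random(n)
    indel_r = rng.random(n) if p_indel > 0 else np.ones(n)
    len_draw = rng.integers(1, 4, size=n)
    kind_draw = rng.integers(0, 2, size=n)
    pick3 = rng.integers(0, 3, size=n)
    ins_bases = rng.integers(0, 4, size=(n, 3)) if p_indel > 0 else None
    out: list[str] = []
    events: list[IndelEvent] = []
    i = 0
    last_event_end = -10
    while i < n:
        base = ref[i]
        if not protected[i] and sub_r[i] < p_sub:
            base = _OTHER_BASES[ref[i]][pick3[i]]
        out.append(base)
        if (
            p_indel > 0
            and indel_r[i] < p_indel
            and i - last_event_end > 5
            and 2 < i < n - 5
            and not protected[i]
        ):
            L = int(len_draw[i])
            if kind_draw[i] == 0 and i + L < n - 2 and not protected[i + 1 : i + L + 1].any():
                # delete the next L reference bases (1-based i+2 .. i+L+1)
                s = _left_align_deletion(ref, i + 2, L)
                events.append(IndelEvent("deletion", s - 1, L))
                i += L
                last_event_end = i
            elif kind_draw[i] == 1:
                ins = "".join("ACGT"[b] for b in ins_bases[i][:L])
                pos, ins_s = _left_align_insertion(ref, i + 1, ins)
                events.append(IndelEvent("insertion", pos, L, inserted=ins_s))
                out.append(ins)
                last_event_end = i
        i += 1
    mutated = NucSequence(seq.id + "_ortholog", "".join(out), seq.description)
    events.sort(key=lambda e: e.ref_pos)
    return mutated, events, 100.0 * (1.0 - p_sub)


# ---------------------------------------------------------------------------
# scenario writer
# ---------------------------------------------------------------------------


def write_scenario(
    outdir: str | Path,
    seed: int,
    scenario: str = "human-casp16p",
    params: GeneratorParams | None = None,
) -> dict[str, Path]:
    """Generate a locus, apply a lesion scenario, and write everything a
    forensic run needs: query locus FASTA + GFF3, intact ortholog CDS and
    protein FASTA (the pre-lesion gene), and the truth manifest JSON."""
    from .gene_models import extract_cds

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seq, model, manifest = generate_caspase16_like_locus(seed, params)
    ortholog_cds, _, _ = extract_cds(model, seq)
    ortholog_cds = NucSequence("ortholog_cds", ortholog_cds.residues)
    ortholog_protein = PepSequence("ortholog_protein",
                                   manifest.derived_protein.residues)
    lesioned_seq, lesioned_model, manifest = inject_lesions(
        seq, model, manifest, scenario
    )
    paths = {
        "genome": outdir / "query_locus.fasta",
        "gff3": outdir / "query_gene.gff3",
        "ortholog_cds": outdir / "ortholog_cds.fasta",
        "ortholog_protein": outdir / "ortholog_protein.fasta",
        "manifest": outdir / "truth_manifest.json",
    }
    write_fasta([lesioned_seq], paths["genome"])
    write_gff3(lesioned_model, paths["gff3"])
    write_fasta([ortholog_cds], paths["ortholog_cds"])
    write_fasta([ortholog_protein], paths["ortholog_protein"])
    paths["manifest"].write_text(manifest.to_json())
    return paths


# ---------------------------------------------------------------------------
# generic helpers for property suites
# ---------------------------------------------------------------------------


def apply_lesions(
    seq: NucSequence, model: GeneModel, lesions: Sequence[Lesion]
) -> tuple[NucSequence, GeneModel]:
    """Validate and apply explicit lesions to any locus (no truth
    bookkeeping; used for randomized property suites)."""
    for l in lesions:
        if l.kind == "dyad_knockout":
            raise GeneratorError("dyad_knockout needs a manifest; use inject_lesions")
        _validate_lesion(model, l)
    order = sorted(
        range(len(lesions)),
        key=lambda i: model.exon(lesions[i].exon).coding_start + lesions[i].position,
        reverse=True,
    )
    s, m = seq.residues, model
    for i in order:
        s, m = _apply_lesion(s, m, lesions[i])
    return NucSequence(seq.id, s, seq.description), m


def random_gene_model(
    seed: int | np.random.Generator,
    n_exons: int | None = None,
    minus_strand: bool | None = None,
) -> tuple[NucSequence, GeneModel]:
    """A random multi-exon gene with a stop-free reading frame.

    Exon 1 is an untranslated leader; internal coding lengths are drawn
    without regard to codon phase, so junctions fall in all three splicing
    phases.  Models are resampled until no single-exon skip would create a
    stop codon in the chimeric junction codon — the skip frame law concerns
    reading-frame arithmetic, not incidental stop creation, so such loci
    are outside its domain.  Optionally reflected onto the minus strand."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    p = GeneratorParams(intron_min=40, intron_max=120, flank=30, utr5_exon=60,
                        utr5_head=12, utr3_tail=40)
    if n_exons is None:
        n_exons = int(rng.integers(4, 10))
    for _ in range(100):
        lens = [int(rng.integers(31, 181)) for _ in range(n_exons - 1)]
        total = sum(lens)
        lens[-1] += (3 - total % 3) % 3 + 3  # room for the stop codon
        cds_codons = _random_sense_codons(rng, sum(lens) // 3 - 1)
        cds_codons[0] = "ATG"
        cds = _codons_to_str(cds_codons) + "TAA"
        # reject models where a skip junction would form a stop codon
        clean = True
        cum = 0
        for k in range(1, len(lens) - 1):  # internal coding exons (2nd..n-1)
            cum += lens[k - 1]
            after = cum + lens[k]
            ph = cum % 3
            if ph:
                junction = cds[cum - ph : cum] + cds[after : after + 3 - ph]
                if len(junction) == 3 and junction in STOP_CODONS:
                    clean = False
                    break
        if not clean:
            continue
        genome, model = _assemble_locus("RANDGENE", "rand_locus", cds, lens, rng, p)
        if minus_strand is None:
            minus_strand = bool(rng.integers(0, 2))
        if minus_strand:
            genome, model = flip_locus(genome, model)
        return genome, model
    raise GeneratorError("could not sample a clean random gene model")


def flip_locus(seq: NucSequence, model: GeneModel) -> tuple[NucSequence, GeneModel]:
    """Reverse-complement a locus and mirror its gene model onto the other
    strand (the spliced transcript is invariant under this reflection)."""
    n = len(seq)
    flipped = tuple(
        Exon(
            e.index,
            n - e.genomic_end + 1,
            n - e.genomic_start + 1,
            None if e.coding_end is None else n - e.coding_end + 1,
            None if e.coding_start is None else n - e.coding_start + 1,
        )
        for e in model.exons
    )
    new_strand = "-" if model.strand == "+" else "+"
    return (
        seq.reverse_complement(),
        GeneModel(model.gene_id, model.seq_id, new_strand, flipped,
                  model.start_codon_exon),
    )
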