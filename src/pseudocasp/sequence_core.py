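"""Sequence containers, FASTA I/O and conceptual translation with frame tracking.

Conventions used across the package
-----------------------------------
* Internal coordinates are 0-based half-open; everything file-facing or
  report-facing is 1-based inclusive (GenBank/GFF3 convention).
* Nucleotide alphabet is ``{A, C, G, T, N}`` (uppercase canonical, ``U``
  mapped to ``T`` on input).  Ambiguity codes other than ``N`` are rejected
  at parse time so that conceptual translation stays deterministic.
* Translation uses the standard genetic code (NCBI table 1) only; the genes
  in scope are nuclear.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal

from Bio import SeqIO
from Bio.Data.CodonTable import unambiguous_dna_by_id
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger("pseudocasp")

NUC_ALPHABET = frozenset("ACGTN")
AA_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWY" + "X*")

_TABLE1 = unambiguous_dna_by_id[1]
#: codon -> one-letter amino acid, standard genetic code
CODON_TABLE: dict[str, str] = dict(_TABLE1.forward_table)
STOP_CODONS: frozenset[str] = frozenset(_TABLE1.stop_codons)  # TAA, TAG, TGA

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class SequenceError(ValueError):
    """Raised for malformed sequences or malformed FASTA records."""


@dataclass(frozen=True)
class NucSequence:
    """A nucleotide sequence over ``{A,C,G,T,N}`` with a FASTA-style id."""

    id: str
    residues: str
    description: str | None = None

    def __post_init__(self) -> None:
        bad = set(self.residues) - NUC_ALPHABET
        if bad:
            pos = next(i for i, c in enumerate(self.residues) if c in bad)
            raise SequenceError(
                f"illegal nucleotide {self.residues[pos]!r} in record "
                f"{self.id!r} at position {pos + 1}"
            )

    def __len__(self) -> int:
        return len(self.residues)

    def reverse_complement(self) -> "NucSequence":
        return NucSequence(
            self.id, self.residues.translate(_COMPLEMENT)[::-1], self.description
        )


@dataclass(frozen=True)
class PepSequence:
    """A protein sequence over the 20 amino acids plus ``X`` and ``*``.

    When produced by translation-to-stop, ``*`` may occur at most once and
    only terminally; frame-corrected conceptual translations replace internal
    stops by ``X`` to preserve that invariant.
    """

    id: str
    residues: str
    description: str | None = None

    def __post_init__(self) -> None:
        bad = set(self.residues) - AA_ALPHABET
        if bad:
            pos = next(i for i, c in enumerate(self.residues) if c in bad)
            raise SequenceError(
                f"illegal amino acid {self.residues[pos]!r} in record "
                f"{self.id!r} at position {pos + 1}"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class TranslationOutcome:
    """Result of conceptual translation of a nucleotide window.

    Satisfies the translation length law ``3 * (len(peptide) + stop_found)
    + trailing_nt == translated_nt`` where ``translated_nt`` is the number
    of nucleotides consumed (up to and including the stop codon when
    translation stops there).
    """

    peptide: PepSequence
    stop_found: bool
    stop_codon_index: int | None  # 0-based codon ordinal of the stop
    trailing_nt: int  # 0-2 nucleotides after the last complete codon

    @property
    def translated_nt(self) -> int:
        return 3 * (len(self.peptide) + int(self.stop_found)) + self.trailing_nt


def _normalize_nuc(raw: str, rec_id: str) -> str:
    s = raw.upper().replace("U", "T")
    bad = set(s) - NUC_ALPHABET
    if bad:
        pos = next(i for i, c in enumerate(s) if c in bad)
        raise SequenceError(
            f"illegal residue {s[pos]!r} in nucleotide record {rec_id!r} "
            f"at position {pos + 1} (ambiguity codes other than N are not supported)"
        )
    return s


def _normalize_pep(raw: str, rec_id: str) -> str:
    s = raw.upper()
    bad = set(s) - AA_ALPHABET
    if bad:
        pos = next(i for i, c in enumerate(s) if c in bad)
        raise SequenceError(
            f"illegal residue {s[pos]!r} in protein record {rec_id!r} at position {pos + 1}"
        )
    return s


def parse_fasta(
    path: str | Path, alphabet: Literal["nucleotide", "protein"]
) -> list[NucSequence] | list[PepSequence]:
    """Read a multi-record FASTA file.

    Residues are uppercased; for the nucleotide alphabet ``U`` is mapped to
    ``T``.  Record order is preserved.  An empty file yields an empty list
    with a warning; an illegal residue raises :class:`SequenceError` naming
    the record and position.
    """
    path = Path(path)
    if alphabet not in ("nucleotide", "protein"):
        raise ValueError(f"unknown alphabet {alphabet!r}")
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        warnings.warn(f"FASTA file {path} contains no records", stacklevel=2)
        return []
    out: list = []
    for rec in records:
        desc = rec.description[len(rec.id):].strip() or None
        raw = str(rec.seq)
        if alphabet == "nucleotide":
            out.append(NucSequence(rec.id, _normalize_nuc(raw, rec.id), desc))
        else:
            out.append(PepSequence(rec.id, _normalize_pep(raw, rec.id), desc))
    return out


def write_fasta(
    seqs: Iterable[NucSequence | PepSequence], path: str | Path, width: int = 60
) -> None:
    """Write sequences as multi-record FASTA, wrapped at ``width`` columns."""
    path = Path(path)
    records = []
    for s in seqs:
        name = s.id if s.description is None else f"{s.id} {s.description}"
        records.append(SeqRecord(Seq(s.residues), id=s.id, description=name[len(s.id):].strip()))
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


def translate_codon(codon: str) -> str:
    """Translate one triplet; any codon containing ``N`` becomes ``X``,
    stop codons become ``*``."""
    if "N" in codon:
        return "X"
    if codon in STOP_CODONS:
        return "*"
    return CODON_TABLE[codon]


def translate_cds(
    seq: NucSequence | str,
    offset: int = 0,
    to_first_stop: bool = True,
    peptide_id: str | None = None,
) -> TranslationOutcome:
    """Conceptually translate ``seq`` reading codons from ``offset``.

    With ``to_first_stop`` (the default) the peptide ends before the first
    stop codon, ``stop_codon_index`` records its 0-based codon ordinal and
    no nucleotide past the stop is consumed; if no stop occurs before the
    sequence end, ``stop_found`` is False.  Without ``to_first_stop`` every
    complete codon in the window is translated: internal stops become ``*``
    residues in the peptide and only a stop that is the *final* complete
    codon is reported via ``stop_found``/``stop_codon_index``.  Codons
    containing ``N`` translate to ``X`` in either mode.
    """
    residues = seq.residues if isinstance(seq, NucSequence) else seq
    if offset not in (0, 1, 2):
        raise ValueError(f"offset must be 0, 1 or 2, got {offset}")
    if offset >= len(residues) and residues:
        raise ValueError(f"offset {offset} beyond sequence of length {len(residues)}")
    window = residues[offset:]
    n_codons = len(window) // 3
    trailing = len(window) - 3 * n_codons
    aa: list[str] = []
    stop_found = False
    stop_index: int | None = None
    for k in range(n_codons):
        codon = window[3 * k : 3 * k + 3]
        r = translate_codon(codon)
        if r == "*":
            if to_first_stop:
                stop_found = True
                stop_index = k
                trailing = 0
                break
            if k == n_codons - 1:
                stop_found = True
                stop_index = k
            else:
                aa.append("*")
        else:
            aa.append(r)
    pid = peptide_id or (seq.id + "_pep" if isinstance(seq, NucSequence) else "pep")
    peptide = PepSequence(pid, "".join(aa))
    return TranslationOutcome(peptide, stop_found, stop_index, trailing)


def reverse_complement(residues: str) -> str:
    """Reverse complement of a raw nucleotide string."""
    return residues.translate(_COMPLEMENT)[::-1]
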