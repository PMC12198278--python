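"""From-scratch global and local pairwise alignment with affine gap costs.

Needleman–Wunsch / Smith–Waterman with the Gotoh three-state recursion.
A gap of length L costs ``gap_open + (L - 1) * gap_extend``; sequences are
scored either by match/mismatch (nucleotide) or a named protein substitution
matrix (BLOSUM62 by default).  Default scoring mirrors the conventions of
the common search/alignment tools: nucleotide +2/−3 with gaps 5/2, protein
BLOSUM62 with gaps 11/1.

The dynamic-programming fill runs as a numba kernel; traceback is done in
Python by re-deriving each predecessor (deterministic tie-break: diagonal,
then gap-in-b, then gap-in-a).  Scores with integer-valued parameters are
exact in the float matrices used.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Literal, Sequence

import numpy as np
from Bio.Align import substitution_matrices
from numba import njit

from .sequence_core import NucSequence, PepSequence

NEG = -1e30

__all__ = [
    "AlignmentParams",
    "AlignmentResult",
    "IndelEvent",
    "global_align",
    "local_align",
    "percent_identity",
    "call_indels",
    "score_alignment",
]


@dataclass(frozen=True)
class AlignmentParams:
    """Scoring parameters for pairwise alignment.

    ``substitution_matrix`` (a named protein matrix, e.g. ``"BLOSUM62"``)
    overrides ``match``/``mismatch`` when set.
    """

    match: float = 2.0
    mismatch: float = -3.0
    substitution_matrix: str | None = None
    gap_open: float = 5.0
    gap_extend: float = 2.0
    mode: Literal["global", "local"] = "global"

    def __post_init__(self) -> None:
        if not (self.gap_open >= self.gap_extend >= 0):
            raise ValueError(
                f"require gap_open >= gap_extend >= 0, got {self.gap_open}/{self.gap_extend}"
            )
        if self.mode not in ("global", "local"):
            raise ValueError(f"unknown mode {self.mode!r}")

    @staticmethod
    def nucleotide(**kw) -> "AlignmentParams":
        return AlignmentParams(**kw)

    @staticmethod
    def protein(**kw) -> "AlignmentParams":
        kw.setdefault("substitution_matrix", "BLOSUM62")
        kw.setdefault("gap_open", 11.0)
        kw.setdefault("gap_extend", 1.0)
        return AlignmentParams(**kw)


@dataclass(frozen=True)
class AlignmentResult:
    """A pairwise alignment with gapped strings and 1-based span coordinates.

    ``column_map`` gives, per alignment column, the 1-based position in each
    sequence or ``None`` where that sequence has a gap.  The score is
    recomputable from the columns and the parameters
    (:func:`score_alignment`).
    """

    aligned_a: str
    aligned_b: str
    score: float
    a_start: int
    a_end: int
    b_start: int
    b_end: int
    a_len: int
    b_len: int
    mode: Literal["global", "local"]
    params: AlignmentParams

    @property
    def column_map(self) -> list[tuple[int | None, int | None]]:
        out = []
        pa, pb = self.a_start - 1, self.b_start - 1
        for ca, cb in zip(self.aligned_a, self.aligned_b):
            ia = ib = None
            if ca != "-":
                pa += 1
                ia = pa
            if cb != "-":
                pb += 1
                ib = pb
            out.append((ia, ib))
        return out

    @property
    def n_columns(self) -> int:
        return len(self.aligned_a)


@dataclass(frozen=True)
class IndelEvent:
    """One insertion/deletion relative to the designated reference.

    ``ref_pos`` is the 1-based reference position *after which* the event
    occurs (0 for an event before the first base), left-aligned within
    repeat runs.  ``deletion`` means the non-reference sequence lacks bases
    that the reference has; ``insertion`` means it carries extra bases.
    """

    kind: Literal["insertion", "deletion"]
    ref_pos: int
    length: int
    frame_shift: int = field(init=False)
    inserted: str = ""

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError("indel length must be >= 1")
        object.__setattr__(self, "frame_shift", self.length % 3)


# ---------------------------------------------------------------------------
# scoring matrices and sequence encoding
# ---------------------------------------------------------------------------

_NUC_ALPHA = "ACGTN"


@lru_cache(maxsize=8)
def _named_matrix(name: str) -> tuple[str, np.ndarray]:
    mat = substitution_matrices.load(name)
    alpha = "".join(mat.alphabet)
    return alpha, np.asarray(mat, dtype=np.float64)


def _score_matrix(params: AlignmentParams) -> tuple[str, np.ndarray]:
    if params.substitution_matrix is not None:
        return _named_matrix(params.substitution_matrix)
    n = len(_NUC_ALPHA)
    s = np.full((n, n), params.mismatch, dtype=np.float64)
    np.fill_diagonal(s, params.match)
    n_idx = _NUC_ALPHA.index("N")
    s[n_idx, :] = params.mismatch  # N never counts as a match
    s[:, n_idx] = params.mismatch
    return _NUC_ALPHA, s


def _encode(residues: str, alphabet: str) -> np.ndarray:
    lut = np.full(128, -1, dtype=np.int16)
    for i, c in enumerate(alphabet):
        lut[ord(c)] = i
    codes = lut[np.frombuffer(residues.encode("ascii"), dtype=np.uint8)]
    if (codes < 0).any():
        bad = residues[int(np.argmax(codes < 0))]
        raise ValueError(f"residue {bad!r} not covered by scoring alphabet {alphabet!r}")
    return codes.astype(np.int16)


def _residues(seq) -> str:
    if isinstance(seq, (NucSequence, PepSequence)):
        return seq.residues
    return str(seq)


# ---------------------------------------------------------------------------
# DP fill (numba) and traceback
# ---------------------------------------------------------------------------


@njit(cache=True)
def _fill(a, b, S, gap_open, gap_extend, local, diag_min, row_block, col_block, neg):
    """Gotoh three-state fill.  State M: a[i-1] aligned to b[j-1]; state X:
    gap in b (consumes a); state Y: gap in a (consumes b).

    ``diag_min`` > 0 restricts to cells with j - i >= diag_min (used for
    self-comparison); ``row_block``/``col_block`` exclude residues from any
    path (used for iterative hit discovery).  ``neg`` sets the matrix dtype
    (float32 for very large problems, float64 otherwise)."""
    n, m = a.shape[0], b.shape[0]
    M = np.full((n + 1, m + 1), neg)
    X = np.full((n + 1, m + 1), neg)
    Y = np.full((n + 1, m + 1), neg)
    M[0, 0] = 0.0
    if not local:
        for i in range(1, n + 1):
            X[i, 0] = -(gap_open + (i - 1) * gap_extend)
        for j in range(1, m + 1):
            Y[0, j] = -(gap_open + (j - 1) * gap_extend)
    else:
        for i in range(1, n + 1):
            M[i, 0] = 0.0
        for j in range(1, m + 1):
            M[0, j] = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            if diag_min > 0 and (j - i) < diag_min:
                continue
            if row_block[i - 1] or col_block[j - 1]:
                continue
            s = S[a[i - 1], b[j - 1]]
            best = M[i - 1, j - 1]
            if X[i - 1, j - 1] > best:
                best = X[i - 1, j - 1]
            if Y[i - 1, j - 1] > best:
                best = Y[i - 1, j - 1]
            if local and best < 0.0:
                best = 0.0
            if best > neg / 2:
                M[i, j] = best + s
            bx = M[i - 1, j] - gap_open
            if X[i - 1, j] - gap_extend > bx:
                bx = X[i - 1, j] - gap_extend
            if Y[i - 1, j] - gap_open > bx:
                bx = Y[i - 1, j] - gap_open
            if bx > neg / 2:
                X[i, j] = bx
            by = M[i, j - 1] - gap_open
            if X[i, j - 1] - gap_open > by:
                by = X[i, j - 1] - gap_open
            if Y[i, j - 1] - gap_extend > by:
                by = Y[i, j - 1] - gap_extend
            if by > neg / 2:
                Y[i, j] = by
    return M, X, Y


_EPS = 1e-6


def _argmax3(m_val: float, x_val: float, y_val: float) -> int:
    """Index of the max with tie-break order M (diagonal), X (gap-in-b),
    Y (gap-in-a)."""
    best, idx = m_val, 0
    if x_val > best + _EPS:
        best, idx = x_val, 1
    if y_val > best + _EPS:
        best, idx = y_val, 2
    return idx


def _match3(m_val: float, x_val: float, y_val: float, target: float) -> int:
    if abs(m_val - target) < _EPS:
        return 0
    if abs(x_val - target) < _EPS:
        return 1
    if abs(y_val - target) < _EPS:
        return 2
    raise AssertionError("traceback lost the optimal path")


def _traceback(a, b, ac, bc, S, params, M, X, Y, i, j, state, local):
    """Walk the Gotoh matrices back from cell (i, j) in ``state``.

    For global alignments the walk ends at (0, 0); for local alignments it
    ends where the running score restarted from zero.  Returns the gapped
    strings plus the 1-based start coordinates of the aligned spans.
    """
    cols_a: list[str] = []
    cols_b: list[str] = []
    go, ge = params.gap_open, params.gap_extend
    while i > 0 or j > 0:
        if state == 0:
            s = S[ac[i - 1], bc[j - 1]]
            prev = M[i, j] - s
            cols_a.append(a[i - 1])
            cols_b.append(b[j - 1])
            i, j = i - 1, j - 1
            if local and prev < _EPS:
                break  # the path restarted from 0 here
            if i == 0 and j == 0:
                break
            state = _match3(M[i, j], X[i, j], Y[i, j], prev)
        elif state == 1:  # gap in b, consumes a[i-1]
            v = X[i, j]
            cols_a.append(a[i - 1])
            cols_b.append("-")
            i -= 1
            if i == 0 and j == 0:
                break
            state = _match3(M[i, j] - go, X[i, j] - ge, Y[i, j] - go, v)
        else:  # gap in a, consumes b[j-1]
            v = Y[i, j]
            cols_a.append("-")
            cols_b.append(b[j - 1])
            j -= 1
            if i == 0 and j == 0:
                break
            state = _match3(M[i, j] - go, X[i, j] - go, Y[i, j] - ge, v)
    return "".join(reversed(cols_a)), "".join(reversed(cols_b)), i + 1, j + 1


def _dtype_for(n: int, m: int):
    return np.float64 if (n + 1) * (m + 1) <= 16_000_000 else np.float32


def _run_fill(a: str, b: str, params: AlignmentParams, local: bool,
              diag_min: int = 0, row_block=None, col_block=None):
    alpha, S = _score_matrix(params)
    ac, bc = _encode(a, alpha), _encode(b, alpha)
    dt = _dtype_for(len(a), len(b))
    if row_block is None:
        row_block = np.zeros(len(a), dtype=np.uint8)
    if col_block is None:
        col_block = np.zeros(len(b), dtype=np.uint8)
    M, X, Y = _fill(ac, bc, S.astype(dt), dt(params.gap_open), dt(params.gap_extend),
                    local, diag_min, row_block, col_block, dt(NEG))
    return ac, bc, S, M, X, Y


def global_align(a, b, params: AlignmentParams | None = None) -> AlignmentResult:
    """Optimal global (Needleman–Wunsch style) alignment under affine gaps.

    Traceback is deterministic with tie-break order diagonal, gap-in-b,
    gap-in-a.  Raises ``ValueError`` on empty input.
    """
    a, b = _residues(a), _residues(b)
    if not a or not b:
        raise ValueError("cannot globally align empty sequences")
    params = params or AlignmentParams()
    ac, bc, S, M, X, Y = _run_fill(a, b, params, local=False)
    n, m = len(a), len(b)
    state = _argmax3(M[n, m], X[n, m], Y[n, m])
    score = float((M[n, m], X[n, m], Y[n, m])[state])
    ga, gb, _, _ = _traceback(a, b, ac, bc, S, params, M, X, Y, n, m, state, local=False)
    return AlignmentResult(ga, gb, score, 1, n, 1, m, n, m, "global", params)


def local_align(a, b, params: AlignmentParams | None = None) -> AlignmentResult:
    """Optimal local (Smith–Waterman style) alignment under affine gaps.

    Returns an empty alignment with score 0 (spans (0, 0)) when nothing
    scores positively.
    """
    a, b = _residues(a), _residues(b)
    if not a or not b:
        raise ValueError("cannot locally align empty sequences")
    params = params or AlignmentParams()
    ac, bc, S, M, X, Y = _run_fill(a, b, params, local=True)
    core = M[1:, 1:]
    flat = int(np.argmax(core))
    bi, bj = divmod(flat, core.shape[1])
    best = float(core[bi, bj])
    n, m = len(a), len(b)
    if best <= 0:
        return AlignmentResult("", "", 0.0, 0, 0, 0, 0, n, m, "local", params)
    ga, gb, sa, sb = _traceback(a, b, ac, bc, S, params, M, X, Y, bi + 1, bj + 1, 0, local=True)
    return AlignmentResult(ga, gb, best, sa, bi + 1, sb, bj + 1, n, m, "local", params)


def score_alignment(aligned_a: str, aligned_b: str, params: AlignmentParams) -> float:
    """Recompute an alignment score from its gapped columns (gap of length L
    costs ``gap_open + (L-1) * gap_extend``, maximal runs per sequence)."""
    alpha, S = _score_matrix(params)
    score = 0.0
    in_gap_a = in_gap_b = False
    for ca, cb in zip(aligned_a, aligned_b):
        if ca == "-" and cb == "-":
            raise ValueError("column with gaps in both sequences")
        if ca == "-":
            score -= params.gap_extend if in_gap_a else params.gap_open
            in_gap_a, in_gap_b = True, False
        elif cb == "-":
            score -= params.gap_extend if in_gap_b else params.gap_open
            in_gap_a, in_gap_b = False, True
        else:
            score += S[alpha.index(ca), alpha.index(cb)]
            in_gap_a = in_gap_b = False
    return score


def percent_identity(aln: AlignmentResult,
                     denominator: str = "columns") -> float:
    """100 x identical columns / denominator.

    ``denominator`` is ``"columns"`` (alignment columns, the default) or
    ``"shorter_sequence"`` (the shorter of the two full sequences).  Gap
    columns never count as identical.
    """
    if aln.n_columns == 0:
        raise ValueError("percent identity undefined for an empty alignment")
    ident = sum(1 for ca, cb in zip(aln.aligned_a, aln.aligned_b)
                if ca != "-" and ca == cb)
    if denominator == "columns":
        denom = aln.n_columns
    elif denominator == "shorter_sequence":
        denom = min(aln.a_len, aln.b_len)
    else:
        raise ValueError(f"unknown denominator {denominator!r}")
    return 100.0 * ident / denom


def _left_align_deletion(ref: str, start: int, length: int) -> int:
    """Shift a deletion of ref[start-1 : start-1+length] left through repeat
    runs; returns the new (1-based) start."""
    while start > 1 and ref[start - 2] == ref[start + length - 2]:
        start -= 1
    return start


def _left_align_insertion(ref: str, pos: int, ins: str) -> tuple[int, str]:
    """Shift an insertion occurring after 1-based ref position ``pos`` left
    through repeat runs; returns the new position and (rotated) string."""
    while pos >= 1 and ref[pos - 1] == ins[-1]:
        ins = ref[pos - 1] + ins[:-1]
        pos -= 1
    return pos, ins


def call_indels(aln: AlignmentResult, reference: str = "a") -> list[IndelEvent]:
    """Call insertion/deletion events from a global alignment.

    Maximal runs of gap columns become single events, positioned on the
    designated reference (``"a"`` or ``"b"``) and left-aligned within
    repeat/homopolymer runs.  Raises on local alignments (incomplete
    coverage would truncate events).
    """
    if aln.mode == "local":
        raise ValueError("indel calling requires a global alignment")
    if reference not in ("a", "b"):
        raise ValueError(f"reference must be 'a' or 'b', got {reference!r}")
    ref_str, other_str = ((aln.aligned_a, aln.aligned_b) if reference == "a"
                          else (aln.aligned_b, aln.aligned_a))
    ref_seq = ref_str.replace("-", "")
    events: list[IndelEvent] = []
    ref_pos = 0  # last consumed reference position
    k = 0
    ncol = len(ref_str)
    while k < ncol:
        if ref_str[k] != "-" and other_str[k] != "-":
            ref_pos += 1
            k += 1
        elif other_str[k] == "-":  # reference bases absent from the other seq
            start = ref_pos + 1
            length = 0
            while k < ncol and other_str[k] == "-":
                ref_pos += 1
                length += 1
                k += 1
            new_start = _left_align_deletion(ref_seq, start, length)
            events.append(IndelEvent("deletion", new_start - 1, length))
        else:  # gap in the reference: extra bases in the other sequence
            ins = []
            while k < ncol and ref_str[k] == "-":
                ins.append(other_str[k])
                k += 1
            pos, ins_s = _left_align_insertion(ref_seq, ref_pos, "".join(ins))
            events.append(IndelEvent("insertion", pos, len(ins_s), inserted=ins_s))
    events.sort(key=lambda e: (e.ref_pos, 0 if e.kind == "deletion" else 1))
    return events


def self_local_align(a, params: AlignmentParams | None = None,
                     diag_min: int = 1,
                     row_block: np.ndarray | None = None,
                     col_block: np.ndarray | None = None) -> AlignmentResult:
    """Best local alignment of a sequence against itself restricted to the
    strict upper triangle (column index at least ``diag_min`` ahead of the
    row index), excluding the trivial self-diagonal.  ``row_block`` /
    ``col_block`` exclude already-claimed residues when hits are harvested
    iteratively."""
    a = _residues(a)
    if not a:
        raise ValueError("cannot self-align an empty sequence")
    params = params or AlignmentParams.protein(mode="local")
    ac, bc, S, M, X, Y = _run_fill(a, a, params, local=True, diag_min=diag_min,
                                   row_block=row_block, col_block=col_block)
    core = M[1:, 1:]
    flat = int(np.argmax(core))
    bi, bj = divmod(flat, core.shape[1])
    best = float(core[bi, bj])
    n = len(a)
    if best <= 0:
        return AlignmentResult("", "", 0.0, 0, 0, 0, 0, n, n, "local", params)
    ga, gb, sa, sb = _traceback(a, a, ac, bc, S, params, M, X, Y,
                                bi + 1, bj + 1, 0, local=True)
    return AlignmentResult(ga, gb, best, sa, bi + 1, sb, bj + 1, n, n, "local", params)


def best_self_local_score(a, params: AlignmentParams | None = None,
                          diag_min: int = 1) -> float:
    """Score of the best strict-upper-triangle local self-alignment (the
    permutation-test statistic; no traceback)."""
    a = _residues(a)
    params = params or AlignmentParams.protein(mode="local")
    _, _, _, M, _, _ = _run_fill(a, a, params, local=True, diag_min=diag_min)
    return max(0.0, float(M[1:, 1:].max()))


def format_alignment(aln: AlignmentResult, width: int = 60) -> str:
    """Human-readable alignment text: gapped sequence pair with a
    per-column markup line (``|`` identity, ``.`` mismatch, space gap)."""
    marks = "".join(
        "|" if ca == cb and ca != "-" else (" " if "-" in (ca, cb) else ".")
        for ca, cb in zip(aln.aligned_a, aln.aligned_b)
    )
    lines = []
    for k in range(0, aln.n_columns, width):
        lines.append(aln.aligned_a[k : k + width])
        lines.append(marks[k : k + width])
        lines.append(aln.aligned_b[k : k + width])
        lines.append("")
    header = (f"# score {aln.score:g}  a:{aln.a_start}-{aln.a_end}"
              f"  b:{aln.b_start}-{aln.b_end}  mode {aln.mode}")
    return "\n".join([header] + lines).rstrip() + "\n"


def indels_to_table(events: Sequence[IndelEvent]):
    """Tabular indel report (kind, ref_pos, length, frame_shift)."""
    import pandas as pd

    return pd.DataFrame(
        {
            "kind": [e.kind for e in events],
            "ref_pos": [e.ref_pos for e in events],
            "length": [e.length for e in events],
            "frame_shift": [e.frame_shift for e in events],
        }
    )
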