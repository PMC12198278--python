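"""Independent brute-force oracles used by the test suite.

The alignment oracles enumerate *all* monotone alignments (as move strings:
diagonal / gap-in-b / gap-in-a) and score them directly from the columns,
sharing no code with the dynamic-programming implementation.  Affine gap
runs cost ``open + (len - 1) * extend`` per maximal run, the same cost model
the package documents.
"""

from __future__ import annotations

from functools import lru_cache
from itertools import product

import numpy as np


@lru_cache(maxsize=None)
def _patterns(m: int, n: int) -> list[tuple[float, tuple[tuple[int, int], ...]]]:
    """All global alignment patterns for lengths (m, n), each as
    (gap_cost_in_open_units, diagonal cells).  Gap cost is returned as a
    pair (n_opens, n_extends) folded into a tuple for later scaling."""
    out = []

    def rec(i, j, moves):
        if i == m and j == n:
            opens = extends = 0
            diag = []
            ai = bj = 0
            prev = ""
            for mv in moves:
                if mv == "D":
                    ai += 1
                    bj += 1
                    diag.append((ai, bj))
                elif mv == "U":
                    ai += 1
                    if prev == "U":
                        extends += 1
                    else:
                        opens += 1
                else:
                    bj += 1
                    if prev == "L":
                        extends += 1
                    else:
                        opens += 1
                prev = mv
            out.append((opens, extends, tuple(diag)))
            return
        if i < m and j < n:
            rec(i + 1, j + 1, moves + "D")
        if i < m:
            rec(i + 1, j, moves + "U")
        if j < n:
            rec(i, j + 1, moves + "L")

    rec(0, 0, "")
    return out


def brute_global_scores(m: int, n: int, match: float, mismatch: float,
                        gap_open: float, gap_extend: float,
                        alphabet: str = "AC") -> dict[tuple[str, str], float]:
    """Optimal global score for every sequence pair of lengths (m, n) over
    the alphabet, by exhaustive enumeration of alignments."""
    seqs_a = ["".join(t) for t in product(alphabet, repeat=m)]
    seqs_b = ["".join(t) for t in product(alphabet, repeat=n)]
    A = np.array([[c for c in s] for s in seqs_a])
    B = np.array([[c for c in s] for s in seqs_b])
    best = np.full((len(seqs_a), len(seqs_b)), -np.inf)
    for opens, extends, diag in _patterns(m, n):
        gap_cost = opens * gap_open + extends * gap_extend
        score = np.full((len(seqs_a), len(seqs_b)), -gap_cost)
        for (ai, bj) in diag:
            eq = A[:, ai - 1][:, None] == B[:, bj - 1][None, :]
            score += np.where(eq, match, mismatch)
        np.maximum(best, score, out=best)
    return {
        (sa, sb): float(best[i, j])
        for i, sa in enumerate(seqs_a)
        for j, sb in enumerate(seqs_b)
    }


def brute_local_score(a: str, b: str, match: float, mismatch: float,
                      gap_open: float, gap_extend: float) -> float:
    """Optimal local score for one pair: max over all substring pairs and
    all alignments between them (empty alignment scores 0)."""
    best = 0.0
    m, n = len(a), len(b)
    for p in range(1, m + 1):
        for q in range(1, n + 1):
            pats = _patterns(p, q)
            for i0 in range(m - p + 1):
                for j0 in range(n - q + 1):
                    for opens, extends, diag in pats:
                        s = -(opens * gap_open + extends * gap_extend)
                        for (ai, bj) in diag:
                            s += match if a[i0 + ai - 1] == b[j0 + bj - 1] else mismatch
                        if s > best:
                            best = s
    return best


def brute_local_scores_all(m: int, n: int, match: float, mismatch: float,
                           gap_open: float, gap_extend: float,
                           alphabet: str = "AC") -> dict[tuple[str, str], float]:
    """Optimal local score for every pair of lengths (m, n), vectorised over
    the sequence space (same enumeration as :func:`brute_local_score`)."""
    seqs_a = ["".join(t) for t in product(alphabet, repeat=m)]
    seqs_b = ["".join(t) for t in product(alphabet, repeat=n)]
    A = np.array([[c for c in s] for s in seqs_a])
    B = np.array([[c for c in s] for s in seqs_b])
    best = np.zeros((len(seqs_a), len(seqs_b)))
    for p in range(1, m + 1):
        for q in range(1, n + 1):
            for opens, extends, diag in _patterns(p, q):
                gap_cost = opens * gap_open + extends * gap_extend
                for i0 in range(m - p + 1):
                    for j0 in range(n - q + 1):
                        score = np.full((len(seqs_a), len(seqs_b)), -gap_cost)
                        for (ai, bj) in diag:
                            eq = A[:, i0 + ai - 1][:, None] == B[:, j0 + bj - 1][None, :]
                            score += np.where(eq, match, mismatch)
                        np.maximum(best, score, out=best)
    return {
        (sa, sb): float(best[i, j])
        for i, sa in enumerate(seqs_a)
        for j, sb in enumerate(seqs_b)
    }


def cumsum_mod3_phases(coding_lengths: list[int]) -> list[int]:
    """Independent splice-phase oracle: cumulative sum mod 3 after each
    element except the last."""
    out = []
    cum = 0
    for ln in coding_lengths[:-1]:
        cum += ln
        out.append(cum % 3)
    return out
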