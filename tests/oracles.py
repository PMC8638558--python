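"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's dynamic programmes: structures are
enumerated exhaustively and alignments enumerated recursively, so agreement
with the O(n^3)/O(nm) implementations is a genuine cross-check.
"""

from __future__ import annotations

from functools import lru_cache
from typing import List, Optional, Tuple

import numpy as np

_PAIR_E = {("G", "C"): -3.0, ("C", "G"): -3.0,
           ("A", "U"): -2.0, ("U", "A"): -2.0,
           ("G", "U"): -1.0, ("U", "G"): -1.0}


def enumerate_structures(seq: str, min_hairpin: int = 3) -> List[frozenset]:
    """All pseudoknot-free structures over canonical pairs."""

    @lru_cache(maxsize=None)
    def rec(i: int, j: int) -> Tuple[frozenset, ...]:
        if i >= j:
            return (frozenset(),)
        out = list(rec(i + 1, j))
        for k in range(i + min_hairpin + 1, j + 1):
            if (seq[i], seq[k]) in _PAIR_E:
                for left in rec(i + 1, k - 1):
                    for right in rec(k + 1, j):
                        out.append(left | right | {(i, k)})
        return tuple(out)

    return list(rec(0, len(seq) - 1))


def brute_force_ensemble(
    seq: str,
    kT: float = 0.6,
    reactivity: Optional[np.ndarray] = None,
    m: float = 1.8,
    b: float = -0.6,
    min_hairpin: int = 3,
) -> Tuple[np.ndarray, float, float]:
    """(bpp, mfe, Z) by full enumeration with Boltzmann weighting."""
    n = len(seq)
    g = np.zeros(n)
    if reactivity is not None:
        react = np.asarray(reactivity, dtype=float)
        ok = ~np.isnan(react)
        g[ok] = m * np.log(react[ok] + 1.0) + b
    structures = enumerate_structures(seq, min_hairpin)
    weights = []
    energies = []
    for s in structures:
        e = sum(_PAIR_E[(seq[i], seq[j])] + g[i] + g[j] for i, j in s)
        energies.append(e)
        weights.append(np.exp(-e / kT))
    weights = np.asarray(weights)
    Z = float(weights.sum())
    bpp = np.zeros(n)
    for s, w in zip(structures, weights):
        for i, j in s:
            bpp[i] += w
            bpp[j] += w
    return bpp / Z, float(min(energies)), Z


def brute_force_alignment_score(
    a: str, b: str,
    match: float = 1.0, mismatch: float = -1.0,
    gap_open: float = -4.0, gap_extend: float = -1.0,
) -> float:
    """Best global affine-gap score by exhaustive recursion (small inputs).

    The first gapped column of a run costs ``gap_open``; each further column
    of the same run costs ``gap_extend``.
    """

    @lru_cache(maxsize=None)
    def rec(i: int, j: int, state: str) -> float:
        if i == len(a) and j == len(b):
            return 0.0
        best = -np.inf
        if i < len(a) and j < len(b):
            s = match if a[i] == b[j] else mismatch
            best = max(best, s + rec(i + 1, j + 1, "m"))
        if i < len(a):  # gap in b
            cost = gap_extend if state == "x" else gap_open
            best = max(best, cost + rec(i + 1, j, "x"))
        if j < len(b):  # gap in a
            cost = gap_extend if state == "y" else gap_open
            best = max(best, cost + rec(i, j + 1, "y"))
        return best

    return float(rec(0, 0, "m"))
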