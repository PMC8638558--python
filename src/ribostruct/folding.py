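"""SHAPE-directed RNA secondary-structure prediction.

The ensemble is the set of all pseudoknot-free structures over canonical
pairs {GC, AU, GU} with a minimum hairpin loop. The energy of a structure is
the sum of per-pair energies plus, for every paired nucleotide, a SHAPE
pseudo-energy of the Deigan form ``m*ln(reactivity+1) + b``. Base-pairing
probabilities come from an exact inside-outside (McCaskill-style) dynamic
programme over this pair-additive model; the simplified model keeps the
exhaustive-enumeration oracle exact and desk-runnable, and the BPP/PPV
analyses built on top of it are engine-agnostic.

Boltzmann weights use per-base rescaling (anchored at the MFE) so that
partition values stay inside double range for window-sized inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, Optional, Tuple

import numpy as np

from .types import ReactivityProfile, StructureResult, TranscriptRecord
from .io import pairs_to_dotbracket

_CANONICAL = {("G", "C"): "GC", ("C", "G"): "GC",
              ("A", "U"): "AU", ("U", "A"): "AU",
              ("G", "U"): "GU", ("U", "G"): "GU"}


@dataclass
class EnergyModel:
    """Pair-additive energy model with SHAPE pseudo-energies.

    ``pair_energies`` are in arbitrary energy units (negative = stabilizing);
    ``kT`` sets the Boltzmann scale. ``shape_m``/``shape_b`` follow the
    standard pseudo-energy convention: a reactive (single-stranded-looking)
    nucleotide is penalized for being paired.
    """

    pair_energies: Dict[str, float] = field(
        default_factory=lambda: {"GC": -3.0, "AU": -2.0, "GU": -1.0}
    )
    min_hairpin: int = 3
    kT: float = 0.6
    shape_m: float = 1.8
    shape_b: float = -0.6

    def __post_init__(self) -> None:
        if self.min_hairpin < 3:
            raise ValueError("min_hairpin must be >= 3")
        if self.kT <= 0:
            raise ValueError("kT must be positive")
        if any(e > 0 for e in self.pair_energies.values()):
            raise ValueError("pair energies must be <= 0")

    def pair_energy(self, a: str, b: str) -> float:
        """Energy of pairing bases a, b; +inf if not a canonical pair."""
        key = _CANONICAL.get((a, b))
        if key is None:
            return np.inf
        return self.pair_energies[key]


def shape_pseudo_energy(
    reactivity: Optional[np.ndarray], n: int, m: float = 1.8, b: float = -0.6
) -> np.ndarray:
    """Per-nucleotide pseudo-energy applied when the nucleotide is paired.

    ``m*ln(reactivity+1) + b`` where reactivity is defined, 0 where missing.
    """
    g = np.zeros(n)
    if reactivity is None:
        return g
    reactivity = np.asarray(reactivity, dtype=float)
    if reactivity.size != n:
        raise ValueError("reactivity length does not match sequence length")
    ok = ~np.isnan(reactivity)
    if (reactivity[ok] < 0).any():
        raise ValueError("reactivity must be >= 0 where defined")
    g[ok] = m * np.log(reactivity[ok] + 1.0) + b
    return g


def _validate_sequence(sequence: str) -> str:
    seq = sequence.upper().replace("T", "U")
    bad = set(seq) - set("ACGUN")
    if bad:
        raise ValueError(f"invalid characters in sequence: {sorted(bad)}")
    return seq


def _pair_energy_matrix(seq: str, model: EnergyModel, g: np.ndarray) -> np.ndarray:
    """E[i, j] = total energy of pair (i, j), +inf where the pair is illegal."""
    n = len(seq)
    E = np.full((n, n), np.inf)
    for i in range(n):
        for j in range(i + model.min_hairpin + 1, n):
            e = model.pair_energy(seq[i], seq[j])
            if np.isfinite(e):
                E[i, j] = e + g[i] + g[j]
    return E


def _mfe_dp(E: np.ndarray, n: int) -> Tuple[np.ndarray, float]:
    """Minimum-energy DP table over the leftmost-base decomposition."""
    # W[i, j+1] = MFE of subsequence [i..j]; empty intervals are 0.
    W = np.zeros((n + 2, n + 1))
    for span in range(1, n + 1):
        for i in range(n - span + 1):
            j = i + span - 1
            best = W[i + 1, j + 1]  # i unpaired
            ks = np.arange(i + 1, j + 1)
            if ks.size:
                cand = E[i, ks] + W[i + 1, ks] + W[ks + 1, j + 1]
                finite = np.isfinite(cand)
                if finite.any():
                    best = min(best, cand[finite].min())
            W[i, j + 1] = best
    return W, float(W[0, n])


_TIE = 1e-9


def _mfe_traceback(E: np.ndarray, W: np.ndarray, n: int) -> frozenset:
    """Deterministic traceback: prefer unpaired, then the smallest partner."""
    pairs = set()
    stack = [(0, n - 1)]
    while stack:
        i, j = stack.pop()
        if i >= j:
            continue
        target = W[i, j + 1]
        if W[i + 1, j + 1] <= target + _TIE:
            stack.append((i + 1, j))
            continue
        for k in range(i + 1, j + 1):
            if not np.isfinite(E[i, k]):
                continue
            if E[i, k] + W[i + 1, k] + W[k + 1, j + 1] <= target + _TIE:
                pairs.add((i, k))
                stack.append((i + 1, k - 1))
                stack.append((k + 1, j))
                break
    return frozenset(pairs)


def _inside_outside(
    E: np.ndarray, n: int, kT: float, mfe: float
) -> Tuple[np.ndarray, np.ndarray]:
    """Exact pair probabilities P[i, j] and per-nucleotide bpp.

    Uses per-base rescaling s = exp(-mfe/(kT*n)) so the dominant structure
    has scaled weight 1 (Z stays in [1, #structures]).
    """
    s = float(np.exp(-mfe / (kT * n))) if mfe < 0 else 1.0
    u = 1.0 / s
    with np.errstate(over="ignore"):
        Q = np.where(np.isfinite(E), np.exp(-E / kT) / (s * s), 0.0)
    # Z[i, j+1] = scaled partition of [i..j]; empty = 1.
    Z = np.ones((n + 2, n + 1))
    for span in range(1, n + 1):
        for i in range(n - span + 1):
            j = i + span - 1
            val = u * Z[i + 1, j + 1]
            ks = np.nonzero(Q[i, i + 1 : j + 1])[0] + i + 1
            if ks.size:
                val += float(np.sum(Q[i, ks] * Z[i + 1, ks] * Z[ks + 1, j + 1]))
            Z[i, j + 1] = val
    Ztot = Z[0, n]

    # Outside O[i, j+1] for the same decomposition; O(0, n-1) = 1.
    O = np.zeros((n + 1, n + 1))
    O[0, n] = 1.0

    def S(a: int, k: int) -> float:
        # sum over enclosing right ends b >= k of O(a,b) * Z(k+1, b)
        return float(np.dot(O[a, k + 1 : n + 1], Z[k + 1, k + 1 : n + 1]))

    for span in range(n - 1, 0, -1):
        for i in range(n - span + 1):
            j = i + span - 1
            t = 0.0
            if i >= 1:
                t += u * O[i - 1, j + 1]
                if j + 1 <= n - 1 and Q[i - 1, j + 1] > 0:
                    t += Q[i - 1, j + 1] * S(i - 1, j + 1)
            if i >= 2:
                ps = np.nonzero(Q[: i - 1, i - 1])[0]
                if ps.size:
                    t += float(np.sum(Q[ps, i - 1] * O[ps, j + 1] * Z[ps + 1, i - 1]))
            O[i, j + 1] = t

    P = np.zeros((n, n))
    for a in range(n):
        ks = np.nonzero(Q[a])[0]
        for k in ks:
            P[a, k] = Q[a, k] * Z[a + 1, k] * S(a, k) / Ztot
    P = np.clip(P, 0.0, 1.0)
    bpp = np.clip(P.sum(axis=0) + P.sum(axis=1), 0.0, 1.0)
    return P, bpp


def mfe_structure(
    sequence: str,
    model: Optional[EnergyModel] = None,
    reactivity: Optional[np.ndarray] = None,
) -> Tuple[str, frozenset, float]:
    """Minimum-energy structure; returns (dotbracket, pairs, energy)."""
    model = model or EnergyModel()
    seq = _validate_sequence(sequence)
    n = len(seq)
    g = shape_pseudo_energy(reactivity, n, model.shape_m, model.shape_b)
    E = _pair_energy_matrix(seq, model, g)
    W, mfe = _mfe_dp(E, n)
    pairs = _mfe_traceback(E, W, n)
    return pairs_to_dotbracket(pairs, n), pairs, mfe


def partition_function(
    sequence: str,
    model: Optional[EnergyModel] = None,
    reactivity: Optional[np.ndarray] = None,
    transcript_id: str = "",
    keep_matrix: bool = False,
) -> StructureResult:
    """Partition function, base-pairing probabilities and MFE structure."""
    model = model or EnergyModel()
    seq = _validate_sequence(sequence)
    n = len(seq)
    g = shape_pseudo_energy(reactivity, n, model.shape_m, model.shape_b)
    E = _pair_energy_matrix(seq, model, g)
    W, mfe = _mfe_dp(E, n)
    pairs = _mfe_traceback(E, W, n)
    P, bpp = _inside_outside(E, n, model.kT, mfe)
    return StructureResult(
        transcript_id=transcript_id,
        dotbracket=pairs_to_dotbracket(pairs, n),
        pairs=pairs,
        bpp=bpp,
        mfe=mfe,
        bpp_matrix_available=keep_matrix,
        bpp_matrix=P if keep_matrix else None,
    )


def fold_transcript(
    sequence: str,
    model: Optional[EnergyModel] = None,
    reactivity: Optional[np.ndarray] = None,
    transcript_id: str = "",
    window: int = 300,
    step: int = 150,
) -> StructureResult:
    """Fold a transcript; long sequences are handled in sliding windows.

    BPP is averaged over all windows covering a position; the MFE dot-bracket
    of a long transcript is assembled from non-overlapping blocks so the pair
    set stays nested.
    """
    model = model or EnergyModel()
    seq = _validate_sequence(sequence)
    n = len(seq)
    react = None if reactivity is None else np.asarray(reactivity, dtype=float)
    if n <= window:
        return partition_function(seq, model, react, transcript_id)

    starts = list(range(0, n - window + 1, step))
    if starts[-1] != n - window:
        starts.append(n - window)
    bpp_sum = np.zeros(n)
    bpp_cnt = np.zeros(n)
    for s0 in starts:
        sl = slice(s0, s0 + window)
        sub = partition_function(
            seq[sl], model, None if react is None else react[sl]
        )
        bpp_sum[sl] += sub.bpp
        bpp_cnt[sl] += 1
    bpp = bpp_sum / bpp_cnt

    pairs = set()
    mfe = 0.0
    for s0 in range(0, n, window):
        sl = slice(s0, min(s0 + window, n))
        _, p, e = mfe_structure(seq[sl], model, None if react is None else react[sl])
        pairs.update((i + s0, j + s0) for i, j in p)
        mfe += e
    return StructureResult(
        transcript_id=transcript_id,
        dotbracket=pairs_to_dotbracket(pairs, n),
        pairs=frozenset(pairs),
        bpp=bpp,
        mfe=mfe,
    )


def ppv(pred_pairs: Iterable[Tuple[int, int]], ref_pairs: Iterable[Tuple[int, int]]) -> float:
    """Positive predictive value: fraction of predicted pairs in the reference."""
    pred = set(pred_pairs)
    if not pred:
        return float("nan")
    return len(pred & set(ref_pairs)) / len(pred)


def reference_agreement(
    reactivity: np.ndarray,
    ref_paired: np.ndarray,
    low: float = 0.3,
    high: float = 0.6,
) -> Tuple[float, float]:
    """Agreement of SHAPE reactivity with a reference structure.

    tp_rate: of nucleotides with reactivity > ``high``, the fraction unpaired
    in the reference. tn_rate: of nucleotides with reactivity < ``low``, the
    fraction paired. Intermediate reactivities are excluded; an empty class
    yields NaN.
    """
    reactivity = np.asarray(reactivity, dtype=float)
    ref_paired = np.asarray(ref_paired, dtype=bool)
    ok = ~np.isnan(reactivity)
    hi = ok & (reactivity > high)
    lo = ok & (reactivity < low)
    tp = float(np.mean(~ref_paired[hi])) if hi.any() else float("nan")
    tn = float(np.mean(ref_paired[lo])) if lo.any() else float("nan")
    return tp, tn


def mean_bpp_by_region(
    structure: StructureResult, transcript: TranscriptRecord
) -> Dict[str, float]:
    """Mean BPP over 5'UTR, CDS, 3'UTR and the full transcript."""
    if structure.length != transcript.length:
        raise ValueError("structure/transcript length mismatch")
    out = {}
    for name, (s, e) in (
        ("utr5", transcript.utr5),
        ("cds", transcript.cds),
        ("utr3", transcript.utr3),
        ("full", (0, transcript.length)),
    ):
        out[name] = float(np.mean(structure.bpp[s:e])) if e > s else float("nan")
    return out
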