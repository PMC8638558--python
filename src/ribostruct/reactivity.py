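"""SHAPE reactivity from RT-stop counts.

Pipeline per transcript and replicate: per-nucleotide stop rates in the
(+) and (-) channels, background subtraction (plus minus minus, clipped at
zero), 2-8% normalization per transcript, then replicate averaging with a
reproducibility (Pearson) report. Positions below the coverage threshold are
missing, and missingness only ever propagates forward.
"""

from __future__ import annotations

import logging
import math
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .types import ReactivityProfile, StopCountProfile

logger = logging.getLogger(__name__)

DEFAULT_MIN_COVERAGE = 50
MIN_DEFINED_FOR_NORM = 20


def stop_rate(profile: StopCountProfile, min_coverage: int = DEFAULT_MIN_COVERAGE) -> np.ndarray:
    """Per-nucleotide RT-stop rate; NaN where coverage < ``min_coverage``."""
    rate = np.full(profile.length, np.nan)
    ok = profile.coverage >= min_coverage
    # min_coverage >= 1 guards the division; a 0-coverage position is masked
    ok &= profile.coverage > 0
    rate[ok] = profile.stops[ok] / profile.coverage[ok]
    return rate


def raw_reactivity(plus_rate: np.ndarray, minus_rate: np.ndarray) -> np.ndarray:
    """Background-subtracted stop excess, clipped at zero; NaN where either is missing."""
    plus_rate = np.asarray(plus_rate, dtype=float)
    minus_rate = np.asarray(minus_rate, dtype=float)
    if plus_rate.shape != minus_rate.shape:
        raise ValueError("plus/minus rate length mismatch")
    raw = np.maximum(plus_rate - minus_rate, 0.0)
    raw[np.isnan(plus_rate) | np.isnan(minus_rate)] = np.nan
    return raw


def normalize_2_8(
    raw: np.ndarray, transcript_id: str = "", min_defined: int = MIN_DEFINED_FOR_NORM
) -> Optional[ReactivityProfile]:
    """2-8% normalization of a per-transcript raw reactivity vector.

    The top 2% of defined values (count = ceil(0.02*n)) are treated as
    outliers and excluded; all values are divided by the mean of the next 8%
    (count = round-half-up(0.08*n)). Returns None (transcript dropped, with a
    warning) when fewer than ``min_defined`` positions are defined or the
    divisor is zero. Ties are broken by value then position for
    bit-reproducibility.
    """
    raw = np.asarray(raw, dtype=float)
    defined = ~np.isnan(raw)
    n = int(defined.sum())
    if n < min_defined:
        logger.warning("normalize_2_8: %s dropped (%d defined positions)", transcript_id, n)
        return None
    vals = raw[defined]
    pos = np.nonzero(defined)[0]
    # sort descending by value, ascending position among ties
    order = np.lexsort((pos, -vals))
    svals = vals[order]
    n_out = math.ceil(0.02 * n)
    n_win = int(math.floor(0.08 * n + 0.5))
    n_win = max(n_win, 1)
    window = svals[n_out : n_out + n_win]
    divisor = float(np.mean(window)) if window.size else 0.0
    if divisor <= 0:
        logger.warning("normalize_2_8: %s dropped (zero normalization divisor)", transcript_id)
        return None
    return ReactivityProfile(
        transcript_id=transcript_id,
        reactivity=raw / divisor,
        coverage_ok=defined,
    )


def merge_replicates(
    profiles: Sequence[ReactivityProfile],
) -> Tuple[ReactivityProfile, float]:
    """Position-wise mean of defined replicate values + replicate Pearson r.

    A position missing in one replicate takes the other's value; the
    correlation is computed on positions defined in all replicates (NaN when
    fewer than 3 such positions or fewer than 2 replicates).
    """
    if not profiles:
        raise ValueError("no replicates to merge")
    lengths = {p.length for p in profiles}
    if len(lengths) != 1:
        raise ValueError("replicate length mismatch")
    mat = np.vstack([p.reactivity for p in profiles])
    with np.errstate(invalid="ignore"):
        merged = np.nanmean(mat, axis=0)
    ok = ~np.isnan(merged)
    rr = float("nan")
    if len(profiles) >= 2:
        both = ~np.isnan(mat).any(axis=0)
        if both.sum() >= 3:
            rs = []
            for i in range(len(profiles)):
                for j in range(i + 1, len(profiles)):
                    a, b = mat[i, both], mat[j, both]
                    if np.std(a) > 0 and np.std(b) > 0:
                        rs.append(stats.pearsonr(a, b)[0])
                    elif np.array_equal(a, b):
                        rs.append(1.0)
            if rs:
                rr = float(np.mean(rs))
    return (
        ReactivityProfile(
            transcript_id=profiles[0].transcript_id, reactivity=merged, coverage_ok=ok
        ),
        rr,
    )


def reactivity_pipeline(
    stop_profiles: Iterable[StopCountProfile],
    min_coverage: int = DEFAULT_MIN_COVERAGE,
) -> Tuple[List[ReactivityProfile], Dict[str, float]]:
    """Full reactivity computation for a collection of stop-count profiles.

    Groups profiles by transcript, matches plus/minus channels per replicate,
    normalizes each replicate with the 2-8% rule and merges replicates.
    Returns merged profiles plus a per-transcript replicate-correlation map.
    """
    by_transcript: Dict[str, Dict[int, Dict[str, StopCountProfile]]] = {}
    for p in stop_profiles:
        by_transcript.setdefault(p.transcript_id, {}).setdefault(p.replicate, {})[
            p.channel
        ] = p

    merged_profiles: List[ReactivityProfile] = []
    correlations: Dict[str, float] = {}
    for tid in sorted(by_transcript):
        reps = []
        for rep in sorted(by_transcript[tid]):
            chans = by_transcript[tid][rep]
            if "plus" not in chans or "minus" not in chans:
                logger.warning("reactivity: %s replicate %d lacks a channel", tid, rep)
                continue
            raw = raw_reactivity(
                stop_rate(chans["plus"], min_coverage),
                stop_rate(chans["minus"], min_coverage),
            )
            prof = normalize_2_8(raw, transcript_id=tid)
            if prof is not None:
                reps.append(prof)
        if not reps:
            continue
        merged, rr = merge_replicates(reps)
        merged_profiles.append(merged)
        correlations[tid] = rr
    return merged_profiles, correlations
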