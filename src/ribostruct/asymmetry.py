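"""Homoeolog-pair structure and translation asymmetry statistics."""

from __future__ import annotations

import logging
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

MIN_POSITIONS = 20


def pair_bpp_test(
    bpp_a: np.ndarray,
    bpp_b: np.ndarray,
    alpha: float = 0.05,
    per_transcript_mean: bool = False,
) -> Tuple[float, str]:
    """Wilcoxon rank-sum comparison of per-nucleotide BPP between homoeologs.

    Returns (p, direction) with direction in {A_higher, B_higher, NSD}.
    ``per_transcript_mean=True`` is a caveat-free alternative that only
    reports the sign of the mean difference (no test). Vectors shorter than
    20 defined positions raise ValueError (pair excluded upstream).
    """
    a = np.asarray(bpp_a, dtype=float)
    b = np.asarray(bpp_b, dtype=float)
    a = a[~np.isnan(a)]
    b = b[~np.isnan(b)]
    if a.size < MIN_POSITIONS or b.size < MIN_POSITIONS:
        raise ValueError("fewer than 20 defined positions")
    if per_transcript_mean:
        diff = float(np.mean(a) - np.mean(b))
        return float("nan"), "A_higher" if diff > 0 else ("B_higher" if diff < 0 else "NSD")
    if np.array_equal(a, b):
        return 1.0, "NSD"
    p = float(stats.ranksums(a, b).pvalue)
    if p >= alpha:
        return p, "NSD"
    return p, "A_higher" if float(np.mean(a) - np.mean(b)) > 0 else "B_higher"


def asymmetry_summary(directions: Iterable[str]) -> Dict[str, float]:
    """Fractions of pairs with A-higher, B-higher or no significant BPP difference."""
    dirs = list(directions)
    n = len(dirs)
    if n == 0:
        return {"A_higher": 0.0, "B_higher": 0.0, "NSD": 1.0, "n": 0}
    return {
        "A_higher": dirs.count("A_higher") / n,
        "B_higher": dirs.count("B_higher") / n,
        "NSD": dirs.count("NSD") / n,
        "n": n,
    }


def delta_correlation(
    delta_bpp: Sequence[float], delta_te: Sequence[float]
) -> Tuple[float, float, int]:
    """Pearson correlation of |delta mean BPP| vs |delta log2 TE| across pairs."""
    db = np.abs(np.asarray(delta_bpp, dtype=float))
    dt = np.abs(np.asarray(delta_te, dtype=float))
    ok = ~(np.isnan(db) | np.isnan(dt))
    n = int(ok.sum())
    if n < 3 or np.std(db[ok]) == 0 or np.std(dt[ok]) == 0:
        return float("nan"), float("nan"), n
    r, p = stats.pearsonr(db[ok], dt[ok])
    return float(r), float(p), n


def grouped_delta_correlation(
    pair_table: pd.DataFrame,
    group_map: Dict[str, str],
    min_pairs: int = 10,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-functional-group |dBPP|-|dTE| correlation with a BH-significance flag.

    ``pair_table`` needs columns pair_id, delta_bpp, delta_te; ``group_map``
    maps pair_id -> group. Groups with fewer than ``min_pairs`` pairs are
    excluded.
    """
    df = pair_table.copy()
    df["group"] = df["pair_id"].map(group_map)
    rows = []
    for group, grp in df.dropna(subset=["group"]).groupby("group", sort=True):
        if len(grp) < min_pairs:
            continue
        r, p, n = delta_correlation(grp["delta_bpp"], grp["delta_te"])
        rows.append((group, r, p, n))
    out = pd.DataFrame(rows, columns=["group", "r", "p", "n"])
    if len(out):
        ok = ~out["p"].isna()
        flags = np.zeros(len(out), dtype=bool)
        if ok.any():
            flags[ok.to_numpy()] = multipletests(out.loc[ok, "p"], method="fdr_bh")[1] < alpha
        out["significant"] = flags
    else:
        out["significant"] = []
    return out


def grouped_te_difference(
    pair_table: pd.DataFrame, group_map: Dict[str, str], min_pairs: int = 10
) -> pd.DataFrame:
    """Per-group mean TE difference (A - B, log2 scale) with its standard error."""
    df = pair_table.copy()
    df["group"] = df["pair_id"].map(group_map)
    rows = []
    for group, grp in df.dropna(subset=["group", "delta_te"]).groupby("group", sort=True):
        if len(grp) < min_pairs:
            continue
        d = grp["delta_te"].to_numpy(dtype=float)
        se = float(np.std(d, ddof=1) / np.sqrt(d.size)) if d.size > 1 else 0.0
        rows.append((group, float(np.mean(d)), se, d.size))
    return pd.DataFrame(rows, columns=["group", "mean_te_diff", "se", "n"])
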