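"""Homoeolog alignment, SNV/indel extraction, eSDC and riboSNitch calling.

Pairs are aligned globally with affine gaps (match +1, mismatch -1, gap open
-4 for the first gapped column, -1 per additional column). A riboSNitch is an
SNV around which both the base-pairing probability and the SHAPE reactivity
differ significantly between the two homoeologs: for each signal, the
absolute A-B differences inside a window around the SNV are compared with
the pair's own outside-window baseline (one-sided rank-sum), plus an
effect-size floor. A paired test on signed differences is not used because
a helix relocation moves BPP up at the new stem and down at the old one,
cancelling in the signed sum.
"""

from __future__ import annotations

import logging
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests
from Bio import Align

from .types import HomoeologPair, Indel, SNVRecord, TranscriptRecord

logger = logging.getLogger(__name__)

TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "U"), ("U", "C")}

MATCH, MISMATCH, GAP_OPEN, GAP_EXTEND = 1.0, -1.0, -4.0, -1.0

MIN_SHARED_COLUMNS = 20


def _aligner() -> Align.PairwiseAligner:
    al = Align.PairwiseAligner()
    al.mode = "global"
    al.match_score = MATCH
    al.mismatch_score = MISMATCH
    al.open_gap_score = GAP_OPEN
    al.extend_gap_score = GAP_EXTEND
    return al


def align_pair(seq_a: str, seq_b: str, a_id: str = "A", b_id: str = "B") -> HomoeologPair:
    """Global affine-gap alignment of a homoeolog pair (deterministic)."""
    if not seq_a or not seq_b:
        raise ValueError("sequences must be non-empty")
    seq_a = seq_a.upper().replace("T", "U")
    seq_b = seq_b.upper().replace("T", "U")
    aln = _aligner().align(seq_a, seq_b)
    best = aln[0]
    return HomoeologPair(
        a_id=a_id, b_id=b_id, aligned_a=str(best[0]), aligned_b=str(best[1]),
        score=float(best.score),
    )


def mutation_class(a: str, b: str) -> str:
    return "transition" if (a, b) in TRANSITIONS else "transversion"


def extract_variants(
    pair: HomoeologPair,
    record_a: Optional[TranscriptRecord] = None,
    record_b: Optional[TranscriptRecord] = None,
) -> Tuple[List[SNVRecord], List[Indel]]:
    """SNVs (mismatch columns, N-columns dropped) and maximal-gap-run indels.

    Genic region is assigned from the A-subgenome annotation; when the B
    annotation disagrees both are recorded and the SNV flagged discordant.
    Also stores the per-pair SNV ratio (SNVs / aligned non-gap columns) on
    the pair via ``pair.snvs``/``pair.indels``.
    """
    snvs: List[SNVRecord] = []
    indels: List[Indel] = []
    ia = ib = 0
    gap_start = None
    gap_which = None
    for col, (ca, cb) in enumerate(zip(pair.aligned_a, pair.aligned_b)):
        if ca == "-" or cb == "-":
            which = "A" if ca == "-" else "B"
            if gap_start is None or gap_which != which:
                if gap_start is not None:
                    indels.append(Indel(gap_start, col - gap_start, gap_which))
                gap_start, gap_which = col, which
        else:
            if gap_start is not None:
                indels.append(Indel(gap_start, col - gap_start, gap_which))
                gap_start = gap_which = None
            if ca != cb and ca in "ACGU" and cb in "ACGU":
                region_a = record_a.region_of(ia) if record_a else "unknown"
                region_b = record_b.region_of(ib) if record_b else "unknown"
                snvs.append(
                    SNVRecord(
                        pair_id=pair.pair_id, pos_a=ia, pos_b=ib,
                        allele_a=ca, allele_b=cb,
                        mutation_class=mutation_class(ca, cb),
                        region=region_a, region_b=region_b,
                        region_discordant=(record_a is not None and record_b is not None
                                           and region_a != region_b),
                    )
                )
        if ca != "-":
            ia += 1
        if cb != "-":
            ib += 1
    if gap_start is not None:
        indels.append(Indel(gap_start, len(pair.aligned_a) - gap_start, gap_which))
    pair.snvs = snvs
    pair.indels = indels
    return snvs, indels


def snv_ratio(pair: HomoeologPair) -> float:
    """SNVs per aligned non-gap column."""
    cols = sum(
        1 for ca, cb in zip(pair.aligned_a, pair.aligned_b) if ca != "-" and cb != "-"
    )
    return len(pair.snvs) / cols if cols else float("nan")


def project_to_alignment(values: np.ndarray, aligned_row: str) -> np.ndarray:
    """Map a per-nucleotide vector onto alignment columns (NaN at gaps)."""
    values = np.asarray(values, dtype=float)
    out = np.full(len(aligned_row), np.nan)
    i = 0
    for col, c in enumerate(aligned_row):
        if c != "-":
            out[col] = values[i]
            i += 1
    if i != values.size:
        raise ValueError("vector length does not match ungapped row length")
    return out


def esdc(
    react_a: np.ndarray,
    react_b: np.ndarray,
    pair: HomoeologPair,
    exponent: float = 0.5,
) -> float:
    """Experimental structure disruption coefficient: (1 - r) * L**exponent.

    Reactivities are projected onto alignment columns; columns with a gap or
    a missing value in either profile are dropped pairwise. Returns NaN with
    fewer than 20 shared columns or degenerate (zero-variance) profiles.
    """
    pa = project_to_alignment(react_a, pair.aligned_a)
    pb = project_to_alignment(react_b, pair.aligned_b)
    ok = ~(np.isnan(pa) | np.isnan(pb))
    L = int(ok.sum())
    if L < MIN_SHARED_COLUMNS:
        return float("nan")
    a, b = pa[ok], pb[ok]
    if np.std(a) == 0 or np.std(b) == 0:
        return 0.0 if np.array_equal(a, b) else float("nan")
    r = float(stats.pearsonr(a, b)[0])
    return (1.0 - r) * L**exponent


def _disruption_test(d_in: np.ndarray, d_out: np.ndarray) -> Tuple[float, float]:
    """Local-disruption test for one signal around an SNV.

    One-sided Wilcoxon rank-sum of |differences| inside the SNV window
    against |differences| elsewhere on the same pair (the pair's own noise
    baseline). A structure flip raises |d| inside the window in both
    directions, which a paired test on signed differences cannot see.
    Returns (p, effect) with effect = mean|d| inside - mean|d| outside
    (mean, not median: a flip that rearranges a third of the window must
    still register).
    """
    d_in = np.abs(d_in[~np.isnan(d_in)])
    d_out = np.abs(d_out[~np.isnan(d_out)])
    if d_in.size == 0 or d_out.size == 0:
        return 1.0, float("nan")
    effect = float(np.mean(d_in) - np.mean(d_out))
    if np.all(d_in == d_in[0]) and np.all(d_out == d_in[0]):
        return 1.0, effect
    p = float(stats.mannwhitneyu(d_in, d_out, alternative="greater").pvalue)
    return p, effect


def call_ribosnitches(
    pair: HomoeologPair,
    bpp_a: np.ndarray,
    bpp_b: np.ndarray,
    react_a: np.ndarray,
    react_b: np.ndarray,
    window: int = 50,
    min_defined: int = 20,
) -> List[SNVRecord]:
    """Compute per-SNV window statistics (raw p-values and effect sizes).

    SNVs closer than window/2 are clustered, tested jointly at the cluster
    centre and flagged non-isolated. The outside-window columns of the same
    pair serve as each signal's noise baseline. The final riboSNitch call is made by
    :func:`finalize_ribosnitch_calls` after BH correction across all SNVs.
    SNVs with fewer than ``min_defined`` defined window columns in either
    signal stay untested (is_ribosnitch = None).
    """
    if not pair.snvs:
        return []
    pa_b = project_to_alignment(bpp_a, pair.aligned_a)
    pb_b = project_to_alignment(bpp_b, pair.aligned_b)
    pa_r = project_to_alignment(react_a, pair.aligned_a)
    pb_r = project_to_alignment(react_b, pair.aligned_b)
    ncol = len(pair.aligned_a)

    # alignment column of each SNV
    a_pos_to_col = {}
    i = 0
    for col, c in enumerate(pair.aligned_a):
        if c != "-":
            a_pos_to_col[i] = col
            i += 1
    snv_cols = [a_pos_to_col[s.pos_a] for s in pair.snvs]

    # chain-cluster SNVs closer than window/2
    clusters: List[List[int]] = []
    for idx, col in enumerate(snv_cols):
        if clusters and col - snv_cols[clusters[-1][-1]] < window / 2:
            clusters[-1].append(idx)
        else:
            clusters.append([idx])

    d_bpp_all = pa_b - pb_b
    d_react_all = pa_r - pb_r
    for cluster in clusters:
        centre = int(round(np.mean([snv_cols[i] for i in cluster])))
        lo, hi = max(0, centre - window), min(ncol, centre + window + 1)
        inside = np.zeros(ncol, dtype=bool)
        inside[lo:hi] = True
        d_bpp, d_bpp_out = d_bpp_all[inside], d_bpp_all[~inside]
        d_react, d_react_out = d_react_all[inside], d_react_all[~inside]
        n_bpp = int((~np.isnan(d_bpp)).sum())
        n_react = int((~np.isnan(d_react)).sum())
        n_out = min(int((~np.isnan(d_bpp_out)).sum()), int((~np.isnan(d_react_out)).sum()))
        tested = n_bpp >= min_defined and n_react >= min_defined and n_out >= min_defined
        if tested:
            p_bpp, eff_bpp = _disruption_test(d_bpp, d_bpp_out)
            p_react, eff_react = _disruption_test(d_react, d_react_out)
        for idx in cluster:
            snv = pair.snvs[idx]
            snv.non_isolated = len(cluster) > 1
            if tested:
                snv.delta_bpp_p = p_bpp
                snv.delta_react_p = p_react
                snv.delta_bpp_effect = eff_bpp
                snv.delta_react_effect = eff_react
                snv.is_ribosnitch = False  # provisional; finalized after BH
            else:
                snv.is_ribosnitch = None
    return pair.snvs


def finalize_ribosnitch_calls(
    snvs: Sequence[SNVRecord],
    alpha: float = 0.05,
    min_effect: float = 0.1,
    use_adjusted: bool = False,
) -> None:
    """Set ``is_ribosnitch`` on tested SNVs.

    Default: both raw p < alpha and both mean-absolute-difference effects
    >= min_effect.
    ``use_adjusted=True`` uses BH-adjusted p-values (adjusted per statistic
    across all tested SNVs) instead of raw p.
    """
    tested = [s for s in snvs if s.is_ribosnitch is not None]
    if not tested:
        return
    p_bpp = np.array([s.delta_bpp_p for s in tested])
    p_react = np.array([s.delta_react_p for s in tested])
    if use_adjusted:
        p_bpp = multipletests(p_bpp, method="fdr_bh")[1]
        p_react = multipletests(p_react, method="fdr_bh")[1]
    for s, pb, pr in zip(tested, p_bpp, p_react):
        s.is_ribosnitch = bool(
            pb < alpha
            and pr < alpha
            and s.delta_bpp_effect >= min_effect
            and s.delta_react_effect >= min_effect
        )


def ribosnitch_region_ratios(
    snvs: Sequence[SNVRecord], strict: bool = False
) -> Dict[str, float]:
    """riboSNitch count / tested SNV count per genic region.

    Untestable SNVs are excluded from numerator and denominator by default;
    ``strict=True`` keeps them in the denominator.
    """
    out = {}
    for region in ("utr5", "cds", "utr3"):
        rs = [s for s in snvs if s.region == region]
        denom = [s for s in rs if strict or s.is_ribosnitch is not None]
        num = [s for s in rs if s.is_ribosnitch]
        out[region] = len(num) / len(denom) if denom else float("nan")
    all_tested = [s for s in snvs if strict or s.is_ribosnitch is not None]
    all_num = [s for s in snvs if s.is_ribosnitch]
    out["all"] = len(all_num) / len(all_tested) if all_tested else float("nan")
    return out


def esdc_snv_correlation(pairs: Sequence[HomoeologPair]) -> pd.DataFrame:
    """Pearson correlation of eSDC with SNV count and with indel length.

    Indel lengths are summed per subgenome (gap in A vs gap in B). Returns a
    table of (covariate, r, p, n); NaN when degenerate.
    """
    esdcs = np.array([p.esdc for p in pairs], dtype=float)
    covs = {
        "snv_count": np.array([len(p.snvs) for p in pairs], dtype=float),
        "indel_len_A": np.array(
            [sum(i.length for i in p.indels if i.which_sequence == "A") for p in pairs],
            dtype=float,
        ),
        "indel_len_B": np.array(
            [sum(i.length for i in p.indels if i.which_sequence == "B") for p in pairs],
            dtype=float,
        ),
    }
    rows = []
    for name, x in covs.items():
        ok = ~(np.isnan(esdcs) | np.isnan(x))
        n = int(ok.sum())
        if n < 3 or np.std(esdcs[ok]) == 0 or np.std(x[ok]) == 0:
            rows.append((name, float("nan"), float("nan"), n))
            continue
        r, p = stats.pearsonr(esdcs[ok], x[ok])
        rows.append((name, float(r), float(p), n))
    return pd.DataFrame(rows, columns=["covariate", "r", "p", "n"])
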