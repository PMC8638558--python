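"""Translation efficiency and codon-usage metrics.

TE is the ratio of length-normalized polysome abundance to mRNA abundance
(TPM-style per replicate). CAI and tAI are geometric means of per-codon
adaptiveness weights, computed in log space. Differential TE between
homoeologs uses a two-sample t test on per-replicate log2 TEs with
Benjamini-Hochberg correction across pairs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests
from Bio.Data.CodonTable import unambiguous_rna_by_id

from .types import ReactivityProfile, TranscriptRecord

logger = logging.getLogger(__name__)

_STANDARD_TABLE = unambiguous_rna_by_id[1]
#: codon -> amino acid (stop codons excluded)
CODON_TO_AA: Dict[str, str] = dict(_STANDARD_TABLE.forward_table)
STOP_CODONS = set(_STANDARD_TABLE.stop_codons)


@dataclass
class CodonUsageTable:
    """Codon frequency counts and derived relative adaptiveness r_i.

    ``r_i = f_i / max(f_j)`` over the synonymous codons of each amino acid.
    """

    f: Dict[str, float]

    def __post_init__(self) -> None:
        by_aa: Dict[str, List[str]] = {}
        for codon, aa in CODON_TO_AA.items():
            by_aa.setdefault(aa, []).append(codon)
        self.r: Dict[str, float] = {}
        for aa, codons in by_aa.items():
            fmax = max(self.f.get(c, 0.0) for c in codons)
            if fmax <= 0:
                continue
            for c in codons:
                if self.f.get(c, 0.0) > 0:
                    self.r[c] = self.f[c] / fmax


@dataclass
class TAIWeights:
    """Relative adaptiveness w_k per codon, normalized so max(w) = 1."""

    w: Dict[str, float]

    def __post_init__(self) -> None:
        if not self.w:
            raise ValueError("empty tAI weight table")
        wmax = max(self.w.values())
        if wmax <= 0:
            raise ValueError("tAI weights must contain positive values")
        self.w = {c: v / wmax for c, v in self.w.items() if v > 0}


def _codons(cds: str) -> List[str]:
    cds = cds.upper().replace("T", "U")
    if len(cds) % 3 != 0:
        raise ValueError("CDS length not divisible by 3")
    return [cds[i : i + 3] for i in range(0, len(cds), 3)]


def _geometric_mean_weights(cds: str, weights: Dict[str, float], label: str) -> float:
    logs = []
    for codon in _codons(cds):
        if codon in STOP_CODONS:
            continue  # stop codon excluded
        if "N" in codon:
            continue  # ambiguous codon skipped, n decremented
        if codon not in weights:
            raise KeyError(f"{label}: codon {codon!r} absent from weight table")
        logs.append(np.log(weights[codon]))
    if not logs:
        raise ValueError(f"{label}: no scorable codons")
    return float(np.exp(np.mean(logs)))


def cai(cds: str, usage: CodonUsageTable) -> float:
    """Codon adaptation index: geometric mean of r_i over the CDS."""
    return _geometric_mean_weights(cds, usage.r, "cai")


def tai(cds: str, weights: TAIWeights) -> float:
    """tRNA adaptation index: geometric mean of w_k over the CDS."""
    return _geometric_mean_weights(cds, weights.w, "tai")


def gc_content(sequence: str, region: Optional[Tuple[int, int]] = None) -> float:
    seq = sequence.upper().replace("T", "U")
    if region is not None:
        seq = seq[region[0] : region[1]]
    seq = seq.replace("N", "")
    if not seq:
        return float("nan")
    return (seq.count("G") + seq.count("C")) / len(seq)


# ---------------------------------------------------------------------------
# Translation efficiency

def compute_abundances(
    counts: pd.DataFrame, lengths: Dict[str, int], length_normalize: bool = True
) -> pd.DataFrame:
    """Per-replicate length-normalized per-million abundances (TPM-style).

    ``counts`` is long-format with columns transcript_id, replicate,
    rna_count, polysome_count. Adds rna_abund and poly_abund columns.
    """
    df = counts.copy()
    df["length"] = df["transcript_id"].map(lengths)
    if df["length"].isna().any():
        missing = df.loc[df["length"].isna(), "transcript_id"].iloc[0]
        raise ValueError(f"unknown transcript id {missing!r} in count table")
    for col, out in (("rna_count", "rna_abund"), ("polysome_count", "poly_abund")):
        dens = df[col] / df["length"] if length_normalize else df[col].astype(float)
        total = dens.groupby(df["replicate"]).transform("sum")
        df[out] = 1e6 * dens / total
    return df


def translation_efficiency(
    counts: pd.DataFrame, lengths: Dict[str, int], length_normalize: bool = True
) -> pd.DataFrame:
    """Per-transcript TE: mean over replicates of poly_abund/rna_abund.

    TE is missing for transcripts with zero RNA abundance in any replicate.
    Returns a frame with per-replicate TEs (te_rep list) and the point
    estimate ``te``.
    """
    df = compute_abundances(counts, lengths, length_normalize)
    rows = []
    for tid, grp in df.groupby("transcript_id", sort=True):
        if (grp["rna_abund"] <= 0).any():
            rows.append((tid, [], float("nan")))
            continue
        te_rep = (grp["poly_abund"] / grp["rna_abund"]).tolist()
        rows.append((tid, te_rep, float(np.mean(te_rep))))
    return pd.DataFrame(rows, columns=["transcript_id", "te_rep", "te"])


def differential_te(
    pairs: Sequence[Tuple[str, str]],
    te_table: pd.DataFrame,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-pair differential TE: t test on log2 per-replicate TEs + BH.

    Direction is A_higher / B_higher / NSD; pairs with fewer than two
    replicate TEs on either side are excluded (logged).
    """
    te_map = dict(zip(te_table["transcript_id"], te_table["te_rep"]))
    rows = []
    for a_id, b_id in pairs:
        ta = np.asarray(te_map.get(a_id, []), dtype=float)
        tb = np.asarray(te_map.get(b_id, []), dtype=float)
        ta = ta[ta > 0]
        tb = tb[tb > 0]
        if ta.size < 2 or tb.size < 2:
            logger.info("differential_te: pair %s|%s excluded (<2 replicates)", a_id, b_id)
            continue
        la, lb = np.log2(ta), np.log2(tb)
        if np.allclose(la, la[0]) and np.allclose(lb, lb[0]) and np.isclose(la[0], lb[0]):
            p = 1.0
        else:
            p = float(stats.ttest_ind(la, lb, equal_var=True).pvalue)
            if np.isnan(p):
                p = 1.0
        rows.append((a_id, b_id, float(np.mean(la) - np.mean(lb)), p))
    df = pd.DataFrame(rows, columns=["a_id", "b_id", "log2_te_ratio", "p"])
    if len(df):
        df["p_adj"] = multipletests(df["p"], method="fdr_bh")[1]
        df["direction"] = np.where(
            df["p_adj"] >= alpha, "NSD",
            np.where(df["log2_te_ratio"] > 0, "A_higher", "B_higher"),
        )
    else:
        df["p_adj"] = []
        df["direction"] = []
    return df


def te_covariate_correlations(
    te: pd.Series, covariates: pd.DataFrame
) -> pd.DataFrame:
    """Pearson correlations of log2(TE) with each covariate column.

    Pairwise-complete observations; TE <= 0 or missing rows are dropped.
    """
    log_te = np.log2(te.where(te > 0))
    rows = []
    for col in covariates.columns:
        x = covariates[col]
        ok = (~log_te.isna()) & (~x.isna())
        n = int(ok.sum())
        if n < 3 or np.std(x[ok]) == 0 or np.std(log_te[ok]) == 0:
            rows.append((col, float("nan"), float("nan"), n))
            continue
        r, p = stats.pearsonr(log_te[ok], x[ok])
        rows.append((col, float(r), float(p), n))
    return pd.DataFrame(rows, columns=["covariate", "r", "p", "n"])


# ---------------------------------------------------------------------------
# Metagene profiles and periodicity

def _scale_region(values: np.ndarray, n_bins: int) -> np.ndarray:
    """Average a (possibly NaN-holding) region vector into n_bins bins."""
    out = np.full(n_bins, np.nan)
    m = values.size
    if m == 0:
        return out
    bins = np.minimum((np.arange(m) * n_bins) // m, n_bins - 1)
    for b in range(n_bins):
        v = values[bins == b]
        v = v[~np.isnan(v)]
        if v.size:
            out[b] = float(np.mean(v))
        else:
            # region shorter than the bin grid: sample the nearest position
            out[b] = values[min(m - 1, (b * m) // n_bins)]
    return out


def metagene_profile(
    reactivities: Dict[str, ReactivityProfile],
    transcripts: Dict[str, TranscriptRecord],
    te_table: pd.DataFrame,
    decile: float = 0.10,
    bins: Tuple[int, int, int] = (50, 100, 50),
) -> Tuple[np.ndarray, np.ndarray]:
    """Start/stop-anchored average reactivity for high- vs low-TE transcripts.

    Each transcript's 5'UTR/CDS/3'UTR is rescaled to fixed bin counts; the
    top and bottom ``decile`` of transcripts by TE are averaged position-wise.
    Returns (high_profile, low_profile) of length sum(bins).
    """
    usable = te_table.dropna(subset=["te"])
    usable = usable[usable["transcript_id"].isin(reactivities)]
    usable = usable.sort_values(["te", "transcript_id"], ascending=[False, True])
    k = max(1, int(round(decile * len(usable))))
    high_ids = usable["transcript_id"].head(k).tolist()
    low_ids = usable["transcript_id"].tail(k).tolist()

    def group_profile(ids: List[str]) -> np.ndarray:
        mats = []
        for tid in ids:
            rec = transcripts[tid]
            react = reactivities[tid].reactivity
            parts = [
                _scale_region(react[s:e], nb)
                for (s, e), nb in zip((rec.utr5, rec.cds, rec.utr3), bins)
            ]
            mats.append(np.concatenate(parts))
        with np.errstate(invalid="ignore"):
            return np.nanmean(np.vstack(mats), axis=0)

    return group_profile(high_ids), group_profile(low_ids)


def periodicity_3nt(profile: np.ndarray, min_length: int = 30) -> float:
    """Normalized period-3 DFT magnitude of a CDS reactivity profile.

    Codons containing a missing position are dropped whole (frame preserved);
    the score is |X(period 3)| / sum(signal), in [0, 1]; 0 for a flat signal.
    """
    x = np.asarray(profile, dtype=float)
    n3 = (x.size // 3) * 3
    x = x[:n3].reshape(-1, 3)
    keep = ~np.isnan(x).any(axis=1)
    x = x[keep].reshape(-1)
    if x.size < min_length:
        raise ValueError(f"periodicity_3nt: need >= {min_length} positions, got {x.size}")
    if (x < 0).any():
        raise ValueError("periodicity_3nt: negative reactivities")
    total = float(np.sum(x))
    if total == 0:
        return 0.0
    k = np.arange(x.size)
    comp = np.sum(x * np.exp(-2j * np.pi * k / 3.0))
    return float(np.abs(comp) / total)
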