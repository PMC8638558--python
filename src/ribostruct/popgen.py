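"""Allele frequencies, fixation index and conservation ratios.

F_ST = sigma_pi^2 / (pi_bar * (1 - pi_bar)) where pi_bar is the mean and
sigma_pi^2 the population (not sample) variance of a chosen allele's
frequency across subpopulations. The conservation ratio of an SNV class on a
transcript is the fraction of its SNVs whose reference-pair allele is the
major allele of the reference subpopulation.
"""

from __future__ import annotations

from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .types import ConservationResult, FstResult, NUC_ORDER, PopulationTable, SNVRecord


def allele_frequencies(
    pop_table: PopulationTable, site_id: str
) -> Tuple[Dict[str, Dict[str, float]], Dict[str, Optional[str]]]:
    """Per-subpopulation allele frequencies f_i = c(i)/sum(c) + major allele.

    Frequency ties for the major allele break alphabetically (A<C<G<U).
    Subpopulations with zero counts get an empty map and major allele None.
    """
    site = pop_table.counts[site_id]
    freqs: Dict[str, Dict[str, float]] = {}
    majors: Dict[str, Optional[str]] = {}
    for subpop, counts in site.items():
        total = sum(counts.values())
        if total == 0:
            freqs[subpop] = {}
            majors[subpop] = None
            continue
        f = {nuc: counts.get(nuc, 0) / total for nuc in NUC_ORDER if counts.get(nuc, 0) > 0}
        freqs[subpop] = f
        majors[subpop] = max(f, key=lambda nuc: (f[nuc], -NUC_ORDER.index(nuc)))
    return freqs, majors


def global_major_allele(pop_table: PopulationTable, site_id: str) -> Optional[str]:
    """Major allele pooled over all subpopulations (A<C<G<U tie-break)."""
    site = pop_table.counts[site_id]
    pooled = {nuc: 0 for nuc in NUC_ORDER}
    for counts in site.values():
        for nuc, c in counts.items():
            pooled[nuc] += c
    if sum(pooled.values()) == 0:
        return None
    return max(NUC_ORDER, key=lambda nuc: (pooled[nuc], -NUC_ORDER.index(nuc)))


def fst(
    frequencies: Sequence[float], snv_id: str = "", labels=None, ddof: int = 0
) -> FstResult:
    """Fixation index from per-subpopulation frequencies of one allele.

    sigma^2 is the population variance by default (divide by the number of
    subpopulations); ``ddof=1`` switches to the sample variance. F_ST is
    clipped to [0, 1] and missing (NaN) when the mean frequency is 0 or 1.
    """
    f = np.asarray(frequencies, dtype=float)
    if f.size < 2:
        raise ValueError("fst requires >= 2 subpopulation frequencies")
    if np.isnan(f).any() or (f < 0).any() or (f > 1).any():
        raise ValueError("frequencies must be in [0, 1]")
    pi_bar = float(np.mean(f))
    sigma2 = float(np.var(f, ddof=ddof))
    if pi_bar <= 0 or pi_bar >= 1:
        value = float("nan")
    else:
        value = min(1.0, max(0.0, sigma2 / (pi_bar * (1 - pi_bar))))
    freq_map = (
        dict(zip(labels, map(float, f))) if labels is not None
        else {str(i): float(v) for i, v in enumerate(f)}
    )
    return FstResult(
        snv_id=snv_id, frequencies=freq_map, pi_bar=pi_bar, sigma2_pi=sigma2, fst=value
    )


def fst_for_site(pop_table: PopulationTable, site_id: str) -> FstResult:
    """F_ST of the global major allele's frequency across subpopulations.

    For biallelic sites the result is identical whichever allele is tracked.
    Subpopulations with no calls at the site are excluded.
    """
    freqs, _ = allele_frequencies(pop_table, site_id)
    major = global_major_allele(pop_table, site_id)
    labels = [p for p in pop_table.subpopulations if freqs[p]]
    if major is None or len(labels) < 2:
        return FstResult(site_id, {}, float("nan"), float("nan"), float("nan"))
    f = [freqs[p].get(major, 0.0) for p in labels]
    return fst(f, snv_id=site_id, labels=labels)


def conservation_ratios(
    snvs: Sequence[SNVRecord],
    pop_table: PopulationTable,
    reference_population: str,
    site_id_of=None,
    allele_of=None,
    region: Optional[str] = None,
) -> List[ConservationResult]:
    """Per-transcript, per-class conservation ratio c(major)/c(total).

    An SNV counts toward c(major) when its reference-pair allele (the
    A-subgenome allele by default) equals the major allele of
    ``reference_population`` at its site. Untested SNVs (is_ribosnitch None)
    are skipped; ``region`` optionally restricts to one genic region.
    """
    # default site id: A-subgenome transcript and coordinate, as written by
    # the pipeline's VCF
    site_id_of = site_id_of or (lambda s: f"{s.pair_id.split('|')[0]}:{s.pos_a}")
    allele_of = allele_of or (lambda s: s.allele_a)
    acc: Dict[Tuple[str, str], List[int]] = {}
    for s in snvs:
        if s.is_ribosnitch is None:
            continue
        if region is not None and s.region != region:
            continue
        sid = site_id_of(s)
        if sid not in pop_table.counts:
            continue
        _, majors = allele_frequencies(pop_table, sid)
        major = majors.get(reference_population)
        if major is None:
            continue
        cls = "ribosnitch" if s.is_ribosnitch else "non_ribosnitch"
        key = (s.pair_id.split("|")[0], cls)
        acc.setdefault(key, []).append(int(allele_of(s) == major))
    return [
        ConservationResult(transcript_id=tid, snv_class=cls, c_major=sum(v), c_total=len(v))
        for (tid, cls), v in sorted(acc.items())
    ]


def class_contrast(
    values_ribosnitch: Sequence[float],
    values_non: Sequence[float],
    test: str = "t",
) -> Dict[str, float]:
    """Two-sample contrast of a statistic between riboSNitch and non classes.

    ``test`` is "t" (Student, equal variance) or "wilcoxon" (rank-sum).
    Requires >= 3 values per class. Returns p, means, medians and standard
    errors.
    """
    a = np.asarray(values_ribosnitch, dtype=float)
    b = np.asarray(values_non, dtype=float)
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    if a.size < 3 or b.size < 3:
        raise ValueError("class_contrast requires >= 3 values per class")
    if test == "t":
        p = float(stats.ttest_ind(a, b, equal_var=True).pvalue)
    elif test == "wilcoxon":
        p = float(stats.ranksums(a, b).pvalue)
    else:
        raise ValueError(f"unknown test {test!r}")
    if np.isnan(p):
        p = 1.0
    return {
        "p": p,
        "mean_ribosnitch": float(np.mean(a)),
        "mean_non": float(np.mean(b)),
        "median_ribosnitch": float(np.median(a)),
        "median_non": float(np.median(b)),
        "se_ribosnitch": float(np.std(a, ddof=1) / np.sqrt(a.size)),
        "se_non": float(np.std(b, ddof=1) / np.sqrt(b.size)),
        "n_ribosnitch": int(a.size),
        "n_non": int(b.size),
    }
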