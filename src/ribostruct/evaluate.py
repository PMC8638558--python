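"""Parameter-recovery and calibration benchmarks on synthetic data.

Each function regenerates its inputs from a seed, runs the relevant pipeline
stages and measures recovery against the generator's ground truth. These are
the quantities a user should inspect to judge whether the pipeline behaves
on data with known answers.
"""

from __future__ import annotations

from typing import Dict, List, Optional, Tuple

import numpy as np
from scipy import stats

from .asymmetry import pair_bpp_test
from .folding import EnergyModel, partition_function
from .reactivity import reactivity_pipeline
from .simulate import (
    SimulationConfig, simulate_expression, simulate_homoeolog_pairs,
    simulate_population, simulate_probing, simulate_switch_pairs, _rng,
)
from .translation import differential_te, translation_efficiency
from .variants import (
    align_pair, call_ribosnitches, extract_variants, finalize_ribosnitch_calls,
)
from . import io as rio


def te_recovery(seed: int, n_pairs: int = 50) -> Tuple[float, int]:
    """Pearson r between estimated and true log2 TE ratios.

    The estimate is the pipeline's own log-scale estimator (mean of
    per-replicate log2 TEs, A minus B).
    """
    cfg = SimulationConfig(seed=seed, n_pairs=n_pairs, mean_len=1000)
    pairs = simulate_homoeolog_pairs(cfg)
    counts, truth = simulate_expression(pairs, cfg)
    lengths = {r.transcript_id: r.length for p in pairs
               for r in (p.record_a, p.record_b)}
    te = translation_efficiency(counts, lengths)
    ids = [(p.record_a.transcript_id, p.record_b.transcript_id) for p in pairs]
    diff = differential_te(ids, te)
    merged = diff.merge(
        truth.assign(a_id=truth["pair_id"].str.split("|").str[0]), on="a_id"
    )
    r = float(stats.pearsonr(merged["log2_te_ratio"],
                             merged["true_log2_te_ratio"])[0])
    return r, len(merged)


def reactivity_auc(seed: int, min_positions: int = 5000) -> Tuple[float, int]:
    """AUC of normalized reactivity for unpaired vs paired positions.

    Truth labels are the ensemble-majority pairedness of the in-silico fold
    that drove the probing simulation. AUC is computed from the Mann-Whitney
    U statistic.
    """
    cfg = SimulationConfig(seed=seed, mean_len=200)
    model = EnergyModel()
    rng_seq = np.random.default_rng([20, seed])
    rng = np.random.default_rng([21, seed])
    labels: List[int] = []
    scores: List[float] = []
    k = 0
    while len(labels) < min_positions:
        seq = "".join(rng_seq.choice(list("ACGU"), size=200))
        from .types import TranscriptRecord
        rec = TranscriptRecord(f"auc{k}", seq)
        k += 1
        s = partition_function(seq, model, transcript_id=rec.transcript_id)
        stops = simulate_probing(rec, s, cfg, rng)
        profs, _ = reactivity_pipeline(stops)
        if not profs:
            continue
        react = profs[0].reactivity
        ok = ~np.isnan(react)
        paired = s.bpp > 0.5
        labels.extend((~paired[ok]).astype(int).tolist())
        scores.extend(react[ok].tolist())
    labels_arr = np.asarray(labels)
    scores_arr = np.asarray(scores)
    pos = scores_arr[labels_arr == 1]
    neg = scores_arr[labels_arr == 0]
    u = stats.mannwhitneyu(pos, neg, alternative="greater").statistic
    return float(u / (pos.size * neg.size)), len(labels)


def _process_switch_fixture(fx, cfg: SimulationConfig, rng, model: EnergyModel):
    """Full chain for one fixture: fold, probe, reactivity, in vivo fold, call."""
    sa = partition_function(fx.record_a.sequence, model)
    sb = partition_function(fx.record_b.sequence, model)
    stops = (simulate_probing(fx.record_a, sa, cfg, rng)
             + simulate_probing(fx.record_b, sb, cfg, rng))
    profs, _ = reactivity_pipeline(stops)
    pr = {p.transcript_id: p for p in profs}
    ra = pr[fx.record_a.transcript_id].reactivity
    rb = pr[fx.record_b.transcript_id].reactivity
    va = partition_function(fx.record_a.sequence, model, ra)
    vb = partition_function(fx.record_b.sequence, model, rb)
    pair = align_pair(fx.record_a.sequence, fx.record_b.sequence,
                      fx.record_a.transcript_id, fx.record_b.transcript_id)
    extract_variants(pair, fx.record_a, fx.record_b)
    call_ribosnitches(pair, va.bpp, vb.bpp, ra, rb)
    n_flipped = int((np.abs(sa.bpp - sb.bpp) >= 0.5).sum())
    return pair.snvs, n_flipped


def ribosnitch_power_and_fpr(
    seed: int, n_power: int = 20, n_null: int = 40, alpha: float = 0.05
) -> Dict[str, float]:
    """Call rate on structure-flipping SNVs and on structure-neutral SNVs.

    Power counts only fixtures whose in-silico folds verify the flip
    (|delta bpp| >= 0.5 at >= 10 positions); the false-positive rate is over
    SNVs whose construct leaves the structure unchanged by design.
    """
    cfg = SimulationConfig(seed=seed)
    model = EnergyModel()
    rng = _rng(cfg, 5)
    power_snvs, null_snvs = [], []
    n_qualified = 0
    flip_called = 0
    for fx in simulate_switch_pairs(cfg, n_power):
        snvs, n_flipped = _process_switch_fixture(fx, cfg, rng, model)
        if n_flipped >= 10:
            n_qualified += 1
            power_snvs.extend(snvs)
    for fx in simulate_switch_pairs(cfg, n_null, null=True):
        snvs, _ = _process_switch_fixture(fx, cfg, rng, model)
        null_snvs.extend(snvs)
    finalize_ribosnitch_calls(power_snvs + null_snvs, alpha=alpha)
    tested_power = [s for s in power_snvs if s.is_ribosnitch is not None]
    tested_null = [s for s in null_snvs if s.is_ribosnitch is not None]
    power = (sum(1 for s in tested_power if s.is_ribosnitch) / len(tested_power)
             if tested_power else float("nan"))
    fpr = (sum(1 for s in tested_null if s.is_ribosnitch) / len(tested_null)
           if tested_null else float("nan"))
    return {"power": power, "fpr": fpr, "n_qualified": n_qualified,
            "n_power_snvs": len(tested_power), "n_null_snvs": len(tested_null)}


def allele_frequency_rmse(
    seed: int, n_sites: int = 40, accessions_per_pop: int = 50, tmpdir=None
) -> Dict[str, float]:
    """Per-subpopulation RMSE of estimated vs generating allele frequencies.

    Genotypes are written to VCF and read back through the population reader,
    so the whole IO path is exercised. 0.05 is the worst-case binomial
    standard error at 100 chromosomes per subpopulation.
    """
    import tempfile
    from pathlib import Path

    cfg = SimulationConfig(
        seed=seed, pop_sizes={"DW": accessions_per_pop, "DEW": accessions_per_pop,
                              "WEW": accessions_per_pop}
    )
    sites = [(f"t{i}:0", f"t{i}", 0, "A", "G", i < max(1, n_sites // 8))
             for i in range(n_sites)]
    truths, vcf_sites, samples, popmap = simulate_population(sites, cfg)
    with tempfile.TemporaryDirectory(dir=tmpdir) as td:
        vcf = Path(td) / "pop.vcf"
        pm = Path(td) / "popmap.tsv"
        rio.write_vcf(vcf, vcf_sites, samples)
        pm.write_text("".join(f"{s}\t{p}\n" for s, p in sorted(popmap.items())))
        table = rio.read_vcf_population(vcf, pm)
    from .popgen import allele_frequencies
    errs: Dict[str, List[float]] = {p: [] for p in table.subpopulations}
    for t in truths:
        freqs, _ = allele_frequencies(table, t.site_id)
        for pop, true_f in t.true_freqs.items():
            errs[pop].append(freqs[pop].get("A", 0.0) - true_f)
    return {pop: float(np.sqrt(np.mean(np.square(e)))) for pop, e in errs.items()}


def te_null_calibration(seed: int, n_pairs: int = 1000,
                        alpha: float = 0.05) -> Tuple[float, int]:
    """BH-significant fraction under a complete TE null (te_logfc_sd = 0)."""
    cfg = SimulationConfig(seed=seed, n_pairs=n_pairs, mean_len=150,
                           te_logfc_sd=0.0)
    pairs = simulate_homoeolog_pairs(cfg)
    counts, _ = simulate_expression(pairs, cfg)
    lengths = {r.transcript_id: r.length for p in pairs
               for r in (p.record_a, p.record_b)}
    te = translation_efficiency(counts, lengths)
    ids = [(p.record_a.transcript_id, p.record_b.transcript_id) for p in pairs]
    diff = differential_te(ids, te, alpha=alpha)
    return float((diff["direction"] != "NSD").mean()), len(diff)


def bpp_null_calibration(seed: int, n_pairs: int = 40,
                         alpha: float = 0.05) -> Tuple[float, int]:
    """Wilcoxon BPP-pair significant fraction on structure-identical pairs.

    A and B share the sequence (hence the generating structure); only the
    probing noise differs, so any systematic BPP difference is spurious.
    """
    cfg = SimulationConfig(seed=seed, mean_len=150)
    model = EnergyModel()
    rng_seq = np.random.default_rng([30, seed])
    rng = np.random.default_rng([31, seed])
    n_sig = n_tested = 0
    for k in range(n_pairs):
        seq = "".join(rng_seq.choice(list("ACGU"), size=150))
        from .types import TranscriptRecord
        rec_a = TranscriptRecord(f"null{k}_A", seq)
        rec_b = TranscriptRecord(f"null{k}_B", seq)
        s = partition_function(seq, model)
        profs_a, _ = reactivity_pipeline(simulate_probing(rec_a, s, cfg, rng))
        profs_b, _ = reactivity_pipeline(simulate_probing(rec_b, s, cfg, rng))
        if not profs_a or not profs_b:
            continue
        va = partition_function(seq, model, profs_a[0].reactivity)
        vb = partition_function(seq, model, profs_b[0].reactivity)
        p, direction = pair_bpp_test(va.bpp, vb.bpp, alpha=alpha)
        n_tested += 1
        n_sig += int(direction != "NSD")
    return (n_sig / n_tested if n_tested else float("nan")), n_tested
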