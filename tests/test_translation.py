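import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ribostruct.simulate import SimulationConfig, simulate_expression, simulate_homoeolog_pairs
from ribostruct.translation import (
    CodonUsageTable, TAIWeights, cai, differential_te, gc_content,
    metagene_profile, periodicity_3nt, tai, te_covariate_correlations,
    translation_efficiency,
)
from ribostruct.types import ReactivityProfile, TranscriptRecord


def _counts(rows):
    return pd.DataFrame(
        rows, columns=["transcript_id", "replicate", "rna_count", "polysome_count"]
    )


class TestTranslationEfficiency:
    def test_ratio_of_abundances(self):
        counts = _counts([("a", 1, 10, 20), ("b", 1, 10, 10)])
        te = translation_efficiency(counts, {"a": 100, "b": 100})
        te_map = dict(zip(te["transcript_id"], te["te"]))
        # equal lengths: abundance ratios reduce to count ratios up to the
        # common per-million factor, which cancels in the poly/rna ratio scale
        assert te_map["a"] / te_map["b"] == pytest.approx(2.0)

    def test_zero_rna_missing(self):
        counts = _counts([("a", 1, 0, 5), ("b", 1, 10, 5)])
        te = translation_efficiency(counts, {"a": 100, "b": 100})
        assert np.isnan(te.set_index("transcript_id").loc["a", "te"])

    def test_poly_equal_rna_gives_unit_te(self):
        counts = _counts([("a", 1, 7, 7), ("b", 1, 13, 13), ("a", 2, 5, 5), ("b", 2, 11, 11)])
        te = translation_efficiency(counts, {"a": 50, "b": 80})
        assert np.allclose(te["te"], 1.0)


class TestGcContent:
    @pytest.mark.parametrize("seq,expected", [("GCGC", 1.0), ("AUAU", 0.0), ("GCAU", 0.5)])
    def test_values(self, seq, expected):
        assert gc_content(seq) == pytest.approx(expected)

    def test_region_restriction(self):
        assert gc_content("GGGGAAAA", region=(4, 8)) == 0.0


class TestCodonIndices:
    def test_cai_all_optimal_codons(self):
        usage = CodonUsageTable({"AAA": 100, "AAG": 25, "GAA": 60, "GAG": 10})
        assert cai("AAAGAA", usage) == pytest.approx(1.0)

    def test_cai_geometric_mean_closed_form(self):
        usage = CodonUsageTable({"AAA": 100, "AAG": 25})
        assert cai("AAAAAG", usage) == pytest.approx(0.5)  # sqrt(1 * 0.25)

    def test_cai_constant_weights(self):
        usage = CodonUsageTable({"CAU": 80, "CAC": 100})
        assert cai("CAUCAUCAU", usage) == pytest.approx(0.8)

    def test_tai_closed_forms(self):
        w = TAIWeights({"AAA": 1.0, "AAG": 0.25})
        assert tai("AAAAAA", w) == pytest.approx(1.0)
        assert tai("AAAAAG", w) == pytest.approx(0.5)
        w2 = TAIWeights({"AAA": 0.5, "AAG": 0.5})
        assert tai("AAAAAG", w2) == pytest.approx(1.0)  # renormalized to max 1

    def test_log_space_matches_direct_product(self):
        rng = np.random.default_rng(0)
        codons = ["AAA", "AAG", "GAA", "GAG", "CAU", "CAC"]
        w = {c: float(rng.uniform(0.05, 1.0)) for c in codons}
        w["AAA"] = 1.0
        weights = TAIWeights(dict(w))
        cds = "".join(rng.choice(codons, size=40))
        direct = np.prod([weights.w[cds[i:i + 3]] for i in range(0, len(cds), 3)]) ** (1 / 40)
        assert tai(cds, weights) == pytest.approx(direct, abs=1e-12)

    def test_stop_codon_excluded_and_unknown_rejected(self):
        usage = CodonUsageTable({"AAA": 10})
        assert cai("AAAUAA", usage) == pytest.approx(1.0)  # UAA is a stop
        with pytest.raises(KeyError):
            cai("GGG", usage)


class TestDifferentialTE:
    def _te_table(self, a_reps, b_reps):
        return pd.DataFrame(
            {"transcript_id": ["a", "b"], "te_rep": [a_reps, b_reps],
             "te": [np.mean(a_reps), np.mean(b_reps)]}
        )

    def test_identical_replicates_nsd(self):
        te = self._te_table([2.0, 2.0, 2.0], [2.0, 2.0, 2.0])
        out = differential_te([("a", "b")], te)
        assert out.loc[0, "direction"] == "NSD"
        assert out.loc[0, "p"] == pytest.approx(1.0)

    def test_clear_difference_significant_with_t_oracle(self):
        a, b = [2.0, 2.1, 1.9], [1.0, 1.05, 0.95]
        out = differential_te([("a", "b")], self._te_table(a, b))
        expected_p = stats.ttest_ind(np.log2(a), np.log2(b), equal_var=True).pvalue
        assert out.loc[0, "p"] == pytest.approx(expected_p)
        assert out.loc[0, "direction"] == "A_higher"

    def test_single_replicate_pair_excluded(self):
        te = self._te_table([2.0], [1.0, 1.1, 0.9])
        out = differential_te([("a", "b")], te)
        assert len(out) == 0

    def test_bh_adjustment_monotone_in_raw_p(self):
        rng = np.random.default_rng(1)
        rows = []
        pairs = []
        for k in range(40):
            a = list(2.0 + rng.normal(0, 0.3, 3))
            b = list(2.0 + rng.normal(0, 0.3, 3))
            rows += [(f"a{k}", a), (f"b{k}", b)]
            pairs.append((f"a{k}", f"b{k}"))
        te = pd.DataFrame(rows, columns=["transcript_id", "te_rep"])
        te["te"] = te["te_rep"].map(np.mean)
        out = differential_te(pairs, te).sort_values("p")
        assert out["p_adj"].is_monotonic_increasing
        assert ((out["p_adj"] >= 0) & (out["p_adj"] <= 1)).all()

    def test_all_null_simulation_controls_significant_fraction(self):
        cfg = SimulationConfig(seed=13, n_pairs=300, mean_len=300, te_logfc_sd=0.0)
        sims = simulate_homoeolog_pairs(cfg)
        counts, _ = simulate_expression(sims, cfg)
        lengths = {r.transcript_id: r.length for p in sims for r in (p.record_a, p.record_b)}
        te = translation_efficiency(counts, lengths)
        pairs = [(p.record_a.transcript_id, p.record_b.transcript_id) for p in sims]
        out = differential_te(pairs, te)
        assert (out["direction"] != "NSD").mean() <= 0.07


class TestCovariateCorrelations:
    def test_self_correlation(self):
        te = pd.Series(np.exp2(np.linspace(1, 3, 50)))
        cov = pd.DataFrame({"log2te": np.log2(te)})
        out = te_covariate_correlations(te, cov)
        assert out.loc[0, "r"] == pytest.approx(1.0)

    def test_affine_invariance(self):
        te = pd.Series(np.exp2(np.linspace(1, 3, 50)))
        cov = pd.DataFrame({"x": 2 * np.log2(te) + 5})
        out = te_covariate_correlations(te, cov)
        assert out.loc[0, "r"] == pytest.approx(1.0)

    def test_independent_covariate_near_zero(self):
        rng = np.random.default_rng(2)
        te = pd.Series(np.exp2(rng.normal(0, 1, 1000)))
        cov = pd.DataFrame({"x": rng.normal(0, 1, 1000)})
        out = te_covariate_correlations(te, cov)
        assert abs(out.loc[0, "r"]) < 0.1


class TestMetagene:
    def _setup(self, n=10, length=60, react_fn=None):
        recs, reacts, te_rows = {}, {}, []
        for k in range(n):
            tid = f"t{k}"
            rec = TranscriptRecord(tid, "A" * length, 15, 45)
            recs[tid] = rec
            te = float(k + 1)
            vals = np.full(length, 0.5) if react_fn is None else react_fn(k, length)
            reacts[tid] = ReactivityProfile(tid, vals, ~np.isnan(vals))
            te_rows.append((tid, te))
        te_table = pd.DataFrame(te_rows, columns=["transcript_id", "te"])
        return recs, reacts, te_table

    def test_flat_input_flat_profiles(self):
        recs, reacts, te_table = self._setup()
        hi, lo = metagene_profile(reacts, recs, te_table)
        np.testing.assert_allclose(hi[~np.isnan(hi)], 0.5)
        np.testing.assert_allclose(lo[~np.isnan(lo)], 0.5)

    def test_half_decile_splits_evenly(self):
        recs, reacts, te_table = self._setup(n=10)
        offset = lambda k, length: np.full(length, 0.2 + (0.2 if k >= 5 else 0.0))
        recs, reacts, te_table = self._setup(n=10, react_fn=offset)
        hi, lo = metagene_profile(reacts, recs, te_table, decile=0.5)
        np.testing.assert_allclose(hi - lo, 0.2, atol=1e-12)

    def test_constructed_offset_recovered(self):
        def react_fn(k, length):
            base = np.full(length, 0.4)
            return base + (0.2 if k >= 9 else 0.0)

        recs, reacts, te_table = self._setup(n=10, react_fn=react_fn)
        hi, lo = metagene_profile(reacts, recs, te_table, decile=0.10)
        np.testing.assert_allclose(hi - lo, 0.2, atol=1e-12)


class TestPeriodicity:
    def test_flat_profile_zero(self):
        assert periodicity_3nt(np.full(60, 0.7)) == pytest.approx(0.0, abs=1e-12)

    def test_pure_codon_signal_unity(self):
        x = np.tile([1.0, 0.0, 0.0], 20)
        assert periodicity_3nt(x) == pytest.approx(1.0)

    def test_offset_strictly_decreases_score(self):
        base = np.tile([1.0, 0.0, 0.0], 20)
        scores = [periodicity_3nt(base + c) for c in (0.0, 0.5, 1.0)]
        assert scores[0] > scores[1] > scores[2]

    def test_missing_codons_dropped_in_frame(self):
        x = np.tile([1.0, 0.0, 0.0], 30)
        x[31] = np.nan  # kills codon 10; frame must be preserved
        assert periodicity_3nt(x) == pytest.approx(1.0)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            periodicity_3nt(np.ones(20))
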