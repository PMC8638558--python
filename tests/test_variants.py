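import numpy as np
import pytest
from scipy import stats

from ribostruct.folding import partition_function
from ribostruct.reactivity import reactivity_pipeline
from ribostruct.simulate import SimulationConfig, simulate_probing, simulate_switch_pairs
from ribostruct.types import HomoeologPair, TranscriptRecord
from ribostruct.variants import (
    align_pair, call_ribosnitches, esdc, esdc_snv_correlation, extract_variants,
    finalize_ribosnitch_calls, mutation_class, project_to_alignment,
    ribosnitch_region_ratios, snv_ratio,
)

from .conftest import random_rna
from .oracles import brute_force_alignment_score


class TestAlignPair:
    def test_identical_sequences_gapless_full_score(self):
        pair = align_pair("ACGUACGU", "ACGUACGU")
        assert pair.aligned_a == pair.aligned_b == "ACGUACGU"
        assert pair.score == 8.0

    def test_single_mismatch_column(self):
        pair = align_pair("ACGU", "AGGU")
        assert pair.aligned_a == "ACGU" and pair.aligned_b == "AGGU"
        snvs, _ = extract_variants(pair)
        assert len(snvs) == 1 and snvs[0].pos_a == 1

    @pytest.mark.parametrize("trial", range(12))
    def test_score_matches_brute_force(self, trial):
        rng = np.random.default_rng(200 + trial)
        a = random_rna(rng, int(rng.integers(3, 9)))
        b = random_rna(rng, int(rng.integers(3, 9)))
        pair = align_pair(a, b)
        assert pair.score == pytest.approx(brute_force_alignment_score(a, b))

    def test_ungapping_recovers_inputs(self):
        a, b = "ACGUACGUCC", "ACGACGUCC"
        pair = align_pair(a, b)
        assert pair.ungapped("A") == a and pair.ungapped("B") == b

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            align_pair("", "ACGU")


class TestExtractVariants:
    def test_no_mismatches_no_snvs(self):
        pair = align_pair("ACGUACGU", "ACGUACGU")
        snvs, indels = extract_variants(pair)
        assert snvs == [] and indels == []

    @pytest.mark.parametrize("a,b,expected", [("A", "G", "transition"),
                                              ("C", "U", "transition"),
                                              ("A", "C", "transversion"),
                                              ("G", "U", "transversion")])
    def test_mutation_classes(self, a, b, expected):
        assert mutation_class(a, b) == expected

    def test_n_columns_dropped(self):
        pair = HomoeologPair("a", "b", "ANGU", "AUGU")
        snvs, _ = extract_variants(pair)
        assert snvs == []

    def test_column_accounting_invariant(self):
        rng = np.random.default_rng(3)
        a = random_rna(rng, 60)
        b = random_rna(rng, 55)
        pair = align_pair(a, b)
        snvs, _ = extract_variants(pair)
        ncol = len(pair.aligned_a)
        gap_cols = sum(1 for x, y in zip(pair.aligned_a, pair.aligned_b)
                       if x == "-" or y == "-")
        match_cols = sum(1 for x, y in zip(pair.aligned_a, pair.aligned_b)
                         if x == y and x != "-")
        n_cols = sum(1 for x, y in zip(pair.aligned_a, pair.aligned_b)
                     if "-" not in (x, y) and ("N" in (x, y)) and x != y)
        assert len(snvs) + match_cols + n_cols + gap_cols == ncol

    def test_region_assignment_from_a_annotation(self):
        rec_a = TranscriptRecord("a", "ACGUACGUA", 3, 6)
        rec_b = TranscriptRecord("b", "ACGAACGUA", 3, 6)
        pair = align_pair(rec_a.sequence, rec_b.sequence, "a", "b")
        snvs, _ = extract_variants(pair, rec_a, rec_b)
        assert snvs[0].region == "cds" and not snvs[0].region_discordant

    def test_snv_ratio_uses_ungapped_columns(self):
        pair = align_pair("ACGUACGU", "AGGUACGU")
        extract_variants(pair)
        assert snv_ratio(pair) == pytest.approx(1 / 8)


class TestEsdc:
    def _pair(self, n):
        seq = "A" * n
        return align_pair(seq, seq)

    def test_identical_profiles_zero(self):
        rng = np.random.default_rng(0)
        v = rng.uniform(0, 2, 50)
        assert esdc(v, v.copy(), self._pair(50)) == pytest.approx(0.0)

    def test_closed_form_r_half_L_100(self):
        rng = np.random.default_rng(1)
        x = rng.normal(0, 1, 100)
        x = (x - x.mean()) / x.std()
        y = rng.normal(0, 1, 100)
        y -= y.mean()
        y -= x * (x @ y) / (x @ x)  # orthogonalize
        y /= y.std()
        b = 0.5 * x + np.sqrt(0.75) * y  # exact Pearson r = 0.5 with x
        a_prof, b_prof = x + 5.0, b + 5.0  # shift to be reactivity-like
        val = esdc(a_prof, b_prof, self._pair(100))
        assert val == pytest.approx(0.5 * 10.0, abs=1e-9)

    def test_anticorrelated_bound(self):
        v = np.linspace(0, 2, 100)
        assert esdc(v, v[::-1].copy(), self._pair(100)) == pytest.approx(20.0)

    def test_shift_and_scale_invariance(self):
        rng = np.random.default_rng(2)
        a = rng.uniform(0, 2, 60)
        b = rng.uniform(0, 2, 60)
        pair = self._pair(60)
        base = esdc(a, b, pair)
        assert esdc(a + 3.0, b + 3.0, pair) == pytest.approx(base)
        assert esdc(a * 2.0, b * 2.0, pair) == pytest.approx(base)

    def test_too_few_shared_columns_missing(self):
        assert np.isnan(esdc(np.ones(10), np.ones(10), self._pair(10)))


class TestRiboSnitchCalling:
    def _run_fixture(self, fixtures, seed=5):
        cfg = SimulationConfig(seed=seed)
        rng = np.random.default_rng([41, seed])
        all_snvs = []
        qualified = []
        for fx in fixtures:
            sa = partition_function(fx.record_a.sequence)
            sb = partition_function(fx.record_b.sequence)
            stops = (simulate_probing(fx.record_a, sa, cfg, rng)
                     + simulate_probing(fx.record_b, sb, cfg, rng))
            profs, _ = reactivity_pipeline(stops)
            pr = {p.transcript_id: p for p in profs}
            ra = pr[fx.record_a.transcript_id].reactivity
            rb = pr[fx.record_b.transcript_id].reactivity
            va = partition_function(fx.record_a.sequence, reactivity=ra)
            vb = partition_function(fx.record_b.sequence, reactivity=rb)
            pair = align_pair(fx.record_a.sequence, fx.record_b.sequence,
                              fx.record_a.transcript_id, fx.record_b.transcript_id)
            extract_variants(pair, fx.record_a, fx.record_b)
            call_ribosnitches(pair, va.bpp, vb.bpp, ra, rb)
            all_snvs.extend(pair.snvs)
            d = np.abs(sa.bpp - sb.bpp)
            qualified.append(int((d >= 0.5).sum()) >= 10)
        finalize_ribosnitch_calls(all_snvs)
        return all_snvs, qualified

    def test_structure_flipping_snv_called(self):
        cfg = SimulationConfig(seed=5)
        fixtures = simulate_switch_pairs(cfg, 3)
        snvs, qualified = self._run_fixture(fixtures)
        assert all(qualified)
        assert all(s.is_ribosnitch for s in snvs)

    def test_null_snv_not_called(self):
        cfg = SimulationConfig(seed=6)
        fixtures = simulate_switch_pairs(cfg, 6, null=True)
        snvs, _ = self._run_fixture(fixtures, seed=6)
        assert not any(s.is_ribosnitch for s in snvs)

    def test_calls_symmetric_in_ab_labels(self):
        cfg = SimulationConfig(seed=7)
        (fx,) = simulate_switch_pairs(cfg, 1)
        rng = np.random.default_rng([42, 7])
        sa = partition_function(fx.record_a.sequence)
        sb = partition_function(fx.record_b.sequence)
        stops = (simulate_probing(fx.record_a, sa, cfg, rng)
                 + simulate_probing(fx.record_b, sb, cfg, rng))
        profs, _ = reactivity_pipeline(stops)
        pr = {p.transcript_id: p for p in profs}
        ra = pr[fx.record_a.transcript_id].reactivity
        rb = pr[fx.record_b.transcript_id].reactivity
        va = partition_function(fx.record_a.sequence, reactivity=ra)
        vb = partition_function(fx.record_b.sequence, reactivity=rb)

        fwd = align_pair(fx.record_a.sequence, fx.record_b.sequence, "a", "b")
        extract_variants(fwd)
        call_ribosnitches(fwd, va.bpp, vb.bpp, ra, rb)
        finalize_ribosnitch_calls(fwd.snvs)

        rev = align_pair(fx.record_b.sequence, fx.record_a.sequence, "b", "a")
        extract_variants(rev)
        call_ribosnitches(rev, vb.bpp, va.bpp, rb, ra)
        finalize_ribosnitch_calls(rev.snvs)
        assert [s.is_ribosnitch for s in fwd.snvs] == [s.is_ribosnitch for s in rev.snvs]


class TestRegionRatios:
    def _snv(self, region, called, pair_id="p"):
        from ribostruct.types import SNVRecord
        s = SNVRecord(pair_id, 0, 0, "A", "G", "transition", region=region)
        s.is_ribosnitch = called
        return s

    def test_zero_ribosnitches(self):
        snvs = [self._snv("cds", False) for _ in range(10)]
        assert ribosnitch_region_ratios(snvs)["cds"] == 0.0

    def test_ratio_arithmetic(self):
        snvs = [self._snv("cds", i < 2) for i in range(100)]
        assert ribosnitch_region_ratios(snvs)["cds"] == pytest.approx(0.02)

    def test_order_invariance(self):
        snvs = ([self._snv("utr5", True)] + [self._snv("utr5", False)] * 3
                + [self._snv("utr3", False)] * 2)
        fwd = ribosnitch_region_ratios(snvs)
        rev = ribosnitch_region_ratios(snvs[::-1])
        for key in fwd:
            assert fwd[key] == pytest.approx(rev[key], nan_ok=True)

    def test_untested_excluded_by_default_counted_in_strict(self):
        snvs = [self._snv("cds", True), self._snv("cds", None), self._snv("cds", False)]
        assert ribosnitch_region_ratios(snvs)["cds"] == pytest.approx(0.5)
        assert ribosnitch_region_ratios(snvs, strict=True)["cds"] == pytest.approx(1 / 3)


class TestEsdcSnvCorrelation:
    def test_identical_pairs_undefined(self):
        pairs = []
        for _ in range(5):
            p = align_pair("ACGUACGU" * 5, "ACGUACGU" * 5)
            extract_variants(p)
            p.esdc = 0.0
            pairs.append(p)
        out = esdc_snv_correlation(pairs)
        assert np.isnan(out.set_index("covariate").loc["snv_count", "r"])

    def test_permuted_esdc_near_zero(self):
        rng = np.random.default_rng(11)
        pairs = []
        for k in range(500):
            p = HomoeologPair("a", "b", "ACGU", "ACGU")
            p.snvs = [None] * int(rng.integers(0, 20))
            p.esdc = float(rng.uniform(0, 10))
            pairs.append(p)
        out = esdc_snv_correlation(pairs)
        assert abs(out.set_index("covariate").loc["snv_count", "r"]) < 0.1

    def test_snv_driven_divergence_detected(self):
        """More substitutions -> larger reactivity divergence -> higher eSDC."""
        rng = np.random.default_rng(12)
        cfg = SimulationConfig(seed=12)
        rng_probe = np.random.default_rng([43, 12])
        pairs = []
        for k in range(25):
            rate = rng.uniform(0.0, 0.15)
            seq_a = random_rna(rng, 120)
            chars = list(seq_a)
            for i in range(len(chars)):
                if rng.random() < rate:
                    chars[i] = {"A": "G", "G": "A", "C": "U", "U": "C"}[chars[i]]
            seq_b = "".join(chars)
            rec_a = TranscriptRecord(f"x{k}_A", seq_a)
            rec_b = TranscriptRecord(f"x{k}_B", seq_b)
            sa = partition_function(seq_a)
            sb = partition_function(seq_b)
            stops = (simulate_probing(rec_a, sa, cfg, rng_probe)
                     + simulate_probing(rec_b, sb, cfg, rng_probe))
            profs, _ = reactivity_pipeline(stops)
            pr = {p.transcript_id: p for p in profs}
            pair = align_pair(seq_a, seq_b, rec_a.transcript_id, rec_b.transcript_id)
            extract_variants(pair)
            pair.esdc = esdc(pr[rec_a.transcript_id].reactivity,
                             pr[rec_b.transcript_id].reactivity, pair)
            pairs.append(pair)
        out = esdc_snv_correlation(pairs)
        assert out.set_index("covariate").loc["snv_count", "r"] > 0.5
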