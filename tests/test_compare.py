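"""Comparative statistics: adjusted correlations, stepwise cutoffs,
resampling machinery and top-difference selection."""

import numpy as np
import pytest

import rohtrack as rt
from _oracles import partial_correlation_one_covariate


class TestSnpDensity:
    def test_uniform_spacing(self):
        positions = np.arange(1, 501) * 10_000  # 1 SNP / 10 kb
        m = rt.SnpMap(
            snp_id=np.array([f"s{i}" for i in range(500)], dtype=object),
            chromosome=np.full(500, 1),
            position_bp=positions,
        )
        d = rt.local_snp_density(m, window_bp=1_000_000)
        interior = d[60:440]
        assert np.all(np.abs(interior - 100.0) <= 1.0)

    def test_single_snp(self):
        m = rt.SnpMap(
            snp_id=np.array(["only"], dtype=object),
            chromosome=np.array([1]),
            position_bp=np.array([5_000_000]),
        )
        assert rt.local_snp_density(m, 1_000_000)[0] == pytest.approx(1.0)

    def test_matches_linear_scan(self, small_map):
        d = rt.local_snp_density(small_map, 800_000)
        for j in (0, 17, 150, 299, 300, 450, 599):
            c, p = small_map.chromosome[j], small_map.position_bp[j]
            n = sum(
                1
                for k in range(len(small_map))
                if small_map.chromosome[k] == c
                and abs(int(small_map.position_bp[k]) - int(p)) <= 400_000
            )
            assert d[j] == pytest.approx(n / 0.8)


class TestAdjustedCorrelation:
    def test_no_covariates_is_plain_pearson(self, rng):
        a, b = rng.random(200), rng.random(200)
        res = rt.adjusted_correlation(a, b)
        assert res.r == pytest.approx(np.corrcoef(a, b)[0, 1], abs=1e-12)
        assert not res.undefined

    def test_identical_tracks(self, rng):
        a = rng.random(100)
        res = rt.adjusted_correlation(a, a)
        assert res.r == pytest.approx(1.0)
        assert res.p_raw < 1e-100

    def test_track_equal_to_covariate_flagged(self, rng):
        a, c = rng.random(100), rng.random(100)
        res = rt.adjusted_correlation(a, c, {"cov": c})
        assert res.undefined
        assert np.isnan(res.r)

    def test_matches_partial_correlation_recursion(self, rng):
        for _ in range(10):
            c = rng.random(150)
            a = 0.5 * c + rng.random(150)
            b = -0.3 * c + rng.random(150)
            res = rt.adjusted_correlation(a, b, {"cov": c})
            assert res.r == pytest.approx(
                partial_correlation_one_covariate(a, b, c), abs=1e-10
            )

    def test_bonferroni_scaling(self, rng):
        a = rng.random(50)
        b = a + rng.normal(0, 0.5, 50)
        res = rt.adjusted_correlation(a, b, alpha_adjust_n=1000)
        assert res.p_bonferroni == pytest.approx(min(1.0, res.p_raw * 1000))


class TestFraProximityCorrelation:
    def test_no_fra_chromosome_flagged_na(self, small_map, rng):
        track = rt.FrequencyTrack(rng.random(len(small_map)), "rohf", "", 10)
        fras = [rt.FragileSite("FRA1A", "1q21", 1, 5_000_000, 7_000_000, 6_000_000)]
        res = rt.fra_proximity_correlation(track, small_map, fras, radius_bp=2_000_000)
        assert res["2"].undefined          # chromosome without any FRA
        assert not res["1"].undefined

    def test_track_equal_to_indicator(self, small_map):
        fras = [rt.FragileSite("FRA1A", "1q21", 1, 5_000_000, 7_000_000, 6_000_000)]
        indicator = np.zeros(len(small_map))
        loci = small_map.locus_indices(1, 4_000_000, 8_000_000)
        indicator[loci] = 1.0
        track = rt.FrequencyTrack(indicator, "rohf", "", 10)
        res = rt.fra_proximity_correlation(track, small_map, fras, radius_bp=2_000_000)
        assert res["1"].r == pytest.approx(1.0)
        assert res["all"].r == pytest.approx(np.corrcoef(indicator, indicator)[0, 1])


class TestStepwise:
    def test_no_cutoff_equals_plain_correlation(self, rng):
        a, b = rng.random(300), rng.random(300)
        (q, n, r), *_ = rt.stepwise_cutoff_correlation(a, b, [0.0])
        assert n == 300
        assert r == pytest.approx(np.corrcoef(a, b)[0, 1])

    def test_identical_tracks_r_one_everywhere(self, rng):
        a = rng.random(400)
        for q, n, r in rt.stepwise_cutoff_correlation(a, a, [0.0, 0.3, 0.6, 0.9]):
            assert r == pytest.approx(1.0)

    def test_non_increasing_quantiles_rejected(self, rng):
        a = rng.random(50)
        with pytest.raises(ValueError):
            rt.stepwise_cutoff_correlation(a, a, [0.5, 0.2])


class TestResampling:
    def test_identical_cohorts_no_significance(self, rng):
        states = rng.random((30, 500)) < 0.2
        res = rt.adult_young_resampling(states, states, n_iter=20,
                                        subsample_size=30, seed=1)
        assert res.n_significant == 0
        assert res.proportion is None
        assert res.n_positive == 0

    def test_reproducible_and_counts_consistent(self, rng):
        adult = rng.random((60, 400)) < 0.25
        young = rng.random((30, 400)) < 0.2
        a = rt.adult_young_resampling(adult, young, n_iter=50, subsample_size=30, seed=9)
        b = rt.adult_young_resampling(adult, young, n_iter=50, subsample_size=30, seed=9)
        assert (a.n_positive, a.n_significant, a.n_significant_positive) == (
            b.n_positive, b.n_significant, b.n_significant_positive
        )
        np.testing.assert_array_equal(a.mean_adult_track, b.mean_adult_track)
        assert a.n_significant_positive <= a.n_significant <= a.n_iter
        assert a.n_positive <= a.n_iter

    def test_published_proportion_arithmetic(self):
        # 552 significant-positive of 747 significant -> 73.9%
        assert round(100 * 552 / 747, 1) == 73.9
        assert round(100 * 686 / 743, 1) == 92.3

    def test_oversized_subsample_rejected(self, rng):
        states = rng.random((10, 50)) < 0.2
        with pytest.raises(ValueError, match="exceeds"):
            rt.adult_young_resampling(states, states, n_iter=5, subsample_size=30)

    def test_mean_adult_track_is_mean_of_subsample_tracks(self, rng):
        adult = rng.random((40, 100)) < 0.3
        young = rng.random((30, 100)) < 0.3
        res = rt.adult_young_resampling(adult, young, n_iter=200,
                                        subsample_size=30, seed=2)
        # the accumulated mean track stays inside the cohort's ROHF envelope
        full = adult.mean(axis=0)
        assert np.all(res.mean_adult_track >= 0) and np.all(res.mean_adult_track <= 1)
        assert np.abs(res.mean_adult_track - full).max() < 0.15


class TestTopDiff:
    def test_full_selection_cutoff_is_minimum(self, rng):
        a, b = rng.random(80), rng.random(80)
        res = rt.top_diff_snps(a, b, 80)
        assert res.cutoff_value == pytest.approx((a - b).min())
        assert len(res.indices) == 80

    def test_constant_difference(self):
        a = np.full(50, 0.7)
        b = np.full(50, 0.2)
        res = rt.top_diff_snps(a, b, 10)
        assert res.cutoff_value == pytest.approx(0.5)
        assert res.n_ties_at_cutoff == 50
        # ties broken by map order: first 10 loci selected
        assert res.indices.tolist() == list(range(10))

    def test_matches_full_sort_oracle(self, rng):
        for _ in range(10):
            a, b = rng.random(120), rng.random(120)
            d = a - b
            res = rt.top_diff_snps(a, b, 25)
            expected = set(np.argsort(-d, kind="stable")[:25].tolist())
            assert set(res.indices.tolist()) == expected
            assert res.cutoff_value == pytest.approx(sorted(d, reverse=True)[24])
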