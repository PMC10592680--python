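"""Balancing-selection test battery: F_ST, U tests, het excess, dispersion."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from _oracles import brute_mann_whitney
from agerank import matched_ranks as mr
from agerank import selection_tests as st_mod
from agerank.io_formats import GeneticMap
from agerank.synthetic_data import het_count_distribution


class TestHudsonFst:
    def test_fixed_difference_is_one(self):
        assert st_mod.hudson_fst(0, 100, 100, 100) == pytest.approx(1.0)

    def test_equal_frequencies_vanish_in_large_n(self):
        small = st_mod.hudson_fst(5, 10, 5, 10)
        assert small < 0  # finite-sample value slightly negative
        big = st_mod.hudson_fst(50_000, 100_000, 50_000, 100_000)
        assert abs(big) < 1e-3

    def test_large_n_closed_form(self):
        n = 10**7
        fst = st_mod.hudson_fst(int(0.2 * n), n, int(0.8 * n), n)
        assert fst == pytest.approx(0.36 / 0.68, abs=1e-6)

    def test_population_exchange_symmetry(self, rng):
        for _ in range(20):
            n1, n2 = rng.integers(2, 50, size=2)
            k1, k2 = rng.integers(0, n1 + 1), rng.integers(0, n2 + 1)
            a = st_mod.hudson_fst(k1, n1, k2, n2)
            b = st_mod.hudson_fst(k2, n2, k1, n1)
            assert a == pytest.approx(b, rel=1e-12) or (np.isnan(a) and np.isnan(b))

    def test_allele_label_swap_invariance(self, rng):
        for _ in range(20):
            n1, n2 = rng.integers(2, 50, size=2)
            k1, k2 = rng.integers(0, n1 + 1), rng.integers(0, n2 + 1)
            a = st_mod.hudson_fst(k1, n1, k2, n2)
            b = st_mod.hudson_fst(n1 - k1, n1, n2 - k2, n2)
            assert a == pytest.approx(b, rel=1e-12) or (np.isnan(a) and np.isnan(b))

    def test_zero_denominator_missing(self):
        assert np.isnan(st_mod.hudson_fst(0, 10, 0, 10))

    def test_small_n_fatal(self):
        with pytest.raises(ValueError):
            st_mod.hudson_fst(1, 1, 1, 2)


class TestMannWhitney:
    def test_separated_pairs(self):
        u, p = st_mod.mann_whitney_u([1, 2], [3, 4], "two-sided")
        assert u == 0.0
        assert p == pytest.approx(2 / 6)

    def test_one_sided_enumeration(self):
        _, p = st_mod.mann_whitney_u([1, 2], [3, 4], "less")
        assert p == pytest.approx(1 / 6)

    def test_identical_multisets_u_half(self):
        x = [1.0, 2.0, 3.0]
        u, _ = st_mod.mann_whitney_u(x, x, "two-sided")
        assert u == len(x) ** 2 / 2

    def test_exact_matches_scipy(self, rng):
        for _ in range(15):
            x = rng.normal(size=int(rng.integers(2, 6)))
            y = rng.normal(size=int(rng.integers(2, 6)))
            u, p = st_mod.mann_whitney_u(x, y, "two-sided")
            ref = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact")
            assert u == pytest.approx(ref.statistic)
            assert p == pytest.approx(ref.pvalue, abs=1e-9)

    def test_approximation_close_to_exact_distribution(self, rng):
        """Normal approximation within 0.005 of the exact p in its regime
        (distinct values, n + m around 28)."""
        for _ in range(20):
            n, m = rng.integers(12, 17, size=2)
            pooled = rng.normal(size=n + m)  # continuous: no ties
            x, y = pooled[:n], pooled[n:]
            _, p_approx = st_mod.mann_whitney_u(x, y, "greater")
            p_exact = stats.mannwhitneyu(x, y, alternative="greater",
                                         method="exact").pvalue
            assert abs(p_approx - p_exact) < 0.005

    def test_empty_sample_fatal(self):
        with pytest.raises(ValueError):
            st_mod.mann_whitney_u([], [1.0], "two-sided")


class TestRecombContrast:
    def _map(self):
        # rates 1.0 below 5000, 2.0 at/after
        return GeneticMap([1, 5000], [1.0, 2.0], [0.0, 0.005])

    def test_separated_groups_significant(self):
        gmap = self._map()
        res = st_mod.recomb_contrast([6000] * 20, [1000] * 20, gmap, "greater")
        assert res.median_fixed == 2.0
        assert res.median_segregating == 1.0
        assert res.p < 1e-5

    def test_identical_groups_null(self, rng):
        gmap = self._map()
        pos = rng.integers(1, 10_000, size=50)
        res = st_mod.recomb_contrast(pos, pos, gmap, "two-sided")
        assert res.p > 0.9

    def test_enumeration_example(self):
        # rates equal to positions: x = [1,2], y = [3,4], y greater
        gmap = GeneticMap([1, 2, 3, 4], [1.0, 2.0, 3.0, 4.0], [0.0] * 4)
        res = st_mod.recomb_contrast([1, 2], [3, 4], gmap, "less")
        assert res.p == pytest.approx(1 / 6)

    def test_empty_group_fatal(self):
        with pytest.raises(ValueError):
            st_mod.recomb_contrast([], [100], self._map())


class TestHetExcess:
    def _null_bins(self, rng, k=120, n=100, size=2000):
        h, prob = het_count_distribution(k, n, 0.0)
        vals = rng.choice(h, size=size, p=prob).astype(float)
        return mr.FrequencyBinSet(bins=(mr.FrequencyBin(k, k, vals),))

    def test_null_focal_not_significant(self, rng):
        bins = self._null_bins(rng)
        h, prob = het_count_distribution(120, 100, 0.0)
        focal = [(120, int(x)) for x in rng.choice(h, size=400, p=prob)]
        res = st_mod.het_excess_test(focal, bins, rng, min_k=100)
        assert abs(res.mean_rank - 0.5) < 3 * np.sqrt(1 / (12 * 400))

    def test_selected_focal_detected(self, rng):
        bins = self._null_bins(rng)
        h, prob = het_count_distribution(120, 100, 0.3)
        focal = [(120, int(x)) for x in rng.choice(h, size=400, p=prob)]
        res = st_mod.het_excess_test(focal, bins, rng, min_k=100)
        assert res.p < 1e-4

    def test_min_k_filter(self, rng):
        bins = self._null_bins(rng)
        with pytest.raises(ValueError):
            st_mod.het_excess_test([(50, 10)], bins, rng, min_k=100)

    def test_single_site_defined(self, rng):
        bins = self._null_bins(rng)
        res = st_mod.het_excess_test([(120, 40)], bins, rng, min_k=100)
        assert res.n_used == 1
        assert np.isfinite(res.z)


class TestHetPower:
    def test_monotone_and_calibrated_smoke(self, rng):
        spectrum = [(int(k), 100) for k in rng.integers(60, 140, size=60)]
        res = st_mod.het_power_analysis(spectrum, [0.0, 0.5], rng,
                                        replicates=200, null_draws_per_k=400)
        p0, p1 = res[0].power, res[1].power
        assert p0 < 0.15  # near alpha
        assert p1 > 0.9

    def test_power_result_invariants(self):
        with pytest.raises(ValueError):
            st_mod.PowerResult(s=0.1, replicates=10, rejections=11, alpha=0.05)


class TestFstRankTest:
    def test_null_focal_calibrated(self, rng):
        nulls_k = np.full(3000, 50)
        nulls_f = rng.beta(1, 10, size=3000)
        bins = mr.build_frequency_bins(nulls_k, nulls_f, target_bin_size=500)
        focal = [(50, float(f)) for f in rng.beta(1, 10, size=200)]
        mean_rank, W, p, n = st_mod.fst_rank_test(focal, bins, rng, min_pooled_k=10)
        assert n == 200
        assert abs(mean_rank - 0.5) < 3 * np.sqrt(1 / (12 * 200))

    def test_maximal_focal_exact_sign_p(self, rng):
        bins = mr.build_frequency_bins(np.full(100, 50), rng.random(100),
                                       target_bin_size=50)
        focal = [(50, 2.0)] * 6  # above every null
        _, _, p, _ = st_mod.fst_rank_test(focal, bins, rng)
        assert p == pytest.approx(1 / 2 ** 6)

    def test_low_pooled_k_excluded(self, rng):
        bins = mr.build_frequency_bins(np.full(100, 50), rng.random(100),
                                       target_bin_size=50)
        with pytest.raises(ValueError):
            st_mod.fst_rank_test([(9, 0.5)], bins, rng, min_pooled_k=10)

    def test_fst_record(self):
        rec = st_mod.FstRecord(key="a", k1=3, n1=10, k2=9, n2=12)
        assert rec.pooled_k == 12
        assert np.isfinite(rec.fst)


class TestDispersion:
    def test_extreme_concentration_minimal_p(self, rng):
        genes = pd.DataFrame({"gene": [f"g{i}" for i in range(50)],
                              "chrom": "1", "length": 1000,
                              "count": [200] + [0] * 49})
        (res,) = st_mod.dispersion_test(genes, rng, replicates=200)
        assert res.p == pytest.approx(1 / 201)

    def test_equal_counts_variance_zero(self, rng):
        genes = pd.DataFrame({"gene": ["a", "b"], "chrom": "1",
                              "length": [100, 100], "count": [5, 5]})
        (res,) = st_mod.dispersion_test(genes, rng, replicates=100)
        assert res.observed_variance == 0.0
        assert res.p == 1.0

    def test_multinomial_counts_not_rejected(self, rng):
        lengths = rng.integers(500, 5000, size=40)
        counts = rng.multinomial(300, lengths / lengths.sum())
        genes = pd.DataFrame({"gene": [f"g{i}" for i in range(40)],
                              "chrom": "1", "length": lengths, "count": counts})
        (res,) = st_mod.dispersion_test(genes, rng, replicates=200)
        assert res.p > 0.01

    def test_rescaling_invariance(self, rng):
        lengths = np.array([1000, 2000, 1500, 800], dtype=float)
        counts = np.array([3, 9, 1, 4], dtype=float)
        genes = pd.DataFrame({"gene": list("abcd"), "chrom": "1",
                              "length": lengths, "count": counts})
        scaled = genes.assign(length=lengths * 7.5, count=counts * 7.5)
        v1 = st_mod.dispersion_test(genes, np.random.default_rng(1), 50)[0]
        v2 = st_mod.dispersion_test(scaled, np.random.default_rng(1), 50)[0]
        assert v1.observed_variance == pytest.approx(v2.observed_variance, rel=1e-9)

    def test_single_gene_skipped_with_warning(self, rng):
        genes = pd.DataFrame({"gene": ["a"], "chrom": "1", "length": [10],
                              "count": [3]})
        with pytest.warns(UserWarning):
            assert st_mod.dispersion_test(genes, rng) == []

    def test_external_null_counts(self, rng):
        genes = pd.DataFrame({"gene": ["a", "b"], "chrom": "1",
                              "length": [100, 100], "count": [10, 0]})
        null = pd.DataFrame({"gene": ["a", "b"] * 20,
                             "replicate": np.repeat(np.arange(20), 2),
                             "count": [5, 5] * 20})
        (res,) = st_mod.dispersion_test(genes, rng, null_counts=null)
        assert res.p == pytest.approx(1 / 21)


class TestBetaCompare:
    def test_identical_sets_u_half(self):
        x = [0.1, 0.5, 0.9]
        mp, mn, u, p = st_mod.beta_compare(x, x)
        assert mp == mn
        assert u == 4.5

    def test_shifted_scores_significant(self, rng):
        pos = rng.normal(1.1, 0.3, size=80)
        neg = rng.normal(0.5, 0.3, size=80)
        mp, mn, _, p = st_mod.beta_compare(pos, neg)
        assert mp > mn
        assert p < 1e-6

    def test_single_score_per_class(self):
        _, _, _, p = st_mod.beta_compare([2.0], [1.0])
        assert p == pytest.approx(1.0)  # two-sided with one obs each

    def test_empty_class_fatal(self):
        with pytest.raises(ValueError):
            st_mod.beta_compare([], [1.0])
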