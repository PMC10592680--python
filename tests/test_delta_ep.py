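"""Rooting, delta-EP arithmetic, bootstrap CIs, and class summaries."""

import numpy as np
import pytest

from agerank import delta_ep as de
from agerank.io_formats import SiteRecord


def make_site(ref="A", alt="G", anc="A", k=3, n2=8, ep_ref=0.2, ep_alt=0.7,
              site_class="nonsynonymous", **kw):
    return SiteRecord(chrom="1", pos=kw.pop("pos", 100), ref_allele=ref,
                      alt_allele=alt, anc_state=anc, k=k, n2=n2, ep_ref=ep_ref,
                      ep_alt=ep_alt, site_class=site_class, **kw)


class TestParsimonyRooting:
    def test_ancestral_equals_reference(self):
        r = de.root_by_parsimony(make_site())
        assert (r.ancestral_allele, r.derived_allele) == ("A", "G")
        assert r.derived_k == 3
        assert r.delta_ep == pytest.approx(0.5)

    def test_ancestral_equals_alternate_flips_orientation(self):
        r = de.root_by_parsimony(make_site(anc="G"))
        assert (r.ancestral_allele, r.derived_allele) == ("G", "A")
        assert r.derived_k == 5
        assert r.delta_ep == pytest.approx(-0.5)

    def test_require_anc_ref_rejects_flipped(self):
        assert de.root_by_parsimony(make_site(anc="G"),
                                    require_anc_equals_ref=True) is None

    def test_ancestral_matching_neither_rejected(self):
        assert de.root_by_parsimony(make_site(anc="C")) is None

    def test_missing_ancestral_rejected(self):
        assert de.root_by_parsimony(make_site(anc=None)) is None

    def test_rerooting_is_noop(self):
        r = de.root_by_parsimony(make_site())
        assert de.root_by_parsimony(r) is r
        assert de.root_by_ml_posteriors(r, {"A": 1.0}) is r

    def test_root_sites_tallies(self):
        sites = [make_site(pos=1), make_site(pos=2, anc="C"),
                 make_site(pos=3, anc=None), make_site(pos=4, anc="G")]
        rooted, tally = de.root_sites(sites, require_anc_equals_ref=True)
        assert len(rooted) == 1
        assert tally["ancestral_matches_neither"] == 1
        assert tally["missing_ancestral"] == 1
        assert tally["ancestral_not_reference"] == 1


class TestMlRooting:
    def test_confident_posterior(self):
        post = {"A": 0.95, "C": 0.02, "G": 0.02, "T": 0.01}
        r = de.root_by_ml_posteriors(make_site(anc=None), post)
        assert (r.ancestral_allele, r.derived_allele) == ("A", "G")

    def test_below_threshold_rejected(self):
        post = {"A": 0.85, "C": 0.05, "G": 0.05, "T": 0.05}
        assert de.root_by_ml_posteriors(make_site(), post) is None

    def test_argmax_not_an_allele_rejected(self):
        post = {"C": 0.95, "A": 0.02, "G": 0.02, "T": 0.01}
        assert de.root_by_ml_posteriors(make_site(), post) is None

    def test_nonnormalized_posteriors_fatal(self):
        with pytest.raises(ValueError):
            de.root_by_ml_posteriors(make_site(), {"A": 0.5, "G": 0.4})

    def test_ml_rooting_ignores_reference_match(self):
        post = {"G": 0.99, "A": 0.005, "C": 0.003, "T": 0.002}
        r = de.root_by_ml_posteriors(make_site(), post)
        assert r.ancestral_allele == "G"


class TestDeltaEp:
    @pytest.mark.parametrize("ep_der,ep_anc,expected", [
        (0.571, 0.154, 0.417),
        (0.3, 0.3, 0.0),
        (0.017, 0.847, -0.830),
    ])
    def test_exact_subtraction(self, ep_der, ep_anc, expected):
        r = de.root_by_parsimony(make_site(ep_ref=ep_anc, ep_alt=ep_der))
        assert de.compute_delta_ep(r) == pytest.approx(expected, abs=1e-12)

    def test_missing_ep_gives_none(self):
        r = de.root_by_parsimony(make_site(ep_alt=None))
        assert de.compute_delta_ep(r) is None

    def test_antisymmetry_under_orientation_swap(self):
        a = de.root_by_parsimony(make_site(anc="A"))
        b = de.root_by_parsimony(make_site(anc="G"))
        assert a.delta_ep == pytest.approx(-b.delta_ep)
        assert a.derived_k + b.derived_k == a.site.n2


class TestBcBootstrap:
    def test_constant_vector_degenerate(self, rng):
        lo, hi = de.bca_bootstrap_ci(np.full(30, 2.5), np.mean, B=200, rng=rng)
        assert (lo, hi) == (2.5, 2.5)

    def test_symmetric_data_close_to_percentile(self, rng):
        """With symmetric data z0 ~ 0, so BC ~ plain percentile interval."""
        x = rng.normal(size=400)
        boot_rng = np.random.default_rng(5)
        lo, hi = de.bca_bootstrap_ci(x, np.mean, B=4000, rng=boot_rng)
        idx = np.random.default_rng(5).integers(0, 400, size=(4000, 400))
        boot = x[idx].mean(axis=1)
        plo, phi = np.quantile(boot, [0.025, 0.975])
        sd = x.std()
        assert abs(lo - plo) < 0.01 * sd
        assert abs(hi - phi) < 0.01 * sd

    def test_interval_brackets_mean_for_skewed_data(self, rng):
        x = rng.exponential(size=200)
        lo, hi = de.bca_bootstrap_ci(x, np.mean, B=1000, rng=rng)
        assert lo < x.mean() < hi

    def test_acceleration_option_runs(self, rng):
        x = rng.exponential(size=60)
        lo, hi = de.bca_bootstrap_ci(x, np.mean, B=500, rng=rng, acceleration=True)
        assert lo < hi

    def test_generic_statistic_fallback(self, rng):
        x = rng.normal(size=50)
        lo, hi = de.bca_bootstrap_ci(x, lambda v: float(np.median(v)), B=300, rng=rng)
        assert lo < hi

    def test_empty_fatal(self, rng):
        with pytest.raises(ValueError):
            de.bca_bootstrap_ci([], np.mean, rng=rng)


class TestSummarizeClasses:
    def test_two_site_toy(self, rng):
        fixed = de.root_by_parsimony(make_site(pos=1, k=8, ep_ref=0.2, ep_alt=0.7))
        poly = de.root_by_parsimony(make_site(pos=2, k=3, ep_ref=0.7, ep_alt=0.2))
        df = de.summarize_classes([fixed, poly], B=100, rng=rng)
        df = df.set_index(["sign", "state"])
        assert df.loc[("positive", "fixed"), "n"] == 1
        assert df.loc[("negative", "polymorphic"), "n"] == 1
        assert df.loc[("positive", "fixed"), "mean_delta_ep"] == pytest.approx(0.5)
        assert df.loc[("negative", "polymorphic"), "mean_delta_ep"] == pytest.approx(-0.5)
        assert df.loc[("positive", "fixed"), "pct_of_sign_class"] == 100.0

    def test_only_fixed_sites(self, rng):
        fixed = de.root_by_parsimony(make_site(pos=1, k=8))
        df = de.summarize_classes([fixed], B=100, rng=rng).set_index(["sign", "state"])
        assert df.loc[("positive", "polymorphic"), "n"] == 0
        assert np.isnan(df.loc[("positive", "polymorphic"), "mean_delta_ep"])

    def test_zero_delta_ep_tallied_separately(self, rng):
        tie = de.root_by_parsimony(make_site(pos=1, ep_ref=0.4, ep_alt=0.4))
        df = de.summarize_classes([tie], B=100, rng=rng)
        assert df["n"].sum() == 0
        assert df.attrs["n_zero_or_missing_delta_ep"] == 1

    def test_recovers_generator_means(self, rng):
        """Class means of simulated EP draws fall inside their bootstrap CIs."""
        sites = []
        for pos in range(1, 401):
            ep_anc = float(np.clip(rng.beta(4, 8), 1e-3, 1 - 1e-3))
            ep_der = float(np.clip(rng.beta(8, 4), 1e-3, 1 - 1e-3))
            sites.append(de.root_by_parsimony(
                make_site(pos=pos, k=int(rng.integers(1, 8)),
                          ep_ref=ep_anc, ep_alt=ep_der)))
        df = de.summarize_classes(sites, B=500, rng=rng).set_index(["sign", "state"])
        row = df.loc[("positive", "polymorphic")]
        true_mean = 8 / 12 - 4 / 12  # E[der] - E[anc]
        half_width = (row["delta_ep_hi"] - row["delta_ep_lo"]) / 2
        assert abs(row["mean_delta_ep"] - true_mean) < 3 * half_width


class TestBinnedMean:
    def test_one_value_per_bin(self, rng):
        df = de.binned_mean([1.0, 2.0], [0.05, 0.15], [0.0, 0.1, 0.2], B=50, rng=rng)
        assert df["n"].tolist() == [1, 1]
        assert df["mean"].tolist() == [1.0, 2.0]

    def test_interior_edge_goes_right(self, rng):
        df = de.binned_mean([7.0], [0.1], [0.0, 0.1, 0.2], B=50, rng=rng)
        assert df["n"].tolist() == [0, 1]

    def test_last_edge_closed(self, rng):
        df = de.binned_mean([7.0], [1.0], [0.0, 0.5, 1.0], B=50, rng=rng)
        assert df["n"].tolist() == [0, 1]

    def test_empty_bin_missing_mean(self, rng):
        df = de.binned_mean([1.0], [0.05], [0.0, 0.1, 0.2], B=50, rng=rng)
        assert np.isnan(df["mean"].iloc[1])

    def test_bad_edges_fatal(self, rng):
        with pytest.raises(ValueError):
            de.binned_mean([1.0], [0.5], [0.2, 0.1], rng=rng)
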