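"""Wright-Fisher simulator and conditional genotype samplers."""

import math

import numpy as np
import pytest

from _oracles import brute_het_distribution
from agerank import synthetic_data as sd


class TestExpectedFreq:
    def test_symmetric_overdominance_equilibrium(self):
        m = sd.SelectionModel.overdominant(0.05)
        assert sd.expected_freq(0.5, m) == pytest.approx(0.5)

    def test_additive_positive_hand_value(self):
        # (1, 1.1, 1.2) at p = 0.1: p* = 0.111 / 1.02
        m = sd.SelectionModel.additive(0.1)
        assert sd.expected_freq(0.1, m) == pytest.approx(0.111 / 1.02, abs=1e-9)

    @pytest.mark.parametrize("p", [0.0, 1.0])
    @pytest.mark.parametrize("model", [
        sd.SelectionModel.neutral(), sd.SelectionModel.additive(-0.05),
        sd.SelectionModel.overdominant(0.3), sd.SelectionModel.staggered(0.1, 0.01, 0.5),
    ])
    def test_boundaries_absorbing(self, p, model):
        assert sd.expected_freq(p, model) == p

    def test_wf_step_boundaries_stay_absorbed(self, rng):
        m = sd.SelectionModel.overdominant(0.5)
        assert sd.wf_step(0.0, m, 50, rng) == 0.0
        assert sd.wf_step(1.0, m, 50, rng) == 1.0


class TestSelectionModelValidation:
    def test_neutral_triple_enforced(self):
        with pytest.raises(ValueError):
            sd.SelectionModel(label="neutral", w_het=1.1)

    def test_overdominant_requires_het_advantage(self):
        with pytest.raises(ValueError):
            sd.SelectionModel(label="overdominant", w_het=0.9)

    def test_additive_midpoint_enforced(self):
        with pytest.raises(ValueError):
            sd.SelectionModel(label="additive_positive", w_het=1.5, w_der_hom=1.2)

    def test_nonpositive_fitness_rejected(self):
        with pytest.raises(ValueError):
            sd.SelectionModel(label="overdominant", w_het=1.2, w_der_hom=0.0)

    def test_staggered_escape_scheme_is_additive(self):
        m = sd.SelectionModel.staggered(0.1, 0.01, 0.5)
        assert m.escaped().triple == (1.0, 1.1, 1.2)


class TestHetCountDistribution:
    def test_two_diploids_neutral(self):
        h, p = sd.het_count_distribution(2, 2, 0.0)
        assert dict(zip(h.tolist(), p)) == pytest.approx({0: 1 / 3, 2: 2 / 3})

    def test_two_diploids_with_selection_matches_oracle(self):
        h, p = sd.het_count_distribution(2, 2, 0.05)
        oracle = brute_het_distribution(2, 2, 0.05)
        assert p[h.tolist().index(2)] == pytest.approx(oracle[2], abs=1e-12)
        assert oracle[2] == pytest.approx(0.688, abs=5e-4)

    @pytest.mark.parametrize("k,n,s", [(5, 6, 0.1), (8, 10, 0.0), (7, 12, -0.05),
                                       (20, 25, 0.3)])
    def test_matches_enumeration_oracle(self, k, n, s):
        h, p = sd.het_count_distribution(k, n, s)
        oracle = brute_het_distribution(k, n, s)
        assert dict(zip(h.tolist(), p)) == pytest.approx(oracle, abs=1e-10)

    @pytest.mark.parametrize("k", [0, 20])
    def test_boundaries_all_or_none(self, k):
        h, p = sd.het_count_distribution(k, 10, 0.2)
        assert h.tolist() == [0] and p.tolist() == [1.0]

    def test_general_fitness_triple(self):
        triple = (1.0, 1.3, 0.8)
        h, p = sd.het_count_distribution(6, 8, triple=triple)
        oracle = brute_het_distribution(6, 8, triple=triple)
        assert dict(zip(h.tolist(), p)) == pytest.approx(oracle, abs=1e-10)

    def test_sampler_distribution_close_to_oracle(self, rng):
        draws = np.array([sd.sample_het_count_conditional(8, 20, 0.0, rng)
                          for _ in range(20_000)])
        oracle = brute_het_distribution(8, 20, 0.0)
        tv = 0.5 * sum(abs(np.mean(draws == h) - p) for h, p in oracle.items())
        assert tv < 0.03


class TestSimulateHetDataset:
    def test_one_triple_per_entry(self, rng):
        spectrum = [(3, 10)] * 10
        out = sd.simulate_het_dataset(spectrum, 0.0, rng)
        assert len(out) == 10
        assert all(k == 3 and n == 10 for k, n, _ in out)

    def test_all_zero_k(self, rng):
        out = sd.simulate_het_dataset([(0, 10)] * 5, 0.1, rng)
        assert all(h == 0 for _, _, h in out)

    def test_replicate_mean_matches_oracle_expectation(self, rng):
        oracle = brute_het_distribution(10, 50, 0.0)
        expect = sum(h * p for h, p in oracle.items())
        var = sum(h * h * p for h, p in oracle.items()) - expect ** 2
        m = 4000
        out = sd.simulate_het_dataset([(10, 50)] * m, 0.0, rng)
        mean = np.mean([h for _, _, h in out])
        assert abs(mean - expect) < 3 * math.sqrt(var / m)

    def test_empty_spectrum_rejected(self, rng):
        with pytest.raises(ValueError):
            sd.simulate_het_dataset([], 0.0, rng)


class TestTrajectories:
    def test_single_generation(self, rng):
        for _ in range(20):
            t = sd.simulate_trajectory(sd.SelectionModel.neutral(), 50, 1, rng)
            assert t.fate in ("segregating", "lost")
            if t.fate == "segregating":
                assert t.true_age == 1

    def test_record_invariants(self):
        with pytest.raises(ValueError):
            sd.TrajectoryRecord(origin_gen=0, freqs=[0.5, 1.2], fate="segregating",
                                true_age=1)
        with pytest.raises(ValueError):
            sd.TrajectoryRecord(origin_gen=0, freqs=[0.5], fate="segregating",
                                true_age=0)

    def test_fates_consistent_with_final_freq(self, rng):
        df = sd.simulate_fates(sd.SelectionModel.neutral(), 50, 500, 400, rng)
        assert ((df["fate"] == "lost") == (df["final_freq"] == 0.0)).all()
        assert ((df["fate"] == "fixed") == (df["final_freq"] == 1.0)).all()

    def test_staggered_escape_changes_dynamics(self, rng):
        # with r = 1 the escape happens immediately: pure additive behaviour
        fast = sd.SelectionModel.staggered(0.5, 1.0, 0.9)
        df = sd.simulate_fates(fast, 100, 400, 2000, rng)
        assert (df["fate"] == "fixed").mean() > 0.3  # ~2s escape probability

    def test_segregating_sampler_returns_requested_count(self, rng):
        p, ages = sd.sample_segregating_sites(sd.SelectionModel.neutral(), 100, 50,
                                              1000, rng)
        assert p.shape == ages.shape == (50,)
        assert np.all((p > 0) & (p < 1))
        assert np.all(ages >= 1)


class TestCohort:
    def test_contract_and_determinism(self):
        cfg = sd.default_cohort_config(N=120, n2=120, sites_per_class=120)
        out1 = sd.simulate_cohort(cfg, np.random.default_rng(7))
        out2 = sd.simulate_cohort(cfg, np.random.default_rng(7))
        sites1, ages1 = out1
        sites2, ages2 = out2
        assert sites1 == sites2
        assert ages1.equals(ages2)
        assert len(sites1) == 360
        neutral = [s for s in sites1 if s.site_class == "noncoding_nonregulatory"]
        assert len(neutral) == 120
        assert (ages1["age_gens"] > 0).all()

    def test_negative_class_mean_delta_ep_negative(self):
        cfg = sd.default_cohort_config(N=120, n2=120, sites_per_class=150)
        sites, _ = sd.simulate_cohort(cfg, np.random.default_rng(3))
        neg = [s.ep_alt - s.ep_ref for s in sites
               if s.site_class == "nonsynonymous" and s.ep_ref > 0.5]
        assert np.mean(neg) < 0

    def test_fixed_class_sites_fixed_in_sample(self):
        classes = {"fx": sd.ClassSpec(model=sd.SelectionModel.additive(0.05),
                                      count=30, fixed=True)}
        cfg = sd.CohortConfig(N=100, n2=100, classes=classes, max_gens=2000)
        sites, ages = sd.simulate_cohort(cfg, np.random.default_rng(5))
        assert all(s.k == s.n2 for s in sites)
        assert len(sites) == 30

    def test_config_validation(self):
        with pytest.raises(ValueError):
            sd.CohortConfig(N=100, n2=101, classes={"a": None})
        with pytest.raises(ValueError):
            sd.ClassSpec(model=sd.SelectionModel.neutral(), count=0)
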