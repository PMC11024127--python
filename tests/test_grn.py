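"""Transcriptional-level tests: propensities, SSA, ODE mode, knockdown."""

import math

import numpy as np
import pytest

import tcommit as tc
from tcommit import _kernels
from tcommit.grn import GeneState, GRNParameters

START = GeneState(R=1, T=2, G=1, P=5, X=8, N=7)

# hand-evaluated Shea-Ackers rates at the progenitor starting counts
EXPECTED_PRODUCTION = {
    "Runx1": (0.10 * 1 + 1.00 * 7) / (1 + 0.10 * 1 + 1.00 * 7),          # 7.1/8.1
    "Tcf7": (5.0 * 2 + 1.0 * 1 + 1.5 * 7 / (0.01 + 5))
            / (1 + 5.0 * 2 + 1.0 * 1 + 1.5 * 7 + 0.5 * 5),               # 13.0958/25
    "Gata3": (0.7 * 2 + 0.5 * 7 / (1.0 + 5))
             / (1 + 0.7 * 2 + 0.5 * 7 + 0.2 * 5),                        # 1.9833/6.9
    "PU.1": 12.5 / 18.7,
    "X": 1.0 / 6.0,
    "Notch": 0.01 / 8.0,
}


class TestPropensities:
    def test_production_matches_hand_evaluation(self, grn_params):
        rates = tc.production_propensities(START, grn_params)
        for i, name in enumerate(tc.SPECIES):
            assert rates[i] == pytest.approx(EXPECTED_PRODUCTION[name], rel=1e-12)

    def test_x_production_without_repressors_is_one(self, grn_params):
        s = GeneState(R=0, T=0, G=0, P=0, X=0, N=0)
        assert tc.production_propensities(s, grn_params)[4] == 1.0

    def test_degradation_is_linear_and_notch_free(self, grn_params):
        rates = tc.degradation_propensities(START, grn_params)
        assert rates[4] == pytest.approx(0.02 * 8)  # X
        assert rates[5] == 0.0                       # Notch never decays
        zero = tc.degradation_propensities(GeneState(0, 0, 0, 0, 0, 0), grn_params)
        assert np.all(zero == 0.0)

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            GeneState(R=-1, T=0, G=0, P=0, X=0, N=0)

    def test_non_finite_parameter_rejected(self):
        with pytest.raises(ValueError):
            GRNParameters(p1=float("nan"))


class TestGillespieStep:
    def test_zero_propensity_censors_at_horizon(self, rng):
        params = GRNParameters(kd_factors=(0.0,) * 6)
        s = GeneState(0, 0, 0, 0, 0, 0, t=0.0)
        out = tc.gillespie_step(s, params, rng, t_max=10.0)
        assert out.t == 10.0 and out.as_array().sum() == 0

    def test_waiting_time_is_exponential_at_total_rate(self):
        # only X degradation active: rate 0.02 * 8 = 0.16 / h, mean wait 6.25 h
        params = GRNParameters(kd_factors=(0.0,) * 6)
        s = GeneState(0, 0, 0, 0, 8, 0, t=0.0)
        rng = np.random.default_rng(11)
        waits = [tc.gillespie_step(s, params, rng, t_max=1e9).t
                 for _ in range(20000)]
        assert np.mean(waits) == pytest.approx(6.25, abs=4 * 6.25 / math.sqrt(20000))

    def test_fixed_seed_reproducible(self, grn_params):
        seqs = []
        for _ in range(2):
            rng = np.random.default_rng(5)
            s = START
            states = []
            for _ in range(50):
                s = tc.gillespie_step(s, grn_params, rng, t_max=1e9)
                states.append((s.t, s.as_array().tolist()))
            seqs.append(states)
        assert seqs[0] == seqs[1]


class TestSimulateGrn:
    def test_degenerate_interval_returns_initial_only(self, grn_params, rng):
        traj = tc.simulate_grn(START, 3.0, 3.0, grn_params, rng)
        assert len(traj) == 1 and traj.final_state.as_array().tolist() == \
            START.as_array().tolist()

    def test_trajectory_invariants_hold(self, grn_params, rng):
        traj = tc.simulate_grn(START, 0.0, 50.0, grn_params, rng)
        traj.validate()
        assert traj.t_end == 50.0

    def test_notch_is_non_decreasing(self, grn_params, rng):
        traj = tc.simulate_grn(START, 0.0, 100.0, grn_params, rng)
        assert np.all(np.diff(traj.states[:, 5]) >= 0)

    def test_counts_never_negative(self, grn_params, rng):
        traj = tc.simulate_grn(START, 0.0, 100.0, grn_params, rng)
        assert np.all(traj.states >= 0)

    def test_pure_death_matches_exponential_decay(self):
        # productions disabled: each species decays at its own gamma
        params = GRNParameters(kd_factors=(0.0,) * 6)
        s0 = GeneState(50, 50, 50, 50, 50, 0)
        rng = np.random.default_rng(2)
        finals = np.empty((3000, 6))
        for k in range(3000):
            finals[k] = tc.simulate_grn(s0, 0.0, 10.0, params, rng).states[-1]
        expected = 50.0 * np.exp(-10.0 * np.append(params.gamma_array(), 0.0))
        for i in range(5):
            se = finals[:, i].std(ddof=1) / math.sqrt(3000)
            assert abs(finals[:, i].mean() - expected[i]) < 4 * se

    def test_birth_death_stationary_mean(self):
        # Tcf7/Gata3 channels disabled and started empty: X production is the
        # bare rate 1/h against decay 0.02/h, stationary mean 50
        params = GRNParameters(kd_factors=(1.0, 0.0, 0.0, 1.0, 1.0, 1.0))
        s0 = GeneState(R=0, T=0, G=0, P=0, X=50, N=0)
        rng = np.random.default_rng(3)
        finals = [tc.simulate_grn(s0, 0.0, 150.0, params, rng).states[-1][4]
                  for _ in range(200)]
        se = np.std(finals, ddof=1) / math.sqrt(200)
        assert abs(np.mean(finals) - 50.0) < 4 * se

    def test_fixed_seed_bit_exact(self, grn_params):
        t1 = tc.simulate_grn(START, 0.0, 40.0, grn_params,
                             np.random.default_rng(9))
        t2 = tc.simulate_grn(START, 0.0, 40.0, grn_params,
                             np.random.default_rng(9))
        assert np.array_equal(t1.times, t2.times)
        assert np.array_equal(t1.states, t2.states)

    def test_kernel_agrees_with_python_step_sampler(self, grn_params):
        """The jitted SSA and the plain-Python step sampler draw from the
        same process: species means at 5 h agree within sampling error."""
        n = 1500
        rng = np.random.default_rng(21)
        py = np.empty((n, 6))
        for k in range(n):
            s = START
            while s.t < 5.0:
                s = tc.gillespie_step(s, grn_params, rng, 5.0)
            py[k] = s.as_array()
        kr = np.empty((n, 6))
        for k in range(n):
            kr[k] = tc.simulate_grn(START, 0.0, 5.0, grn_params,
                                    rng).states[-1]
        se = np.sqrt(py.var(0, ddof=1) / n + kr.var(0, ddof=1) / n)
        z = (py.mean(0) - kr.mean(0)) / np.where(se > 0, se, 1.0)
        assert np.all(np.abs(z) < 4)


class TestOdeMode:
    def test_empty_system_stays_zero(self):
        params = GRNParameters(kd_factors=(0.0,) * 6)
        sol = tc.integrate_ode(np.zeros(6), (0.0, 50.0), params)
        assert np.allclose(sol.y, 0.0, atol=1e-9)

    def test_notch_strictly_increasing(self, grn_params):
        sol = tc.integrate_ode(START, (0.0, 50.0), grn_params)
        assert np.all(np.diff(sol.y[5]) > 0)

    def test_knockdown_scales_deterministic_production(self, grn_params):
        kd_params, _ = tc.apply_knockdown(grn_params, None, "Tcf7", 0.2)
        wt = tc.integrate_ode(START, (0.0, 80.0), grn_params)
        kd = tc.integrate_ode(START, (0.0, 80.0), kd_params)
        assert kd.y[1, -1] < wt.y[1, -1]  # Tcf7 suppressed
        assert kd.y[4, -1] > wt.y[4, -1]  # X rises when Tcf7 is knocked down


class TestKnockdown:
    def test_initial_count_rounding(self, grn_params):
        _, s = tc.apply_knockdown(grn_params, START, "PU.1", 0.2,
                                  scale_initial=True)
        assert s.P == 1  # 5 * 0.2 = 1 exactly
        _, s = tc.apply_knockdown(grn_params, START, "Tcf7", 0.2,
                                  scale_initial=True)
        assert s.T == 0  # 0.4 rounds to 0
        _, s = tc.apply_knockdown(grn_params, START, "PU.1", 0.5,
                                  scale_initial=True)
        assert s.P == 3  # 2.5 rounds away from zero

    def test_factor_one_is_identity(self, grn_params):
        p, s = tc.apply_knockdown(grn_params, START, "Gata3", 1.0,
                                  scale_initial=True)
        assert p == grn_params and s == START

    def test_unknown_gene_rejected(self, grn_params):
        with pytest.raises(ValueError):
            tc.apply_knockdown(grn_params, START, "Bcl11b", 0.2)

    def test_factor_out_of_range_rejected(self, grn_params):
        for bad in (0.0, -0.1, 1.5):
            with pytest.raises(ValueError):
                tc.apply_knockdown(grn_params, START, "Tcf7", bad)
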