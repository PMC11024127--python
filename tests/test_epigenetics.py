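"""Regulatory-region tests: channels, SSA, conservation, per-site oracle."""

import math

import numpy as np
import pytest
from scipy.stats import chi2_contingency

import tcommit as tc
from tcommit import _kernels
from tcommit.epigenetics import RegulatoryRegion
from tcommit.grn import GRNTrajectory


def constant_inputs_trajectory(X, R, N, t0=0.0, t_end=1e9):
    """A one-segment GRN trajectory holding (X, R, N) fixed."""
    state = np.array([[R, 0, 0, 0, X, N]], dtype=np.int64)
    return GRNTrajectory(times=np.array([t0]), states=state, t_end=t_end)


class TestChannelPropensities:
    def test_no_inputs_silences_direct_channels(self, epi_params):
        region = RegulatoryRegion(C=200, I=200, O=100)
        channels = tc.channel_propensities(region, (0, 0, 0), epi_params)
        direct = [ch for ch in channels if ch.mediator is None]
        mediated = [ch for ch in channels if ch.mediator is not None]
        assert all(ch.propensity == 0 for ch in direct)
        assert any(ch.propensity > 0 for ch in mediated)

    def test_fully_closed_region_only_opens(self, epi_params):
        # all sites closed: only the Notch/Runx1-coupled C->I channel can fire
        region = RegulatoryRegion(C=500, I=0, O=0)
        channels = tc.channel_propensities(region, (8, 1, 7), epi_params)
        rates = {(ch.source, ch.target, ch.mediator): ch.propensity
                 for ch in channels}
        # attempt rate (k2*7 + k3*1) times the C-match probability 500/500
        assert rates[("C", "I", None)] == pytest.approx(
            (0.20 * 7 + 0.20 * 1) * 500 / 500)
        assert sum(r for key, r in rates.items() if key != ("C", "I", None)) == 0

    def test_fully_open_region_without_x_is_absorbing(self, epi_params):
        region = RegulatoryRegion(C=0, I=0, O=500)
        channels = tc.channel_propensities(region, (0, 5, 5), epi_params)
        assert all(ch.propensity == 0 for ch in channels)

    def test_exactly_nine_channels_no_direct_o_c(self, epi_params):
        channels = tc.channel_propensities(
            RegulatoryRegion(C=100, I=200, O=200), (3, 1, 7), epi_params)
        assert len(channels) == 9
        assert not any({ch.source, ch.target} == {"O", "C"} for ch in channels)


class TestEpigeneticStep:
    def test_single_available_channel_fires(self, epi_params, rng):
        region = RegulatoryRegion(C=500, I=0, O=0)
        new, t = tc.epigenetic_step(region, 0.0, (8, 1, 7), epi_params, rng,
                                    t_max=1e9)
        assert (new.C, new.I, new.O) == (499, 1, 0)

    def test_conservation_and_censoring(self, epi_params, rng):
        region = RegulatoryRegion(C=100, I=200, O=200)
        t = 0.0
        for _ in range(200):
            region, t = tc.epigenetic_step(region, t, (5, 1, 7), epi_params,
                                           rng, t_max=50.0)
            assert region.C + region.I + region.O == 500
            if t == 50.0:
                break

    def test_absorbing_state_censors(self, epi_params, rng):
        region = RegulatoryRegion(C=0, I=0, O=500)
        new, t = tc.epigenetic_step(region, 0.0, (0, 1, 7), epi_params, rng,
                                    t_max=25.0)
        assert t == 25.0 and new == region


class TestEvolveRegion:
    def test_silent_inputs_leave_open_region_unchanged(self, epi_params, rng):
        region = RegulatoryRegion(C=0, I=0, O=500)
        traj = tc.evolve_region(region, constant_inputs_trajectory(0, 0, 0),
                                0.0, 200.0, epi_params, rng)
        assert traj.final_region == region and len(traj) == 1

    def test_zero_length_interval(self, epi_params, rng):
        region = RegulatoryRegion(C=250, I=125, O=125)
        traj = tc.evolve_region(region, constant_inputs_trajectory(5, 1, 7),
                                3.0, 3.0, epi_params, rng)
        assert traj.final_region == region

    def test_strong_x_closes_open_region(self, epi_params):
        region = RegulatoryRegion(C=0, I=0, O=500)
        rng = np.random.default_rng(4)
        finals = [tc.evolve_region(region,
                                   constant_inputs_trajectory(50, 0, 0),
                                   0.0, 40.0, epi_params, rng).final_region.O
                  for _ in range(50)]
        assert np.mean(finals) < 500 and min(finals) < 500

    def test_opening_drift_without_x(self, epi_params):
        # with X = 0 and positive Runx1/Notch the expected open count grows
        region = RegulatoryRegion(C=400, I=50, O=50)
        rng = np.random.default_rng(5)
        finals = [tc.evolve_region(region,
                                   constant_inputs_trajectory(0, 1, 7),
                                   0.0, 30.0, epi_params, rng).final_region.O
                  for _ in range(200)]
        assert np.mean(finals) > 50

    def test_not_covering_interval_rejected(self, epi_params, rng):
        region = RegulatoryRegion(C=500, I=0, O=0)
        traj = constant_inputs_trajectory(5, 1, 7, t0=0.0, t_end=10.0)
        with pytest.raises(ValueError):
            tc.evolve_region(region, traj, 0.0, 20.0, epi_params, rng)

    def test_record_flag_does_not_change_the_draws(self, epi_params):
        region = RegulatoryRegion(C=500, I=0, O=0)
        traj = constant_inputs_trajectory(5, 1, 7)
        a = tc.evolve_region(region, traj, 0.0, 30.0, epi_params,
                             np.random.default_rng(6), record=True)
        b = tc.evolve_region(region, traj, 0.0, 30.0, epi_params,
                             np.random.default_rng(6), record=False)
        assert a.final_region == b.final_region


class TestOpenThreshold:
    @pytest.mark.parametrize("O,expected", [(375, True), (374, False),
                                            (500, True), (0, False)])
    def test_75_percent_threshold_inclusive(self, O, expected, epi_params):
        region = RegulatoryRegion(C=500 - O, I=0, O=O)
        assert tc.is_region_open(region, epi_params) is expected


class TestConservationBulk:
    def test_long_trajectory_conserves_sites_and_never_jumps_o_c(self, epi_params):
        region = RegulatoryRegion(C=500, I=0, O=0)
        traj = tc.evolve_region(region, constant_inputs_trajectory(8, 1, 7),
                                0.0, 5000.0, epi_params,
                                np.random.default_rng(7))
        states = traj.states
        assert len(states) > 5000
        assert np.all(states.sum(axis=1) == 500)
        d = np.diff(states, axis=0)
        # every event moves exactly one site between two adjacent states
        assert np.all(np.abs(d).sum(axis=1) == 2)
        assert not np.any((d[:, 0] != 0) & (d[:, 2] != 0))


class TestPerSiteOracle:
    def test_count_ssa_matches_literal_rejection_sampler(self, epi_params):
        """The aggregated channel propensities must reproduce the literal
        scheme — pick a channel at its attempt rate, pick a random site that
        must match the source state, pick a random mediator that must match —
        simulated over an explicit list of S = 10 site states."""
        S, X, R, N = 10, 2.0, 1.0, 2.0
        params = tc.EpigeneticParameters(S=S)
        k1, k2, k3, al, be, gm, de, ep = params.rate_tuple()
        nrep = 3000
        rng = np.random.default_rng(42)

        counts_a = []
        gt = np.array([0.0])
        gx, gr, gn = np.array([X]), np.array([R]), np.array([N])
        for _ in range(nrep):
            *_, c, i_, o = _kernels.epi_ssa(
                4, 3, 3, S, gt, gx, gr, gn, 0.0, 1.0,
                k1, k2, k3, al, be, gm, de, ep,
                int(rng.integers(2**31)), False)
            counts_a.append((c, i_, o))

        src = [2, 1, 0, 1, 2, 1, 1, 0, 1]
        tgt = [1, 0, 1, 2, 1, 0, 2, 1, 0]
        med = [None, None, None, None, 0, 0, 2, 2, 1]
        rates = np.array([k1 * X, k1 * X, k2 * N + k3 * R, k2 * N + k3 * R,
                          al, be, gm, de, ep])
        total, cum = rates.sum(), np.cumsum(rates)
        counts_b = []
        for _ in range(nrep):
            sites = np.array([0] * 4 + [1] * 3 + [2] * 3)
            t = 0.0
            while True:
                t += rng.exponential(1.0 / total)
                if t >= 1.0:
                    break
                ch = int(np.searchsorted(cum, rng.random() * total,
                                         side="right"))
                s = int(rng.integers(S))
                if sites[s] != src[ch]:
                    continue
                if med[ch] is not None:
                    m = int(rng.integers(S))
                    if sites[m] != med[ch]:
                        continue
                sites[s] = tgt[ch]
            counts_b.append((int((sites == 0).sum()), int((sites == 1).sum()),
                             int((sites == 2).sum())))

        from collections import Counter
        ca, cb = Counter(counts_a), Counter(counts_b)
        keys = sorted(set(ca) | set(cb))
        ta = np.array([ca.get(k, 0) for k in keys])
        tb = np.array([cb.get(k, 0) for k in keys])
        keep = (ta + tb) >= 10
        ta = np.append(ta[keep], ta[~keep].sum())
        tb = np.append(tb[keep], tb[~keep].sum())
        _, pvalue, _, _ = chi2_contingency(np.vstack([ta, tb]))
        assert pvalue > 0.01


class TestValidation:
    def test_site_counts_must_sum_to_total(self):
        with pytest.raises(ValueError):
            RegulatoryRegion(C=100, I=100, O=100, S=500)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            RegulatoryRegion(C=-1, I=251, O=250, S=500)
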