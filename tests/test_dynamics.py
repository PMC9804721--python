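"""Integration, limit cycles and turnover; eigenvalues vs simulated behaviour."""

import numpy as np
import pytest

from thermoniche import (IntegrationError, NoCoexistenceError,
                         chemostat_equilibria, consumer_turnover,
                         cycle_summary, integrate, logistic_equilibria,
                         respiration)

HOPFS_R05 = (16.282863890, 28.674981509)
RNG = np.random.default_rng(20220827)


def _coex(model, T, cp, params):
    recs = (chemostat_equilibria(T, cp, params) if model == "chemostat"
            else logistic_equilibria(T, cp, params))
    return {r.label: r for r in recs}["coexistence"]


class TestIntegrate:
    def test_stable_equilibrium_is_invariant(self, box1, chemostat):
        eq = _coex("chemostat", 25.0, box1, chemostat)
        traj = integrate("chemostat", 25.0, (eq.R_hat, eq.C_hat), 500.0,
                         box1, chemostat)
        drift = np.max(np.hypot(traj.R - eq.R_hat, traj.C - eq.C_hat))
        assert drift < 1e-7

    def test_consumer_free_chemostat_relaxes_to_supply(self, box1, chemostat):
        traj = integrate("chemostat", 25.0, (0.2, 0.0), 30.0, box1, chemostat)
        assert np.all(np.diff(traj.R) > -1e-12)
        assert traj.R[-1] == pytest.approx(chemostat.S, abs=1e-8)
        assert np.all(traj.C == 0.0)

    def test_unstable_focus_repels_onto_bounded_orbit(self, box1, resource):
        """Inside the cycle region the orbit leaves the equilibrium but stays bounded."""
        eq = _coex("logistic", 25.0, box1, resource)
        traj = integrate("logistic", 25.0, (eq.R_hat * 1.01, eq.C_hat * 1.01),
                         3000.0, box1, resource)
        final_dist = np.hypot(traj.R[-1] - eq.R_hat, traj.C[-1] - eq.C_hat)
        assert final_dist > 0.05
        assert traj.R.max() < 10 and traj.C.max() < 10

    def test_trajectory_invariants(self, box1, chemostat):
        traj = integrate("chemostat", 20.0, (0.5, 0.3), 100.0, box1, chemostat)
        assert np.all(np.diff(traj.times) > 0)
        assert np.all(traj.states >= 0)
        assert len(traj.times) == len(traj.states)

    def test_unknown_model_rejected(self, box1, chemostat):
        with pytest.raises(ValueError):
            integrate("ratio_dependent", 20.0, (0.5, 0.3), 10.0, box1, chemostat)


class TestCycleSummary:
    def test_stable_temperature_collapses_to_equilibrium(self, box1_r1, resource):
        eq = _coex("logistic", 25.0, box1_r1, resource)
        cs = cycle_summary("logistic", 25.0, box1_r1, resource,
                           transient=1500.0, window=300.0)
        assert cs.converged
        assert cs.R_min == pytest.approx(eq.R_hat, abs=1e-6)
        assert cs.R_max == pytest.approx(eq.R_hat, abs=1e-6)

    def test_amplitude_grows_past_the_hopf_point(self, box1, resource):
        """Supercritical onset: amplitude increases with distance into the
        cycle region, and the cycle brackets the unstable equilibrium."""
        amps = []
        for T in (HOPFS_R05[1] - 0.4, HOPFS_R05[1] - 1.2, HOPFS_R05[1] - 2.4):
            cs = cycle_summary("logistic", T, box1, resource,
                               transient=2500.0, window=400.0)
            eq = _coex("logistic", T, box1, resource)
            assert cs.R_min < eq.R_hat < cs.R_max
            amps.append(cs.amplitude_R)
        assert amps[0] > 1e-3
        assert amps[0] < amps[1] < amps[2]

    def test_no_coexistence_is_a_typed_error(self, box1, resource):
        with pytest.raises(NoCoexistenceError):
            cycle_summary("logistic", 2.0, box1, resource)


class TestStabilityCrossValidation:
    @pytest.mark.parametrize("T, expect_stable", [
        (12.0, True), (20.0, True), (30.0, True),   # chemostat: always stable
    ])
    def test_chemostat_eigenvalues_predict_convergence(self, box1, chemostat,
                                                       T, expect_stable):
        eq = _coex("chemostat", T, box1, chemostat)
        assert eq.stable is expect_stable
        for _ in range(3):
            init = (float(RNG.uniform(0.05, 1.5)), float(RNG.uniform(0.05, 2.0)))
            traj = integrate("chemostat", T, init, 800.0, box1, chemostat)
            assert np.hypot(traj.R[-1] - eq.R_hat, traj.C[-1] - eq.C_hat) < 1e-6

    @pytest.mark.parametrize("T", [14.0, 20.0, 25.0, 31.0])
    def test_logistic_eigenvalues_predict_asymptotics(self, box1, resource, T):
        eq = _coex("logistic", T, box1, resource)
        init = (eq.R_hat * 1.02, eq.C_hat * 1.02)
        traj = integrate("logistic", T, init, 2500.0, box1, resource)
        final = np.hypot(traj.R[-1] - eq.R_hat, traj.C[-1] - eq.C_hat)
        if eq.stable:
            assert final < 1e-5
        else:
            assert final > 1e-3


class TestTurnover:
    def test_equals_respiration_at_coexistence(self, box1, chemostat, resource):
        """(1-delta) f(R*,T) = m(T): the equilibrium condition itself."""
        for model, cp, params in (("chemostat", box1, chemostat),
                                  ("logistic", box1, resource)):
            for T in (14.0, 22.0, 28.0):
                assert consumer_turnover(T, cp, params, model) == pytest.approx(
                    respiration(T, cp), rel=1e-12)

    def test_lowest_at_cold_end_and_rising_with_warming(self, box1, chemostat):
        T = np.arange(10.5, 30.5, 0.25)
        to = np.array([consumer_turnover(float(t), box1, chemostat, "chemostat")
                       for t in T])
        assert np.all(np.diff(to) > 0)
        assert to.argmin() == 0

    def test_approximately_exponential_in_T(self, box1, chemostat):
        """log-turnover is nearly linear with slope ~ m_b at warm temperatures."""
        T = np.arange(20.0, 30.0, 0.5)
        to = np.array([consumer_turnover(float(t), box1, chemostat, "chemostat")
                       for t in T])
        slope = np.polyfit(T, np.log(to), 1)[0]
        assert 0.5 * box1.m_b < slope < 1.1 * box1.m_b

    def test_infeasible_temperature_signalled(self, box1, chemostat):
        with pytest.raises(NoCoexistenceError):
            consumer_turnover(2.0, box1, chemostat, "chemostat")


class TestEnergyBalance:
    def test_inflow_consumed_equals_uptake_at_equilibrium(self, box1, chemostat):
        from thermoniche import functional_response
        for T in (12.0, 20.0, 28.0):
            eq = _coex("chemostat", T, box1, chemostat)
            inflow = chemostat.D * (chemostat.S - eq.R_hat)
            uptake = functional_response(eq.R_hat, T, box1) * eq.C_hat
            assert abs(inflow - uptake) < 1e-10
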