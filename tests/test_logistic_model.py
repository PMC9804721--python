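"""Logistic-resource model: equilibria, Hopf structure, branch scan."""

from dataclasses import replace

import numpy as np
import pytest
from scipy.optimize import brentq

from thermoniche import (ResourceTraits, carrying_capacity, hopf_points,
                         hopf_threshold_capacity, logistic_branch_scan,
                         logistic_equilibria, logistic_rhs,
                         resource_intrinsic_rate, rstar)

R_ZEROS = (4.3147169515766475, 38.65322440551046)
HOPFS_R05 = (16.282863890, 28.674981509)


class TestRhs:
    def test_extinct_resource_stays_extinct(self, box1, resource):
        dR, _ = logistic_rhs((0.0, 0.7), 20.0, box1, resource)
        assert dR == 0.0

    def test_thermal_stress_never_rescued_by_density_dependence(self, box1, resource):
        """Where r < 0, dR/dt < 0 for any positive R without consumers."""
        for T in (1.0, 39.5):
            assert resource_intrinsic_rate(T, resource, box1.T_I) < 0
            for R in (0.01, 0.5, 5.0):
                dR, _ = logistic_rhs((R, 0.0), T, box1, resource)
                assert dR < 0

    def test_carrying_capacity_is_consumer_free_equilibrium(self, box1, resource):
        K = carrying_capacity(25.0, resource, box1.T_I)
        dR, _ = logistic_rhs((K, 0.0), 25.0, box1, resource)
        assert abs(dR) < 1e-10

    def test_negative_state_rejected(self, box1, resource):
        with pytest.raises(ValueError):
            logistic_rhs((0.1, -1.0), 25.0, box1, resource)


class TestEquilibria:
    def test_only_stable_trivial_under_thermal_stress(self, box1, resource):
        recs = logistic_equilibria(1.0, box1, resource)
        assert [r.label for r in recs] == ["trivial"]
        assert recs[0].stable

    def test_efficient_consumer_coexistence_is_unstable_in_cycle_region(
            self, box1, resource):
        recs = {r.label: r for r in logistic_equilibria(25.0, box1, resource)}
        coex = recs["coexistence"]
        assert coex.R_hat == pytest.approx(0.26178853963077986, rel=1e-12)
        assert coex.C_hat == pytest.approx(0.5725972488511771, rel=1e-10)
        assert not coex.stable  # K(25) exceeds the enrichment threshold for R_0=0.5

    def test_prudent_consumer_coexistence_is_stable(self, box1_r2, resource):
        recs = {r.label: r for r in logistic_equilibria(25.0, box1_r2, resource)}
        assert recs["coexistence"].stable

    def test_negative_K_never_reported_as_equilibrium(self, box1, resource):
        for T in (1.0, 39.5):  # r < 0 here
            labels = [r.label for r in logistic_equilibria(T, box1, resource)]
            assert "resource_only" not in labels

    def test_zero_rhs_residual_at_every_equilibrium(self, box1, resource):
        for T in np.arange(0.0, 40.0, 0.5):
            for rec in logistic_equilibria(float(T), box1, resource):
                dR, dC = logistic_rhs((rec.R_hat, rec.C_hat), float(T), box1, resource)
                assert abs(dR) < 1e-10 and abs(dC) < 1e-10


class TestHopf:
    def test_two_hopf_points_for_efficient_consumer(self, box1, resource, T_grid):
        hs = hopf_points(T_grid, box1, resource)
        assert len(hs) == 2
        assert hs[0] == pytest.approx(HOPFS_R05[0], abs=1e-6)
        assert hs[1] == pytest.approx(HOPFS_R05[1], abs=1e-6)

    def test_no_hopf_for_moderate_and_prudent_consumers(
            self, box1_r1, box1_r2, resource, T_grid):
        assert hopf_points(T_grid, box1_r1, resource) == []
        assert hopf_points(T_grid, box1_r2, resource) == []

    def test_detected_points_match_closed_form_threshold(self, box1, resource, T_grid):
        """Trace zero exactly where K(T) crosses R0*((1-d)Imax+m)/((1-d)Imax-m)."""
        def gap(T):
            return (carrying_capacity(T, resource, box1.T_I)
                    - hopf_threshold_capacity(T, box1))
        oracle = [brentq(gap, 10, 20, xtol=1e-10), brentq(gap, 25, 32, xtol=1e-10)]
        detected = hopf_points(T_grid, box1, resource)
        np.testing.assert_allclose(detected, oracle, atol=1e-6)

    def test_trace_vanishes_and_det_positive_at_hopf(self, box1, resource, T_grid):
        from thermoniche.logistic_model import _coexistence_state, _jacobian
        for Th in hopf_points(T_grid, box1, resource, refine_xtol=1e-12):
            R, C = _coexistence_state(Th, box1, resource)
            J = _jacobian(R, C, Th, box1, resource)
            assert abs(J[0, 0] + J[1, 1]) < 1e-8
            assert np.linalg.det(J) > 0


@pytest.fixture(scope="module")
def branch(box1_r1, resource, T_grid):
    return logistic_branch_scan(T_grid, box1_r1, resource)


class TestBranchScan:
    def test_resource_birth_death_transcriticals(self, branch):
        bifs = sorted(branch.bifurcation_temperatures("transcritical"))
        assert bifs[0] == pytest.approx(R_ZEROS[0], abs=1e-5)
        assert bifs[-1] == pytest.approx(R_ZEROS[1], abs=1e-5)

    def test_four_transcriticals_and_no_hopf_for_R0_1(self, branch):
        assert len(branch.bifurcation_temperatures("transcritical")) == 4
        assert branch.bifurcation_temperatures("hopf") == []

    def test_coexistence_band_strictly_inside_resource_band(self, branch):
        bifs = sorted(branch.bifurcation_temperatures("transcritical"))
        r_lo, in_lo, in_hi, r_hi = bifs
        assert r_lo < in_lo < in_hi < r_hi

    def test_resource_density_rises_approaching_upper_limit(self, branch):
        """R_hat = R*(T) increases toward realized Tmax (no mismatch)."""
        coex = sorted(branch.coexistence(), key=lambda r: r.T)
        R = np.array([r.R_hat for r in coex])
        tail = R[-40:]
        assert np.all(np.diff(tail) > 0)

    def test_coexistence_resource_tracks_rstar(self, branch, box1_r1):
        for rec in branch.coexistence()[::37]:
            assert rec.R_hat == pytest.approx(rstar(rec.T, box1_r1), rel=1e-12)


class TestLiebigLimitation:
    def test_narrow_resource_niche_sets_consumer_limits(self, box1):
        """With a resource niche nested inside the consumer's, coexistence
        limits follow r(T)=0, not consumer physiology (law of the minimum)."""
        rt = ResourceTraits(beta_r=30.0)
        lo = brentq(lambda T: resource_intrinsic_rate(T, rt, box1.T_I), 5, 25)
        hi = brentq(lambda T: resource_intrinsic_rate(T, rt, box1.T_I), 25, 45)
        assert lo > 7.96 + 3 and hi < 33.08 - 0.5  # strictly inside consumer niche
        branch = logistic_branch_scan(np.arange(5, 40, 0.05), box1, rt)
        coex_T = [r.T for r in branch.coexistence()]
        assert min(coex_T) > lo and max(coex_T) < hi
        assert min(coex_T) - lo < 2.0  # lower edge pinned near resource zero
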