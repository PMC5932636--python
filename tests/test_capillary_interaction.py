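"""Parallel-capillary interaction: flux partition, pair models, decay scales."""

import math
from dataclasses import replace

import numpy as np
import pytest

from coshlib.params import (
    CapillarySpec,
    ResistanceSet,
    TissueSpec,
    k_iv,
    krogh_radius_from_spacing,
)
from coshlib.mean_saturation import extravascular_drop, integrate_mean
from coshlib.capillary_interaction import (
    CapillaryPairState,
    DeltaProfile,
    equal_flux_reference,
    integrate_delta_linearized,
    integrate_pair_explicit,
    integrate_pair_nonlinear,
    interaction_scales,
    pair_conservation_error,
    solve_flux_partition,
)


@pytest.fixture()
def pair_state(array_cap, array_tissue, sol, curve, resistances):
    return CapillaryPairState.from_spacing(
        40.0, spec_phi=array_cap, spec_psi=array_cap, S_a_phi=0.8,
        S_a_psi=0.6, tissue=array_tissue, sol=sol, curve=curve,
        resistances=resistances)


class TestFluxPartition:
    A = 2 * 40.0**2

    def test_symmetric_pressures_split_evenly(self, array_tissue):
        K = k_iv(0.3)
        j_phi, j_psi = solve_flux_partition(60.0, 60.0, self.A, array_tissue,
                                            2.5, K, K)
        expected = array_tissue.M0 * (self.A / 2 - math.pi * 2.5**2)
        assert j_phi == pytest.approx(expected, rel=1e-10)
        assert j_psi == pytest.approx(expected, rel=1e-10)

    def test_swap_symmetry(self, array_tissue):
        K = k_iv(0.3)
        a = solve_flux_partition(66.0, 52.0, self.A, array_tissue, 2.5, K, K)
        b = solve_flux_partition(52.0, 66.0, self.A, array_tissue, 2.5, K, K)
        assert a[0] == pytest.approx(b[1], rel=1e-10)
        assert a[1] == pytest.approx(b[0], rel=1e-10)

    def test_total_flux_constraint_exact(self, array_tissue):
        K = k_iv(0.3)
        j_phi, j_psi = solve_flux_partition(66.0, 52.0, self.A, array_tissue,
                                            2.5, K, K)
        j_tot = array_tissue.M0 * (self.A - 2 * math.pi * 2.5**2)
        assert j_phi + j_psi == pytest.approx(j_tot, rel=1e-14)
        assert j_phi > j_psi  # the better-oxygenated capillary supplies more

    def test_against_brute_force_scan(self, array_tissue):
        # residual of the Po2-continuity equation scanned on a fine grid
        K_phi, K_psi = k_iv(0.3), k_iv(0.45)
        P_phi, P_psi = 66.0, 48.0
        j_phi, _ = solve_flux_partition(P_phi, P_psi, self.A, array_tissue,
                                        2.5, K_phi, K_psi)
        j_tot = array_tissue.M0 * (self.A - 2 * math.pi * 2.5**2)
        grid = np.linspace(-2 * j_tot, 3 * j_tot, 1_000_001)

        def resid(j):
            dp_phi = np.array([extravascular_drop(v, array_tissue, 2.5)
                               for v in j])
            dp_psi = np.array([extravascular_drop(v, array_tissue, 2.5)
                               for v in j_tot - j])
            return (P_phi - K_phi * j - dp_phi) - (
                P_psi - K_psi * (j_tot - j) - dp_psi)

        # vectorized drop is slow via list comp on 1e6; subsample bracket
        coarse = grid[:: 1000]
        r = resid(coarse)
        k = int(np.argmax(r < 0))
        fine = np.linspace(coarse[k - 1], coarse[k], 100_001)
        rf = resid(fine)
        j_scan = fine[int(np.argmax(rf < 0))]
        assert abs(j_phi - j_scan) < (fine[1] - fine[0]) * 2

    def test_unbracketable_inputs_raise(self, array_tissue):
        with pytest.raises(RuntimeError):
            solve_flux_partition(math.nan, 50.0, self.A, array_tissue, 2.5,
                                 8.0, 8.0)


class TestNonlinearPairModel:
    def test_identical_inlets_never_differ(self, array_cap, array_tissue,
                                           sol, curve, resistances):
        state = CapillaryPairState.from_spacing(
            40.0, spec_phi=array_cap, spec_psi=array_cap, S_a_phi=0.7,
            S_a_psi=0.7, tissue=array_tissue, sol=sol, curve=curve,
            resistances=resistances)
        pp = integrate_pair_nonlinear(state)
        assert np.allclose(pp.delta_S, 0.0, atol=1e-10)

    def test_baseline_difference_drops_by_half(self, pair_state):
        pp = integrate_pair_nonlinear(pair_state)
        assert 0.40 <= pp.drop_fraction <= 0.55

    def test_pair_mean_matches_average_consumption_ode(self, pair_state,
                                                       array_cap, sol,
                                                       curve):
        pp = integrate_pair_nonlinear(pair_state)
        # a single capillary consuming half the slice total
        r_t_eq = math.sqrt(
            pair_state.total_consumption_per_length
            / (2 * math.pi * pair_state.tissue.M0) + array_cap.r_w**2)
        tis = replace(pair_state.tissue, r_t=r_t_eq)
        ref = integrate_mean(0.7, array_cap, tis, sol, curve)
        mean_pair = 0.5 * (pp.S_phi + pp.S_psi)
        dS = ref.S_a - ref.S_v
        assert abs(mean_pair[-1] - ref.S_v) < 0.01 * dS

    def test_conservation(self, pair_state):
        pp = integrate_pair_nonlinear(pair_state, dx_out=0.25)
        assert pair_conservation_error(pp, pair_state) < 1e-4

    def test_countercurrent_flow(self, pair_state):
        pp = integrate_pair_nonlinear(pair_state, countercurrent=True)
        # psi flows in -x: its imposed inlet value is met at x = L
        assert pp.S_psi[-1] == pytest.approx(0.6, abs=1e-4)
        # both capillaries still lose oxygen along their own flow direction
        assert pp.S_phi[-1] < pp.S_phi[0]
        assert pp.S_psi[0] < pp.S_psi[-1]


class TestExplicitPairModel:
    def test_identical_inlets_never_differ(self, array_cap, array_tissue,
                                           sol, curve, resistances):
        state = CapillaryPairState.from_spacing(
            40.0, spec_phi=array_cap, spec_psi=array_cap, S_a_phi=0.7,
            S_a_psi=0.7, tissue=array_tissue, sol=sol, curve=curve,
            resistances=resistances)
        pp = integrate_pair_explicit(state)
        assert np.allclose(pp.delta_S, 0.0, atol=1e-12)

    def test_interaction_terms_antisymmetric(self, pair_state):
        pp = integrate_pair_explicit(pair_state)
        j_bar = pair_state.tissue.M0 * math.pi * (
            pair_state.r_t_mean**2 - pair_state.spec_phi.r_w**2)
        assert np.allclose(pp.jt_phi + pp.jt_psi, 2 * j_bar, rtol=1e-12)

    def test_close_to_nonlinear_model(self, pair_state):
        nl = integrate_pair_nonlinear(pair_state)
        ex = integrate_pair_explicit(pair_state)
        drop = nl.delta_S_a - nl.delta_S_v
        assert abs(ex.delta_S_v - nl.delta_S_v) <= 0.08 * drop

    def test_conservation(self, pair_state):
        pp = integrate_pair_explicit(pair_state, dx_out=0.25)
        assert pair_conservation_error(pp, pair_state) < 1e-4

    def test_refuses_unequal_linear_density(self, array_cap, array_tissue,
                                            sol, curve, resistances):
        other = replace(array_cap, mu_LD=0.5)
        state = CapillaryPairState.from_spacing(
            40.0, spec_phi=array_cap, spec_psi=other, S_a_phi=0.8,
            S_a_psi=0.6, tissue=array_tissue, sol=sol, curve=curve,
            resistances=resistances)
        with pytest.raises(ValueError):
            integrate_pair_explicit(state)

    def test_allows_unequal_velocities(self, array_cap, array_tissue, sol,
                                       curve, resistances):
        other = replace(array_cap, v_rbc=1500.0)
        state = CapillaryPairState.from_spacing(
            40.0, spec_phi=array_cap, spec_psi=other, S_a_phi=0.8,
            S_a_psi=0.6, tissue=array_tissue, sol=sol, curve=curve,
            resistances=resistances)
        pp = integrate_pair_explicit(state)
        assert pp.delta_S_v < pp.delta_S_a


class TestLinearizedDeltaModel:
    def test_zero_difference_stays_zero(self, pair_state):
        dp = integrate_delta_linearized(0.7, 0.0, pair_state)
        assert np.allclose(dp.delta_S, 0.0, atol=1e-14)

    def test_antisymmetry_under_sign_flip(self, pair_state):
        plus = integrate_delta_linearized(0.7, 0.2, pair_state)
        minus = integrate_delta_linearized(0.7, -0.2, pair_state)
        assert np.allclose(plus.delta_S, -minus.delta_S, rtol=1e-10)

    def test_monotone_decay_without_sign_change(self, pair_state):
        dp = integrate_delta_linearized(0.7, 0.2, pair_state)
        assert np.all(dp.delta_S > 0)
        assert np.all(np.diff(np.abs(dp.delta_S)) < 0)

    def test_frozen_mean_gives_exact_exponential(self, pair_state,
                                                 array_cap, array_tissue,
                                                 sol, curve, resistances):
        dp = integrate_delta_linearized(0.7, 0.2, pair_state,
                                        freeze_mean=True, rtol=1e-11,
                                        atol=1e-13)
        L_CI, _ = interaction_scales(0.7, array_cap, array_tissue,
                                     resistances, sol, curve,
                                     r_t_mean=pair_state.r_t_mean)
        expected = 0.2 * np.exp(-dp.x / L_CI)
        assert np.allclose(dp.delta_S, expected, rtol=1e-8)

    def test_close_to_nonlinear_model(self, pair_state):
        nl = integrate_pair_nonlinear(pair_state)
        dp = integrate_delta_linearized(0.7, 0.2, pair_state)
        drop = nl.delta_S_a - nl.delta_S_v
        assert abs(dp.delta_S[-1] - nl.delta_S_v) <= 0.08 * drop

    def test_refuses_unequal_velocities(self, array_cap, array_tissue, sol,
                                        curve, resistances):
        other = replace(array_cap, v_rbc=1500.0)
        state = CapillaryPairState.from_spacing(
            40.0, spec_phi=array_cap, spec_psi=other, S_a_phi=0.8,
            S_a_psi=0.6, tissue=array_tissue, sol=sol, curve=curve,
            resistances=resistances)
        with pytest.raises(ValueError):
            integrate_delta_linearized(0.7, 0.2, state)


class TestEqualFluxReference:
    def test_matches_interacting_model_for_equal_inlets(self, array_cap,
                                                        array_tissue, sol,
                                                        curve, resistances):
        state = CapillaryPairState.from_spacing(
            40.0, spec_phi=array_cap, spec_psi=array_cap, S_a_phi=0.7,
            S_a_psi=0.7, tissue=array_tissue, sol=sol, curve=curve,
            resistances=resistances)
        ef = equal_flux_reference(state)
        nl = integrate_pair_nonlinear(state)
        assert np.allclose(ef.S_phi, nl.S_phi, atol=1e-6)

    def test_interaction_reduces_distal_difference(self, pair_state):
        ef = equal_flux_reference(pair_state)
        nl = integrate_pair_nonlinear(pair_state)
        assert nl.delta_S_v < ef.delta_S_v

    def test_unequal_linear_density_interaction_dominates(
            self, array_cap, array_tissue, sol, curve, resistances):
        # mu_LD 0.6 / 0.2 with equal inlets: heterogeneity arises purely
        # from hematocrit; interaction suppresses most of it
        phi = replace(array_cap, mu_LD=0.6)
        psi = replace(array_cap, mu_LD=0.2)
        state = CapillaryPairState.from_spacing(
            40.0, spec_phi=phi, spec_psi=psi, S_a_phi=0.7, S_a_psi=0.7,
            tissue=array_tissue, sol=sol, curve=curve,
            resistances=resistances)
        ef = equal_flux_reference(state)
        nl = integrate_pair_nonlinear(state)
        assert abs(nl.delta_S_v) < 0.6 * abs(ef.delta_S_v)

    def test_conservation(self, pair_state):
        pp = equal_flux_reference(pair_state, dx_out=0.25)
        assert pair_conservation_error(pp, pair_state) < 1e-4


class TestInteractionScales:
    def test_decay_time_independent_of_velocity(self, array_tissue, sol,
                                                curve, resistances):
        taus = []
        for v in (400.0, 2000.0):
            cap = CapillarySpec(r_c=1.6, r_p=2.0, r_w=2.5, L=100.0, v_rbc=v)
            _, tau = interaction_scales(0.64, cap, array_tissue, resistances,
                                        sol, curve, r_t_mean=22.6)
            taus.append(tau)
        assert taus[0] == pytest.approx(taus[1], rel=1e-14)

    def test_decay_length_scales_with_velocity(self, array_tissue, sol,
                                               curve, resistances):
        caps = [CapillarySpec(r_c=1.6, r_p=2.0, r_w=2.5, L=100.0, v_rbc=v)
                for v in (500.0, 1000.0)]
        Ls = [interaction_scales(0.64, c, array_tissue, resistances, sol,
                                 curve, r_t_mean=22.6)[0] for c in caps]
        assert Ls[1] == pytest.approx(2 * Ls[0], rel=1e-12)

    def test_increases_with_linear_density(self, array_tissue, sol, curve,
                                           resistances):
        taus = []
        for mu in (0.2, 0.4, 0.6):
            cap = CapillarySpec(r_c=1.6, r_p=2.0, r_w=2.5, L=100.0, mu_LD=mu)
            _, tau = interaction_scales(0.5, cap, array_tissue, resistances,
                                        sol, curve, r_t_mean=22.6)
            taus.append(tau)
        assert taus[0] < taus[1] < taus[2]

    def test_weak_logarithmic_spacing_dependence(self, array_cap,
                                                 array_tissue, sol, curve,
                                                 resistances):
        taus = [interaction_scales(
            0.5, array_cap, array_tissue, resistances, sol, curve,
            r_t_mean=krogh_radius_from_spacing(d))[1] for d in (20.0, 60.0)]
        assert taus[1] > taus[0]          # grows with spacing
        assert taus[1] / taus[0] < 2.0    # but less than twofold for 3x

    def test_maximal_near_slope_minimum(self, array_cap, array_tissue, sol,
                                        curve, resistances):
        S_grid = np.linspace(0.1, 0.9, 81)
        taus = [interaction_scales(float(s), array_cap, array_tissue,
                                   resistances, sol, curve,
                                   r_t_mean=22.6)[1] for s in S_grid]
        S_star = S_grid[int(np.argmax(taus))]
        assert abs(S_star - curve.slope_minimizer()) < 0.02
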