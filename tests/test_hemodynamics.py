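"""Microcirculation solvers: Poiseuille/Starling laws, pressure solvers, coupling."""

import dataclasses

import numpy as np
import pytest

from plaqueangio.angiogenesis import VesselNetwork
from plaqueangio.hemodynamics import (
    HemoParams,
    build_nodal_system,
    couple,
    exchange_coefficient_grid,
    global_balance,
    node_conservation_residuals,
    poiseuille_flow,
    solve_interstitial,
    solve_intravascular,
    starling_flux,
)

from conftest import make_random_tree_network


class TestSegmentLaws:
    def test_zero_pressure_drop_gives_zero_flow(self):
        assert poiseuille_flow(4e-4, 3e-5, 0.0, 2e-3) == 0.0

    def test_quartic_radius_dependence(self):
        q1 = poiseuille_flow(4e-4, 3e-5, 1.0, 2e-3)
        q2 = poiseuille_flow(8e-4, 3e-5, 1.0, 2e-3)
        assert q2 == pytest.approx(16 * q1)

    def test_poiseuille_hand_value(self):
        # pi (4e-4)^4 / (8 * 3e-5 * 2e-3) per mmHg
        q = poiseuille_flow(4e-4, 3e-5, 1.0, 2e-3)
        assert q == pytest.approx(np.pi * (4e-4) ** 4 / (8 * 3e-5 * 2e-3), rel=1e-12)
        assert q == pytest.approx(1.68e-7, rel=5e-3)

    def test_bad_geometry_rejected(self):
        with pytest.raises(ValueError):
            poiseuille_flow(0.0, 3e-5, 1.0, 2e-3)

    def test_starling_equilibrium_is_exactly_zero(self):
        # dP = sigma_T (pi_V - pi_i) = 0.82 * 5 = 4.1 mmHg
        q = starling_flux(4e-4, 2e-3, 2.8e-7, 10.0, 10.0 - 4.1, 0.82, 20.0, 15.0)
        assert q == 0.0

    def test_starling_hand_value_and_linearity(self):
        q = starling_flux(4e-4, 2e-3, 2.8e-7, 10.0, 0.0, 0.82, 20.0, 15.0)
        assert q == pytest.approx(2 * np.pi * 4e-4 * 2e-3 * 2.8e-7 * 5.9, rel=1e-12)
        assert q == pytest.approx(8.3e-12, rel=2e-2)
        half = starling_flux(4e-4, 2e-3, 1.4e-7, 10.0, 0.0, 0.82, 20.0, 15.0)
        assert half == pytest.approx(q / 2)


def _chain_network(n=12, nx=32, ny=32):
    net = VesselNetwork(ny=ny, nx=nx, h_cm=0.4 / 200)
    y = ny // 2
    net.roots = np.array([[2, y]])
    net.A[y, 2] = True
    for i in range(n):
        net.add_segment((2 + i, y), (3 + i, y))
    return net


class TestIntravascular:
    def test_pure_poiseuille_chain_is_linear_in_arclength(self):
        params = HemoParams(L_p=0.0, tol=1e-12)
        net = _chain_network(n=10)
        P, err, sys = solve_intravascular(net, np.zeros((32, 32)), params)
        xs = sys.node_xy[:, 0]
        expected = 10.0 + (1.0 - 10.0) * (xs - 2) / 10.0
        assert np.allclose(P, expected, atol=1e-5)

    def test_maximum_principle(self, rng):
        params = HemoParams()
        for _ in range(5):
            net = make_random_tree_network(rng, n_nodes=40)
            P, _, _ = solve_intravascular(net, np.zeros((64, 64)), params,
                                          method="direct")
            assert P.min() >= params.P_out - 1e-9
            assert P.max() <= params.P_in + 1e-9

    def test_iteration_matches_direct_solve(self, rng):
        params = HemoParams(tol=1e-13)
        for _ in range(8):
            net = make_random_tree_network(rng, n_nodes=25)
            P_i = rng.random((64, 64))
            P_it, err, _ = solve_intravascular(net, P_i, params)
            P_d, _, _ = solve_intravascular(net, P_i, params, method="direct")
            assert np.abs(P_it - P_d).max() < 1e-8


class TestInterstitial:
    def test_no_vessels_zero_boundary_gives_zero_field(self):
        params = HemoParams()
        z = np.zeros((20, 20))
        P, err, _ = solve_interstitial(z, z, z.astype(bool), params, z.astype(bool))
        assert (P == 0).all()

    def test_single_source_peaks_at_the_vessel_cell(self):
        params = HemoParams()
        n = 21
        a2 = np.zeros((n, n))
        a2[10, 10] = 0.5
        mask = a2 > 0
        Pe = np.where(mask, 5.0, 0.0)
        P, _, _ = solve_interstitial(a2, Pe, mask, params, np.zeros((n, n), bool))
        assert P[10, 10] == P.max() > 0
        # radially decreasing toward the boundary along the axes
        assert (np.diff(P[10, 10:]) <= 1e-12).all()
        assert (np.diff(P[10:, 10]) <= 1e-12).all()

    def test_sor_matches_direct_solve(self, rng):
        params = HemoParams(tol=1e-13)
        for _ in range(5):
            n = 10
            mask = np.zeros((n, n), bool)
            cells = rng.integers(1, n - 1, size=(5, 2))
            mask[cells[:, 0], cells[:, 1]] = True
            a2 = np.where(mask, 0.3, 0.0)
            Pe = np.where(mask, rng.uniform(3, 6, (n, n)), 0.0)
            dm = np.zeros((n, n), bool)
            P_sor, err, _ = solve_interstitial(a2, Pe, mask, params, dm)
            P_dir, _, _ = solve_interstitial(a2, Pe, mask, params, dm, method="direct")
            assert np.abs(P_sor - P_dir).max() < 1e-8

    def test_omega_outside_range_rejected(self):
        params = HemoParams(omega=2.5)
        z = np.zeros((8, 8))
        with pytest.raises(ValueError):
            solve_interstitial(z, z, z.astype(bool), params, z.astype(bool))


class TestCoupling:
    def test_impermeable_wall_decouples_the_problems(self, rng):
        params = HemoParams(L_p=0.0)
        net = make_random_tree_network(rng, n_nodes=30)
        state = couple(net, params)
        assert np.abs(state.Q_t).max() == 0.0
        assert np.abs(state.P_i).max() == 0.0

    def test_conservation_and_global_balance(self, rng):
        params = HemoParams()
        net = make_random_tree_network(rng, n_nodes=60)
        state = couple(net, params)
        sys = build_nodal_system(net, params)
        res = node_conservation_residuals(state, sys, params)
        assert res.max() <= 1e-5
        inflow, outflow, leak = global_balance(state, sys)
        assert inflow == pytest.approx(outflow + leak, rel=1e-6)

    def test_starling_sign_property(self, rng):
        params = HemoParams()
        net = make_random_tree_network(rng, n_nodes=50)
        state = couple(net, params)
        a, b = state.seg_nodes[:, 0], state.seg_nodes[:, 1]
        pbar_v = 0.5 * (state.P_V_nodes[a] + state.P_V_nodes[b])
        xy = state.node_xy
        pi_n = state.P_i[xy[:, 1], xy[:, 0]]
        pbar_i = 0.5 * (pi_n[a] + pi_n[b])
        drive = pbar_v - pbar_i - params.oncotic_jump
        assert np.all(np.sign(state.Q_t) == np.sign(drive))

    def test_total_leak_monotone_in_permeability(self, rng):
        net = make_random_tree_network(rng, n_nodes=50)
        totals = []
        for lp in (1.4e-7, 2.8e-7, 5.6e-7):
            state = couple(net, HemoParams(L_p=lp))
            totals.append(np.abs(state.Q_t).sum())
        assert totals[0] <= totals[1] <= totals[2]

    def test_exchange_coefficient_scales_with_wall_area(self):
        net = _chain_network(n=4)
        params = HemoParams()
        a2 = exchange_coefficient_grid(net, params)
        # interior chain cells carry both adjacent segments' full wall areas
        w1 = 2 * np.pi * 4e-4 * net.seg_len[0]
        expected_interior = 2 * w1 * params.L_p / (params.K * net.h_cm)
        y = 16
        assert a2[y, 4] == pytest.approx(expected_interior)
        assert a2[y, 2] == pytest.approx(expected_interior / 2)  # chain end
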