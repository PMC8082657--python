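"""Nine-point tip walk: motion law, branching, anastomosis, topology invariants."""

import dataclasses

import numpy as np
import pytest

from plaqueangio.angiogenesis import (
    LEN2,
    OFFSETS,
    OPPOSITE,
    BranchConfig,
    Tip,
    TipBoundaryError,
    VesselNetwork,
    anastomose,
    branch,
    init_network,
    motion_coefficients,
    move_tips,
    run_angiogenesis,
)
from plaqueangio.fields import init_fields
from plaqueangio.hemorrhage import compute_mvd


def _stencil_oracle(c, f, x, y, coeffs, gain):
    """Naive re-derivation of the nine movement probabilities."""
    chi = coeffs.chi_0 * coeffs.k_1 / (coeffs.k_1 + c[y, x])
    offsets = [(0, 0), (1, 0), (-1, 0), (0, 1), (0, -1),
               (-1, 1), (1, -1), (-1, -1), (1, 1)]
    raw = [0.0]
    for k in range(1, 9):
        dx, dy = offsets[k]
        l2 = 1.0 if k <= 4 else 2.0
        dc = c[y + dy, x + dx] - c[y - dy, x - dx]
        df = f[y + dy, x + dx] - f[y - dy, x - dx]
        raw.append(max(0.0, gain * (coeffs.D_n + (chi * dc + coeffs.rho_0 * df) / (2 * l2))))
    raw[0] = max(0.0, 1.0 - sum(raw[1:]))
    s = sum(raw)
    return np.array(raw) / (s if s > 0 else 1.0)


class TestMotionCoefficients:
    def test_uniform_fields_give_isotropic_moves(self, baseline_coeffs):
        c = np.full((9, 9), 1.3)
        f = np.ones((9, 9))
        p = motion_coefficients(c, f, (4, 4), baseline_coeffs, motion_gain=100.0)
        assert p.sum() == pytest.approx(1.0, abs=1e-14)
        assert np.allclose(p[1:], p[1]), "eight directions must be equiprobable"
        assert p[0] == pytest.approx(1.0 - 8 * 100.0 * baseline_coeffs.D_n)

    def test_steep_vegf_gradient_selects_its_direction(self, baseline_coeffs):
        c = np.tile(np.linspace(0.0, 2.0, 9), (9, 1))  # increasing in +x
        f = np.ones((9, 9))
        p = motion_coefficients(c, f, (4, 4), baseline_coeffs, motion_gain=100.0)
        assert p[1] == max(p[1:]), "+x must be the strict directional maximum"
        assert p[1] > p[2]

    def test_matches_independent_stencil_oracle(self, baseline_coeffs, rng):
        for _ in range(25):
            c = 1.0 + 0.3 * rng.standard_normal((9, 9)).cumsum(axis=1) / 3
            f = np.clip(1.0 - 0.05 * rng.random((9, 9)), 0, 1)
            c = np.abs(c)
            p = motion_coefficients(c, f, (4, 4), baseline_coeffs, motion_gain=700.0)
            q = _stencil_oracle(c, f, 4, 4, baseline_coeffs, 700.0)
            assert p.sum() == pytest.approx(1.0, abs=1e-12)
            assert np.allclose(p, q, atol=1e-12)

    def test_boundary_margin_rejected(self, baseline_coeffs):
        c = np.ones((9, 9))
        with pytest.raises(TipBoundaryError):
            motion_coefficients(c, c, (0, 4), baseline_coeffs)


def _single_tip_net(nx=15, ny=15, at=(7, 7)):
    net = VesselNetwork(ny=ny, nx=nx, h_cm=0.4 / 200)
    net.roots = np.array([at])
    net.A[at[1], at[0]] = True
    net.tips.append(Tip(*at, age=0, branch_id=0))
    net.next_branch_id = 1
    return net


class _ChemStub:
    def __init__(self, c, f):
        self.c, self.f = c, f


class TestMoveTips:
    def test_zero_motion_leaves_network_unchanged(self, baseline_coeffs, rng):
        net = _single_tip_net()
        coeffs = dataclasses.replace(baseline_coeffs, D_n=0.0, chi_0=0.0, rho_0=0.0)
        chem = _ChemStub(np.ones((15, 15)), np.ones((15, 15)))
        added = move_tips(net, chem, rng, np.zeros((15, 15), bool), coeffs)
        assert added == 0 and net.n_segments == 0
        assert (net.tips[0].x, net.tips[0].y) == (7, 7)

    def test_forced_axial_move_creates_one_cell_segment(self, baseline_coeffs, rng):
        net = _single_tip_net()
        # a VEGF spot on the +x neighbour only: every other directional
        # difference is zero or negative, so P(+x) = 1 after clamping
        c = np.zeros((15, 15))
        c[7, 8] = 5.0
        coeffs = dataclasses.replace(baseline_coeffs, D_n=0.0, rho_0=0.0, chi_0=10.0)
        chem = _ChemStub(c, np.ones((15, 15)))
        added = move_tips(net, chem, rng, np.zeros((15, 15), bool), coeffs,
                          motion_gain=1e6)
        assert added == 1
        assert (net.tips[0].x, net.tips[0].y) == (8, 7)
        assert net.seg_len[0] == pytest.approx(0.4 / 200)

    def test_lumen_blocks_movement(self, baseline_coeffs, rng):
        net = _single_tip_net()
        c = np.tile(np.linspace(0.0, 14.0, 15), (15, 1))
        coeffs = dataclasses.replace(baseline_coeffs, D_n=0.0, rho_0=0.0, chi_0=10.0)
        lumen = np.zeros((15, 15), bool)
        lumen[:, 8:] = True
        chem = _ChemStub(c, np.ones((15, 15)))
        added = move_tips(net, chem, rng, lumen, coeffs, motion_gain=1e6)
        assert added == 0 and (net.tips[0].x, net.tips[0].y) == (7, 7)

    def test_empirical_move_frequencies_match_probabilities(self, baseline_coeffs):
        c = 1.0 + np.add.outer(np.linspace(0, 0.3, 15), np.linspace(0, 0.2, 15))
        f = np.ones((15, 15))
        p = motion_coefficients(c, f, (7, 7), baseline_coeffs, motion_gain=3000.0)
        trials = 8000
        counts = np.zeros(9)
        rng = np.random.default_rng(7)
        for _ in range(trials):
            net = _single_tip_net()
            move_tips(net, _ChemStub(c, f), rng, np.zeros((15, 15), bool),
                      baseline_coeffs, motion_gain=3000.0)
            tip = net.tips[0]
            d = (tip.x - 7, tip.y - 7)
            k = next(i for i in range(9) if tuple(OFFSETS[i]) == d)
            counts[k] += 1
        freq = counts / trials
        sigma = np.sqrt(p * (1 - p) / trials)
        assert (np.abs(freq - p) <= 3 * sigma + 1e-12).all()


class TestBranching:
    def _net_with_aged_tip(self, age):
        net = _single_tip_net()
        net.tips[0].age = age
        return net

    def test_young_tips_never_branch(self, baseline_coeffs, rng):
        net = self._net_with_aged_tip(0)
        c = np.full((15, 15), 10.0)
        cfg = BranchConfig(scale=1.0)
        events = branch(net, c, rng, cfg, np.zeros((15, 15), bool), baseline_coeffs)
        assert events == 0

    def test_crowded_tips_never_branch(self, baseline_coeffs, rng):
        net = self._net_with_aged_tip(100)
        for k in range(1, 9):
            dx, dy = OFFSETS[k]
            net.add_segment((7, 7), (7 + dx, 7 + dy))
        c = np.full((15, 15), 10.0)
        events = branch(net, c, rng, BranchConfig(), np.zeros((15, 15), bool),
                        baseline_coeffs)
        assert events == 0

    def test_mature_tip_splits_into_two_daughters(self, baseline_coeffs, rng):
        net = self._net_with_aged_tip(100)
        net.c_ref = 1.0
        c = np.full((15, 15), 10.0)  # ratio >> top tier -> probability 1
        events = branch(net, c, rng, BranchConfig(), np.zeros((15, 15), bool),
                        baseline_coeffs)
        assert events == 1
        assert net.n_segments == 2
        actives = net.active_tips
        assert len(actives) == 2 and all(t.age == 0 for t in actives)

    def test_tier_function_is_monotone_step(self):
        cfg = BranchConfig()
        # brute-force enumeration over the tier boundaries
        expected = {0.1: 0.0, 0.29: 0.0, 0.31: 0.2, 0.51: 0.3, 0.71: 0.4, 0.9: 1.0}
        for ratio, p in expected.items():
            assert cfg.probability(ratio) == pytest.approx(p)
        grid = np.linspace(0, 1.5, 400)
        vals = [cfg.probability(r) for r in grid]
        assert (np.diff(vals) >= 0).all()
        assert cfg.probability(0.05) == 0.0 and cfg.probability(2.0) == 1.0


class TestAnastomosis:
    def test_two_tips_on_one_cell_keep_the_elder(self):
        net = _single_tip_net()
        net.tips[0].age = 5
        net.tips.append(Tip(7, 7, age=9, branch_id=1))
        retired = anastomose(net)
        assert retired == 1
        survivor = net.active_tips
        assert len(survivor) == 1 and survivor[0].age == 9

    def test_age_tie_broken_by_lower_branch_id(self):
        net = _single_tip_net()
        net.tips[0].age = 5
        net.tips.append(Tip(7, 7, age=5, branch_id=1))
        anastomose(net)
        assert net.active_tips[0].branch_id == 0

    def test_tip_landing_on_vessel_node_is_retired(self):
        net = _single_tip_net()
        net.tips[0].landed_on_occupied = True
        retired = anastomose(net)
        assert retired == 1 and not net.active_tips

    def test_no_contact_changes_nothing(self):
        net = _single_tip_net()
        net.tips.append(Tip(9, 9, age=1, branch_id=1))
        assert anastomose(net) == 0
        assert len(net.active_tips) == 2


def _check_topology(net):
    """A/B reciprocity, endpoint occupancy, and root-connectivity."""
    ny, nx = net.A.shape
    ys, xs, ks = np.nonzero(net.B)
    for y, x, k in zip(ys, xs, ks):
        dx, dy = OFFSETS[k]
        assert net.B[y + dy, x + dx, OPPOSITE[k]], "B must be reciprocal"
        assert net.A[y, x] and net.A[y + dy, x + dx]
    # BFS from roots over segments reaches every occupied node
    seen = set()
    frontier = [tuple(r) for r in net.roots]
    seen.update(frontier)
    while frontier:
        x, y = frontier.pop()
        for k in range(1, 9):
            if net.B[y, x, k]:
                dx, dy = OFFSETS[k]
                nxt = (x + dx, y + dy)
                if nxt not in seen:
                    seen.add(nxt)
                    frontier.append(nxt)
    occupied = {(int(x), int(y)) for y, x in zip(*np.nonzero(net.A))}
    assert occupied == seen, "every occupied node must connect to a root"


def test_growth_preserves_topology_and_determinism(small_domain, baseline_coeffs):
    chem1 = init_fields(small_domain, baseline_coeffs)
    hist1 = run_angiogenesis(
        small_domain, chem1, baseline_coeffs, np.random.default_rng(3),
        branch_cfg=BranchConfig(scale=0.003), stage_steps=60, max_stages=4,
        motion_gain=500.0,
    )
    for snap in hist1.snapshots:
        _check_topology(snap.network)
    chem2 = init_fields(small_domain, baseline_coeffs)
    hist2 = run_angiogenesis(
        small_domain, chem2, baseline_coeffs, np.random.default_rng(3),
        branch_cfg=BranchConfig(scale=0.003), stage_steps=60, max_stages=4,
        motion_gain=500.0,
    )
    assert hist1.termination_stage == hist2.termination_stage
    n1, n2 = hist1.snapshots[-1].network, hist2.snapshots[-1].network
    assert n1.seg_a == n2.seg_a and n1.seg_b == n2.seg_b
    assert (n1.A == n2.A).all()


def test_mvd_is_nondecreasing_over_stages(small_domain, baseline_coeffs):
    chem = init_fields(small_domain, baseline_coeffs)
    hist = run_angiogenesis(
        small_domain, chem, baseline_coeffs, np.random.default_rng(5),
        branch_cfg=BranchConfig(scale=0.003), stage_steps=60, max_stages=5,
        motion_gain=500.0,
    )
    mvds = [compute_mvd(s.network, small_domain, "ALL") for s in hist.snapshots]
    assert (np.diff(mvds) >= 0).all()
    assert len(hist.snapshots) == hist.termination_stage


def test_zero_rates_terminate_immediately(small_domain, baseline_coeffs):
    coeffs = dataclasses.replace(baseline_coeffs, D_n=0.0, chi_0=0.0, rho_0=0.0)
    chem = init_fields(small_domain, coeffs)
    hist = run_angiogenesis(
        small_domain, chem, coeffs, np.random.default_rng(1),
        branch_cfg=BranchConfig(probs=(0, 0, 0, 0, 0)), stage_steps=30,
        max_stages=5, motion_gain=0.0,
    )
    assert hist.termination_stage == 1
    assert hist.snapshots[-1].network.n_segments == 0
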