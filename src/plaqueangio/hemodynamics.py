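"""Coupled microcirculation hemodynamics on a grown capillary network.

Three coupled sub-problems are solved on each staged network:

* intravascular nodal pressures ``P_V`` -- Poiseuille flow through the
  segments with Starling transvascular leakage, nodal flow conservation
  ``sum_k (Q_V^k - Q_t^k) B^k = 0`` with Dirichlet pressures at the 12
  vasa-vasorum roots (``P_in``) and at dead-end terminals (``P_out``);
* interstitial pressure ``P_i`` -- Darcy flow through the plaque tissue with
  a distributed Starling source on vessel-occupied cells,
  ``lap(P_i) = alpha^2 (P_i - P_e) A`` with ``P_e = P_V - sigma_T (pi_V -
  pi_i)``, Dirichlet ``P_i = 0`` on the outer boundary and in the lumen;
* the Starling exchange itself, ``Q_t = 2 pi R dl L_p (Pbar_V - Pbar_i -
  sigma_T (pi_V - pi_i))`` per segment, charged at each endpoint node.

The two pressure problems are alternated until both relative-change residuals
fall below tolerance, then flows (Poiseuille ``Q_V``, Starling ``Q_t``, net
``Q``), intravascular velocities ``U_V = Q_V / (pi R^2)`` and the Darcy
interstitial velocity ``U_i = -K grad(P_i)`` are evaluated.

Both pressure solvers exist in two verified-equivalent forms: the iterative
schemes (nodal fixed-point iteration; red-black successive over-relaxation)
and direct sparse solves of the identical linear systems.  The direct forms
are the pipeline default for speed; the iterative forms are first-class and
cross-checked against the direct ones in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .angiogenesis import VesselNetwork


class ConvergenceError(RuntimeError):
    """Raised when an iterative pressure solve fails to converge."""

    def __init__(self, msg, residuals=None):
        super().__init__(msg)
        self.residuals = residuals or []


@dataclass(frozen=True)
class HemoParams:
    """Baseline hemodynamic parameters (pressures in mmHg, lengths in cm)."""

    K: float = 41.3e-9        # interstitial hydraulic conductivity, cm^2/(mmHg s)
    L_p: float = 2.8e-7       # wall hydraulic permeability, cm/(mmHg s)
    sigma_T: float = 0.82     # osmotic reflection coefficient
    pi_V: float = 20.0        # plasma colloid osmotic pressure, mmHg
    pi_i: float = 15.0        # interstitial colloid osmotic pressure, mmHg
    P_in: float = 10.0        # root (vasa vasorum) pressure, mmHg
    P_out: float = 1.0        # dead-end terminal pressure, mmHg
    mu_bar: float = 3.0e-5    # blood viscosity, mmHg s (~4 mPa s)
    omega: float = 1.5        # SOR relaxation coefficient
    tol: float = 1.0e-6       # residual tolerance for both pressure solves
    alpha_scale: float = 1.0  # multiplier on the alpha^2 exchange closure
    max_iter: int = 200_000

    def __post_init__(self):
        if not 0.0 <= self.sigma_T <= 1.0:
            raise ValueError("sigma_T must lie in [0, 1]")
        for name in ("K", "pi_V", "pi_i", "P_in", "P_out", "mu_bar", "tol"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.L_p < 0:  # an impermeable wall (L_p = 0) is a valid limit
            raise ValueError("L_p must be non-negative")

    @property
    def oncotic_jump(self) -> float:
        """sigma_T (pi_V - pi_i), the Starling equilibrium pressure drop."""
        return self.sigma_T * (self.pi_V - self.pi_i)


@dataclass
class HemodynamicState:
    """Converged hemodynamic solution on one staged network."""

    node_xy: np.ndarray       # (N, 2) vessel node coordinates (cells)
    P_V_nodes: np.ndarray     # (N,) nodal intravascular pressure, mmHg
    P_V: np.ndarray           # (ny, nx) P_V rasterized on vessel cells (0 else)
    P_i: np.ndarray           # (ny, nx) interstitial pressure, mmHg
    Q_V: np.ndarray           # (S,) per-segment Poiseuille flow, cm^3/s
    Q_t: np.ndarray           # (S,) per-segment Starling flow, cm^3/s
    Q: np.ndarray             # (S,) net flow Q_V - Q_t, cm^3/s
    U_V: np.ndarray           # (S,) intravascular velocity, cm/s
    U_i: np.ndarray           # (2, ny, nx) interstitial velocity, cm/s
    err_PV: float
    err_Pi: float
    outer_iters: int
    root_nodes: np.ndarray = None
    terminal_nodes: np.ndarray = None
    seg_nodes: np.ndarray = None  # (S, 2) node indices of each segment


def poiseuille_flow(R: float, mu: float, dP: float, dl: float) -> float:
    """Poiseuille segment flow pi R^4 dP / (8 mu dl), signed by dP."""
    if R <= 0 or mu <= 0 or dl <= 0:
        raise ValueError("radius, viscosity and length must be positive")
    return np.pi * R**4 * dP / (8.0 * mu * dl)


def starling_flux(
    R: float, dl: float, L_p: float,
    Pbar_V: float, Pbar_i: float,
    sigma_T: float, pi_V: float, pi_i: float,
) -> float:
    """Starling transvascular flow 2 pi R dl L_p (dP - sigma_T d pi)."""
    if R <= 0 or dl <= 0:
        raise ValueError("radius and length must be positive")
    return 2.0 * np.pi * R * dl * L_p * (Pbar_V - Pbar_i - sigma_T * (pi_V - pi_i))


@dataclass
class _NodalSystem:
    """Assembled intravascular problem: indices, conductances, Dirichlet data."""

    node_xy: np.ndarray
    node_index: dict
    seg_nodes: np.ndarray   # (S, 2) node indices
    g: np.ndarray           # (S,) Poiseuille conductance pi R^4/(8 mu dl)
    beta: np.ndarray        # (S,) wall exchange coefficient 2 pi R dl L_p
    dirichlet: np.ndarray   # (N,) bool
    dirichlet_value: np.ndarray
    root_nodes: np.ndarray
    terminal_nodes: np.ndarray


def build_nodal_system(network: VesselNetwork, params: HemoParams) -> _NodalSystem:
    """Index the network nodes and assemble per-segment coefficients.

    Roots carry ``P_in``; dead ends (degree-1 non-root nodes, i.e. exits
    where vessels stopped growing) carry ``P_out``; anastomosed loops carry
    no Dirichlet condition.  Isolated roots (no segments) are excluded.
    """
    if network.n_segments == 0:
        raise ValueError("network has no segments")
    cells = sorted(set(network.seg_a) | set(network.seg_b))
    node_index = {c: i for i, c in enumerate(cells)}
    node_xy = np.array(cells, dtype=int)
    S = network.n_segments
    seg_nodes = np.empty((S, 2), dtype=int)
    degree = np.zeros(len(cells), dtype=int)
    for i in range(S):
        a = node_index[network.seg_a[i]]
        b = node_index[network.seg_b[i]]
        seg_nodes[i] = (a, b)
        degree[a] += 1
        degree[b] += 1
    R = np.asarray(network.seg_R)
    dl = np.asarray(network.seg_len)
    g = np.pi * R**4 / (8.0 * params.mu_bar * dl)
    beta = 2.0 * np.pi * R * dl * params.L_p
    root_set = {tuple(r) for r in network.roots} if network.roots is not None else set()
    is_root = np.array([tuple(c) in root_set for c in cells])
    dirichlet = is_root | (degree == 1)
    value = np.where(is_root, params.P_in, params.P_out)
    return _NodalSystem(
        node_xy=node_xy,
        node_index=node_index,
        seg_nodes=seg_nodes,
        g=g,
        beta=beta,
        dirichlet=dirichlet,
        dirichlet_value=np.where(dirichlet, value, 0.0),
        root_nodes=np.flatnonzero(is_root),
        terminal_nodes=np.flatnonzero(dirichlet & ~is_root),
    )


def _segment_Pbar_i(sys: _NodalSystem, P_i: np.ndarray) -> np.ndarray:
    """Mean interstitial pressure along each segment (endpoint average)."""
    xy = sys.node_xy
    pi_nodes = P_i[xy[:, 1], xy[:, 0]]
    return 0.5 * (pi_nodes[sys.seg_nodes[:, 0]] + pi_nodes[sys.seg_nodes[:, 1]])


def solve_intravascular(
    network: VesselNetwork,
    P_i: np.ndarray,
    params: HemoParams,
    method: str = "iterative",
    P0: np.ndarray = None,
    sys: _NodalSystem = None,
) -> tuple:
    """Solve nodal P_V for fixed interstitial pressure.

    ``method='iterative'`` runs the nodal fixed-point update

        P_c <- [sum_k (g_k - beta_k/2) P_k + sum_k beta_k (Pbar_i,k + sigma_T dpi)]
               / sum_k (g_k + beta_k/2)

    (the conservation equation solved for the centre pressure) to the
    relative-change tolerance; ``method='direct'`` solves the identical
    sparse linear system.  Returns ``(P_V_nodes, err, system)``.
    """
    if sys is None:
        sys = build_nodal_system(network, params)
    pbar_i = _segment_Pbar_i(sys, P_i)
    rhs_seg = sys.beta * (pbar_i + params.oncotic_jump)
    N = len(sys.node_xy)
    a, b = sys.seg_nodes[:, 0], sys.seg_nodes[:, 1]
    off = sys.g - 0.5 * sys.beta
    diag_c = sys.g + 0.5 * sys.beta
    # Assemble: for free node c, sum_k diag_c = off * P_k + rhs_seg
    diag = np.zeros(N)
    np.add.at(diag, a, diag_c)
    np.add.at(diag, b, diag_c)
    rhs = np.zeros(N)
    np.add.at(rhs, a, rhs_seg)
    np.add.at(rhs, b, rhs_seg)
    W = sp.coo_matrix(
        (np.concatenate([off, off]), (np.concatenate([a, b]), np.concatenate([b, a]))),
        shape=(N, N),
    ).tocsr()
    fixed = sys.dirichlet
    if method == "direct":
        Amat = sp.diags(diag) - W
        Amat = Amat.tolil()
        for i in np.flatnonzero(fixed):
            Amat.rows[i] = [i]
            Amat.data[i] = [1.0]
        bvec = np.where(fixed, sys.dirichlet_value, rhs)
        P = spla.spsolve(Amat.tocsr(), bvec)
        return P, 0.0, sys
    if method != "iterative":
        raise ValueError(f"unknown method {method!r}")
    P = P0.copy() if P0 is not None else np.full(N, params.P_out)
    P[fixed] = sys.dirichlet_value[fixed]
    err = np.inf
    for it in range(params.max_iter):
        Pn = (W @ P + rhs) / np.maximum(diag, 1e-300)
        Pn[fixed] = sys.dirichlet_value[fixed]
        denom = np.abs(Pn).sum()
        err = np.abs(Pn - P).sum() / max(denom, 1e-300)
        P = Pn
        if err <= params.tol:
            return P, err, sys
    raise ConvergenceError(
        f"intravascular iteration stalled at err={err:.3e} after {params.max_iter} sweeps"
    )


def exchange_coefficient_grid(
    network: VesselNetwork, params: HemoParams
) -> np.ndarray:
    """Per-cell alpha^2 dx^2: wall-exchange strength of the Darcy source.

    Each segment contributes its full wall area ``2 pi R dl`` to both
    endpoint cells (matching the nodal conservation convention); the closure
    is ``alpha^2 = W_cell L_p / (K dx^2 h)`` with slab depth ``h = dx``,
    returned premultiplied by ``dx^2``.
    """
    wall = np.zeros_like(network.A, dtype=float)
    for i in range(network.n_segments):
        w = 2.0 * np.pi * network.seg_R[i] * network.seg_len[i]
        ax, ay = network.seg_a[i]
        bx, by = network.seg_b[i]
        wall[ay, ax] += w
        wall[by, bx] += w
    return params.alpha_scale * wall * params.L_p / (params.K * network.h_cm)


def rasterize_nodal(network_or_xy, values: np.ndarray, shape: tuple) -> np.ndarray:
    """Scatter nodal values onto the grid (zeros elsewhere)."""
    xy = network_or_xy
    grid = np.zeros(shape)
    grid[xy[:, 1], xy[:, 0]] = values
    return grid


def solve_interstitial(
    alpha2dx2: np.ndarray,
    P_e: np.ndarray,
    vessel_mask: np.ndarray,
    params: HemoParams,
    dirichlet_mask: np.ndarray,
    method: str = "sor",
    P0: np.ndarray = None,
    lu=None,
) -> tuple:
    """Solve the interstitial Darcy pressure with distributed vessel sources.

    Discrete equation per free cell (grid units):

        P(E) + P(W) + P(N) + P(S) - 4 P - a2 A (P - P_e) = 0,  a2 = alpha^2 dx^2

    with Dirichlet zero on ``dirichlet_mask`` (outer boundary + lumen).
    ``method='sor'`` runs red-black successive over-relaxation with
    relaxation ``params.omega``; ``method='direct'`` solves the same sparse
    system (pass ``lu`` to reuse a factorization).  Returns ``(P_i, err, lu)``.
    """
    if not 0.0 < params.omega < 2.0:
        raise ValueError("SOR relaxation omega must lie in (0, 2)")
    ny, nx = P_e.shape
    a2 = np.where(vessel_mask, alpha2dx2, 0.0)
    src = a2 * np.where(vessel_mask, P_e, 0.0)
    fixed = dirichlet_mask.copy()
    fixed[0, :] = fixed[-1, :] = fixed[:, 0] = fixed[:, -1] = True
    free = ~fixed

    if method == "direct":
        if lu is None:
            idx = -np.ones((ny, nx), dtype=int)
            ii = np.flatnonzero(free.ravel())
            idx.ravel()[ii] = np.arange(len(ii))
            rows, cols, vals = [], [], []
            yy, xx = np.nonzero(free)
            me = idx[yy, xx]
            rows.append(me)
            cols.append(me)
            vals.append(4.0 + a2[yy, xx])
            for dy, dx in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                nb = idx[yy + dy, xx + dx]
                ok = nb >= 0
                rows.append(me[ok])
                cols.append(nb[ok])
                vals.append(np.full(ok.sum(), -1.0))
            Amat = sp.csc_matrix(
                (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
                shape=(len(ii), len(ii)),
            )
            lu = (spla.splu(Amat), idx)
        splu_obj, idx = lu
        bvec = src[free]
        P = np.zeros((ny, nx))
        P[free] = splu_obj.solve(bvec)
        return P, 0.0, lu

    if method != "sor":
        raise ValueError(f"unknown method {method!r}")
    P = P0.copy() if P0 is not None else np.zeros((ny, nx))
    P[fixed] = 0.0
    yy, xx = np.indices((ny, nx))
    red = ((yy + xx) % 2 == 0) & free
    black = ((yy + xx) % 2 == 1) & free
    omega = params.omega
    denom = 4.0 + a2
    err = np.inf
    for it in range(params.max_iter):
        P_prev_sum = np.abs(P).sum()
        delta = 0.0
        for mask in (red, black):
            nb = (
                np.roll(P, 1, 0) + np.roll(P, -1, 0)
                + np.roll(P, 1, 1) + np.roll(P, -1, 1)
            )
            upd = P + omega * (src + nb - denom * P) / denom
            delta += np.abs(upd[mask] - P[mask]).sum()
            P[mask] = upd[mask]
        err = delta / max(np.abs(P).sum(), P_prev_sum, 1e-300)
        if err <= params.tol:
            return P, err, None
    raise ConvergenceError(
        f"SOR stalled at err={err:.3e} after {params.max_iter} sweeps"
    )


def interstitial_velocity(P_i: np.ndarray, K: float, h_cm: float) -> np.ndarray:
    """Darcy velocity U_i = -K grad(P_i), central differences, cm/s."""
    gy, gx = np.gradient(P_i, h_cm)
    return np.stack([-K * gx, -K * gy])


def couple(
    network: VesselNetwork,
    params: HemoParams,
    dirichlet_mask: np.ndarray = None,
    method_pv: str = "direct",
    method_pi: str = "direct",
    max_outer: int = 200,
) -> HemodynamicState:
    """Fully coupled microcirculation solve on one staged network.

    Alternates the intravascular and interstitial pressure solves until both
    relative-change residuals are below ``params.tol``, then evaluates the
    segment flows and velocities.  ``dirichlet_mask`` marks interstitial
    pressure sinks (lumen cells); the outer grid boundary is always clamped.
    """
    ny, nx = network.A.shape
    if dirichlet_mask is None:
        dirichlet_mask = np.zeros((ny, nx), dtype=bool)
    sys = build_nodal_system(network, params)
    alpha2dx2 = exchange_coefficient_grid(network, params)
    vessel_mask = network.A
    P_i = np.zeros((ny, nx))
    P_nodes = None
    lu = None
    residuals = []
    for outer in range(1, max_outer + 1):
        P_old = None if P_nodes is None else P_nodes.copy()
        P_nodes, _, sys = solve_intravascular(
            network, P_i, params, method=method_pv, P0=P_nodes, sys=sys
        )
        err_pv = (
            np.inf if P_old is None
            else np.abs(P_nodes - P_old).sum() / max(np.abs(P_nodes).sum(), 1e-300)
        )
        P_e = rasterize_nodal(sys.node_xy, P_nodes - params.oncotic_jump, (ny, nx))
        P_i_old = P_i.copy()
        P_i, _, lu = solve_interstitial(
            alpha2dx2, P_e, vessel_mask, params, dirichlet_mask,
            method=method_pi, P0=P_i, lu=lu,
        )
        err_pi = np.abs(P_i - P_i_old).sum() / max(np.abs(P_i).sum(), 1e-300)
        residuals.append((err_pv, err_pi))
        if err_pv <= params.tol and err_pi <= params.tol:
            break
    else:
        raise ConvergenceError(
            "outer coupling did not converge", residuals=residuals
        )

    pbar_i = _segment_Pbar_i(sys, P_i)
    a, b = sys.seg_nodes[:, 0], sys.seg_nodes[:, 1]
    dP = P_nodes[a] - P_nodes[b]
    R = np.asarray(network.seg_R)
    dl = np.asarray(network.seg_len)
    Q_V = np.pi * R**4 * dP / (8.0 * params.mu_bar * dl)
    pbar_v = 0.5 * (P_nodes[a] + P_nodes[b])
    Q_t = sys.beta * (pbar_v - pbar_i - params.oncotic_jump)
    U_i = interstitial_velocity(P_i, params.K, network.h_cm)
    return HemodynamicState(
        node_xy=sys.node_xy,
        P_V_nodes=P_nodes,
        P_V=rasterize_nodal(sys.node_xy, P_nodes, (ny, nx)),
        P_i=P_i,
        Q_V=Q_V,
        Q_t=Q_t,
        Q=Q_V - Q_t,
        U_V=Q_V / (np.pi * R**2),
        U_i=U_i,
        err_PV=residuals[-1][0] if residuals else 0.0,
        err_Pi=residuals[-1][1],
        outer_iters=len(residuals),
        root_nodes=sys.root_nodes,
        terminal_nodes=sys.terminal_nodes,
        seg_nodes=sys.seg_nodes.copy(),
    )


def node_conservation_residuals(
    state: HemodynamicState, sys_or_network, params: HemoParams
) -> np.ndarray:
    """Relative nodal flow-conservation residuals at interior nodes.

    For each non-Dirichlet node: |sum_k (Q_V^k - Q_t^k)| normalized by the
    local flow scale sum_k |Q_V^k|.
    """
    if isinstance(sys_or_network, VesselNetwork):
        sys = build_nodal_system(sys_or_network, params)
    else:
        sys = sys_or_network
    N = len(sys.node_xy)
    net_flow = np.zeros(N)
    scale = np.zeros(N)
    a, b = sys.seg_nodes[:, 0], sys.seg_nodes[:, 1]
    # Q_V positive a -> b; at node a it is an outflow.  Conservation:
    # sum_k inflow_k - sum_k Q_t_k = 0 at every interior node.
    np.add.at(net_flow, a, -state.Q_V - state.Q_t)
    np.add.at(net_flow, b, state.Q_V - state.Q_t)
    np.add.at(scale, a, np.abs(state.Q_V))
    np.add.at(scale, b, np.abs(state.Q_V))
    interior = ~sys.dirichlet
    return np.abs(net_flow[interior]) / np.maximum(scale[interior], 1e-300)


def global_balance(state: HemodynamicState, sys: _NodalSystem) -> tuple:
    """(root inflow, terminal outflow, total transvascular flow), cm^3/s.

    Inflow is the net flow leaving root nodes through their segments plus
    their own wall leak; conservation requires inflow = outflow + total leak
    over interior nodes (node-summed convention).
    """
    N = len(sys.node_xy)
    a, b = sys.seg_nodes[:, 0], sys.seg_nodes[:, 1]
    out_node = np.zeros(N)
    np.add.at(out_node, a, state.Q_V)
    np.add.at(out_node, b, -state.Q_V)
    leak_node = np.zeros(N)
    np.add.at(leak_node, a, state.Q_t)
    np.add.at(leak_node, b, state.Q_t)
    roots = sys.root_nodes
    terms = sys.terminal_nodes
    inflow = out_node[roots].sum()
    outflow = -out_node[terms].sum()
    interior_leak = leak_node.sum() - leak_node[roots].sum() - leak_node[terms].sum()
    return inflow, outflow, interior_leak
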