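"""Continuum chemical fields of the plaque microenvironment.

Six fields live on the plaque grid: endothelial-cell density ``n`` (carried on
the discrete vessel network), smooth-muscle-cell indicator ``s``, macrophage
indicator ``g``, VEGF concentration ``c``, extracellular-matrix concentration
``f`` and matrix-metalloproteinase concentration ``m``.  The chemicals obey
explicit finite-difference updates of the coupled reaction--diffusion system

    dc/dt = D_c lap(c) - lambda n c + eta_c s c
    df/dt = -eta_f m f
    dm/dt = D_m lap(m) + kappa_m n + kappa_g g - sigma_m m

with zero-flux (Neumann) outer boundaries.  ``s`` and ``g`` are static
indicator fields (no evolution equations exist for them); ``n`` is not
time-stepped as a PDE -- its discretization enters only through the sprout-tip
movement probabilities (see :mod:`plaqueangio.angiogenesis`).

Initial conditions: VEGF is high at the two shoulder centers,

    c(x, y, 0) = (nu - r1)^2 / (nu - 0.4771) + (nu - r2)^2 / (nu - 0.4771)

with ``r1``, ``r2`` the distances to the shoulder centers in units of the
domain side; ``f = 1`` and ``m = 0`` everywhere; ``n = 1`` on sprout seeds;
``s = 0`` on the necrotic core and lumen (1 elsewhere); ``g = 1`` on the
shoulders (0 elsewhere).

The baseline parameters are dimensional (CGS/molar); the simulation runs in
unit-grid, unit-step variables produced by :func:`nondimensionalize`.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .geometry import PlaqueDomain, Region

#: Default physical scales: one grid cell of the 4 mm / 200 grid, and the
#: per-step time implied by the per-step VEGF diffusion number 0.00145.
CELL_CM = 2.0e-3
STEP_S = 0.02


@dataclass(frozen=True)
class FieldParams:
    """Baseline dimensional parameters of the chemical system (CGS, molar).

    Defaults are the baseline simulation values: diffusion coefficients in
    cm^2/s, taxis coefficients in cm^2/(s M), rate constants in 1/(M s) or
    1/s as indicated.  ``beta`` is carried for completeness but appears in no
    governing equation.
    """

    D_n: float = 1.0e-10       # EC random motility, cm^2/s
    chi_0: float = 2600.0      # chemotaxis coefficient, cm^2/(s M)
    k_1: float = 7.0e-10       # chemotaxis saturation constant, M
    rho_0: float = 1000.0      # haptotaxis coefficient, cm^2/(s M)
    D_c: float = 2.9e-7        # VEGF diffusion, cm^2/s
    lam: float = 750.0         # VEGF uptake by ECs, 1/(M s)
    eta_c: float = 750.0       # VEGF production by SMCs, 1/(M s)
    eta_f: float = 130.0       # ECM degradation by MMP, cm^3/(s M)
    D_m: float = 1.0e-10       # MMP diffusion, cm^2/s
    kappa_m: float = 1.0e-3    # MMP production by ECs, 1/(cm^3 s)
    kappa_g: float = 1.0e-3    # MMP production by macrophages, 1/(cm^3 s)
    sigma_m: float = 1.0e-8    # MMP decay, 1/s
    nu: float = 1.07           # VEGF initial-profile constant
    beta: float = 0.4          # listed baseline value; unused by the equations

    def __post_init__(self):
        for name in (
            "D_n", "chi_0", "k_1", "rho_0", "D_c", "lam", "eta_c",
            "eta_f", "D_m", "kappa_m", "kappa_g", "sigma_m",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass(frozen=True)
class StepCoefficients:
    """Per-step, unit-grid coefficients actually used by the updates."""

    D_n: float
    chi_0: float
    k_1: float
    rho_0: float
    D_c: float
    lam: float
    eta_c: float
    eta_f: float
    D_m: float
    kappa_m: float
    kappa_g: float
    sigma_m: float
    nu: float
    c_cap_factor: float = 10.0  # VEGF ceiling as a multiple of the initial max


def nondimensionalize(
    params: FieldParams,
    length_scale: float = CELL_CM,
    time_scale: float = STEP_S,
    *,
    vegf_scale: float = 1.0e-9,
    ecm_scale: float = 1.0e-9,
    cell_scale: float = 3.33e-5,
    mmp_scale: float = 3.85e-4,
    mmp_production_volume: float = 50.0,
    c_cap_factor: float = 10.0,
) -> StepCoefficients:
    """Scale the dimensional parameters to unit grid spacing and unit step.

    ``length_scale`` (cm per grid cell) and ``time_scale`` (s per simulation
    step) rescale diffusion and taxis: ``D' = D T / L^2``.  The molar scales
    map the order-one nondimensional fields onto concentrations: ``vegf_scale``
    sets the unit of ``c`` (so ``k_1' = k_1 / vegf_scale``), ``ecm_scale`` the
    unit of ``f``; ``cell_scale``, ``mmp_scale`` and ``mmp_production_volume``
    are the effective molar weights of the 0/1 cell-indicator fields in the
    uptake, production and degradation terms -- the one part of the parameter
    table the dimensional values do not determine.
    """
    if length_scale <= 0 or time_scale <= 0:
        raise ValueError("length and time scales must be positive")
    L2 = length_scale**2
    T = time_scale
    return StepCoefficients(
        D_n=params.D_n * T / L2,
        chi_0=params.chi_0 * vegf_scale * T / L2,
        k_1=params.k_1 / vegf_scale,
        rho_0=params.rho_0 * ecm_scale * T / L2,
        D_c=params.D_c * T / L2,
        lam=params.lam * cell_scale * T,
        eta_c=params.eta_c * cell_scale * T,
        eta_f=params.eta_f * mmp_scale * T,
        D_m=params.D_m * T / L2,
        kappa_m=params.kappa_m * mmp_production_volume * T,
        kappa_g=params.kappa_g * mmp_production_volume * T,
        sigma_m=params.sigma_m * T,
        nu=params.nu,
        c_cap_factor=c_cap_factor,
    )


class FieldStabilityError(ValueError):
    """Raised when an explicit step exceeds its stability bound."""


@dataclass
class ChemicalState:
    """Grid fields of the chemical system plus the elapsed step counter."""

    n: np.ndarray
    s: np.ndarray
    g: np.ndarray
    c: np.ndarray
    f: np.ndarray
    m: np.ndarray
    t: int = 0
    c0_max: float = 0.0
    cap_events: int = 0

    def copy(self) -> "ChemicalState":
        return ChemicalState(
            n=self.n.copy(), s=self.s.copy(), g=self.g.copy(),
            c=self.c.copy(), f=self.f.copy(), m=self.m.copy(),
            t=self.t, c0_max=self.c0_max, cap_events=self.cap_events,
        )


def init_fields(domain: PlaqueDomain, coeffs: StepCoefficients) -> ChemicalState:
    """Initial chemical state on a segmented domain.

    VEGF follows the two-shoulder profile with distances measured in units of
    the domain side; ECM starts at 1, MMP at 0; the indicator fields follow
    the region labels and sprout seeds.
    """
    if domain.shoulder_centers is None or len(domain.shoulder_centers) != 2:
        raise ValueError("domain is missing its two shoulder centers")
    ny, nx = domain.region_label.shape
    xs, ys = np.meshgrid(np.arange(nx, dtype=float), np.arange(ny, dtype=float))
    nu = coeffs.nu
    denom = nu - 0.4771
    c = np.zeros((ny, nx))
    for sc in domain.shoulder_centers:
        r = np.hypot(xs - sc[0], ys - sc[1]) / nx  # unit length = domain side
        c += (nu - r) ** 2 / denom
    lab = domain.region_label
    s = np.ones((ny, nx))
    s[(lab == Region.NC) | (lab == Region.LUMEN)] = 0.0
    g = np.zeros((ny, nx))
    g[lab == Region.SA] = 1.0
    n = np.zeros((ny, nx))
    n[domain.sprout_seeds[:, 1], domain.sprout_seeds[:, 0]] = 1.0
    return ChemicalState(
        n=n, s=s, g=g, c=c,
        f=np.ones((ny, nx)), m=np.zeros((ny, nx)),
        t=0, c0_max=float(c.max()),
    )


def _laplacian_neumann(u: np.ndarray) -> np.ndarray:
    """Five-point Laplacian with reflective (zero-flux) boundaries, h = 1."""
    p = np.pad(u, 1, mode="edge")
    return p[:-2, 1:-1] + p[2:, 1:-1] + p[1:-1, :-2] + p[1:-1, 2:] - 4.0 * u


def stability_limit(coeffs: StepCoefficients) -> float:
    """Largest admissible explicit step for the chemical diffusion terms."""
    dmax = max(coeffs.D_c, coeffs.D_m)
    return np.inf if dmax == 0 else 0.25 / dmax


def step_fields(
    state: ChemicalState,
    A: np.ndarray,
    coeffs: StepCoefficients,
    dt: float = 1.0,
) -> ChemicalState:
    """Advance ``c``, ``f``, ``m`` by one forward-Euler step (in place).

    ``A`` is the vessel-node occupancy grid; the endothelial density ``n`` is
    held on it.  VEGF is clipped at ``c_cap_factor`` times its initial maximum
    (the production term ``eta_c s c`` is positive feedback with no printed
    saturation); cap activations are counted in ``state.cap_events``.
    """
    limit = stability_limit(coeffs)
    if dt > limit:
        raise FieldStabilityError(
            f"dt={dt} exceeds the explicit stability bound; max admissible dt={limit:.6g}"
        )
    n = A.astype(float)
    c, f, m = state.c, state.f, state.m
    dc = coeffs.D_c * _laplacian_neumann(c) - coeffs.lam * n * c + coeffs.eta_c * state.s * c
    dm = (
        coeffs.D_m * _laplacian_neumann(m)
        + coeffs.kappa_m * n + coeffs.kappa_g * state.g
        - coeffs.sigma_m * m
    )
    c += dt * dc
    f *= np.exp(-coeffs.eta_f * m * dt)  # exact decay: keeps f in [0, 1]
    m += dt * dm
    np.clip(c, 0.0, None, out=c)
    np.clip(m, 0.0, None, out=m)
    if state.c0_max > 0:
        ceiling = coeffs.c_cap_factor * state.c0_max
        over = c > ceiling
        if over.any():
            state.cap_events += int(over.sum())
            np.clip(c, None, ceiling, out=c)
    state.n = n
    state.t += 1
    return state
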