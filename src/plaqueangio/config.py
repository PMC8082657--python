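"""Simulation configuration: every baseline parameter plus the model knobs.

A :class:`SimulationConfig` is a validated, YAML-round-trippable record of
one simulation: the baseline parameter table (dimensional values in CGS /
mmHg / molar units), the grid specification, the RNG seed, solver tolerances
and the reconstruction knobs (branching tiers, media width, nondimensional
scales, ...).  Unknown keys are rejected.
"""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator

from .angiogenesis import BranchConfig
from .fields import FieldParams, StepCoefficients, nondimensionalize
from .hemodynamics import HemoParams
from .hemorrhage import IPHParams


class SimulationConfig(BaseModel):
    """All parameters of one plaque neovascularization + hemorrhage run."""

    model_config = ConfigDict(extra="forbid", populate_by_name=True)

    # --- chemical-field parameters (dimensional baseline values) ---
    D_n: float = 1.0e-10
    chi_0: float = 2600.0
    k_1: float = 7.0e-10
    rho_0: float = 1000.0
    D_c: float = 2.9e-7
    lam: float = Field(default=750.0, alias="lambda")
    eta_c: float = 750.0
    eta_f: float = 130.0
    D_m: float = 1.0e-10
    kappa_m: float = 1.0e-3
    kappa_g: float = 1.0e-3
    sigma_m: float = 1.0e-8
    nu: float = 1.07
    beta: float = 0.4  # listed baseline value; appears in no governing equation

    # --- hemodynamic parameters ---
    R_0_um: float = 4.0
    K: float = 41.3e-9
    L_p: float = 2.8e-7
    sigma_T: float = 0.82
    pi_V: float = 20.0
    pi_i: float = 15.0
    P_in: float = 10.0
    P_out: float = 1.0
    mu_bar: float = 3.0e-5
    omega: float = 1.5
    tol: float = 1.0e-6
    alpha_scale: float = 1.0
    pv_method: str = "direct"
    pi_method: str = "direct"

    # --- hemorrhage transport ---
    phi: float = 0.4
    psi: float = 0.05
    gamma: float = 0.4
    thr_factor: float = 1.3
    convection_step_s: float = 800.0

    # --- grid and geometry ---
    nx: int = 200
    ny: int = 200
    extent_cm: float = 0.4
    stenosis_fraction: float = 0.8
    fc_thickness: float = 3.0
    media_width: float = 3.0

    # --- run control ---
    seed: int = 0
    stage_steps: int = 150
    max_stages: int = 20
    analysis_stages: int = 6

    # --- angiogenesis knobs ---
    branch_thresholds: tuple = (0.3, 0.5, 0.7, 0.8)
    branch_probs: tuple = (0.0, 0.2, 0.3, 0.4, 1.0)
    psi_age: int = 15
    branch_scale: float = 0.003
    motion_gain: float = 500.0

    # --- nondimensionalization scales ---
    length_scale_cm: float = 2.0e-3
    time_scale_s: float = 0.02
    vegf_scale: float = 1.0e-9
    ecm_scale: float = 1.0e-9
    cell_scale: float = 3.33e-5
    mmp_scale: float = 3.85e-4
    mmp_production_volume: float = 50.0
    c_cap_factor: float = 10.0

    @field_validator(
        "k_1", "D_c", "nu", "R_0_um", "K", "L_p", "pi_V", "pi_i",
        "P_in", "P_out", "mu_bar", "tol", "phi", "extent_cm",
        "length_scale_cm", "time_scale_s", "vegf_scale",
    )
    @classmethod
    def _positive(cls, v, info):
        if v <= 0:
            raise ValueError(f"{info.field_name} must be positive")
        return v

    @field_validator("D_n", "chi_0", "rho_0", "lam", "eta_c", "eta_f",
                     "D_m", "kappa_m", "kappa_g", "sigma_m", "psi", "gamma",
                     "branch_scale", "motion_gain", "alpha_scale")
    @classmethod
    def _non_negative(cls, v, info):
        if v < 0:
            raise ValueError(f"{info.field_name} must be non-negative")
        return v

    @field_validator("nx", "ny", "stage_steps", "max_stages")
    @classmethod
    def _positive_int(cls, v, info):
        if v < 1:
            raise ValueError(f"{info.field_name} must be >= 1")
        return v

    # --- derived parameter bundles ---

    def field_params(self) -> FieldParams:
        return FieldParams(
            D_n=self.D_n, chi_0=self.chi_0, k_1=self.k_1, rho_0=self.rho_0,
            D_c=self.D_c, lam=self.lam, eta_c=self.eta_c, eta_f=self.eta_f,
            D_m=self.D_m, kappa_m=self.kappa_m, kappa_g=self.kappa_g,
            sigma_m=self.sigma_m, nu=self.nu, beta=self.beta,
        )

    def step_coefficients(self) -> StepCoefficients:
        return nondimensionalize(
            self.field_params(),
            length_scale=self.length_scale_cm,
            time_scale=self.time_scale_s,
            vegf_scale=self.vegf_scale,
            ecm_scale=self.ecm_scale,
            cell_scale=self.cell_scale,
            mmp_scale=self.mmp_scale,
            mmp_production_volume=self.mmp_production_volume,
            c_cap_factor=self.c_cap_factor,
        )

    def hemo_params(self) -> HemoParams:
        return HemoParams(
            K=self.K, L_p=self.L_p, sigma_T=self.sigma_T,
            pi_V=self.pi_V, pi_i=self.pi_i,
            P_in=self.P_in, P_out=self.P_out,
            mu_bar=self.mu_bar, omega=self.omega, tol=self.tol,
            alpha_scale=self.alpha_scale,
        )

    def branch_configuration(self) -> BranchConfig:
        return BranchConfig(
            thresholds=tuple(self.branch_thresholds),
            probs=tuple(self.branch_probs),
            age_gate=self.psi_age,
            scale=self.branch_scale,
        )

    def iph_params(self) -> IPHParams:
        return IPHParams(
            phi=self.phi, psi=self.psi, gamma=self.gamma,
            thr_factor=self.thr_factor,
            convection_step_s=self.convection_step_s,
        )

    # --- serialization ---

    def to_yaml(self, path) -> None:
        data = self.model_dump(by_alias=True)
        data["branch_thresholds"] = list(self.branch_thresholds)
        data["branch_probs"] = list(self.branch_probs)
        Path(path).write_text(yaml.safe_dump(data, sort_keys=True))


def validate_config(path) -> SimulationConfig:
    """Parse a YAML config file, filling defaults and checking invariants.

    An empty file yields the full baseline configuration.  Unknown keys,
    non-positive physical parameters or a missing grid raise a descriptive
    error.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    data = yaml.safe_load(path.read_text())
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ValueError(f"config root must be a mapping, got {type(data).__name__}")
    for key in ("branch_thresholds", "branch_probs"):
        if key in data and isinstance(data[key], list):
            data[key] = tuple(data[key])
    return SimulationConfig(**data)
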