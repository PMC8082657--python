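# Methods

`plaqueangio` simulates the formation of immature microvessels inside a
carotid atherosclerotic plaque and the hemodynamic consequences that make
those vessels a source of intraplaque hemorrhage (IPH).  It couples three
submodels on one 200 x 200 grid covering a 4 mm x 4 mm plaque cross-section
(20 um cells): a hybrid discrete-continuum angiogenesis model, a coupled
microcirculation flow model, and an extravascular plasma-transport model.

## Geometry

The plaque cross-section is segmented into lumen, necrotic core (NC),
shoulders (SA), fibrous cap (FC), a media band and exterior tissue.  The
package ships a parametric synthetic geometry: an off-center circular lumen
inside a circular vessel wall leaves a crescent plaque whose areal stenosis
degree is a parameter (default 0.8, emulating a high-grade carotid
stenosis).  Segmentation uses the classical wedge construction: the two
plaque tips are joined to the lumen center, the bisector of that angle is
extended to the outer boundary (point `b`), and the lines tip-`b` separate
the core from the two shoulders; cells within a configurable cap thickness
(default 3 cells = 60 um) of the lumen form the fibrous cap.  The media is a
3-cell band outside the wall.  Twelve vasa-vasorum sprout seeds sit on the
media at 30-degree steps around the lumen center.  The synthetic mask is a
stand-in for a histology-derived segmentation; `segment_domain` accepts any
polygon-based segmentation input in the same format.

## Chemical microenvironment

Six fields live on the grid: endothelial density `n` (carried on the
discrete network), static smooth-muscle (`s`) and macrophage (`g`)
indicators, and three chemicals evolved by explicit finite differences with
zero-flux boundaries:

    dc/dt = D_c lap(c) - lambda n c + eta_c s c        (VEGF)
    df/dt = -eta_f m f                                  (ECM)
    dm/dt = D_m lap(m) + kappa_m n + kappa_g g - sigma_m m   (MMP)

VEGF starts high at the two shoulder centers,
`c0 = sum_i (nu - r_i)^2/(nu - 0.4771)` with `r_i` the distance to shoulder
center `i` in units of the domain side and `nu = 1.07`; ECM starts at 1, MMP
at 0.  `s` vanishes on the core and lumen, `g` marks the shoulders.  The ECM
equation is integrated with its exact per-step integrating factor
`f <- f exp(-eta_f m dt)`, which preserves positivity, monotone decay and
the closed-form solution to machine precision.  Because the VEGF production
term `eta_c s c` is positive feedback with no stated saturation, `c` is
capped at 10x its initial maximum and cap activations are counted.

### Scales

The parameter table is dimensional (CGS/molar); the simulation runs in
unit-grid, unit-step variables.  One cell is 2e-3 cm; the per-step time
0.02 s follows from anchoring the per-step VEGF diffusion number at
`D_c' = 0.00145` (comfortably inside the explicit stability limit 0.25).
A VEGF unit of 1e-9 M makes the saturation constant `k_1' = 0.7` so the
order-one initial profile sits in the sensitive range of the chemotactic
sensitivity `chi_0 k_1/(k_1 + c)`.  The remaining scales — the effective
molar weights of the 0/1 indicator fields in the uptake/production terms,
the ECM/MMP units, the tip-walk gain and the per-step branching scale — are
not derivable from the table; they were fixed once, during model bring-up,
so that the baseline simulation reproduces the documented qualitative
regime: the network grows over roughly a dozen 150-step stages ("months"),
densifies in the shoulders, and stops when sprout activity ceases.  They are
all exposed in `SimulationConfig` and documented as reconstruction choices.

## Angiogenesis (2D9P tip walk)

Sprout tips perform a biased random walk on the nine-point neighbourhood.
The movement probabilities come from the explicit nine-point discretization
of the endothelial transport equation: an isotropic random-motility weight
`D_n` plus chemotaxis (`chi_0 k_1/(k_1+c) grad c`) and haptotaxis
(`rho_0 grad f`) biases evaluated as central differences along each
direction, with diagonal differences carrying the 1/l^2 spacing factor.
Negative raw coefficients are clamped to zero, the stationary weight absorbs
the remainder, and the nine values are normalized; a tip samples its move
from the cumulative distribution.  Tips never enter the lumen and are
retired at the one-cell boundary margin.

Branching occurs only at tips, only after a 15-step maturation age, only
with at least two free neighbour cells, and with a probability that is a
monotone step function of local VEGF relative to the initial shoulder
maximum (tiers 0/0.2/0.3/0.4/1.0 at 0.3/0.5/0.7/0.8, scaled by the
`branch_scale` knob — the "MVD knob" used for density sensitivity groups).
A tip landing on an occupied node anastomoses: the segment closes a loop and
the arriving tip is retired; when two tips meet on one cell the elder (ties:
lower branch id) survives.  Topology is tracked in the node-occupancy matrix
`A` and the reciprocal per-direction segment matrix `B`, with per-segment
length (20 or 28.3 um) and constant radius 4 um.  A stage is 150 steps; the
run terminates at the first stage adding no segment (growth and sprouting
both zero), or at a hard cap of 20 stages.

Tip order within a step, move sampling, branching decisions and daughter
placement all draw from one seeded generator, so a run is bit-reproducible
from its config and seed.

## Microcirculation

On each staged network three coupled problems are solved in mmHg/cm/s units:

* **Intravascular pressure.** Poiseuille conductances
  `g = pi R^4/(8 mu dl)` (viscosity 3e-5 mmHg s =~ 4 mPa s, constant) and
  Starling wall exchange `beta = 2 pi R dl L_p` define nodal conservation
  `sum_k [Q_V - Q_t] = 0`, with the segment's full transvascular flow
  charged at each endpoint and segment pressures taken as endpoint means.
  Dirichlet values: 10 mmHg at the 12 roots, 1 mmHg at dead-end terminals
  ("exits where vessels stop growing"); anastomotic loops carry no boundary
  condition.  The nodal fixed-point iteration and a direct sparse solve of
  the identical system are both implemented and agree to <=1e-8; the direct
  form is the pipeline default because the fixed point needs O(L^2) sweeps
  on chains of length L.
* **Interstitial pressure.** Darcy flow with a distributed Starling source
  on vessel cells: `lap(P_i) = alpha^2 (P_i - P_e) A`,
  `P_e = P_V - sigma_T(pi_V - pi_i)`.  The exchange closure takes each
  cell's summed segment wall area `W`: `alpha^2 = W L_p / (K dx^2 h)` with
  slab depth `h = dx` (config-scalable).  Boundaries: `P_i = 0` on the outer
  rim and in the lumen (pressure sink).  Solved by red-black SOR
  (omega = 1.5) or an equivalent factorized direct solve (pipeline default,
  factorization reused across outer iterations).
* **Coupling.** The two solves alternate until both relative-change
  residuals fall below 1e-6 (the Starling coupling is weak, so 3-5 outer
  iterations suffice), then segment flows `Q_V`, wall flows `Q_t`, the
  intravascular velocity `U_V = Q_V/(pi R^2)` and the Darcy velocity
  `U_i = -K grad P_i` (central differences) are evaluated.

Interior nodal conservation holds to ~1e-5 relative and global
inflow = outflow + total leak to 1e-6 relative on every staged network.

## Hemorrhage

The extravascular plasma concentration `S_IPH` obeys

    dS/dt = phi lap9(S) - psi div(S U_i) + gamma Q_t

with a conservative nine-point diffusion stencil (phi = 0.4 per step),
first-order upwind divergence-form convection (the mass-conserving reading
of the printed `psi S U_i` term), zero-flux boundaries, and per-segment wall
flows deposited on both endpoint cells.  Negative concentrations (possible
under reabsorbing walls) are clamped at zero and counted.  The Darcy
velocity is bridged to grid units by a convection clock of 800 s per step,
chosen so leaked plasma percolates across the lesion over the simulated
horizon; this keeps transport source/diffusion dominated, the regime in
which reducing wall permeability reduces hemorrhage.  Steps are internally
substepped to 90% of the combined advection-diffusion stability limit.

High-IPH regions are plaque cells with `S_IPH` above 1.3x the plaque-mean
concentration (the threshold factor that best matches the MR appearance of
hemorrhage in the emulated patient case); a sweep utility scans factors
0.5-2.0.  Microvessel density
(MVD) is vessel-occupied cells per mm^2 of a region.  In the sensitivity
sweeps (wall permeability; branching-scale density knob) the threshold is an
absolute criterion fixed by each seed's baseline run — re-deriving the
relative threshold per condition would cancel the leakage change being
measured.

## Pipeline and quasi-static coupling

Angiogenesis and chemistry advance every step; the microcirculation is
re-solved once per 150-step stage on the then-current network, and `S_IPH`
advances every step using the latest velocity and wall-flow fields.  Each
stage logs segment/tip counts, region MVDs, the interstitial pressure peak
and the IPH area; a run directory stores the config, seed, CSV tables,
field grids, and GraphML/JSON network exports, and is bit-reproducible.

## Problem sizes used in the shipped analyses

The test suite and the reproduction script use the full 200 x 200 baseline
geometry with a 10-seed ensemble for the headline quantities (interstitial
pressure peak, root-to-network pressure/velocity decay, termination stage),
and a 100 x 100 desk-scale grid for the seed-paired sensitivity sweeps.

## Known limitations

* The synthetic crescent geometry reproduces the topology, not the
  irregular outline, of a histological plaque; quantitative region areas
  (hence absolute MVD and IPH areas) depend on it.
* `s` and `g` are static; no plaque growth, hypoxia/oxygen transport,
  hematocrit rheology, vessel regression or radius adaptation.
* The per-step rate scales and the two walk/branching clocks are
  reconstruction choices identified from the documented baseline behavior,
  not measured quantities; conclusions should rest on comparisons between
  configurations, which share these scales.
* With all inflow entering through 12 root chains and dead ends clamped at
  the outlet pressure, denser networks throttle their own perfusion: total
  wall leakage (and hence the IPH area under an absolute threshold) can
  *fall* as density rises.  The direction of the density-hemorrhage
  relationship is therefore sensitive to this boundary-condition scheme.
* The beta = 0.4 entry of the baseline table is stored in the config but
  appears in no governing equation (none is given for it); it is unused.
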