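# plaqueangio

Mechanistic simulation of **intraplaque neovascularization and hemorrhage**
in a carotid atherosclerotic plaque cross-section, for vascular-biology
modelers studying why immature microvessels make plaques vulnerable.

Microvessels sprouting from the adventitial vasa vasorum grow into the
plaque, guided by VEGF released in the macrophage-rich shoulder regions.
Their immature, leaky walls let plasma escape into the interstitium —
intraplaque hemorrhage (IPH), a hallmark of vulnerable lesions.  The package
couples three submodels on one 200 x 200 grid (4 mm x 4 mm):

1. **Hybrid discrete-continuum angiogenesis (2D9P).**  Reaction-diffusion
   fields for VEGF `c`, extracellular matrix `f` and MMP `m`
   (`dc/dt = D_c lap c - lambda n c + eta_c s c`, `df/dt = -eta_f m f`,
   `dm/dt = D_m lap m + kappa_m n + kappa_g g - sigma_m m`) drive a
   stochastic nine-point tip walk: movement probabilities P0..P8 from the
   discretized endothelial transport equation (random motility, chemotaxis
   `chi_0 k_1/(k_1+c) grad c`, haptotaxis `rho_0 grad f`), VEGF-dependent
   tip branching, and anastomosis on contact.  Twelve sprouts start on the
   media at 30-degree spacing.
2. **Microcirculation hemodynamics.**  On each monthly stage: Poiseuille
   flow `Q_V = pi R^4 dP/(8 mu dl)` through the network, Starling
   transvascular exchange `Q_t = 2 pi R dl L_p (P_V - P_i - sigma_T(pi_V -
   pi_i))`, and Darcy interstitial flow `U_i = -K grad P_i`, solved as two
   alternating pressure problems (nodal fixed point / SOR, each with a
   verified direct-solve twin) to joint 1e-6 convergence.
3. **Hemorrhage transport.**  The extravascular plasma concentration obeys
   `dS/dt = phi lap S - psi div(S U_i) + gamma Q_t`; plaque cells above
   1.3x the mean concentration are scored as high-IPH regions.

See `docs/methods.md` for assumptions, parameter scales, and limitations.

## Worked example

```bash
plaqueangio run --seed 1 --out run1
```

prints

```
terminated at stage T=13: 1019 segments, MVD=153.5/mm^2, IPH area=0.904 mm^2, max P_i=2.03 mmHg
```

meaning: with the baseline parameter table and seed 1, neovascularization
stopped at stage T = 13 (~13 months; growth and sprouting both zero), having
laid down 1019 capillary segments at an overall microvessel density of
153.5 vessels/mm^2 concentrated in the shoulders; the leaky network raised
the interstitial pressure peak to 2.0 mmHg (normal tissue is ~0 mmHg), and
0.904 mm^2 of plaque exceeded the hemorrhage threshold.  The run directory
contains the segmented geometry (`region_labels.png`, `domain.json`),
per-stage metrics (`stages.csv`), the final network with pressures and
flows (`network_T13.graphml/.json`), field grids (`fields.npz`,
`P_i_T13.csv`, `S_IPH.csv`), and a machine-readable `summary.json`; rerunning
with the stored `config.yaml` and seed reproduces it bit-identically.

Other subcommands: `plaqueangio geometry` (segmentation only),
`grow` (angiogenesis only), `hemo`, `iph`, and
`sweep --param lp --levels 0.5,1.0 --seeds 10` for seed-paired sensitivity
studies of wall permeability or microvessel density.  As a library:

```python
from plaqueangio import SimulationConfig, run_pipeline
result = run_pipeline(SimulationConfig(seed=1))
result.summary["max_P_i"]      # interstitial pressure peak, mmHg
result.stage_records           # per-stage DataFrame
```

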