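# ckics — confinement k-space image correlation spectroscopy

Membrane proteins rarely diffuse freely: lipid microdomains and molecular
complexes transiently trap them, producing two coexisting dynamic
populations — molecules moving over large distances between traps, and
molecules rattling inside them. `ckics` is a toolkit for studying this
regime with k-space image correlation spectroscopy (kICS): it simulates 2D
Brownian motion among static, partially permeable circular domains,
synthesizes realistic fluorescence image time series from the trajectories,
and analyzes image stacks (synthetic or experimental TIFFs) with a
two-component correlation fit that quantifies the confinement.

It is written for quantitative fluorescence microscopists and method
developers who want a reproducible, scriptable reference implementation of
the analysis plus a ground-truth simulator to validate it against.

## The analysis in brief

The spatial Fourier transform Ĩ(**k**, t) of each (mean-subtracted) frame is
correlated across time lags,

    r(k², τ) = ⟨ Ĩ(k, t) · Ĩ*(k, t+τ) ⟩,

circularly averaged over |**k**| annuli, and normalized by its τ = 0 value,
which cancels the PSF envelope and all photophysical prefactors.

* For a single freely diffusing species, ln r is linear in k² with slope
  −(Dτ + ω0²/4); regressing the per-τ slopes on τ yields D and the PSF e⁻²
  radius ω0.
* For confined diffusion every τ row is fit with a sum of two Gaussian
  decays,

      r(k², τ) = A_M e^(−k² g_M) + A_μ e^(−k² g_μ),  g_M ≥ g_μ,

  whose τ trends carry the confinement parameters: **D_M** (early-lag slope
  of g_M — diffusion at large spatial scales), **D_μ** (same for g_μ —
  mobility at small scales), **Plateau_μ** (late-lag saturation of g_μ —
  the effective confined area over 4), and the amplitude saturations
  **A_M**, **A_μ** (late-lag number fractions of the free and confined
  populations). The partition coefficient β (fraction of particles inside
  domains) links them through D_eff = D_free·(1 − β).

The model and estimator details — boundary-crossing rules, PSF conventions,
the adaptive k² fitting bound, merged-row handling at early lags — are in
[docs/methods.md](docs/methods.md).

## Worked example

```python
from ckics import RunConfig, SimulationConfig, AnalysisConfig, run_pipeline

sim = SimulationConfig(
    region_px=128, n_frames=720, burn_in_frames=120,   # 12.8 μm patch
    D_in=0.001, D_out=0.01,                            # μm²/s
    P_in=0.5, P_out=0.1,
    domain_radius=0.2, area_fraction=0.05,             # μm, fraction
    particle_density=5.0, seed=5,
)
res = run_pipeline(RunConfig(simulation=sim,
                             analysis=AnalysisConfig(crop_px=112, max_tau=60)))
p = res.parameters
print(f"beta      = {res.partition.beta_mean:.3f}")
print(f"D_M       = {p.D_M:.5f} um^2/s")
print(f"D_mu      = {p.D_mu:.5f} um^2/s")
print(f"Plateau_mu= {p.plateau_mu:.5f} um^2 -> eff. radius {p.effective_radius:.3f} um")
print(f"sat A_M   = {p.sat_A_M:.3f}   sat A_mu = {p.sat_A_mu:.3f}")
```

prints

```
beta      = 0.443
D_M       = 0.00135 um^2/s
D_mu      = 0.00135 um^2/s
Plateau_mu= 0.00503 um^2 -> eff. radius 0.142 um
sat A_M   = 0.076   sat A_mu = 0.924
```

Read: with domains of radius 0.2 μm covering 5% of the membrane and an
escape probability of 0.1, some 44% of particles are trapped at any time
(β). The macro population diffuses at an effective 0.00135 μm²/s — an
order of magnitude below the free D_out = 0.01, but still above
D_in = 0.001 — and only ~8% of the late-lag correlation amplitude comes
from the free population. The micro plateau of 0.0050 μm² corresponds to an
effective confinement radius of 0.14 μm, the domain scale blurred by the
pixel floor.

The same pipeline runs from the shell:

```
ckics full --config run.yaml          # simulate + render + analyze
ckics analyze stack.tif --pixel-size 0.1 --frame-time 0.04 --out results/
ckics sweep --parameter domain_radius --values 0.2,0.3,0.4,0.5 --replicates 2
ckics fixtures fixtures/ --scale tiny
```

`full` writes six artifacts per run — `images.tif`, `cf.csv`, `fits.csv`,
`parameters.json`, `beta.json`, `provenance.json` — each stamped with the
seed and a configuration hash, so a run can be reproduced exactly.

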