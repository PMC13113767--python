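# Methods

`ckics` implements confinement k-space image correlation spectroscopy: a
simulator of 2D Brownian motion in a field of static, partially permeable
circular microdomains; a fluorescence-microscopy image synthesizer; and the
k-space correlation and two-component fitting pipeline that turns an image
time series into confinement parameters.

## The simulated system

Point particles diffuse in a square membrane patch of side
`region_px × pixel_size` (default 30 μm) with periodic boundaries, so the
particle number is conserved. Static circular domains of radius
`domain_radius` (default 0.2 μm) cover a set `area_fraction` of the patch
(default 5%); centers are drawn uniformly under a 2-radius minimum
separation, with bounded rejection sampling (10 000 tries per domain; an
unpackable request raises `PackingError`). Domains are placed fully inside
the patch so that the disk geometry is consistent with the periodic particle
motion.

Per frame each particle takes a Gaussian step with per-axis standard
deviation `sqrt(2 D Δt)`, where `D` is `D_in` (default 0.001 μm²/s) inside a
domain and `D_out` (default 0.01 μm²/s) outside, chosen by the particle's
region at the start of the substep. A step whose endpoint changes region is
accepted with probability `P_in` (entering, default 0.5) or `P_out`
(escaping, default 0.1); a refused crossing is resolved by the
`boundary_policy`:

* `reject_step` (default): the substep is cancelled and the particle keeps
  its pre-step position. This slightly inflates dwell times near the
  boundary because a blocked particle loses its whole displacement.
* `reflect`: the endpoint is folded radially back across the circle of the
  adjudicating domain, approximating specular reflection; degenerate folds
  fall back to cancelling the step.

`substeps_per_frame` (default 1) subdivides the frame step; with a large
frame time a single step can tunnel across a small domain, and substepping
bounds that error. Only the first region change per substep is adjudicated —
the 2-radius center separation makes double crossings rare at the default
step sizes.

The frame time may be set explicitly or derived (`frame_time="auto"`) as
`(domain_radius/5)² / (4 D_in)`: the RMS one-axis step inside a domain is
then a fifth of the domain radius, so a confined particle needs on the order
of 25 frames to explore its domain regardless of the radius. This keeps the
micro-component dynamics sampled comparably across radius sweeps.

The first `burn_in_frames` (default 200 of 2200) are discarded so the
occupancy reaches its partitioning steady state. One `numpy` generator
seeded by `seed` drives placement, initialization, and stepping in that
documented order; runs are bit-reproducible.

The partition coefficient β is the time-averaged fraction of particles
inside domains, and `effective_diffusion` implements
`D_eff = D_free (1 − β)`. An ensemble MSD helper (periodic unwrapping by
minimum-image per-frame increments) provides a trajectory-level diffusion
estimate used as an independent oracle against the image-level estimates.

## Image synthesis

Each particle contributes a 2D Gaussian PSF at its exact sub-pixel position:
pixel `(i, j)` records `I0 Σ_n exp(−(i−x_n)²/2σ²) exp(−(j−y_n)²/2σ²)` with
coordinates in pixel units. The user-facing `psf_radius` is the e⁻² beam
radius ω0 (default 0.28 μm), so σ = ω0/2; this convention matters because
ω0²/4 is the τ-independent intercept of the single-species k-space fit.
Stamps are truncated at 5σ (error < 1e−5 of the peak) and wrap periodically
at the frame edges, matching the periodic particle motion: the uncropped
frame is exactly periodic, and any central crop whose margin exceeds the
stamp half-width is unaffected by the wrapping.

Background noise is additive i.i.d. zero-mean Gaussian with standard
deviation `noise_param × I0`, so the implied signal-to-noise ratio is
`1/noise_param` (0.2 ⇒ SN 5). No photon (Poisson) noise, camera gain, or
digitization is modelled. Analysis crops the central region of the frame
(300 → 256 px at full scale, ≈7.3% margin per side by default), emulating an
imaging ROI open to particle exchange; for fully periodic synthetic frames
an uncropped analysis is leakage-free and the crop is a fidelity choice, not
a necessity.

## Correlation function

Frames are mean-subtracted (per frame) and Fourier transformed; the raw CF
is `r(k, τ) = ⟨Ĩ(k,t) Ĩ*(k,t+τ)⟩_t` using all `n_frames − τ` pairs, real
part retained and the relative imaginary residue logged as a stationarity
diagnostic (warning above 5%). Wavenumbers are angular (`k = 2πf`), putting
k² on the 0–200 μm⁻² scale natural for 0.1 μm pixels. Circular averaging
uses annuli one frequency step wide up to the Nyquist ring (N/2 bins for an
even N-pixel frame), excluding DC; each bin is centered at the mean k² of
its member modes, which avoids small-k bias. Normalization divides every
bin by its τ = 0 value, cancelling the PSF envelope and all static
prefactors; bins whose τ = 0 power falls below 1e−9 of the maximum are
masked. `max_tau` defaults to 100 frames — longer lags average too few
frame pairs to be useful.

Two properties of the normalized CF of these synthetic series shape the
fitting choices below. First, for confined systems the micro component is
dominated at late τ by the static domain-enrichment pattern, whose k-profile
is a disk form factor, not a Gaussian: beyond its first node (k² ≈ 14.7/R²)
the profile turns up again in side lobes. Second, at very high spatial
frequencies the normalized CF of pixel-sampled images rises toward a
pixel-locked residue regardless of dynamics. Both effects put an upper
limit on the k² range over which a two-Gaussian model is meaningful.

## Two-component fitting

Each τ > 0 row of the normalized CF is fit with
`A_μ e^(−k² g_μ) + A_M e^(−k² g_M)`, parameterized as `g_M = g_μ + Δ`,
Δ ≥ 0, so the macro/micro labeling (`g_M ≥ g_μ`) holds by construction.
Rows are fitted from the latest τ backwards, warm-starting each row from
its successor (at late τ the two decays are well separated; continuation
carries that separation toward early τ), with two fresh seeds per row from
a single-exponential envelope fit. Bounds are A ∈ [0, 2], g ∈ [0, ∞).

The upper k² fitting bound defaults to a model-based two-pass rule: a pilot
fit of the late-lag profile within k² ≤ 60 μm⁻² (always inside the
form-factor node for domains comparable to or larger than the PSF) measures
the micro exponent g_μ, and the bound is set to min(200, 1.5/g_μ). The
constant calibrates the node position against the *measured* exponent: on
these simulations the fitted g_μ of the partially permeable enrichment
pattern is roughly a third of the hard-disk R²/4, while the node stays at
14.7/R², so 1.5/g_μ lands just below the node across radii 0.2–0.5 μm.
Profile-shape heuristics (cutting at the late-profile minimum or its first
valley) proved fragile against frozen single-realization bumps at desk
scale and were abandoned. A noise-aware cap of 60 μm⁻² is exposed for noisy
data (at SN 5 the CF above that range is noise-corrupted).

At early lags the two exponents both approach zero and the decomposition is
statistically degenerate. Rather than reporting an unidentifiable split,
each row compares the two-Gaussian fit against a single Gaussian by AIC;
rows where the second component does not pay for itself are recorded as
*merged*, carrying the composite decay in both exponents with the amplitude
split evenly. AIC is used instead of BIC deliberately: with only ~20–60
annulus bins per row, BIC's `ln n` penalty suppresses a macro remnant that
is clearly systematic across rows.

Extraction (`extract_parameters`):

* `D_M`, `D_μ` — weighted least-squares slopes of `g_M(τ)` and `g_μ(τ)`
  over the early window (default: first 5 nonzero lags). Merged rows
  contribute their composite exponent; split rows with a vanishing
  amplitude (< 0.01) are excluded, since their exponent is unconstrained.
  At the default confinement this makes `D_M` an effective short-time
  coefficient lying between `D_in` and `D_out` and tracking
  `D_out (1 − β)` in rank across confinement strengths, though its absolute
  value underestimates `D_eff` when the static domain pattern carries a
  large share of the correlation power.
* `Plateau_μ` and the saturations — the trailing quarter of the τ rows is
  statistically stationary, so those rows are averaged into one late
  profile that is refit with the same model selection; this sharper fit
  supplies `plateau_mu = g_μ` and the row-renormalized amplitude fractions
  `sat_A_M`, `sat_A_mu`. If even the averaged profile supports only one
  Gaussian, the surviving slow decay is attributed to the micro component
  (`sat_A_M = 0`): at late τ the macro has decayed away. When a custom late
  window is supplied, per-row means over that window are used instead.
* `effective_radius = 2 √plateau_mu` — in a circular corral of radius R the
  steady-state 2D MSD is ≈ R² and a Gaussian CF exponent carries MSD/4, so
  this convention maps the plateau back to a length comparable to the true
  radius.

Confidence intervals are normal-approximation intervals from the regression
standard errors (slopes) and the standard error of the late-window row means
(plateau, saturations).

`fit_two_free_species` is the validation mode for a mixture of two
non-interconverting species: one global fit across all (k², τ) with
exponents constrained to `D·τ`, returning both diffusion coefficients and
the number fraction; a relative gap between the two coefficients below 5%
is flagged degenerate.

## What the synthetic data do and do not emulate

The generator reproduces the features that drive the correlation analysis:
partitioning kinetics with separate interior/exterior mobilities, static
non-overlapping domains, periodic transport, diffraction-limited Gaussian
imaging of sub-pixel positions, and white background noise. It does not
model photophysics (bleaching, blinking), Poisson/EMCCD noise, mobile or
overlapping domains, boundary diffusion-gradient corrections, flow, or
meshwork (picket-fence) confinement. Tests passing on these data therefore
validate the estimator chain under the stated model, not robustness to
photophysical artifacts in real recordings.

## Desk-scale study conditions

The default physical scale (300 px region, 2200 frames, 4500 particles) is
expensive to sweep, so the test suite and the acceptance script run a
reduced geometry chosen once: a 128 px (12.8 μm) region analyzed over the
central 112 px, 600 retained frames after a 120-frame burn-in, density
5/μm², `max_tau` 60, and two (tests) or three (acceptance script) seeds per
condition. At this scale every headline parameter is resolvable, but two
consequences are worth keeping in mind: sweep trends are asserted on
seed-averaged values through rank direction plus endpoint ordering rather
than point-by-point monotonicity, and the absolute `D_M` at strong
confinement sits below `D_out (1 − β)` (the trend matches; the numeric band
is reported as a soft check). The sub-resolution saturation length measured
here comes out near 0.08 μm — the same order as the pixel size, consistent
with fluctuations being observable only at the pixel scale.

## Numerical choices and edge cases

* Annulus binning: `round(|k|/Δk)`; rings beyond Nyquist are discarded.
* Masked bins (zero τ = 0 power) propagate as NaN and are excluded from all
  fits; a row with fewer than 8 usable bins is flagged non-converged.
* More than half the rows failing to converge raises `FitError`; a τ window
  with fewer than 3 usable rows raises `WindowError`.
* `curve_fit` uses analytic-free trust-region bounds with `maxfev = 5000`;
  per-row multi-start keeps the smallest-SSR solution.
* Domain membership is a strict-interior test against the nearest center
  (k-d tree); a particle exactly on a boundary counts as outside.
* TIFF stacks are written as 32-bit float grayscale; calibration always
  travels through configuration, never TIFF tags.

## Known limitations

* Amplitude saturations for strongly coherent domain patterns (large radii
  at small fields of view) hit the detection floor: `sat_A_M` reports 0
  when the macro remnant is below the realization noise.
* The early-lag `D_M` is an effective, estimator-defined quantity; its
  absolute calibration against `D_eff` degrades as the static pattern's
  share of correlation power grows.
* The plateau of sub-resolution domains reflects the pixel/PSF floor, not
  domain geometry; only its saturation (non-dependence on the true radius)
  is meaningful.
* Rectangular frames are not supported by the circular average; crop to a
  square first.
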