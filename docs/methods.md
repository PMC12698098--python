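# Methods

## Physical model

The package models a window-contact THz reflection measurement of skin as a
1-D stratified system: quartz incidence half-space, `L` "ridge layers" of
equal thickness `d_f` discretising the skin's furrow-and-ridge micro-relief,
and a bulk-skin half-space.  Each ridge layer is a Landau–Lifshitz–Looyenga
(LLL) two-phase effective medium of skin and air; the cube-root mixing rule
is used because it imposes no inclusion-shape constraint and is well suited
to biological composites.  The air volume fraction follows
`V_A^N = V_A1·cos²((N−1)π/2L)` for layer `N = 1..L`: the first (window-side)
layer carries the full deformation parameter `V_A1` and the fraction decays
over a quarter period, so the deepest layer approaches but is not forced to
zero.  The squared-cosine shape approximates a ridge's cross-sectional
profile; the exact argument of the cosine is a modelling choice (the decay
could plausibly span other fractions of a period), made here so that `V_A1`
is the single deformation knob and the profile is strictly non-increasing.

Skin is itself an LLL mixture of a dry biological background (nondispersive
ε = 2.5 by default) and water (double-Debye, ε_inf = 3.3,
Δε₁ = 75 at τ₁ = 8.24 ps, Δε₂ = 1.6 at τ₂ = 0.18 ps — standard
liquid-water THz parameters; all overridable).  Hydration rises with depth
from 20% at the surface to 65% at the bottom of the deepest ridge layer,
interpolated linearly by default (a cosine-ramp option exists because the
true profile shape between the endpoints is not sharply constrained);
each layer is assigned the hydration at its centre depth `(N−½)·d_f`.  The
bulk half-space uses the bottom hydration, or a measured permittivity
spectrum loaded from CSV.

### Sign conventions

Time dependence `e^{+jωt}`; permittivity `ε = ε' − jε''` with `ε'' ≥ 0`
(passivity ⇒ `Im(ε) ≤ 0` as a complex number), refractive index `√ε` on the
branch `Im(n) ≤ 0`, round-trip phase factor `e^{−2jδ}` with
`δ = (2π/λ)·n·d·cosθ`.  Under this convention multiplying a numpy `rfft`
spectrum by the reflectance and inverting produces causal, decaying echoes.
The mathematically equivalent conjugate convention writes the same recursion
with `e^{+2jδ}`; magnitudes and all derived quantities are identical.

### Reflectance

Two independent implementations are maintained deliberately: the
single-interface recursion (evaluated bottom-up from the deepest interface)
and a 2×2 characteristic-matrix product.  They agree to better than 1e-10
on random lossy stacks of up to 30 layers, which is the package's standing
correctness check for the optics core.  Oblique incidence uses the complex
Snell invariant with branches fixed so transmitted waves decay into loss;
the default is normal incidence (the probe geometry is configurable but, at
θ = 0, polarization is immaterial).  The 2 mm quartz window is treated as
the semi-infinite incidence medium by default, as is standard for
window-contact probes whose front-face echo is separated in time and removed
by referencing; an optional mode includes it as a finite layer.

## Signals and analysis quantities

A simulated pulse is the inverse FFT of reflectance × reference spectrum
(zero-padded to a power of two; no window functions or spectral filters
anywhere, matching the raw-signal analysis philosophy).  Analysis
quantities: peak-to-peak (P2P) per trace; the occlusion curve P2P(τ); the
deconvolved response `M(f) = E_sample(f)/E_ref(f)` with a validity mask
where the reference magnitude falls below 1% of its peak (masking instead of
dividing by near-zero); per-frequency change of |M| from the first to the
last measurement over the 0.2–1.5 THz band; and per-frequency Pearson
correlation between the |M|(τ) tracks of two series.  Pointwise pulse
comparisons are preceded by integer-lag cross-correlation alignment, since
the loss is defined pointwise but acquisition timing is arbitrary.

## Fitting

The loss is the squared L2 norm of the difference between simulated and
measured pulses.  (A squared-signal variant `Σ(E_sim² − E_meas²)²` is
available behind a flag for sensitivity checks; the plain difference is the
default because it is the same error functional the layer-count robustness
analysis defines.)  Minimisation uses Gaussian-process Bayesian
optimization: Matérn-5/2 kernel with a white-noise term, expected
improvement maximised on a dense deterministic candidate grid, 10 seeded
random initial points and 40 iterations by default, followed by a bounded
local polish (Brent) in a ±5%-of-range window around the incumbent — the
loss surfaces here are smooth and unimodal, so the polish buys precision
cheaply without changing the global search.  GP hyperparameters are
re-optimised every 5th iteration and frozen in between to keep the
per-evaluation overhead low.  Two runs with the same seed are bit-identical.

The two-stage procedure fixes ridge-layer thickness first: `d_f` (bounds
2–10 µm) is optimised with `V_A1` held at 0.5.  Because the compression time
at which the skin actually passes through that mid-range deformation is
unknown, the `d_f` objective takes the *minimum* loss over the
stride-selected pulses of the series — profiling the unknown time out.  When
the deformation trajectory crosses 0.5 this makes the noiseless `d_f`
estimate essentially exact, whereas anchoring to any fixed pulse imprints
that pulse's deformation mismatch on `d_f` and thence a systematic bias
(~0.03) on every subsequent `V_A1` estimate.  `V_A1 ∈ [0, 1]` is then fitted
at every 10th pulse (configurable stride), warm-starting each search at the
previous optimum since the trajectory is slowly varying.

## Layer-count selection

For each total ridge height `d` in {15, 30, 45, 60} µm, an error matrix over
10 `V_A1` values × L = 1..15 (with `d_f = d/L`) is filled with the squared-L2
simulation error against a measured pulse (the first of the series by
default).  The robustness metric per column is
`w·mean/max(mean) + (1−w)·std/max(std)` with `w = 0.5`: both terms
max-normalised so the combination is scale-free; the exact normalisation is
a design choice, and `w` is exposed.  Layer counts within 5% of the minimum
metric form the acceptable set; the selected `L` is the smallest count in
the intersection of all heights' sets, and an empty intersection raises an
error carrying the per-height sets.  On synthetic data generated with
L* = 12 the procedure returns 11, stable across noise seeds.

## Synthetic data

The generator emulates a 90 s occlusion measurement at 12 pulses/s
(1080 pulses).  The reference is a band-limited single-cycle pulse built in
the frequency domain (odd Gaussian band, centre 0.5 THz, FWHM 0.5 THz,
1024 samples at 0.1 ps ⇒ Nyquist 5 THz), normalised to 1 mV peak-to-peak.
The deformation trajectory is
`V_A1(τ) = v_end + (v_start − v_end)·e^{−τ/T} − s·τ` (clipped to [0, 1]),
defaulting to `v_start = 0.57`, asymptote `v_end = 0.398`, `T = 15 s`,
`s = 2×10⁻⁴ s⁻¹` — chosen so the realised 90 s excursion is 0.57 → 0.380
(Δ ≈ 0.19), a fast elastic-like exponential followed by a quasi-linear
viscous-like tail.  Noise is additive white Gaussian on the time-domain
amplitude, default sd 0.002 mV (≈42 dB below the simulated pulse P2P,
a typical time-domain-spectroscopy noise floor at ~12 Hz acquisition).

What the generator does *not* emulate — and what passing recovery tests
therefore do not establish for real data: baseline drift, system dispersion
or jitter, occlusion-driven hydration change (the trajectory moves `V_A1`
only, with a fixed hydration profile), lateral heterogeneity of the contact,
and any mismatch between the assumed and true dielectric models.  Recovery
results on synthetic data bound the estimator's statistical error under a
correctly specified forward model, nothing more.

## Numerical choices and degenerate inputs

FFT length: next power of two of the reference length.  Deconvolution
floor: 1% of peak reference magnitude.  Alignment: integer-sample lags only
(sub-sample alignment is unnecessary when simulated and measured traces
share a grid).  Passivity (`Im ε ≤ 0`, `|r| ≤ 1`) is validated at
construction; zero-thickness layers are exact no-ops; half-spaces reject
phase-thickness evaluation; collapsed optimizer bounds return the point
itself; fewer than 3 τ points make Pearson correlation an error rather than
a NaN.  Layer thickness `d/L` outside 0.25–100 µm is rejected as
unphysical in the robustness sweep.

## Known limitations

* The model is strictly 1-D; lateral ridge geometry and roughness scattering
  beyond the effective-medium treatment are out of scope.
* Absolute mV scales are meaningful only relative to the supplied reference
  pulse; synthetic defaults use a 1 mV reference.
* For a pure `V_A1` step (0.57 → 0.38) the model's |M| change over
  0.2–0.5 THz is *smaller* than over 0.5–1.5 THz at the default 30 µm ridge
  height: thin-film sensitivity grows with frequency until the stack's
  interference dip enters the low band, which here requires total ridge
  heights ≳130 µm.  Deformation alone, under these study conditions, does
  not reproduce a low-frequency-dominated attenuation pattern; processes the
  generator does not model (e.g. occlusion-driven hydration increase, whose
  water absorption is strongest at the low-THz end) are plausible
  contributors in real measurements.
* The layer-count robustness metric's normalisation is one of several
  defensible choices; rankings, not absolute metric values, should be
  interpreted.
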