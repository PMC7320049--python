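# Methods

This note records the model, its assumptions, the defaults and the numerical
choices, in the package's own words. Nothing here states an empirical result
that the tests or `scripts/acceptance.py` do not themselves compute.

## Spectral model

A 1-D frequency-domain ¹H NMR spectrum on a uniform ppm axis is modelled as

χ(ν, **w**, **θ**) = Σ_k w_k · S_k(ν; θ_P,k, θ_S,k, **θ**_GS,k, θ_PB,k),

with each component S_k a sum of pseudo-Voigt peaks. Conventions and choices:

* **Pseudo-Voigt form**: V(ν) = α·[β·L(ν) + (1−β)·G(ν)], with Lorentzian L
  and Gaussian G both normalized to **unit peak height** and sharing γ as the
  **half width at half maximum** (divide a FWHM by 2 before supplying it).
  This height parameterization makes the value at ν = ω exactly α. β = 1 is
  pure Lorentzian — the natural NMR line shape — and β = 0 pure Gaussian;
  the interpolation direction is a convention and is flagged here because
  other software uses the opposite one.
* **Effective peak position** = ω + δω + θ_GS[group] + θ_S. All terms are
  additive, so composition order is irrelevant; they are listed in
  per-peak → per-group → per-component order.
* **Peak groups**: peaks sorted by position join the current group while the
  gap to the *previous* peak is ≤ Δν = 0.12 ppm (a chain rule: a long chain of
  closely spaced peaks is one group even if its ends are far apart); a larger
  gap opens a new group. Group ids are contiguous from 0.
* **Closed-form areas**: a Lorentzian of height α and HWHM γ has area παγ; the
  Gaussian analogue is αγ√(π/ln 2). Pseudo-Voigt areas interpolate linearly.
  Width broadening therefore scales a component's area linearly — which is why
  the generators compute unit-weight areas *after* applying distortions.
* **Grid**: ascending ppm internally (descending display order is a rendering
  concern); default window 5.6–9.0 ppm, 1692 points, 43.3 MHz. Peak mass
  falling outside the grid is silently truncated; a warning is logged when
  more than 1 % of a peak's analytic area is lost. Trapezoidal integration on
  this grid is effectively exact for these line shapes (the sampling error of
  the trapezoidal rule decays exponentially once γ spans ≥ 3 grid steps), so
  the practical integration error is edge truncation, not quadrature.

## Fitting (pure components and the IHM baseline)

Both fits use SciPy's bounded trust-region-reflective least squares with
ftol = xtol = gtol = 1e−10 and an iteration cap (500 evaluations per
parameter for the pure fit, 500 for the mixture fit). Non-convergence is
reported in the result object, never raised.

* `fit_pure_component`: free (ω, α, γ, β) per peak with bounds α ≥ 0, γ > 0,
  β ∈ [0, 1]; initialization from user-supplied peaks or local maxima above
  5 % of the spectrum maximum (the tallest `n_peaks` maxima, widths from the
  half-height width). Overlapping lines that present a single maximum are
  fitted as one effective peak; no splitting heuristics.
* `fit_mixture` (the IHM-style baseline): minimizes the squared residual over
  the weights plus, by default, θ_S (±0.015 ppm), θ_GS (±0.01 ppm) and θ_PB
  (±15 %) per component — each family releasable independently. Weights start
  from a non-negative linear least-squares warm start with all distortions at
  identity (a convex, cheap initialization); shifts start at 0, broadening at
  1. Per-component areas are trapezoidal integrals of each fitted weighted
  component. An all-zero spectrum short-circuits to w = 0.
* **Identifiability**: with both θ_S and θ_GS released, a rigid shift of a
  whole component is degenerate (θ_S = c and θ_GS ≡ c produce identical
  spectra). The fit returns one of the equivalent solutions; the physically
  meaningful quantity is the per-group effective shift θ_S + θ_GS[g], and
  quantification (weights, areas) is unaffected.

## Synthetic-data generators

Defaults are the study conditions: target component area uniform on
0–180 a.u.; X_i line broadening drawn from {0.2, 0.5, 0.8, 1.0, 1.5} Hz
(equal probability) and component shift uniform on ±0.015 ppm; X_ii per-peak
jitter ±0.005 ppm, component shift ±0.015 ppm, group shift ±0.01 ppm, peak
broadening ±15 %, noise amplitude factor ±15 %; 300,000 spectra for a
production dataset (tests and the acceptance run use 10²–10³-spectrum
instances of the same generators). All "0–±r" ranges are read as symmetric
U(−r, +r).

* **Line broadening** is realized as convolution with a unit-mass Lorentzian
  kernel of FWHM = lb Hz (converted to ppm via the spectrometer frequency) —
  the frequency-domain equivalent of exponential apodization of the FID. The
  kernel extends ±60 HWHM and is renormalized to unit discrete mass, so the
  total integral is preserved exactly up to edge effects.
* **X_i**: per component, broaden → shift (linear interpolation, zero-filled
  edges) → scale so the full-window trapezoidal area equals the drawn target;
  the label *is* the target. The measured noise embedded in a pure spectrum
  scales with its area — the route's known limitation.
* **X_ii**: per component, render the distorted unit component, then set
  w_k = target / unit-area, so the noise-free area equals the target exactly.
  Empirical noise is resampled with replacement, independently per grid point,
  from a pool of baseline intensities of a measured blank, then scaled by
  1 + U(−0.15, +0.15) per spectrum. The "noise factor" is interpreted as this
  multiplicative amplitude perturbation (an additive-percentage reading would
  couple noise to signal height; the amplitude reading keeps noise a property
  of the instrument, which matches how baseline noise behaves).
* **Determinism**: one seeded generator drives the parameter draws in a fixed,
  documented order (per spectrum, per component: jitter per peak, component
  shift, group shifts, broadening, target area); a *second* stream derived
  from the same seed drives the noise, so labels and parameters are
  bit-identical with noise on or off. Re-running any generator with the same
  config and seed reproduces the dataset bit for bit.

## The network

Locally connected 1-D convolution (each of the P = ⌊(L − 9)/9⌋ + 1 window
positions owns its own 9-tap kernel and bias per filter), ELU activation,
flatten, dense K-node output with ReLU. Parameter count
P·F·(kernel+1) + (P·F·K + K); for L = 1692, F = 4, K = 4 this is 10,532.
A `conv_type="shared"` switch swaps in an ordinary weight-sharing convolution
for ablation.

Training: MSE loss, Adam (β₁ = 0.9, β₂ = 0.999, ε = 1e−8), batch size 1024,
400 epochs, learning rate stepped 1e−4 → 3e−5 → 1e−5 at epochs 170 and 240
(a third announced step at epoch 310 repeats 1e−5 and is a no-op in the
implementation). Inputs and labels are min–max normalized by their training
maxima; the two scalars are stored on the model, applied to measured spectra
at prediction time, and invert the predictions back to a.u. AWGN with
σ = 0.04 (normalized units) is drawn **fresh per batch** — per-batch noise is
the standard augmentation reading and gives the regularizing effect a single
pre-noised dataset would not — and never applied at evaluation. The 95:5
train/validation split, weight initialization (Glorot uniform), batch
shuffling and AWGN all derive from the one config seed; training is
single-threaded NumPy and exactly reproducible. An optional reference pair
(measured spectra, reference areas) is evaluated after every epoch as a
second validation track in a.u. Early stopping is deliberately not applied;
training runs to the configured epoch count so the model converges over the
full label range rather than the range a small measured validation set
happens to cover.

Scaled-down runs (tests, examples, acceptance) use the same architecture on
the same 1692-point grid with 2,000–5,000 spectra, batch 256, a constant
learning rate of 1e−3 and ≤ 50 epochs: with only a few hundred optimizer
steps available, the production schedule's 1e−4 would leave the fit far from
converged, and 1e−3 is stable for this model. These sizes are the package's
chosen demonstration conditions; production use scales the dataset and
schedule back up to the defaults.

## Reference-data curation

* `match_nearest`: each target timestamp takes the reference row of minimal
  |Δt|; an exact midpoint tie takes the earlier row.
* `steady_state_mask`: 11-point moving OLS line against the true timestamps
  (hours), per component; a window is steady iff |slope| < 0.1 mol h⁻¹ **and**
  the residual standard deviation about the fitted line is < 0.01 mol L⁻¹ for
  all components (strict inequalities). The residual-spread reading (rather
  than the raw window std) is used because a raw std conflates slope with
  scatter; both readings and the marking mode (center sample vs whole window)
  are configurable.
* `remove_outliers`: drop rows where any component's |hf − lf| exceeds
  0.04 mol L⁻¹ strictly (an exact-boundary deviation is kept; a 1e−12
  absolute slack absorbs binary representation error).
* `kennard_stone_select`: classic max–min selection on Euclidean distance
  over unscaled component vectors (an optional min–max scaling flag is not
  default because the toy components share one unit and scale); ties break
  to the lowest index, making the selection deterministic and giving the
  prefix-chain property (the first k of a k+1 selection equal the
  k-selection).

## The toy study system

`make_toy_library` stands in for the laboratory: four aromatic species
(8–12 pseudo-Voigt lines each, binomial multiplet patterns, widths 0.008–0.012
ppm HWHM ≈ 0.7–1 Hz at 43.3 MHz, β ∈ [0.3, 0.6], positions 6.4–8.2 ppm with
overlapping multiplets), rendered pure spectra with 0.5 % white noise, a
baseline-noise pool from a synthetic blank, and a 10-hour process trajectory
(200 samples at 3-minute cadence, four plateaus joined by ramps) observed by
an accurate reference channel at a different cadence and a noisy low-field
channel (σ = 0.003 mol L⁻¹). The low-field trace carries two isolated spikes
(caught by the steady-state filter) and two 12-sample calibration-bias
episodes of ±0.06 mol L⁻¹ (steady in the low-field trace alone, caught only
by the hf-vs-lf outlier filter) so every curation stage does real work.

What the toy system does *not* emulate: phase and baseline errors, solvent
background, temperature-dependent shift trajectories, peak asymmetry, and
model mismatch between the "measured" spectra and the pseudo-Voigt model
(the toy pure spectra are themselves pseudo-Voigt renders plus noise).
Passing tests therefore demonstrate the machinery — label bookkeeping,
optimization, training dynamics, filtering logic — not performance on real
instrument data, where preprocessing quality and model mismatch dominate.

## Degenerate inputs and edge behaviour

Empty peak lists are valid for grouping (empty result) but not for component
models; all-zero spectra are rejected by normalization and short-circuited by
the mixture fit; series shorter than the steady-state window yield an
all-false mask with a warning; spectra are validated for finiteness and
length at construction. File readers fail with the offending line number and
never return partial objects; descending-ppm text spectra are accepted and
flipped.
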