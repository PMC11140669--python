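# Methods

This note documents the models and procedures implemented in `ramankit`,
the defaults and why they were chosen, what the synthetic-data generator
does and does not emulate, and the package's known limitations.

## Data model

All data flow through `SpectralContainer`: a float64 array whose last axis
is spectral, paired with a strictly increasing wavenumber axis (cm⁻¹).
Axes supplied in decreasing order are reversed together with the
intensities at construction, so every downstream operation can assume one
direction. Zero to three leading dimensions encode a single spectrum, a
stack, an image scan, and a volume. NaN intensities are rejected at
construction; an explicit `nan_policy="zero"` converts them with a warning,
since vendor exports occasionally contain masked pixels. Band lookup
(`band_slice`) is nearest-neighbor with ties resolved toward the lower
index.

## Preprocessing

All operations are per-spectrum along the last axis, never mutate their
input, and commute with flattening (verified by property tests).

**Cropping** retains bands inclusively within `[min_wn, max_wn]`; the
standard biological choice is the 700–1800 cm⁻¹ fingerprint region.

**Despiking (Whitaker–Hayes).** First differences `dᵢ = yᵢ − yᵢ₋₁` are
scored with the modified z-score `Zᵢ = 0.6745 (dᵢ − median d)/MAD(d)`;
`|Z| > z_threshold` flags the later point of the offending difference.
Flagged points are replaced by the mean of unflagged neighbors within
`±(window−1)/2` bands, falling back to linear interpolation between the
nearest unflagged points when the window is exhausted. Defaults
`z_threshold = 6.5`, `window = 5` are deliberately conservative (cosmic
spikes sit tens of MADs above the difference noise floor, so a high
threshold costs little recall and keeps false positives rare). When
`MAD(d) = 0` on a non-constant spectrum the mean absolute deviation is
used; constant spectra pass through unchanged.

*Limitations.* The score is scale-free: on strictly noiseless smooth
spectra the MAD of the differences collapses and peak slopes themselves
become outliers — measured on noiseless multi-peak fixtures, ~40% of
points get altered, versus 0.02% once a realistic 2%-of-peak noise floor is
present. Operating characteristics are therefore only meaningful (and are
quoted) for spectra with a noise floor, which physical detectors always
provide. Additionally, when a spike lands on a steep peak slope the
windowed-mean replacement leaves a small kink that a second pass may
re-flag, so despiking is idempotent on flat-background fixtures but not
strictly idempotent everywhere (~0.01% of points on slope-spike fixtures).

**Denoising.** Savitzky–Golay fits a degree-`polyorder` polynomial over an
odd window (defaults 3/7); interior points reproduce polynomials of degree
≤ `polyorder` to machine precision, and edges use polynomial extrapolation
of the edge fit. Gaussian smoothing uses a unit-sum kernel truncated at
4σ with reflect padding; default σ = 1 band, matched to sampling rather
than to any particular peak width.

**Baselines.** ASLS minimizes `Σ wᵢ(yᵢ−zᵢ)² + λ‖Δ²z‖²`, iterating
`wᵢ = p` above the baseline and `1−p` below, from uniform weights, until
fewer than `tol` of the weights flip (defaults λ = 1e5, p = 0.01,
max_iter = 30, tol = 1e−3). Because `ΔᵀΔ` acts as a discrete fourth
difference, polynomials up to cubic are reproduced in the interior and
bias concentrates at the boundaries; on line and cubic baseline-only
fixtures the residual RMS is below 1% of the baseline amplitude, and a
narrow peak on a line keeps its height within 1%.

asPLS replaces the fixed asymmetry with logistic weights
`wᵢ = 1/(1 + exp(2(rᵢ − σ₋)/σ₋))` (σ₋ = std of negative residuals) and
scales the penalty per point by `αᵢ = |rᵢ|/max|r|`. The adaptive penalty
feeds back — larger residuals stiffen the baseline locally — which makes
asPLS effectively stiffer than ASLS at equal nominal λ on smooth peak-free
input. Its default is therefore its own: λ = 1e4, which gives sub-1%
residual RMS on line/cubic baselines and ~0.05% peak-height error on
peak fixtures. Iteration stops at weight stability or when σ₋ = 0
(one-sided fit). Non-convergence at `max_iter` warns and returns the best
iterate.

**Normalization** offers global min-max to [0,1], per-spectrum min-max,
and per-spectrum division by the trapezoidal integral over the wavenumber
axis (unit area). Degenerate spectra (constant, nonpositive area) raise
errors naming the offending pixel. Background subtraction requires exact
axis equality — resampling is intentionally out of scope.

## Pipelines

A `Pipeline` is an ordered list of registered step names with fully
concrete, JSON-serializable parameters. Where a published protocol names a
method but not its parameters, the package defaults are embedded at
construction time, so a saved protocol is self-contained and replays
bit-identically anywhere. Custom steps serialize by registered name only —
shared protocol files never embed executable code. Two built-in protocols
are provided: `cell_phenotyping` (crop 700–1800 → despike → SG(3,7) →
ASLS → global min-max), the recipe used ahead of unmixing cell scans, and
`pipeline_I` (crop 700–1800 → despike → Gaussian → ASLS → per-spectrum
unit area), a representative throughput protocol. The CLI writes a
provenance sidecar (resolved pipeline JSON, input SHA-256, tool version)
sufficient to re-run any output exactly.

## Unmixing

PCA (mean-centered SVD) supplies the K−1-dimensional projection N-FINDR
operates in; rank deficiency below the requested dimension is an error
reporting the achievable rank. The N-FINDR search initializes with K
distinct random pixels, sweeps endmember slots replacing a slot by any
pixel that strictly increases `|det M|` (ties keep the incumbent, for
determinism), and stops when a full pass makes no replacement. The
determinant is linear in the replaced row, so each slot's candidate scan is
a single cofactor inner product over all pixels. The search is a local
optimizer: `n_restarts` seeded restarts (default 10) guard against local
optima, and validation against exhaustive search uses a larger budget (30)
sized for global convergence on ≤35-pixel instances, where unstructured
point clouds have strong local optima. Volumes are reported as
`|det M|/(K−1)!`.

FCLS augments `Eᵀ` with the row `γ·1ᵀ` (γ = 1e3 × the largest endmember
norm), solves nonnegative least squares per pixel, and renormalizes to
exact unit sum; the heavy row bounds the sum-to-one violation before
renormalization restores it exactly. An ill-conditioned endmember Gram
matrix (condition number > 1e10) triggers a warning. On noiseless convex
mixtures the per-pixel abundance error is at machine level (~1e−14
measured).

## Synthetic scenes

The generator produces scenes under the exact linear mixing model so that
unmixing can be validated against analytic ground truth:

- **Endmembers**: sums of Gaussian and Lorentzian bands (default 6 per
  component, widths 5–30 cm⁻¹, 30% Lorentzian) on a 400–1800 cm⁻¹ axis of
  500 bands, normalized to unit peak height; components are resampled until
  pairwise spectral angles exceed 0.25 rad so they are distinguishable.
- **Abundances**: symmetric Dirichlet (default concentration 1) per pixel,
  with one pure pixel planted per component by default — N-FINDR is only
  correct under the pure-pixel assumption, and the planting makes that
  assumption hold by construction.
- **Baseline**: a shared random polynomial (default degree 3), shifted
  nonnegative and scaled to half the peak signal, with 5% per-pixel scale
  jitter — emulating autofluorescence that varies smoothly and slightly
  per pixel.
- **Spikes**: Bernoulli(5e−4) per (pixel, band) cell with amplitudes 3–8
  in signal units.
- **Noise**: either plain additive Gaussian, or the *paper-noise* protocol
  — per-spectrum min–max to [0,1] followed by additive Gaussian noise
  (default σ = 0.15), emulating the preparation of low-SNR spectra at a
  controlled noise level. The measured mean per-spectrum residual std
  reproduces σ to well within 5%.

All randomness flows from a single seed. What the generator does **not**
emulate: nonlinear mixing, instrument response functions, Poisson shot
noise, wavenumber miscalibration, or the statistical families of any
specific published simulator. Passing recovery tests on these scenes
demonstrates correctness of the algorithms under the linear model with
pure pixels — not robustness to the full messiness of measured data.

### Validation oracle for end-to-end recovery

Unmixing after preprocessing operates in the preprocessed representation,
so recovery is scored against the ground truth *propagated through the
same transformation*: truth endmembers are passed through the same crop →
denoise → baseline steps (despiking is skipped — the truth is spike-free
and noiseless, where the scale-free z-score would flag peak slopes), and
per-spectrum area normalization reparametrizes abundances as
`a′ₖ = aₖsₖ/Σⱼaⱼsⱼ` with `sₖ` the processed-endmember areas; the
comparison applies that exact reparametrization to the truth. Comparing
against raw truth instead conflates preprocessing's intended
representation change with unmixing error.

On the standard validation scene (20×20, K = 4, baseline + spikes + 5%
additive noise, one planted pure pixel per component) N-FINDR selects
precisely the planted pure pixels; the endmember spectral angle is then
bounded below by the noise carried by those single pixels,
`≈ ‖n‖/‖e‖ ≈ 0.15–0.2` rad at this SNR and spectral density. That floor
is a property of pixel-selection extractors, not of the implementation:
reducing it requires denser spectra, lower noise, or estimators that
average over many near-pure pixels. Abundance RMSE on the same scenes is
0.03–0.05.

## Problem sizes

Validation workloads are sized for interactive runs: 500-mixture FCLS
checks, 20 brute-force N-FINDR instances (≤35 pixels, K = 3), 20×20
end-to-end scenes, and 1000-spectrum despiking/noise studies; all complete
in seconds while leaving the measured quantities' interpretations
unchanged at larger sizes.

## Known limitations

- N-FINDR with few restarts can stall in local optima on unstructured
  data; the restart budget trades time for reliability.
- FCLS is solved pixel-by-pixel (active-set NNLS); very large volumes
  would benefit from a blocked solver.
- Background subtraction requires exact axis equality; no resampling.
- The MAT-file reader requires explicit variable names — vendor export
  schemas are not guessed.
- Baseline estimators are 1-D per spectrum; no spatial regularization.
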