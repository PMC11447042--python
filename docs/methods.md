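# Methods

## Model and assumptions

All three methods assume Beer–Lambert behavior: absorbance at each
wavelength is proportional to concentration and additive across
non-interacting absorbers, `A(λ) = Σᵢ cᵢ aᵢ(λ)`, over the whole working
range (no stray-light saturation, no chemical interaction between the two
drugs, excipients non-absorbing). Spectra are sampled on a regular
wavelength grid — 1 nm over 200–400 nm by default, matching common
benchtop UV–Vis export conventions; 0.1 nm grids are supported. All
transforms operate on aligned grids; spectra recorded on different grids
are linearly interpolated (never extrapolated) before division.

Dividing a mixture spectrum by a divisor spectrum of the interfering
analyte turns the interferent's contribution into an additive constant.
The three signal extractors — ratio difference (RD), symmetric-difference
first derivative (¹DD), and mean centering (MC) — are linear functionals
that annihilate constants, so each returns a scalar proportional to the
target concentration and blind to the interferent. Linearity also means
mixture signals are exactly the sum of pure-component signals, which is
the basis of several structural tests.

## Parameters

| Parameter | Default | Units | Role |
|---|---|---|---|
| division guard ε | 0.01 | AU | wavelengths with &#124;A_div&#124; < ε are masked, not clipped: the ratio would otherwise blow up where the divisor analyte stops absorbing |
| Δλ (¹DD) | 4 | nm | half-window of the symmetric difference; must be a multiple of the grid step |
| scaling factor k (¹DD) | 10 | — | cosmetic multiplier kept for comparability with instrument-software output; cancels in calibration |
| MC window | 200–305 | nm | range over which the ratio spectrum is mean-centered (applies to both analytes unless configured per analyte) |
| divisor concentrations | TST 16, BPL 10 | µg/mL | the published optimum divisors; higher divisor concentration lowers noise amplification (mean of 1/&#124;A_div&#124;) |
| analysis wavelengths | RD 210/224 & 255/265; ¹DD 232 & 243; MC 223 & 245 | nm | the published per-method read-out wavelengths (BPL & TST respectively) |

The derivative operator is the symmetric difference
`D(λ) = k·[P(λ+Δλ) − P(λ−Δλ)]/(2Δλ)`. Instrument software rarely
documents its derivative kernel; symmetric differencing is the standard
reading of "scaling factor and Δλ" settings and is exact for locally
quadratic signals, which the tests exploit as an oracle. A Savitzky–Golay
first derivative (window and polynomial order configurable) is provided
for noisier data but is not the default. Δλ is interpreted in nm, not in
points, so signals agree across grid densities.

Signals are kept signed throughout — no absolute values — and calibration
handles negative slopes; LOD/LOQ use |S|.

## Calibration and validation statistics

Calibration is unweighted ordinary least squares of signal on
concentration (no 1/c weighting; none is indicated for this assay type).
σ is the residual standard deviation with n−2 degrees of freedom; the
SD-of-intercept alternative from the ICH Q2 family is available via
`sigma="intercept"`. r² is the squared Pearson correlation, identical to
the coefficient of determination for simple OLS. Inverse prediction
outside the calibrated range returns the value but emits a warning — QC
users need the number together with the flag.

Recovery summaries use the sample SD (n−1) and RSD = 100·SD/mean.
Method comparison uses the pooled-variance two-sample t (the published
critical value 2.306 corresponds to df = n₁+n₂−2 = 8, which identifies
the pooled rather than Welch form) and the larger-over-smaller
variance-ratio F (all published F ≥ 1; critical 6.388 = F(0.05; 4, 4)).
Standard-addition recovery scores only the added increment,
`100·(spiked − base)/added`, so a constant matrix bias cancels.
Published summary tables print per-level mean recoveries (5 values per
column); summaries can be computed either on those per-level means (to
reproduce the printed tables) or on all raw determinations in pipeline
mode.

Wavelength selection scores every candidate (pair) by calibration r²,
|slope| and interferent rejection (max |interferent signal| across its
levels, threshold 1% of the target's mid-range signal), choosing the
highest r² subject to rejection, tie-broken by larger |slope|. r² is
rounded to 10 decimals before ranking so that floating-point ties —
ubiquitous on noise-free data where every candidate fits perfectly — are
resolved by the documented tie-break rather than by rounding noise.
Divisor ranking uses r² then lower noise amplification; on noise-free
data this deterministically prefers higher divisor concentrations.

## The synthetic generator

True molar absorptivity curves of the two drugs are not published
numerically, so the generator uses Gaussian absorption bands as clearly
synthetic stand-ins that reproduce the assay's geometry: a weak absorber
with deep-UV end absorption, a main band peaking near 225 nm and a weak
long-wavelength tail (BPL-like); and a strong absorber with deep-UV,
236 nm and 296 nm bands spanning the whole window (TST-like). Band
positions follow the published qualitative overlap; band heights were
sized from the noise-propagation identity — additive absorbance noise of
SD s maps to ratio-amplitude noise s/|A_div(λ)| and thence to a
concentration SD of `s·sqrt(Σ 1/A_div(λᵢ)²)/|S|` — so that 0.002 AU of
instrument noise yields the sub-2% recovery RSDs characteristic of a
validated assay at the published mixture compositions. The BPL tail band
keeps a 10 µg/mL divisor above the division guard throughout the MC
window; its deep-UV band prevents an artificial masked region at the
short-wavelength edge.

Noise is additive white Gaussian on absorbance, optionally plus a
per-spectrum constant baseline offset; multiplicative/shot noise is out
of scope (the methods' theory assumes additive noise on A). Every
stochastic operation requires an explicit seed and there is no global
generator state. Excipients (talc, starch, magnesium stearate) are
modeled as non-absorbing.

What passing tests on this generator do **not** show: absolute slopes,
LODs and LOQs of the real assay (those depend on the physical spectra),
robustness to instrument artifacts (stray light, wavelength
miscalibration), solvent/pH effects, or deviations from Beer–Lambert
linearity at high absorbance. They do show that the transforms, the
calibration algebra, the selectivity structure and the statistics layer
are correct, and how noise propagates through each method.

## Numerical choices and degenerate inputs

* Grid regularity is enforced at 1e-9 nm; wavelength lookup tolerance is
  1e-6 nm, and off-grid reads of derived signals raise rather than
  silently interpolate.
* Masked samples are stored as NaN with an explicit validity mask and
  never participate in any computation; transforms propagate masks
  (a derivative point is valid only if both ±Δλ neighbours are valid).
* Fewer than 3 unmasked ratio samples, all-equal calibration
  concentrations, and zero-slope inversions raise typed errors
  (`DegenerateRatioError`, `RankError`, `InversionError`).
* A perfectly horizontal degenerate fit (e.g. symmetric points) returns
  slope 0 with positive σ; its r² is 0.
* With both group SDs zero, the t statistic is 0 for equal means and
  flagged infinite for unequal means.

## Study sizes

The bundled study design mirrors the published geometry: 8-level
calibrations, 5 mixture ratios × 3 replicates × 3 days, and a tablet base
with 3 co-spiked levels × 3 replicates (71 spectra). Monte-Carlo checks
use 200 replicates for recovery/unbiasedness/σ̂ properties and 10,000
simulated pairs for the type-I error of the t comparison; these sizes give
standard errors comfortably below the asserted bounds while keeping the
full suite fast.

## Known limitations

* Single-divisor binary-mixture resolution only: no double-divisor,
  successive-derivative or ternary extensions, and no second or higher
  derivatives.
* MC's window mean is an arithmetic mean of samples, so MC signals carry
  a small O(1/n) grid-density dependence (and more where the window
  includes near-guard amplitudes); RD and ¹DD are exactly grid-invariant
  at shared wavelengths.
* No baseline correction or smoothing beyond the optional Savitzky–Golay
  derivative; vendor binary formats (JCAMP-DX, SPC) are not read.
* One published comparison cell (the BPL-¹DD t statistic) is inconsistent
  with its own printed inputs under the pooled formula; it is carried in
  the reference data with an explicit flag and excluded from numerical
  checks.
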