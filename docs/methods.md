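# Methods

## Measurement model

A pump–probe campaign is modelled as follows.  A sample of photo-reactive
protein with ground state pG is excited by a laser shot that promotes a
fraction *f* (default 0.1) of the ground state into the first photocycle
intermediate.  The subsequent chemistry is first-order,

    dC/dt = K C,      C(0⁺) = (1 − f, f, 0, …),

with a rate matrix K whose columns sum to zero (mass conservation) and
whose off-diagonal entries are non-negative.  The solution
C(t) = exp(Kt) C(0) is evaluated analytically through the
eigendecomposition of K; when K is numerically defective (eigenvalue gap
below 10⁻⁹ of the spectral radius, or eigenvector condition number above
10¹²) the code falls back to the scaled-and-squared matrix exponential per
time point and flags the result.  The relaxation times of the campaign are
the negative reciprocal non-zero eigenvalues of K — for sequential schemes
these coincide with the step times, so truth values for parameter-recovery
tests are exact by construction.

Species spectra are sums of Gaussian bands in wavelength, normalised so the
summed profile's maximum equals the species' peak decadic extinction;
absorbance follows Beer–Lambert, and the concentration × path product is
set so the dark-state spectrum peaks at a chosen optical density (default
1.0).  Gaussians in wavelength (rather than energy) keep closed-form
checks — peak value, 1σ points, band areas — exact.

Detector counts at delay t are

    S(λ, t) = B(λ)·Δt_gate·10^(−A(λ,t)) + d·Δt_exposure,

with B the lamp rate (a smooth cubic-spline Xenon-continuum template times
a calibration scale), d the dark-current rate, realised as Poisson counts
plus Gaussian readout noise and clipped at the detector full well (clipped
delays are flagged).  Dark frames contain only dark current and readout
noise.  Every accumulation is one laser shot; permanent bleaching
multiplies the total protein by (1 − b) per shot, and the dark-state
spectrum is re-recorded after the campaign so the bleach check has both
endpoints.  One integer seed drives a single `numpy` Generator; draws occur
in a fixed order (dark-state frames, then per delay the sample shots and
the dark frame, then reference frames), so identical seeds give identical
campaigns bit for bit.

## Default scenarios

*Solution*: species pG (446 nm, σ 15 nm, peak extinction 45 500
cm² mmol⁻¹), pR (485 nm) and pB (355 nm); sequential pG → pR → pB → pG
with τ₁ = 290 µs, τ₂ = 0.45 s; 10 delays log-spaced 30 µs – 2 s.  The pB
band lies almost entirely below the 410–530 nm analysis window, so pB is
visible only through the kinetics, as for the real protein.

*Crystal*: pG at 449 nm; the ground-state recovery is biphasic, modelled
as pR branching (0.7/0.3) into two non-interconverting pB sub-states with
recovery times 61 ms and 0.70 s (τ₁ = 2.6 ms for pR decay); 34 delays
log-spaced 25 µs – 3 s.  With both sub-states sharing one 355 nm band the
difference matrix restricted to 410–530 nm would be numerically rank 2 and
the third kinetic phase spectrally invisible there; real crystal data do
show a third significant component.  The slower sub-state therefore
carries a red-shifted, broader band (375 nm, σ 30 nm) whose blue tail
reaches the window.  pR/pB widths and extinctions are declared simulator
defaults — the literature states band maxima but not these shapes — and
are configurable.

*Photoswitch mode*: two stable isomers E and Z with fixed spectra; a pulse
converts a fraction *f*, the transient is the linear mixture
(1−f)·A_E + f·A_Z and difference spectra are taken against the initial
pure state.  A two-state mixture family necessarily shares isosbestic
points wherever A_E = A_Z; systems whose transients lack an isosbestic
point involve more than two states and are outside this mode's scope.

Noise level is parameterised as the difference-signal SNR: the lamp scale
is solved analytically from the target SNR and the noise-free peak |ΔA|
using σ_ΔA ≈ √(2/N)/ln 10 at N transmitted counts (the reference noise is
common to both absorbances and cancels in the difference).

## Absorbance reduction

Decadic absorbance A = −log10(S_sample/S_ref) on dark-corrected counts;
"log" is read as log10 throughout (standard optical convention: A = 1 at
10 % transmission); no natural-log mode is offered.  Where the sample
signal falls below ε = 10⁻⁶ of the reference the value is capped at
−log10 ε = 6 and flagged, so dead pixels never propagate infinities.
Arithmetic between spectra requires exactly matching wavelength grids
(elementwise within 10⁻⁹ nm); resampling is always explicit (linear
interpolation, extrapolation refused).  Two reference policies exist: one
reference for the whole series (default) or per-delay darks/references,
needed when the CCD exposure varies with gate delay and dark current would
otherwise not cancel.  Mismatched exposures or gate widths raise warnings
rather than errors, since the offset they introduce is constant and is
absorbed by the fitted A₀.

## SVD and significance

The difference matrix, windowed to 410–530 nm, is decomposed with
`numpy.linalg.svd`; signs are fixed by making the largest-magnitude
element of each spectral vector positive.  A component is significant iff

1. its singular value is ≥ 1 % of the largest (configurable), and
2. its spectral vector has lag-1 autocorrelation ≥ 0.8, and
3. its temporal vector passes the same test **when the series has at
   least 16 delays**.

The temporal exception is deliberate: the lag-1 autocorrelation of a unit
n-vector is bounded by cos(π/(n+1)), and on a 10-point series even a
perfectly smooth sign-changing kinetic vector scores ≈ 0.6, below any
threshold that still rejects noise.  The spectral vectors, with hundreds
of wavelength points, retain full discriminating power at any series
length, and pure-noise matrices still yield zero significant components.
The whole rule is invariant to rescaling the data.

## Global fit

The significant right singular vectors (by default weighted by their
singular values, so stronger components dominate the shared estimate) are
fitted by y_j(t) = A₀,j + Σᵢ Aᵢ,j exp(−t/τᵢ) with τ shared across
vectors.  Sums of exponentials are notoriously multi-modal and the linear
and nonlinear parameters are separable, so the fit uses variable
projection: at each trial of log₁₀ τ the amplitudes and offsets are solved
exactly by linear least squares, and only the τ are optimised with bounded
trust-region least squares (`scipy.optimize.least_squares`,
bounds [t_min/10, t_max·10], xtol = ftol = 10⁻¹⁴).  Thirty-two starts are
used by default: one evenly log-spaced, the rest log-uniform from a seeded
generator; the lowest-residual converged start wins, ties (within 10⁻⁹
relative) broken by the smaller fast τ.  Fitting more exponentials than
significant vectors is allowed but warned; 2·n_exp + 1 parameters
exceeding the number of delays is an error.  τ standard errors come from
the linearised covariance at the optimum (scaled inverse JᵀJ in log₁₀ τ);
a bootstrap is not built in.  A BIC scan across n_exp ∈ {1, 2, 3} is
available as a diagnostic but never applied silently.  Reported values are
raw doubles; two-significant-figure rounding is applied only in display
strings, matching the usual table style for relaxation times.

The single-wavelength fit runs the identical engine on one row of the
difference matrix (nearest grid row, with a warning when off-grid), as a
consistency check on the global analysis.

## Photon and sample budgets

Photon numbers use N = P·Δt·λ/(hc) with CODATA constants and a 500 nm
reference photon.  Per-channel counts divide by 1024 channels (full
vertical binning) and scale linearly with slit width (a 50 µm slit passes
1/8 of a 400 µm slit); the measured spectral resolutions (12 nm at 400 µm,
3 nm at 50 µm) are exact lookups — no resolution model is claimed for
other widths, which raise an error.  Drop mass is volume × concentration
(1 nL × 1 mg/mL = 1 ng).

## File formats

Series are wide CSV — first column `wavelength_nm`, one column per delay
named by the delay in seconds in scientific notation — with a `.meta.json`
sidecar (quantity, gate widths, exposures, accumulations).  Values are
written in shortest round-trip notation and parsed with
`float_precision="round_trip"`, so write → read reproduces the matrix bit
for bit.  Single spectra use a 2-column CSV.  Units are fixed internally:
seconds, nanometres, decadic absorbance.

## Problem sizes and what the tests show

The bundled campaigns use 356 wavelengths (385–740 nm at 1 nm) and 10 or
34 delays; Monte-Carlo studies use 20 seeds at SNR ≈ 50 (solution
recovery) and SNR ≈ 100 (crystal three-component detection), sizes chosen
to estimate pass rates with useful resolution while keeping a full suite
run in well under a minute of fitting time.  The simulator reproduces the
statistical structure the analysis assumes — Poisson counts, exposure-
proportional dark current, geometric bleaching, exact first-order
kinetics.  It does not emulate lamp flicker or drift, wavelength-
calibration error, detector nonlinearity and fixed-pattern noise,
scattering baselines, photoproduct accumulation beyond a uniform bleach,
or sub-10 ns photophysics (the early femto/picosecond intermediates are
outside the simulated time range by design).  Passing tests therefore
demonstrate correctness of the reduction and fitting machinery and
robustness at realistic counting noise, not immunity to those systematic
effects in real measurements.

## Known limitations

* Target analysis (species-associated spectra from a posited scheme) and
  temperature-series thermodynamic fits are out of scope; the fit reports
  phenomenological relaxation times only.
* The significance rule is a heuristic; for series with 10–15 delays it
  relies on spectral smoothness and the singular-value ratio alone.
* The photoswitch mode is strictly two-state.
* Per-delay reference spectra are supported in the reduction, but the
  simulator's bundled scenarios record a single reference (constant gate
  width), matching the default reduction policy.
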