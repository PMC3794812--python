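# trabs — time-resolved difference absorption spectroscopy

`trabs` analyses time series of transient absorption spectra of
photo-reactive proteins, of the kind recorded with a gated-ICCD
microspectrophotometer: a nanosecond laser pulse starts a photocycle (the
canonical example is photoactive yellow protein, PYP, with its
pG → pR → pB → pG cycle), a continuous Xenon lamp probes the sample, and
entire visible spectra are captured at log-spaced pump–probe delays from
tens of microseconds to seconds.  Because no such raw data set ships with
the package, it also contains a full forward simulator — Beer–Lambert
band spectra, first-order rate-matrix kinetics, shot noise, dark current,
bleaching — so every stage of the analysis can be exercised and validated
against exact ground truth.

It is intended for spectroscopists reducing gated-detector measurements and
for anyone who wants a tested reference implementation of SVD-based global
lifetime analysis.

## The analysis

Raw frames are detector-dark corrected and converted to decadic absorbance
against a buffer-only reference,

    A(λ)_Δt = −log10( S(λ)_Δt / S(λ)_ref ),

and the dark-state absorbance A(λ)_D is subtracted to give difference
spectra ΔA(λ, t).  The wavelength × time matrix, restricted to the
signal-carrying window (410–530 nm by default), is factorised by singular
value decomposition, ΔA = U S Vᵀ.  The j significant right singular
vectors — selected by a singular-value ratio plus smoothness
(lag-1 autocorrelation) rule — are fitted globally by

    y_j(t) = A_0,j + Σ_i A_i,j · exp(−t / τ_i),

with the relaxation times τ_i shared across vectors and an offset A_0,j
that absorbs residual baseline and slight permanent bleaching.  The fit
uses variable projection (amplitudes and offsets solved linearly at every
trial of τ) with bounded multi-start nonlinear least squares, deterministic
under a seed.  Macroscopic rates are reported as Λ_i = 1/τ_i.

Photon-budget helpers estimate the photons per gate and per CCD wavelength
channel (full vertical binning) from a measured probe power, and the
protein mass contained in a solution drop.

## Worked example

Run the bundled noise-free solution scenario — a 10-delay log-spaced
series from 30 µs to 2 s with relaxation times of 290 µs and 0.45 s in the
generator:

```
$ trabs run --kind pyp_solution --seed 1 --out out/
scenario: pyp_solution  (seed 1, config a777a62b71898d65)
analysis window: 410-530 nm, 10 time delays
significant components: 2
relaxation times:
  tau = 2.9e-04 s   Lambda = 3.4e+03 1/s
  tau = 4.5e-01 s   Lambda = 2.2e+00 1/s
residual norm: 7.854e-16
no permanent bleaching detected
```

The SVD finds exactly two kinetic components; the global fit returns the
fast pR → pB phase (τ₁ = 2.9 × 10⁻⁴ s) and the slow pB → pG ground-state
recovery (τ₂ = 0.45 s), matching the generator truth to machine precision
since no noise was added.  `out/` additionally contains the difference
series as wide CSV + JSON sidecar, the full fit report (`report.json`) and
the single-wavelength cross-check at 485 nm.

The same pipeline is available as a library:

```python
import trabs
report = trabs.run_pipeline(trabs.example_config("pyp_crystal", seed=1))
print(report["fit"]["tau_display"])   # ['2.6e-03', '6.1e-02', '7.0e-01']
```

The crystal scenario has a biphasic ground-state recovery and yields three
significant components with relaxation times 2.6 ms, 61 ms and 0.70 s.

Other subcommands: `trabs simulate` (write a synthetic raw campaign),
`trabs absorbance` (reduce raw CSV series to difference spectra),
`trabs analyze` (SVD + global fit of an existing series), and
`trabs budget`, e.g.

```
$ trabs budget --power 5e-5 --gate 1e-6
total photons:        1.258560e+08  (1.3e+08)
photons per channel:  1.229062e+05  (1.23e+05)
spectral resolution:  12 nm
```

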