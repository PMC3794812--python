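"""Synthetic transmission-spectrum time series with photocycle kinetics.

The generator emulates a gated-ICCD microspectrophotometer probing a
photoactive protein with a continuous Xenon lamp:

* species absorption as sums of Gaussian bands (Beer-Lambert),
* sequential first-order photocycle kinetics ``dC/dt = K C`` solved
  analytically by eigendecomposition,
* Poisson shot noise on detector counts plus Gaussian readout noise,
* dark current proportional to the CCD exposure,
* optional slight permanent bleaching (per-laser-shot loss of protein).

Every run is reproducible from a single integer seed; random draws consume
the stream in a fixed, documented order (per time point: sample shots, then
the dark frame; then reference, then dark-state frames).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.linalg import expm

from .core import (
    AbsorbanceSpectrum,
    SpectralSeries,
    SpectrumMeta,
    TransmissionSpectrum,
    WavelengthGrid,
)

__all__ = [
    "SpeciesBand",
    "KineticModel",
    "InstrumentModel",
    "SimulationResult",
    "PhotoswitchResult",
    "kinetic_profiles",
    "species_spectrum",
    "simulate_series",
    "simulate_photoswitch",
    "xenon_baseline",
    "default_grid",
    "pyp_solution_model",
    "pyp_crystal_model",
    "counts_for_snr",
    "peak_rate_for_snr",
]

#: pG decadic extinction at the band maximum, cm^2 mmol^-1
PG_PEAK_EXTINCTION = 45_500.0


@dataclass(frozen=True)
class SpeciesBand:
    """Absorption spectrum of one species as a sum of Gaussian bands.

    The summed profile is normalised so its maximum equals
    ``peak_extinction`` (decadic, cm^2 mmol^-1); ``rel_amplitudes`` set the
    band heights relative to each other before normalisation.
    """

    name: str
    centers: tuple[float, ...]
    widths: tuple[float, ...]
    peak_extinction: float
    rel_amplitudes: Optional[tuple[float, ...]] = None

    def __post_init__(self) -> None:
        c = tuple(float(x) for x in np.atleast_1d(self.centers))
        w = tuple(float(x) for x in np.atleast_1d(self.widths))
        object.__setattr__(self, "centers", c)
        object.__setattr__(self, "widths", w)
        if len(c) != len(w):
            raise ValueError("centers and widths must have equal length")
        if any(x <= 0 for x in w):
            raise ValueError("band widths must be positive")
        if self.peak_extinction < 0:
            raise ValueError("peak_extinction must be >= 0")
        a = self.rel_amplitudes
        a = tuple(1.0 for _ in c) if a is None else tuple(float(x) for x in a)
        if len(a) != len(c) or any(x < 0 for x in a):
            raise ValueError("rel_amplitudes must be non-negative, one per band")
        object.__setattr__(self, "rel_amplitudes", a)

    def _profile(self, wavelengths: np.ndarray) -> np.ndarray:
        lam = np.asarray(wavelengths, dtype=float)
        out = np.zeros_like(lam)
        for c, w, a in zip(self.centers, self.widths, self.rel_amplitudes):
            out += a * np.exp(-0.5 * ((lam - c) / w) ** 2)
        return out

    def extinction(self, wavelengths: np.ndarray) -> np.ndarray:
        """Decadic extinction (cm^2 mmol^-1) at the requested wavelengths."""
        # normalise on a dense grid that contains the band centers, so a
        # single band is scaled exactly by its center value
        lo = min(self.centers) - 6 * max(self.widths)
        hi = max(self.centers) + 6 * max(self.widths)
        dense = np.union1d(np.linspace(lo, hi, 2001), np.array(self.centers))
        peak = self._profile(dense).max()
        if peak == 0.0:
            return np.zeros_like(np.asarray(wavelengths, dtype=float))
        return self.peak_extinction / peak * self._profile(wavelengths)


@dataclass(frozen=True)
class KineticModel:
    """First-order photocycle: species, rate matrix, excitation, bleaching.

    ``rate_matrix`` K (s^-1) defines ``dC/dt = K C``; columns must sum to
    zero (mass conservation) with non-negative off-diagonal entries.
    Species 0 is the ground (dark) state; the laser pulse promotes
    ``excited_fraction`` of it into species ``excited_index`` at t = 0.
    ``bleach_per_shot`` is the fraction of total protein permanently lost
    per laser shot.
    """

    species: tuple[SpeciesBand, ...]
    rate_matrix: np.ndarray
    excited_fraction: float = 0.1
    bleach_per_shot: float = 0.0
    excited_index: int = 1

    def __post_init__(self) -> None:
        K = np.asarray(self.rate_matrix, dtype=float)
        object.__setattr__(self, "rate_matrix", K)
        object.__setattr__(self, "species", tuple(self.species))
        n = len(self.species)
        if K.shape != (n, n):
            raise ValueError(f"rate matrix must be {n}x{n} for {n} species")
        off = K - np.diag(np.diag(K))
        if np.any(off < 0):
            raise ValueError("off-diagonal rate coefficients must be >= 0")
        colsum = np.abs(K.sum(axis=0))
        scale = max(np.abs(K).max(), 1.0)
        if np.any(colsum > 1e-9 * scale):
            raise ValueError("columns of the rate matrix must sum to 0")
        if not 0.0 <= self.excited_fraction <= 1.0:
            raise ValueError("excited_fraction must lie in [0, 1]")
        if not 0.0 <= self.bleach_per_shot < 1.0:
            raise ValueError("bleach_per_shot must lie in [0, 1)")
        if not 0 <= self.excited_index < n:
            raise ValueError("excited_index out of range")

    @property
    def n_species(self) -> int:
        return len(self.species)

    def initial_populations(self) -> np.ndarray:
        """Fractions right after the pump pulse (species 0 is ground)."""
        c0 = np.zeros(self.n_species)
        c0[0] = 1.0 - self.excited_fraction
        c0[self.excited_index] = self.excited_fraction
        return c0

    def dark_populations(self) -> np.ndarray:
        c = np.zeros(self.n_species)
        c[0] = 1.0
        return c

    def relaxation_times(self) -> np.ndarray:
        """Relaxation times tau_i = -1/lambda_i of the decaying eigenmodes, ascending."""
        ev = np.linalg.eigvals(self.rate_matrix)
        decaying = np.real(ev[np.real(ev) < -1e-12 * max(np.abs(ev).max(), 1.0)])
        return np.sort(-1.0 / decaying)


@dataclass(frozen=True)
class KineticProfiles:
    """Concentration fractions per species and time, plus solver diagnostics."""

    concentrations: np.ndarray  # n_species x n_times
    eigenvalues: np.ndarray
    used_expm_fallback: bool


def kinetic_profiles(model: KineticModel, times: np.ndarray) -> KineticProfiles:
    """Solve ``C(t) = expm(K t) C(0)`` analytically via eigendecomposition.

    Falls back to scaled-and-squared ``expm`` per time point (flagged in the
    result) when K is numerically defective — nearly repeated eigenvalues
    make the eigenvector matrix ill-conditioned.
    """
    t = np.asarray(times, dtype=float)
    if np.any(t < 0):
        raise ValueError("times must be >= 0")
    K = model.rate_matrix
    c0 = model.initial_populations()
    ev, V = np.linalg.eig(K)
    scale = max(np.abs(ev).max(), 1.0)
    gaps = np.abs(ev[:, None] - ev[None, :])[~np.eye(len(ev), dtype=bool)]
    defective = (gaps.size > 0 and gaps.min() < 1e-9 * scale) or (
        np.linalg.cond(V) > 1e12
    )
    if defective:
        C = np.column_stack([expm(K * tk) @ c0 for tk in t])
        C = np.real(C)
    else:
        alpha = np.linalg.solve(V, c0)
        C = np.real(V @ (alpha[:, None] * np.exp(ev[:, None] * t[None, :])))
    C = np.clip(C, 0.0, 1.0)
    return KineticProfiles(C, ev, bool(defective))


def species_spectrum(
    band: SpeciesBand,
    grid: WavelengthGrid,
    concentration: float,
    path_cm: float = 1.0,
) -> AbsorbanceSpectrum:
    """Beer-Lambert absorbance of one species: ``eps(lambda) * c * l``.

    ``concentration`` in mmol cm^-3 equivalents so that the product with the
    decadic extinction (cm^2 mmol^-1) and the path (cm) is dimensionless.
    """
    values = band.extinction(grid.values) * concentration * path_cm
    return AbsorbanceSpectrum(grid, values, SpectrumMeta(kind="dark_corrected"))


# ---------------------------------------------------------------------------
# instrument


def xenon_baseline() -> Callable[[np.ndarray], np.ndarray]:
    """Smooth template of a cw-Xenon lamp over 385-740 nm (relative units).

    Cubic-spline through a handful of knots: a broad visible continuum
    peaking near 470 nm and falling gently toward the red.  Qualitative
    shape only; users calibrate the absolute level via ``peak_rate``.
    """
    knots_nm = np.array([385, 400, 420, 450, 467, 490, 520, 560, 600, 650, 700, 740.0])
    knots_rel = np.array(
        [0.35, 0.55, 0.75, 0.95, 1.0, 0.92, 0.80, 0.72, 0.68, 0.62, 0.58, 0.55]
    )
    spline = CubicSpline(knots_nm, knots_rel)

    def baseline(lam: np.ndarray) -> np.ndarray:
        return np.clip(spline(np.asarray(lam, dtype=float)), 1e-3, None)

    return baseline


@dataclass(frozen=True)
class InstrumentModel:
    """Detector and lamp parameters of the simulated spectrometer.

    baseline
        relative lamp intensity versus wavelength (callable), scaled by
        ``peak_rate`` counts per second of gate at the template maximum.
    dark_rate
        dark-current counts per second of CCD exposure per pixel.
    readout_sigma
        Gaussian readout noise, counts (std dev per read).
    full_well
        saturation level in counts; expected or realised counts above it
        are clipped and flagged.
    """

    baseline: Callable[[np.ndarray], np.ndarray] = field(default_factory=xenon_baseline)
    peak_rate: float = 1e11
    dark_rate: float = 50.0
    readout_sigma: float = 3.0
    full_well: float = np.inf

    def __post_init__(self) -> None:
        if self.peak_rate < 0 or self.dark_rate < 0 or self.readout_sigma < 0:
            raise ValueError("instrument parameters must be non-negative")

    def lamp_rate(self, wavelengths: np.ndarray) -> np.ndarray:
        """Expected lamp counts per second of gate at each wavelength."""
        return self.peak_rate * self.baseline(wavelengths)


def default_grid(lo: float = 385.0, hi: float = 740.0, step: float = 1.0) -> WavelengthGrid:
    """The probing range of the instrument at 1 nm sampling."""
    return WavelengthGrid(np.arange(lo, hi + 0.5 * step, step))


def counts_for_snr(snr: float, delta_a_max: float) -> float:
    """Transmitted counts per frame needed for a target difference-absorbance SNR.

    The difference absorbance at one delay subtracts two absorbances sharing
    the reference, so shot noise enters twice:
    ``sigma_dA ~ sqrt(2/N) / ln 10`` at N transmitted counts.
    """
    sigma = delta_a_max / snr
    return 2.0 / (np.log(10.0) ** 2 * sigma**2)


def peak_rate_for_snr(
    snr: float,
    model: "KineticModel",
    grid: WavelengthGrid,
    times: np.ndarray,
    gate_width: float,
    dark_state_od: float = 1.0,
    instrument_baseline: Optional[Callable] = None,
) -> float:
    """Lamp scale that yields the requested SNR on the peak difference signal.

    Runs the noise-free forward model, finds the wavelength/time of maximum
    |dA|, and solves for the lamp rate that delivers ``counts_for_snr``
    transmitted counts there within one gate.
    """
    baseline = instrument_baseline or xenon_baseline()
    A, dA, _ = truth_absorbance(model, grid, times, dark_state_od)
    i, k = np.unravel_index(np.argmax(np.abs(dA)), dA.shape)
    n_needed = counts_for_snr(snr, np.abs(dA[i, k]))
    transmitted_rel = baseline(grid.values[i]) * 10.0 ** (-A[i, k])
    return n_needed / (transmitted_rel * gate_width)


# ---------------------------------------------------------------------------
# forward model


def truth_absorbance(
    model: KineticModel,
    grid: WavelengthGrid,
    times: np.ndarray,
    dark_state_od: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Noise-free absorbance matrix A(lambda, t), difference dA, and dark A_D.

    The concentration x path product is chosen so the dark-state spectrum
    peaks at ``dark_state_od`` absorbance units.
    """
    E = np.column_stack([b.extinction(grid.values) for b in model.species])
    a_dark_unit = E @ model.dark_populations()
    scale = dark_state_od / a_dark_unit.max()
    prof = kinetic_profiles(model, times)
    A = scale * (E @ prof.concentrations)
    A_D = scale * a_dark_unit
    return A, A - A_D[:, None], A_D


@dataclass(frozen=True)
class SimulationResult:
    """Raw counts, calibration frames and the exact ground truth of one run."""

    raw: SpectralSeries  # mean counts per accumulation at each delay
    darks: tuple[TransmissionSpectrum, ...]  # per-delay detector darks
    reference: TransmissionSpectrum  # buffer-only transmission
    reference_dark: TransmissionSpectrum
    dark_state_before: TransmissionSpectrum  # S_D before the series
    dark_state_after: TransmissionSpectrum  # S_D after all laser shots
    dark_state_dark: TransmissionSpectrum
    truth: dict
    saturated_columns: tuple[int, ...]


def _noisy_counts(
    rng: np.random.Generator,
    expected: np.ndarray,
    readout_sigma: float,
    noise: bool,
) -> np.ndarray:
    if not noise:
        return expected.copy()
    out = rng.poisson(expected).astype(float)
    if readout_sigma > 0:
        out += rng.normal(0.0, readout_sigma, size=expected.shape)
    return np.clip(out, 0.0, None)


def simulate_series(
    model: KineticModel,
    instrument: InstrumentModel,
    times: np.ndarray,
    *,
    grid: Optional[WavelengthGrid] = None,
    gate_widths=None,
    exposures=None,
    n_accumulations: int = 1,
    dark_state_od: float = 1.0,
    seed: int = 0,
    noise: bool = True,
) -> SimulationResult:
    """Simulate one pump-probe measurement campaign.

    For each time delay the expected sample counts are
    ``lamp_rate * gate * 10**(-A(lambda, t)) + dark_rate * exposure``,
    realised as Poisson counts plus Gaussian readout noise and clipped at
    the full well.  Dark frames contain dark current and readout noise only.
    Each accumulation is one laser shot; with ``bleach_per_shot > 0`` the
    total protein decays geometrically over shots, and the dark-state
    spectrum is re-recorded after the series so bleaching can be checked.

    With ``noise=False`` every frame equals its expectation, so the
    absorbance pipeline inverts the forward model exactly.
    """
    grid = grid or default_grid()
    t = np.asarray(times, dtype=float)
    n_t = t.size
    gate_widths = np.broadcast_to(np.asarray(gate_widths if gate_widths is not None else 1e-6, dtype=float), (n_t,))
    exposures = np.broadcast_to(np.asarray(exposures if exposures is not None else 1e-3, dtype=float), (n_t,))
    rng = np.random.default_rng(seed)

    E = np.column_stack([b.extinction(grid.values) for b in model.species])
    a_dark_unit = E @ model.dark_populations()
    scale = dark_state_od / a_dark_unit.max()
    A_D = scale * a_dark_unit
    prof = kinetic_profiles(model, t)

    lamp = instrument.lamp_rate(grid.values)
    survive = 1.0 - model.bleach_per_shot

    raw_cols = np.empty((len(grid), n_t))
    A_truth = np.empty((len(grid), n_t))
    darks: list[TransmissionSpectrum] = []
    saturated: list[int] = []
    shots_fired = 0

    # S_D before the series (no laser, no bleach yet)
    gate_ref, expo_ref = float(gate_widths[0]), float(exposures[0])
    meta_dark0 = SpectrumMeta(None, gate_ref, expo_ref, n_accumulations, "raw")
    exp_sd = lamp * gate_ref * 10.0 ** (-A_D) + instrument.dark_rate * expo_ref

    def accumulate(expected_per_frame: np.ndarray, n_acc: int) -> np.ndarray:
        total = np.zeros_like(expected_per_frame)
        for _ in range(n_acc):
            total += _noisy_counts(rng, expected_per_frame, instrument.readout_sigma, noise)
        return total / n_acc

    sd_before = accumulate(exp_sd, n_accumulations)
    sd_dark = accumulate(
        np.full(len(grid), instrument.dark_rate * expo_ref), n_accumulations
    )

    for k in range(n_t):
        gate, expo = float(gate_widths[k]), float(exposures[k])
        acc = np.zeros(len(grid))
        a_mean = np.zeros(len(grid))
        for _ in range(n_accumulations):
            bleach = survive**shots_fired
            A = scale * bleach * (E @ prof.concentrations[:, k])
            expected = lamp * gate * 10.0 ** (-A) + instrument.dark_rate * expo
            if np.any(expected > instrument.full_well) and k not in saturated:
                saturated.append(k)
            expected = np.minimum(expected, instrument.full_well)
            acc += np.minimum(
                _noisy_counts(rng, expected, instrument.readout_sigma, noise),
                instrument.full_well,
            )
            a_mean += A
            shots_fired += 1
        raw_cols[:, k] = acc / n_accumulations
        A_truth[:, k] = a_mean / n_accumulations
        dark_expected = np.full(len(grid), instrument.dark_rate * expo)
        darks.append(
            TransmissionSpectrum(
                grid,
                accumulate(dark_expected, n_accumulations),
                SpectrumMeta(float(t[k]), gate, expo, n_accumulations, "dark"),
            )
        )

    # reference (buffer only) and its dark
    exp_ref = lamp * gate_ref + instrument.dark_rate * expo_ref
    reference = TransmissionSpectrum(
        grid,
        accumulate(exp_ref, n_accumulations),
        SpectrumMeta(None, gate_ref, expo_ref, n_accumulations, "reference"),
    )
    reference_dark = TransmissionSpectrum(
        grid,
        accumulate(np.full(len(grid), instrument.dark_rate * expo_ref), n_accumulations),
        SpectrumMeta(None, gate_ref, expo_ref, n_accumulations, "dark"),
    )

    # S_D after the series: protein bleached by all shots fired, no new shots
    bleach_final = survive**shots_fired
    exp_sd_after = lamp * gate_ref * 10.0 ** (-A_D * bleach_final) + instrument.dark_rate * expo_ref
    sd_after = accumulate(exp_sd_after, n_accumulations)

    if saturated:
        warnings.warn(
            f"expected counts exceed full well at time columns {saturated}",
            RuntimeWarning,
        )

    raw = SpectralSeries(
        grid,
        t,
        raw_cols,
        quantity="transmission",
        meta={
            "gate_widths_s": gate_widths.tolist(),
            "exposures_s": exposures.tolist(),
            "accumulations": int(n_accumulations),
        },
    )
    truth = {
        "absorbance": A_truth,
        "dark_absorbance": A_D,
        "difference": A_truth - A_D[:, None],
        "relaxation_times_s": model.relaxation_times(),
        "bleach_factor_final": bleach_final,
        "excited_fraction": model.excited_fraction,
        "dark_state_od": dark_state_od,
        "seed": int(seed),
        "expm_fallback": prof.used_expm_fallback,
    }
    return SimulationResult(
        raw=raw,
        darks=tuple(darks),
        reference=reference,
        reference_dark=reference_dark,
        dark_state_before=TransmissionSpectrum(grid, sd_before, meta_dark0),
        dark_state_after=TransmissionSpectrum(grid, sd_after, meta_dark0),
        dark_state_dark=TransmissionSpectrum(
            grid, sd_dark, SpectrumMeta(None, gate_ref, expo_ref, n_accumulations, "dark")
        ),
        truth=truth,
        saturated_columns=tuple(saturated),
    )


# ---------------------------------------------------------------------------
# photoswitch mode (two stable isomeric states)


@dataclass(frozen=True)
class PhotoswitchResult:
    grid: WavelengthGrid
    e_state: AbsorbanceSpectrum
    z_state: AbsorbanceSpectrum
    transient: AbsorbanceSpectrum  # mixture after partial conversion
    difference_from_e: AbsorbanceSpectrum
    difference_from_z: AbsorbanceSpectrum


def simulate_photoswitch(
    e_band: SpeciesBand,
    z_band: SpeciesBand,
    converted_fraction: float,
    grid: WavelengthGrid,
    od: float = 1.0,
    instrument: Optional[InstrumentModel] = None,
    gate_width: float = 50e-9,
    seed: int = 0,
) -> PhotoswitchResult:
    """Two-state photoswitch: pure-state spectra, transient mixture, differences.

    The transient after a pulse converting fraction ``f`` of the E form is
    ``(1-f) A_E + f A_Z`` (and symmetrically starting from Z).  With an
    ``instrument`` supplied, each spectrum is pushed through the photon-count
    forward model and recovered via ``-log10(S/S_ref)``, adding shot noise.
    """
    if not 0.0 <= converted_fraction <= 1.0:
        raise ValueError("converted_fraction must lie in [0, 1]")
    eps_e = e_band.extinction(grid.values)
    eps_z = z_band.extinction(grid.values)
    scale = od / max(eps_e.max(), eps_z.max())
    a_e, a_z = scale * eps_e, scale * eps_z
    f = converted_fraction
    a_mix = (1.0 - f) * a_e + f * a_z
    a_mix_rev = (1.0 - f) * a_z + f * a_e

    if instrument is not None:
        rng = np.random.default_rng(seed)
        lamp = instrument.lamp_rate(grid.values) * gate_width

        def measure(a: np.ndarray) -> np.ndarray:
            s = rng.poisson(lamp * 10.0 ** (-a)).astype(float)
            s_ref = rng.poisson(lamp).astype(float)
            return -np.log10(np.clip(s, 1.0, None) / np.clip(s_ref, 1.0, None))

        a_e, a_z = measure(a_e), measure(a_z)
        a_mix, a_mix_rev = measure(a_mix), measure(a_mix_rev)

    meta = SpectrumMeta(kind="dark_corrected", gate_width=gate_width)
    return PhotoswitchResult(
        grid=grid,
        e_state=AbsorbanceSpectrum(grid, a_e, meta),
        z_state=AbsorbanceSpectrum(grid, a_z, meta),
        transient=AbsorbanceSpectrum(grid, a_mix, meta),
        difference_from_e=AbsorbanceSpectrum(grid, a_mix - a_e, meta),
        difference_from_z=AbsorbanceSpectrum(grid, a_mix_rev - a_z, meta),
    )


# ---------------------------------------------------------------------------
# ready-made scenarios


def _band(name, centers, widths, eps, amps=None) -> SpeciesBand:
    return SpeciesBand(name, tuple(np.atleast_1d(centers)), tuple(np.atleast_1d(widths)), eps, amps)


def pyp_solution_model(
    tau1: float = 290e-6,
    tau2: float = 0.45,
    excited_fraction: float = 0.1,
    bleach_per_shot: float = 0.0,
) -> KineticModel:
    """Sequential pG -> pR -> pB -> pG photocycle (solution defaults).

    ``tau1`` is the pR->pB relaxation, ``tau2`` the pB->pG ground-state
    recovery.  Band centers: pG 446 nm, pR 485 nm, pB 355 nm; the pB band
    lies almost entirely below the 410-530 nm analysis window, so pB is seen
    through the kinetics rather than its own absorption — as for the real
    protein.  Widths (sigma 15 nm) and the pR/pB extinctions are simulator
    defaults, not measured values; the pG peak extinction anchors the scale.
    """
    k1, k2 = 1.0 / tau1, 1.0 / tau2
    # species order: pG, pR, pB
    K = np.array(
        [
            [0.0, 0.0, k2],
            [0.0, -k1, 0.0],
            [0.0, k1, -k2],
        ]
    )
    species = (
        _band("pG", 446.0, 15.0, PG_PEAK_EXTINCTION),
        _band("pR", 485.0, 15.0, 38_000.0),
        _band("pB", 355.0, 15.0, 25_000.0),
    )
    return KineticModel(species, K, excited_fraction, bleach_per_shot)


def pyp_crystal_model(
    tau1: float = 2.6e-3,
    tau2: float = 61e-3,
    tau3: float = 0.70,
    branch: tuple[float, float] = (0.7, 0.3),
    excited_fraction: float = 0.1,
    bleach_per_shot: float = 0.0,
) -> KineticModel:
    """Crystal photocycle with biphasic ground-state recovery.

    pR decays into two non-interconverting pB sub-states in the ratio
    ``branch``; each recovers to pG with its own rate, producing the two
    slow phases observed in crystals.  The slower sub-state carries a
    red-shifted, broader band (375 nm, sigma 30 nm) whose blue tail reaches
    the 410-530 nm analysis window — this makes the third kinetic component
    spectrally visible there, as it is in real crystal data.
    """
    if not np.isclose(sum(branch), 1.0):
        raise ValueError("branch fractions must sum to 1")
    k1, k2, k3 = 1.0 / tau1, 1.0 / tau2, 1.0 / tau3
    b1, b2 = branch
    # species order: pG, pR, pB1 (fast recovery), pB2 (slow recovery)
    K = np.array(
        [
            [0.0, 0.0, k2, k3],
            [0.0, -k1, 0.0, 0.0],
            [0.0, b1 * k1, -k2, 0.0],
            [0.0, b2 * k1, 0.0, -k3],
        ]
    )
    species = (
        _band("pG", 449.0, 15.0, PG_PEAK_EXTINCTION),
        _band("pR", 485.0, 15.0, 38_000.0),
        _band("pB1", 355.0, 20.0, 25_000.0),
        _band("pB2", 375.0, 30.0, 30_000.0),
    )
    return KineticModel(species, K, excited_fraction, bleach_per_shot)


def alpha_pec_bands() -> tuple[SpeciesBand, SpeciesBand]:
    """Default E/Z photoswitch bands (centers/widths are simulator defaults).

    The Z form absorbs to the red of the E form with a blue shoulder,
    mimicking a partially decoupled chromophore ring.
    """
    e = _band("E", (505.0,), (22.0,), 40_000.0)
    z = _band("Z", (565.0, 505.0), (20.0, 25.0), 42_000.0, (1.0, 0.35))
    return e, z
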