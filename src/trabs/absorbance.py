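"""Reduction of raw transmission counts to difference absorption spectra.

The chain is the standard flash-photolysis one: subtract detector darks,
form decadic absorbance against the buffer-only reference,
``A(lambda) = -log10(S_sample / S_ref)``, and subtract the dark-state
protein absorbance to obtain difference spectra ``dA(lambda, t)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np

from .core import (
    AbsorbanceSpectrum,
    SpectralSeries,
    SpectrumMeta,
    TransmissionSpectrum,
)

__all__ = [
    "CLIP_EPS",
    "dark_correct",
    "compute_absorbance",
    "absorbance_series",
    "difference_series",
    "average_accumulations",
    "check_bleaching",
    "BleachReport",
]

#: clipping floor: sample counts below CLIP_EPS * reference are capped
CLIP_EPS = 1e-6


def dark_correct(
    raw: TransmissionSpectrum, dark: TransmissionSpectrum
) -> TransmissionSpectrum:
    """Subtract the detector-dark frame from a raw frame."""
    raw.grid.require_match(dark.grid)
    if dark.meta.kind != "dark":
        raise ValueError(f"dark frame has kind {dark.meta.kind!r}, expected 'dark'")
    if not np.isclose(raw.meta.exposure, dark.meta.exposure, rtol=1e-6):
        warnings.warn(
            "exposure mismatch between raw and dark frame; dark current will "
            "not cancel (per-timepoint darks are required when the CCD "
            "exposure varies with gate delay)",
            RuntimeWarning,
        )
    return TransmissionSpectrum(
        raw.grid,
        raw.counts - dark.counts,
        replace(raw.meta, kind="dark_corrected"),
    )


def compute_absorbance(
    sample: TransmissionSpectrum,
    reference: TransmissionSpectrum,
    eps: float = CLIP_EPS,
) -> AbsorbanceSpectrum:
    """Decadic absorbance ``A = -log10(S_sample / S_ref)``.

    Both inputs must be dark-corrected.  Where the sample signal falls below
    ``eps`` times the reference the value is capped at ``-log10(eps)`` and
    flagged in the result's ``clipped`` mask, so dead pixels never produce
    infinities silently.
    """
    sample.grid.require_match(reference.grid)
    for name, spec in (("sample", sample), ("reference", reference)):
        if spec.meta.kind != "dark_corrected":
            raise ValueError(f"{name} must be dark-corrected, got kind {spec.meta.kind!r}")
    bad = reference.counts <= 0
    if np.any(bad):
        wl = sample.grid.values[bad]
        raise ValueError(
            f"reference counts <= 0 after dark correction at wavelengths {wl.tolist()} nm"
        )
    if not np.isclose(sample.meta.gate_width, reference.meta.gate_width, rtol=1e-6):
        warnings.warn(
            "gate width differs between sample and reference; the absorbance "
            "acquires a constant offset log10(gate_sample/gate_ref)",
            RuntimeWarning,
        )
    ratio = sample.counts / reference.counts
    clipped = ratio <= eps
    values = -np.log10(np.clip(ratio, eps, None))
    return AbsorbanceSpectrum(sample.grid, values, sample.meta, clipped=clipped)


def absorbance_series(
    raw: SpectralSeries,
    darks: Sequence[TransmissionSpectrum],
    reference: TransmissionSpectrum,
    reference_dark: Optional[TransmissionSpectrum] = None,
    eps: float = CLIP_EPS,
) -> SpectralSeries:
    """Apply dark correction and the absorbance formula to every time column.

    ``darks`` is either one frame reused for all delays (single-reference
    policy) or one frame per delay (per-timepoint policy, required when the
    CCD exposure varies with gate delay).
    """
    if raw.quantity != "transmission":
        raise ValueError("absorbance_series expects a transmission series")
    n_t = raw.n_times
    if len(darks) not in (1, n_t):
        raise ValueError(f"need 1 or {n_t} dark frames, got {len(darks)}")
    ref_corr = (
        dark_correct(reference, reference_dark) if reference_dark is not None else reference
    )
    if ref_corr.meta.kind != "dark_corrected":
        raise ValueError("reference must be dark-corrected (or pass reference_dark)")
    gates = raw.meta.get("gate_widths_s", [reference.meta.gate_width] * n_t)
    expos = raw.meta.get("exposures_s", [reference.meta.exposure] * n_t)
    n_acc = raw.meta.get("accumulations", 1)
    cols = np.empty_like(raw.data)
    any_clip = np.zeros(len(raw.grid), dtype=bool)
    for k in range(n_t):
        frame = TransmissionSpectrum(
            raw.grid,
            raw.data[:, k],
            SpectrumMeta(float(raw.times[k]), float(gates[k]), float(expos[k]), n_acc, "raw"),
        )
        dark = darks[k if len(darks) == n_t else 0]
        a = compute_absorbance(dark_correct(frame, dark), ref_corr, eps=eps)
        cols[:, k] = a.values
        any_clip |= a.clipped
    meta = dict(raw.meta)
    if np.any(any_clip):
        meta["clipped_wavelengths_nm"] = raw.grid.values[any_clip].tolist()
    return SpectralSeries(raw.grid, raw.times, cols, quantity="absorbance", meta=meta)


def difference_series(
    series: SpectralSeries, dark_absorbance: AbsorbanceSpectrum
) -> SpectralSeries:
    """Subtract the dark-state absorbance from every column: dA = A(t) - A_D."""
    if series.quantity != "absorbance":
        raise ValueError("difference_series expects an absorbance series")
    series.grid.require_match(dark_absorbance.grid)
    return SpectralSeries(
        series.grid,
        series.times,
        series.data - dark_absorbance.values[:, None],
        quantity="difference_absorbance",
        meta=dict(series.meta),
    )


def average_accumulations(
    spectra: Sequence[TransmissionSpectrum],
) -> TransmissionSpectrum:
    """Elementwise mean of repeated shots; accumulations metadata = count."""
    if len(spectra) == 0:
        raise ValueError("need at least one spectrum")
    first = spectra[0]
    for s in spectra[1:]:
        first.grid.require_match(s.grid)
        if not np.isclose(s.meta.gate_width, first.meta.gate_width, rtol=1e-9):
            raise ValueError("cannot average spectra with different gate widths")
    mean = np.mean([s.counts for s in spectra], axis=0)
    return TransmissionSpectrum(
        first.grid, mean, replace(first.meta, accumulations=len(spectra))
    )


@dataclass(frozen=True)
class BleachReport:
    max_abs_delta: float
    noise_floor: float
    bleached: bool


def check_bleaching(
    dark_before: AbsorbanceSpectrum,
    dark_after: AbsorbanceSpectrum,
    noise_floor: float,
    window: Optional[tuple[float, float]] = None,
) -> BleachReport:
    """Compare dark-state absorbance before/after a series.

    Permanent bleaching shows up as a non-recovering drop of the dark-state
    band; ``bleached`` is True when max|dA| over the analysis window exceeds
    the stated noise floor.
    """
    dark_before.grid.require_match(dark_after.grid)
    delta = np.abs(dark_after.values - dark_before.values)
    if window is not None:
        lam = dark_before.grid.values
        sel = (lam >= window[0]) & (lam <= window[1])
        if not np.any(sel):
            raise ValueError("bleach window does not overlap the grid")
        delta = delta[sel]
    m = float(delta.max())
    return BleachReport(m, float(noise_floor), m > noise_floor)
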