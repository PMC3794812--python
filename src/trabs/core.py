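"""Shared domain containers, grids and file I/O for time-resolved absorption data.

Units are fixed package-wide: wavelengths in nanometres, times in seconds,
decadic (log10) absorbance.  Any unit conversion happens at the CLI boundary,
never inside the numerical code.

Two spectra may be combined arithmetically only when their wavelength grids
match exactly (elementwise within ``GRID_ATOL`` nm); anything else must go
through :func:`resample` explicitly, so no interpolation ever happens silently.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "GRID_ATOL",
    "FormatError",
    "GridMismatchError",
    "WavelengthGrid",
    "SpectrumMeta",
    "TransmissionSpectrum",
    "AbsorbanceSpectrum",
    "SpectralSeries",
    "make_logtime_grid",
    "read_series",
    "write_series",
    "read_spectrum",
    "write_spectrum",
    "resample",
]

#: absolute tolerance (nm) for two wavelength grids to count as identical
GRID_ATOL = 1e-9

SPECTRUM_KINDS = ("raw", "dark", "reference", "dark_corrected")
SERIES_QUANTITIES = ("transmission", "absorbance", "difference_absorbance")


class FormatError(ValueError):
    """A file does not conform to the wide-CSV/sidecar dialect."""


class GridMismatchError(ValueError):
    """Arithmetic was attempted between spectra on different wavelength grids."""


@dataclass(frozen=True)
class WavelengthGrid:
    """Strictly increasing wavelength axis in nm."""

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.ndim != 1 or v.size < 2:
            raise ValueError("wavelength grid needs at least 2 points")
        if np.any(v <= 0):
            raise ValueError("wavelengths must be positive")
        if np.any(np.diff(v) <= 0):
            bad = int(np.argmax(np.diff(v) <= 0)) + 1
            raise ValueError(f"wavelengths not strictly increasing at index {bad}")

    def __len__(self) -> int:
        return self.values.size

    def matches(self, other: "WavelengthGrid", atol: float = GRID_ATOL) -> bool:
        return len(self) == len(other) and bool(
            np.allclose(self.values, other.values, rtol=0.0, atol=atol)
        )

    def require_match(self, other: "WavelengthGrid") -> None:
        if not self.matches(other):
            raise GridMismatchError(
                "wavelength grids differ; resample explicitly before combining"
            )


@dataclass(frozen=True)
class SpectrumMeta:
    """Acquisition metadata attached to a single spectrum.

    time_delay
        pump-probe delay in seconds, or None for dark/reference frames.
    gate_width
        image-intensifier gate duration in seconds (sets the time resolution).
    exposure
        CCD exposure in seconds; dark current accumulates over this interval.
    accumulations
        number of laser shots averaged into the spectrum.
    kind
        one of raw | dark | reference | dark_corrected.
    """

    time_delay: Optional[float] = None
    gate_width: float = 1e-6
    exposure: float = 1e-3
    accumulations: int = 1
    kind: str = "raw"

    def __post_init__(self) -> None:
        if self.kind not in SPECTRUM_KINDS:
            raise ValueError(f"kind must be one of {SPECTRUM_KINDS}, got {self.kind!r}")
        if self.accumulations < 1:
            raise ValueError("accumulations must be >= 1")


@dataclass(frozen=True)
class TransmissionSpectrum:
    """Detector counts versus wavelength (raw, dark, reference or dark-corrected)."""

    grid: WavelengthGrid
    counts: np.ndarray
    meta: SpectrumMeta = field(default_factory=SpectrumMeta)

    def __post_init__(self) -> None:
        c = np.asarray(self.counts, dtype=float)
        object.__setattr__(self, "counts", c)
        if c.shape != (len(self.grid),):
            raise ValueError("counts length must equal grid length")
        if self.meta.kind != "dark_corrected" and np.any(c < 0):
            raise ValueError("raw counts must be non-negative")

    def with_counts(self, counts: np.ndarray, **meta_changes) -> "TransmissionSpectrum":
        meta = replace(self.meta, **meta_changes) if meta_changes else self.meta
        return TransmissionSpectrum(self.grid, counts, meta)


@dataclass(frozen=True)
class AbsorbanceSpectrum:
    """Decadic absorbance versus wavelength.

    ``clipped`` marks wavelengths where the transmitted signal fell below the
    clipping floor and the absorbance value was capped (see absorbance module).
    """

    grid: WavelengthGrid
    values: np.ndarray
    meta: SpectrumMeta = field(default_factory=SpectrumMeta)
    clipped: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.shape != (len(self.grid),):
            raise ValueError("values length must equal grid length")
        if not np.all(np.isfinite(v)):
            raise ValueError("absorbance must be finite (apply the clipping policy)")
        if self.clipped is not None:
            m = np.asarray(self.clipped, dtype=bool)
            object.__setattr__(self, "clipped", m)
            if m.shape != v.shape:
                raise ValueError("clipped mask shape must match values")


@dataclass(frozen=True)
class SpectralSeries:
    """Wavelength x time-delay matrix sharing one wavelength grid.

    ``data[i, k]`` is the value at ``grid.values[i]``, ``times[k]``.
    """

    grid: WavelengthGrid
    times: np.ndarray
    data: np.ndarray
    quantity: str = "transmission"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        d = np.asarray(self.data, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "data", d)
        if self.quantity not in SERIES_QUANTITIES:
            raise ValueError(
                f"quantity must be one of {SERIES_QUANTITIES}, got {self.quantity!r}"
            )
        if t.ndim != 1 or t.size == 0:
            raise ValueError("times must be a non-empty 1-D array")
        if np.any(t <= 0):
            raise ValueError("time delays must be positive")
        if t.size > 1 and np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if d.shape != (len(self.grid), t.size):
            raise ValueError(
                f"data shape {d.shape} does not match (n_wavelengths={len(self.grid)},"
                f" n_times={t.size})"
            )

    @property
    def n_times(self) -> int:
        return self.times.size


def make_logtime_grid(t_min: float, t_max: float, n: int) -> np.ndarray:
    """Return ``n`` time delays equidistant in log10(t), endpoints inclusive.

    Log-equidistant sampling weighs fast and slow kinetic phases equally,
    which is the standard design for photocycle time series spanning many
    decades (e.g. tens of microseconds to seconds).
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    if not (0 < t_min < t_max):
        raise ValueError("need 0 < t_min < t_max")
    times = np.geomspace(t_min, t_max, n)
    # pin endpoints exactly; geomspace can be off in the last ulp
    times[0], times[-1] = t_min, t_max
    return times


# ---------------------------------------------------------------------------
# wide-CSV + JSON sidecar I/O


def _format_time(t: float) -> str:
    # shortest representation that round-trips the double exactly
    return np.format_float_scientific(t, unique=True, trim="0")


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".meta.json")


def write_series(series: SpectralSeries, path) -> Path:
    """Write a series as wide CSV (first column ``wavelength_nm``) plus sidecar.

    Values are written in shortest round-trip notation, so write->read
    reproduces the matrix bit-for-bit.
    """
    path = Path(path)
    df = pd.DataFrame(
        series.data,
        index=pd.Index(series.grid.values, name="wavelength_nm"),
        columns=[_format_time(t) for t in series.times],
    )
    df.to_csv(path)
    sidecar = {
        "quantity": series.quantity,
        "times_s": [float(t) for t in series.times],
        **{k: v for k, v in series.meta.items()},
    }
    with open(_sidecar_path(path), "w") as fh:
        json.dump(sidecar, fh, indent=1, sort_keys=True)
    return path


def read_series(path) -> SpectralSeries:
    """Read a wide-CSV series and its ``.meta.json`` sidecar."""
    path = Path(path)
    side = _sidecar_path(path)
    if not side.exists():
        raise FormatError(f"missing sidecar file {side.name}")
    with open(side) as fh:
        meta = json.load(fh)
    if "quantity" not in meta:
        raise FormatError("sidecar missing required field 'quantity'")
    try:
        df = pd.read_csv(path, index_col=0, float_precision="round_trip")
    except pd.errors.ParserError as exc:  # ragged rows etc.
        raise FormatError(f"malformed CSV {path.name}: {exc}") from exc
    if df.index.name != "wavelength_nm":
        raise FormatError(
            f"first column must be 'wavelength_nm', got {df.index.name!r}"
        )
    wl = df.index.to_numpy(dtype=float)
    if np.any(np.diff(wl) <= 0):
        bad = int(np.argmax(np.diff(wl) <= 0)) + 2  # +1 header, +1 0-based
        raise FormatError(f"wavelengths not strictly increasing at CSV row {bad}")
    try:
        times = np.array([float(c) for c in df.columns])
    except ValueError as exc:
        raise FormatError(f"column names must be time delays in seconds: {exc}") from exc
    quantity = meta.pop("quantity")
    meta.pop("times_s", None)
    return SpectralSeries(
        grid=WavelengthGrid(wl),
        times=times,
        data=df.to_numpy(dtype=float),
        quantity=quantity,
        meta=meta,
    )


def write_spectrum(grid: WavelengthGrid, values: np.ndarray, path) -> Path:
    """Write a single spectrum as 2-column CSV (``wavelength_nm,value``)."""
    path = Path(path)
    pd.DataFrame(
        {"value": np.asarray(values, dtype=float)},
        index=pd.Index(grid.values, name="wavelength_nm"),
    ).to_csv(path)
    return path


def read_spectrum(path) -> tuple[WavelengthGrid, np.ndarray]:
    path = Path(path)
    df = pd.read_csv(path, index_col=0, float_precision="round_trip")
    if df.index.name != "wavelength_nm" or df.shape[1] != 1:
        raise FormatError("single spectra use a 2-column CSV 'wavelength_nm,value'")
    wl = df.index.to_numpy(dtype=float)
    if np.any(np.diff(wl) <= 0):
        bad = int(np.argmax(np.diff(wl) <= 0)) + 2
        raise FormatError(f"wavelengths not strictly increasing at CSV row {bad}")
    return WavelengthGrid(wl), df.iloc[:, 0].to_numpy(dtype=float)


def resample(spectrum, target: WavelengthGrid):
    """Linearly interpolate a spectrum onto ``target``; no extrapolation.

    Returns an object of the same type.  Values at wavelengths shared between
    source and target grids are reproduced exactly.
    """
    src = spectrum.grid.values
    tgt = target.values
    if tgt[0] < src[0] - GRID_ATOL or tgt[-1] > src[-1] + GRID_ATOL:
        raise ValueError(
            f"target range [{tgt[0]}, {tgt[-1]}] nm exceeds source range "
            f"[{src[0]}, {src[-1]}] nm; extrapolation is not supported"
        )
    if isinstance(spectrum, TransmissionSpectrum):
        return TransmissionSpectrum(
            target, np.interp(tgt, src, spectrum.counts), spectrum.meta
        )
    if isinstance(spectrum, AbsorbanceSpectrum):
        return AbsorbanceSpectrum(
            target, np.interp(tgt, src, spectrum.values), spectrum.meta
        )
    raise TypeError(f"cannot resample object of type {type(spectrum).__name__}")
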