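"""SVD-based global kinetic analysis of difference absorption spectra.

The wavelength x time difference matrix is factorised as
``dA = U S V^T``; the few right singular vectors (rSVs) carrying kinetic
signal are fitted globally by a sum of exponentials with an offset,

    y_j(t) = A_{0,j} + sum_i A_{i,j} exp(-t / tau_i),

with the relaxation times tau_i shared across vectors.  The fit uses
variable projection: at each trial of tau the amplitudes and offsets, which
enter linearly, are solved exactly by linear least squares, and only the
tau are optimised nonlinearly (bounded, multi-start, deterministic under a
seed).  The offset absorbs baseline drifts and slight permanent sample
bleaching.  Macroscopic rates are the reciprocals, Lambda_i = 1 / tau_i.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from math import floor, log10
from typing import Optional

import numpy as np
from scipy.optimize import least_squares

from .core import SpectralSeries

__all__ = [
    "SvdResult",
    "GlobalFitResult",
    "window",
    "svd_decompose",
    "lag1_autocorrelation",
    "select_significant",
    "global_fit",
    "single_wavelength_fit",
    "fit_exponentials",
    "tau_rate_convert",
    "format_sig",
    "round_sig",
    "reconstruct_fit",
    "bic_scan",
]


def window(series: SpectralSeries, lam_lo: float, lam_hi: float) -> SpectralSeries:
    """Restrict a series to ``lam_lo <= lambda <= lam_hi`` (inclusive).

    Wavelengths outside the analysed band contribute only noise to the SVD,
    so they are cut before decomposition.
    """
    lam = series.grid.values
    sel = (lam >= lam_lo) & (lam <= lam_hi)
    if not np.any(sel):
        raise ValueError(
            f"window [{lam_lo}, {lam_hi}] nm does not overlap grid "
            f"[{lam[0]}, {lam[-1]}] nm"
        )
    from .core import WavelengthGrid

    return SpectralSeries(
        WavelengthGrid(lam[sel]),
        series.times,
        series.data[sel, :],
        quantity=series.quantity,
        meta=dict(series.meta),
    )


@dataclass(frozen=True)
class SvdResult:
    """Singular value decomposition of a difference-spectrum matrix.

    ``lsv`` columns are spectral (wavelength-space) components, ``rsv``
    columns temporal (time-space) components; ``data = lsv @ diag(s) @ rsv.T``.
    Sign convention: the largest-magnitude element of each left vector is
    positive.
    """

    singular_values: np.ndarray
    lsv: np.ndarray
    rsv: np.ndarray
    wavelengths: np.ndarray
    times: np.ndarray
    window: Optional[tuple[float, float]] = None


def svd_decompose(series: SpectralSeries) -> SvdResult:
    U, s, Vt = np.linalg.svd(series.data, full_matrices=False)
    V = Vt.T
    # fix signs: largest-|.| element of each left vector positive
    for j in range(U.shape[1]):
        i = int(np.argmax(np.abs(U[:, j])))
        if U[i, j] < 0:
            U[:, j] = -U[:, j]
            V[:, j] = -V[:, j]
    lam = series.grid.values
    return SvdResult(
        singular_values=s,
        lsv=U,
        rsv=V,
        wavelengths=lam,
        times=series.times,
        window=(float(lam[0]), float(lam[-1])),
    )


def lag1_autocorrelation(v: np.ndarray) -> float:
    """Normalised lag-1 autocorrelation ``sum v_i v_{i+1} / sum v_i^2``.

    Smooth signal-bearing singular vectors score near 1; white-noise
    vectors score near 0.  Standard rank-selection diagnostic for SVD of
    kinetic data.
    """
    v = np.asarray(v, dtype=float)
    denom = float(v @ v)
    if denom == 0.0:
        return 0.0
    return float(v[:-1] @ v[1:]) / denom


#: minimum number of delays for the temporal autocorrelation test to have
#: discriminating power; a unit n-vector cannot exceed cos(pi/(n+1)), so on
#: short series even a perfectly smooth sign-changing vector falls below
#: any useful threshold
MIN_TIMES_FOR_TEMPORAL_AC = 16


def select_significant(
    svd: SvdResult, s_threshold: float = 0.01, ac_threshold: float = 0.8
) -> tuple[int, np.ndarray]:
    """Count components carrying kinetic signal.

    A component is significant iff its singular value is at least
    ``s_threshold`` of the largest AND its vectors are smooth (lag-1
    autocorrelation >= ``ac_threshold``).  The spectral (left) vectors are
    always tested; the temporal (right) vectors only when the series has at
    least ``MIN_TIMES_FOR_TEMPORAL_AC`` delays, below which the test cannot
    separate smooth vectors from noise.  The rule is scale-invariant in the
    data.
    """
    s = svd.singular_values
    if s.size == 0 or s[0] == 0.0:
        return 0, np.zeros(s.size, dtype=bool)
    test_temporal = svd.times.size >= MIN_TIMES_FOR_TEMPORAL_AC
    mask = np.zeros(s.size, dtype=bool)
    for i in range(s.size):
        mask[i] = (
            s[i] >= s_threshold * s[0]
            and lag1_autocorrelation(svd.lsv[:, i]) >= ac_threshold
            and (
                not test_temporal
                or lag1_autocorrelation(svd.rsv[:, i]) >= ac_threshold
            )
        )
    return int(mask.sum()), mask


@dataclass(frozen=True)
class GlobalFitResult:
    """Result of the global multi-exponential fit.

    tau are sorted ascending; ``rates[i] * tau[i] == 1`` exactly.
    ``amplitudes[i, j]`` belongs to exponential i in fitted vector j,
    ``offsets[j]`` is A_{0,j}.  ``tau_stderr`` comes from the linearised
    covariance at the optimum (NaN when the Jacobian is degenerate).
    """

    n_exp: int
    tau: np.ndarray
    rates: np.ndarray
    amplitudes: np.ndarray
    offsets: np.ndarray
    weighted: bool
    residual_norm: float
    tau_stderr: np.ndarray
    n_significant: int
    n_starts_converged: int

    def summary(self) -> dict:
        """Report payload with raw values plus 2-significant-figure display."""
        return {
            "n_exp": self.n_exp,
            "n_significant": self.n_significant,
            "tau_s": [float(t) for t in self.tau],
            "rates_per_s": [float(r) for r in self.rates],
            "tau_display": [format_sig(t, 2) for t in self.tau],
            "rates_display": [format_sig(r, 2) for r in self.rates],
            "amplitudes": self.amplitudes.tolist(),
            "offsets": self.offsets.tolist(),
            "weighted": self.weighted,
            "residual_norm": float(self.residual_norm),
            "tau_stderr_s": [float(t) for t in self.tau_stderr],
        }


def _design_matrix(tau: np.ndarray, t: np.ndarray) -> np.ndarray:
    return np.column_stack([np.ones_like(t)] + [np.exp(-t / ti) for ti in tau])


def _project(logtau: np.ndarray, t: np.ndarray, Y: np.ndarray):
    """Solve the linear subproblem at fixed tau; return coefficients and residual."""
    M = _design_matrix(10.0**logtau, t)
    coef, *_ = np.linalg.lstsq(M, Y, rcond=None)
    return coef, Y - M @ coef


def fit_exponentials(
    times: np.ndarray,
    Y: np.ndarray,
    n_exp: int,
    n_starts: int = 32,
    seed: int = 0,
    tau_bounds: Optional[tuple[float, float]] = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float, np.ndarray, int]:
    """Variable-projection fit of ``Y`` (n_times x m) by shared exponentials.

    Returns ``(tau, amplitudes, offsets, residual_norm, tau_stderr,
    n_converged)``.  Multi-modal in tau, hence multi-start: one start evenly
    log-spaced over the time range plus seeded log-uniform draws; the best
    converged start wins, ties broken by smaller tau_1.
    """
    t = np.asarray(times, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")
    if n_exp < 1:
        raise ValueError("n_exp must be >= 1")
    if 2 * n_exp + 1 > t.size:
        raise ValueError(
            f"{n_exp} exponentials need at least {2 * n_exp + 1} time points, "
            f"got {t.size}"
        )
    lo, hi = tau_bounds if tau_bounds is not None else (t.min() / 10.0, t.max() * 10.0)
    llo, lhi = np.log10(lo), np.log10(hi)
    rng = np.random.default_rng(seed)

    starts = [np.linspace(llo + 0.15 * (lhi - llo), lhi - 0.15 * (lhi - llo), n_exp)]
    while len(starts) < n_starts:
        starts.append(np.sort(rng.uniform(llo, lhi, size=n_exp)))

    def residual(logtau: np.ndarray) -> np.ndarray:
        return _project(logtau, t, Y)[1].ravel()

    candidates = []
    for x0 in starts:
        try:
            res = least_squares(
                residual, x0, bounds=(llo, lhi), method="trf", xtol=1e-14, ftol=1e-14
            )
        except Exception:
            continue
        if res.success:
            candidates.append((float(np.linalg.norm(res.fun)), np.sort(10.0**res.x)[0], res))
    if not candidates:
        raise RuntimeError("no fit start converged")
    n_converged = len(candidates)
    if n_converged < len(starts):
        warnings.warn(
            f"{len(starts) - n_converged} of {len(starts)} fit starts failed",
            RuntimeWarning,
        )
    best_rnorm = min(c[0] for c in candidates)
    # ties (within 1e-9 relative) broken by the smaller fast relaxation time
    res = min(
        (c for c in candidates if c[0] <= best_rnorm * (1.0 + 1e-9)),
        key=lambda c: c[1],
    )[2]
    logtau = np.sort(res.x)
    tau = 10.0**logtau
    coef, R = _project(logtau, t, Y)
    rnorm = float(np.linalg.norm(R))

    # linearised covariance of logtau at the optimum
    tau_stderr = np.full(n_exp, np.nan)
    dof = Y.size - (n_exp + Y.shape[1] * (n_exp + 1))
    if dof > 0:
        J = res.jac
        JtJ = J.T @ J
        try:
            cov = np.linalg.inv(JtJ) * (rnorm**2 / dof)
            sig_logtau = np.sqrt(np.clip(np.diag(cov), 0.0, None))
            order = np.argsort(res.x)
            tau_stderr = tau * np.log(10.0) * sig_logtau[order]
        except np.linalg.LinAlgError:
            pass

    offsets = coef[0, :].copy()
    amplitudes = coef[1:, :].copy()
    return tau, amplitudes, offsets, rnorm, tau_stderr, n_converged


def global_fit(
    svd: SvdResult,
    n_exp: Optional[int] = None,
    weighted: bool = True,
    n_starts: int = 32,
    seed: int = 0,
    s_threshold: float = 0.01,
    ac_threshold: float = 0.8,
    mask: Optional[np.ndarray] = None,
    tau_bounds: Optional[tuple[float, float]] = None,
) -> GlobalFitResult:
    """Globally fit the significant rSVs by a sum of exponentials with offset.

    ``weighted=True`` scales each rSV by its singular value before fitting,
    so stronger components dominate the shared-tau estimate.  ``n_exp``
    defaults to the number of significant components.
    """
    if mask is None:
        n_sig, mask = select_significant(svd, s_threshold, ac_threshold)
    else:
        mask = np.asarray(mask, dtype=bool)
        n_sig = int(mask.sum())
    if n_sig < 1:
        raise ValueError("no significant singular vectors to fit")
    if n_exp is None:
        n_exp = n_sig
    if n_exp > n_sig:
        warnings.warn(
            f"fitting {n_exp} exponentials to {n_sig} significant vectors; "
            "the extra phase may be poorly determined",
            RuntimeWarning,
        )
    Y = svd.rsv[:, mask]
    if weighted:
        Y = Y * svd.singular_values[mask][None, :]
    tau, amps, offs, rnorm, stderr, n_conv = fit_exponentials(
        svd.times, Y, n_exp, n_starts=n_starts, seed=seed, tau_bounds=tau_bounds
    )
    return GlobalFitResult(
        n_exp=n_exp,
        tau=tau,
        rates=1.0 / tau,
        amplitudes=amps,
        offsets=offs,
        weighted=weighted,
        residual_norm=rnorm,
        tau_stderr=stderr,
        n_significant=n_sig,
        n_starts_converged=n_conv,
    )


def single_wavelength_fit(
    series: SpectralSeries,
    lam: float,
    n_exp: int,
    n_starts: int = 32,
    seed: int = 0,
) -> GlobalFitResult:
    """Fit the trace at one wavelength with the same engine as the global fit.

    Off-grid wavelengths fall back to the nearest row with a warning.
    """
    lam_grid = series.grid.values
    i = int(np.argmin(np.abs(lam_grid - lam)))
    if abs(lam_grid[i] - lam) > 1e-9:
        warnings.warn(
            f"wavelength {lam} nm not on grid; using nearest {lam_grid[i]} nm",
            RuntimeWarning,
        )
    trace = series.data[i, :]
    tau, amps, offs, rnorm, stderr, n_conv = fit_exponentials(
        series.times, trace, n_exp, n_starts=n_starts, seed=seed
    )
    return GlobalFitResult(
        n_exp=n_exp,
        tau=tau,
        rates=1.0 / tau,
        amplitudes=amps,
        offsets=offs,
        weighted=False,
        residual_norm=rnorm,
        tau_stderr=stderr,
        n_significant=1,
        n_starts_converged=n_conv,
    )


def tau_rate_convert(x):
    """Reciprocal conversion between relaxation times and macroscopic rates."""
    x = np.asarray(x, dtype=float)
    if np.any(x <= 0):
        raise ValueError("relaxation times / rates must be positive")
    out = 1.0 / x
    return float(out) if out.ndim == 0 else out


def round_sig(x: float, n: int = 2) -> float:
    """Round to ``n`` significant figures (report style)."""
    if x == 0:
        return 0.0
    return round(x, n - 1 - floor(log10(abs(x))))


def format_sig(x: float, n: int = 2) -> str:
    """Format with ``n`` significant figures, e.g. 3448.3 -> '3.4e+03'."""
    return f"{round_sig(float(x), n):.{n - 1}e}"


def reconstruct_fit(
    svd: SvdResult, fit: GlobalFitResult, mask: Optional[np.ndarray] = None
) -> tuple[np.ndarray, np.ndarray]:
    """Rebuild the fitted dA matrix and the residual map data - fitted."""
    if mask is None:
        _, mask = select_significant(svd)
    mask = np.asarray(mask, dtype=bool)
    M = _design_matrix(fit.tau, svd.times)
    coef = np.vstack([fit.offsets[None, :], fit.amplitudes])
    fitted_Y = M @ coef  # n_times x j, weighted scale if fit.weighted
    if fit.weighted:
        fitted = svd.lsv[:, mask] @ fitted_Y.T
    else:
        fitted = svd.lsv[:, mask] @ (svd.singular_values[mask][:, None] * fitted_Y.T)
    data = svd.lsv @ (svd.singular_values[:, None] * svd.rsv.T)
    return fitted, data - fitted


def bic_scan(
    svd: SvdResult,
    n_exp_range=(1, 2, 3),
    weighted: bool = True,
    n_starts: int = 32,
    seed: int = 0,
) -> dict[int, float]:
    """Bayesian information criterion across model sizes (diagnostic only).

    Never applied silently: callers choose n_exp themselves, typically the
    number of significant components.
    """
    n_sig, mask = select_significant(svd)
    out = {}
    for n_exp in n_exp_range:
        if 2 * n_exp + 1 > svd.times.size:
            continue
        fit = global_fit(
            svd, n_exp=n_exp, weighted=weighted, n_starts=n_starts, seed=seed, mask=mask
        )
        n_obs = svd.times.size * max(n_sig, 1)
        k = n_exp + max(n_sig, 1) * (n_exp + 1)
        rss = fit.residual_norm**2
        out[n_exp] = n_obs * np.log(max(rss, 1e-300) / n_obs) + k * np.log(n_obs)
    return out
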