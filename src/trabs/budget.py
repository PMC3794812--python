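"""Photon- and sample-budget arithmetic for gated-detector spectroscopy.

Estimates how many probe photons reach the photocathode within one gate,
how they distribute over the CCD wavelength channels (full vertical
binning), and how much protein a solution drop contains.  These numbers
decide whether a single sub-microsecond exposure carries enough signal.
"""

from __future__ import annotations

from scipy.constants import c as SPEED_OF_LIGHT
from scipy.constants import h as PLANCK

from .kinetics import format_sig, round_sig

__all__ = [
    "photon_count",
    "photons_per_channel",
    "spectral_resolution",
    "drop_mass",
    "round_sig",
    "format_sig",
]

#: reference photon wavelength (nm) used for energy conversion
REF_WAVELENGTH_NM = 500.0
#: CCD channels in full vertical binning mode
DEFAULT_CHANNELS = 1024
#: reference slit width (um) at which the per-channel numbers are quoted
REF_SLIT_UM = 400.0

# measured spectral resolution per slit width; no interpolation model is
# claimed, so only the calibrated widths are accepted
_RESOLUTION_NM = {400.0: 12.0, 50.0: 3.0}


def photon_count(power_w: float, wavelength_nm: float = REF_WAVELENGTH_NM, duration_s: float = 1.0) -> float:
    """Photons delivered by ``power`` within ``duration`` at one wavelength.

    ``N = P * dt * lambda / (h c)`` with CODATA constants; bilinear in
    power and duration.
    """
    if power_w < 0 or wavelength_nm <= 0 or duration_s < 0:
        raise ValueError("power/duration must be >= 0 and wavelength > 0")
    photon_energy = PLANCK * SPEED_OF_LIGHT / (wavelength_nm * 1e-9)
    return power_w * duration_s / photon_energy


def photons_per_channel(
    total: float,
    n_channels: int = DEFAULT_CHANNELS,
    slit_width_um: float = REF_SLIT_UM,
    ref_slit_um: float = REF_SLIT_UM,
) -> float:
    """Photons per wavelength channel in full vertical binning.

    The total divides evenly over the channels; narrowing the slit cuts the
    flux linearly with slit width (a 50 um slit passes 1/8 of a 400 um
    slit).  The resolution change with slit width does not enter here.
    """
    if total < 0 or n_channels < 1 or slit_width_um <= 0 or ref_slit_um <= 0:
        raise ValueError("invalid photon-budget arguments")
    return total / n_channels * (slit_width_um / ref_slit_um)


def spectral_resolution(slit_width_um: float) -> float:
    """Measured spectral resolution (nm) for a calibrated slit width."""
    try:
        return _RESOLUTION_NM[float(slit_width_um)]
    except KeyError:
        raise ValueError(
            f"no calibration for slit width {slit_width_um} um; "
            f"known widths: {sorted(_RESOLUTION_NM)}"
        ) from None


def drop_mass(volume_nl: float, concentration_mg_per_ml: float) -> float:
    """Protein mass (ng) in a drop: volume (nL) x concentration (mg/mL).

    1 nL of a 1 mg/mL solution holds exactly 1 ng, so the product is the
    mass in ng directly.
    """
    if volume_nl < 0 or concentration_mg_per_ml < 0:
        raise ValueError("volume and concentration must be >= 0")
    return volume_nl * concentration_mg_per_ml
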