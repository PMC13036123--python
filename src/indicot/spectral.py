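"""Radiometric panel calibration and multispectral vegetation indices.

The sensor model is a five-band multispectral camera (blue, green, red,
red-edge, NIR).  Fourteen vegetation indices spanning five families —
visible-light, structural, red-edge, soil-adjusted and composite — are
implemented exactly as commonly tabulated for cotton nitrogen retrieval,
including a few formulations that deviate from textbook conventions
(``NGI`` uses green/red rather than green/NIR; ``MRETVI`` carries a leading
1.2 factor).  Deviations are deliberate and documented next to each formula.

All index functions are vectorised: scalars, numpy arrays and pandas Series
all work, so the same code path serves plot tables and raster pixels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

__all__ = [
    "BAND_NAMES",
    "BAND_INFO",
    "PanelReference",
    "DEFAULT_PANEL",
    "empirical_line_calibrate",
    "VI_NAMES",
    "compute_vi",
    "compute_all_vis",
]

#: Canonical band order used throughout the package (raster band order too).
BAND_NAMES = ("blue", "green", "red", "red_edge", "nir")

#: Per-band sensor metadata: central wavelength (nm), bandwidth (nm) and the
#: grey reference panel reflectance (fraction) used for empirical-line
#: calibration.
BAND_INFO = {
    "blue": {"wavelength_nm": 475, "bandwidth_nm": 32, "panel_reflectance": 0.65},
    "green": {"wavelength_nm": 560, "bandwidth_nm": 27, "panel_reflectance": 0.63},
    "red": {"wavelength_nm": 668, "bandwidth_nm": 14, "panel_reflectance": 0.62},
    "red_edge": {"wavelength_nm": 717, "bandwidth_nm": 12, "panel_reflectance": 0.61},
    "nir": {"wavelength_nm": 842, "bandwidth_nm": 57, "panel_reflectance": 0.60},
}


@dataclass(frozen=True)
class PanelReference:
    """Grey-panel reference for single-point empirical-line calibration.

    Attributes
    ----------
    reflectance : mapping band -> known panel reflectance fraction in (0, 1].
    digital_number : mapping band -> panel digital number recorded by the
        sensor ( > 0 ).
    """

    reflectance: Mapping[str, float] = field(
        default_factory=lambda: {
            b: BAND_INFO[b]["panel_reflectance"] for b in BAND_NAMES
        }
    )
    digital_number: Mapping[str, float] = field(
        default_factory=lambda: {b: 1.0 for b in BAND_NAMES}
    )

    def __post_init__(self) -> None:
        for band in BAND_NAMES:
            if band not in self.reflectance or band not in self.digital_number:
                raise ValueError(f"panel reference missing band {band!r}")
            r = self.reflectance[band]
            if not 0.0 < r <= 1.0:
                raise ValueError(f"panel reflectance for {band!r} must be in (0, 1], got {r}")
            if self.digital_number[band] <= 0:
                raise ValueError(f"panel digital number for {band!r} must be > 0")


DEFAULT_PANEL = PanelReference()


def empirical_line_calibrate(dn, panel: PanelReference, band: str):
    """Convert digital numbers to reflectance via a one-point empirical line.

    The line passes through the origin and the panel observation, i.e.
    ``reflectance = dn * (panel_reflectance / panel_dn)``, clipped to [0, 1].
    A dark-current (two-point) correction is intentionally not applied.

    Parameters
    ----------
    dn : scalar or array of non-negative digital numbers.
    panel : the grey-panel reference.
    band : one of ``BAND_NAMES``.
    """
    if band not in BAND_NAMES:
        raise ValueError(f"unknown band {band!r}; expected one of {BAND_NAMES}")
    dn = np.asarray(dn, dtype=float)
    if np.any(~np.isfinite(dn)) or np.any(dn < 0):
        raise ValueError(f"digital numbers for band {band!r} must be finite and >= 0")
    gain = panel.reflectance[band] / panel.digital_number[band]
    out = np.clip(dn * gain, 0.0, 1.0)
    return float(out) if out.ndim == 0 else out


# --- vegetation indices -----------------------------------------------------
# Each formula is written exactly as used in the cotton nitrogen-diagnosis
# setting this package targets.  b/g/r/re/n are reflectance fractions.

def _mretvi(b, g, r, re, n):
    # leading 1.2 factor kept as printed in the source tabulation
    return 1.2 * (1.2 * (n - g) - 2.5 * (r - g))


def _rvi(b, g, r, re, n):
    return n / r


def _rervi(b, g, r, re, n):
    return n / re


def _ngi(b, g, r, re, n):
    # green/red normalised difference (conventionally called NGRDI; kept
    # under the NGI name used in this pipeline)
    return (g - r) / (g + r)


def _npci(b, g, r, re, n):
    return (r - b) / (r + b)


def _ndre(b, g, r, re, n):
    return (n - re) / (n + re)


def _nli(b, g, r, re, n):
    return (n**2 - r) / (n**2 + r)


def _vari(b, g, r, re, n):
    return (g - r) / (g + r - b)


def _ndvi(b, g, r, re, n):
    return (n - r) / (n + r)


def _evi(b, g, r, re, n):
    return 2.5 * (n - r) / (n + 6.0 * r - 7.5 * b + 1.0)


def _ngbdi(b, g, r, re, n):
    return (g - b) / (g + b)


def _osavi(b, g, r, re, n):
    return (n - r) / (n + r + 0.16)


def _rendvi(b, g, r, re, n):
    return (re - r) / (re + r)


def _savi(b, g, r, re, n):
    return 1.5 * (n - r) / (n + r + 0.5)


_VI_FUNCS = {
    "MRETVI": _mretvi,
    "RVI": _rvi,
    "RERVI": _rervi,
    "NGI": _ngi,
    "NPCI": _npci,
    "NDRE": _ndre,
    "NLI": _nli,
    "VARI": _vari,
    "NDVI": _ndvi,
    "EVI": _evi,
    "NGBDI": _ngbdi,
    "OSAVI": _osavi,
    "RENDVI": _rendvi,
    "SAVI": _savi,
}

#: The 14 supported vegetation index names, in canonical order.
VI_NAMES = tuple(_VI_FUNCS)


def _validate_bands(bands: Mapping[str, object]) -> tuple:
    vals = []
    for name in BAND_NAMES:
        if name not in bands:
            raise ValueError(f"band set missing {name!r}; required bands: {BAND_NAMES}")
        v = np.asarray(bands[name], dtype=float)
        with np.errstate(invalid="ignore"):
            bad = np.isfinite(v) & ((v < 0.0) | (v > 1.0))
        if np.any(bad):
            raise ValueError(f"reflectance for band {name!r} outside [0, 1]")
        vals.append(v)
    return tuple(vals)


def compute_vi(name: str, bands: Mapping[str, object], strict: bool = False):
    """Compute one vegetation index from a band set.

    Parameters
    ----------
    name : index name, one of ``VI_NAMES``.
    bands : mapping with keys ``blue, green, red, red_edge, nir`` holding
        reflectance fractions (scalars or aligned arrays).
    strict : if True, a zero denominator raises instead of yielding NaN.
        The lenient default suits raster pixels, where degenerate values
        occur routinely and are flagged as NaN for downstream masking.
    """
    if name not in _VI_FUNCS:
        raise ValueError(f"unknown vegetation index {name!r}; valid names: {sorted(_VI_FUNCS)}")
    b, g, r, re, n = _validate_bands(bands)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = _VI_FUNCS[name](b, g, r, re, n)
    out = np.asarray(out, dtype=float)
    out = np.where(np.isinf(out), np.nan, out)
    if strict and np.any(np.isnan(out) & ~_any_nan_input(b, g, r, re, n)):
        raise ZeroDivisionError(f"zero denominator while computing {name}")
    return float(out) if out.ndim == 0 else out


def _any_nan_input(*arrs):
    out = np.zeros(np.broadcast(*arrs).shape, dtype=bool)
    for a in arrs:
        out |= np.isnan(a)
    return out


def compute_all_vis(bands: Mapping[str, object], strict: bool = False) -> dict:
    """Compute all 14 vegetation indices; returns ``{name: value}``.

    NaN entries (zero denominators, NaN inputs) are kept, never dropped, so
    callers can mask them explicitly.
    """
    return {name: compute_vi(name, bands, strict=strict) for name in VI_NAMES}
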