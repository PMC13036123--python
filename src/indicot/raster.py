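"""Lightweight georeferenced raster container.

A :class:`RasterGrid` holds a stack of equally shaped bands in row-major,
north-up orientation with a simple (x_origin, y_origin, pixel_size)
geotransform: pixel (row, col) has its centre at
``x = x_origin + (col + 0.5) * pixel_size`` and
``y = y_origin - (row + 0.5) * pixel_size``.
Invalid pixels are carried as a boolean validity mask; float surfaces use
NaN as the nodata sentinel, classification surfaces use byte code 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = ["RasterGrid", "CLASS_CODES", "CLASS_LABELS"]

#: Byte codes for the three-level nitrogen-status surface (0 = nodata).
CLASS_CODES = {"nodata": 0, "deficient": 1, "adequate": 2, "excessive": 3}
CLASS_LABELS = {v: k for k, v in CLASS_CODES.items()}


@dataclass
class RasterGrid:
    """Multi-band reflectance grid with optional derived surfaces.

    Attributes
    ----------
    bands : float array of shape (n_bands, rows, cols); reflectance fractions.
    band_names : tuple of band names in storage order.
    x_origin, y_origin : map coordinates of the top-left corner.
    pixel_size : side length of a (square) pixel in map units; > 0.
    mask : bool array (rows, cols); True where the pixel is valid.
    indi : optional float surface of the integrated nitrogen diagnosis index.
    classes : optional uint8 surface of nitrogen-status codes (CLASS_CODES).
    """

    bands: np.ndarray
    band_names: tuple
    x_origin: float = 0.0
    y_origin: float = 0.0
    pixel_size: float = 1.0
    mask: Optional[np.ndarray] = None
    indi: Optional[np.ndarray] = None
    classes: Optional[np.ndarray] = None
    plot_ids: Optional[np.ndarray] = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.bands = np.asarray(self.bands, dtype=float)
        if self.bands.ndim != 3:
            raise ValueError("bands must have shape (n_bands, rows, cols)")
        if len(self.band_names) != self.bands.shape[0]:
            raise ValueError("band_names length must match number of bands")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")
        if self.mask is None:
            self.mask = ~np.any(np.isnan(self.bands), axis=0)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.bands.shape[1:]:
            raise ValueError("mask shape must match band shape")

    @property
    def shape(self) -> tuple:
        return self.bands.shape[1:]

    def band(self, name: str) -> np.ndarray:
        try:
            i = self.band_names.index(name)
        except ValueError:
            raise ValueError(
                f"raster has no band {name!r}; bands present: {self.band_names}"
            ) from None
        return self.bands[i]

    def band_dict(self) -> dict:
        """Bands as a name -> 2-D array mapping (NaN outside the mask)."""
        out = {}
        for name, arr in zip(self.band_names, self.bands):
            a = arr.copy()
            a[~self.mask] = np.nan
            out[name] = a
        return out

    def pixel_center(self, row: int, col: int) -> tuple:
        return (
            self.x_origin + (col + 0.5) * self.pixel_size,
            self.y_origin - (row + 0.5) * self.pixel_size,
        )

    def copy(self) -> "RasterGrid":
        return RasterGrid(
            bands=self.bands.copy(),
            band_names=tuple(self.band_names),
            x_origin=self.x_origin,
            y_origin=self.y_origin,
            pixel_size=self.pixel_size,
            mask=self.mask.copy(),
            indi=None if self.indi is None else self.indi.copy(),
            classes=None if self.classes is None else self.classes.copy(),
            plot_ids=None if self.plot_ids is None else self.plot_ids.copy(),
        )
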