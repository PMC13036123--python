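"""Readers, writers and run manifests.

Frozen plot-table schema (units are part of the contract):

==================  =======================================================
column              meaning / unit
==================  =======================================================
treatment           treatment label, e.g. ``W1.0N300``
irrigation_fraction multiplier of full irrigation (dimensionless)
n_rate              nitrogen application, kg N ha⁻¹
replicate           positive integer replicate index
stage               growth-stage label
stage_index         1-based temporal order of the stage
irrigation_mm       seasonal irrigation amount, mm
dm                  aboveground dry matter, Mg ha⁻¹
lnc_upper           upper-canopy leaf N concentration, g/100 g
ldw_upper           upper-canopy leaf dry weight, g m⁻²
lnw_upper           upper-canopy leaf N weight, g N m⁻²
lai                 leaf area index (dimensionless)
blue..nir           band reflectance fractions in [0, 1]
==================  =======================================================

Rasters are written as multi-band TIFF with the geotransform, band names
and nodata convention serialised as JSON into the ImageDescription tag, so
a written grid reads back bit-identically without any GIS stack.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import tifffile
import yaml

from .raster import RasterGrid
from .spectral import BAND_NAMES

__all__ = [
    "PLOT_TABLE_COLUMNS",
    "read_plot_table",
    "write_plot_table",
    "write_raster",
    "read_raster",
    "write_layout_geojson",
    "read_layout_geojson",
    "PipelineConfig",
    "load_config",
    "save_config",
    "RunManifest",
]

#: Required columns and their kind ("num" or "str").
PLOT_TABLE_COLUMNS = {
    "treatment": "str",
    "irrigation_fraction": "num",
    "n_rate": "num",
    "replicate": "num",
    "stage": "str",
    "stage_index": "num",
    "irrigation_mm": "num",
    "dm": "num",
    "lnc_upper": "num",
    "ldw_upper": "num",
    "lnw_upper": "num",
    "lai": "num",
    **{b: "num" for b in BAND_NAMES},
}


def read_plot_table(path) -> pd.DataFrame:
    """Read and validate a plot observation table (CSV)."""
    df = pd.read_csv(path)
    missing = [c for c in PLOT_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"plot table {path} missing required columns: {missing}")
    for col, kind in PLOT_TABLE_COLUMNS.items():
        if kind != "num":
            continue
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[vals.isna() & df[col].notna()].tolist()
        if bad:
            lines = [i + 2 for i in bad[:5]]  # 1-based + header
            raise ValueError(f"non-numeric values in column {col!r} at file lines {lines}")
        df[col] = vals
    dup = df.duplicated(subset=["treatment", "replicate", "stage"])
    if dup.any():
        lines = [i + 2 for i in df.index[dup][:5].tolist()]
        raise ValueError(f"duplicate (treatment, replicate, stage) keys at file lines {lines}")
    for b in BAND_NAMES:
        if ((df[b] < 0) | (df[b] > 1)).any():
            raise ValueError(f"reflectance column {b!r} outside [0, 1]")
    if (df["dm"] <= 0).any():
        raise ValueError("dry matter column 'dm' must be > 0")
    if (df["lai"] < 0).any():
        raise ValueError("'lai' must be >= 0")
    return df


def write_plot_table(df: pd.DataFrame, path) -> None:
    missing = [c for c in PLOT_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"cannot write plot table: missing columns {missing}")
    df.to_csv(path, index=False)


# --- raster I/O -------------------------------------------------------------

def write_raster(raster: RasterGrid, path) -> None:
    """Write a RasterGrid as a multi-band float TIFF (NaN = nodata).

    Derived surfaces, when present, are appended as extra bands named
    ``indi`` (float) and ``classes`` (byte codes recast to float).
    """
    arrays = [raster.bands[i] for i in range(raster.bands.shape[0])]
    names = list(raster.band_names)
    if raster.indi is not None:
        arrays.append(raster.indi)
        names.append("indi")
    if raster.classes is not None:
        arrays.append(raster.classes.astype(float))
        names.append("classes")
    stack = np.stack(arrays).astype("float64")
    meta = {
        "band_names": names,
        "x_origin": raster.x_origin,
        "y_origin": raster.y_origin,
        "pixel_size": raster.pixel_size,
        "nodata": "nan",
    }
    tifffile.imwrite(str(path), stack, photometric="minisblack", description=json.dumps(meta))


def read_raster(path, expect_bands: int = 5) -> RasterGrid:
    """Read a TIFF written by :func:`write_raster` back into a RasterGrid."""
    with tifffile.TiffFile(str(path)) as tif:
        stack = tif.asarray()
        desc = tif.pages[0].description
    meta = json.loads(desc) if desc else {}
    names = meta.get("band_names")
    if stack.ndim == 2:
        stack = stack[None]
    if names is None:
        names = list(BAND_NAMES[: stack.shape[0]])
    indi = classes = None
    if "indi" in names:
        indi = stack[names.index("indi")]
    if "classes" in names:
        classes = stack[names.index("classes")].astype(np.uint8)
    band_idx = [i for i, n in enumerate(names) if n not in ("indi", "classes")]
    spectral_names = tuple(names[i] for i in band_idx)
    if len(spectral_names) != expect_bands:
        raise ValueError(
            f"raster {path} has {len(spectral_names)} reflectance bands; expected {expect_bands}"
        )
    return RasterGrid(
        bands=stack[band_idx],
        band_names=spectral_names,
        x_origin=float(meta.get("x_origin", 0.0)),
        y_origin=float(meta.get("y_origin", 0.0)),
        pixel_size=float(meta.get("pixel_size", 1.0)),
        indi=indi,
        classes=classes,
    )


def write_layout_geojson(layout, path) -> None:
    """Write [(plot_id, shapely polygon), ...] as a GeoJSON FeatureCollection."""
    features = []
    for pid, geom in layout:
        features.append(
            {
                "type": "Feature",
                "properties": {"plot_id": pid},
                "geometry": geom.__geo_interface__,
            }
        )
    Path(path).write_text(
        json.dumps({"type": "FeatureCollection", "features": features}, indent=2)
    )


def read_layout_geojson(path) -> list:
    from shapely.geometry import shape

    data = json.loads(Path(path).read_text())
    return [
        (feat["properties"]["plot_id"], shape(feat["geometry"]))
        for feat in data["features"]
    ]


# --- configuration ----------------------------------------------------------

@dataclass
class PipelineConfig:
    """End-to-end pipeline configuration (YAML-serialisable)."""

    output_dir: str = "indicot_run"
    seed: int = 20260317
    # generator
    replicates: int = 3
    reflectance_noise: float = 0.008
    pixel_size: float = 0.5
    # INDI
    weighting_scheme: str = "inverse_cv"
    indicators: tuple = ("lai", "lnw_upper")
    # screening
    screen_threshold: float = 0.6
    r_max: float = 0.90
    vif_max: float = 10.0
    use_default_features: bool = True
    # model
    model_family: str = "regularized_gradient_boosted_trees"
    # dilution / classification
    theta: float = 0.95
    class_delta: float = 0.05
    map_stage: str = "boll_setting"
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("a seed is required: every stochastic stage is seeded")
        if not 0 < self.screen_threshold < 1:
            raise ValueError("screen_threshold must be in (0, 1)")
        if self.class_delta < 0:
            raise ValueError("class_delta must be >= 0")
        self.indicators = tuple(self.indicators)


def load_config(path) -> PipelineConfig:
    data = yaml.safe_load(Path(path).read_text()) or {}
    known = {f for f in PipelineConfig.__dataclass_fields__}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config fields: {sorted(unknown)}")
    return PipelineConfig(**data)


def save_config(cfg: PipelineConfig, path) -> None:
    d = asdict(cfg)
    d["indicators"] = list(d["indicators"])
    Path(path).write_text(yaml.safe_dump(d, sort_keys=True))


# --- run manifests ----------------------------------------------------------

def _sha256_file(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


@dataclass
class RunManifest:
    """Provenance record for one pipeline stage run."""

    stage: str
    config_hash: str
    seed: int
    outputs: dict = field(default_factory=dict)
    inputs: dict = field(default_factory=dict)
    package_version: str = ""
    timestamp: str = ""

    @classmethod
    def create(cls, stage: str, cfg: PipelineConfig, inputs=(), outputs=()) -> "RunManifest":
        from . import __version__

        d = asdict(cfg)
        d["indicators"] = list(d["indicators"])
        cfg_hash = hashlib.sha256(
            json.dumps(d, sort_keys=True).encode()
        ).hexdigest()
        m = cls(
            stage=stage,
            config_hash=cfg_hash,
            seed=cfg.seed,
            package_version=__version__,
            timestamp=time.strftime("%Y-%m-%dT%H:%M:%S"),
        )
        for p in inputs:
            m.inputs[str(p)] = _sha256_file(Path(p))
        for p in outputs:
            m.outputs[str(p)] = _sha256_file(Path(p))
        return m

    def write(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, sort_keys=True))
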