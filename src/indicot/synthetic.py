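"""Synthetic water × nitrogen factorial experiment for drip-irrigated cotton.

The generator emulates the statistical structure a canopy nitrogen-diagnosis
pipeline assumes, without pretending to be a crop or radiative-transfer
model:

* a 4 irrigation × 4 nitrogen factorial (16 treatments, default 3
  replicates → 48 plot samples at each of 4 growth stages);
* aboveground dry matter (DM, Mg ha⁻¹) following a four-stage logistic
  trajectory scaled by water and nitrogen response factors;
* upper-canopy leaf N concentration obeying a power-law dilution
  ``N = s(n_rate) · a(I) · DM^(−b(I))`` with irrigation-dependent
  parameters (quadratic a(I), b(I)) and a bounded supply multiplier s —
  sub-critical for the zero-N control, ≈ 1 at the reference rate,
  slightly above 1 at high rates;
* leaf area index (LAI) as a saturating function of DM and N supply, and
  upper-canopy leaf dry weight as an allometric share of DM;
* five-band canopy reflectance from an exponential gap-fraction mixing
  model driven by LAI and a chlorophyll proxy, so that red-edge/NIR
  vegetation indices correlate strongly (|r| > 0.6) with LAI and leaf
  nitrogen weight.

All randomness flows through a config-scoped seed; identical configs give
byte-identical tables and rasters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import box

from .dilution import COTTON_DILUTION_REFERENCE
from .raster import RasterGrid
from .spectral import BAND_NAMES

__all__ = [
    "STAGES",
    "WeatherRecord",
    "TreatmentSpec",
    "GeneratorConfig",
    "et0_penman",
    "etc_from_et0",
    "KC_SCHEDULE",
    "enumerate_treatments",
    "generate_experiment",
    "generate_reflectance",
    "build_field_layout",
    "generate_raster",
    "rasterize_stage",
]

#: Phenological stages sampled, in temporal order.
STAGES = ("squaring", "flowering", "boll_setting", "boll_opening")

#: FAO-recommended crop coefficients for cotton by season segment.
KC_SCHEDULE = {"initial": 0.70, "mid_season": 1.15, "late_season": 0.75}


# --- agronomic drivers ------------------------------------------------------

@dataclass(frozen=True)
class WeatherRecord:
    """One day of weather for reference-evapotranspiration calculation.

    Units: Rn, G in MJ m⁻² day⁻¹; T in °C; u2 in m s⁻¹ at 2 m height;
    es, ea in kPa; delta (slope of the saturation vapour-pressure curve)
    and gamma (psychrometric constant) in kPa °C⁻¹.
    """

    rn: float
    g: float
    t: float
    u2: float
    es: float
    ea: float
    delta: float
    gamma: float

    def __post_init__(self) -> None:
        for name in ("rn", "g", "t", "u2", "es", "ea", "delta", "gamma"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ValueError(f"weather field {name!r} must be finite, got {v}")
        if self.ea < 0 or self.es < self.ea:
            raise ValueError("vapour pressures must satisfy es >= ea >= 0")
        if self.u2 < 0:
            raise ValueError("wind speed u2 must be >= 0")


def et0_penman(w: WeatherRecord) -> float:
    """FAO-56 Penman–Monteith reference evapotranspiration, mm day⁻¹.

    ``ET0 = [0.408 Δ (Rn − G) + γ 900/(T+273) u2 (es − ea)]
    / [Δ + γ (1 + 0.34 u2)]``.
    """
    denom = w.delta + w.gamma * (1.0 + 0.34 * w.u2)
    if denom <= 0:
        raise ValueError("delta + gamma*(1 + 0.34*u2) must be > 0")
    num = 0.408 * w.delta * (w.rn - w.g) + w.gamma * (900.0 / (w.t + 273.0)) * w.u2 * (
        w.es - w.ea
    )
    return num / denom


def etc_from_et0(et0: float, kc: float) -> float:
    """Crop evapotranspiration ``ETc = ET0 × Kc`` (mm day⁻¹)."""
    if et0 < 0:
        raise ValueError("et0 must be >= 0")
    if kc <= 0:
        raise ValueError("crop coefficient kc must be > 0")
    return et0 * kc


# --- experiment design ------------------------------------------------------

@dataclass(frozen=True)
class TreatmentSpec:
    """One cell of the water × nitrogen factorial.

    irrigation_fraction multiplies the full-irrigation (100 % ETc) seasonal
    amount; n_rate is the nitrogen application in kg N ha⁻¹.
    """

    irrigation_fraction: float
    n_rate: float
    replicate: int = 1

    def __post_init__(self) -> None:
        if self.irrigation_fraction <= 0:
            raise ValueError("irrigation_fraction must be > 0")
        if self.n_rate < 0:
            raise ValueError("n_rate must be >= 0")
        if self.replicate < 1:
            raise ValueError("replicate must be a positive integer")

    @property
    def name(self) -> str:
        rate = int(self.n_rate) if float(self.n_rate).is_integer() else self.n_rate
        return f"W{self.irrigation_fraction:g}N{rate}"


def _default_a_coeffs() -> tuple:
    # quadratic a(I) through the reference table, rescaled to g/100 g
    ref = COTTON_DILUTION_REFERENCE
    c = np.polyfit(ref["irrigation_mm"], 100.0 * ref["a"], 2)
    return tuple(float(v) for v in c)


def _default_b_coeffs() -> tuple:
    ref = COTTON_DILUTION_REFERENCE
    c = np.polyfit(ref["irrigation_mm"], ref["b"], 2)
    return tuple(float(v) for v in c)


@dataclass(frozen=True)
class GeneratorConfig:
    """Everything the synthetic experiment depends on, seed included.

    The defaults define the reference study conditions: 16 treatments × 3
    replicates × 4 stages, full irrigation 405.32 mm, dilution-law truth
    a(I), b(I) taken as quadratics through the published per-irrigation
    parameter table (a rescaled to g/100 g so leaf N concentrations are
    physically plausible percentages).
    """

    stages: tuple = STAGES
    replicates: int = 3
    irrigation_fractions: tuple = (0.6, 0.8, 1.0, 1.2)
    n_rates: tuple = (0.0, 245.0, 300.0, 350.0)
    full_irrigation_mm: float = 405.32
    #: quadratic (c2, c1, c0) for the dilution parameter a(I), g/100 g
    true_a_coefficients: tuple = field(default_factory=_default_a_coeffs)
    #: quadratic (c2, c1, c0) for the dilution exponent b(I)
    true_b_coefficients: tuple = field(default_factory=_default_b_coeffs)
    #: supply multiplier s(n_rate) on leaf N concentration
    n_supply_multiplier: Mapping[float, float] = field(
        default_factory=lambda: {0.0: 0.75, 245.0: 1.00, 300.0: 1.05, 350.0: 1.08}
    )
    #: dry-matter response to nitrogen rate (saturating; zero-N control
    #: loses ~40 % of biomass on this low-native-N soil)
    n_dm_response: Mapping[float, float] = field(
        default_factory=lambda: {0.0: 0.62, 245.0: 0.96, 300.0: 1.00, 350.0: 1.01}
    )
    #: dry-matter response to irrigation fraction (severe deficit at 60 %
    #: ETc; peaks near full irrigation)
    water_dm_response: Mapping[float, float] = field(
        default_factory=lambda: {0.6: 0.70, 0.8: 0.88, 1.0: 1.00, 1.2: 1.01}
    )
    #: logistic DM trajectory: dm_max · σ(growth_rate · (stage − midpoint));
    #: the early midpoint reflects drip-irrigated cotton having substantial
    #: canopy by squaring, with biomass plateauing through boll stages
    dm_max: float = 14.0
    dm_growth_rate: float = 1.0
    dm_midpoint: float = 1.0
    #: LAI saturation: lai_max · (1 − exp(−lai_k · DM)) · N-supply tweak
    lai_max: float = 5.5
    lai_k: float = 0.16
    #: upper-canopy leaf dry weight share: g m⁻² per Mg ha⁻¹ of DM
    leaf_share: float = 10.0
    #: chlorophyll proxy scale (g N m⁻² of LNW at which proxy ≈ 0.63)
    chl_scale: float = 0.9
    #: per-stage soil/background brightness multipliers (moist spring soil,
    #: drying through the season, open bolls brightening the background)
    stage_soil_brightness: tuple = (1.00, 0.93, 1.06, 1.18)
    #: per-stage canopy NIR asymptote (senescence depresses NIR late)
    stage_nir_asymptote: tuple = (0.55, 0.56, 0.54, 0.48)
    #: multiplicative lognormal noise sigmas
    dm_noise: float = 0.06
    n_noise: float = 0.05
    lai_noise: float = 0.06
    #: additive Gaussian reflectance noise (reflectance units)
    reflectance_noise: float = 0.005
    seed: int = 20260317

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        for s in (self.dm_noise, self.n_noise, self.lai_noise, self.reflectance_noise):
            if s < 0:
                raise ValueError("noise scales must be >= 0")
        if len(self.irrigation_fractions) != len(set(self.irrigation_fractions)):
            raise ValueError("irrigation fractions must be distinct")
        if len(self.n_rates) != len(set(self.n_rates)):
            raise ValueError("nitrogen rates must be distinct")

    # generator-truth dilution parameters -----------------------------------
    def true_a(self, irrigation_mm) -> np.ndarray:
        return np.polyval(self.true_a_coefficients, np.asarray(irrigation_mm, dtype=float))

    def true_b(self, irrigation_mm) -> np.ndarray:
        return np.polyval(self.true_b_coefficients, np.asarray(irrigation_mm, dtype=float))

    def noiseless(self) -> "GeneratorConfig":
        """A copy with every noise source switched off."""
        return replace(self, dm_noise=0.0, n_noise=0.0, lai_noise=0.0, reflectance_noise=0.0)

    @property
    def n_treatments(self) -> int:
        return len(self.irrigation_fractions) * len(self.n_rates)

    @property
    def samples_per_stage(self) -> int:
        return self.n_treatments * self.replicates


def enumerate_treatments(cfg: GeneratorConfig) -> list:
    """All (fraction, rate, replicate) cells of the factorial, in design order."""
    return [
        TreatmentSpec(f, r, rep)
        for f in cfg.irrigation_fractions
        for r in cfg.n_rates
        for rep in range(1, cfg.replicates + 1)
    ]


# --- reflectance model ------------------------------------------------------

#: Bare-soil reflectance spectrum (dry clay loam; increases with wavelength).
SOIL_REFLECTANCE = {"blue": 0.12, "green": 0.18, "red": 0.22, "red_edge": 0.24, "nir": 0.25}
#: Dense-canopy NIR asymptote.
VEG_NIR = 0.55
#: Canopy extinction coefficient for the exponential gap fraction.
GAP_K = 0.55


def generate_reflectance(
    lai,
    chl_proxy,
    noise_scale: float = 0.0,
    rng: Optional[np.random.Generator] = None,
    soil_brightness: float = 1.0,
    nir_asymptote: float = VEG_NIR,
) -> dict:
    """Five-band canopy reflectance from LAI and a chlorophyll proxy.

    An exponential gap-fraction mixing model: each band is a soil/vegetation
    mixture weighted by ``gap = exp(−k·LAI)``.  NIR rises toward a dense-
    canopy asymptote; blue, green and red fall with chlorophyll (stronger
    absorption); the red edge sits between red and NIR and slides toward
    red as chlorophyll increases.  ``soil_brightness`` scales the bare-soil
    spectrum (soil moisture / open-boll background phenology) and
    ``nir_asymptote`` lets senescence depress the dense-canopy NIR level.
    Gaussian noise of ``noise_scale`` is added per band and the result
    clipped to [0, 1].

    This is a correlation-structure emulator, not a radiative-transfer
    model: it produces the trait–index couplings the diagnosis pipeline
    relies on and nothing more.
    """
    lai = np.asarray(lai, dtype=float)
    chl = np.asarray(chl_proxy, dtype=float)
    if np.any(lai < 0):
        raise ValueError("lai must be >= 0")
    if np.any((chl < 0) | (chl > 1)):
        raise ValueError("chl_proxy must be in [0, 1]")
    if noise_scale < 0:
        raise ValueError("noise_scale must be >= 0")

    gap = np.exp(-GAP_K * lai)
    veg = {
        "blue": 0.09 - 0.05 * chl,
        "green": 0.16 - 0.08 * chl,
        "red": 0.14 - 0.10 * chl,
        "nir": np.broadcast_to(np.asarray(nir_asymptote, dtype=float), chl.shape),
    }
    bands = {}
    for name in ("blue", "green", "red", "nir"):
        bands[name] = soil_brightness * SOIL_REFLECTANCE[name] * gap + veg[name] * (1.0 - gap)
    # red edge: mixture point between red and NIR, shifting with chlorophyll
    bands["red_edge"] = bands["red"] + (bands["nir"] - bands["red"]) * (0.55 - 0.30 * chl)

    if noise_scale > 0:
        if rng is None:
            raise ValueError("an rng is required when noise_scale > 0")
        for name in BAND_NAMES:
            bands[name] = bands[name] + rng.normal(0.0, noise_scale, size=np.shape(bands[name]))
    out = {name: np.clip(np.asarray(bands[name], dtype=float), 0.0, 1.0) for name in BAND_NAMES}
    if lai.ndim == 0:
        out = {k: float(v) for k, v in out.items()}
    return out


# --- plot-table generation --------------------------------------------------

def generate_experiment(cfg: GeneratorConfig) -> pd.DataFrame:
    """Generate the full plot × stage observation table.

    Returns one row per (stage, treatment, replicate) with columns:
    ``treatment, irrigation_fraction, n_rate, replicate, stage,
    stage_index, irrigation_mm, dm, lnc_upper, ldw_upper, lnw_upper, lai,
    chl_proxy, blue, green, red, red_edge, nir``.

    Units: irrigation in mm; DM in Mg ha⁻¹; leaf N concentration in
    g/100 g; leaf dry weight and leaf N weight in g m⁻²; reflectances as
    fractions.  ``lnw_upper = ldw_upper × lnc_upper / 100`` holds exactly.
    """
    rng = np.random.default_rng(cfg.seed)
    rows = []
    for stage_index, stage in enumerate(cfg.stages, start=1):
        logistic = 1.0 / (1.0 + math.exp(-cfg.dm_growth_rate * (stage_index - cfg.dm_midpoint)))
        for spec in enumerate_treatments(cfg):
            irr = spec.irrigation_fraction * cfg.full_irrigation_mm
            a_i = float(cfg.true_a(irr))
            b_i = float(cfg.true_b(irr))
            s_n = cfg.n_supply_multiplier[spec.n_rate]
            dm_mean = (
                cfg.dm_max
                * logistic
                * cfg.water_dm_response[spec.irrigation_fraction]
                * cfg.n_dm_response[spec.n_rate]
            )
            dm = dm_mean * _lognormal(rng, cfg.dm_noise)
            lnc = s_n * a_i * dm ** (-b_i) * _lognormal(rng, cfg.n_noise)
            lai = (
                cfg.lai_max
                * (1.0 - math.exp(-cfg.lai_k * dm))
                * (0.88 + 0.12 * s_n)
                * _lognormal(rng, cfg.lai_noise)
            )
            ldw = cfg.leaf_share * dm
            lnw = ldw * lnc / 100.0
            chl = 1.0 - math.exp(-lnw / cfg.chl_scale)
            bands = generate_reflectance(
                lai, chl, cfg.reflectance_noise, rng,
                soil_brightness=cfg.stage_soil_brightness[stage_index - 1],
                nir_asymptote=cfg.stage_nir_asymptote[stage_index - 1],
            )
            rows.append(
                {
                    "treatment": spec.name,
                    "irrigation_fraction": spec.irrigation_fraction,
                    "n_rate": spec.n_rate,
                    "replicate": spec.replicate,
                    "stage": stage,
                    "stage_index": stage_index,
                    "irrigation_mm": irr,
                    "dm": dm,
                    "lnc_upper": lnc,
                    "ldw_upper": ldw,
                    "lnw_upper": lnw,
                    "lai": lai,
                    "chl_proxy": chl,
                    **bands,
                }
            )
    return pd.DataFrame(rows)


def _lognormal(rng: np.random.Generator, sigma: float) -> float:
    # mean-one multiplicative noise; exactly 1.0 when sigma == 0
    if sigma == 0:
        return 1.0
    return float(np.exp(rng.normal(-0.5 * sigma**2, sigma)))


# --- raster generation ------------------------------------------------------

def build_field_layout(
    plot_ids: Sequence[str],
    n_cols: int = 4,
    plot_width: float = 6.0,
    plot_height: float = 9.0,
    gap: float = 2.0,
    origin: tuple = (0.0, 0.0),
) -> list:
    """Rectangular plot polygons on a regular grid, row-major from origin.

    Returns ``[(plot_id, shapely Polygon), ...]`` — a synthetic stand-in
    for a surveyed plot-boundary layer.
    """
    x0, y0 = origin
    layout = []
    for i, pid in enumerate(plot_ids):
        r, c = divmod(i, n_cols)
        xa = x0 + c * (plot_width + gap)
        ya = y0 + r * (plot_height + gap)
        layout.append((pid, box(xa, ya, xa + plot_width, ya + plot_height)))
    return layout


def generate_raster(
    plot_layout: Sequence,
    plot_values: pd.DataFrame,
    pixel_size: float = 0.5,
    noise_scale: float = 0.008,
    seed: int = 0,
    pad_pixels: int = 1,
) -> RasterGrid:
    """Rasterise per-plot band means onto a north-up grid.

    Every pixel whose centre falls inside a plot polygon draws its five
    band values as ``plot mean + Gaussian(0, noise_scale)`` (clipped to
    [0, 1]); pixels outside all plots are nodata.  Overlapping plots are
    rejected.

    Parameters
    ----------
    plot_layout : sequence of (plot_id, shapely polygon).
    plot_values : DataFrame indexed by plot_id with the five band columns.
    """
    if pixel_size <= 0:
        raise ValueError("pixel_size must be > 0")
    ids = [pid for pid, _ in plot_layout]
    geoms = [g for _, g in plot_layout]
    if len(set(ids)) != len(ids):
        raise ValueError("plot ids must be unique")
    for i in range(len(geoms)):
        for j in range(i + 1, len(geoms)):
            if geoms[i].intersection(geoms[j]).area > 1e-12:
                raise ValueError(f"plots {ids[i]!r} and {ids[j]!r} overlap")
    missing = [pid for pid in ids if pid not in plot_values.index]
    if missing:
        raise ValueError(f"plot_values missing rows for plots: {missing}")
    for band in BAND_NAMES:
        if band not in plot_values.columns:
            raise ValueError(f"plot_values missing band column {band!r}")

    minx = min(g.bounds[0] for g in geoms)
    miny = min(g.bounds[1] for g in geoms)
    maxx = max(g.bounds[2] for g in geoms)
    maxy = max(g.bounds[3] for g in geoms)
    x_origin = minx - pad_pixels * pixel_size
    y_origin = maxy + pad_pixels * pixel_size
    n_cols = int(math.ceil((maxx - x_origin) / pixel_size)) + pad_pixels
    n_rows = int(math.ceil((y_origin - miny) / pixel_size)) + pad_pixels

    cols = np.arange(n_cols)
    rows = np.arange(n_rows)
    xs = x_origin + (cols + 0.5) * pixel_size
    ys = y_origin - (rows + 0.5) * pixel_size
    xx, yy = np.meshgrid(xs, ys)

    plot_index = np.full((n_rows, n_cols), -1, dtype=int)
    for k, geom in enumerate(geoms):
        inside = shapely.contains_xy(geom, xx.ravel(), yy.ravel()).reshape(n_rows, n_cols)
        plot_index[inside] = k

    rng = np.random.default_rng(seed)
    bands = np.full((len(BAND_NAMES), n_rows, n_cols), np.nan)
    mask = plot_index >= 0
    for bi, band in enumerate(BAND_NAMES):
        means = np.asarray(
            [plot_values.loc[pid, band] for pid in ids], dtype=float
        )
        surface = np.full((n_rows, n_cols), np.nan)
        surface[mask] = means[plot_index[mask]]
        if noise_scale > 0:
            surface[mask] = surface[mask] + rng.normal(0.0, noise_scale, size=int(mask.sum()))
        bands[bi] = np.clip(surface, 0.0, 1.0)
    return RasterGrid(
        bands=bands,
        band_names=BAND_NAMES,
        x_origin=x_origin,
        y_origin=y_origin,
        pixel_size=pixel_size,
        mask=mask,
        plot_ids=plot_index,
    )


def rasterize_stage(
    obs: pd.DataFrame,
    stage: str,
    pixel_size: float = 0.5,
    noise_scale: float = 0.008,
    seed: int = 0,
) -> tuple:
    """Build a synthetic field raster for one growth stage.

    Plot-level band means (across replicates) are laid out on a regular
    grid of rectangular plots, one per treatment, and rasterised.  Returns
    ``(raster, layout, plot_means)`` so callers can relate pixels back to
    treatments.
    """
    sub = obs[obs["stage"] == stage]
    if sub.empty:
        raise ValueError(f"no observations for stage {stage!r}")
    means = sub.groupby("treatment")[list(BAND_NAMES)].mean()
    layout = build_field_layout(list(means.index))
    raster = generate_raster(layout, means, pixel_size=pixel_size, noise_scale=noise_scale, seed=seed)
    return raster, layout, means
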