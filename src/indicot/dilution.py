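"""Critical nitrogen dilution curves and the nitrogen nutrition index.

The critical nitrogen concentration Nc is the minimum N concentration that
still supports maximum biomass; it declines with aboveground dry matter DM
(Mg ha⁻¹) as the power law ``Nc = a * DM**(-b)``, where ``a`` is the N
concentration at DM = 1 Mg ha⁻¹ and ``b`` the dilution exponent.  Under
drip irrigation both parameters respond to the seasonal irrigation amount I
(mm); quadratic responses a(I) and b(I) combine into a single
irrigation-aware model ``Nc(I, DM) = a(I) * DM**(-b(I))``.

The nitrogen nutrition index NNI = Ni / Nc (measured over critical
concentration) diagnoses status: < 1 deficient, = 1 optimal, > 1 surplus.

``COTTON_DILUTION_REFERENCE`` holds published per-irrigation parameter
values for upper-canopy leaves of drip-irrigated cotton in Xinjiang (four
irrigation levels, a in g g⁻¹-scale units as printed, b dimensionless);
the irrigation amounts are exact multiples of the full-irrigation season
total 405.32 mm.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = [
    "COTTON_DILUTION_REFERENCE",
    "DilutionCurve",
    "ParamResponse",
    "NNIRecord",
    "select_critical_points",
    "fit_power_dilution",
    "fit_quadratic_response",
    "fit_irrigation_responses",
    "nc_model",
    "compute_nni",
    "classify_nni",
    "fit_dilution_by_irrigation",
]

#: Published reference dilution-curve parameters for drip-irrigated cotton
#: (upper-canopy leaves) at 60/80/100/120 % of full irrigation.
COTTON_DILUTION_REFERENCE = pd.DataFrame(
    {
        "treatment": ["W0.6", "W0.8", "W1.0", "W1.2"],
        "irrigation_mm": [243.19, 324.26, 405.32, 486.38],
        "a": [0.0228, 0.0241, 0.0255, 0.0261],
        "b": [0.38, 0.40, 0.42, 0.43],
        "r_squared": [0.88, 0.91, 0.90, 0.88],
    }
)


@dataclass(frozen=True)
class DilutionCurve:
    """Fitted power-law dilution curve ``Nc = a * DM**(-b)``."""

    a: float
    b: float
    r_squared: float
    irrigation_mm: Optional[float] = None
    n_points: int = 0
    converged: bool = True

    def __post_init__(self) -> None:
        if self.a <= 0:
            raise ValueError("dilution parameter a must be > 0")
        if self.r_squared > 1.0 + 1e-12:
            raise ValueError("R² cannot exceed 1")
        if self.r_squared < 0:
            warnings.warn("negative R² in dilution fit (worse than the mean model)")

    def predict(self, dm) -> np.ndarray:
        dm = np.asarray(dm, dtype=float)
        if np.any(dm <= 0):
            raise ValueError("dry matter must be > 0")
        out = self.a * dm ** (-self.b)
        return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class ParamResponse:
    """Quadratic response of a dilution parameter to irrigation amount.

    ``value(I) = c2*I**2 + c1*I + c0`` over the fitted irrigation range.
    """

    name: str
    coefficients: tuple  # (c2, c1, c0)
    r_squared: float
    i_range: tuple = (None, None)

    def __call__(self, irrigation_mm, clamp: bool = True):
        i = np.asarray(irrigation_mm, dtype=float)
        lo, hi = self.i_range
        if lo is not None and clamp:
            if np.any((i < lo) | (i > hi)):
                warnings.warn(
                    f"irrigation amount outside fitted range [{lo:g}, {hi:g}] mm "
                    f"for parameter {self.name!r}; clamping to range endpoints"
                )
            i = np.clip(i, lo, hi)
        out = np.polyval(self.coefficients, i)
        return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class NNIRecord:
    """One nitrogen-nutrition-index diagnosis."""

    ni: float
    nc: float
    nni: float
    label: str


def select_critical_points(
    obs: pd.DataFrame,
    dm_col: str = "dm",
    n_col: str = "lnc_upper",
    date_col: str = "stage",
    rate_col: str = "n_rate",
    theta: float = 0.95,
) -> pd.DataFrame:
    """Select one (DMmax, Ncritical) pair per sampling date.

    For every date, treatment means are taken per N rate; ``DMmax`` is the
    largest mean dry matter across rates, and ``Ncritical`` is the mean N
    concentration of the *lowest* N rate whose mean DM reaches
    ``theta * DMmax`` (a plateau rule: the cheapest rate already achieving
    near-maximum growth pins the critical concentration).  Dates where no
    rate qualifies are skipped with a warning.
    """
    if not 0 < theta <= 1:
        raise ValueError("theta must be in (0, 1]")
    rows = []
    for date, grp in obs.groupby(date_col, sort=False):
        means = grp.groupby(rate_col)[[dm_col, n_col]].mean()
        if len(means) < 2:
            warnings.warn(f"date {date!r} has fewer than 2 N rates; skipped")
            continue
        if (means[dm_col] <= 0).any():
            raise ValueError(f"non-positive dry matter mean at date {date!r}")
        dm_max = means[dm_col].max()
        qualifying = means[means[dm_col] >= theta * dm_max]
        if qualifying.empty:  # cannot happen for theta <= 1, kept for safety
            warnings.warn(f"no N rate reaches {theta}·DMmax at date {date!r}; skipped")
            continue
        rate = qualifying.index.min()
        rows.append(
            {
                date_col: date,
                "n_rate": rate,
                "dm_max": dm_max,
                "n_critical": means.loc[rate, n_col],
            }
        )
    return pd.DataFrame(rows)


def _r_squared(y: np.ndarray, yhat: np.ndarray) -> float:
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - np.mean(y)) ** 2))
    if ss_tot == 0:
        return 1.0 if ss_res == 0 else 0.0
    return 1.0 - ss_res / ss_tot


def fit_power_dilution(
    dm: Sequence[float],
    n: Sequence[float],
    irrigation_mm: Optional[float] = None,
) -> DilutionCurve:
    """Fit ``Nc = a * DM**(-b)`` by nonlinear least squares.

    Initial values come from ordinary least squares on the log–log form;
    R² is computed on the original (not log) scale.  If the nonlinear
    optimiser fails, the closed-form log–log fit is returned flagged as
    non-converged.
    """
    dm = np.asarray(dm, dtype=float)
    n = np.asarray(n, dtype=float)
    if dm.shape != n.shape or dm.size < 3:
        raise ValueError("need >= 3 aligned (DM, N) points")
    if np.any(dm <= 0) or np.any(n <= 0):
        raise ValueError("DM and N must be strictly positive")

    slope, intercept = np.polyfit(np.log(dm), np.log(n), 1)
    a0, b0 = float(np.exp(intercept)), float(-slope)

    def model(x, a, b):
        return a * x ** (-b)

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, _ = curve_fit(model, dm, n, p0=(a0, max(b0, 0.0)), maxfev=10000)
        a_hat, b_hat = float(popt[0]), float(popt[1])
        converged = True
    except RuntimeError:
        a_hat, b_hat, converged = a0, b0, False
        warnings.warn("power-law fit did not converge; log–log closed form used")
    r2 = _r_squared(n, model(dm, a_hat, b_hat))
    return DilutionCurve(
        a=a_hat, b=b_hat, r_squared=r2, irrigation_mm=irrigation_mm,
        n_points=int(dm.size), converged=converged,
    )


def fit_quadratic_response(
    irrigation_mm: Sequence[float],
    values: Sequence[float],
    name: str = "a",
) -> ParamResponse:
    """Ordinary-least-squares quadratic of a dilution parameter versus I."""
    i = np.asarray(irrigation_mm, dtype=float)
    v = np.asarray(values, dtype=float)
    if i.shape != v.shape:
        raise ValueError("irrigation amounts and values must align")
    if np.unique(i).size < 3:
        raise ValueError("need >= 3 distinct irrigation amounts for a quadratic fit")
    coeffs = np.polyfit(i, v, 2)
    r2 = _r_squared(v, np.polyval(coeffs, i))
    return ParamResponse(
        name=name,
        coefficients=tuple(float(c) for c in coeffs),
        r_squared=r2,
        i_range=(float(i.min()), float(i.max())),
    )


def fit_irrigation_responses(curves: Iterable[DilutionCurve]) -> tuple:
    """Fit a(I) and b(I) quadratics from per-irrigation dilution curves."""
    curves = list(curves)
    ivals = [c.irrigation_mm for c in curves]
    if any(v is None for v in ivals):
        raise ValueError("every curve needs its irrigation amount set")
    a_resp = fit_quadratic_response(ivals, [c.a for c in curves], name="a")
    b_resp = fit_quadratic_response(ivals, [c.b for c in curves], name="b")
    return a_resp, b_resp


def nc_model(irrigation_mm, dm, a_response: ParamResponse, b_response: ParamResponse):
    """Irrigation-aware critical concentration ``Nc = a(I) * DM**(-b(I))``.

    Irrigation amounts outside the fitted range are clamped (with a
    warning) rather than extrapolated, because an extrapolated quadratic
    a(I) can turn non-positive.
    """
    dm = np.asarray(dm, dtype=float)
    if np.any(dm <= 0):
        raise ValueError("dry matter must be > 0")
    a = np.asarray(a_response(irrigation_mm), dtype=float)
    b = np.asarray(b_response(irrigation_mm), dtype=float)
    if np.any(a <= 0):
        raise ValueError("a(I) <= 0 at the requested irrigation amount; model breakdown")
    out = a * dm ** (-b)
    return float(out) if out.ndim == 0 else out


def classify_nni(nni, delta: float = 0.05):
    """Three-level diagnosis around the NNI = 1 optimum.

    deficient if ``nni < 1 - delta``; surplus if ``nni > 1 + delta``;
    optimal otherwise.  ``delta = 0`` reproduces the strict rule (< 1
    deficient, > 1 surplus, = 1 optimal).
    """
    if delta < 0:
        raise ValueError("delta must be >= 0")
    nni_arr = np.asarray(nni, dtype=float)
    if np.any(nni_arr < 0):
        raise ValueError("NNI must be >= 0")
    out = np.where(
        nni_arr < 1.0 - delta, "deficient", np.where(nni_arr > 1.0 + delta, "surplus", "optimal")
    )
    return str(out) if out.ndim == 0 else out


def compute_nni(ni: float, nc: float, delta: float = 0.05) -> NNIRecord:
    """Nitrogen nutrition index ``NNI = Ni / Nc`` with its diagnosis label."""
    if nc <= 0:
        raise ValueError("critical concentration Nc must be > 0")
    if ni < 0:
        raise ValueError("measured concentration Ni must be >= 0")
    nni = ni / nc
    return NNIRecord(ni=float(ni), nc=float(nc), nni=float(nni), label=classify_nni(nni, delta))


def fit_dilution_by_irrigation(
    obs: pd.DataFrame,
    dm_col: str = "dm",
    n_col: str = "lnc_upper",
    date_col: str = "stage",
    rate_col: str = "n_rate",
    irrigation_col: str = "irrigation_mm",
    group_col: str = "irrigation_fraction",
    theta: float = 0.95,
) -> pd.DataFrame:
    """Per-irrigation-level dilution-curve fits from a plot table.

    For each irrigation level: select critical (DMmax, Ncritical) points per
    date, fit the power law, and report one row of (irrigation amount, a, b,
    R²) — the tabular surface a practitioner publishes for the curves.
    """
    rows = []
    for level, grp in obs.groupby(group_col, sort=True):
        pts = select_critical_points(
            grp, dm_col=dm_col, n_col=n_col, date_col=date_col,
            rate_col=rate_col, theta=theta,
        )
        if len(pts) < 3:
            warnings.warn(f"irrigation level {level!r}: fewer than 3 critical points; skipped")
            continue
        irr = float(grp[irrigation_col].mean())
        curve = fit_power_dilution(pts["dm_max"], pts["n_critical"], irrigation_mm=irr)
        rows.append(
            {
                group_col: level,
                "irrigation_mm": irr,
                "a": curve.a,
                "b": curve.b,
                "r_squared": curve.r_squared,
                "n_points": curve.n_points,
            }
        )
    return pd.DataFrame(rows)
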