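"""Trait inversion from vegetation indices and nitrogen-status mapping.

The workflow mirrors standard UAV trait-retrieval practice: Pearson
screening of candidate vegetation indices against the target (|r| > 0.6
strictly), collinearity pruning (pairwise |r| > 0.90, then VIF > 10),
tree-ensemble regression (bagged trees / gradient boosting / regularised
gradient boosting a.k.a. XGBoost) tuned by 5-fold cross-validation on a
stratified 70/30 split, and finally pixel-level application of the fitted
model to a five-band raster with a three-class nitrogen-status surface
derived through a per-stage linear INDI→NNI link.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import linregress
from sklearn.ensemble import GradientBoostingRegressor, RandomForestRegressor
from sklearn.model_selection import GridSearchCV, KFold, train_test_split
from xgboost import XGBRegressor

from .dilution import classify_nni
from .raster import CLASS_CODES, RasterGrid
from .spectral import BAND_NAMES, compute_all_vis

__all__ = [
    "DEFAULT_FEATURES",
    "FeatureScreenReport",
    "ModelSpec",
    "EvaluationResult",
    "add_vegetation_indices",
    "pearson_screen",
    "vif",
    "collinearity_filter",
    "evaluate_metrics",
    "train_inversion_model",
    "invert_raster",
    "indi_nni_link",
    "classify_map",
]

#: Index sets reported as final model inputs per target (reproducibility
#: defaults); data-driven screening is the alternative mode.
DEFAULT_FEATURES = {
    "lai": ("MRETVI", "RVI", "RERVI"),
    "lnw_upper": ("NGBDI", "NGI", "NDRE"),
    "indi": ("MRETVI", "RERVI", "NLI", "EVI"),
}

MODEL_FAMILIES = (
    "bagged_trees",
    "gradient_boosted_trees",
    "regularized_gradient_boosted_trees",
)


@dataclass
class FeatureScreenReport:
    """Outcome of feature screening / collinearity filtering.

    ``correlations`` holds every candidate's Pearson r with the target;
    ``removed`` maps each dropped feature to the reason it was dropped.
    """

    correlations: dict
    selected: list
    removed: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in self.selected:
            if name in self.removed:
                raise ValueError(f"feature {name!r} both selected and removed")


@dataclass(frozen=True)
class ModelSpec:
    """Ensemble-regression configuration.

    ``family`` picks the estimator; the grid covers the tuned
    hyperparameters (number of trees, maximum depth, learning rate where
    applicable, minimum samples to split).  Training uses a seeded 70/30
    train/validation split and 5-fold cross-validated grid search on the
    training portion; everything is single-threaded for reproducibility.
    """

    family: str = "regularized_gradient_boosted_trees"
    n_estimators: tuple = (100, 300)
    max_depth: tuple = (3, 5)
    learning_rate: tuple = (0.05, 0.1)
    min_samples_split: tuple = (2, 5)
    folds: int = 5
    train_fraction: float = 0.70
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in MODEL_FAMILIES:
            raise ValueError(f"unknown family {self.family!r}; valid: {MODEL_FAMILIES}")
        if self.folds < 2:
            raise ValueError("folds must be >= 2")
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must be in (0, 1)")

    def build_estimator(self):
        if self.family == "bagged_trees":
            return RandomForestRegressor(random_state=self.seed, n_jobs=1)
        if self.family == "gradient_boosted_trees":
            return GradientBoostingRegressor(random_state=self.seed)
        return XGBRegressor(
            random_state=self.seed, n_jobs=1, verbosity=0, objective="reg:squarederror"
        )

    def param_grid(self) -> dict:
        grid = {"n_estimators": list(self.n_estimators), "max_depth": list(self.max_depth)}
        if self.family == "bagged_trees":
            grid["min_samples_split"] = list(self.min_samples_split)
        elif self.family == "gradient_boosted_trees":
            grid["learning_rate"] = list(self.learning_rate)
            grid["min_samples_split"] = list(self.min_samples_split)
        else:
            grid["learning_rate"] = list(self.learning_rate)
            # xgboost's analogue of a minimum-samples constraint
            grid["min_child_weight"] = [max(1, v // 2) for v in self.min_samples_split]
        return grid


@dataclass(frozen=True)
class EvaluationResult:
    """Goodness-of-fit metrics on a (held-out) sample set.

    R² = 1 − SSE/SST; RMSE = sqrt(SSE/n) in target units;
    RE = mean(|ŷ−y| / |y|) × 100 %, undefined (NaN, flagged) if any y = 0.
    """

    r2: float
    rmse: float
    re_pct: float
    n: int
    re_defined: bool = True


def add_vegetation_indices(obs: pd.DataFrame, strict: bool = False) -> pd.DataFrame:
    """Append the 14 vegetation-index columns to a plot table."""
    bands = {b: obs[b].to_numpy(dtype=float) for b in BAND_NAMES}
    vis = compute_all_vis(bands, strict=strict)
    out = obs.copy()
    for name, vals in vis.items():
        out[name] = vals
    return out


def pearson_screen(
    features: pd.DataFrame, target, threshold: float = 0.6
) -> FeatureScreenReport:
    """Keep features whose |Pearson r| with the target is strictly > threshold."""
    y = np.asarray(target, dtype=float)
    if len(features) != y.size or y.size < 3:
        raise ValueError("need >= 3 aligned samples")
    correlations, selected, removed = {}, [], {}
    for name in features.columns:
        x = features[name].to_numpy(dtype=float)
        if np.std(x) == 0 or np.any(~np.isfinite(x)):
            correlations[name] = np.nan
            removed[name] = "undefined correlation (constant or non-finite feature)"
            continue
        r = float(np.corrcoef(x, y)[0, 1])
        correlations[name] = r
        if abs(r) > threshold:
            selected.append(name)
        else:
            removed[name] = f"|r| = {abs(r):.3f} <= {threshold}"
    return FeatureScreenReport(correlations=correlations, selected=selected, removed=removed)


def vif(features: pd.DataFrame) -> pd.Series:
    """Variance inflation factor per feature.

    ``VIF_j = 1 / (1 − R²_j)`` with R²_j from regressing feature j on all
    other features (intercept included).  Perfect collinearity is reported
    as +inf.
    """
    x = features.to_numpy(dtype=float)
    n, p = x.shape
    if n < p + 2:
        raise ValueError("need at least n_features + 2 samples for VIFs")
    if np.any(x.std(axis=0) == 0):
        raise ValueError("constant features have undefined VIF; remove them first")
    out = {}
    for j, name in enumerate(features.columns):
        yj = x[:, j]
        others = np.delete(x, j, axis=1)
        design = np.column_stack([np.ones(n), others])
        beta, *_ = np.linalg.lstsq(design, yj, rcond=None)
        resid = yj - design @ beta
        ss_tot = float(np.sum((yj - yj.mean()) ** 2))
        r2 = 1.0 - float(np.sum(resid**2)) / ss_tot
        out[name] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return pd.Series(out, name="vif")


def collinearity_filter(
    features: pd.DataFrame,
    target,
    r_max: float = 0.90,
    vif_max: float = 10.0,
) -> FeatureScreenReport:
    """Prune redundant features, one at a time, deterministically.

    First resolves every pairwise |r| > ``r_max`` by dropping the pair
    member with the weaker |r| against the target; then, while any VIF
    exceeds ``vif_max``, drops the feature with the highest VIF.  Each
    removal is logged with its reason.
    """
    y = np.asarray(target, dtype=float)
    kept = list(features.columns)
    removed = {}
    target_r = {
        name: abs(float(np.corrcoef(features[name], y)[0, 1])) for name in kept
    }

    def worst_pair():
        best = None
        for i in range(len(kept)):
            for j in range(i + 1, len(kept)):
                r = abs(float(np.corrcoef(features[kept[i]], features[kept[j]])[0, 1]))
                if r > r_max and (best is None or r > best[0]):
                    best = (r, kept[i], kept[j])
        return best

    while True:
        pair = worst_pair()
        if pair is None:
            break
        r, a, b = pair
        drop = a if target_r[a] < target_r[b] else b
        keep = b if drop == a else a
        removed[drop] = f"pairwise |r| = {r:.3f} > {r_max} with {keep!r}, weaker target correlation"
        kept.remove(drop)

    while len(kept) >= 2:
        vifs = vif(features[kept])
        worst = vifs.idxmax()
        if vifs[worst] <= vif_max:
            break
        removed[worst] = f"VIF = {vifs[worst]:.2f} > {vif_max}"
        kept.remove(worst)

    if not kept:
        raise ValueError(
            "collinearity filtering removed every feature; relax r_max/vif_max"
        )
    correlations = {name: target_r.get(name, np.nan) for name in features.columns}
    return FeatureScreenReport(correlations=correlations, selected=kept, removed=removed)


def evaluate_metrics(y_obs, y_pred) -> EvaluationResult:
    """R², RMSE and relative error between observed and predicted values."""
    y = np.asarray(y_obs, dtype=float)
    yhat = np.asarray(y_pred, dtype=float)
    if y.shape != yhat.shape or y.size < 2:
        raise ValueError("need >= 2 aligned observation/prediction pairs")
    sse = float(np.sum((y - yhat) ** 2))
    sst = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - sse / sst if sst > 0 else (1.0 if sse == 0 else 0.0)
    rmse = float(np.sqrt(sse / y.size))
    if np.any(y == 0):
        re_pct, re_defined = float("nan"), False
    else:
        re_pct = float(np.mean(np.abs(yhat - y) / np.abs(y)) * 100.0)
        re_defined = True
    return EvaluationResult(r2=r2, rmse=rmse, re_pct=re_pct, n=int(y.size), re_defined=re_defined)


def train_inversion_model(
    X: pd.DataFrame,
    y,
    spec: ModelSpec = ModelSpec(),
    stage_labels=None,
) -> tuple:
    """Fit one ensemble family with CV-tuned hyperparameters.

    A seeded 70/30 split (stratified by growth stage when labels are
    given) separates calibration from validation; a 5-fold grid search on
    the calibration portion picks hyperparameters, the winner is refitted
    on the whole calibration set, and metrics are reported on the held-out
    30 %.  Returns ``(fitted_model, EvaluationResult, details)`` where
    ``details`` records the split indices, best hyperparameters and
    per-sample validation predictions.
    """
    X = pd.DataFrame(X)
    y = np.asarray(y, dtype=float)
    if len(X) != y.size:
        raise ValueError("X and y must align")
    n_val = int(round((1.0 - spec.train_fraction) * y.size))
    if y.size - n_val < spec.folds:
        raise ValueError("too few training samples for the requested folds")

    idx = np.arange(y.size)
    strat = None if stage_labels is None else np.asarray(stage_labels)
    train_idx, val_idx = train_test_split(
        idx,
        test_size=1.0 - spec.train_fraction,
        random_state=spec.seed,
        stratify=strat,
    )
    cv = KFold(n_splits=spec.folds, shuffle=True, random_state=spec.seed)
    search = GridSearchCV(
        spec.build_estimator(),
        spec.param_grid(),
        cv=cv,
        scoring="neg_root_mean_squared_error",
        n_jobs=1,
        refit=True,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        search.fit(X.iloc[train_idx], y[train_idx])
    model = search.best_estimator_
    y_pred = np.asarray(model.predict(X.iloc[val_idx]), dtype=float)
    result = evaluate_metrics(y[val_idx], y_pred)
    details = {
        "train_index": train_idx,
        "validation_index": val_idx,
        "best_params": dict(search.best_params_),
        "validation_predictions": y_pred,
        "cv_best_score": float(search.best_score_),
    }
    return model, result, details


def invert_raster(model, raster: RasterGrid, feature_names: Sequence[str]) -> RasterGrid:
    """Pixel-level application of a fitted inversion model.

    For every valid pixel the selected vegetation indices are computed
    from the five bands and fed to the model; nodata pixels and pixels
    with any NaN index propagate to nodata.  The result is a copy of the
    raster carrying the predicted INDI surface.
    """
    for band in BAND_NAMES:
        if band not in raster.band_names:
            raise ValueError(f"raster is missing required band {band!r}")
    out = raster.copy()
    bands = raster.band_dict()
    rows, cols = raster.shape
    vis = compute_all_vis({b: bands[b].ravel() for b in BAND_NAMES})
    feats = np.column_stack([np.asarray(vis[name], dtype=float) for name in feature_names])
    valid = raster.mask.ravel() & np.all(np.isfinite(feats), axis=1)
    surface = np.full(rows * cols, np.nan)
    if valid.any():
        X = pd.DataFrame(feats[valid], columns=list(feature_names))
        surface[valid] = np.asarray(model.predict(X), dtype=float)
    out.indi = surface.reshape(rows, cols)
    out.mask = valid.reshape(rows, cols)
    return out


def indi_nni_link(indi, nni, stages, min_samples: int = 3) -> dict:
    """Per-stage ordinary-least-squares line ``NNI = slope·INDI + intercept``.

    Returns ``{stage: {"slope", "intercept", "r2", "n"}}``.  A stage with
    fewer than ``min_samples`` samples or degenerate INDI variance is
    rejected.
    """
    indi = pd.Series(np.asarray(indi, dtype=float)).reset_index(drop=True)
    nni = pd.Series(np.asarray(nni, dtype=float)).reset_index(drop=True)
    stages = pd.Series(stages).reset_index(drop=True)
    links = {}
    for stage, idx in stages.groupby(stages).groups.items():
        x, yv = indi.loc[idx], nni.loc[idx]
        if len(x) < min_samples:
            raise ValueError(f"stage {stage!r} has fewer than {min_samples} samples")
        if x.std(ddof=0) == 0:
            raise ValueError(f"stage {stage!r} has degenerate INDI variance")
        fit = linregress(x, yv)
        links[stage] = {
            "slope": float(fit.slope),
            "intercept": float(fit.intercept),
            "r2": float(fit.rvalue**2),
            "n": int(len(x)),
        }
    return links


def classify_map(
    indi_surface: np.ndarray,
    stage: str,
    links: Mapping[str, Mapping[str, float]],
    delta: float = 0.05,
    mask: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Three-class nitrogen-status surface from an INDI surface.

    Each pixel's INDI maps through the stage's linear INDI→NNI link to a
    predicted NNI, classified with the ±delta band around the NNI = 1
    optimum.  Byte codes: 0 nodata, 1 deficient, 2 adequate, 3 excessive.
    """
    if stage not in links:
        raise ValueError(f"no INDI→NNI link fitted for stage {stage!r}")
    link = links[stage]
    surf = np.asarray(indi_surface, dtype=float)
    valid = np.isfinite(surf)
    if mask is not None:
        valid &= np.asarray(mask, dtype=bool)
    nni = link["slope"] * surf + link["intercept"]
    out = np.zeros(surf.shape, dtype=np.uint8)
    labels = classify_nni(np.clip(np.where(valid, nni, 1.0), 0.0, None), delta=delta)
    label_to_code = {"deficient": CLASS_CODES["deficient"],
                     "optimal": CLASS_CODES["adequate"],
                     "surplus": CLASS_CODES["excessive"]}
    for label, code in label_to_code.items():
        out[valid & (labels == label)] = code
    return out
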