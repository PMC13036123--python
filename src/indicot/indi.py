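"""Integrated Nitrogen Diagnosis Index (INDI) construction.

INDI is a weighted linear combination of stage-wise standardised nitrogen
indicators — by default leaf area index (LAI) and upper-canopy leaf
nitrogen weight (LNWupper):

    INDI_sample = Σ_i w_i · Z(X_i, sample)

where Z standardises each indicator *within its growth stage* (removing
stage-scale differences) and the weights come from one of three schemes:

* ``inverse_cv`` — w_i ∝ 1/CV_i, CV the coefficient of variation of the
  *raw* indicator pooled across treatments and stages.  Indicators with
  lower relative variability contribute more, stabilising the index.
* ``equal`` — w_i = 1/n.
* ``entropy`` — the entropy-weight method: min–max scale each indicator,
  form column proportions, compute Shannon entropy e_j with the 1/ln m
  normaliser, and weight by the divergence d_j = 1 − e_j.

CVs are deliberately computed on raw values and standardisation applied
stage-wise: the CV of a stage-standardised column is undefined (mean 0),
so only this ordering gives a single well-defined global weight pair.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

__all__ = [
    "WeightingResult",
    "IndiResult",
    "coefficient_of_variation",
    "inverse_cv_weights",
    "equal_weights",
    "entropy_weights",
    "zscore_by_stage",
    "compute_indi",
    "build_indi",
    "scheme_agreement",
]

SCHEMES = ("inverse_cv", "equal", "entropy")


@dataclass(frozen=True)
class WeightingResult:
    """Per-indicator weights for one scheme, with intermediates.

    ``intermediates`` holds the CVs (inverse_cv) or entropies/divergences
    (entropy) behind the weights; empty for equal weighting.
    """

    scheme: str
    indicator_names: tuple
    weights: tuple
    intermediates: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if len(self.indicator_names) != w.size:
            raise ValueError("one weight per indicator required")
        if np.any(w < 0):
            raise ValueError("weights must be non-negative")
        if abs(w.sum() - 1.0) > 1e-12:
            raise ValueError(f"weights must sum to 1 (got {w.sum()!r})")

    def as_series(self) -> pd.Series:
        return pd.Series(self.weights, index=list(self.indicator_names), name=self.scheme)


@dataclass
class IndiResult:
    """INDI values plus the standardised scores and weights behind them."""

    weights: WeightingResult
    zscores: pd.DataFrame  # one column per indicator, stage-wise standardised
    indi: pd.Series
    stages: pd.Series


def coefficient_of_variation(values, ddof: int = 1) -> float:
    """CV = sample standard deviation / mean (dimensionless).

    Requires >= 2 values and a strictly positive mean; a CV of a
    near-zero-mean variable is meaningless and is rejected.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("need at least 2 values for a CV")
    mean = v.mean()
    if mean <= 1e-12:
        raise ValueError(f"CV undefined: mean must be strictly positive (got {mean:g})")
    return float(v.std(ddof=ddof) / mean)


def inverse_cv_weights(cvs: Sequence[float], names: Optional[Sequence[str]] = None) -> WeightingResult:
    """Normalised inverse-CV weights: ``w_i = (1/CV_i) / Σ_k (1/CV_k)``."""
    cvs = np.asarray(cvs, dtype=float)
    if np.any(cvs <= 0):
        raise ValueError("all CVs must be > 0 for inverse-CV weighting")
    inv = 1.0 / cvs
    w = inv / inv.sum()
    names = tuple(names) if names is not None else tuple(f"x{i+1}" for i in range(cvs.size))
    return WeightingResult(
        scheme="inverse_cv",
        indicator_names=names,
        weights=tuple(float(x) for x in w),
        intermediates={"cv": dict(zip(names, cvs.tolist()))},
    )


def equal_weights(n: int, names: Optional[Sequence[str]] = None) -> WeightingResult:
    """Equal weighting: each of the n indicators gets 1/n."""
    if n < 1:
        raise ValueError("need at least one indicator")
    names = tuple(names) if names is not None else tuple(f"x{i+1}" for i in range(n))
    return WeightingResult(
        scheme="equal", indicator_names=names, weights=tuple([1.0 / n] * n)
    )


def entropy_weights(matrix, names: Optional[Sequence[str]] = None, eps: float = 1e-6) -> WeightingResult:
    """Entropy-weight method over an (m samples × n indicators) matrix.

    Each indicator column is min–max scaled to [0, 1] and shifted by
    ``eps`` (so zero proportions never enter the logarithm), converted to
    proportions p_ij, and scored by Shannon entropy
    ``e_j = −(1/ln m) Σ_i p_ij ln p_ij``.  The weight of indicator j is its
    normalised divergence ``d_j / Σ d_k`` with ``d_j = 1 − e_j``: columns
    that discriminate more among samples weigh more.  A constant column
    carries no information and gets weight 0; an all-constant matrix is
    rejected.
    """
    if isinstance(matrix, pd.DataFrame):
        if names is None:
            names = tuple(matrix.columns)
        matrix = matrix.to_numpy(dtype=float)
    x = np.asarray(matrix, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("need an (m >= 2 samples) x (n indicators) matrix")
    m, n = x.shape
    names = tuple(names) if names is not None else tuple(f"x{i+1}" for i in range(n))

    rng_span = x.max(axis=0) - x.min(axis=0)
    divergences = np.zeros(n)
    entropies = np.full(n, 1.0)
    for j in range(n):
        if rng_span[j] == 0:
            continue  # constant column: entropy 1, divergence 0
        scaled = (x[:, j] - x[:, j].min()) / rng_span[j] + eps
        p = scaled / scaled.sum()
        entropies[j] = float(-(p * np.log(p)).sum() / np.log(m))
        divergences[j] = 1.0 - entropies[j]
    total = divergences.sum()
    if total <= 0:
        raise ValueError("all indicators are constant: entropy weights undefined")
    w = divergences / total
    return WeightingResult(
        scheme="entropy",
        indicator_names=names,
        weights=tuple(float(v) for v in w),
        intermediates={
            "entropy": dict(zip(names, entropies.tolist())),
            "divergence": dict(zip(names, divergences.tolist())),
        },
    )


def zscore_by_stage(values, stages, ddof: int = 1) -> pd.Series:
    """Stage-wise z-scores: ``(x − stage mean) / stage sample SD``.

    Every stage needs >= 2 samples and nonzero dispersion; a degenerate
    stage is reported by name.
    """
    v = pd.Series(np.asarray(values, dtype=float))
    s = pd.Series(stages).reset_index(drop=True)
    if len(v) != len(s):
        raise ValueError("values and stage labels must align")
    out = pd.Series(np.nan, index=v.index)
    for stage, idx in s.groupby(s).groups.items():
        grp = v.loc[idx]
        if len(grp) < 2:
            raise ValueError(f"stage {stage!r} has fewer than 2 samples")
        sd = grp.std(ddof=ddof)
        if sd == 0 or not np.isfinite(sd):
            raise ValueError(f"stage {stage!r} has zero dispersion; z-scores undefined")
        out.loc[idx] = (grp - grp.mean()) / sd
    return out


def compute_indi(zscores, weights: WeightingResult) -> pd.Series:
    """Weighted linear combination of standardised indicators."""
    z = pd.DataFrame(zscores)
    if z.shape[1] != len(weights.weights):
        raise ValueError(
            f"{z.shape[1]} indicator columns but {len(weights.weights)} weights"
        )
    w = np.asarray(weights.weights, dtype=float)
    return pd.Series(z.to_numpy(dtype=float) @ w, index=z.index, name="indi")


def build_indi(
    obs: pd.DataFrame,
    indicators: Sequence[str] = ("lai", "lnw_upper"),
    scheme: str = "inverse_cv",
    stage_col: str = "stage",
    ddof: int = 1,
) -> IndiResult:
    """End-to-end INDI construction from a plot table.

    Weights are global (one set for the whole dataset): CVs/entropies use
    the raw indicator columns pooled over all stages and treatments, while
    standardisation is applied within each stage.
    """
    if scheme not in SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}; valid schemes: {SCHEMES}")
    missing = [c for c in list(indicators) + [stage_col] if c not in obs.columns]
    if missing:
        raise ValueError(f"observation table missing columns: {missing}")

    names = tuple(indicators)
    if scheme == "inverse_cv":
        cvs = [coefficient_of_variation(obs[c], ddof=ddof) for c in names]
        weights = inverse_cv_weights(cvs, names)
    elif scheme == "equal":
        weights = equal_weights(len(names), names)
    else:
        weights = entropy_weights(obs[list(names)], names)

    z = pd.DataFrame(
        {c: zscore_by_stage(obs[c].to_numpy(), obs[stage_col], ddof=ddof).to_numpy() for c in names},
        index=obs.index,
    )
    indi = compute_indi(z, weights)
    return IndiResult(weights=weights, zscores=z, indi=indi, stages=obs[stage_col])


def scheme_agreement(
    indi_by_scheme: dict,
    stages,
    min_samples: int = 3,
) -> pd.DataFrame:
    """Per-stage Spearman rank correlation between INDI scheme pairs.

    Returns a tidy frame (stage, scheme_a, scheme_b, rho).  Ties receive
    average ranks (scipy convention).  Stages with fewer than
    ``min_samples`` samples are skipped with a warning.
    """
    import warnings

    schemes = list(indi_by_scheme)
    stages = pd.Series(stages).reset_index(drop=True)
    series = {k: pd.Series(np.asarray(v, dtype=float)).reset_index(drop=True) for k, v in indi_by_scheme.items()}
    rows = []
    for stage, idx in stages.groupby(stages).groups.items():
        if len(idx) < min_samples:
            warnings.warn(f"stage {stage!r} has fewer than {min_samples} samples; skipped")
            continue
        for i in range(len(schemes)):
            for j in range(i + 1, len(schemes)):
                rho = spearmanr(series[schemes[i]].loc[idx], series[schemes[j]].loc[idx]).statistic
                rows.append(
                    {"stage": stage, "scheme_a": schemes[i], "scheme_b": schemes[j], "rho": float(rho)}
                )
    return pd.DataFrame(rows)
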