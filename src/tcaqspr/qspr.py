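"""Correlation, single-descriptor linear regression, and RBF-kernel SVR.

The modelling stage relates one topological index (the descriptor ``t``) to
one physicochemical property (the response ``u``) at a time:

* Pearson correlation per (index, property) cell, as a 5 x 6 matrix per
  hydrogen mode.
* Ordinary least squares ``u = v + w t`` fitted on *all* observations (no
  train/test split), scored by the coefficient of determination
  ``R² = 1 - Σ(z - ẑ)² / Σ(z - z̄)²`` and by ``RMSE = sqrt(mean((z - ẑ)²))``
  with denominator ``n``.  For a single-descriptor OLS fit on the full data,
  ``R²`` equals the squared Pearson coefficient — an identity used as an
  internal consistency check.
* ε-insensitive support vector regression with the RBF kernel
  ``K(x, y) = exp(-α ‖x - y‖²)``, tuned by exhaustive grid search
  (``C ∈ {10, 50, 100, 500}``, ``ε ∈ {0.1, 0.2, 0.3, 0.4, 0.5}``,
  ``gamma ∈ {scale, auto}`` — 40 combinations) using mean 5-fold
  cross-validated R² on an 80 % training split, then refit on the full
  training split and scored on the held-out 20 %.  The dual optimisation is
  delegated to scikit-learn's :class:`~sklearn.svm.SVR`; this module fixes
  the objective, kernel, grid, and selection protocol.

Everything is deterministic given the seed that drives the train/test split
and the fold shuffling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence, Union

import numpy as np
import pandas as pd
from sklearn.metrics import r2_score
from sklearn.model_selection import KFold, train_test_split
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVR

from .molgraph import HydrogenMode

__all__ = [
    "ConstantColumnError",
    "DegenerateFitError",
    "ConfigurationError",
    "CorrelationMatrix",
    "LRFit",
    "SVRSpec",
    "SVRResult",
    "ScalingTransform",
    "pearson_matrix",
    "fit_lr",
    "rbf_kernel",
    "feature_scaling",
    "tune_svr",
    "select_best_index",
]


class ConstantColumnError(ValueError):
    """A correlation or scaling input column is constant (undefined result)."""


class DegenerateFitError(ValueError):
    """The regression design is degenerate (constant descriptor, n too small)."""


class ConfigurationError(ValueError):
    """An SVR tuning specification is invalid for the given data."""


@dataclass(frozen=True)
class CorrelationMatrix:
    """Pearson coefficients, indices (rows) x properties (columns)."""

    mode: HydrogenMode | None
    r: pd.DataFrame


@dataclass(frozen=True)
class LRFit:
    """Full-data single-descriptor OLS fit and its quality metrics."""

    property: str
    index: str
    mode: str | None
    intercept: float
    slope: float
    r2: float
    rmse: float
    n: int

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self.intercept + self.slope * np.asarray(x, dtype=float)


@dataclass(frozen=True)
class SVRSpec:
    """Grid and protocol for RBF-SVR tuning.

    The defaults are the study protocol: 80/20 split, 5-fold CV on the
    training part, a 4 x 5 x 2 = 40-point grid, features standardized inside
    the CV pipeline, targets left on their raw scale (ε is in target units).
    """

    c_grid: tuple[float, ...] = (10.0, 50.0, 100.0, 500.0)
    epsilon_grid: tuple[float, ...] = (0.1, 0.2, 0.3, 0.4, 0.5)
    gamma_modes: tuple[str, ...] = ("scale", "auto")
    split_fraction: float = 0.8
    cv_folds: int = 5
    seed: int = 42
    scale_features: bool = True

    def __post_init__(self) -> None:
        if any(c <= 0 for c in self.c_grid):
            raise ConfigurationError("C must be positive")
        if any(e < 0 for e in self.epsilon_grid):
            raise ConfigurationError("epsilon must be non-negative")
        if any(g not in ("scale", "auto") for g in self.gamma_modes):
            raise ConfigurationError("gamma mode must be 'scale' or 'auto'")
        if not self.c_grid or not self.epsilon_grid or not self.gamma_modes:
            raise ConfigurationError("empty hyperparameter grid")
        if not 0 < self.split_fraction < 1:
            raise ConfigurationError("split_fraction must lie in (0, 1)")
        if self.cv_folds < 2:
            raise ConfigurationError("cv_folds must be >= 2")

    @property
    def grid_size(self) -> int:
        return len(self.c_grid) * len(self.epsilon_grid) * len(self.gamma_modes)


@dataclass(frozen=True)
class SVRResult:
    """Outcome of one tuned SVR: chosen hyperparameters and test metrics."""

    property: str
    index: str
    mode: str | None
    C: float
    epsilon: float
    gamma: str
    cv_r2: float
    test_r2: float
    test_rmse: float
    seed: int
    scaled: bool


def _column(x: Sequence[float] | np.ndarray, name: str = "x") -> np.ndarray:
    arr = np.asarray(x, dtype=float).ravel()
    if arr.size == 0:
        raise ValueError(f"{name} is empty")
    return arr


def pearson_matrix(
    indices: pd.DataFrame,
    props: pd.DataFrame,
    mode: HydrogenMode | str | None = None,
) -> CorrelationMatrix:
    """Sample Pearson coefficient for every (index, property) cell.

    Both frames must share their row keys (drugs).  A constant column makes
    the coefficient undefined and raises :class:`ConstantColumnError` naming
    the offending column rather than silently emitting zero.
    """
    common = [k for k in indices.index if k in props.index]
    if len(common) < 3:
        raise ValueError("need at least 3 paired observations")
    xi = indices.loc[common]
    yp = props.loc[common]
    for frame, label in ((xi, "index"), (yp, "property")):
        for col in frame.columns:
            if np.ptp(frame[col].to_numpy(dtype=float)) == 0:
                raise ConstantColumnError(f"constant {label} column {col!r}")
    r = pd.DataFrame(
        {
            p: {
                i: float(np.corrcoef(xi[i].to_numpy(float), yp[p].to_numpy(float))[0, 1])
                for i in xi.columns
            }
            for p in yp.columns
        }
    ).loc[list(xi.columns), list(yp.columns)]
    return CorrelationMatrix(mode=HydrogenMode(mode) if mode else None, r=r)


def fit_lr(
    x: Sequence[float] | np.ndarray,
    y: Sequence[float] | np.ndarray,
    property_name: str = "",
    index_name: str = "",
    mode: str | None = None,
) -> LRFit:
    """OLS fit of ``y = v + w x`` on all observations, with R² and RMSE.

    RMSE uses denominator ``n`` (not ``n - 2``); R² is computed against the
    mean of the observed values.
    """
    xa, ya = _column(x, "x"), _column(y, "y")
    if xa.size != ya.size:
        raise ValueError("x and y must have equal length")
    if xa.size < 3:
        raise DegenerateFitError("need at least 3 observations")
    if np.ptp(xa) == 0:
        raise DegenerateFitError("descriptor column is constant")
    slope, intercept = np.polyfit(xa, ya, 1)
    pred = intercept + slope * xa
    ss_res = float(np.sum((ya - pred) ** 2))
    ss_tot = float(np.sum((ya - ya.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot
    rmse = math.sqrt(ss_res / xa.size)
    return LRFit(
        property=property_name,
        index=index_name,
        mode=mode,
        intercept=float(intercept),
        slope=float(slope),
        r2=r2,
        rmse=rmse,
        n=int(xa.size),
    )


def rbf_kernel(
    x: Sequence[float] | np.ndarray, y: Sequence[float] | np.ndarray, alpha: float
) -> float:
    """RBF kernel value ``exp(-alpha * ||x - y||^2)`` in ``(0, 1]``."""
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    xa, ya = _column(x, "x"), _column(y, "y")
    if xa.size != ya.size:
        raise ValueError("x and y must have equal length")
    return float(np.exp(-alpha * float(np.sum((xa - ya) ** 2))))


@dataclass(frozen=True)
class ScalingTransform:
    """Invertible standardization ``z = (x - mean) / sd``."""

    mean: float
    sd: float

    def apply(self, x: np.ndarray) -> np.ndarray:
        return (np.asarray(x, dtype=float) - self.mean) / self.sd

    def invert(self, z: np.ndarray) -> np.ndarray:
        return np.asarray(z, dtype=float) * self.sd + self.mean


def feature_scaling(x: Sequence[float] | np.ndarray) -> tuple[np.ndarray, ScalingTransform]:
    """Standardize a column to mean 0, sd 1, returning the stored transform."""
    xa = _column(x)
    sd = float(xa.std())
    if sd == 0:
        raise ConstantColumnError("cannot scale a constant column")
    t = ScalingTransform(mean=float(xa.mean()), sd=sd)
    return t.apply(xa), t


def _make_pipeline(C: float, epsilon: float, gamma: str, scale: bool) -> Pipeline:
    steps = []
    if scale:
        steps.append(("scale", StandardScaler()))
    steps.append(("svr", SVR(kernel="rbf", C=C, epsilon=epsilon, gamma=gamma)))
    return Pipeline(steps)


def tune_svr(
    x: Sequence[float] | np.ndarray,
    y: Sequence[float] | np.ndarray,
    spec: SVRSpec = SVRSpec(),
    property_name: str = "",
    index_name: str = "",
    mode: str | None = None,
) -> SVRResult:
    """Grid-search RBF-SVR under the study protocol.

    The data are split 80/20 (seeded), each grid point is scored by mean
    R² over shuffled 5-fold CV on the training split, the winner is refit on
    the whole training split and evaluated on the held-out test part (R² and
    RMSE with denominator ``n_test``).  Grid points are visited in
    deterministic order (C ascending, then ε ascending, then ``scale`` before
    ``auto``) and only a strictly better CV score displaces the incumbent, so
    ties resolve toward the less complex model.  A fold whose validation R²
    is undefined (constant fold target) scores ``-inf``.
    """
    xa, ya = _column(x, "x"), _column(y, "y")
    if xa.size != ya.size:
        raise ValueError("x and y must have equal length")
    if xa.size < 10:
        raise ConfigurationError("need at least 10 observations to split and tune")
    X = xa.reshape(-1, 1)
    X_tr, X_te, y_tr, y_te = train_test_split(
        X, ya, train_size=spec.split_fraction, random_state=spec.seed, shuffle=True
    )
    if X_tr.shape[0] < spec.cv_folds:
        raise ConfigurationError(
            f"training split of {X_tr.shape[0]} cannot support {spec.cv_folds}-fold CV"
        )
    kf = KFold(n_splits=spec.cv_folds, shuffle=True, random_state=spec.seed)
    folds = list(kf.split(X_tr))

    best: tuple[float, float, float, str] | None = None
    for C in spec.c_grid:
        for eps in spec.epsilon_grid:
            for gamma in spec.gamma_modes:
                scores = []
                for tr_idx, va_idx in folds:
                    pipe = _make_pipeline(C, eps, gamma, spec.scale_features)
                    pipe.fit(X_tr[tr_idx], y_tr[tr_idx])
                    y_va = y_tr[va_idx]
                    if np.ptp(y_va) == 0:
                        scores.append(-np.inf)
                        continue
                    scores.append(r2_score(y_va, pipe.predict(X_tr[va_idx])))
                mean_r2 = float(np.mean(scores))
                if best is None or mean_r2 > best[0]:
                    best = (mean_r2, C, eps, gamma)
    assert best is not None
    cv_r2, C, eps, gamma = best
    final = _make_pipeline(C, eps, gamma, spec.scale_features)
    final.fit(X_tr, y_tr)
    pred = final.predict(X_te)
    test_r2 = float(r2_score(y_te, pred))
    test_rmse = float(np.sqrt(np.mean((y_te - pred) ** 2)))
    return SVRResult(
        property=property_name,
        index=index_name,
        mode=mode,
        C=float(C),
        epsilon=float(eps),
        gamma=gamma,
        cv_r2=cv_r2,
        test_r2=test_r2,
        test_rmse=test_rmse,
        seed=spec.seed,
        scaled=spec.scale_features,
    )


def svr_full_predictions(
    x: Sequence[float] | np.ndarray,
    y: Sequence[float] | np.ndarray,
    spec: SVRSpec,
    C: float,
    epsilon: float,
    gamma: str,
) -> np.ndarray:
    """Predictions for *all* observations from an SVR fit on the training split.

    Reconstructs the same seeded 80/20 split as :func:`tune_svr`, fits the
    given hyperparameter combination on the training part, and predicts every
    input row (the data behind actual-vs-predicted plots).
    """
    xa, ya = _column(x, "x"), _column(y, "y")
    X = xa.reshape(-1, 1)
    idx = np.arange(xa.size)
    tr_idx, _ = train_test_split(
        idx, train_size=spec.split_fraction, random_state=spec.seed, shuffle=True
    )
    pipe = _make_pipeline(C, epsilon, gamma, spec.scale_features)
    pipe.fit(X[tr_idx], ya[tr_idx])
    return pipe.predict(X)


FitLike = Union[LRFit, SVRResult]


def _score(fit: FitLike) -> float:
    return fit.r2 if isinstance(fit, LRFit) else fit.test_r2


def select_best_index(results: Iterable[FitLike]) -> Mapping[str, FitLike]:
    """Best fit per property, by highest R² (test R² for SVR).

    Ties break toward the lexicographically first index name, so the
    selection is deterministic.
    """
    best: dict[str, FitLike] = {}
    for fit in results:
        cur = best.get(fit.property)
        if (
            cur is None
            or _score(fit) > _score(cur)
            or (_score(fit) == _score(cur) and fit.index < cur.index)
        ):
            best[fit.property] = fit
    return best
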