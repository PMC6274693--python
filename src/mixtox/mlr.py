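"""Ordinary least squares, heuristic descriptor pre-screening, forward
stepwise selection, and the bundled reference models.

Estimators follow the scikit-learn protocol (``fit``/``predict``,
``get_params``/``set_params``, trailing-underscore fitted attributes) and can
be composed with scikit-learn pipelines and model selection. Module-level
functions (:func:`fit_ols`, :func:`heuristic_prescreen`,
:func:`forward_stepwise`, :func:`predict`) are thin wrappers over them.

Conventions, chosen to match the source data tables:

* R² is the squared Pearson correlation between fitted and observed values
  (identical to the coefficient of determination for OLS with intercept).
* Two root-mean-square errors are exposed: ``rms_`` = sqrt(SSE/N) and
  ``rms_see_`` = sqrt(SSE/(N−p−1)), the standard error of estimate. The
  reference linear models report the latter.
* F = (R²/p) / ((1−R²)/(N−p−1)) with p the number of descriptors.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .errors import FitError, ValidationError


def _as_frame(X) -> pd.DataFrame:
    if isinstance(X, pd.DataFrame):
        return X
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    return pd.DataFrame(X, columns=[f"x{i + 1}" for i in range(X.shape[1])])


@dataclass
class LinearModel:
    """A named linear model: intercept plus coefficients keyed by descriptor.

    Used both for refit results and for the bundled reference models. The
    ``stats`` mapping carries whatever fit statistics are known (r2, q2_loo,
    f, rms, n_train).
    """

    name: str
    intercept: float
    coefficients: dict[str, float]
    stats: dict[str, float] = field(default_factory=dict)

    def predict(self, X) -> np.ndarray:
        """b0 + sum(b_j * x_j); columns matched by name for DataFrames."""
        if isinstance(X, pd.DataFrame):
            missing = [k for k in self.coefficients if k not in X.columns]
            if missing:
                raise ValidationError(f"missing descriptor column(s): {missing}")
            mat = X[list(self.coefficients)].to_numpy(dtype=float)
        else:
            mat = np.atleast_2d(np.asarray(X, dtype=float))
            if mat.shape[1] != len(self.coefficients):
                raise ValidationError(
                    f"expected {len(self.coefficients)} columns, got {mat.shape[1]}"
                )
        beta = np.array(list(self.coefficients.values()))
        return self.intercept + mat @ beta

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(
            {"name": self.name, "intercept": self.intercept,
             "coefficients": self.coefficients, "stats": self.stats},
            indent=2,
        )
        if path is not None:
            Path(path).write_text(payload)
        return payload

    @classmethod
    def from_json(cls, text_or_path: str | Path) -> "LinearModel":
        p = Path(str(text_or_path))
        text = p.read_text() if p.exists() else str(text_or_path)
        raw = json.loads(text)
        return cls(raw["name"], raw["intercept"], raw["coefficients"],
                   raw.get("stats", {}))


#: Published reference models on the (NTB, ACIC2, QMaxC) descriptor triple:
#: the single-compound model, the binary-mixture training model, and the
#: mixture model refit after removing the two applicability-domain outliers.
REFERENCE_MODELS: dict[str, LinearModel] = {
    "single_compound": LinearModel(
        "single_compound", 0.236,
        {"ntb": -0.769, "acic2": 1.609, "qmaxc": 55.778},
        {"n_train": 55, "r2": 0.736, "q2_loo": 0.720, "f": 47.334, "rms": 1.042},
    ),
    "mixture_training": LinearModel(
        "mixture_training", -0.405,
        {"ntb": -0.688, "acic2": 1.847, "qmaxc": 63.611},
        {"n_train": 79, "r2": 0.869, "q2_loo": 0.864, "rms": 0.599},
    ),
    "mixture_improved": LinearModel(
        "mixture_improved", -0.397,
        {"ntb": -0.619, "acic2": 1.740, "qmaxc": 64.914},
        {"n_train": 77, "r2": 0.872, "q2_loo": 0.866, "f": 165.068, "rms": 0.566},
    ),
}


class OLSRegressor(RegressorMixin, BaseEstimator):
    """Ordinary least squares with intercept.

    Requires at least p+2 rows for p descriptors, a full-rank design, and no
    constant descriptor column. Fitted attributes include leave-one-out q²
    (computed exactly through the hat matrix) alongside R², F, and both RMS
    conventions.
    """

    def fit(self, X, y):
        X = _as_frame(X)
        y = np.asarray(y, dtype=float).ravel()
        n, p = X.shape
        if len(y) != n:
            raise ValidationError(f"X has {n} rows but y has {len(y)}")
        if n < p + 2:
            raise FitError(f"need at least p+2={p + 2} rows to fit {p} descriptors, got {n}")
        const = [c for c in X.columns if np.ptp(X[c].to_numpy()) == 0.0]
        if const:
            raise FitError(f"constant descriptor column(s): {const}")

        design = np.column_stack([np.ones(n), X.to_numpy(dtype=float)])
        if np.linalg.matrix_rank(design) < p + 1:
            raise FitError("singular design matrix (collinear descriptors)")
        beta, *_ = np.linalg.lstsq(design, y, rcond=None)

        self.feature_names_in_ = np.array(X.columns, dtype=object)
        self.n_features_in_ = p
        self.intercept_ = float(beta[0])
        self.coef_ = beta[1:]
        self.n_train_ = n

        fitted = design @ beta
        resid = y - fitted
        sse = float(resid @ resid)
        sst = float(((y - y.mean()) ** 2).sum())
        self.r2_ = 1.0 - sse / sst if sst > 0 else 1.0
        self.rms_ = float(np.sqrt(sse / n))
        dof = n - p - 1
        self.rms_see_ = float(np.sqrt(sse / dof)) if dof > 0 else np.nan
        self.f_stat_ = (
            (self.r2_ / p) / ((1.0 - self.r2_) / dof)
            if p > 0 and dof > 0 and self.r2_ < 1.0
            else np.inf
        )
        # exact LOO through the hat matrix
        hat = np.einsum(
            "ij,jk,ik->i", design, np.linalg.inv(design.T @ design), design
        )
        loo_resid = resid / (1.0 - hat)
        press = float(loo_resid @ loo_resid)
        self.q2_loo_ = 1.0 - press / sst if sst > 0 else 1.0
        self.leverages_ = hat
        return self

    def predict(self, X):
        check_is_fitted(self)
        X = _as_frame(X)
        if list(X.columns) != list(self.feature_names_in_):
            missing = [c for c in self.feature_names_in_ if c not in X.columns]
            if missing:
                raise ValidationError(f"missing descriptor column(s): {missing}")
            X = X[list(self.feature_names_in_)]
        return self.intercept_ + X.to_numpy(dtype=float) @ self.coef_

    def to_linear_model(self, name: str = "ols") -> LinearModel:
        check_is_fitted(self)
        return LinearModel(
            name, self.intercept_,
            dict(zip(self.feature_names_in_, map(float, self.coef_))),
            {"n_train": self.n_train_, "r2": self.r2_, "q2_loo": self.q2_loo_,
             "f": self.f_stat_, "rms": self.rms_, "rms_see": self.rms_see_},
        )


def _one_parameter_stats(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """(F, t) of the slope in the one-descriptor regression y = a + b*x."""
    n = len(y)
    xc = x - x.mean()
    yc = y - y.mean()
    sxx = float(xc @ xc)
    b = float(xc @ yc) / sxx
    resid = yc - b * xc
    s2 = float(resid @ resid) / (n - 2)
    t = b / np.sqrt(s2 / sxx) if s2 > 0 else np.inf
    return t * t, t


def heuristic_prescreen(
    X_pool: pd.DataFrame,
    y,
    f_min: float = 1.0,
    t_min: float = 0.1,
    r_max: float = 0.80,
) -> list[str]:
    """Heuristic descriptor pre-screen.

    Drops columns with missing values or zero variance, then those whose
    one-parameter regression fails F >= f_min or |t| >= t_min, and finally
    greedily removes the later member of every remaining pair correlated
    beyond |r| > r_max. Raises :class:`FitError` if nothing survives.
    """
    X_pool = _as_frame(X_pool)
    y = np.asarray(y, dtype=float).ravel()
    kept: list[str] = []
    for name in X_pool.columns:
        col = X_pool[name].to_numpy(dtype=float)
        if not np.isfinite(col).all() or np.ptp(col) == 0.0:
            continue
        f, t = _one_parameter_stats(col, y)
        if f >= f_min and abs(t) >= t_min:
            kept.append(name)
    # pairwise decorrelation, earlier column wins
    surviving = list(kept)
    for i, a in enumerate(kept):
        if a not in surviving:
            continue
        for b in kept[i + 1:]:
            if b not in surviving:
                continue
            r = np.corrcoef(X_pool[a], X_pool[b])[0, 1]
            if abs(r) > r_max:
                surviving.remove(b)
    if not surviving:
        raise FitError("heuristic pre-screen rejected every descriptor")
    return surviving


class ForwardStepwiseRegressor(RegressorMixin, BaseEstimator):
    """Greedy forward descriptor selection on top of OLS.

    Each step adds the descriptor that maximizes fitted R²; selection stops
    when the best gain falls below ``delta_r2_break``. Ties are broken by
    the lowest column index. With ``prescreen=True`` the pool is first
    reduced by :func:`heuristic_prescreen`. An empty selection yields an
    intercept-only model (the response mean).
    """

    def __init__(self, delta_r2_break: float = 0.02, prescreen: bool = False,
                 f_min: float = 1.0, t_min: float = 0.1, r_max: float = 0.80):
        self.delta_r2_break = delta_r2_break
        self.prescreen = prescreen
        self.f_min = f_min
        self.t_min = t_min
        self.r_max = r_max

    def fit(self, X, y):
        X = _as_frame(X)
        y = np.asarray(y, dtype=float).ravel()
        pool = list(X.columns)
        if self.prescreen:
            pool = heuristic_prescreen(X, y, self.f_min, self.t_min, self.r_max)

        selected: list[str] = []
        current_r2 = 0.0
        self.path_: list[tuple[str, float]] = []
        while pool:
            if len(X) < len(selected) + 3:  # next fit would violate n >= p+2
                break
            best_name, best_r2 = None, -np.inf
            for name in pool:
                try:
                    r2 = OLSRegressor().fit(X[selected + [name]], y).r2_
                except FitError:
                    continue
                if r2 > best_r2:
                    best_name, best_r2 = name, r2
            if best_name is None or best_r2 - current_r2 < self.delta_r2_break:
                break
            selected.append(best_name)
            pool.remove(best_name)
            current_r2 = best_r2
            self.path_.append((best_name, best_r2))

        self.selected_features_ = list(selected)
        if selected:
            ols = OLSRegressor().fit(X[selected], y)
            self._ols = ols
            self.intercept_ = ols.intercept_
            self.coef_ = ols.coef_
            for attr in ("r2_", "q2_loo_", "rms_", "rms_see_", "f_stat_", "n_train_"):
                setattr(self, attr, getattr(ols, attr))
        else:
            self._ols = None
            self.intercept_ = float(np.mean(y))
            self.coef_ = np.array([])
            self.r2_ = 0.0
            self.n_train_ = len(y)
        self.feature_names_in_ = np.array(X.columns, dtype=object)
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X):
        check_is_fitted(self)
        X = _as_frame(X)
        if self._ols is None:
            return np.full(len(X), self.intercept_)
        return self._ols.predict(X[self.selected_features_])

    def to_linear_model(self, name: str = "stepwise") -> LinearModel:
        check_is_fitted(self)
        if self._ols is None:
            return LinearModel(name, self.intercept_, {}, {"n_train": self.n_train_})
        return self._ols.to_linear_model(name)


def fit_ols(X, y) -> OLSRegressor:
    """Least-squares fit of y on all columns of X (with intercept)."""
    return OLSRegressor().fit(X, y)


def forward_stepwise(X_pool, y, delta_r2_break: float = 0.02,
                     **prescreen_kwargs) -> ForwardStepwiseRegressor:
    """Greedy forward selection over a (pre-screened) descriptor pool."""
    return ForwardStepwiseRegressor(
        delta_r2_break=delta_r2_break, **prescreen_kwargs
    ).fit(X_pool, y)


def predict(model, X) -> np.ndarray:
    """Evaluate a fitted estimator, a LinearModel, or a reference-model name."""
    if isinstance(model, str):
        model = REFERENCE_MODELS[model]
    return model.predict(X)
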