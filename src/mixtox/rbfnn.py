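"""Radial basis function network regression.

A single hidden layer of Gaussian units h_j(x) = exp(−‖x−c_j‖²/r²) with a
shared width r, a linear output layer fit by least squares, and training by
greedy forward subset selection of centers from the training points. The
width is either fixed or chosen by scanning a grid (0.1–4.0 in steps of 0.1
by default) against a leave-one-out RMS criterion.

Inputs are standardized (centered and scaled by training statistics) before
any distance computation by default, and the transform is stored with the
network: the descriptors live on very different scales (a partial charge of
order 0.1 next to an information content of several bits), and a shared
Euclidean width is only meaningful on comparable coordinates. The
module-level wrappers (:func:`forward_center_selection`,
:func:`width_scan`, :func:`fit_output_weights`) operate in the input space
exactly as given (no standardization) so widths keep their stated units.

The preset ``reference`` (14 hidden units, width 1.2) reproduces the
published network architecture for the mixture dataset.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .errors import FitError, ValidationError

DEFAULT_WIDTH_GRID = np.round(np.arange(0.1, 4.0 + 1e-9, 0.1), 10)

PRESETS = {"reference": {"n_hidden": 14, "width": 1.2}}


def rbf_activation(x, center, width: float) -> float | np.ndarray:
    """Gaussian unit output exp(−‖x−c‖²/r²) in (0, 1]."""
    if width <= 0:
        raise ValidationError(f"width must be > 0, got {width}")
    x = np.asarray(x, dtype=float)
    center = np.asarray(center, dtype=float)
    if x.shape[-1] != center.shape[-1]:
        raise ValidationError(
            f"dimension mismatch: x has {x.shape[-1]}, center has {center.shape[-1]}"
        )
    d2 = ((x - center) ** 2).sum(axis=-1)
    return np.exp(-d2 / width**2)


def _activation_matrix(X: np.ndarray, centers: np.ndarray, width: float) -> np.ndarray:
    d2 = ((X[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
    return np.exp(-d2 / width**2)


def fit_output_weights(centers, width: float, X_train, y_train):
    """Least squares of y on the Gaussian activations plus a constant column.

    Duplicate centers are rejected (they make the activation matrix exactly
    rank-deficient); any other numerically singular design raises
    :class:`FitError`.
    """
    centers = np.atleast_2d(np.asarray(centers, dtype=float))
    X = np.atleast_2d(np.asarray(X_train, dtype=float))
    y = np.asarray(y_train, dtype=float).ravel()
    if width <= 0:
        raise ValidationError(f"width must be > 0, got {width}")
    uniq = np.unique(centers, axis=0)
    if len(uniq) != len(centers):
        raise FitError("duplicate centers are not allowed")
    H = _activation_matrix(X, centers, width)
    design = np.column_stack([H, np.ones(len(X))])
    # n centers drawn from n points give an n x (n+1) design of full row rank;
    # only a genuine column/row collapse (huge width, redundant centers) errors
    if np.linalg.matrix_rank(design) < min(design.shape):
        raise FitError("singular activation matrix (width too large or centers redundant)")
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    return beta[:-1], float(beta[-1])


class RBFNetworkRegressor(RegressorMixin, BaseEstimator):
    """Gaussian RBF network trained by forward center selection.

    Parameters
    ----------
    n_hidden : int, default 14
        Number of hidden units (centers drawn from the training points).
    width : float or None, default 1.2
        Shared Gaussian width in (standardized) input units. ``None``
        triggers a grid scan over ``width_grid``.
    width_grid : array-like or None
        Candidate widths for the scan; defaults to 0.1..4.0 step 0.1.
    criterion : {"loo_rms", "train_rms"}, default "loo_rms"
        Score minimized by the width scan. Leave-one-out RMS is computed
        exactly through the hat matrix of the linear output layer.
    standardize : bool, default True
        Center/scale inputs by training statistics before distances.
    """

    def __init__(self, n_hidden: int = 14, width: float | None = 1.2,
                 width_grid=None, criterion: str = "loo_rms",
                 standardize: bool = True):
        self.n_hidden = n_hidden
        self.width = width
        self.width_grid = width_grid
        self.criterion = criterion
        self.standardize = standardize

    # -- internals ---------------------------------------------------------

    @staticmethod
    def _greedy_centers(X: np.ndarray, y: np.ndarray, width: float,
                        n_hidden: int) -> tuple[list[int], list[float]]:
        """Greedy forward selection of training points as centers.

        Returns the selected row indices and the training-RMS path (one
        value per added unit; non-increasing). Ties break on the lowest
        candidate index.
        """
        n = len(X)
        A = _activation_matrix(X, X, width)  # all candidate activations
        ones = np.ones((n, 1))
        selected: list[int] = []
        rms_path: list[float] = []
        for _ in range(n_hidden):
            best_idx, best_rms = None, np.inf
            for cand in range(n):
                if cand in selected:
                    continue
                design = np.column_stack([A[:, selected + [cand]], ones])
                beta, *_ = np.linalg.lstsq(design, y, rcond=None)
                resid = y - design @ beta
                cand_rms = float(np.sqrt(np.mean(resid**2)))
                if cand_rms < best_rms - 1e-15:
                    best_idx, best_rms = cand, cand_rms
            if best_idx is None:
                break
            selected.append(best_idx)
            rms_path.append(best_rms)
        return selected, rms_path

    @staticmethod
    def _loo_rms(design: np.ndarray, y: np.ndarray) -> float:
        beta, *_ = np.linalg.lstsq(design, y, rcond=None)
        resid = y - design @ beta
        hat = np.einsum(
            "ij,jk,ik->i", design, np.linalg.pinv(design.T @ design), design
        )
        denom = np.clip(1.0 - hat, 1e-12, None)
        return float(np.sqrt(np.mean((resid / denom) ** 2)))

    def _score_width(self, X: np.ndarray, y: np.ndarray, width: float) -> float:
        selected, rms_path = self._greedy_centers(X, y, width, self._n_hidden_eff)
        design = np.column_stack(
            [_activation_matrix(X, X[selected], width), np.ones(len(X))]
        )
        if self.criterion == "train_rms":
            return rms_path[-1]
        return self._loo_rms(design, y)

    # -- estimator API -----------------------------------------------------

    def fit(self, X, y):
        feature_names = (
            list(X.columns) if isinstance(X, pd.DataFrame)
            else [f"x{i + 1}" for i in range(np.atleast_2d(np.asarray(X)).shape[1])]
        )
        X = np.atleast_2d(np.asarray(X, dtype=float))
        y = np.asarray(y, dtype=float).ravel()
        n, p = X.shape
        if not 1 <= self.n_hidden <= n:
            raise FitError(f"n_hidden must be in [1, n_train={n}], got {self.n_hidden}")
        if self.criterion not in ("loo_rms", "train_rms"):
            raise ValidationError(f"unknown criterion {self.criterion!r}")
        self._n_hidden_eff = self.n_hidden

        if self.standardize:
            self.x_mean_ = X.mean(axis=0)
            scale = X.std(axis=0)
            self.x_scale_ = np.where(scale > 0, scale, 1.0)
        else:
            self.x_mean_ = np.zeros(p)
            self.x_scale_ = np.ones(p)
        Z = (X - self.x_mean_) / self.x_scale_

        if self.width is None:
            grid = DEFAULT_WIDTH_GRID if self.width_grid is None else np.asarray(
                self.width_grid, dtype=float
            )
            if grid.size == 0:
                raise ValidationError("width grid is empty")
            scores = [self._score_width(Z, y, w) for w in grid]
            best = int(np.argmin(scores))  # ties -> smallest width (first index)
            self.width_ = float(grid[best])
            self.width_scores_ = dict(zip(map(float, grid), scores))
        else:
            if self.width <= 0:
                raise ValidationError(f"width must be > 0, got {self.width}")
            self.width_ = float(self.width)
            self.width_scores_ = None

        selected, rms_path = self._greedy_centers(Z, y, self.width_, self._n_hidden_eff)
        self.center_indices_ = selected
        self.centers_ = Z[selected]
        self.weights_, self.bias_ = fit_output_weights(self.centers_, self.width_, Z, y)
        self.rms_path_ = rms_path
        self.train_rms_ = rms_path[-1]
        self.feature_names_in_ = np.array(feature_names, dtype=object)
        self.n_features_in_ = p
        self.n_train_ = n
        return self

    def predict(self, X):
        check_is_fitted(self)
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.n_features_in_:
            raise ValidationError(
                f"expected {self.n_features_in_} features, got {X.shape[1]}"
            )
        Z = (X - self.x_mean_) / self.x_scale_
        H = _activation_matrix(Z, self.centers_, self.width_)
        return H @ self.weights_ + self.bias_

    # -- serialization -----------------------------------------------------

    def to_json(self, path: str | Path | None = None) -> str:
        check_is_fitted(self)
        payload = json.dumps({
            "feature_names": list(self.feature_names_in_),
            "centers": self.centers_.tolist(),
            "width": self.width_,
            "weights": self.weights_.tolist(),
            "bias": self.bias_,
            "x_mean": self.x_mean_.tolist(),
            "x_scale": self.x_scale_.tolist(),
        }, indent=2)
        if path is not None:
            Path(path).write_text(payload)
        return payload

    @classmethod
    def from_json(cls, text_or_path: str | Path) -> "RBFNetworkRegressor":
        p = Path(str(text_or_path))
        raw = json.loads(p.read_text() if p.exists() else str(text_or_path))
        net = cls(n_hidden=len(raw["centers"]), width=raw["width"])
        net.centers_ = np.asarray(raw["centers"], dtype=float)
        net.width_ = float(raw["width"])
        net.weights_ = np.asarray(raw["weights"], dtype=float)
        net.bias_ = float(raw["bias"])
        net.x_mean_ = np.asarray(raw["x_mean"], dtype=float)
        net.x_scale_ = np.asarray(raw["x_scale"], dtype=float)
        net.feature_names_in_ = np.array(raw["feature_names"], dtype=object)
        net.n_features_in_ = net.centers_.shape[1]
        return net


def forward_center_selection(X_train, y_train, width: float,
                             n_hidden_max: int) -> RBFNetworkRegressor:
    """Greedy center selection at a fixed width, in raw input units."""
    return RBFNetworkRegressor(
        n_hidden=n_hidden_max, width=width, standardize=False
    ).fit(X_train, y_train)


def width_scan(X_train, y_train, n_hidden_max: int, grid=None,
               criterion: str = "loo_rms") -> tuple[float, RBFNetworkRegressor]:
    """Scan candidate widths (raw input units) and return the best network."""
    net = RBFNetworkRegressor(
        n_hidden=n_hidden_max, width=None, width_grid=grid,
        criterion=criterion, standardize=False,
    ).fit(X_train, y_train)
    return net.width_, net


def predict(network: RBFNetworkRegressor, X) -> np.ndarray:
    return network.predict(X)
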