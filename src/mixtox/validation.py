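"""Model-quality statistics and validation procedures.

Covers the statistics used to judge the mixture-toxicity models: R² (squared
Pearson correlation between observed and predicted), RMS, Fisher's F,
leave-one-out q², the Golbraikh–Tropsha external-validation criteria
(through-origin coefficients R0²/R0'² and slopes k/k'), variance inflation
factors, descriptor mean effects, Y-randomization, grouped leave-many-out
cross-validation, and the leverage / Williams-plot applicability domain.

The through-origin quantities follow the standard external-validation
convention: with observed y and predicted ŷ,

    k  = Σ y·ŷ / Σ ŷ²         (slope of y on ŷ through the origin)
    k' = Σ y·ŷ / Σ y²         (slope of ŷ on y through the origin)
    R0²  = 1 − Σ(y − k·ŷ)²  / Σ(y − ȳ)²
    R0'² = 1 − Σ(ŷ − k'·y)² / Σ(ŷ − ŷ̄)²

and a model passes the external criteria when q² > 0.5, R² > 0.6,
(R²−R0²)/R² < 0.1 (or the primed variant), and 0.85 ≤ k ≤ 1.15 (or k').
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FitError, UndefinedStatisticError, ValidationError
from .mlr import LinearModel, OLSRegressor, _as_frame


@dataclass
class ValidationReport:
    """External/internal validation statistics for one observed/predicted pair."""

    n: int
    r2: float
    rms: float
    f_stat: float
    k: float
    k_prime: float
    r0_sq: float
    r0_prime_sq: float
    q2_loo: float | None = None
    gt_pass: dict[str, bool | None] = field(default_factory=dict)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(asdict(self), indent=2)
        if path is not None:
            Path(path).write_text(payload)
        return payload


@dataclass
class ADReport:
    """Applicability-domain summary for a Williams plot."""

    h_star: float
    n_train: int
    n_parameters: int
    table: pd.DataFrame  # id, leverage, std_residual, set, x_outlier, y_outlier
    x_outliers: list
    y_outliers: list

    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index=False)


def _check_pair(y_obs, y_pred, min_n: int = 1) -> tuple[np.ndarray, np.ndarray]:
    y_obs = np.asarray(y_obs, dtype=float).ravel()
    y_pred = np.asarray(y_pred, dtype=float).ravel()
    if len(y_obs) != len(y_pred):
        raise ValidationError(
            f"length mismatch: {len(y_obs)} observed vs {len(y_pred)} predicted"
        )
    if len(y_obs) < min_n:
        raise ValidationError(f"need at least {min_n} samples, got {len(y_obs)}")
    return y_obs, y_pred


def r_squared(y_obs, y_pred) -> float:
    """Squared Pearson correlation between observed and predicted values."""
    y_obs, y_pred = _check_pair(y_obs, y_pred, min_n=3)
    if np.ptp(y_obs) == 0 or np.ptp(y_pred) == 0:
        raise UndefinedStatisticError("R² undefined: a vector has zero variance")
    return float(np.corrcoef(y_obs, y_pred)[0, 1] ** 2)


def rms(y_obs, y_pred, ddof: int = 0) -> float:
    """Root-mean-square residual, sqrt(SSE/(N−ddof)).

    ``ddof=0`` is the plain form; ``ddof=p+1`` gives the standard error of
    estimate of a p-descriptor model with intercept.
    """
    y_obs, y_pred = _check_pair(y_obs, y_pred)
    n = len(y_obs)
    if n - ddof <= 0:
        raise ValidationError(f"ddof={ddof} leaves no degrees of freedom for n={n}")
    resid = y_obs - y_pred
    return float(np.sqrt(resid @ resid / (n - ddof)))


def f_statistic(r2: float, n: int, p: int) -> float:
    """Fisher statistic (R²/p) / ((1−R²)/(n−p−1))."""
    if n - p - 1 <= 0:
        raise ValidationError(f"n={n} too small for p={p} descriptors")
    if r2 >= 1.0:
        return np.inf
    return (r2 / p) / ((1.0 - r2) / (n - p - 1))


def loo_q2(fit_procedure, X, y) -> float:
    """Leave-one-out cross-validated q² = 1 − PRESS/SS_tot.

    ``fit_procedure(X, y)`` must return an object with ``predict``. Each
    sample is predicted by a model refit without it.
    """
    X = _as_frame(X)
    y = np.asarray(y, dtype=float).ravel()
    n = len(y)
    if n < 5:
        raise ValidationError(f"leave-one-out needs n >= 5, got {n}")
    press = 0.0
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        try:
            model = fit_procedure(X.iloc[mask], y[mask])
        except Exception as exc:
            raise FitError(f"leave-one-out refit failed at index {i}: {exc}") from exc
        pred = float(np.asarray(model.predict(X.iloc[[i]])).ravel()[0])
        press += (y[i] - pred) ** 2
    sst = float(((y - y.mean()) ** 2).sum())
    if sst == 0:
        raise UndefinedStatisticError("q² undefined: response has zero variance")
    return 1.0 - press / sst


def golbraikh_tropsha(y_obs, y_pred, q2: float | None = None) -> ValidationReport:
    """External-validation report with through-origin slopes and coefficients.

    The q² criterion can only be judged when a cross-validated q² for the
    external set is supplied; its flag is ``None`` otherwise.
    """
    y_obs, y_pred = _check_pair(y_obs, y_pred, min_n=5)
    sum_pp = float(y_pred @ y_pred)
    sum_oo = float(y_obs @ y_obs)
    if sum_pp == 0 or sum_oo == 0:
        raise UndefinedStatisticError("through-origin slope undefined: zero denominator")
    k = float(y_obs @ y_pred) / sum_pp
    k_prime = float(y_obs @ y_pred) / sum_oo
    r2 = r_squared(y_obs, y_pred)
    sst_obs = float(((y_obs - y_obs.mean()) ** 2).sum())
    sst_pred = float(((y_pred - y_pred.mean()) ** 2).sum())
    r0_sq = 1.0 - float(((y_obs - k * y_pred) ** 2).sum()) / sst_obs
    r0_prime_sq = 1.0 - float(((y_pred - k_prime * y_obs) ** 2).sum()) / sst_pred
    gt_pass = {
        "q2_gt_0.5": None if q2 is None else bool(q2 > 0.5),
        "r2_gt_0.6": bool(r2 > 0.6),
        "r0_ratio_lt_0.1": bool(
            (r2 - r0_sq) / r2 < 0.1 or (r2 - r0_prime_sq) / r2 < 0.1
        ),
        "k_in_band": bool(0.85 <= k <= 1.15 or 0.85 <= k_prime <= 1.15),
    }
    n = len(y_obs)
    return ValidationReport(
        n=n, r2=r2, rms=rms(y_obs, y_pred),
        f_stat=f_statistic(r2, n, 3) if n > 4 else np.nan,
        k=k, k_prime=k_prime, r0_sq=r0_sq, r0_prime_sq=r0_prime_sq,
        q2_loo=q2, gt_pass=gt_pass,
    )


def vif(r: float) -> float:
    """Variance inflation factor 1/(1−r²) for a pairwise correlation r."""
    if abs(r) >= 1:
        raise UndefinedStatisticError(f"VIF infinite for |r| >= 1 (r={r})")
    return 1.0 / (1.0 - r * r)


def mean_effect(model, X_train) -> dict[str, float]:
    """Signed, normalized descriptor contributions MF_j; sums to 1.

    MF_j = β_j Σ_i d_ij / Σ_j (β_j Σ_i d_ij) over the training descriptor
    matrix.
    """
    X_train = _as_frame(X_train)
    if isinstance(model, LinearModel):
        coefs = model.coefficients
    else:
        coefs = dict(zip(model.feature_names_in_, model.coef_))
    terms = {name: float(beta * X_train[name].sum()) for name, beta in coefs.items()}
    denom = sum(terms.values())
    if denom == 0:
        raise UndefinedStatisticError("mean effect undefined: Σ β_j Σ_i d_ij = 0")
    return {name: t / denom for name, t in terms.items()}


def y_randomization(fit_procedure, X, y, n_repeats: int = 10, seed: int = 0):
    """Response-scrambling robustness test.

    Shuffles y ``n_repeats`` times (seeded), refits, and records (R², q²)
    per repeat plus their averages. Repeats whose inner fit fails are
    recorded with the error message rather than aborting the test.
    """
    if n_repeats < 1:
        raise ValidationError(f"n_repeats must be >= 1, got {n_repeats}")
    X = _as_frame(X)
    y = np.asarray(y, dtype=float).ravel()
    rng = np.random.default_rng(seed)
    results = []
    for rep in range(n_repeats):
        y_shuf = rng.permutation(y)
        try:
            model = fit_procedure(X, y_shuf)
            r2 = r_squared(y_shuf, model.predict(X))
            q2 = loo_q2(fit_procedure, X, y_shuf)
            results.append({"repeat": rep, "r2": r2, "q2": q2, "error": None})
        except Exception as exc:  # recorded per repeat, not fatal
            results.append({"repeat": rep, "r2": None, "q2": None, "error": str(exc)})
    ok = [r for r in results if r["error"] is None]
    averages = {
        "r2": float(np.mean([r["r2"] for r in ok])) if ok else None,
        "q2": float(np.mean([r["q2"] for r in ok])) if ok else None,
        "n_failed": len(results) - len(ok),
    }
    return results, averages


def lmo_crossvalidation(fit_procedure, X, y, labels):
    """Grouped leave-many-out cross-validation over predefined subsets.

    Each fold holds out one label group, fits on the rest, and reports
    (R², F, RMS) for the training part and the held-out part, plus averages
    across folds. RMS here is the plain sqrt(SSE/N) of each part.
    """
    X = _as_frame(X)
    y = np.asarray(y, dtype=float).ravel()
    labels = np.asarray(labels)
    groups = sorted(pd.unique(labels))
    folds = []
    for g in groups:
        held = labels == g
        if held.sum() == 0 or held.all():
            raise ValidationError(f"group {g!r} does not partition the data")
        model = fit_procedure(X.iloc[~held], y[~held])
        p = len(getattr(model, "coef_", getattr(model, "coefficients", [])))
        yhat_tr = np.asarray(model.predict(X.iloc[~held]))
        yhat_te = np.asarray(model.predict(X.iloc[held]))
        r2_tr = r_squared(y[~held], yhat_tr)
        r2_te = r_squared(y[held], yhat_te)
        folds.append({
            "held_out": g, "n_train": int((~held).sum()), "n_test": int(held.sum()),
            "r2_train": r2_tr, "f_train": f_statistic(r2_tr, int((~held).sum()), p),
            "rms_train": rms(y[~held], yhat_tr),
            "r2_test": r2_te, "f_test": f_statistic(r2_te, int(held.sum()), p),
            "rms_test": rms(y[held], yhat_te),
        })
    keys = ["r2_train", "f_train", "rms_train", "r2_test", "f_test", "rms_test"]
    averages = {k: float(np.mean([f[k] for f in folds])) for k in keys}
    return folds, averages


def leverage(X_train_design, x_query) -> float | np.ndarray:
    """Hat-matrix quadratic form h = xᵀ(XᵀX)⁻¹x.

    ``X_train_design`` must be the full design matrix (including the
    intercept column when the model has one); ``x_query`` one row or a
    matrix of rows in the same layout.
    """
    D = np.atleast_2d(np.asarray(X_train_design, dtype=float))
    q = np.atleast_2d(np.asarray(x_query, dtype=float))
    xtx = D.T @ D
    if np.linalg.matrix_rank(xtx) < xtx.shape[0]:
        raise FitError("singular cross-product matrix; design is rank-deficient")
    h = np.einsum("ij,jk,ik->i", q, np.linalg.inv(xtx), q)
    return float(h[0]) if np.asarray(x_query).ndim == 1 else h


def williams_ad(model, X_train, y_train, X_query=None, y_query=None,
                h_star_formula: str = "3m") -> ADReport:
    """Leverage vs standardized cross-validated residuals (Williams plot).

    The model's descriptor columns define the design; the OLS fit on the
    training set supplies externally studentized (leave-one-out) residuals.
    The leverage limit is h* = 3m/n with m the descriptor count
    (``h_star_formula="standard"`` uses the common 3(m+1)/n instead);
    samples beyond h* are X-outliers and |standardized residual| > 3 marks
    Y-outliers. Query rows get leverages against the training design and,
    when their response is known, residuals standardized by the training
    residual scale (prediction variant, √(1+h)).
    """
    X_train = _as_frame(X_train)
    y_train = np.asarray(y_train, dtype=float).ravel()
    if isinstance(model, LinearModel):
        features = list(model.coefficients)
    else:
        features = list(model.feature_names_in_)
    ols = OLSRegressor().fit(X_train[features], y_train)
    n, m = len(X_train), len(features)
    h_star = 3.0 * m / n if h_star_formula == "3m" else 3.0 * (m + 1) / n

    design = np.column_stack([np.ones(n), X_train[features].to_numpy(dtype=float)])
    h = ols.leverages_
    resid = y_train - ols.predict(X_train[features])
    dof = n - m - 1
    s2 = float(resid @ resid) / dof
    # externally studentized residuals
    s2_i = (dof * s2 - resid**2 / (1.0 - h)) / (dof - 1)
    std_resid = resid / np.sqrt(s2_i * (1.0 - h))

    rows = pd.DataFrame({
        "id": X_train.index, "set": "train", "leverage": h, "std_residual": std_resid,
    })
    if X_query is not None:
        X_query = _as_frame(X_query)
        qdesign = np.column_stack(
            [np.ones(len(X_query)), X_query[features].to_numpy(dtype=float)]
        )
        hq = leverage(design, qdesign)
        if y_query is not None:
            yq = np.asarray(y_query, dtype=float).ravel()
            rq = (yq - ols.predict(X_query[features])) / np.sqrt(s2 * (1.0 + hq))
        else:
            rq = np.full(len(X_query), np.nan)
        rows = pd.concat([rows, pd.DataFrame({
            "id": X_query.index, "set": "query", "leverage": hq, "std_residual": rq,
        })], ignore_index=True)

    rows["x_outlier"] = rows["leverage"] > h_star
    rows["y_outlier"] = rows["std_residual"].abs() > 3.0
    return ADReport(
        h_star=h_star, n_train=n, n_parameters=m + 1, table=rows,
        x_outliers=list(rows.loc[rows.x_outlier, "id"]),
        y_outliers=list(rows.loc[rows.y_outlier.fillna(False), "id"]),
    )
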