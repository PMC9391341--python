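"""Dose-reconstruction models.

Two regression models map the net signal N back to absorbed dose:

* the microarray model ``D = k1 N + k2 N^2 + k3 sqrt(T)`` (T = days after
  exposure, no intercept), fitted either by ordinary least squares or by
  robust M-estimation (iteratively reweighted least squares with Tukey
  bisquare weights, MAD residual scale);
* the qPCR model ``D = b0 + b1 N + b2 N^2`` with optional sex main effect
  and interactions (``Sex``, ``Sex x N``, ``Sex x N^2``; male = 1,
  female = 0), fitted by OLS; non-significant sex terms are dropped to the
  reduced quadratic model.

Both are exposed as scikit-learn regressors (:class:`NetSignalDoseModel`,
:class:`QuadraticDoseRegressor`) plus thin functional wrappers mirroring
the pipeline's stage vocabulary.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin

from .datatypes import FitError, FitMetrics, NetSignalVector, ValidationError, sex_to_numeric

#: Tukey bisquare tuning constant (95% Gaussian efficiency)
TUKEY_C = 4.685
#: MAD-to-sigma consistency factor for Gaussian residuals
MAD_SCALE = 0.6745

_TIME_POWERS = {"sqrt": 0.5, "linear": 1.0, "quadratic": 2.0}


def _time_regressor(time: np.ndarray, structure: str) -> np.ndarray:
    if structure not in _TIME_POWERS:
        raise ValidationError(f"unknown time structure {structure!r}")
    return np.asarray(time, float) ** _TIME_POWERS[structure]


def build_design(
    n: np.ndarray, time: np.ndarray, structure: str = "sqrt", additive: bool = True
) -> tuple[np.ndarray, list[str]]:
    """Regressor matrix for a dose model variant (no intercept).

    Additive: columns [N, N^2, g(T)]; multiplicative: [N g(T), N^2 g(T)]
    where g raises T to the structure's power.
    """
    n = np.asarray(n, dtype=float)
    g = _time_regressor(time, structure)
    if additive:
        X = np.column_stack([n, n**2, g])
        names = ["k1", "k2", "k3"]
    else:
        X = np.column_stack([n * g, n**2 * g])
        names = ["k1", "k2"]
    return X, names


def _wls_solve(X: np.ndarray, y: np.ndarray, w: np.ndarray) -> np.ndarray:
    sw = np.sqrt(w)
    beta, *_ = np.linalg.lstsq(X * sw[:, None], y * sw, rcond=None)
    return beta


def irls_tukey(
    X: np.ndarray,
    y: np.ndarray,
    c: float = TUKEY_C,
    max_iter: int = 50,
    tol: float = 1e-8,
) -> tuple[np.ndarray, np.ndarray, float, bool, int]:
    """Robust M-estimation via IRLS with Tukey bisquare weights.

    Starts from the OLS solution; the residual scale is re-estimated each
    iteration as MAD(|r|)/0.6745.  A (near-)zero scale means an essentially
    exact fit, in which case all weights are 1 and the OLS solution is
    returned as-is — this makes the robust fit coincide with OLS on
    noise-free data.

    Returns (beta, weights, scale, converged, n_iter).
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    beta = _wls_solve(X, y, np.ones(len(y)))
    w = np.ones(len(y))
    scale_floor = 1e-10 * max(1.0, float(np.abs(y).max(initial=0.0)))
    scale = 0.0
    for it in range(1, max_iter + 1):
        r = y - X @ beta
        scale = float(np.median(np.abs(r))) / MAD_SCALE
        if scale <= scale_floor:
            return beta, np.ones(len(y)), scale, True, it
        u = r / (c * scale)
        w = np.where(np.abs(u) < 1.0, (1.0 - u**2) ** 2, 0.0)
        if w.sum() == 0:
            raise FitError("all observations down-weighted to zero")
        beta_new = _wls_solve(X, y, w)
        if np.max(np.abs(beta_new - beta)) < tol * max(1.0, np.max(np.abs(beta_new))):
            return beta_new, w, scale, True, it
        beta = beta_new
    return beta, w, scale, False, max_iter


def _wls_inference(
    X: np.ndarray, y: np.ndarray, beta: np.ndarray, w: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Standard errors and two-sided t p-values from the final weighted system."""
    n, p = X.shape
    r = y - X @ beta
    df = max(n - p, 1)
    sigma2 = float(np.sum(w * r**2)) / df
    xtwx = X.T @ (w[:, None] * X)
    cov = sigma2 * np.linalg.pinv(xtwx)
    se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = np.where(se > 0, beta / se, np.inf * np.sign(beta))
    pvals = 2.0 * stats.t.sf(np.abs(tstat), df=df)
    return se, pvals


class NetSignalDoseModel(RegressorMixin, BaseEstimator):
    """Dose model ``D = k1 N + k2 N^2 + k3 g(T)`` (additive) or
    ``D = (k1 N + k2 N^2) g(T)`` (multiplicative), no intercept.

    Parameters
    ----------
    loss : "robust" (Tukey-bisquare IRLS) or "ols"
    time_structure : "sqrt" | "linear" | "quadratic" — the power of T in g
    additive : whether the time term enters additively
    tuning_constant, max_iter, tol : IRLS controls
    cond_threshold : design condition number above which the fit is flagged

    fit(X, y) takes X of shape (n, 2) with columns [N, time_days] and dose
    in Gy as y.  Fitted attributes: ``coef_`` (k1, k2[, k3]), ``se_``,
    ``pvalues_``, ``weights_``, ``scale_``, ``converged_``, ``n_iter_``,
    ``condition_number_``, ``ill_conditioned_``.
    """

    def __init__(
        self,
        loss: str = "robust",
        time_structure: str = "sqrt",
        additive: bool = True,
        tuning_constant: float = TUKEY_C,
        max_iter: int = 50,
        tol: float = 1e-8,
        cond_threshold: float = 1e8,
    ):
        self.loss = loss
        self.time_structure = time_structure
        self.additive = additive
        self.tuning_constant = tuning_constant
        self.max_iter = max_iter
        self.tol = tol
        self.cond_threshold = cond_threshold

    def _split_X(self, X) -> tuple[np.ndarray, np.ndarray]:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != 2:
            raise ValidationError("X must have two columns: [net_signal, time_days]")
        return X[:, 0], X[:, 1]

    def fit(self, X, y):
        if self.loss not in ("robust", "ols"):
            raise ValidationError(f"unknown loss {self.loss!r}")
        n_val, time = self._split_X(X)
        y = np.asarray(y, dtype=float)
        if len(y) < 4:
            raise ValidationError("need >= 4 samples")
        if np.unique(y).size < 2:
            # degenerate all-zero-dose data is allowed; a single nonzero
            # constant dose cannot identify the no-intercept model
            if not np.allclose(y, 0.0):
                raise ValidationError("need >= 2 distinct doses")
        if (time < 0).any():
            raise ValidationError("time_days must be >= 0")
        design, names = build_design(n_val, time, self.time_structure, self.additive)
        self.n_features_in_ = 2
        self.coef_names_ = names
        with np.errstate(divide="ignore"):
            self.condition_number_ = float(np.linalg.cond(design))
        self.ill_conditioned_ = not np.isfinite(self.condition_number_) or (
            self.condition_number_ > self.cond_threshold
        )
        if self.loss == "ols":
            beta, *_ = np.linalg.lstsq(design, y, rcond=None)
            w = np.ones(len(y))
            self.scale_ = float(np.std(y - design @ beta))
            self.converged_, self.n_iter_ = True, 0
        else:
            beta, w, scale, converged, n_iter = irls_tukey(
                design, y, c=self.tuning_constant, max_iter=self.max_iter, tol=self.tol
            )
            if not converged:
                raise FitError(
                    f"robust fit did not converge in {self.max_iter} iterations "
                    f"(scale={scale:.4g}, coef={beta})"
                )
            self.scale_, self.converged_, self.n_iter_ = scale, converged, n_iter
        self.coef_ = beta
        self.weights_ = w
        self.se_, self.pvalues_ = _wls_inference(design, y, beta, w)
        return self

    def predict(self, X) -> np.ndarray:
        """Raw (unfloored) reconstructed dose in Gy."""
        if not hasattr(self, "coef_"):
            raise FitError("model is not fitted")
        n_val, time = self._split_X(X)
        design, _ = build_design(n_val, time, self.time_structure, self.additive)
        return design @ self.coef_


@dataclass
class Eq1Fit:
    """Fitted coefficients of D = k1 N + k2 N^2 + k3 sqrt(T)."""

    k1: float
    k2: float
    k3: float
    se_k1: float
    se_k2: float
    se_k3: float
    p_k1: float
    p_k2: float
    p_k3: float
    loss: str
    converged: bool
    n_iterations: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "parameter": ["k1", "k2", "k3"],
                "estimate": [self.k1, self.k2, self.k3],
                "se": [self.se_k1, self.se_k2, self.se_k3],
                "p_value": [self.p_k1, self.p_k2, self.p_k3],
            }
        )


def fit_eq1(
    n: NetSignalVector | np.ndarray,
    time_days: np.ndarray,
    dose_gy: np.ndarray,
    loss: str = "robust",
) -> Eq1Fit:
    """Fit the microarray dose model on net signal, time, and dose."""
    values = n.values if isinstance(n, NetSignalVector) else np.asarray(n, float)
    model = NetSignalDoseModel(loss=loss).fit(
        np.column_stack([values, np.asarray(time_days, float)]), dose_gy
    )
    k = model.coef_
    return Eq1Fit(
        k1=float(k[0]),
        k2=float(k[1]),
        k3=float(k[2]),
        se_k1=float(model.se_[0]),
        se_k2=float(model.se_[1]),
        se_k3=float(model.se_[2]),
        p_k1=float(model.pvalues_[0]),
        p_k2=float(model.pvalues_[1]),
        p_k3=float(model.pvalues_[2]),
        loss=loss,
        converged=bool(model.converged_),
        n_iterations=int(model.n_iter_),
    )


def predict_dose_eq1(
    fit: Eq1Fit, n, time_days
) -> tuple[np.ndarray, np.ndarray]:
    """Reconstructed dose from an Eq1Fit: (raw, floored-at-0).

    Fit metrics use the raw values; per-sample reports typically show the
    floored column since negative absorbed dose is unphysical.
    """
    if not fit.converged:
        raise FitError("fit did not converge; predictions unavailable")
    values = n.values if isinstance(n, NetSignalVector) else np.asarray(n, float)
    time = np.asarray(time_days, dtype=float)
    if (time < 0).any():
        raise ValidationError("time_days must be >= 0")
    raw = fit.k1 * values + fit.k2 * values**2 + fit.k3 * np.sqrt(time)
    return raw, np.maximum(raw, 0.0)


class QuadraticDoseRegressor(RegressorMixin, BaseEstimator):
    """OLS dose reconstruction ``D = b0 + b1 N + b2 N^2`` with optional
    sex terms (Sex, Sex x N, Sex x N^2; male = 1, female = 0).

    fit(X, y): X is (n, 1) with column [N], or (n, 2) with columns
    [N, sex01] when ``include_sex_terms``.  Fitted attributes ``params_``,
    ``bse_``, ``pvalues_`` are pandas Series indexed by term name
    (Intercept, N, N2[, Sex, SexN, SexN2]); ``result_`` holds the
    statsmodels results object.
    """

    TERMS_REDUCED = ["Intercept", "N", "N2"]
    TERMS_FULL = ["Intercept", "N", "N2", "Sex", "SexN", "SexN2"]

    def __init__(self, include_sex_terms: bool = False):
        self.include_sex_terms = include_sex_terms

    def _design(self, X) -> pd.DataFrame:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValidationError("X must be 2-dimensional")
        n = X[:, 0]
        cols = {"Intercept": np.ones(len(n)), "N": n, "N2": n**2}
        if self.include_sex_terms:
            if X.shape[1] < 2:
                raise ValidationError(
                    "include_sex_terms requires X columns [N, sex01]"
                )
            s = X[:, 1]
            if not np.isin(s, (0.0, 1.0)).all():
                raise ValidationError("sex column must be coded 0 (F) / 1 (M)")
            cols.update({"Sex": s, "SexN": s * n, "SexN2": s * n**2})
        return pd.DataFrame(cols)

    def fit(self, X, y):
        design = self._design(X)
        y = np.asarray(y, dtype=float)
        if self.include_sex_terms:
            s = design["Sex"]
            if s.nunique() < 2:
                raise ValidationError(
                    "only one sex present; fit the reduced (no-sex) model instead"
                )
            if len(y) < 7:
                raise ValidationError("need >= 7 samples for the sex model")
        self._X_fit = np.asarray(X, dtype=float)
        self._y_fit = y
        res = sm.OLS(y, design).fit()
        self.result_ = res
        self.params_ = res.params
        self.bse_ = res.bse
        self.pvalues_ = res.pvalues
        self.n_features_in_ = self._X_fit.shape[1]
        return self

    @property
    def terms(self) -> list[str]:
        return self.TERMS_FULL if self.include_sex_terms else self.TERMS_REDUCED

    def predict(self, X) -> np.ndarray:
        if not hasattr(self, "params_"):
            raise FitError("model is not fitted")
        return np.asarray(self.result_.predict(self._design(X)), dtype=float)

    def coefficient_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "parameter": list(self.params_.index),
                "estimate": self.params_.to_numpy(),
                "se": self.bse_.to_numpy(),
                "p_value": self.pvalues_.to_numpy(),
            }
        )


def fit_quadratic_sex_model(
    n: NetSignalVector | np.ndarray, dose_gy, sex
) -> QuadraticDoseRegressor:
    """Full qPCR dose model with sex main effect and interactions."""
    values = n.values if isinstance(n, NetSignalVector) else np.asarray(n, float)
    sex01 = sex_to_numeric(sex) if not np.issubdtype(np.asarray(sex).dtype, np.number) else np.asarray(sex, float)
    X = np.column_stack([values, sex01])
    return QuadraticDoseRegressor(include_sex_terms=True).fit(X, dose_gy)


def reduce_model(
    full: QuadraticDoseRegressor, alpha: float = 0.05
) -> tuple[QuadraticDoseRegressor, bool]:
    """Drop the sex terms when none is significant at ``alpha``.

    Returns ``(model, reduced)``.  If every Sex-containing p-value exceeds
    alpha, the model is refitted on {1, N, N^2} only; otherwise the full
    model is returned unchanged with ``reduced=False``.
    """
    if not full.include_sex_terms:
        raise ValidationError("reduce_model expects a model with sex terms")
    sex_p = full.pvalues_[["Sex", "SexN", "SexN2"]]
    # On an exact (zero-residual) fit the sex coefficients are numerically
    # zero but their 0/0 t-statistics are meaningless; a zero coefficient
    # carries no sex signal and is droppable regardless of its nominal p.
    zero_tol = 1e-8 * max(1.0, float(np.abs(full._y_fit).max()))
    droppable = (sex_p > alpha) | (
        full.params_[["Sex", "SexN", "SexN2"]].abs() < zero_tol
    )
    if droppable.all():
        reduced = QuadraticDoseRegressor(include_sex_terms=False).fit(
            full._X_fit[:, :1], full._y_fit
        )
        return reduced, True
    return full, False


def predict_dose_quadratic(
    model: QuadraticDoseRegressor, n, sex=None
) -> tuple[np.ndarray, np.ndarray]:
    """Reconstructed dose from the quadratic model: (raw, floored-at-0)."""
    values = n.values if isinstance(n, NetSignalVector) else np.asarray(n, float)
    if model.include_sex_terms:
        if sex is None:
            raise ValidationError("model has sex terms; sex must be supplied")
        sex01 = (
            sex_to_numeric(sex)
            if not np.issubdtype(np.asarray(sex).dtype, np.number)
            else np.asarray(sex, float)
        )
        X = np.column_stack([values, sex01])
    else:
        X = values[:, None]
    raw = model.predict(X)
    return raw, np.maximum(raw, 0.0)


def fit_metrics(d_hat, d_true) -> FitMetrics:
    """RMSE (Gy) and R^2 of reconstructed vs actual dose, on raw predictions."""
    d_hat = np.asarray(d_hat, dtype=float)
    d_true = np.asarray(d_true, dtype=float)
    if d_hat.shape != d_true.shape or d_hat.size < 2:
        raise ValidationError("d_hat and d_true must be equal-length, size >= 2")
    rmse = float(np.sqrt(np.mean((d_hat - d_true) ** 2)))
    ss_tot = float(np.sum((d_true - d_true.mean()) ** 2))
    if ss_tot == 0:
        return FitMetrics(r2=float("nan"), rmse=rmse, n_samples=d_true.size, r2_defined=False)
    r2 = 1.0 - float(np.sum((d_hat - d_true) ** 2)) / ss_tot
    return FitMetrics(r2=r2, rmse=rmse, n_samples=d_true.size)


def compare_time_structures(
    n: NetSignalVector | np.ndarray,
    time_days,
    dose_gy,
    n_splits: int = 100,
    base_seed: int = 0,
) -> pd.DataFrame:
    """Rank all dose-model time-structure variants by held-out RMSE.

    Twelve variants — time raised to powers {1/2, 1, 2}, entering additively
    or multiplicatively, each fitted by robust and OLS losses — are scored
    by mean test RMSE over repeated random half splits.  With a single time
    point in the data the time term is absorbed and all structures are
    declared tied.
    """
    from .evaluation import repeated_split_evaluation  # deferred: avoids cycle

    values = n.values if isinstance(n, NetSignalVector) else np.asarray(n, float)
    time = np.asarray(time_days, dtype=float)
    dose = np.asarray(dose_gy, dtype=float)
    tied = np.unique(time).size == 1

    rows = []
    for structure in ("sqrt", "linear", "quadratic"):
        for additive in (True, False):
            for loss in ("robust", "ols"):
                proto = NetSignalDoseModel(
                    loss=loss, time_structure=structure, additive=additive
                )
                ev = repeated_split_evaluation(
                    values, time, dose, model_spec=proto,
                    n_splits=n_splits, base_seed=base_seed,
                )
                rows.append(
                    {
                        "time_structure": structure,
                        "additive": additive,
                        "loss": loss,
                        "mean_test_rmse": ev.summary["test_rmse_mean"],
                        "sd_test_rmse": ev.summary["test_rmse_sd"],
                        "n_failed_splits": ev.n_failed,
                    }
                )
    out = pd.DataFrame(rows)
    if tied:
        out["rank"] = 1
    else:
        out["rank"] = out["mean_test_rmse"].rank(method="min").astype(int)
    out["tied"] = tied
    return out.sort_values("mean_test_rmse", kind="mergesort").reset_index(drop=True)
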