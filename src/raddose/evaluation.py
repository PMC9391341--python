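"""Repeated random half-split validation and signature-size sensitivity.

The stability of a dose-reconstruction model is assessed by repeatedly
splitting the samples into random halves, refitting on the training half,
and scoring RMSE/R^2 on both halves.  Per-split seeds derive
deterministically from one base seed (seed + split index), so a full run is
reproducible from a single integer.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import clone

from .datatypes import FitError, NetSignalVector, ValidationError
from .models import NetSignalDoseModel, QuadraticDoseRegressor, fit_metrics

MODEL_SPECS = ("eq1_robust", "eq1_ols", "quadratic")


@dataclass
class SplitEvaluation:
    """Per-split records plus mean/SD summaries of each metric."""

    records: pd.DataFrame  # columns: seed, train_r2, train_rmse, test_rmse, test_r2
    summary: dict
    n_splits: int
    n_failed: int = 0
    failures: list = field(default_factory=list)

    def recompute_summary(self) -> dict:
        return _summarize(self.records)


def _summarize(records: pd.DataFrame) -> dict:
    out = {}
    for col in ("train_r2", "train_rmse", "test_rmse", "test_r2"):
        vals = records[col].to_numpy(float)
        out[f"{col}_mean"] = float(np.mean(vals)) if vals.size else float("nan")
        out[f"{col}_sd"] = float(np.std(vals, ddof=1)) if vals.size > 1 else 0.0
    return out


def random_half_split(
    sample_ids, seed: int, stratify=None
) -> tuple[list, list]:
    """Disjoint, exhaustive random halves (sizes differ by <= 1).

    With ``stratify`` (per-sample labels, e.g. dose), each stratum is halved
    separately so small dose groups cannot vanish from one half.
    """
    ids = list(sample_ids)
    if len(ids) < 4:
        raise ValidationError("need >= 4 samples to split")
    rng = np.random.default_rng(seed)
    if stratify is None:
        perm = rng.permutation(len(ids))
        half = len(ids) // 2
        train = [ids[i] for i in perm[:half]]
        test = [ids[i] for i in perm[half:]]
    else:
        labels = np.asarray(stratify)
        if labels.shape[0] != len(ids):
            raise ValidationError("stratify length mismatch")
        train, test = [], []
        # alternate which half receives the extra sample of odd strata
        extra_to_train = True
        for lab in pd.unique(labels):
            idx = np.flatnonzero(labels == lab)
            perm = rng.permutation(idx)
            half = len(perm) // 2
            if len(perm) % 2 == 1 and extra_to_train:
                half += 1
            if len(perm) % 2 == 1:
                extra_to_train = not extra_to_train
            train.extend(ids[i] for i in perm[:half])
            test.extend(ids[i] for i in perm[half:])
    return train, test


def _resolve_model(model_spec) -> tuple[object, bool]:
    """Return (prototype estimator, uses_time)."""
    if isinstance(model_spec, str):
        if model_spec == "eq1_robust":
            return NetSignalDoseModel(loss="robust"), True
        if model_spec == "eq1_ols":
            return NetSignalDoseModel(loss="ols"), True
        if model_spec == "quadratic":
            return QuadraticDoseRegressor(), False
        raise ValidationError(
            f"unknown model_spec {model_spec!r}; expected one of {MODEL_SPECS}"
        )
    return model_spec, isinstance(model_spec, NetSignalDoseModel)


def repeated_split_evaluation(
    n: NetSignalVector | np.ndarray,
    time_days,
    dose_gy,
    model_spec="eq1_robust",
    n_splits: int = 1000,
    base_seed: int = 0,
    stratify_by_dose: bool = False,
) -> SplitEvaluation:
    """Refit the model on random training halves, score train and test halves.

    ``model_spec`` is ``"eq1_robust"`` (default), ``"eq1_ols"``,
    ``"quadratic"``, or any unfitted estimator taking X=[N, time] (dose
    models) / X=[N] (quadratic).  Split fit failures are recorded and
    excluded from the summary.
    """
    values = n.values if isinstance(n, NetSignalVector) else np.asarray(n, float)
    time = np.asarray(time_days, dtype=float)
    dose = np.asarray(dose_gy, dtype=float)
    proto, uses_time = _resolve_model(model_spec)
    X = np.column_stack([values, time]) if uses_time else values[:, None]

    idx = np.arange(len(dose))
    strat = dose if stratify_by_dose else None
    rows, failures = [], []
    for split in range(n_splits):
        seed = base_seed + split
        tr, te = random_half_split(idx, seed=seed, stratify=strat)
        tr = np.asarray(tr)
        te = np.asarray(te)
        try:
            model = clone(proto).fit(X[tr], dose[tr])
            m_tr = fit_metrics(model.predict(X[tr]), dose[tr])
            m_te = fit_metrics(model.predict(X[te]), dose[te])
        except (FitError, ValidationError, np.linalg.LinAlgError) as exc:
            failures.append({"seed": seed, "error": str(exc)})
            continue
        rows.append(
            {
                "seed": seed,
                "train_r2": m_tr.r2,
                "train_rmse": m_tr.rmse,
                "test_rmse": m_te.rmse,
                "test_r2": m_te.r2,
            }
        )
    records = pd.DataFrame(
        rows, columns=["seed", "train_r2", "train_rmse", "test_rmse", "test_r2"]
    )
    return SplitEvaluation(
        records=records,
        summary=_summarize(records),
        n_splits=n_splits,
        n_failed=len(failures),
        failures=failures,
    )


def group_size_sensitivity(
    expr,
    correlations: pd.DataFrame,
    size_pairs=((10, 10), (20, 10), (30, 30)),
) -> pd.DataFrame:
    """Correlation of N with dose for alternative signature group sizes.

    One row per (n_up, n_down) pair; pairs exceeding the available ranked
    genes are flagged rather than fatal.
    """
    from .netsignal import correlate_net_signal_with_dose, net_signal_array
    from .signature import select_signature

    rows = []
    for n_up, n_down in size_pairs:
        row = {"n_up": n_up, "n_down": n_down, "spearman_rho": float("nan"),
               "pearson_r": float("nan"), "flagged": False, "reason": ""}
        try:
            sig = select_signature(correlations, n_up=n_up, n_down=n_down)
            ns = net_signal_array(expr, sig)
            corr = correlate_net_signal_with_dose(ns, expr.dose)
            row["spearman_rho"] = corr["spearman_rho"]
            row["pearson_r"] = corr["pearson_r"]
            row["flagged"] = not corr["defined"]
        except ValidationError as exc:
            row["flagged"] = True
            row["reason"] = str(exc)
        rows.append(row)
    return pd.DataFrame(rows)
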