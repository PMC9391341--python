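"""The net-signal statistic N: difference between aggregates of the
up-regulated and down-regulated signature gene groups.

On arrays N is the difference of group *medians* of log2 signals.  On qPCR
the group aggregate on the delta-Ct (log2) scale is the arithmetic mean —
the geometric mean on the linear expression scale.  Because up-regulated
genes' delta-Ct falls with dose while down-regulated genes' rises, qPCR N
*decreases* with dose; array N increases.

N is invariant to any per-sample additive constant applied to all genes
(global normalization shifts, RNA input), which is what makes it a robust
dimension reduction for dose reconstruction.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin

from .datatypes import (
    ExpressionMatrix,
    GeneSignature,
    NetSignalVector,
    ValidationError,
)

_AGGREGATORS = {
    # geometric mean on the linear scale == arithmetic mean on the log2 scale
    "geometric_mean": np.mean,
    "median": np.median,
}


class NetSignalTransformer(TransformerMixin, BaseEstimator):
    """Reduce a samples x genes matrix to the per-sample net signal.

    Stateless apart from parameter validation; ``fit`` only records the
    feature layout.  ``transform`` returns shape (n_samples, 1) so the
    transformer drops into sklearn pipelines ahead of a dose model.
    """

    def __init__(
        self,
        signature: GeneSignature | None = None,
        aggregator: str = "median",
        feature_names: list[str] | None = None,
    ):
        self.signature = signature
        self.aggregator = aggregator
        self.feature_names = feature_names

    def fit(self, X, y=None):
        if self.signature is None:
            raise ValidationError("signature is required")
        if self.aggregator not in _AGGREGATORS:
            raise ValidationError(f"unknown aggregator {self.aggregator!r}")
        names = (
            [str(c) for c in X.columns]
            if isinstance(X, pd.DataFrame)
            else list(self.feature_names or [])
        )
        if not names:
            raise ValidationError("gene names required (DataFrame or feature_names)")
        missing = [g for g in self.signature.genes if g not in names]
        if missing:
            raise ValidationError(f"signature genes absent from input: {missing}")
        self._col_index = {g: i for i, g in enumerate(names)}
        self.n_features_in_ = len(names)
        return self

    def transform(self, X) -> np.ndarray:
        if not hasattr(self, "_col_index"):
            self.fit(X)
        agg = _AGGREGATORS[self.aggregator]
        Xa = np.asarray(X, dtype=float)
        up = [self._col_index[g] for g in self.signature.up_genes]
        dn = [self._col_index[g] for g in self.signature.down_genes]
        n = agg(Xa[:, up], axis=1) - agg(Xa[:, dn], axis=1)
        return n[:, None]


def net_signal_array(expr: ExpressionMatrix, sig: GeneSignature) -> NetSignalVector:
    """Median(up-group signals) - median(down-group signals), per sample."""
    missing = [g for g in sig.genes if g not in expr.signal.index]
    if missing:
        raise ValidationError(f"signature genes absent from matrix: {missing}")
    up = expr.signal.loc[sig.up_genes].to_numpy(float)
    dn = expr.signal.loc[sig.down_genes].to_numpy(float)
    values = np.median(up, axis=0) - np.median(dn, axis=0)
    return NetSignalVector(
        sample_ids=expr.sample_ids,
        values=values,
        aggregator="median",
        platform="array",
        signature=sig,
    )


def net_signal_qpcr(
    dct: pd.DataFrame, sig: GeneSignature, aggregator: str = "geometric_mean"
) -> NetSignalVector:
    """Per-sample N from a delta-Ct table (one row per sample x gene).

    With the default aggregator the group statistic is the arithmetic mean
    of delta-Ct — the geometric mean of linear-scale expression.  N is in
    cycle units and decreases with dose.
    """
    if aggregator not in _AGGREGATORS:
        raise ValidationError(f"unknown aggregator {aggregator!r}")
    agg = _AGGREGATORS[aggregator]
    present = set(dct["gene"].unique())
    missing = [g for g in sig.genes if g not in present]
    if missing:
        raise ValidationError(f"signature genes absent from delta-Ct table: {missing}")
    wide = dct.pivot_table(index="sample_id", columns="gene", values="dct", sort=False)
    if wide[sig.genes].isna().any().any():
        bad = wide.index[wide[sig.genes].isna().any(axis=1)].tolist()
        raise ValidationError(f"samples missing signature genes: {bad[:5]}")
    values = agg(wide[sig.up_genes].to_numpy(float), axis=1) - agg(
        wide[sig.down_genes].to_numpy(float), axis=1
    )
    return NetSignalVector(
        sample_ids=[str(s) for s in wide.index],
        values=values,
        aggregator=aggregator,
        platform="qpcr",
        signature=sig,
    )


def correlate_net_signal_with_dose(ns: NetSignalVector, dose) -> dict:
    """Spearman and Pearson correlation of N with dose.

    A constant net signal makes both undefined; the result is flagged
    rather than raising.
    """
    dose = np.asarray(dose, dtype=float)
    if len(ns) < 3:
        raise ValidationError("need >= 3 samples")
    if dose.shape[0] != len(ns):
        raise ValidationError("dose length mismatch")
    if np.std(ns.values) == 0 or np.std(dose) == 0:
        return {
            "spearman_rho": np.nan,
            "spearman_p": np.nan,
            "pearson_r": np.nan,
            "pearson_p": np.nan,
            "defined": False,
        }
    rho, p_s = stats.spearmanr(ns.values, dose)
    r, p_p = stats.pearsonr(ns.values, dose)
    return {
        "spearman_rho": float(rho),
        "spearman_p": float(p_s),
        "pearson_r": float(r),
        "pearson_p": float(p_p),
        "defined": True,
    }
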