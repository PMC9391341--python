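"""Dose-correlated gene ranking and signature selection.

Genes are ranked by the Spearman correlation of their expression with dose
across all samples (all post-exposure time points combined), retained when
the Bonferroni-corrected p-value is below alpha, and the signature is the
top ``n_up`` positively and top ``n_down`` negatively correlated survivors.

:class:`SpearmanSignatureSelector` packages the whole procedure as a
scikit-learn transformer whose :meth:`~SpearmanSignatureSelector.transform`
emits the per-sample net signal, so it composes with sklearn pipelines; the
module-level functions are thin wrappers operating on
:class:`~raddose.datatypes.ExpressionMatrix`.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin

from .datatypes import ExpressionMatrix, GeneSignature, ValidationError

#: below this sample count, Spearman p-values use the exact permutation null
EXACT_P_MAX_N = 10


def _spearman_t_pvalue(rho: np.ndarray, n: int) -> np.ndarray:
    """Two-sided p from the large-sample t approximation with n-2 df."""
    rho = np.clip(rho, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p[np.isinf(t)] = 0.0
    return np.minimum(p, 1.0)


def _exact_spearman_p(x: np.ndarray, y: np.ndarray, rho_obs: float) -> float:
    """Exact two-sided permutation p-value P(|rho| >= |rho_obs|) for small n.

    Enumerates all permutations of one variable; tie structures are
    respected because correlations are computed on midranks.
    """
    n = len(x)
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rx = (rx - rx.mean()) / rx.std()
    ry = (ry - ry.mean()) / ry.std()
    target = abs(rho_obs) - 1e-12
    count = 0
    total = 0
    for perm in itertools.permutations(range(n)):
        r = float(np.dot(rx[list(perm)], ry)) / n
        if abs(r) >= target:
            count += 1
        total += 1
    return count / total


def spearman_dose_correlations(
    X: np.ndarray, dose: np.ndarray, gene_ids: list[str]
) -> pd.DataFrame:
    """Spearman rho of each gene (columns of X, samples x genes) with dose.

    Returns a DataFrame with one row per gene: rho, two-sided p_value,
    p_bonferroni (multiplier = number of genes actually tested, i.e. with
    defined rho), direction, and a ``constant`` flag for zero-variance genes
    (flagged, excluded from ranking).  Rows are ordered by descending rho
    with constant genes last.
    """
    X = np.asarray(X, dtype=float)
    dose = np.asarray(dose, dtype=float)
    n, g = X.shape
    if np.unique(dose).size < 3:
        raise ValidationError("need >= 3 distinct dose levels")

    ranks = np.apply_along_axis(stats.rankdata, 0, X)
    dose_ranks = stats.rankdata(dose)
    constant = ranks.std(axis=0) == 0
    dr = dose_ranks - dose_ranks.mean()
    dr_norm = np.sqrt((dr**2).sum())
    rc = ranks - ranks.mean(axis=0)
    denom = np.sqrt((rc**2).sum(axis=0)) * dr_norm
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = (rc * dr[:, None]).sum(axis=0) / denom
    rho[constant] = np.nan

    if n < EXACT_P_MAX_N:
        p = np.array(
            [
                np.nan
                if constant[j]
                else _exact_spearman_p(X[:, j], dose, rho[j])
                for j in range(g)
            ]
        )
    else:
        p = _spearman_t_pvalue(rho, n)
        p[constant] = np.nan

    n_tested = int((~constant).sum())
    out = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "rho": rho,
            "p_value": p,
            "p_bonferroni": np.minimum(1.0, p * n_tested),
            "direction": np.where(rho > 0, "up", "down"),
            "constant": constant,
        }
    )
    out.loc[out["constant"], "direction"] = "undefined"
    out = out.sort_values(
        by=["constant", "rho"], ascending=[True, False], kind="mergesort"
    ).reset_index(drop=True)
    return out


def rank_genes_by_dose_correlation(expr: ExpressionMatrix) -> pd.DataFrame:
    """Rank all genes of an expression matrix by Spearman correlation with dose."""
    return spearman_dose_correlations(
        expr.signal.to_numpy(float).T, expr.dose, expr.gene_ids
    )


def bonferroni_filter(correlations: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Keep genes whose Bonferroni-corrected p-value is below alpha.

    Order is preserved; constant (untestable) genes never survive.  An empty
    survivor set is a valid result.
    """
    if correlations.empty:
        raise ValidationError("correlations table is empty")
    keep = (correlations["p_bonferroni"] < alpha) & ~correlations["constant"]
    return correlations.loc[keep].reset_index(drop=True)


def select_signature(
    correlations: pd.DataFrame, n_up: int = 20, n_down: int = 10
) -> GeneSignature:
    """Top ``n_up`` positive-rho and ``n_down`` negative-rho genes.

    Ties in rho are broken by smaller raw p-value, then lexicographic gene ID.
    """
    usable = correlations.loc[~correlations["constant"]]
    pos = usable.loc[usable["rho"] > 0].copy()
    neg = usable.loc[usable["rho"] < 0].copy()
    if len(pos) < n_up or len(neg) < n_down:
        raise ValidationError(
            f"insufficient survivors: need {n_up} positive (have {len(pos)}) "
            f"and {n_down} negative (have {len(neg)})"
        )
    pos = pos.sort_values(
        by=["rho", "p_value", "gene_id"], ascending=[False, True, True], kind="mergesort"
    )
    neg = neg.sort_values(
        by=["rho", "p_value", "gene_id"], ascending=[True, True, True], kind="mergesort"
    )
    return GeneSignature(
        up_genes=pos["gene_id"].head(n_up).tolist(),
        down_genes=neg["gene_id"].head(n_down).tolist(),
    )


def pairwise_correlation_matrix(
    expr: ExpressionMatrix, genes: list[str], method: str = "spearman"
) -> pd.DataFrame:
    """Symmetric gene-gene correlation matrix over the given genes.

    Constant genes yield NaN rows/columns (flagged, diagonal kept at 1).
    """
    if len(genes) < 2:
        raise ValidationError("need >= 2 genes")
    missing = [g for g in genes if g not in expr.signal.index]
    if missing:
        raise ValidationError(f"genes absent from matrix: {missing}")
    if method not in ("spearman", "pearson"):
        raise ValidationError(f"unknown method {method!r}")
    sub = expr.signal.loc[genes].to_numpy(float)
    if method == "spearman":
        sub = np.apply_along_axis(stats.rankdata, 1, sub)
    sd = sub.std(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(sub)
    corr[sd == 0, :] = np.nan
    corr[:, sd == 0] = np.nan
    np.fill_diagonal(corr, 1.0)
    return pd.DataFrame(corr, index=genes, columns=genes)


class SpearmanSignatureSelector(TransformerMixin, BaseEstimator):
    """Select a dose-correlated gene signature and emit the net signal.

    fit(X, y)
        ``X`` is samples x genes (array or DataFrame; gene names come from
        DataFrame columns or ``feature_names``), ``y`` is dose in Gy.
        Ranks genes by Spearman correlation with dose, applies the
        Bonferroni filter at ``alpha``, and keeps the top ``n_up`` / ``n_down``
        survivors per direction.

    transform(X)
        Per-sample net signal (median of up genes minus median of down
        genes), shape (n_samples, 1).

    Attributes
    ----------
    correlations_ : DataFrame of per-gene rho / p / p_bonferroni / direction
    signature_ : GeneSignature of the selected genes
    """

    def __init__(
        self,
        n_up: int = 20,
        n_down: int = 10,
        alpha: float = 0.05,
        feature_names: list[str] | None = None,
    ):
        self.n_up = n_up
        self.n_down = n_down
        self.alpha = alpha
        self.feature_names = feature_names

    def _names(self, X) -> list[str]:
        if isinstance(X, pd.DataFrame):
            return [str(c) for c in X.columns]
        if self.feature_names is not None:
            return list(self.feature_names)
        return [f"g{j}" for j in range(np.asarray(X).shape[1])]

    def fit(self, X, y):
        names = self._names(X)
        Xa = np.asarray(X, dtype=float)
        if Xa.ndim != 2 or Xa.shape[0] != len(np.asarray(y)):
            raise ValidationError("X must be samples x genes matching len(y)")
        self.feature_names_in_ = np.asarray(names, dtype=object)
        self.n_features_in_ = Xa.shape[1]
        self.correlations_ = spearman_dose_correlations(Xa, np.asarray(y, float), names)
        survivors = bonferroni_filter(self.correlations_, alpha=self.alpha)
        self.signature_ = select_signature(survivors, n_up=self.n_up, n_down=self.n_down)
        self._col_index = {g: i for i, g in enumerate(names)}
        return self

    def transform(self, X) -> np.ndarray:
        if not hasattr(self, "signature_"):
            raise ValidationError("selector is not fitted")
        Xa = np.asarray(X, dtype=float)
        up_idx = [self._col_index[g] for g in self.signature_.up_genes]
        dn_idx = [self._col_index[g] for g in self.signature_.down_genes]
        n = np.median(Xa[:, up_idx], axis=1) - np.median(Xa[:, dn_idx], axis=1)
        return n[:, None]
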