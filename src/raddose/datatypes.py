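"""Core containers shared by all pipeline stages.

The two structured containers are :class:`ExpressionMatrix` (a genes x
samples log2-signal matrix paired with per-sample metadata) and
:class:`GeneSignature` (the ordered up-/down-regulated gene lists).  qPCR
Ct data and per-gene correlation tables travel as plain :class:`pandas.DataFrame`
objects with documented schemas — see :mod:`raddose.qpcr` and
:mod:`raddose.signature`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd


class ValidationError(ValueError):
    """Raised when an input table or configuration fails validation."""


class FitError(RuntimeError):
    """Raised when a model fit cannot be completed (rank deficiency,
    non-convergence, degenerate inputs)."""


#: Required columns of a long-format Ct table (one row per well).
CT_TABLE_COLUMNS = ("sample_id", "mouse_id", "sex", "dose_gy", "gene", "well", "ct")

#: Required columns of the per-sample metadata accompanying an expression matrix.
METADATA_COLUMNS = ("dose_gy", "time_days", "study")


@dataclass
class ExpressionMatrix:
    """Normalized log2-scale expression signals with sample metadata.

    Parameters
    ----------
    signal : DataFrame, shape (n_genes, n_samples)
        Rows indexed by gene ID, columns by sample ID.
    metadata : DataFrame, shape (n_samples, >=3)
        Indexed by sample ID; must carry ``dose_gy`` (>= 0), ``time_days``
        (> 0) and ``study`` columns.  A ``sex`` column is optional.
    """

    signal: pd.DataFrame
    metadata: pd.DataFrame

    def __post_init__(self) -> None:
        if self.signal.index.duplicated().any():
            dups = self.signal.index[self.signal.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicated gene IDs: {dups[:5]}")
        missing = [c for c in METADATA_COLUMNS if c not in self.metadata.columns]
        if missing:
            raise ValidationError(f"metadata missing columns: {missing}")
        sig_samples = list(self.signal.columns)
        meta_samples = list(self.metadata.index)
        if set(sig_samples) != set(meta_samples):
            only_sig = sorted(set(sig_samples) - set(meta_samples))
            only_meta = sorted(set(meta_samples) - set(sig_samples))
            raise ValidationError(
                "sample IDs differ between matrix and metadata: "
                f"matrix-only={only_sig[:5]}, metadata-only={only_meta[:5]}"
            )
        # align metadata row order to matrix column order
        self.metadata = self.metadata.loc[sig_samples]
        dose = pd.to_numeric(self.metadata["dose_gy"], errors="coerce")
        time = pd.to_numeric(self.metadata["time_days"], errors="coerce")
        if dose.isna().any() or (dose < 0).any():
            raise ValidationError("dose_gy must be numeric and >= 0 for every sample")
        if time.isna().any() or (time <= 0).any():
            raise ValidationError("time_days must be numeric and > 0 for every sample")
        self.metadata["dose_gy"] = dose.astype(float)
        self.metadata["time_days"] = time.astype(float)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.signal.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.signal.columns)

    @property
    def dose(self) -> np.ndarray:
        return self.metadata["dose_gy"].to_numpy(float)

    @property
    def time(self) -> np.ndarray:
        return self.metadata["time_days"].to_numpy(float)

    @property
    def n_genes(self) -> int:
        return self.signal.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    def equals(self, other: "ExpressionMatrix") -> bool:
        return self.signal.equals(other.signal) and self.metadata.equals(other.metadata)


@dataclass
class GeneSignature:
    """Ordered up- and down-regulated gene lists.

    ``up_genes`` are sorted by descending dose correlation, ``down_genes``
    by ascending (most negative first).
    """

    up_genes: list[str]
    down_genes: list[str]

    def __post_init__(self) -> None:
        self.up_genes = list(self.up_genes)
        self.down_genes = list(self.down_genes)
        overlap = set(self.up_genes) & set(self.down_genes)
        if overlap:
            raise ValidationError(f"up/down gene lists overlap: {sorted(overlap)[:5]}")
        if not self.up_genes or not self.down_genes:
            raise ValidationError("both up and down gene lists must be nonempty")

    @property
    def n_up(self) -> int:
        return len(self.up_genes)

    @property
    def n_down(self) -> int:
        return len(self.down_genes)

    @property
    def genes(self) -> list[str]:
        return self.up_genes + self.down_genes

    def swapped(self) -> "GeneSignature":
        """Signature with the up and down groups exchanged (negates N)."""
        return GeneSignature(up_genes=self.down_genes, down_genes=self.up_genes)


@dataclass
class NetSignalVector:
    """Per-sample scalar net signal N with provenance.

    N is the difference between an aggregate of the up-regulated group and
    an aggregate of the down-regulated group; units are log2-signal units
    on arrays and Ct cycles (delta-Ct) on qPCR.
    """

    sample_ids: list[str]
    values: np.ndarray
    aggregator: str  # "median" | "geometric_mean"
    platform: str  # "array" | "qpcr"
    signature: GeneSignature

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.sample_ids) != self.values.shape[0]:
            raise ValidationError("sample_ids and values length mismatch")
        if self.aggregator not in ("median", "geometric_mean"):
            raise ValidationError(f"unknown aggregator {self.aggregator!r}")
        if self.platform not in ("array", "qpcr"):
            raise ValidationError(f"unknown platform {self.platform!r}")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"sample_id": self.sample_ids, "net_signal": self.values}
        ).set_index("sample_id")

    def __len__(self) -> int:
        return self.values.shape[0]


@dataclass
class FitMetrics:
    """Goodness of reconstruction: RMSE (Gy) and R^2 of predicted vs actual dose."""

    r2: float
    rmse: float
    n_samples: int
    r2_defined: bool = True


def validate_ct_table(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a long-format Ct table and coerce dtypes.

    Required columns: sample_id, mouse_id, sex (M/F), dose_gy, gene, well, ct.
    """
    missing = [c for c in CT_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"Ct table missing columns: {missing}")
    out = df.copy()
    out["ct"] = pd.to_numeric(out["ct"], errors="coerce")
    if out["ct"].isna().any() or (out["ct"] <= 0).any():
        raise ValidationError("ct values must be numeric and > 0")
    out["dose_gy"] = pd.to_numeric(out["dose_gy"], errors="coerce")
    if out["dose_gy"].isna().any() or (out["dose_gy"] < 0).any():
        raise ValidationError("dose_gy must be numeric and >= 0")
    bad_sex = set(out["sex"].unique()) - {"M", "F"}
    if bad_sex:
        raise ValidationError(f"unknown sex codes: {sorted(bad_sex)} (expected M/F)")
    return out


def sex_to_numeric(sex: Sequence[str]) -> np.ndarray:
    """Encode sex for regression: male = 1, female = 0."""
    arr = np.asarray(sex)
    out = np.where(arr == "M", 1.0, np.where(arr == "F", 0.0, np.nan))
    if np.isnan(out).any():
        raise ValidationError("sex labels must be 'M' or 'F'")
    return out
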