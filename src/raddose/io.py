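"""Delimited-text readers and writers shared by all pipeline stages.

All tables are TSV with header rows; fitted models and summaries are JSON.
The expression matrix travels as a pair of files: the signal matrix (genes
as rows, first column ``gene_id``) and a sample-metadata table
(``sample_id``, ``dose_gy``, ``time_days``, ``study``[, ``sex``]).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import (
    ExpressionMatrix,
    GeneSignature,
    NetSignalVector,
    ValidationError,
    validate_ct_table,
)


def _require(path) -> Path:
    p = Path(path)
    if not p.exists():
        raise ValidationError(f"input file not found: {p}")
    return p


def read_expression_matrix(matrix_path, metadata_path) -> ExpressionMatrix:
    """Read and validate a (matrix TSV, metadata TSV) pair."""
    mpath = _require(matrix_path)
    spath = _require(metadata_path)
    mat = pd.read_csv(mpath, sep="\t", index_col=0)
    bad = mat.columns[~mat.apply(lambda c: pd.to_numeric(c, errors="coerce").notna().all())]
    if len(bad):
        raise ValidationError(f"non-numeric signal values in columns: {list(bad)[:5]}")
    mat = mat.astype(float)
    mat.index = mat.index.astype(str)
    mat.index.name = "gene_id"
    meta = pd.read_csv(spath, sep="\t", index_col=0)
    meta.index = meta.index.astype(str)
    meta.index.name = "sample_id"
    return ExpressionMatrix(signal=mat, metadata=meta)


def write_expression_matrix(expr: ExpressionMatrix, matrix_path, metadata_path) -> None:
    Path(matrix_path).parent.mkdir(parents=True, exist_ok=True)
    expr.signal.to_csv(matrix_path, sep="\t", index_label="gene_id")
    expr.metadata.to_csv(metadata_path, sep="\t", index_label="sample_id")


def read_ct_table(path) -> pd.DataFrame:
    """Read and validate a long-format Ct table TSV."""
    df = pd.read_csv(_require(path), sep="\t")
    return validate_ct_table(df)


def write_ct_table(df: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False)


def write_signature(sig: GeneSignature, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Path(path).write_text(
        json.dumps(
            {"up_genes": sig.up_genes, "down_genes": sig.down_genes}, indent=2
        )
        + "\n"
    )


def read_signature(path) -> GeneSignature:
    data = json.loads(_require(path).read_text())
    try:
        return GeneSignature(up_genes=data["up_genes"], down_genes=data["down_genes"])
    except KeyError as exc:
        raise ValidationError(f"signature file missing key: {exc}") from exc


def write_net_signal(ns: NetSignalVector, metadata: pd.DataFrame, path) -> None:
    """Per-sample N with metadata columns (dose_gy, time_days, sex where present)."""
    out = ns.to_frame()
    keep = [c for c in ("dose_gy", "time_days", "study", "sex") if c in metadata.columns]
    out = out.join(metadata[keep], how="left")
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    out.to_csv(path, sep="\t", index_label="sample_id")


def read_net_signal(path) -> pd.DataFrame:
    df = pd.read_csv(_require(path), sep="\t", index_col="sample_id")
    if "net_signal" not in df.columns:
        raise ValidationError("net-signal table must have a 'net_signal' column")
    return df


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def write_json(obj, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Path(path).write_text(json.dumps(_jsonable(obj), indent=2, allow_nan=True) + "\n")


def read_json(path) -> dict:
    return json.loads(_require(path).read_text())
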