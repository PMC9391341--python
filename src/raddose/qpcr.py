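"""qRT-PCR Ct processing: well collapsing, delta-Ct, and 2^-ddCt fold change.

Ct is log2-scale by construction, so normalizing against the *arithmetic*
mean of the reference-gene Cts is exactly the geometric mean of the
reference genes on the linear expression scale.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .datatypes import ValidationError, validate_ct_table

#: default well-replicate spread (cycles) above which a pair is flagged
WELL_SPREAD_THRESHOLD = 0.5

_META_COLS = ["sample_id", "mouse_id", "sex", "dose_gy", "gene"]


def collapse_wells(
    table: pd.DataFrame, spread_threshold: float = WELL_SPREAD_THRESHOLD
) -> pd.DataFrame:
    """Average well replicates to one row per (sample, gene).

    Adds ``n_wells``, ``ct_spread`` (max-min across wells) and a boolean
    ``flagged`` column marking pairs whose spread exceeds the threshold.
    Flagged rows are kept — the policy is warn, never auto-drop.  Missing
    (sample, gene) combinations simply stay missing.
    """
    df = validate_ct_table(table)
    grouped = df.groupby(_META_COLS, sort=False, as_index=False).agg(
        ct=("ct", "mean"),
        n_wells=("ct", "size"),
        ct_spread=("ct", lambda s: float(s.max() - s.min())),
    )
    grouped["flagged"] = grouped["ct_spread"] > spread_threshold
    return grouped


def delta_ct(
    table: pd.DataFrame, reference_genes: list[str]
) -> tuple[pd.DataFrame, list[str]]:
    """Per-sample delta-Ct against the mean of the reference-gene Cts.

    ``table`` must already be collapsed to one row per (sample, gene).
    Returns ``(dct_table, excluded_samples)``: samples missing any reference
    gene are excluded (with their IDs reported), not imputed.  Reference
    genes themselves are dropped from the output; by construction their own
    dct values average to 0 within each sample.
    """
    if not reference_genes:
        raise ValidationError("reference_genes must be nonempty")
    df = table.copy()
    refs = df[df["gene"].isin(reference_genes)]
    ref_counts = refs.groupby("sample_id")["gene"].nunique()
    norm = refs.groupby("sample_id")["ct"].mean()

    excluded = sorted(
        s
        for s in df["sample_id"].unique()
        if ref_counts.get(s, 0) < len(reference_genes)
    )
    df = df[~df["sample_id"].isin(excluded)]
    df = df[~df["gene"].isin(reference_genes)].copy()
    df["dct"] = df["ct"].to_numpy() - norm.loc[df["sample_id"]].to_numpy()
    return df.drop(columns=["ct"]), excluded


def fold_change_ddct(dct: pd.DataFrame, control_dose: float = 0.0) -> pd.DataFrame:
    """2^-ddCt fold change relative to the mean control-group delta-Ct.

    The control group is all samples at ``control_dose`` (both sexes
    pooled).  Every gene must be present in the control group.
    """
    controls = dct[dct["dose_gy"] == control_dose]
    if controls.empty:
        raise ValidationError(f"no control samples at dose {control_dose} Gy")
    control_mean = controls.groupby("gene")["dct"].mean()
    missing = sorted(set(dct["gene"].unique()) - set(control_mean.index))
    if missing:
        raise ValidationError(f"genes absent from control group: {missing}")
    out = dct.copy()
    out["ddct"] = out["dct"].to_numpy() - control_mean.loc[out["gene"]].to_numpy()
    out["fold_change"] = 2.0 ** (-out["ddct"])
    return out
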