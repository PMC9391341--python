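"""End-to-end pipeline orchestration: select -> net signal -> fit -> evaluate.

A :class:`PipelineConfig` (YAML/JSON/dict) fully determines one run; every
artifact is written to the output directory together with a manifest
recording the config hash and seeds, so identical configs reproduce
identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .datatypes import GeneSignature, ValidationError
from .evaluation import MODEL_SPECS, group_size_sensitivity, repeated_split_evaluation
from .io import (
    read_ct_table,
    read_expression_matrix,
    write_json,
    write_net_signal,
    write_signature,
)
from .models import (
    fit_eq1,
    fit_metrics,
    fit_quadratic_sex_model,
    predict_dose_eq1,
    predict_dose_quadratic,
    reduce_model,
)
from .netsignal import net_signal_array, net_signal_qpcr
from .qpcr import collapse_wells, delta_ct
from .signature import bonferroni_filter, rank_genes_by_dose_correlation, select_signature
from .simulate import DEFAULT_QPCR_DOWN, DEFAULT_QPCR_UP, DEFAULT_REFERENCE_GENES


@dataclass
class PipelineConfig:
    """Validated configuration of one pipeline run. Unknown keys are rejected."""

    kind: str  # "array" | "qpcr"
    out_dir: str
    matrix: str | None = None
    metadata: str | None = None
    ct_table: str | None = None
    n_up: int = 20
    n_down: int = 10
    aggregator: str = "geometric_mean"
    model_spec: str = "eq1_robust"
    alpha: float = 0.05
    n_splits: int = 1000
    seed: int = 0
    reference_genes: list[str] = field(
        default_factory=lambda: list(DEFAULT_REFERENCE_GENES)
    )
    up_genes: list[str] = field(default_factory=lambda: list(DEFAULT_QPCR_UP))
    down_genes: list[str] = field(default_factory=lambda: list(DEFAULT_QPCR_DOWN))

    def __post_init__(self) -> None:
        if self.kind not in ("array", "qpcr"):
            raise ValidationError(f"kind must be 'array' or 'qpcr', got {self.kind!r}")
        if self.kind == "array" and not (self.matrix and self.metadata):
            raise ValidationError("array pipeline requires matrix and metadata paths")
        if self.kind == "qpcr" and not self.ct_table:
            raise ValidationError("qpcr pipeline requires a ct_table path")
        if self.model_spec not in MODEL_SPECS:
            raise ValidationError(f"model_spec must be one of {MODEL_SPECS}")
        if not (0 < self.alpha < 1):
            raise ValidationError("alpha must be in (0, 1)")
        if self.n_splits < 1 or self.n_up < 1 or self.n_down < 1:
            raise ValidationError("n_splits, n_up, n_down must be >= 1")

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        p = Path(path)
        if not p.exists():
            raise ValidationError(f"config file not found: {p}")
        data = yaml.safe_load(p.read_text())
        if not isinstance(data, dict):
            raise ValidationError("config must be a mapping")
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute select -> net signal -> fit -> evaluate and write all artifacts.

    Returns the result bundle (signature, net signal, fits, metrics,
    evaluation summary) as a dict; writes TSV/JSON artifacts plus a manifest
    under ``config.out_dir``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle: dict = {"kind": config.kind}
    artifacts: list[str] = []

    try:
        if config.kind == "array":
            bundle.update(_run_array(config, out, artifacts))
        else:
            bundle.update(_run_qpcr(config, out, artifacts))
    except Exception as exc:
        raise type(exc)(f"[{config.kind} pipeline] {exc}") from exc

    manifest = {
        "package_version": __version__,
        "config": config.to_dict(),
        "config_sha256": config.digest(),
        "seed": config.seed,
        "artifacts": artifacts,
    }
    write_json(manifest, out / "manifest.json")
    bundle["manifest"] = manifest
    return bundle


def _run_array(config: PipelineConfig, out: Path, artifacts: list[str]) -> dict:
    expr = read_expression_matrix(config.matrix, config.metadata)
    correlations = rank_genes_by_dose_correlation(expr)
    survivors = bonferroni_filter(correlations, alpha=config.alpha)
    sig = select_signature(survivors, n_up=config.n_up, n_down=config.n_down)
    ns = net_signal_array(expr, sig)

    loss = "ols" if config.model_spec == "eq1_ols" else "robust"
    fit = fit_eq1(ns, expr.time, expr.dose, loss=loss)
    raw, floored = predict_dose_eq1(fit, ns, expr.time)
    metrics = fit_metrics(raw, expr.dose)
    evaluation = repeated_split_evaluation(
        ns, expr.time, expr.dose,
        model_spec=config.model_spec, n_splits=config.n_splits,
        base_seed=config.seed,
    )
    sensitivity = group_size_sensitivity(expr, survivors)

    correlations.to_csv(out / "correlations.tsv", sep="\t", index=False)
    write_signature(sig, out / "signature.json")
    write_net_signal(ns, expr.metadata, out / "net_signal.tsv")
    write_json(fit, out / "fit_eq1.json")
    write_json(
        {"metrics": metrics, "split_summary": evaluation.summary,
         "n_failed_splits": evaluation.n_failed},
        out / "evaluation.json",
    )
    evaluation.records.to_csv(out / "splits.tsv", sep="\t", index=False)
    sensitivity.to_csv(out / "sensitivity.tsv", sep="\t", index=False)
    recon = ns.to_frame()
    recon["dose_gy"] = expr.dose
    recon["dose_reconstructed"] = raw
    recon["dose_reconstructed_floored"] = floored
    recon.to_csv(out / "reconstruction.tsv", sep="\t", index_label="sample_id")
    artifacts += [
        "correlations.tsv", "signature.json", "net_signal.tsv", "fit_eq1.json",
        "evaluation.json", "splits.tsv", "sensitivity.tsv", "reconstruction.tsv",
    ]
    return {
        "signature": sig,
        "net_signal": ns,
        "fit": fit,
        "metrics": metrics,
        "evaluation": evaluation,
        "sensitivity": sensitivity,
    }


def _run_qpcr(config: PipelineConfig, out: Path, artifacts: list[str]) -> dict:
    table = read_ct_table(config.ct_table)
    collapsed = collapse_wells(table)
    dct, excluded = delta_ct(collapsed, reference_genes=list(config.reference_genes))
    sig = GeneSignature(up_genes=list(config.up_genes), down_genes=list(config.down_genes))
    ns = net_signal_qpcr(dct, sig, aggregator=config.aggregator)

    meta = (
        dct[["sample_id", "sex", "dose_gy"]]
        .drop_duplicates("sample_id")
        .set_index("sample_id")
        .loc[ns.sample_ids]
    )
    full = fit_quadratic_sex_model(ns, meta["dose_gy"].to_numpy(), meta["sex"].tolist())
    model, reduced = reduce_model(full, alpha=config.alpha)
    sex = meta["sex"].tolist() if model.include_sex_terms else None
    raw, floored = predict_dose_quadratic(model, ns, sex=sex)
    metrics = fit_metrics(raw, meta["dose_gy"].to_numpy())
    metrics_floored = fit_metrics(floored, meta["dose_gy"].to_numpy())

    write_signature(sig, out / "signature.json")
    write_net_signal(ns, meta, out / "net_signal.tsv")
    full.coefficient_table().to_csv(out / "fit_full.tsv", sep="\t", index=False)
    model.coefficient_table().to_csv(out / "fit_final.tsv", sep="\t", index=False)
    write_json(
        {
            "reduced": reduced,
            "excluded_samples": excluded,
            "metrics_raw": metrics,
            "metrics_floored": metrics_floored,
        },
        out / "evaluation.json",
    )
    recon = ns.to_frame().join(meta)
    recon["dose_reconstructed"] = raw
    recon["dose_reconstructed_floored"] = floored
    recon.to_csv(out / "reconstruction.tsv", sep="\t", index_label="sample_id")
    artifacts += [
        "signature.json", "net_signal.tsv", "fit_full.tsv", "fit_final.tsv",
        "evaluation.json", "reconstruction.tsv",
    ]
    return {
        "signature": sig,
        "net_signal": ns,
        "full_model": full,
        "model": model,
        "reduced": reduced,
        "metrics": metrics,
        "excluded_samples": excluded,
    }
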