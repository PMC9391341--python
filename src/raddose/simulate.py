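"""Synthetic data generators with known ground-truth dose-response structure.

Both generators invert the package's dose-reconstruction models so that the
full analysis pipeline, run on noise-free output, recovers the generating
parameters exactly — parameter recovery is the primary correctness surface.

Array generator
    Dose D and time T (days) determine a ground-truth net signal N*(D, T),
    the nonnegative root of ``k1 N + k2 N^2 + k3 sqrt(T) = D`` (floored at 0
    where D < k3 sqrt(T)).  Up-regulated genes gain ``w_g N*/2`` log2 units,
    down-regulated genes lose the same amount, background genes carry no
    dose term.  Additive per-study offsets emulate residual batch effects
    after median-array normalization; these cancel exactly in the
    median-difference net signal.

qPCR generator
    Dose determines a ground-truth delta-Ct-scale net signal N*(D), the root
    of ``b2 N^2 + b1 N + (b0 - D) = 0`` on the branch where N decreases with
    dose.  Up genes receive delta-Ct ``offset + N*/2`` (falling with dose),
    down genes ``offset - N*/2`` (rising), so the difference of group means
    reproduces N* exactly.  Raw well Cts are reference Ct plus delta-Ct plus
    Gaussian noise, duplicated per well.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .datatypes import ExpressionMatrix, GeneSignature, ValidationError

# Final qPCR panel: 3 up- and 4 down-regulated genes plus two reference genes.
DEFAULT_QPCR_UP = ("Phlda3", "Rhoc", "Lrg1")
DEFAULT_QPCR_DOWN = ("Cd19", "Cxcr5", "Ly6D", "Ccr7")
DEFAULT_REFERENCE_GENES = ("Actb", "Gapdh")

# Plausible baseline delta-Ct offsets (cycles vs the Actb/Gapdh mean); the
# two groups are mean-matched so the zero-dose net signal is exactly 0.
_DEFAULT_QPCR_OFFSETS: Mapping[str, float] = {
    "Phlda3": 5.0,
    "Rhoc": 4.5,
    "Lrg1": 8.5,
    "Cd19": 6.5,
    "Cxcr5": 8.0,
    "Ly6D": 6.0,
    "Ccr7": 3.5,
}

_REFERENCE_BASE_CT: Mapping[str, float] = {"Actb": 17.5, "Gapdh": 19.5}


@dataclass
class ArraySimConfig:
    """Study conditions for the multi-study microarray emulation.

    Defaults emulate the merged public datasets: 8 dose levels spanning
    0–10 Gy, sampling times 1–7 days, ~320 samples across 8 studies, a
    20-up/10-down signature against 500 dose-null background genes, and the
    published dose-model coefficients as ground truth.
    """

    n_up_genes: int = 20
    n_down_genes: int = 10
    n_background_genes: int = 500
    doses: Sequence[float] = (0.0, 1.0, 2.0, 3.0, 4.0, 6.0, 8.0, 10.0)
    times: Sequence[float] = (1.0, 2.0, 3.0, 7.0)
    samples_per_condition: int = 10
    k1: float = 0.906
    k2: float = 0.274
    k3: float = 0.549
    gene_effect_weights: Sequence[float] | None = None  # default: uniform 1.0
    baseline_mean: float = 8.0
    baseline_sd: float = 1.5
    noise_sd: float = 0.3
    study_effects: Sequence[float] = (-0.4, -0.2, 0.0, 0.1, 0.2, -0.3, 0.3, 0.4)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_up_genes", "n_down_genes", "samples_per_condition"):
            if getattr(self, name) < 1:
                raise ValidationError(f"{name} must be >= 1")
        if self.n_background_genes < 0:
            raise ValidationError("n_background_genes must be >= 0")
        if any(d < 0 for d in self.doses):
            raise ValidationError("doses must be >= 0")
        if any(t <= 0 for t in self.times):
            raise ValidationError("times must be > 0")
        if self.k2 <= 0:
            raise ValidationError("k2 must be > 0 (dose -> N inversion)")
        if self.noise_sd < 0 or self.baseline_sd < 0:
            raise ValidationError("noise_sd and baseline_sd must be >= 0")
        if self.gene_effect_weights is not None:
            w = np.asarray(self.gene_effect_weights, float)
            if w.shape[0] != self.n_up_genes + self.n_down_genes:
                raise ValidationError(
                    "gene_effect_weights must have one entry per signature gene"
                )
            if (w <= 0).any():
                raise ValidationError("gene_effect_weights must be > 0")
        # reject non-invertible dose/time combinations
        for d in self.doses:
            for t in self.times:
                if d >= self.k3 * math.sqrt(t):
                    disc = self.k1**2 + 4.0 * self.k2 * (d - self.k3 * math.sqrt(t))
                    if disc < 0:
                        raise ValidationError(
                            f"dose->N inversion has no real root at D={d}, T={t}"
                        )

    @property
    def signature(self) -> GeneSignature:
        up = [f"UP{i:03d}" for i in range(1, self.n_up_genes + 1)]
        down = [f"DN{i:03d}" for i in range(1, self.n_down_genes + 1)]
        return GeneSignature(up_genes=up, down_genes=down)


def true_net_signal_array(
    dose: np.ndarray | float,
    time: np.ndarray | float,
    k1: float,
    k2: float,
    k3: float,
) -> np.ndarray:
    """Ground-truth N*(D, T): nonnegative root of k1 N + k2 N^2 = D - k3 sqrt(T).

    Where the dose is below the time term (D < k3 sqrt(T)) the net signal is
    floored at 0: dose 0 defines the baseline.
    """
    dose = np.asarray(dose, dtype=float)
    time = np.asarray(time, dtype=float)
    rhs = dose - k3 * np.sqrt(time)
    disc = k1**2 + 4.0 * k2 * rhs
    n = np.where(rhs >= 0, (-k1 + np.sqrt(np.maximum(disc, 0.0))) / (2.0 * k2), 0.0)
    return np.maximum(n, 0.0)


def generate_array_study(config: ArraySimConfig) -> ExpressionMatrix:
    """Simulate a merged multi-study expression matrix. Deterministic given seed."""
    rng = np.random.default_rng(config.seed)
    sig = config.signature
    n_sig = sig.n_up + sig.n_down
    genes = sig.up_genes + sig.down_genes + [
        f"BG{i:04d}" for i in range(1, config.n_background_genes + 1)
    ]
    n_genes = len(genes)

    if config.gene_effect_weights is None:
        weights = np.ones(n_sig)
    else:
        weights = np.asarray(config.gene_effect_weights, float)

    baselines = rng.normal(config.baseline_mean, config.baseline_sd, n_genes)
    # Median-match the signature groups so the zero-noise net signal equals
    # the ground-truth N* exactly (the dose-0 baseline contributes 0).
    up_sl = slice(0, sig.n_up)
    dn_sl = slice(sig.n_up, n_sig)
    baselines[up_sl] += config.baseline_mean - np.median(baselines[up_sl])
    baselines[dn_sl] += config.baseline_mean - np.median(baselines[dn_sl])

    conditions = [(d, t) for d in config.doses for t in config.times]
    n_samples = len(conditions) * config.samples_per_condition
    dose = np.repeat([c[0] for c in conditions], config.samples_per_condition)
    time = np.repeat([c[1] for c in conditions], config.samples_per_condition)
    n_star = true_net_signal_array(dose, time, config.k1, config.k2, config.k3)

    study_offsets = np.asarray(config.study_effects, float)
    study_idx = np.arange(n_samples) % len(study_offsets)
    sample_offset = study_offsets[study_idx]

    # per-gene dose loading: +w/2 for up, -w/2 for down, 0 for background
    loading = np.zeros(n_genes)
    loading[up_sl] = weights[: sig.n_up] / 2.0
    loading[dn_sl] = -weights[sig.n_up :] / 2.0

    signal = (
        baselines[:, None]
        + loading[:, None] * n_star[None, :]
        + sample_offset[None, :]
    )
    if config.noise_sd > 0:
        signal = signal + rng.normal(0.0, config.noise_sd, signal.shape)

    sample_ids = [f"S{i:04d}" for i in range(1, n_samples + 1)]
    metadata = pd.DataFrame(
        {
            "dose_gy": dose,
            "time_days": time,
            "study": [f"study{j + 1}" for j in study_idx],
            "sex": ["M" if i % 2 == 0 else "F" for i in range(n_samples)],
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    mat = pd.DataFrame(signal, index=pd.Index(genes, name="gene_id"), columns=sample_ids)
    return ExpressionMatrix(signal=mat, metadata=metadata)


@dataclass
class QpcrSimConfig:
    """Study conditions for the independent qRT-PCR validation cohort.

    Defaults emulate 5 male + 5 female mice per dose at 0–8 Gy sampled 24 h
    after exposure, duplicate wells, two reference genes, and the published
    quadratic dose-reconstruction coefficients as the generative inverse.
    """

    up_genes: Sequence[str] = DEFAULT_QPCR_UP
    down_genes: Sequence[str] = DEFAULT_QPCR_DOWN
    reference_genes: Sequence[str] = DEFAULT_REFERENCE_GENES
    doses: Sequence[float] = (0.0, 1.0, 2.0, 3.0, 4.0, 6.0, 8.0)
    mice_per_sex_per_dose: int = 5
    b0: float = 2.592
    b1: float = -0.785
    b2: float = 0.048
    per_gene_offsets: Mapping[str, float] | None = None
    well_replicates: int = 2
    ct_noise_sd: float = 0.15
    sex_effect: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mice_per_sex_per_dose < 1 or self.well_replicates < 1:
            raise ValidationError("counts must be >= 1")
        if self.ct_noise_sd < 0:
            raise ValidationError("ct_noise_sd must be >= 0")
        if not self.up_genes or not self.down_genes or not self.reference_genes:
            raise ValidationError("gene lists must be nonempty")
        if set(self.up_genes) & set(self.down_genes):
            raise ValidationError("up/down gene lists overlap")
        # every configured dose must map to a real net signal
        for d in self.doses:
            true_net_signal_qpcr(d, self.b0, self.b1, self.b2)

    @property
    def signature(self) -> GeneSignature:
        return GeneSignature(up_genes=list(self.up_genes), down_genes=list(self.down_genes))

    def resolved_offsets(self) -> dict[str, float]:
        """Per-gene delta-Ct offsets, mean-matched between the two groups.

        The group means are recentred to their common average so that the
        group-mean difference carries only the dose term N*.
        """
        raw = dict(self.per_gene_offsets) if self.per_gene_offsets else {
            g: _DEFAULT_QPCR_OFFSETS.get(g, 6.0)
            for g in list(self.up_genes) + list(self.down_genes)
        }
        missing = [g for g in list(self.up_genes) + list(self.down_genes) if g not in raw]
        if missing:
            raise ValidationError(f"per_gene_offsets missing genes: {missing}")
        up_mean = float(np.mean([raw[g] for g in self.up_genes]))
        dn_mean = float(np.mean([raw[g] for g in self.down_genes]))
        target = 0.5 * (up_mean + dn_mean)
        out = {}
        for g in self.up_genes:
            out[g] = raw[g] - up_mean + target
        for g in self.down_genes:
            out[g] = raw[g] - dn_mean + target
        return out


def true_net_signal_qpcr(
    dose: float, b0: float, b1: float, b2: float
) -> float:
    """Ground-truth N*(D): root of b2 N^2 + b1 N + (b0 - D) = 0 on the
    branch where N decreases with dose (dD/dN = b1 + 2 b2 N < 0)."""
    if abs(b2) < 1e-12:
        if b1 == 0:
            raise ValidationError("b1 and b2 cannot both be ~0")
        return (dose - b0) / b1
    disc = b1**2 - 4.0 * b2 * (b0 - dose)
    if disc < 0:
        raise ValidationError(
            f"dose {dose} Gy has no real net-signal root for (b0,b1,b2)="
            f"({b0},{b1},{b2})"
        )
    sq = math.sqrt(disc)
    roots = ((-b1 - sq) / (2 * b2), (-b1 + sq) / (2 * b2))
    for r in roots:
        if b1 + 2 * b2 * r < 0:
            return r
    # disc == 0: both roots coincide at the branch point
    return roots[0]


def generate_qpcr_cohort(config: QpcrSimConfig) -> pd.DataFrame:
    """Simulate a long-format Ct table (one row per well). Deterministic given seed.

    Columns: sample_id, mouse_id, sex, dose_gy, gene, well, ct.
    """
    rng = np.random.default_rng(config.seed)
    offsets = config.resolved_offsets()
    up = list(config.up_genes)
    down = list(config.down_genes)
    refs = list(config.reference_genes)
    ref_base = {
        g: _REFERENCE_BASE_CT.get(g, 18.0 + 1.5 * i) for i, g in enumerate(refs)
    }
    ref_mean = float(np.mean([ref_base[g] for g in refs]))

    rows: list[tuple] = []
    for dose in config.doses:
        n_star = true_net_signal_qpcr(dose, config.b0, config.b1, config.b2)
        for sex in ("M", "F"):
            for m in range(1, config.mice_per_sex_per_dose + 1):
                mouse_id = f"{sex}_{dose:g}Gy_{m}"
                # per-mouse global Ct shift (RNA input); cancels in delta-Ct
                shift = rng.normal(0.0, 0.3) if config.ct_noise_sd > 0 else 0.0
                n_eff = n_star + (config.sex_effect if sex == "M" else 0.0)
                targets = {}
                for g in up:
                    targets[g] = offsets[g] + n_eff / 2.0
                for g in down:
                    targets[g] = offsets[g] - n_eff / 2.0
                for g in refs + up + down:
                    base = (
                        ref_base[g] + shift
                        if g in ref_base
                        else ref_mean + shift + targets[g]
                    )
                    for w in range(1, config.well_replicates + 1):
                        noise = (
                            rng.normal(0.0, config.ct_noise_sd)
                            if config.ct_noise_sd > 0
                            else 0.0
                        )
                        rows.append(
                            (mouse_id, mouse_id, sex, float(dose), g, w, base + noise)
                        )
    return pd.DataFrame(
        rows,
        columns=["sample_id", "mouse_id", "sex", "dose_gy", "gene", "well", "ct"],
    )
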