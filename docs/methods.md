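# Methods

## The dose-reconstruction problem

A blood gene-expression signature for biodosimetry consists of two gene
groups: transcripts induced by irradiation (p53/DNA-damage response genes
such as *Phlda3*, *Rhoc*, *Lrg1*) and transcripts depleted with dose
(B-cell lineage markers such as *Cd19*, *Cxcr5*, *Ly6D*, *Ccr7*, reflecting
radiosensitive cell populations). Rather than treating each gene as a
separate predictor — the genes are strongly inter-correlated with similar
dose-response shapes — the panel is collapsed to one scalar per sample, the
**net signal**

N = agg(up-regulated group) − agg(down-regulated group),

with agg = median of log2 signals on arrays and agg = arithmetic mean of
ΔCt on qPCR (equivalently the geometric mean of linear-scale expression,
since Ct is log2 by construction). Because every gene of a sample shares
additive offsets (global normalization shifts, RNA input), N cancels them
exactly; this is the statistic's main robustness property and is asserted as
an invariance test.

Sign convention: array N *increases* with dose (log2 signal of up genes
rises). qPCR N is computed on the ΔCt scale, where more template means
*fewer* cycles, so N *decreases* with dose; the quadratic model's N
coefficient is therefore negative.

## Models

**Microarray model.** D = k1·N + k2·N² + k3·√T, with D absorbed dose (Gy),
T days after exposure (0.25–7 d in the data the model is meant for), and no
intercept (at N = 0, T = 0 the reconstruction is 0). The √T term is an
empirical correction for the decay of the transcriptional response with
time. The model is linear in (k1, k2, k3) given the regressors
(N, N², √T), so the OLS variant is closed-form; the default is robust
M-estimation:

* iteratively reweighted least squares with Tukey bisquare weights,
  tuning constant c = 4.685 (95% Gaussian efficiency);
* residual scale re-estimated each iteration as median(|r|)/0.6745 (MAD);
* start at the OLS solution; converged when the largest coefficient change
  is < 1e-8 (relative); at most 50 iterations, non-convergence is an error;
* if the scale collapses below ~1e-10·max|y| the fit is exact, all weights
  are 1, and the robust solution *is* the OLS solution — this makes
  zero-noise round trips bitwise comparable across losses;
* standard errors from the final weighted normal equations
  (σ̂² = Σw r²/(n−p), cov = σ̂²(XᵀWX)⁻¹), two-sided t p-values with n−p df.

Alternative time structures (T, T² instead of √T; multiplicative
(k1 N + k2 N²)·g(T) instead of additive) are all linear in their parameters
after transforming the regressors, so the same fitting machinery scores all
6 structures × 2 losses by held-out RMSE over repeated half splits. With a
single time point every structure spans the same column space and the
ranking is declared tied.

**qPCR model.** D = b0 + b1·N + b2·N², first fitted (OLS, statsmodels) with
sex terms {Sex, Sex×N, Sex×N²} (male = 1, female = 0). If no sex-containing
term is significant at α = 0.05 the model is refitted on {1, N, N²}. On an
exact (zero-residual) fit the sex t-statistics are 0/0-degenerate, so a
coefficient that is numerically zero (|b| < 1e-8·max|D|) is treated as
droppable regardless of its nominal p-value.

**Predictions and metrics.** Both models return raw and floored-at-zero
reconstructions; negative absorbed dose is unphysical, but flooring changes
RMSE, so all reported metrics (RMSE = √mean(Ď−D)², R² = 1 − SSres/SStot)
use the raw predictions and the floored column is provided for per-sample
reporting. Zero variance in the true doses leaves R² undefined (flagged,
not an error).

## Signature selection

Spearman correlation of each gene with dose is computed across all samples
with all time points pooled (the stability-over-time criterion is exactly
this pooled correlation, not a per-time filter). Ties get midranks.
p-values use the t approximation with n−2 df for n ≥ 10 and the exact
permutation null (full enumeration) below that. The Bonferroni multiplier
is the number of genes actually tested; zero-variance genes are flagged and
excluded from testing and ranking. Signature ties are broken by smaller raw
p, then lexicographic gene ID, so selection is fully deterministic.

## Split validation

Samples are split into random halves (sizes differ by ≤ 1), the model is
refitted on the training half, and train R²/RMSE plus test RMSE/R² are
recorded; defaults are 1000 splits with per-split seed = base seed + split
index, so one integer reproduces the entire run. The default split is
unstratified; a dose-stratified mode is provided because small dose groups
can otherwise vanish from one half. Split-level fit failures are recorded
and excluded, with the count reported.

## Synthetic data generators

The generators are first-class components: they define the conditions every
downstream stage is tested under, and their ground truth is constructed by
*inverting the dose models*, which makes parameter recovery a well-posed
correctness criterion.

**Array generator.** For each sample with dose D and time T the ground-truth
net signal N\*(D,T) is the nonnegative root of k1 N + k2 N² = D − k3√T,
floored at 0 where D < k3√T (dose 0 defines the baseline). Up genes get
log2 signal baseline + w·N\*/2, down genes baseline − w·N\*/2, background
genes carry no dose term; Gaussian noise on the log2 scale and additive
per-study offsets (which cancel in N) complete the model. With uniform
weights the group median separates as median(baselines) ± N\*/2, so the
generator recenters each signature group's baselines to a common median —
this makes the zero-noise net signal equal N\* exactly and the zero-noise
refit recover (k1, k2, k3) to machine precision. Defaults emulate a merged
multi-study compendium: doses 0–10 Gy, times 1–7 d, 10 samples per
condition (n = 320), 20 up / 10 down / 500 background genes, baselines
~N(8, 1.5²) log2 units, noise SD 0.3 log2 units, 8 study offsets within
±0.4 log2 units, and (k1, k2, k3) = (0.906, 0.274, 0.549) as generating
truth.

**qPCR generator.** Ground-truth N\*(D) is the root of
b2 N² + b1 N + (b0 − D) = 0 on the branch where N decreases with dose
(b1 + 2 b2 N < 0). Per-gene ΔCt targets are gene offsets ± N\*/2 (up genes
take the share that falls with dose), with the two groups' offsets
mean-matched so the group-mean difference reproduces N\* exactly. Raw well
Ct = reference Ct + per-mouse input shift + ΔCt + Gaussian noise, duplicated
per well. Defaults: the 3-up/4-down panel with Actb/Gapdh references,
5 mice/sex/dose at 0–8 Gy (n = 70), duplicate wells, Ct noise SD 0.15
cycles (typical TaqMan duplicate variability), optional additive sex effect
on N (default 0), and (b0, b1, b2) = (2.592, −0.785, 0.048) as generating
truth.

**What the generators do and do not emulate.** They reproduce the *structure*
of both platforms (dose–response shape, time decay, batch offsets, reference
normalization, duplicate wells, a null sex effect) but only *technical*
noise. Real cohorts add inter-animal biological variability of the
transcriptional response, which dominates reconstruction error in practice;
synthetic R²/RMSE are therefore far better than anything achievable on real
animals, and passing tests demonstrate pipeline correctness — unbiased
recovery, exact identities, calibrated nulls — not field performance of the
assay.

## Numerical and design choices

* **Dose floor region.** Samples with D < k3√T sit off-model by
  construction (their N\* is clamped at 0 while the no-intercept model
  predicts k3√T). Exact round-trip and parameter-recovery experiments
  therefore use conditions with every dose above the floor (≥ 2 Gy with
  T ≤ 4 d at the default coefficients); the floor region is retained in the
  default study conditions because it is realistic (low-dose, late-time
  samples genuinely reconstruct poorly).
* **Recovery experiments.** Statistical recovery of (k1, k2, k3) is
  assessed with Gaussian residuals on the dose scale (SD 0.5 Gy) and exact
  net-signal regressors, the design under which the estimator is unbiased;
  recovery of (b0, b1, b2) runs the full Ct→ΔCt→N→reduction pipeline, where
  technical noise is small enough that attenuation is negligible. Noise in
  N itself (errors-in-variables) biases quadratic-model coefficients — a
  property of any regress-dose-on-signal design, documented rather than
  corrected.
* **Sex-term joint null.** The probability that all three correlated
  level-0.05 sex tests exceed 0.05 simultaneously under the null is bounded
  in [0.857, 0.95] and depends on the cohort's collinearity; for the default
  design it measures ≈ 0.88–0.90 (the perfectly calibrated benchmark with
  homoscedastic dose noise gives ≈ 0.88). Joint exceedance just below 0.9
  is thus the expected behavior of a correct implementation, not an
  inflation artifact.
* **Well QC.** Duplicate wells are averaged (order relative to ΔCt is
  immaterial for arithmetic means); pairs with spread > 0.5 cycles are
  flagged but never auto-dropped. Samples missing a reference gene are
  excluded with a reported reason, never imputed.
* **ΔΔCt controls.** The control group is all 0 Gy animals, sexes pooled.
* **Problem sizes.** Test and acceptance runs use 200-seed recovery
  ensembles, 200–1000 half splits, and the default cohort sizes (n = 306–320
  arrays, n = 70 mice); these sizes give Monte-Carlo error well below the
  assertion tolerances while keeping a full run in the low minutes.

## Known limitations

* No amplification-efficiency correction or standard curves on the qPCR
  side; ΔCt assumes ideal doubling.
* The array path assumes pre-normalized log2 signals; no probe-level
  processing or probe-to-gene collapsing.
* Dose–response inversion is deterministic; no interval or Bayesian dose
  estimates.
* The generators' Gaussian technical noise understates real biological
  dispersion (see above), and the additive study offsets understate
  gene-specific batch effects.
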