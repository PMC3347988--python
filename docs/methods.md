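# Methods

## The experiment and the quantity of interest

Polysome profiling separates a cell lysate on a linear 0–50% sucrose
gradient by velocity sedimentation. mRNAs engaged by many ribosomes
(polysomes) sediment fast; free messenger ribonucleoproteins stay near the
top. Fractionating the gradient into 13 fractions and measuring the
28S/18S rRNA ratio in each identifies the polysomal fractions (ratio ≈ 2,
the stoichiometry of intact ribosomes) and the free-RNA fractions (ratio
clearly ≠ 2). Pooled polysomal (p) and non-polysomal (np) RNA is profiled
on arrays at two time points — immediately before (0 h) and 6 h after
hormonal induction of 3T3-L1 preadipocytes — in biological triplicate.

Translational regulation of a gene appears as a *shift* of its mRNA
between the two pools over time. With group means of log2 intensity
p0, p6, np0, np6, the polysome-shift statistic is the contrast of
contrasts

    M = (p6 − np6) − (p0 − np0)   [log2 fold change],

which cancels anything that affects both pools equally (total mRNA
abundance changes, shared induction responses) and anything constant in
time (baseline polysome association).

## Statistical model

Each gene g is a 2×2 cell-means model over fraction × time with a common
residual variance σ²_g, estimated by the pooled within-group variance s²_g
on d = N − 4 degrees of freedom (d = 8 for triplicates).

**Variance moderation.** With thousands of genes and three replicates,
per-gene variances are noisy; they are shrunk toward an inverse-chi-square
prior with hyperparameters (d0, s0²) fitted across genes by moment
matching on the log scale. Since log s²_g = log σ²_g + log(χ²_d/d), the
quantity

    e_g = log s²_g − ψ(d/2) + log(d/2)

is unbiased for log σ²_g with known sampling variance ψ′(d/2) (ψ, ψ′ are
the digamma and trigamma functions). Hence

    ψ′(d0/2) = var(e) − ψ′(d/2),        solved for d0 by bracketed
                                        root-finding on the (strictly
                                        decreasing) trigamma,
    s0²      = exp( mean(e) + ψ(d0/2) − log(d0/2) ).

If var(e) ≤ ψ′(d/2) the observed spread is no larger than pure sampling
noise, d0 = ∞ and s0² = exp(mean(e)) (complete shrinkage). Genes with
s²_g = 0 carry no log-scale information and are excluded from the fit;
below 20 usable genes a warning is raised. The moderated variance is

    s̃²_g = (d0·s0² + d·s²_g) / (d0 + d),

and the moderated statistic t_g = M_g / sqrt(s̃²_g · Σ_groups 1/n) is
referred to Student t with d0 + d degrees of freedom (standard normal at
d0 = ∞). d0 = 0 is accepted as an explicit no-moderation sentinel in
which t_g is the ordinary contrast t with d degrees of freedom; the
pipeline falls back to it when the data are noise-free and the prior is
undefined. P-values are two-sided and adjusted by the Benjamini–Hochberg
step-up procedure.

**Equivalence (TOST).** Unchanged association is declared positively, not
by failure to reject: with margin ε (default 0.2 log2) the two one-sided
hypotheses H0: M ≤ −ε and H0: M ≥ +ε are tested with the same moderated
SE and degrees of freedom, and p_TOST is the larger of the two one-sided
p-values; equivalence is declared when p_TOST < α (default 0.05). At
|M| = ε exactly, p_TOST ≥ 0.5 by construction.

**Total translation activity.** Per sample, the mean log2 intensity over
gene probes summarizes RNA content; per time point a one-sided Welch
two-sample t-test asks whether the polysomal pool exceeds the free pool.

**Degenerate inputs.** Noise-free data yield s²_g = 0 and SE = 0; the
implementation then reports p = 0 when M ≠ 0 and p = 1 otherwise (for
TOST: 0 / 0.5 / 1 for |M| below / at / beyond ε), with a warning. Pooled
variances below 1e-20 — the square of double-precision rounding on
~10-unit log2 intensities — are snapped to exactly 0 so these branches
trigger reliably, and |M| < 1e-9 counts as zero there.

## Classification cascade

Screen: fdr < 0.05 and |M| > 1. Calls, with all inequalities strict
(ties fail):

- **Up**: screen ∧ M > 2 ∧ p6 > p0 ∧ p6 > np6 ∧ np6 < np0 ∧ p0 < np0.
- **Down**: screen ∧ M < −2 ∧ p6 < p0 ∧ p0 > np0. (No extra fdr gate
  beyond the screen — an asymmetry of the original procedure, kept
  deliberately.)
- **Equal**: p_TOST < α, evaluated only among genes not called Up/Down.
- everything else: Unclassified.

The directional conditions exclude false positives from falling total
mRNA steady-state levels: a transcript whose abundance drops in both
pools (free more than polysomal) produces a large positive M without any
genuine recruitment into polysomes, but fails p6 > p0.

## Gradient fraction QC

Sucrose % is regressed on fraction index; the gradient passes when
r² ≥ 0.98 and no residual exceeds 2% sucrose (a constant profile has
undefined r², reported as 0 and failed). Usable fractions with
|ratio − 2| ≤ 0.3 are polysomal candidates, other usable fractions
free-RNA candidates; each pool is the longest contiguous run of its
candidates, isolated stragglers are discarded with a warning. Usable
fractions between the runs form the buffer zone; when the runs touch, the
free-run fraction at the junction is demoted to the buffer so the pools
stay cleanly separated — the boundary fraction is ambiguous by nature and
sacrificing it costs little material. "Close to two" has no published
numeric criterion; the 0.3 tolerance is a parameter, not an estimate.

## Spike-in normalization and sample QC

An additive per-sample shift on the log2 scale equalizes each sample's
median spike value with the grand median of spike medians. The median is
robust to a single bad spike; additivity preserves the range and every
between-probe difference within a sample, and makes the operation
idempotent. No quantile or loess step is applied — deliberately minimal.
One consequence: per-sample offsets are inverted only up to a single
global constant (the median of the true offsets), which cancels in every
contrast the pipeline computes.

Sample QC computes pairwise Pearson correlations over gene probes
(pairwise-complete on missing values; constant samples are flagged and
excluded), average-linkage hierarchical clustering on 1 − r, and the
first two principal components. QC passes when the 2-cluster cut
separates the fractions perfectly and, within each fraction, a 2-cluster
cut separates the time points.

## Validation calculators

**ΔΔCt q-PCR.** Technical replicates are averaged first; ΔCt subtracts
the arithmetic-mean Ct of the normalizer genes in the same design cell
(the combination rule for multiple normalizers is unstated in the
literature this follows; the mean is the simplest symmetric choice).
In fraction–time mode, per biological replicate,

    ΔΔCt = (ΔCt_p,6 − ΔCt_p,0) − (ΔCt_np,6 − ΔCt_np,0),
    fold = 2^(−ΔΔCt),

oriented so that a polysome-specific increase gives fold > 1, matching
the sign of M. Amplification efficiency is fixed at 2 (the method's
assumption). A two-sided one-sample t-test compares replicate ΔΔCt with
0, and a two-way ANOVA (type II) on ΔCt separates time and fraction main
effects. Time-calibrated mode (ΔΔCt against a calibrator time) serves
differentiation-marker QC.

**Densitometry.** Band intensities are divided by the β-actin band of the
same lane; the T6/T0 ratio is formed within each (biological, technical,
measurement) cell, averaged over technical replicates, then over
measurement repeats — one value per biological replicate — and tested
two-sided against 1. The nesting order matters only for unbalanced
counts; with balanced counts it equals the flat average (tested).

## Synthetic data: what it emulates and what it does not

The generator reproduces the study design exactly: 12 samples
(2 fractions × 2 times × 3 biological replicates), 2000 gene probes, 30
spike probes at fixed true abundances identical across samples, a
13-fraction gradient, and triplicate Ct plates with 3 normalizers drawn
from planted null genes.

Planted classes (deterministic counts from the configured proportions):

| class          | default share | four-cell pattern (offsets from baseline)            | true M |
|----------------|---------------|------------------------------------------------------|--------|
| up             | 2.5%          | p0 −δ, p6 +(2.5 − 2δ), np0 0, np6 −δ                 | +2.5   |
| down           | 0.25%         | p0 +2.5, others 0                                    | −2.5   |
| mrna_artifact  | 5%            | p6 −0.5, np6 −3.0 (steady-state drop at 6 h)         | +2.5*  |
| equal          | 1.5%          | all 0                                                | 0      |
| null           | rest          | all 0, plus structure terms below                    | 0      |

δ = 0.6 log2 is the `directional_margin`: mRNA recruited into polysomes
leaves the free pool, so up-regulated genes deplete np at 6 h (and start
slightly polysome-poor at 0 h), making the five strict Up conditions hold
exactly without noise while keeping M = +2.5 exactly. Down genes carry
elevated polysomal association at 0 h that is lost by 6 h — the only
pattern the Down filter accepts. *Artifact genes get a large positive M
by construction yet must be rejected by p6 > p0; they are the test load
for the directional filters.

Null genes additionally receive a baseline polysome-association offset
(SD 1.0 log2, both time points of the polysomal pool) and a shared
induction response (SD 0.3 log2, both pools at 6 h). Both cancel exactly
in M, so they change no gene's truth, but they give the sample matrix the
fraction-first, time-second clustering structure that real profiling data
shows and QC checks for. Noise is additive Gaussian on the log2 scale:
biological SD 0.25 (each sample is an independent gradient preparation —
replicate noise does **not** cancel in M), technical SD 0.1. Per-sample
distortion is affine on log2 (default: pure offsets U(−2, 2)), which the
additive spike normalization inverts.

Gradient profiles: sucrose exactly affine (50(i−1)/12 %) plus optional
noise; design ratios 0.2 (fractions 1–4, unusable buffer/lysate), 0.7
(5–7, free RNA), 1.4 (8, ambiguous boundary), 2.0 (9–11, polysomal), 0.3
(12–13, unusable debris). Ct plates encode abundance as one cycle per
two-fold (Ct = 20 − planted log2 offset), with per-cell SD 0.15 and
per-well SD 0.05 by default.

Not emulated: probe sequences and cross-hybridization, intensity-dependent
(nonlinear) array distortions, heteroskedastic or heavy-tailed gene
variances (the variance prior in simulated data is near-degenerate, so
estimated d0 is large there; the dedicated recovery experiment plants a
known d0 = 4 instead), correlated biological replicates, and q-PCR
efficiency deviations from 2. Passing tests therefore show the
*procedures* are correct under their stated assumptions, not that real
arrays meet those assumptions.

## Problem sizes and defaults

Simulations use 2000 genes × 12 samples (seconds per run), 10 seeds for
operating characteristics, 5000 genes for the moderation-recovery and
TOST-size experiments, 200 random vectors for the BH cross-check — sizes
at which the moment estimators are stable and every Monte Carlo band in
the tests is comfortably wider than its standard error. Key defaults:
fdr 0.05, screen |M| > 1, call |M| > 2, ε = 0.2 (log2), α_eq = 0.05,
ratio tolerance 0.3, r² ≥ 0.98.

## Known limitations

- With triplicates and biological SD ≈ 0.25, the moderated SE of M is
  ≈ 0.3 log2 — larger than ε = 0.2 — so the TOST almost never declares
  equivalence on the noisy synthetic data; the Equal class is exercised
  through the noise-free limit and the dedicated size experiment at the
  margin.
- The same small-n caveat applies to the validation calculators: in the
  densitometry demo (`analysis/06`), the planted-null gene reaches nominal
  p = 0.034 at one seed — with three biological replicates such type-I
  events are expected, and single-digit-replicate assay p-values should be
  read accordingly.
- The Down rule's missing fdr gate (beyond the screen) is preserved from
  the original cascade; with m_call = 2 it is practically inert but it is
  an asymmetry, not an oversight of this implementation.
- Spike normalization corrects offsets only; a genuine per-sample *scale*
  distortion (slope ≠ 1 on log2) is outside its model and would require
  regression on spike levels, which the minimal design deliberately
  omits.
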