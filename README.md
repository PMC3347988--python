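# polyshift

Analysis pipeline for sucrose-gradient **polysome profiling** experiments:
from gradient-fraction QC and pooling, through spike-in normalization and a
moderated *polysome shift* statistic, to a three-way gene classification
(up / down / equal) and the wet-lab validation calculators (ΔΔCt q-PCR and
Western-blot densitometry). It is written for translatome studies of the
kind used on early 3T3-L1 adipogenesis — two gradient pools (polysomal /
non-polysomal) at two time points in biological triplicate — and ships a
synthetic-data generator with planted ground truth so every stage is
testable end to end without any external download.

## The statistic

For each gene, with mean log2 intensities p0, p6 (polysomal pool at 0 h
and 6 h after induction) and np0, np6 (non-polysomal pool), the change in
ribosomal association over time is the contrast of contrasts

```
M = (p6 − np6) − (p0 − np0)        (log2 fold change)
```

M cancels total-mRNA abundance changes (which move both pools) and
baseline polysome association (which is constant in time). It is tested
with an empirical-Bayes **moderated t**: per-gene variances are shrunk
toward an inverse-chi-square prior (d0, s0²) fitted across all genes by
moment matching, giving t = M / √(s̃²·Σ1/n) on d0 + d degrees of freedom,
with Benjamini–Hochberg FDR control. Unchanged genes are called
positively by **TOST equivalence** (margin ε = 0.2 log2). The final
cascade (fdr < 0.05, |M| > 1 screen; |M| > 2 call; strict directional
filters p6 > p0, p6 > np6, np6 < np0, p0 < np0 that reject steady-state
mRNA artifacts) yields the Up / Down / Equal sets. Details and formulas:
[docs/methods.md](docs/methods.md).

## Worked example

The numbered scripts under `analysis/` run the whole study on synthetic
data and write their tables under `results/`:

```
python analysis/01_simulate.py
python analysis/02_fraction_qc.py
python analysis/03_normalize_qc.py
python analysis/04_shift_stats.py
python analysis/05_classify.py
python analysis/06_validation_assays.py
```

`02` checks the gradient and reproduces the bench pooling:

```
gradient fit: 4.17 %/fraction, r^2 = 1.0000, max residual 0.00% -> linear
pooling: free RNA = fractions [5, 6, 7], buffer = [8], polysomal = [9, 10, 11],
discarded = [1, 2, 3, 4, 12, 13]
```

i.e. fractions with 28S/18S ≈ 2 (intact ribosomes) form the polysomal
pool, fractions with ratio far from 2 the free-RNA pool, and the
ambiguous boundary fraction 8 is sacrificed for clean separation.

`04`–`05` on the noisy dataset (2000 genes, 50 planted up at M = +2.5,
5 down, 100 total-mRNA artifacts, triplicates, σ_bio = 0.25):

```
noisy: prior d0 = 109.1, s0^2 = 0.0747; 158 genes at fdr < 0.05, 157 also with |M| > 1
noisy: screen 151/6 (up/down), Up = 51, Down = 5, Equal = 0
  up sensitivity 0.960, up FDP 0.059, artifact genes leaked into Up/Down: 3
```

48 of the 50 planted up genes are recovered (sensitivity 0.96) with 3
false Up calls (FDP 0.059); in the noise-free companion run the recovery
is exact (Up = 50, Down = 5, zero artifacts). `06` validates called genes
with the q-PCR calculator — e.g. a planted 5.66-fold gene is recovered at
6.07-fold (ΔΔCt −2.60, one-sample p = 0.012) — and the densitometry
calculator recovers a planted 1.4-fold protein increase at 1.44
(p = 7e-4). The planted-null protein shows p = 0.034 at this seed: with
three biological replicates such nominal type-I events are expected, and
the methods note discusses reading small-n assay p-values.

A thin `polyshift` CLI exposes the same stages
(`polyshift simulate | qc-fractions | normalize | shift | classify |
qpcr | densitometry | run`); `polyshift run --seed 1 --out-dir out/`
executes the full pipeline and writes a Markdown report with a manifest.

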