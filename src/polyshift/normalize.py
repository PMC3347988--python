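"""Spike-in normalization and sample-level quality control.

One-color arrays report intensities on an arbitrary per-sample scale, so
relative RNA amounts across gradient pools are only comparable through the
exogenous spike-in probes added in fixed amount per microgram of pooled RNA.
Normalization here is deliberately minimal: a per-sample additive shift on
the log2 scale that equalizes the spike medians, which preserves the range
and shape of the data within each sample (no quantile or loess step).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average, fcluster
from scipy.spatial.distance import squareform


@dataclass
class ExpressionMatrix:
    """Log2 intensities, probes x samples, with per-probe spike flags.

    ``values`` is a DataFrame indexed by probe id with one column per
    sample; ``is_spike`` is a boolean Series on the same probe index.
    """

    values: pd.DataFrame
    is_spike: pd.Series

    def __post_init__(self) -> None:
        if self.values.columns.duplicated().any():
            dups = self.values.columns[self.values.columns.duplicated()].tolist()
            raise ValueError(f"duplicate sample ids: {dups}")
        self.is_spike = self.is_spike.reindex(self.values.index)
        if self.is_spike.isna().any():
            missing = self.is_spike.index[self.is_spike.isna()].tolist()[:5]
            raise ValueError(f"probes without spike flag, e.g. {missing}")
        self.is_spike = self.is_spike.astype(bool)

    @property
    def probe_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    def genes(self) -> pd.DataFrame:
        """Non-spike rows of the matrix."""
        return self.values.loc[~self.is_spike]

    def spikes(self) -> pd.DataFrame:
        return self.values.loc[self.is_spike]

    def copy(self) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.copy(), self.is_spike.copy())


@dataclass
class QCReport:
    """Outcome of sample-level quality control."""

    correlation: pd.DataFrame
    linkage: np.ndarray
    pc_scores: pd.DataFrame
    explained_variance_ratio: np.ndarray
    fraction_separation: bool
    time_separation: dict
    flagged_samples: list = field(default_factory=list)

    @property
    def passed(self) -> bool:
        return self.fraction_separation and all(self.time_separation.values())


def spike_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Equalize per-sample spike medians by an additive log2 shift.

    For each sample the median log2 value of its spike probes is computed
    and the sample is shifted by (grand median of spike medians - sample
    spike median), so that after normalization every sample's spike median
    equals the grand median.  Being additive per sample, the correction
    never changes between-probe differences within a sample and is
    idempotent.

    Raises
    ------
    ValueError
        If the matrix contains no spike probes, or some sample has no
        finite spike value (named in the message).
    """
    if not matrix.is_spike.any():
        raise ValueError("no spike probes in matrix; cannot normalize")
    spikes = matrix.spikes()
    medians = spikes.median(axis=0, skipna=True)
    dead = medians.index[medians.isna()].tolist()
    if dead:
        raise ValueError(f"samples with all spike values missing: {dead}")
    grand = float(np.median(medians.to_numpy()))
    shifted = matrix.values.add(grand - medians, axis=1)
    return ExpressionMatrix(shifted, matrix.is_spike.copy())


def _cut_two(linkage_matrix: np.ndarray) -> np.ndarray:
    return fcluster(linkage_matrix, t=2, criterion="maxclust")


def _separates(cluster_labels: np.ndarray, groups: pd.Series) -> bool:
    """True when a 2-cluster cut coincides with the 2-level grouping."""
    tab = pd.crosstab(cluster_labels, groups)
    if tab.shape != (2, 2):
        return False
    return bool(
        (np.diag(tab.to_numpy()) == 0).all()
        or (np.diag(np.fliplr(tab.to_numpy())) == 0).all()
    )


def sample_qc(matrix: ExpressionMatrix, design: pd.DataFrame) -> QCReport:
    """Correlation, hierarchical clustering and PCA sanity checks.

    Computes the pairwise Pearson correlation of samples over non-spike
    probes, average-linkage hierarchical clustering on the distance 1 - r,
    and the first two principal components.  The report passes when
    cutting the dendrogram at k=2 separates the gradient fractions
    perfectly and, within each fraction, a k=2 cut separates the two time
    points -- the clustering structure expected of a sound polysome
    profiling experiment.

    Samples with zero variance have their correlations set to missing and
    are flagged rather than crashing the report.
    """
    design = design.set_index("sample_id") if "sample_id" in design.columns else design
    genes = matrix.genes()[list(design.index)]
    if genes.shape[1] < 4:
        raise ValueError("sample QC needs >= 4 samples")

    flagged = [s for s in genes.columns if genes[s].std(skipna=True) == 0]
    corr = genes.corr(method="pearson")  # pairwise-complete
    for s in flagged:
        corr.loc[s, :] = np.nan
        corr.loc[:, s] = np.nan
    if flagged:
        warnings.warn(f"constant-variance samples flagged in QC: {flagged}")

    dist = 1.0 - corr.to_numpy(copy=True)
    np.fill_diagonal(dist, 0.0)
    dist = np.nan_to_num(dist, nan=2.0)  # worst-case distance for dead samples
    dist = (dist + dist.T) / 2
    dist = np.clip(dist, 0.0, None)
    link = average(squareform(dist, checks=False))
    cut = _cut_two(link)
    fraction_ok = _separates(cut, design["fraction"])

    time_ok = {}
    for frac, sub in design.groupby("fraction", sort=True):
        idx = [genes.columns.get_loc(s) for s in sub.index]
        sub_dist = dist[np.ix_(idx, idx)]
        sub_link = average(squareform(sub_dist, checks=False))
        time_ok[str(frac)] = _separates(_cut_two(sub_link), sub["time"])

    centred = genes.sub(genes.mean(axis=1), axis=0).fillna(0.0).to_numpy()
    u, s, vt = np.linalg.svd(centred, full_matrices=False)
    var = s**2
    evr = var / var.sum() if var.sum() > 0 else var
    scores = pd.DataFrame(
        (vt[:2].T * s[:2]), index=genes.columns, columns=["PC1", "PC2"]
    )

    return QCReport(
        correlation=corr,
        linkage=link,
        pc_scores=scores,
        explained_variance_ratio=evr[:2],
        fraction_separation=fraction_ok,
        time_separation=time_ok,
        flagged_samples=flagged,
    )
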