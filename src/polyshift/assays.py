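"""Validation-assay calculators: delta-delta-Ct q-PCR and Western-blot
densitometry ratios.

Both assays quantify relative changes against internal references.  q-PCR
uses the exponential-amplification assumption (efficiency 2: one cycle per
two-fold) so a normalizer-corrected Ct double difference converts to a
fold change as 2^(-ddCt).  Densitometry normalizes each band to the
beta-actin band of the same lane and relates the 6 h value to the 0 h
value of the same replicate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
import statsmodels.formula.api as smf


@dataclass
class DdctResult:
    """Relative-quantification outcome for one gene."""

    gene_id: str
    ddct_per_replicate: np.ndarray
    ddct_mean: float
    fold_change: float
    p_one_sample: float
    anova_p_time: float = float("nan")
    anova_p_fraction: float = float("nan")


def _delta_ct(ct: pd.DataFrame, normalizers: list[str]) -> pd.DataFrame:
    """Normalizer-corrected Ct per (gene, fraction, time, replicate).

    Technical replicates are averaged first; the normalizer reference is
    the arithmetic mean Ct over the normalizer genes in the same design
    cell.
    """
    cells = (
        ct.groupby(["gene_id", "fraction", "time", "replicate"], sort=True)["ct"]
        .mean()
        .reset_index()
    )
    norm = (
        cells[cells["gene_id"].isin(normalizers)]
        .groupby(["fraction", "time", "replicate"])["ct"]
        .agg(["mean", "size"])
        .rename(columns={"mean": "norm_ct"})
    )
    if (norm["size"] < len(normalizers)).any():
        bad = norm.index[norm["size"] < len(normalizers)].tolist()
        raise ValueError(f"missing normalizer Ct in design cells: {bad}")
    merged = cells.merge(norm["norm_ct"], on=["fraction", "time", "replicate"])
    merged["dct"] = merged["ct"] - merged["norm_ct"]
    return merged


def compute_ddct(
    ct: pd.DataFrame,
    normalizers: list[str],
    mode: str = "fraction_time",
    calibrator_time: str = "t0",
) -> list[DdctResult]:
    """Delta-delta-Ct relative quantification with one-sample tests.

    Parameters
    ----------
    ct : DataFrame
        Tidy Ct table with columns gene_id, fraction, time, replicate,
        technical_rep, ct.  For ``time_calibrated`` mode the fraction
        column may hold a single level (e.g. total RNA).
    normalizers : list of gene ids
        Reference genes; their mean Ct per design cell is subtracted.
    mode : {"fraction_time", "time_calibrated"}
        ``fraction_time`` computes, per biological replicate, the double
        difference (dCt_p,t6 - dCt_p,t0) - (dCt_np,t6 - dCt_np,t0); its
        sign convention makes a polysome-specific increase give a negative
        ddCt, i.e. fold = 2^(-ddCt) > 1, matching the sign of M.
        ``time_calibrated`` compares each time point to the calibrator
        time (adipogenesis marker QC).

    Returns one :class:`DdctResult` per non-normalizer gene, including a
    two-sided one-sample t-test of the replicate ddCt values against 0
    and, in ``fraction_time`` mode, two-way ANOVA p-values for the time
    and fraction main effects on dCt.
    """
    if not normalizers:
        raise ValueError("at least one normalizer gene is required")
    missing = set(normalizers) - set(ct["gene_id"])
    if missing:
        raise ValueError(f"normalizer genes absent from Ct table: {sorted(missing)}")
    if mode not in ("fraction_time", "time_calibrated"):
        raise ValueError(f"unknown mode {mode!r}")
    if (ct["ct"] <= 0).any():
        raise ValueError("Ct values must be > 0 cycles")

    dct = _delta_ct(ct, list(normalizers))
    targets = [g for g in dct["gene_id"].unique() if g not in normalizers]

    results = []
    for gene in targets:
        sub = dct[dct["gene_id"] == gene]
        if mode == "fraction_time":
            wide = sub.pivot_table(
                index="replicate", columns=["fraction", "time"], values="dct"
            )
            try:
                ddct = (
                    wide[("polysomal", "t6")] - wide[("polysomal", "t0")]
                ) - (
                    wide[("non_polysomal", "t6")] - wide[("non_polysomal", "t0")]
                )
            except KeyError as exc:
                raise ValueError(f"gene {gene}: design cell missing: {exc}") from exc
            anova_p_time, anova_p_fraction = _anova_dct(sub)
        else:
            wide = sub.pivot_table(index="replicate", columns="time", values="dct")
            others = [t for t in wide.columns if t != calibrator_time]
            if len(others) != 1:
                raise ValueError(
                    "time_calibrated mode expects exactly one non-calibrator time"
                )
            ddct = wide[others[0]] - wide[calibrator_time]
            anova_p_time = anova_p_fraction = float("nan")
        ddct = ddct.dropna()
        if len(ddct) < 2:
            warnings.warn(f"gene {gene}: < 2 biological replicates, t-test skipped")
            p_one = float("nan")
        elif np.ptp(ddct.to_numpy()) == 0:
            # noise-free replicates: the value is known exactly
            p_one = 1.0 if ddct.iloc[0] == 0 else 0.0
        else:
            p_one = float(stats.ttest_1samp(ddct, 0.0).pvalue)
        mean_ddct = float(ddct.mean())
        results.append(
            DdctResult(
                gene_id=gene,
                ddct_per_replicate=ddct.to_numpy(),
                ddct_mean=mean_ddct,
                fold_change=float(2.0 ** (-mean_ddct)),
                p_one_sample=p_one,
                anova_p_time=anova_p_time,
                anova_p_fraction=anova_p_fraction,
            )
        )
    return results


def _anova_dct(sub: pd.DataFrame) -> tuple[float, float]:
    """Two-way ANOVA of dCt on time and fraction (type II)."""
    data = sub.rename(columns={"dct": "delta_ct"})
    if data["delta_ct"].var(ddof=1) == 0:
        return float("nan"), float("nan")
    model = smf.ols("delta_ct ~ C(time) * C(fraction)", data=data).fit()
    table = sm.stats.anova_lm(model, typ=2)
    return (
        float(table.loc["C(time)", "PR(>F)"]),
        float(table.loc["C(fraction)", "PR(>F)"]),
    )


@dataclass
class DensitometryResult:
    """Fold change of a protein band between time points."""

    gene_id: str
    ratio_per_replicate: np.ndarray
    mean_ratio: float
    p_vs_one: float


def densitometry_ratios(table: pd.DataFrame) -> list[DensitometryResult]:
    """Actin-normalized T6/T0 band ratios with a one-sample test against 1.

    Expects a tidy table with columns gene_id, biological_rep,
    technical_rep, measurement_rep, time (T0/T6), band_intensity,
    actin_intensity.  Per measurement the band is normalized to actin;
    the T6/T0 ratio is formed within each (biological, technical,
    measurement) cell, averaged over technical replicates, then over
    measurement repeats, yielding one value per biological replicate.
    A two-sided one-sample t-test asks whether the replicate mean ratio
    differs from 1.
    """
    if (table["actin_intensity"] <= 0).any():
        raise ValueError("actin intensity must be > 0")
    if (table["band_intensity"] <= 0).any():
        raise ValueError("band intensity must be > 0")
    t = table.copy()
    t["normalized"] = t["band_intensity"] / t["actin_intensity"]
    wide = t.pivot_table(
        index=["gene_id", "biological_rep", "technical_rep", "measurement_rep"],
        columns="time",
        values="normalized",
    )
    if "T0" not in wide.columns or "T6" not in wide.columns:
        raise ValueError("both time points T0 and T6 are required per replicate")
    if wide[["T0", "T6"]].isna().any().any():
        raise ValueError("both time points T0 and T6 are required per replicate")
    wide["ratio"] = wide["T6"] / wide["T0"]
    per_meas = (
        wide.reset_index()
        .groupby(["gene_id", "biological_rep", "measurement_rep"])["ratio"]
        .mean()
    )
    per_bio = (
        per_meas.reset_index()
        .groupby(["gene_id", "biological_rep"])["ratio"]
        .mean()
    )

    results = []
    for gene, ratios in per_bio.groupby(level="gene_id"):
        vals = ratios.to_numpy()
        if len(vals) < 2:
            warnings.warn(f"gene {gene}: < 2 biological replicates, t-test skipped")
            p = float("nan")
        elif np.ptp(vals) == 0:
            p = 1.0 if np.allclose(vals, 1.0) else 0.0
        else:
            p = float(stats.ttest_1samp(vals, 1.0).pvalue)
        results.append(
            DensitometryResult(
                gene_id=str(gene),
                ratio_per_replicate=vals,
                mean_ratio=float(vals.mean()),
                p_vs_one=p,
            )
        )
    return results
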