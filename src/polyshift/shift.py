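"""Polysome-shift statistics: cell means, empirical-Bayes moderation,
the contrast M = (p6 - np6) - (p0 - np0), BH adjustment, TOST equivalence
and the global translation-activity test.

The model per gene is a 2x2 cell-means layout over fraction (polysomal /
non-polysomal) and time (0 h / 6 h).  The quantity of interest is the
change of ribosomal association over time, the "contrast of contrasts"

    M = (p6 - np6) - (p0 - np0)          (log2 fold change),

tested with a t-statistic whose per-gene residual variance is shrunk
toward a prior estimated across all genes.  The prior (d0, s0^2) is an
inverse-chi-square distribution for the true variances, fitted by moment
matching on the log residual variances: with d residual degrees of
freedom per gene,

    e_g = log(s2_g) - psi(d/2) + log(d/2)

is an unbiased estimate of log(sigma2_g) up to the prior spread, so

    psi'(d0/2) = var(e) - psi'(d/2)
    s0^2       = exp(mean(e) + psi(d0/2) - log(d0/2)),

with d0 = infinity (complete shrinkage) when the observed spread of e is
no larger than the chi-square sampling spread.  The moderated variance is
the precision-weighted compromise

    s~2 = (d0 * s0^2 + d * s2) / (d0 + d),

and t = M / sqrt(s~2 * sum(1/n_g)) has a Student t distribution with
d0 + d degrees of freedom under the null (normal when d0 = infinity).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, special, stats
from statsmodels.stats.multitest import multipletests

GROUP_COLUMNS = ("p0", "p6", "np0", "np6")


@dataclass
class ModerationParams:
    """Empirical-Bayes prior for the residual variances.

    d0 is the prior degrees of freedom (may be ``inf``), s0_2 the prior
    variance on the log2^2 scale.  d0 = 0 is accepted as the explicit
    "no moderation" limit in which the ordinary per-gene variance is used.
    """

    d0: float
    s0_2: float

    def __post_init__(self) -> None:
        if self.d0 < 0:
            raise ValueError("d0 must be >= 0")
        if self.d0 > 0 and not self.s0_2 > 0:
            raise ValueError("s0_2 must be > 0")


def _group_of(design: pd.DataFrame) -> pd.Series:
    frac = design["fraction"].map({"polysomal": "p", "non_polysomal": "np"})
    time = design["time"].map({"t0": "0", "t6": "6"})
    if frac.isna().any() or time.isna().any():
        bad = design.loc[frac.isna() | time.isna(), "sample_id"].tolist()
        raise ValueError(f"unrecognized fraction/time labels for samples {bad}")
    return frac + time


def fit_gene_models(matrix, design: pd.DataFrame) -> pd.DataFrame:
    """Per-gene cell means and pooled residual variance.

    Parameters
    ----------
    matrix : ExpressionMatrix
        Spike-normalized log2 intensities; only non-spike probes are fitted.
    design : DataFrame
        Columns sample_id, fraction, time, replicate.

    Returns
    -------
    DataFrame indexed by gene_id with columns p0, p6, np0, np6 (group
    means), s2 (pooled within-group variance), df (N - 4) and n_p0..n_np6
    (group sizes).
    """
    design = design.copy()
    design["group"] = _group_of(design).to_numpy()
    present = set(design["group"])
    missing = [g for g in GROUP_COLUMNS if g not in present]
    if missing:
        raise ValueError(f"design is missing groups: {missing}")

    genes = matrix.genes()
    out = pd.DataFrame(index=genes.index)
    n_total = 0
    ss = np.zeros(len(genes))
    for g in GROUP_COLUMNS:
        cols = design.loc[design["group"] == g, "sample_id"].tolist()
        vals = genes[cols].to_numpy()
        out[g] = vals.mean(axis=1)
        out[f"n_{g}"] = len(cols)
        ss += ((vals - out[g].to_numpy()[:, None]) ** 2).sum(axis=1)
        n_total += len(cols)
    df = n_total - 4
    if df < 1:
        raise ValueError("pooled residual degrees of freedom < 1")
    s2 = ss / df
    # squared double-precision rounding of ~10-unit log2 intensities lands
    # around 1e-30; snap that dust to an exact zero so noise-free data take
    # the documented degenerate branches
    s2[s2 < 1e-20] = 0.0
    out["s2"] = s2
    out["df"] = df
    out.index.name = "gene_id"
    return out


def _trigamma_inverse(y: float) -> float:
    """Solve psi'(x) = y for x > 0 (psi' is strictly decreasing)."""
    if y <= 0:
        return math.inf
    # psi'(x) ~ 1/x + 1/(2x^2); bracket around the 1/y first guess
    lo, hi = 1.0 / y, 1.0 / y + 1.0
    while special.polygamma(1, lo) < y:
        lo /= 2.0
        if lo < 1e-300:
            return math.inf
    while special.polygamma(1, hi) > y:
        hi *= 2.0
    return float(optimize.brentq(lambda x: special.polygamma(1, x) - y, lo, hi,
                                 xtol=1e-12, rtol=1e-12))


def estimate_moderation(fits: pd.DataFrame) -> ModerationParams:
    """Moment-matching fit of the inverse-chi-square variance prior.

    Uses only genes with s2 > 0 (a zero sample variance carries no
    information about the prior on the log scale).  Warns below 20 usable
    genes; errors when every s2 is zero, since noise-free data needs no
    moderation.
    """
    s2 = fits["s2"].to_numpy(float)
    d = fits["df"].to_numpy(float)
    pos = s2 > 0
    if not pos.any():
        raise ValueError("all residual variances are zero; moderation undefined")
    if pos.sum() < 20:
        warnings.warn(
            f"only {int(pos.sum())} genes with positive variance; "
            "prior estimates will be unstable"
        )
    s2, d = s2[pos], d[pos]
    half = d / 2.0
    e = np.log(s2) - special.digamma(half) + np.log(half)
    mean_e = float(e.mean())
    spread = float(e.var(ddof=1)) - float(special.polygamma(1, half).mean())
    if spread <= 0:
        return ModerationParams(d0=math.inf, s0_2=float(np.exp(mean_e)))
    x = _trigamma_inverse(spread)  # x = d0/2
    if not math.isfinite(x):
        return ModerationParams(d0=math.inf, s0_2=float(np.exp(mean_e)))
    d0 = 2.0 * x
    s0_2 = float(np.exp(mean_e + special.digamma(x) - math.log(x)))
    return ModerationParams(d0=d0, s0_2=s0_2)


def _moderated_variance(s2, d, mod: ModerationParams):
    if math.isinf(mod.d0):
        return np.full_like(np.asarray(s2, float), mod.s0_2)
    if mod.d0 == 0:
        return np.asarray(s2, float)
    return (mod.d0 * mod.s0_2 + d * s2) / (mod.d0 + d)


def _tail_df(mod: ModerationParams, d):
    return None if math.isinf(mod.d0) else mod.d0 + d


def shift_contrast(fits: pd.DataFrame, mod: ModerationParams) -> pd.DataFrame:
    """Moderated test of the polysome-shift contrast for every gene.

    Returns a DataFrame with the group means carried through plus M,
    se, t, p.  Degenerate genes with SE = 0 get p = 0 when M != 0 and
    p = 1 otherwise (with a warning), which is the correct noise-free
    limit.
    """
    p0, p6 = fits["p0"].to_numpy(), fits["p6"].to_numpy()
    np0, np6 = fits["np0"].to_numpy(), fits["np6"].to_numpy()
    m = (p6 - np6) - (p0 - np0)
    inv_n = sum(1.0 / fits[f"n_{g}"].to_numpy(float) for g in GROUP_COLUMNS)
    s2_tilde = _moderated_variance(fits["s2"].to_numpy(float),
                                   fits["df"].to_numpy(float), mod)
    se = np.sqrt(s2_tilde * inv_n)

    t = np.zeros_like(m)
    p = np.ones_like(m)
    ok = se > 0
    t[ok] = m[ok] / se[ok]
    df = _tail_df(mod, fits["df"].to_numpy(float))
    if df is None:
        p[ok] = 2.0 * stats.norm.sf(np.abs(t[ok]))
    else:
        p[ok] = 2.0 * stats.t.sf(np.abs(t[ok]), df[ok] if np.ndim(df) else df)
    if (~ok).any():
        warnings.warn(f"{int((~ok).sum())} genes have zero SE (noise-free input)")
        m0 = np.where(np.abs(m[~ok]) < 1e-9, 0.0, m[~ok])  # rounding dust
        t[~ok] = np.where(m0 > 0, np.inf, np.where(m0 < 0, -np.inf, 0.0))
        p[~ok] = np.where(m0 != 0, 0.0, 1.0)

    out = fits[[*GROUP_COLUMNS]].copy()
    out["M"] = m
    out["se"] = se
    out["t"] = t
    out["p"] = p
    return out


def adjust_bh(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (FDR)."""
    p = np.asarray(pvalues, float)
    if p.size == 0:
        return p
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def tost_equivalence(
    fits: pd.DataFrame, mod: ModerationParams, epsilon: float = 0.2
) -> np.ndarray:
    """Two one-sided tests of |M| < epsilon using the moderated SE and df.

    The TOST p-value is the larger of the one-sided p-values for
    H0: M <= -epsilon and H0: M >= +epsilon; equivalence is declared
    downstream when it falls below alpha.  With SE = 0 the data determine
    M exactly and the p-value degenerates to 0 / 0.5 / 1 according to
    whether |M| is below, at, or beyond the margin.
    """
    if epsilon <= 0:
        raise ValueError("epsilon must be > 0")
    p0, p6 = fits["p0"].to_numpy(), fits["p6"].to_numpy()
    np0, np6 = fits["np0"].to_numpy(), fits["np6"].to_numpy()
    m = (p6 - np6) - (p0 - np0)
    inv_n = sum(1.0 / fits[f"n_{g}"].to_numpy(float) for g in GROUP_COLUMNS)
    s2_tilde = _moderated_variance(fits["s2"].to_numpy(float),
                                   fits["df"].to_numpy(float), mod)
    se = np.sqrt(s2_tilde * inv_n)
    df = _tail_df(mod, fits["df"].to_numpy(float))

    p_tost = np.empty_like(m)
    ok = se > 0
    t_lo = (m[ok] + epsilon) / se[ok]   # H0: M <= -eps, reject for large t
    t_hi = (m[ok] - epsilon) / se[ok]   # H0: M >= +eps, reject for small t
    if df is None:
        p_lo = stats.norm.sf(t_lo)
        p_hi = stats.norm.cdf(t_hi)
    else:
        dfo = df[ok] if np.ndim(df) else df
        p_lo = stats.t.sf(t_lo, dfo)
        p_hi = stats.t.cdf(t_hi, dfo)
    p_tost[ok] = np.maximum(p_lo, p_hi)

    deg = ~ok
    if deg.any():
        a = np.abs(m[deg])
        at_margin = np.abs(a - epsilon) < 1e-12
        p_tost[deg] = np.where(a < epsilon, 0.0, np.where(at_margin, 0.5, 1.0))
    return p_tost


def shift_results(
    matrix, design: pd.DataFrame, mod: ModerationParams | None = None,
    epsilon: float = 0.2
) -> tuple[pd.DataFrame, ModerationParams]:
    """Fit, moderate and test every gene; convenience wrapper.

    Falls back to no moderation (d0 = 0) when the data are noise-free and
    the prior is undefined.
    """
    fits = fit_gene_models(matrix, design)
    if mod is None:
        try:
            mod = estimate_moderation(fits)
        except ValueError:
            warnings.warn("noise-free data: proceeding without moderation")
            mod = ModerationParams(d0=0.0, s0_2=1.0)
    res = shift_contrast(fits, mod)
    res["fdr"] = adjust_bh(res["p"].to_numpy())
    res["p_tost"] = tost_equivalence(fits, mod, epsilon)
    return res, mod


def total_translation_activity(matrix, design: pd.DataFrame) -> pd.DataFrame:
    """One-sided test that polysomal RNA content exceeds the free pool.

    Per sample the summary is the mean log2 intensity over non-spike
    probes; per time point a one-sided Welch two-sample t-test of
    polysomal > free is run.  Returns a DataFrame indexed by time with
    columns statistic, df, p.
    """
    genes = matrix.genes()
    rows = {}
    for time, sub in design.groupby("time", sort=True):
        poly = sub.loc[sub["fraction"] == "polysomal", "sample_id"]
        free = sub.loc[sub["fraction"] == "non_polysomal", "sample_id"]
        if len(poly) < 2 or len(free) < 2:
            raise ValueError(f"time point {time}: need >= 2 replicates per fraction")
        a = genes[list(poly)].mean(axis=0).to_numpy()
        b = genes[list(free)].mean(axis=0).to_numpy()
        if np.ptp(a) == 0 and np.ptp(b) == 0:
            # degenerate noise-free input: the comparison is exact
            delta = float(a[0] - b[0])
            rows[time] = {
                "statistic": math.copysign(math.inf, delta) if delta else 0.0,
                "df": float(len(a) + len(b) - 2),
                "p": 0.0 if delta > 0 else (0.5 if delta == 0 else 1.0),
            }
            continue
        res = stats.ttest_ind(a, b, equal_var=False, alternative="greater")
        rows[time] = {"statistic": float(res.statistic), "df": float(res.df),
                      "p": float(res.pvalue)}
    return pd.DataFrame(rows).T
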