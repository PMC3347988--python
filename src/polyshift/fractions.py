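"""Gradient-fraction QC: linearity check, 28S/18S classification, pooling plan.

A linear 0-50% sucrose gradient is fractionated from the top into 13
fractions.  Fractions whose 28S/18S rRNA ratio is close to two contain
intact assembled ribosomes (polysomal RNA); usable fractions with a ratio
clearly different from two carry free (non-polysomal) RNA.  The boundary
fraction between the two runs is excluded to keep the pools cleanly
separated, and the buffer/debris fractions at the gradient ends are
discarded.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats


@dataclass
class FractionProfile:
    """One gradient fraction: index, refractometer reading, rRNA ratio."""

    fraction_index: int
    sucrose_pct: float
    ratio_28s_18s: float
    usable: bool = True

    def __post_init__(self) -> None:
        if self.ratio_28s_18s < 0:
            raise ValueError("28S/18S ratio must be >= 0")


@dataclass
class LinearityReport:
    """Least-squares fit of sucrose % on fraction index."""

    slope: float
    intercept: float
    r_squared: float
    max_abs_residual: float
    passed: bool


@dataclass
class PoolingPlan:
    """Disjoint assignment of fractions 1..13 to pools."""

    free_fractions: list[int]
    polysomal_fractions: list[int]
    buffer_zone: list[int]
    discarded: list[int]

    def __post_init__(self) -> None:
        groups = [
            self.free_fractions,
            self.polysomal_fractions,
            self.buffer_zone,
            self.discarded,
        ]
        seen: set[int] = set()
        for g in groups:
            overlap = seen.intersection(g)
            if overlap:
                raise ValueError(f"pooling plan lists overlap on {sorted(overlap)}")
            seen.update(g)


def check_gradient_linearity(
    profiles: list[FractionProfile],
    r2_min: float = 0.98,
    resid_max: float = 2.0,
) -> LinearityReport:
    """Verify the sucrose gradient is linear in fraction index.

    Fits sucrose_pct ~ fraction_index by ordinary least squares over all
    fractions with a sucrose reading (the refractometer reads every
    fraction, usable or not) and flags failure when r^2 < ``r2_min`` or
    the largest absolute residual exceeds ``resid_max`` (percent sucrose).
    A constant profile has undefined r^2, reported as 0 and failed.
    """
    x = np.array([p.fraction_index for p in profiles], float)
    y = np.array([p.sucrose_pct for p in profiles], float)
    if len(x) < 3:
        raise ValueError("gradient linearity check needs >= 3 fractions")
    if np.ptp(y) == 0:
        return LinearityReport(0.0, float(y[0]), 0.0, 0.0, passed=False)
    fit = stats.linregress(x, y)
    resid = y - (fit.intercept + fit.slope * x)
    r2 = float(fit.rvalue**2)
    max_resid = float(np.max(np.abs(resid)))
    return LinearityReport(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=r2,
        max_abs_residual=max_resid,
        passed=(r2 >= r2_min and max_resid <= resid_max),
    )


def _longest_run(indices: list[int]) -> list[int]:
    """Longest contiguous run of sorted integers; earliest run wins ties."""
    if not indices:
        return []
    runs, current = [], [indices[0]]
    for i in indices[1:]:
        if i == current[-1] + 1:
            current.append(i)
        else:
            runs.append(current)
            current = [i]
    runs.append(current)
    return max(runs, key=len)


def classify_fractions(
    profiles: list[FractionProfile],
    ratio_target: float = 2.0,
    ratio_tol: float = 0.3,
) -> PoolingPlan:
    """Build the pooling plan from 28S/18S ratios.

    Usable fractions with |ratio - target| <= ``ratio_tol`` are polysomal
    candidates, the remaining usable fractions free-RNA candidates; each
    pool is the longest contiguous run of its candidates (isolated
    stragglers are pushed to discarded with a warning).  The usable
    fraction(s) between the two runs form the buffer zone; when the runs
    touch, the free fraction at the junction is demoted to the buffer zone
    so the pools stay cleanly separated.  Unusable fractions are discarded.

    Raises
    ------
    ValueError
        When either pool would end up with fewer than 2 fractions.
    """
    profiles = sorted(profiles, key=lambda p: p.fraction_index)
    usable = [p for p in profiles if p.usable]
    poly_cand = [
        p.fraction_index
        for p in usable
        if abs(p.ratio_28s_18s - ratio_target) <= ratio_tol
    ]
    free_cand = [
        p.fraction_index
        for p in usable
        if abs(p.ratio_28s_18s - ratio_target) > ratio_tol
    ]

    poly = _longest_run(sorted(poly_cand))
    free = _longest_run(sorted(free_cand))
    if len(free) < 2 or len(poly) < 2:
        raise ValueError(
            "pooling impossible: need >= 2 fractions in both the free "
            f"and polysomal pools (got free={free}, polysomal={poly})"
        )

    stragglers = sorted((set(poly_cand) - set(poly)) | (set(free_cand) - set(free)))

    lo, hi = (free, poly) if free[0] < poly[0] else (poly, free)
    between = [
        p.fraction_index
        for p in usable
        if lo[-1] < p.fraction_index < hi[0]
    ]
    buffer_zone = list(between)
    if not buffer_zone:
        # runs are adjacent: sacrifice the free-pool fraction at the junction
        junction = free[-1] if free[0] < poly[0] else free[0]
        free = [i for i in free if i != junction]
        buffer_zone = [junction]
        if len(free) < 2:
            raise ValueError("free pool too small after separating the pools")
    else:
        stragglers = [s for s in stragglers if s not in buffer_zone]

    if stragglers:
        warnings.warn(
            f"isolated fractions {stragglers} did not join a contiguous pool; discarded"
        )
    assigned = set(free) | set(poly) | set(buffer_zone)
    discarded = [p.fraction_index for p in profiles if p.fraction_index not in assigned]
    return PoolingPlan(
        free_fractions=free,
        polysomal_fractions=poly,
        buffer_zone=buffer_zone,
        discarded=discarded,
    )
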