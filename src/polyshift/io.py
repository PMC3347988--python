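"""Readers and writers for the pipeline's tab-separated interchange files.

All intermediate artifacts are plain TSV/CSV so a run is auditable with
standard tools.  A minimal reader for GEO series-matrix-format TSV is
included for users who want to point the pipeline at a deposited series;
it is never required by the synthetic workflow.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .fractions import FractionProfile, PoolingPlan
from .normalize import ExpressionMatrix


def write_expression_matrix(matrix: ExpressionMatrix, path) -> None:
    out = matrix.values.copy()
    out.insert(0, "is_spike", matrix.is_spike.astype(int))
    out.to_csv(path, sep="\t")


def read_expression_matrix(path, spike_probes: list[str] | None = None) -> ExpressionMatrix:
    """Read a probes-x-samples TSV.

    Spike probes are flagged either by an ``is_spike`` column in the file
    or by an explicit ``spike_probes`` list.
    """
    frame = pd.read_csv(path, sep="\t", index_col=0)
    if "is_spike" in frame.columns:
        is_spike = frame.pop("is_spike").astype(bool)
    elif spike_probes is not None:
        is_spike = pd.Series(frame.index.isin(spike_probes), index=frame.index)
    else:
        raise ValueError(
            "matrix file has no is_spike column and no spike list was given"
        )
    return ExpressionMatrix(frame.astype(float), is_spike)


def write_design(design: pd.DataFrame, path) -> None:
    design.to_csv(path, sep="\t", index=False)


def read_design(path) -> pd.DataFrame:
    design = pd.read_csv(path, sep="\t")
    required = {"sample_id", "fraction", "time", "replicate"}
    missing = required - set(design.columns)
    if missing:
        raise ValueError(f"design file lacks columns: {sorted(missing)}")
    return design


def write_truth(truth: pd.DataFrame, path) -> None:
    truth.to_csv(path, sep="\t", index=False)


def read_truth(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_profiles(profiles: list[FractionProfile], path) -> None:
    pd.DataFrame(
        {
            "fraction_index": [p.fraction_index for p in profiles],
            "sucrose_pct": [p.sucrose_pct for p in profiles],
            "ratio_28s_18s": [p.ratio_28s_18s for p in profiles],
            "usable": [int(p.usable) for p in profiles],
        }
    ).to_csv(path, sep="\t", index=False)


def read_profiles(path) -> list[FractionProfile]:
    frame = pd.read_csv(path, sep="\t")
    return [
        FractionProfile(
            fraction_index=int(r.fraction_index),
            sucrose_pct=float(r.sucrose_pct),
            ratio_28s_18s=float(r.ratio_28s_18s),
            usable=bool(r.usable),
        )
        for r in frame.itertuples()
    ]


def write_pooling_plan(plan: PoolingPlan, path) -> None:
    rows = []
    for pool, fractions in (
        ("free", plan.free_fractions),
        ("polysomal", plan.polysomal_fractions),
        ("buffer", plan.buffer_zone),
        ("discarded", plan.discarded),
    ):
        rows.extend({"fraction_index": i, "pool": pool} for i in fractions)
    pd.DataFrame(rows).sort_values("fraction_index").to_csv(path, sep="\t", index=False)


def write_ct_table(ct: pd.DataFrame, path) -> None:
    ct.to_csv(path, index=False)


def read_ct_table(path) -> pd.DataFrame:
    ct = pd.read_csv(path)
    required = {"gene_id", "fraction", "time", "replicate", "technical_rep", "ct"}
    missing = required - set(ct.columns)
    if missing:
        raise ValueError(f"Ct table lacks columns: {sorted(missing)}")
    return ct


def read_series_matrix(path, design_map: pd.DataFrame,
                       spike_probes: list[str]) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Read a GEO series-matrix TSV plus a user-supplied sample mapping.

    ``design_map`` must carry columns sample_id (the GSM title or
    accession used as column header), fraction, time, replicate.  Lines
    starting with ``!`` (series metadata) are skipped; the expression
    block between the table-begin/end markers is parsed.
    """
    lines = Path(path).read_text().splitlines()
    rows = [
        ln for ln in lines
        if ln and not ln.startswith("!") and not ln.startswith("#")
    ]
    from io import StringIO

    frame = pd.read_csv(StringIO("\n".join(rows)), sep="\t", index_col=0)
    frame = frame.dropna(axis=1, how="all")
    design = design_map.copy()
    unknown = set(design["sample_id"]) - set(frame.columns)
    if unknown:
        raise ValueError(f"mapped samples not in series matrix: {sorted(unknown)}")
    frame = frame[design["sample_id"].tolist()].astype(float)
    is_spike = pd.Series(frame.index.isin(spike_probes), index=frame.index)
    if not is_spike.any():
        raise ValueError("none of the listed spike probes occur in the matrix")
    return ExpressionMatrix(frame, is_spike), design
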