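"""End-to-end orchestration: simulate -> fraction QC -> normalize -> shift
-> classify -> report, with every intermediate written to disk and a
manifest recording the configuration and seed."""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import io as pio
from .classify import classify_genes, order_for_heatmap
from .config import SimConfig, Thresholds
from .fractions import check_gradient_linearity, classify_fractions
from .normalize import sample_qc, spike_normalize
from .shift import shift_results, total_translation_activity
from .simulate import (
    generate_ct_table,
    generate_expression_dataset,
    generate_fraction_profiles,
)

logger = logging.getLogger("polyshift")


@dataclass
class RunConfig:
    """Configuration of a pipeline run.

    In simulation mode (``sim`` set) all inputs are generated; otherwise
    ``matrix_path`` / ``design_path`` / ``profiles_path`` must point to
    existing files.
    """

    out_dir: Path
    sim: SimConfig | None = None
    matrix_path: Path | None = None
    design_path: Path | None = None
    profiles_path: Path | None = None
    thresholds: Thresholds = field(default_factory=Thresholds)
    seed: int = 0
    ratio_tol: float = 0.3
    r2_min: float = 0.98
    resid_max: float = 2.0
    log_level: str = "INFO"


@dataclass
class RunReport:
    """Aggregated outcome of one pipeline run."""

    pooling_plan: dict
    linearity: dict
    qc_passed: bool
    moderation: dict
    class_summary: dict
    translation: dict
    thresholds: Thresholds
    seed: int
    confusion: pd.DataFrame | None = None


def _stage(name: str):
    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise RuntimeError(f"pipeline stage '{name}' failed: {exc}") from exc

        return inner

    return wrap


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute the full analysis, writing intermediates under ``out_dir``.

    Returns a :class:`RunReport`; in simulation mode it includes the
    confusion table of called class versus planted class.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(stream=sys.stderr, level=config.log_level)

    truth = None
    if config.sim is not None:
        sim = config.sim
        matrix, design, truth = generate_expression_dataset(sim)
        profiles = generate_fraction_profiles(sim)
        pio.write_expression_matrix(matrix, out / "matrix_raw.tsv")
        pio.write_design(design, out / "design.tsv")
        pio.write_truth(truth, out / "truth.tsv")
        pio.write_profiles(profiles, out / "profiles.tsv")
    else:
        for name, p in (
            ("matrix", config.matrix_path),
            ("design", config.design_path),
            ("profiles", config.profiles_path),
        ):
            if p is None or not Path(p).exists():
                raise FileNotFoundError(f"required {name} file missing: {p}")
        matrix = pio.read_expression_matrix(config.matrix_path)
        design = pio.read_design(config.design_path)
        profiles = pio.read_profiles(config.profiles_path)

    linearity = _stage("fraction-qc")(check_gradient_linearity)(
        profiles, config.r2_min, config.resid_max
    )
    plan = _stage("fraction-qc")(classify_fractions)(
        profiles, ratio_tol=config.ratio_tol
    )
    pio.write_pooling_plan(plan, out / "pooling_plan.tsv")
    logger.info("pooling plan: free=%s polysomal=%s buffer=%s",
                plan.free_fractions, plan.polysomal_fractions, plan.buffer_zone)

    norm = _stage("normalize")(spike_normalize)(matrix)
    pio.write_expression_matrix(norm, out / "matrix_normalized.tsv")
    qc = _stage("sample-qc")(sample_qc)(norm, design)
    logger.info("sample QC %s", "PASS" if qc.passed else "FAIL")

    results, mod = _stage("shift")(shift_results)(
        norm, design, epsilon=config.thresholds.epsilon
    )
    translation = _stage("shift")(total_translation_activity)(norm, design)

    labelled, summary = _stage("classify")(classify_genes)(
        results, config.thresholds
    )
    labelled.to_csv(out / "shift_results.tsv", sep="\t")
    order_for_heatmap(labelled).to_csv(out / "heatmap_matrix.tsv", sep="\t")

    confusion = None
    if truth is not None:
        merged = labelled.join(truth.set_index("gene_id"))
        confusion = pd.crosstab(merged["true_class"], merged["gene_class"])
        confusion.to_csv(out / "confusion.tsv", sep="\t")

    report = RunReport(
        pooling_plan={
            "free": plan.free_fractions,
            "polysomal": plan.polysomal_fractions,
            "buffer": plan.buffer_zone,
            "discarded": plan.discarded,
        },
        linearity={
            "slope": linearity.slope,
            "r_squared": linearity.r_squared,
            "max_abs_residual": linearity.max_abs_residual,
            "passed": linearity.passed,
        },
        qc_passed=qc.passed,
        moderation={"d0": mod.d0, "s0_2": mod.s0_2},
        class_summary=summary,
        translation={t: row["p"] for t, row in translation.iterrows()},
        thresholds=config.thresholds,
        seed=config.seed,
        confusion=confusion,
    )
    _write_manifest(config, out)
    (out / "report.md").write_text(render_report(report))
    return report


def _write_manifest(config: RunConfig, out: Path) -> None:
    import numpy, scipy, pandas, statsmodels

    from . import __version__

    payload = {
        "seed": config.seed,
        "thresholds": vars(config.thresholds),
        "sim": config.sim.to_dict() if config.sim else None,
        "versions": {
            "polyshift": __version__,
            "numpy": numpy.__version__,
            "scipy": scipy.__version__,
            "pandas": pandas.__version__,
            "statsmodels": statsmodels.__version__,
        },
    }
    blob = json.dumps(payload, sort_keys=True)
    payload["config_hash"] = hashlib.sha256(blob.encode()).hexdigest()[:16]
    (out / "manifest.json").write_text(json.dumps(payload, indent=2))


def render_report(report: RunReport) -> str:
    """Human-readable Markdown summary of a run."""
    th = report.thresholds
    lines = [
        "# Polysome-shift analysis report",
        "",
        f"- seed: {report.seed}",
        f"- thresholds: fdr < {th.fdr_max}, screen |M| > {th.m_screen}, "
        f"call |M| > {th.m_call}, epsilon = {th.epsilon}, alpha_eq = {th.alpha_eq}",
        f"- gradient linearity: r^2 = {report.linearity['r_squared']:.4f}, "
        f"max residual = {report.linearity['max_abs_residual']:.3f}% "
        f"({'PASS' if report.linearity['passed'] else 'FAIL'})",
        f"- pooling plan: free {report.pooling_plan['free']}, "
        f"buffer {report.pooling_plan['buffer']}, "
        f"polysomal {report.pooling_plan['polysomal']}",
        f"- sample QC: {'PASS' if report.qc_passed else 'FAIL'}",
        f"- moderation prior: d0 = {report.moderation['d0']:.4g}, "
        f"s0^2 = {report.moderation['s0_2']:.4g}",
        "",
        "## Gene classes",
        "",
        f"- screen (fdr & |M|): {report.class_summary['screen_up']} up / "
        f"{report.class_summary['screen_down']} down",
        f"- Up: {report.class_summary['up']}",
        f"- Down: {report.class_summary['down']}",
        f"- Equal: {report.class_summary['equal']}",
        f"- Unclassified: {report.class_summary['unclassified']}",
        "",
        "## Total translation activity (polysomal > free, one-sided p)",
        "",
    ]
    for t, p in report.translation.items():
        lines.append(f"- {t}: p = {p:.3g}")
    if report.confusion is not None:
        lines += ["", "## Confusion (planted vs called)", "",
                  report.confusion.to_string()]
    return "\n".join(lines) + "\n"
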