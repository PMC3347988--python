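"""Synthetic polysome-profiling data with known ground truth.

Emulates the full measurement chain of a gradient-fractionation experiment
in 3T3-L1 preadipocytes: 13 sucrose-gradient fractions with 28S/18S rRNA
ratios, pooled polysomal / non-polysomal RNA at 0 h and 6 h after hormonal
induction in biological triplicate, log2 array intensities with spike-in
probes and per-sample distortions, and triplicate q-PCR Ct plates with
normalizer genes.  Every planted effect is recorded in a truth table so
downstream stages can be scored exactly.

The planted gene classes:

``up``
    Polysome-shift of +``effect_up`` log2 units: polysomal signal rises at
    6 h while the free pool is depleted by ``directional_margin`` (mRNA
    recruited into polysomes leaves the free pool), so all five strict
    directional conditions of the classifier hold in the noise-free limit
    and the planted M equals ``effect_up`` exactly.
``down``
    Elevated polysomal association at 0 h (p0 > np0) that is lost by 6 h,
    giving M = ``effect_down`` < 0 with p6 < p0 -- the only pattern the
    down filter accepts.
``mrna_artifact``
    A total-mRNA steady-state drop at 6 h hitting BOTH pools, the free pool
    harder than the polysomal one.  This produces a large positive M
    without any genuine translational up-regulation; the directional filter
    p6 > p0 must reject it.
``equal``
    Planted M = 0; target of the equivalence (TOST) test.
``null``
    Everything else; M = 0.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import SimConfig
from .fractions import FractionProfile
from .normalize import ExpressionMatrix

GROUPS = ("p0", "p6", "np0", "np6")  # (fraction, time) cell labels

_GROUP_DESIGN = {
    "p0": ("polysomal", "t0"),
    "p6": ("polysomal", "t6"),
    "np0": ("non_polysomal", "t0"),
    "np6": ("non_polysomal", "t6"),
}


def _class_offsets(config: SimConfig) -> dict[str, np.ndarray]:
    """Per-class group-mean offsets (p0, p6, np0, np6) from baseline, log2."""
    d = config.directional_margin
    up = np.array([-d, config.effect_up - 2 * d, 0.0, -d])
    down = np.array([abs(config.effect_down), 0.0, 0.0, 0.0])
    artifact = np.array(
        [0.0, -config.artifact_drop_polysomal, 0.0, -config.artifact_drop_nonpolysomal]
    )
    zero = np.zeros(4)
    return {"up": up, "down": down, "mrna_artifact": artifact, "equal": zero, "null": zero}


def _true_m(offsets: np.ndarray) -> float:
    p0, p6, np0, np6 = offsets
    return float((p6 - np6) - (p0 - np0))


def _assign_classes(config: SimConfig) -> np.ndarray:
    """Deterministic class counts from the configured proportions."""
    n = config.n_genes
    counts = {
        "up": round(config.frac_up * n),
        "down": round(config.frac_down * n),
        "mrna_artifact": round(config.frac_mrna_artifact * n),
        "equal": round(config.frac_equal * n),
    }
    if sum(counts.values()) > n:
        raise ValueError("class proportions leave no room for null genes")
    labels = []
    for cls, c in counts.items():
        labels.extend([cls] * c)
    labels.extend(["null"] * (n - len(labels)))
    return np.array(labels)


def make_design(replicates: int = 3) -> pd.DataFrame:
    """Sample design table: 2 fractions x 2 times x replicates."""
    rows = []
    for grp in GROUPS:
        fraction, time = _GROUP_DESIGN[grp]
        for r in range(1, replicates + 1):
            rows.append(
                {
                    "sample_id": f"{grp}_r{r}",
                    "fraction": fraction,
                    "time": time,
                    "replicate": r,
                }
            )
    return pd.DataFrame(rows)


def generate_expression_dataset(
    config: SimConfig,
) -> tuple[ExpressionMatrix, pd.DataFrame, pd.DataFrame]:
    """Simulate the spike-in microarray experiment.

    Returns
    -------
    matrix : ExpressionMatrix
        Log2 intensities for ``n_genes`` gene probes plus ``n_spikes``
        spike probes, with per-sample affine distortion applied.
    design : DataFrame
        Columns sample_id, fraction, time, replicate.
    truth : DataFrame
        Columns gene_id, true_class, true_M (log2).
    """
    rng = np.random.default_rng(config.seed)
    design = make_design(config.replicates)
    n_samples = len(design)

    classes = _assign_classes(config)
    offsets = _class_offsets(config)
    gene_ids = np.array([f"GENE{i:05d}" for i in range(config.n_genes)])
    baseline = rng.normal(config.baseline_mean, config.baseline_sd, config.n_genes)

    # group-mean matrix mu[gene, group]; columns ordered as GROUPS
    mu = baseline[:, None] + np.vstack([offsets[c] for c in classes])

    # Null genes additionally carry a baseline polysome-association offset
    # (both time points of the polysomal pool) and a shared-steady-state
    # induction response (both pools at 6 h).  Both cancel exactly in
    # M = (p6-np6)-(p0-np0), so planted truth is untouched, but they give
    # the samples the fraction-then-time clustering structure real
    # profiling data shows.  Planted classes keep their exact four-cell
    # pattern so the strict directional filters behave deterministically.
    is_null = classes == "null"
    assoc = np.where(is_null, rng.normal(0.0, config.sigma_fraction_assoc,
                                         config.n_genes), 0.0)
    time_eff = np.where(is_null, rng.normal(0.0, config.sigma_time_effect,
                                            config.n_genes), 0.0)
    mu[:, GROUPS.index("p0")] += assoc
    mu[:, GROUPS.index("p6")] += assoc + time_eff
    mu[:, GROUPS.index("np6")] += time_eff

    group_of_sample = [s.rsplit("_r", 1)[0] for s in design["sample_id"]]
    gidx = np.array([GROUPS.index(g) for g in group_of_sample])
    clean = mu[:, gidx]
    clean = clean + rng.normal(0.0, config.sigma_bio, clean.shape)
    clean = clean + rng.normal(0.0, config.sigma_tech, clean.shape)

    # spike probes: identical true abundance in every sample
    spike_ids = np.array([f"SPIKE{i:03d}" for i in range(config.n_spikes)])
    spike_levels = np.linspace(4.0, 14.0, max(config.n_spikes, 1))[: config.n_spikes]
    spikes = np.tile(spike_levels[:, None], (1, n_samples))
    spikes = spikes + rng.normal(0.0, config.sigma_tech, spikes.shape)

    values = np.vstack([clean, spikes])
    scale = rng.uniform(*config.sample_scale_range, n_samples)
    offset = rng.uniform(*config.sample_offset_range, n_samples)
    values = values * scale[None, :] + offset[None, :]

    frame = pd.DataFrame(
        values,
        index=pd.Index(np.concatenate([gene_ids, spike_ids]), name="probe_id"),
        columns=design["sample_id"].tolist(),
    )
    is_spike = pd.Series(
        np.concatenate(
            [np.zeros(config.n_genes, bool), np.ones(config.n_spikes, bool)]
        ),
        index=frame.index,
    )
    truth = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "true_class": classes,
            "true_M": [_true_m(offsets[c]) for c in classes],
        }
    )
    return ExpressionMatrix(frame, is_spike), design, truth


# per-fraction 28S/18S design values and usability of the 13-fraction gradient:
# 1-4 buffer/lysate/fat, 5-7 free RNA (ratio far from 2), 8 ambiguous boundary,
# 9-11 polysomal (ratio ~ 2), 12-13 cell debris.
_RATIO_DESIGN = (
    [0.2] * 4 + [0.7] * 3 + [1.4] + [2.0] * 3 + [0.3] * 2
)
_USABLE = [False] * 4 + [True] * 7 + [False] * 2


def generate_fraction_profiles(
    config: SimConfig | None = None,
    *,
    n_fractions: int = 13,
    sucrose_noise_sd: float = 0.0,
    ratio_noise_sd: float = 0.0,
    seed: int | None = None,
) -> list[FractionProfile]:
    """Simulate a 13-fraction 0-50% sucrose gradient profile.

    Sucrose concentration is affine in fraction index (a stable linear
    gradient); the 28S/18S ratio is ~2 for the polysomal fractions 9-11,
    clearly below 2 for the free-RNA fractions 5-7, intermediate for the
    boundary fraction 8, and the buffer/debris fractions 1-4 and 12-13
    carry unusable readings.
    """
    if n_fractions != 13:
        raise ValueError("the gradient protocol collects exactly 13 fractions")
    if seed is None:
        seed = config.seed if config is not None else 0
    rng = np.random.default_rng(seed)
    profiles = []
    for i in range(1, n_fractions + 1):
        sucrose = 50.0 * (i - 1) / (n_fractions - 1)
        sucrose += rng.normal(0.0, sucrose_noise_sd)
        ratio = _RATIO_DESIGN[i - 1] + rng.normal(0.0, ratio_noise_sd)
        profiles.append(
            FractionProfile(
                fraction_index=i,
                sucrose_pct=float(max(sucrose, 0.0)),
                ratio_28s_18s=float(max(ratio, 0.0)),
                usable=_USABLE[i - 1],
            )
        )
    return profiles


def generate_ct_table(
    truth: pd.DataFrame,
    config: SimConfig,
    *,
    target_genes: list[str] | None = None,
    n_normalizers: int = 3,
    technical_reps: int = 3,
    base_ct: float = 20.0,
    sigma_ct: float = 0.15,
    sigma_ct_tech: float = 0.05,
) -> pd.DataFrame:
    """Simulate a triplicate q-PCR plate over the 2x2 fraction/time design.

    Ct values follow the exponential-amplification model: one cycle fewer
    per two-fold abundance increase, so a gene's planted polysome shift
    ``true_M`` appears as a Ct double difference of ``-true_M`` cycles.
    Normalizer genes are taken from the planted nulls (true_M = 0), so
    their Ct is constant across conditions up to noise.

    Returns a tidy table with columns gene_id, fraction, time, replicate,
    technical_rep, ct, is_normalizer.
    """
    if n_normalizers < 1:
        raise ValueError("at least one normalizer gene is required")
    rng = np.random.default_rng(config.seed + 1)
    truth = truth.set_index("gene_id")

    nulls = truth.index[truth["true_M"] == 0.0]
    if len(nulls) < n_normalizers:
        raise ValueError("not enough true_M == 0 genes to serve as normalizers")
    normalizers = list(nulls[:n_normalizers])

    if target_genes is None:
        target_genes = []
        for cls in ("up", "down", "equal"):
            target_genes.extend(truth.index[truth["true_class"] == cls][:2])
    missing = [g for g in target_genes if g not in truth.index]
    if missing:
        raise ValueError(f"target genes absent from truth table: {missing}")

    offsets = _class_offsets(config)
    rows = []
    for gene in list(target_genes) + normalizers:
        off = offsets[truth.loc[gene, "true_class"]]
        for gi, grp in enumerate(GROUPS):
            fraction, time = _GROUP_DESIGN[grp]
            for r in range(1, config.replicates + 1):
                cell_ct = base_ct - off[gi] + rng.normal(0.0, sigma_ct)
                for t in range(1, technical_reps + 1):
                    rows.append(
                        {
                            "gene_id": gene,
                            "fraction": fraction,
                            "time": time,
                            "replicate": r,
                            "technical_rep": t,
                            "ct": cell_ct + rng.normal(0.0, sigma_ct_tech),
                            "is_normalizer": gene in normalizers,
                        }
                    )
    table = pd.DataFrame(rows)
    if (table["ct"] <= 0).any():
        raise ValueError("simulated Ct <= 0; lower the noise or raise base_ct")
    return table
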