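"""Configuration dataclasses shared across the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict


@dataclass
class SimConfig:
    """Parameters of the synthetic polysome-profiling experiment.

    The simulated design mirrors the bench experiment: two gradient pools
    (polysomal / non-polysomal) at two time points (0 h and 6 h after
    hormonal induction), in biological triplicate, measured as log2
    intensities on a one-color array with exogenous spike-in probes.

    Parameters
    ----------
    n_genes : int
        Number of (non-spike) gene probes.
    n_spikes : int
        Number of spike-in probes; their true abundances are identical in
        every sample so they calibrate per-sample distortions.
    replicates : int
        Biological replicates per (fraction, time) group.
    frac_up, frac_down, frac_equal, frac_mrna_artifact : float
        Proportions of genes planted as translationally up-regulated,
        down-regulated, explicitly unchanged (equivalence-test targets) and
        as total-mRNA artifacts (a steady-state change hitting both
        fractions at 6 h, which the directional classification filters must
        reject).  The remainder are nulls.
    effect_up, effect_down : float
        Planted polysome-shift effect sizes on the log2 scale
        (``effect_down`` is negative).
    directional_margin : float
        Log2 depletion of the free (non-polysomal) pool at 6 h, and of the
        polysomal pool at 0 h, planted for up-regulated genes so that mRNA
        conservation is respected: transcripts recruited into polysomes
        leave the free pool.  This makes the strict directional conditions
        of the classifier (p6>p0, p6>np6, np6<np0, p0<np0) hold exactly in
        the noise-free limit while keeping the planted M equal to
        ``effect_up``.
    sigma_bio : float
        Biological replicate SD (log2); each of the 12 samples is an
        independent gradient preparation.
    sigma_tech : float
        Measurement SD (log2) added per observation.
    sigma_fraction_assoc : float
        SD (log2) of the per-gene baseline polysome-association offset:
        transcripts differ widely in how strongly they are loaded onto
        polysomes regardless of induction.  Applied to both time points of
        the polysomal pool of null genes, it cancels exactly in M but gives
        samples the between-fraction structure that quality control expects
        to recover.
    sigma_time_effect : float
        SD (log2) of the per-gene transcriptome response to hormonal
        induction, applied to BOTH pools at 6 h of null genes (a
        steady-state change, invisible to M); drives the within-fraction
        time clustering.
    sample_scale_range, sample_offset_range : (float, float)
        Per-sample affine distortion of the log2 scale, drawn uniformly.
        The default leaves the scale at 1 (pure offsets), which the additive
        spike normalization inverts exactly.
    seed : int
        Seed for all randomness.
    """

    n_genes: int = 2000
    n_spikes: int = 30
    replicates: int = 3
    frac_up: float = 0.025
    frac_down: float = 0.0025
    frac_equal: float = 0.015
    frac_mrna_artifact: float = 0.05
    effect_up: float = 2.5
    effect_down: float = -2.5
    directional_margin: float = 0.6
    artifact_drop_polysomal: float = 0.5
    artifact_drop_nonpolysomal: float = 3.0
    sigma_bio: float = 0.25
    sigma_tech: float = 0.1
    sigma_fraction_assoc: float = 1.0
    sigma_time_effect: float = 0.3
    sample_scale_range: tuple[float, float] = (1.0, 1.0)
    sample_offset_range: tuple[float, float] = (-2.0, 2.0)
    baseline_mean: float = 8.0
    baseline_sd: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        total = (
            self.frac_up + self.frac_down + self.frac_equal + self.frac_mrna_artifact
        )
        if total > 1 + 1e-12:
            raise ValueError(f"class proportions sum to {total:.4f} > 1")
        for name in ("frac_up", "frac_down", "frac_equal", "frac_mrna_artifact"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.sigma_bio < 0 or self.sigma_tech < 0:
            raise ValueError("noise SDs must be >= 0")
        if self.replicates < 2:
            raise ValueError("replicates must be >= 2")
        if self.effect_up <= 0:
            raise ValueError("effect_up must be > 0")
        if self.effect_down >= 0:
            raise ValueError("effect_down must be < 0")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["sample_scale_range"] = list(self.sample_scale_range)
        d["sample_offset_range"] = list(self.sample_offset_range)
        return d


@dataclass
class Thresholds:
    """Cut-offs of the classification cascade.

    ``fdr_max`` and ``m_screen`` define the initial screen (fdr < 0.05 and
    |M| > 1); ``m_call`` is the stricter |M| > 2 bound required for an
    up/down call; ``epsilon`` is the TOST region of similarity on the log2
    scale and ``alpha_eq`` the level at which equivalence is declared.
    """

    fdr_max: float = 0.05
    m_screen: float = 1.0
    m_call: float = 2.0
    epsilon: float = 0.2
    alpha_eq: float = 0.05

    def __post_init__(self) -> None:
        if not (0 < self.fdr_max < 1):
            raise ValueError("fdr_max must be in (0, 1)")
        if not (self.m_call >= self.m_screen > 0):
            raise ValueError("require m_call >= m_screen > 0")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be > 0")
        if not (0 < self.alpha_eq < 1):
            raise ValueError("alpha_eq must be in (0, 1)")
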