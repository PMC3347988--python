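"""Statistical core: cell-means fits, empirical-Bayes moderation, the
polysome-shift contrast, BH adjustment, TOST and the translation-activity
test, each checked against an independent oracle."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from polyshift.config import SimConfig
from polyshift.normalize import ExpressionMatrix, spike_normalize
from polyshift.shift import (
    ModerationParams,
    adjust_bh,
    estimate_moderation,
    fit_gene_models,
    shift_contrast,
    shift_results,
    tost_equivalence,
    total_translation_activity,
)
from polyshift.simulate import generate_expression_dataset, make_design
from conftest import noise_free_config


def matrix_from_groups(groups: dict[str, np.ndarray]) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Build a matrix from per-group replicate values, one gene per row set."""
    design = make_design(replicates=len(next(iter(groups.values()))[0]))
    n_genes = len(next(iter(groups.values())))
    cols = {}
    for grp, vals in groups.items():
        for r in range(vals.shape[1]):
            cols[f"{grp}_r{r + 1}"] = vals[:, r]
    frame = pd.DataFrame(cols, index=[f"G{i}" for i in range(n_genes)])
    frame = frame[[s for s in design.sample_id]]
    return (
        ExpressionMatrix(frame, pd.Series(False, index=frame.index)),
        design,
    )


class TestFitGeneModels:
    def test_hand_computed_pooled_variance(self):
        reps = np.array([[1.0, 2.0, 3.0]])
        m, design = matrix_from_groups({g: reps for g in ("p0", "p6", "np0", "np6")})
        fits = fit_gene_models(m, design)
        row = fits.iloc[0]
        assert row.s2 == pytest.approx(1.0, abs=1e-12)  # var{1,2,3} = 1 pooled
        assert row.df == 8
        for g in ("p0", "p6", "np0", "np6"):
            assert row[g] == pytest.approx(2.0)

    def test_noise_free_gene_has_zero_variance_and_planted_means(self, noise_free_dataset):
        matrix, design, truth = noise_free_dataset
        fits = fit_gene_models(matrix, design)
        assert fits.s2.max() == pytest.approx(0.0, abs=1e-20)
        m = (fits.p6 - fits.np6) - (fits.p0 - fits.np0)
        np.testing.assert_allclose(
            m.to_numpy(), truth.set_index("gene_id").loc[fits.index, "true_M"],
            atol=1e-12,
        )

    def test_sample_column_order_irrelevant(self, noisy_dataset):
        matrix, design, _ = noisy_dataset
        shuffled = ExpressionMatrix(
            matrix.values[list(reversed(matrix.values.columns))], matrix.is_spike
        )
        pd.testing.assert_frame_equal(
            fit_gene_models(matrix, design), fit_gene_models(shuffled, design)
        )

    def test_missing_group_is_an_error(self, noisy_dataset):
        matrix, design, _ = noisy_dataset
        broken = design[design.fraction != "polysomal"]
        with pytest.raises(ValueError, match="p0"):
            fit_gene_models(matrix, broken)


class TestModeration:
    def test_parameter_recovery(self, rng):
        d0, s0_2, d, n = 4.0, 0.05, 8, 5000
        sigma2 = s0_2 * d0 / rng.chisquare(d0, n)
        s2 = sigma2 * rng.chisquare(d, n) / d
        mod = estimate_moderation(pd.DataFrame({"s2": s2, "df": d}))
        assert mod.d0 == pytest.approx(d0, rel=0.25)
        assert mod.s0_2 == pytest.approx(s0_2, rel=0.10)

    def test_identical_variances_take_infinite_d0_branch(self):
        fits = pd.DataFrame({"s2": np.full(100, 0.3), "df": 8})
        mod = estimate_moderation(fits)
        assert math.isinf(mod.d0)
        assert mod.s0_2 > 0

    def test_gene_order_invariance(self, rng):
        s2 = rng.chisquare(8, 500) / 8
        fits = pd.DataFrame({"s2": s2, "df": 8})
        shuffled = fits.sample(frac=1.0, random_state=0)
        a = estimate_moderation(fits)
        b = estimate_moderation(shuffled)
        assert a.d0 == pytest.approx(b.d0, rel=1e-12)
        assert a.s0_2 == pytest.approx(b.s0_2, rel=1e-12)

    def test_all_zero_variances_error(self):
        with pytest.raises(ValueError):
            estimate_moderation(pd.DataFrame({"s2": [0.0, 0.0], "df": 8}))


def ordinary_contrast_t(groups: dict[str, np.ndarray]) -> np.ndarray:
    """Brute-force per-gene contrast t from raw replicate values."""
    means = {g: v.mean(axis=1) for g, v in groups.items()}
    m = (means["p6"] - means["np6"]) - (means["p0"] - means["np0"])
    ss = sum(((v - means[g][:, None]) ** 2).sum(axis=1) for g, v in groups.items())
    n_total = sum(v.shape[1] for v in groups.values())
    s2 = ss / (n_total - 4)
    inv_n = sum(1.0 / v.shape[1] for v in groups.values())
    return m / np.sqrt(s2 * inv_n)


class TestShiftContrast:
    def test_m_is_double_difference(self):
        groups = {
            "p6": np.full((1, 3), 10.0),
            "np6": np.full((1, 3), 8.0),
            "p0": np.full((1, 3), 7.0),
            "np0": np.full((1, 3), 7.0),
        }
        m, design = matrix_from_groups(groups)
        fits = fit_gene_models(m, design)
        res = shift_contrast(fits, ModerationParams(d0=1.0, s0_2=0.1))
        assert res.M.iloc[0] == pytest.approx(2.0, abs=1e-12)

    def test_no_moderation_limit_equals_ordinary_t(self, rng):
        groups = {g: rng.normal(8, 1, (50, 3)) for g in ("p0", "p6", "np0", "np6")}
        m, design = matrix_from_groups(groups)
        fits = fit_gene_models(m, design)
        res = shift_contrast(fits, ModerationParams(d0=0.0, s0_2=1.0))
        np.testing.assert_allclose(
            res.t.to_numpy(), ordinary_contrast_t(groups), atol=1e-12, rtol=1e-12
        )
        # and the p-values are the ordinary two-sided Student tail with d df
        expect_p = 2 * stats.t.sf(np.abs(ordinary_contrast_t(groups)), 8)
        np.testing.assert_allclose(res.p.to_numpy(), expect_p, atol=1e-12)

    def test_infinite_d0_limit_is_closed_form_z(self, rng):
        groups = {g: rng.normal(8, 1, (50, 3)) for g in ("p0", "p6", "np0", "np6")}
        m, design = matrix_from_groups(groups)
        fits = fit_gene_models(m, design)
        s0_2 = 0.8
        res = shift_contrast(fits, ModerationParams(d0=math.inf, s0_2=s0_2))
        m_vals = ((fits.p6 - fits.np6) - (fits.p0 - fits.np0)).to_numpy()
        z = m_vals / np.sqrt(s0_2 * (4.0 / 3.0))
        np.testing.assert_allclose(res.t.to_numpy(), z, atol=1e-10)
        np.testing.assert_allclose(
            res.p.to_numpy(), 2 * stats.norm.sf(np.abs(z)), atol=1e-12
        )

    def test_zero_shift_gives_p_one(self):
        groups = {g: np.tile([[7.0, 8.0, 9.0]], (1, 1)) for g in
                  ("p0", "p6", "np0", "np6")}
        m, design = matrix_from_groups(groups)
        fits = fit_gene_models(m, design)
        res = shift_contrast(fits, ModerationParams(d0=4.0, s0_2=0.05))
        assert res.t.iloc[0] == 0.0
        assert res.p.iloc[0] == 1.0

    def test_degenerate_zero_se(self, noise_free_dataset):
        matrix, design, truth = noise_free_dataset
        fits = fit_gene_models(matrix, design)
        with pytest.warns(UserWarning, match="zero SE"):
            res = shift_contrast(fits, ModerationParams(d0=0.0, s0_2=1.0))
        shifted = truth.set_index("gene_id").true_M != 0
        assert (res.p[shifted.loc[res.index]] == 0).all()
        assert (res.p[~shifted.loc[res.index]] == 1).all()

    def test_time_swap_negates_m_keeps_p(self, noisy_dataset):
        matrix, design, _ = noisy_dataset
        swapped = design.copy()
        swapped["time"] = swapped["time"].map({"t0": "t6", "t6": "t0"})
        mod = ModerationParams(d0=4.0, s0_2=0.05)
        a = shift_contrast(fit_gene_models(matrix, design), mod)
        b = shift_contrast(fit_gene_models(matrix, swapped), mod)
        np.testing.assert_allclose(a.M.to_numpy(), -b.M.to_numpy(), atol=1e-12)
        np.testing.assert_allclose(a.p.to_numpy(), b.p.to_numpy(), atol=1e-12)

    def test_null_p_values_are_uniform(self):
        cfg = SimConfig(seed=31, n_genes=2000, frac_up=0, frac_down=0,
                        frac_equal=0, frac_mrna_artifact=0,
                        sigma_fraction_assoc=0.0, sigma_time_effect=0.0)
        matrix, design, _ = generate_expression_dataset(cfg)
        res, _ = shift_results(spike_normalize(matrix), design)
        ks = stats.kstest(res.p.to_numpy(), "uniform").statistic
        assert ks < 0.05


def brute_force_bh(p: np.ndarray) -> np.ndarray:
    """O(m^2) step-up definition: adj_i = min over p_j >= p_i of m*p_j/rank_j."""
    m = len(p)
    ranks = np.array([(p <= pj).sum() for pj in p])
    adj = np.empty(m)
    for i in range(m):
        candidates = [m * p[j] / ranks[j] for j in range(m) if p[j] >= p[i]]
        adj[i] = min(1.0, min(candidates))
    return adj


class TestBenjaminiHochberg:
    def test_hand_example(self):
        np.testing.assert_allclose(
            adjust_bh([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03], atol=1e-12
        )

    def test_single_p_unchanged(self):
        assert adjust_bh([0.2])[0] == pytest.approx(0.2)

    def test_matches_brute_force_on_random_vectors(self, rng):
        for _ in range(200):
            m = int(rng.integers(1, 40))
            p = rng.uniform(0, 1, m)
            if rng.random() < 0.3:  # exercise ties
                p = np.round(p, 1)
            np.testing.assert_allclose(adjust_bh(p), brute_force_bh(p), atol=1e-12)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            adjust_bh([0.5, 1.2])
        with pytest.raises(ValueError):
            adjust_bh([-0.1])


class TestTost:
    def make_fits(self, m_values, s2, n=3, df=8):
        k = len(m_values)
        return pd.DataFrame(
            {
                "p0": 0.0, "np0": 0.0, "np6": 0.0, "p6": np.asarray(m_values),
                "n_p0": n, "n_p6": n, "n_np0": n, "n_np6": n,
                "s2": s2, "df": df,
            }
        )

    def test_zero_m_zero_se_limit_declares_equivalence(self, noise_free_dataset):
        matrix, design, truth = noise_free_dataset
        fits = fit_gene_models(matrix, design)
        p = tost_equivalence(fits, ModerationParams(d0=0.0, s0_2=1.0), 0.2)
        null = (truth.set_index("gene_id").true_M == 0).loc[fits.index]
        assert (p[null.to_numpy()] == 0).all()
        assert (p[~null.to_numpy()] == 1).all()

    def test_m_at_margin_gives_p_at_least_half(self):
        fits = self.make_fits([0.2, -0.2], s2=0.05)
        p = tost_equivalence(fits, ModerationParams(d0=4.0, s0_2=0.05), 0.2)
        assert (p >= 0.5).all()

    def test_type_one_error_controlled_at_margin(self, rng):
        """Genes whose true shift sits exactly on the margin must be
        declared equivalent at most ~alpha of the time."""
        eps, n_genes, d = 0.2, 5000, 8
        se_true = 0.08
        s2_true = se_true**2 / (4.0 / 3.0)
        m_hat = eps + rng.normal(0, se_true, n_genes)
        s2 = s2_true * rng.chisquare(d, n_genes) / d
        fits = self.make_fits(m_hat, s2=s2, df=d)
        mod = estimate_moderation(fits)
        p = tost_equivalence(fits, mod, eps)
        declared = (p < 0.05).sum()
        # binomial 99% upper band around alpha = 0.05
        bound = 0.05 * n_genes + 2.576 * math.sqrt(n_genes * 0.05 * 0.95)
        assert declared <= bound


class TestTotalTranslation:
    def test_polysomal_excess_is_significant(self, rng):
        cfg = noise_free_config(seed=8)
        matrix, design, _ = generate_expression_dataset(cfg)
        shifted = matrix.copy()
        poly = design.loc[design.fraction == "polysomal", "sample_id"]
        shifted.values[list(poly)] += 1.0
        jitter = rng.normal(0, 1e-6, shifted.values.shape)
        shifted.values.iloc[:, :] = shifted.values.to_numpy() + jitter
        res = total_translation_activity(shifted, design)
        assert (res.p < 1e-6).all()

    def test_identical_groups_give_half(self):
        # polysomal replicate r duplicates free replicate r exactly, with
        # real between-replicate variation: t = 0, so one-sided p = 0.5
        groups = {
            "p0": np.array([[7.0, 8.0, 9.5]]),
            "np0": np.array([[7.0, 8.0, 9.5]]),
            "p6": np.array([[6.0, 8.5, 9.0]]),
            "np6": np.array([[6.0, 8.5, 9.0]]),
        }
        m, design = matrix_from_groups(groups)
        res = total_translation_activity(m, design)
        assert res.p.to_numpy() == pytest.approx([0.5, 0.5], abs=1e-12)

    def test_matches_welch_oracle(self, noisy_dataset):
        matrix, design, _ = noisy_dataset
        res = total_translation_activity(matrix, design)
        genes = matrix.genes()
        for time in ("t0", "t6"):
            sub = design[design.time == time]
            a = genes[list(sub.loc[sub.fraction == "polysomal", "sample_id"])].mean().to_numpy()
            b = genes[list(sub.loc[sub.fraction == "non_polysomal", "sample_id"])].mean().to_numpy()
            na, nb = len(a), len(b)
            va, vb = a.var(ddof=1), b.var(ddof=1)
            t = (a.mean() - b.mean()) / math.sqrt(va / na + vb / nb)
            df = (va / na + vb / nb) ** 2 / (
                (va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1)
            )
            p = stats.t.sf(t, df)
            assert res.loc[time, "statistic"] == pytest.approx(t, abs=1e-10)
            assert res.loc[time, "p"] == pytest.approx(p, abs=1e-10)

    def test_single_replicate_errors(self, noisy_dataset):
        matrix, design, _ = noisy_dataset
        broken = design[design.sample_id != "p0_r1"]
        broken = broken[broken.sample_id != "p0_r2"]
        with pytest.raises(ValueError):
            total_translation_activity(matrix, broken)
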