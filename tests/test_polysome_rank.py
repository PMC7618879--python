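"""Paired-fraction NB model: filtering, fitting, contrasts, shrinkage, metrics."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy import stats

from translate_rank import synthdata
from translate_rank.polysome_rank import (POLYSOMAL, SUBPOLYSOMAL,
                                          adaptive_shrink,
                                          contrast_translation,
                                          filter_low_expression, fit_paired_nb,
                                          ranked_list, ranking_metric,
                                          size_factors)

from conftest import make_count_matrix


# ---------------------------------------------------------------------------
# expression filtering


class TestFilterLowExpression:
    def _cm_with_gene(self, per_group_counts):
        """4 conditions x 4 reps x 2 fractions, single gene, explicit counts
        per (condition, fraction, replicate)."""
        conds = ["A", "B", "C", "D"]
        cols, vals, meta = [], [], []
        for cond in conds:
            for rep in range(1, 5):
                for frac in (SUBPOLYSOMAL, POLYSOMAL):
                    cols.append(f"{cond}_r{rep}_{frac}")
                    vals.append(per_group_counts.get((cond, frac), [5] * 4)[rep - 1])
                    meta.append((cond, rep, frac))
        from translate_rank.polysome_rank import CountMatrix
        counts = pd.DataFrame([vals], index=["g0"], columns=cols)
        samples = pd.DataFrame(meta, index=cols,
                               columns=["condition", "replicate", "fraction"])
        return CountMatrix(counts=counts, samples=samples)

    def test_three_of_four_zeros_in_one_group_drops_gene(self):
        cm = self._cm_with_gene({("A", POLYSOMAL): [0, 0, 0, 7]})
        out = filter_low_expression(cm, mode="polysome")
        assert len(out.counts) == 0

    def test_two_zeros_per_group_kept(self):
        cm = self._cm_with_gene({(c, f): [0, 0, 3, 3]
                                 for c in "ABCD"
                                 for f in (SUBPOLYSOMAL, POLYSOMAL)})
        out = filter_low_expression(cm, mode="polysome")
        assert list(out.counts.index) == ["g0"]

    def test_all_positive_matrix_unchanged(self):
        cm = make_count_matrix({(c, f): [3, 8, 1]
                                for c in ("A", "B")
                                for f in (SUBPOLYSOMAL, POLYSOMAL)})
        out = filter_low_expression(cm, mode="polysome")
        pd.testing.assert_frame_equal(out.counts, cm.counts)

    def test_total_mode_pools_fractions_and_uses_half_threshold(self):
        # zero in 2 of 4 replicates of one condition (pooled fractions)
        cm = self._cm_with_gene({("A", POLYSOMAL): [0, 0, 5, 5],
                                 ("A", SUBPOLYSOMAL): [0, 0, 5, 5]})
        assert len(filter_low_expression(cm, mode="total").counts) == 0
        # zero in only 1 of 4 pooled replicates: kept
        cm2 = self._cm_with_gene({("A", POLYSOMAL): [0, 5, 5, 5],
                                  ("A", SUBPOLYSOMAL): [0, 5, 5, 5]})
        assert len(filter_low_expression(cm2, mode="total").counts) == 1

    def test_idempotent(self):
        cm, _ = synthdata.gen_polysome_counts(300, n_replicates=4,
                                              dispersion=0.3, seed=5,
                                              baseline_logmean=1.0)
        once = filter_low_expression(cm, mode="polysome")
        twice = filter_low_expression(once, mode="polysome")
        pd.testing.assert_frame_equal(once.counts, twice.counts)


# ---------------------------------------------------------------------------
# NB fitting


class TestFitPairedNB:
    def test_saturated_balanced_case_exact(self, unit_size_factors):
        cm = make_count_matrix({("A", SUBPOLYSOMAL): [100],
                                ("A", POLYSOMAL): [200]})
        eff = fit_paired_nb(cm, dispersion=1e-8,
                            sample_size_factors=unit_size_factors(cm))
        assert eff.log2fc.loc["g0", "A"] == pytest.approx(1.0, abs=1e-6)

    def test_equal_fractions_give_zero_coefficient(self, unit_size_factors):
        cm = make_count_matrix({("A", SUBPOLYSOMAL): [150],
                                ("A", POLYSOMAL): [150]})
        eff = fit_paired_nb(cm, dispersion=1e-8,
                            sample_size_factors=unit_size_factors(cm))
        assert eff.log2fc.loc["g0", "A"] == pytest.approx(0.0, abs=1e-6)

    def test_poisson_limit_noise_free_closed_form(self, unit_size_factors):
        # balanced noise-free data reproduce the closed-form log ratios
        sub = np.array([50, 120, 400])
        poly = np.array([100, 90, 1600])
        cm = make_count_matrix({("A", SUBPOLYSOMAL): sub,
                                ("A", POLYSOMAL): poly})
        eff = fit_paired_nb(cm, dispersion=1e-8,
                            sample_size_factors=unit_size_factors(cm))
        expected = np.log2(poly / sub)
        assert np.allclose(eff.log2fc["A"].to_numpy(), expected, atol=1e-6)

    def test_matches_statsmodels_glm_per_gene(self, unit_size_factors):
        """Batched IRLS agrees with an independent per-gene GLM fit."""
        cm, _ = synthdata.gen_polysome_counts(
            6, conditions=["A"], n_replicates=4, dispersion=0.1, seed=3)
        alpha = 0.1
        eff = fit_paired_nb(cm, dispersion=alpha,
                            sample_size_factors=unit_size_factors(cm))
        sub = cm.samples
        reps = sorted(sub["replicate"].unique())
        X = np.column_stack(
            [np.ones(len(sub))]
            + [(sub["replicate"] == r).to_numpy(float) for r in reps[1:]]
            + [(sub["fraction"] == POLYSOMAL).to_numpy(float)])
        for g in range(6):
            y = cm.counts.iloc[g].to_numpy(float)
            fit = sm.GLM(y, X,
                         family=sm.families.NegativeBinomial(alpha=alpha)).fit()
            assert eff.log2fc.iloc[g, 0] == pytest.approx(
                fit.params[-1] / np.log(2), abs=1e-4)
            assert eff.se.iloc[g, 0] == pytest.approx(
                fit.bse[-1] / np.log(2), rel=1e-3)

    def test_all_zero_gene_rejected(self):
        cm = make_count_matrix({("A", SUBPOLYSOMAL): [0, 5],
                                ("A", POLYSOMAL): [0, 5]})
        with pytest.raises(ValueError, match="all-zero"):
            fit_paired_nb(cm, dispersion=0.1)

    def test_size_factors_median_of_ratios(self):
        rng = np.random.default_rng(0)
        base = rng.integers(50, 500, size=(100, 1)).astype(float)
        sf_true = np.array([0.5, 1.0, 2.0, 1.5])
        counts = pd.DataFrame(np.rint(base * sf_true),
                              columns=list("abcd")).astype(int)
        sf = size_factors(counts)
        assert np.allclose(sf / stats.gmean(sf),
                           sf_true / stats.gmean(sf_true), rtol=0.02)


class TestContrast:
    def test_identical_conditions_zero_delta_p_one(self, unit_size_factors):
        cm = make_count_matrix({("A", SUBPOLYSOMAL): [100],
                                ("A", POLYSOMAL): [200],
                                ("B", SUBPOLYSOMAL): [100],
                                ("B", POLYSOMAL): [200]})
        eff = fit_paired_nb(cm, dispersion=1e-8,
                            sample_size_factors=unit_size_factors(cm))
        eff = contrast_translation(eff, "A", "B")
        tab = eff.contrasts["A_vs_B"]
        assert tab["delta_log2fc"].iloc[0] == pytest.approx(0.0, abs=1e-6)
        assert tab["pvalue"].iloc[0] == pytest.approx(1.0, abs=1e-4)

    def test_contrast_arithmetic(self):
        from translate_rank.polysome_rank import EffectTable
        idx = pd.Index(["g0"])
        eff = EffectTable(
            log2fc=pd.DataFrame({"A": [2.0], "B": [0.5]}, index=idx),
            se=pd.DataFrame({"A": [0.5], "B": [0.5]}, index=idx),
            dispersion=pd.Series(0.1, index=idx),
            converged=pd.Series(True, index=idx))
        eff = contrast_translation(eff, "A", "B")
        tab = eff.contrasts["A_vs_B"]
        assert tab["delta_log2fc"].iloc[0] == pytest.approx(1.5)
        assert tab["se"].iloc[0] == pytest.approx(np.sqrt(0.5), abs=1e-6)
        z = 1.5 / np.sqrt(0.5)
        assert tab["pvalue"].iloc[0] == pytest.approx(2 * stats.norm.sf(z))

    def test_unknown_condition_rejected(self, unit_size_factors):
        cm = make_count_matrix({("A", SUBPOLYSOMAL): [100],
                                ("A", POLYSOMAL): [200]})
        eff = fit_paired_nb(cm, dispersion=1e-8,
                            sample_size_factors=unit_size_factors(cm))
        with pytest.raises(KeyError):
            contrast_translation(eff, "A", "nope")

    def test_sign_agreement_with_truth_for_large_effects(self):
        eff_mat, delta = synthdata.study_fraction_effects(800, seed=7)
        cm, _ = synthdata.gen_polysome_counts(800, n_replicates=4,
                                              dispersion=0.1, seed=7,
                                              fraction_log2fc=eff_mat)
        cmf = filter_low_expression(cm)
        eff = fit_paired_nb(cmf)
        eff = contrast_translation(eff, "ASP-shSCR", "ASP-shGRIN2D")
        tab = eff.contrasts["ASP-shSCR_vs_ASP-shGRIN2D"]
        d = delta.loc[tab.index]
        big = d.abs() >= 1.0
        agree = (np.sign(tab["delta_log2fc"][big]) == np.sign(d[big])).mean()
        assert agree >= 0.95


# ---------------------------------------------------------------------------
# adaptive shrinkage


def _dense_grid_posterior_mean(x, s, pi, sigma):
    """Numerical posterior mean under the fitted mixture prior: point mass
    handled analytically, normal components integrated on a dense grid."""
    mu = np.linspace(-5 * (abs(x) + 5 * s), 5 * (abs(x) + 5 * s), 200001)
    prior = np.zeros_like(mu)
    for w, sig in zip(pi[1:], sigma[1:]):
        prior += w * stats.norm.pdf(mu, 0, sig)
    like = stats.norm.pdf(x, mu, s)
    num = np.trapezoid(mu * prior * like, mu)
    den = np.trapezoid(prior * like, mu) + pi[0] * stats.norm.pdf(x, 0, s)
    return num / den


class TestAdaptiveShrink:
    def test_all_zero_values_stay_zero(self):
        out = adaptive_shrink(np.zeros(10), np.ones(10))
        assert np.allclose(out, 0.0)

    def test_strong_signal_survives(self):
        rng = np.random.default_rng(0)
        vals = np.concatenate([[10.0], rng.normal(0, 0.3, 1000)])
        ses = np.concatenate([[0.1], np.full(1000, 0.3)])
        out = adaptive_shrink(vals, ses)
        assert abs(out[0] - 10.0) / 10.0 < 0.05

    def test_matches_dense_grid_posterior_oracle(self):
        rng = np.random.default_rng(1)
        vals = np.concatenate([rng.normal(0, 0.2, 15), [3.0, -2.5, 1.0,
                                                        0.4, -0.1]])
        ses = np.full(20, 0.5)
        out, pi = adaptive_shrink(vals, ses, return_weights=True)
        from translate_rank.polysome_rank import _shrink_grid
        sigma = np.concatenate([[0.0], _shrink_grid(vals, ses)])
        for j in range(20):
            oracle = _dense_grid_posterior_mean(vals[j], ses[j], pi, sigma)
            assert out[j] == pytest.approx(oracle, abs=1e-4)

    def test_sparse_truth_rmse_improves(self):
        rng = np.random.default_rng(2)
        truth = np.where(rng.random(2000) < 0.1,
                         rng.choice([1.5, -1.5], 2000), 0.0)
        se = np.full(2000, 0.5)
        obs = truth + rng.normal(0, 0.5, 2000)
        shr = adaptive_shrink(obs, se)
        assert np.sqrt(((shr - truth) ** 2).mean()) \
            < np.sqrt(((obs - truth) ** 2).mean())

    def test_never_expands_and_preserves_order_at_equal_se(self):
        rng = np.random.default_rng(3)
        vals = rng.normal(0, 1, 500)
        ses = np.full(500, 0.4)
        out = adaptive_shrink(vals, ses)
        assert np.all(np.abs(out) <= np.abs(vals) + 1e-9)
        assert np.abs(out).mean() <= np.abs(vals).mean()
        order_in = np.argsort(np.abs(vals))
        assert np.all(np.diff(np.abs(out)[order_in]) >= -1e-9)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            adaptive_shrink(np.array([]), np.array([]))


# ---------------------------------------------------------------------------
# ranking metric


class TestRankingMetric:
    @pytest.mark.parametrize("log2fc,p,weight,expected", [
        (2.0, 0.01, 1.0, 4.0),
        (-1.0, 0.1, 0.5, -0.5),
        (3.0, 1.0, 1.0, 0.0),
        (0.0, 1e-10, 1.0, 0.0),
        (1.0, 0.001, 1.0, 3.0),
    ])
    def test_formula(self, log2fc, p, weight, expected):
        assert ranking_metric(log2fc, p, weight) == pytest.approx(expected,
                                                                  abs=1e-12)

    def test_antisymmetric_in_sign(self):
        rng = np.random.default_rng(0)
        fc = rng.normal(size=50)
        p = rng.uniform(1e-6, 1, 50)
        assert np.allclose(ranking_metric(fc, p), -ranking_metric(-fc, p))

    def test_monotone_decreasing_in_p(self):
        ps = np.logspace(-8, 0, 40)
        vals = ranking_metric(np.full(40, 2.0), ps)
        assert np.all(np.diff(vals) <= 0)

    def test_zero_p_floored_with_warning(self):
        with pytest.warns(RuntimeWarning, match="floored"):
            v = ranking_metric(1.0, 0.0)
        assert np.isfinite(v) and v == pytest.approx(300.0)

    def test_ranked_list_tie_order_deterministic(self):
        s = ranked_list(["b", "a", "c"], [1.0, 1.0, 2.0])
        assert list(s.index) == ["c", "a", "b"]
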