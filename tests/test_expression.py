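import numpy as np
import pytest

from boolgba import (
    ExpressionMatrix,
    call_differential_expression,
    condition_specificity,
    drop_constant_genes,
    fit_two_component_mixture,
    normalize_expression,
    simulate_expression,
)

from conftest import norm_from_means


class TestNormalization:
    def test_identical_samples_give_equal_effects_and_zero_residuals(self):
        col = np.array([1.0, 5.0, 9.0])
        expr = ExpressionMatrix(
            gene_ids=["a", "b", "c"],
            sample_ids=["s1", "s2", "s3", "s4"],
            values=np.tile(col[:, None], (1, 4)),
            condition_of={"s1": "A", "s2": "A", "s3": "B", "s4": "B"},
        )
        res = normalize_expression(expr)
        effects = list(res.hybridization_effects.values())
        assert np.allclose(effects, effects[0])
        assert np.allclose(res.residuals, 0.0)

    def test_constant_sample_offset_is_recovered_exactly(self):
        # s2 = s1 + 2.0 everywhere: hybridization effects differ by exactly 2
        rng = np.random.default_rng(0)
        base = rng.normal(8, 1, size=(3, 1))
        values = np.hstack([base, base + 2.0, base + 0.5, base - 1.0])
        expr = ExpressionMatrix(
            gene_ids=["a", "b", "c"],
            sample_ids=["s1", "s2", "s3", "s4"],
            values=values,
            condition_of={"s1": "A", "s2": "A", "s3": "B", "s4": "B"},
        )
        res = normalize_expression(expr)
        h = res.hybridization_effects
        assert h["s2"] - h["s1"] == pytest.approx(2.0, abs=1e-12)

    def test_reconstruction_identity_and_residual_cell_means(self, toy_expression):
        res = normalize_expression(toy_expression)
        expr = toy_expression
        cond_idx = {c: k for k, c in enumerate(res.conditions)}
        for i, g in enumerate(expr.gene_ids):
            for j, s in enumerate(expr.sample_ids):
                k = cond_idx[expr.condition_of[s]]
                recon = (
                    res.hybridization_effects[s]
                    + res.gene_condition_means[i, k]
                    + res.residuals[i, j]
                )
                assert recon == pytest.approx(expr.values[i, j], abs=1e-9)
        # residuals mean to zero within every gene x condition cell
        for c in res.conditions:
            cols = expr.samples_in(c)
            assert np.allclose(res.residuals[:, cols].mean(axis=1), 0.0, atol=1e-9)

    def test_recovers_planted_condition_means(self, default_synthetic):
        expr, _ = default_synthetic
        res = normalize_expression(expr)
        # generator truth: reconstruct planted means from a noise-free rerun
        truth_expr, _ = simulate_expression(noise_sd=1e-9, hyb_sd=1e-9, seed=0)
        truth_norm = normalize_expression(truth_expr)
        r = np.corrcoef(
            res.gene_condition_means.ravel(),
            truth_norm.gene_condition_means.ravel(),
        )[0, 1]
        assert r > 0.99

    def test_non_finite_value_names_the_cell(self):
        values = np.ones((2, 2))
        values[1, 0] = np.nan
        with pytest.raises(ValueError, match="g2.*s1|non-finite"):
            ExpressionMatrix(
                gene_ids=["g1", "g2"],
                sample_ids=["s1", "s2"],
                values=values,
                condition_of={"s1": "A", "s2": "B"},
            )

    def test_drop_constant_genes(self, toy_expression):
        expr = toy_expression
        values = expr.values.copy()
        values[1, :] = 3.0
        flat = ExpressionMatrix(expr.gene_ids, expr.sample_ids, values, expr.condition_of)
        with pytest.warns(UserWarning, match="constant"):
            out = drop_constant_genes(flat)
        assert out.gene_ids == ["g1", "g3"]


class TestMixture:
    def test_recovers_planted_two_component_mixture(self):
        rng = np.random.default_rng(1)
        x = np.concatenate([rng.normal(0, 1, 950), rng.normal(4, 1, 50)])
        fit = fit_two_component_mixture(x, seed=0)
        assert fit.weight_null == pytest.approx(0.95, abs=0.03)
        assert fit.mean_alt == pytest.approx(4.0, abs=0.5)
        assert fit.converged

    def test_null_data_yields_no_confident_posteriors(self):
        x = np.random.default_rng(5).normal(0, 1, 1000)
        fit = fit_two_component_mixture(x)
        assert fit.posteriors.max() < 0.95

    def test_sign_flip_negates_means_keeps_posteriors(self):
        rng = np.random.default_rng(2)
        x = np.concatenate([rng.normal(0, 1, 200), rng.normal(3, 1, 40)])
        f1 = fit_two_component_mixture(x)
        f2 = fit_two_component_mixture(-x)
        assert f2.mean_null == pytest.approx(-f1.mean_null, abs=1e-6)
        assert f2.mean_alt == pytest.approx(-f1.mean_alt, abs=1e-6)
        assert np.allclose(f1.posteriors, f2.posteriors, atol=1e-8)

    def test_permutation_invariance_of_fit(self):
        rng = np.random.default_rng(3)
        x = np.concatenate([rng.normal(0, 1, 100), rng.normal(4, 1, 20)])
        f1 = fit_two_component_mixture(x)
        f2 = fit_two_component_mixture(rng.permutation(x))
        assert f1.mean_alt == pytest.approx(f2.mean_alt, abs=1e-6)
        assert f1.weight_null == pytest.approx(f2.weight_null, abs=1e-8)

    def test_degenerate_inputs_raise(self):
        with pytest.raises(ValueError, match="zero-variance|identical"):
            fit_two_component_mixture(np.full(50, 2.0))
        with pytest.raises(ValueError, match="at least 10"):
            fit_two_component_mixture(np.arange(5.0))


class TestDifferentialExpression:
    def test_null_contrast_flags_nothing(self):
        norm = norm_from_means(np.tile([[5.0, 5.0, 5.0, 5.0]], (20, 1)))
        de = call_differential_expression(norm, ("Carcinoma", "Normal"))
        assert de.de_flag.sum() == 0

    def test_planted_de_recovery_sensitivity_and_fdr(self):
        expr, truth = simulate_expression(n_genes=1000, n_de=50, n_cs=0, seed=11)
        norm = normalize_expression(expr)
        de = call_differential_expression(norm, ("Carcinoma", "Normal"), 0.01, seed=0)
        planted = truth.de_genes["Carcinoma"]
        flagged = de.de_genes()
        sensitivity = len(flagged & planted) / len(planted)
        realized_fdr = len(flagged - planted) / max(len(flagged), 1)
        assert sensitivity >= 0.90
        assert realized_fdr <= 2 * 0.01

    def test_contrast_antisymmetry(self, default_synthetic):
        expr, _ = default_synthetic
        norm = normalize_expression(expr)
        ab = call_differential_expression(norm, ("Carcinoma", "Normal"), seed=0)
        ba = call_differential_expression(norm, ("Normal", "Carcinoma"), seed=0)
        assert np.allclose(ab.difference, -ba.difference)
        assert ab.de_genes() == ba.de_genes()

    def test_flag_set_shrinks_with_stricter_fdr(self, default_synthetic):
        expr, _ = default_synthetic
        norm = normalize_expression(expr)
        flags = [
            call_differential_expression(norm, ("Carcinoma", "Normal"), f, seed=0).de_genes()
            for f in (0.10, 0.05, 0.01, 0.001)
        ]
        for looser, stricter in zip(flags, flags[1:]):
            assert stricter <= looser

    def test_unknown_condition_raises(self, default_synthetic):
        expr, _ = default_synthetic
        norm = normalize_expression(expr)
        with pytest.raises(KeyError, match="Tumor"):
            call_differential_expression(norm, ("Tumor", "Normal"))


class TestConditionSpecificity:
    def test_uniform_gene_has_flat_cs_and_no_flag(self):
        norm = norm_from_means([[5.0, 5, 5, 5], [6.0, 6, 6, 6], [4.0, 4, 4, 4]])
        cs = condition_specificity(norm)
        assert np.allclose(cs.cs[0], 0.25)
        assert not cs.cs_flag.any()

    def test_cs_value_matches_direct_ratio(self):
        norm = norm_from_means([[8.0, 1, 1, 1]] + [[2.0, 2, 2, 2]] * 10)
        cs = condition_specificity(norm)
        assert cs.cs[0, 0] == pytest.approx(8 / 11)

    def test_rows_sum_to_one_for_positive_totals(self, default_synthetic):
        expr, _ = default_synthetic
        cs = condition_specificity(normalize_expression(expr))
        sums = np.nansum(cs.cs[~cs.excluded], axis=1)
        assert np.allclose(sums, 1.0, atol=1e-9)

    def test_planted_cs_genes_recovered_exactly(self):
        expr, truth = simulate_expression(n_genes=500, n_de=0, n_cs=5, cs_fold=10.0, seed=7)
        cs = condition_specificity(normalize_expression(expr))
        for c in cs.conditions:
            assert cs.specific_genes(c) == truth.cs_genes[c]

    def test_zero_total_gene_excluded_never_flagged(self):
        norm = norm_from_means([[0.0, 0, 0, 0], [1.0, 2, 3, 4], [4.0, 3, 2, 1]])
        cs = condition_specificity(norm)
        assert cs.excluded[0]
        assert np.isnan(cs.cs[0]).all()
        assert not cs.cs_flag[0].any()

    def test_negative_means_are_shifted_before_ratio(self):
        norm = norm_from_means([[-2.0, 0, 1, 1], [1.0, 1, 1, 1]])
        cs = condition_specificity(norm)
        assert cs.shift == pytest.approx(2.0)
        assert np.allclose(np.nansum(cs.cs, axis=1), 1.0)
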