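import numpy as np
import pytest
import statsmodels.api as sm
from hypothesis import given, settings
from hypothesis import strategies as st

from hidmed import (GenotypeMatrix, estimate_direct_effects,
                    estimate_mediator_effects, filter_outlier_snps,
                    orient_snps, run_step1, simulate_dataset, study_config)
from hidmed.exceptions import RankDeficiencyError


def _random_genotypes(rng, n, p):
    dos = rng.binomial(2, rng.uniform(0.1, 0.5, p), size=(n, p)).astype(np.int8)
    return GenotypeMatrix(dos, [f"snp{j}" for j in range(p)])


class TestOlsAgainstStatsmodels:
    @pytest.mark.parametrize("n,p", [(200, 5), (500, 20)])
    def test_mediator_effects_match_reference_ols(self, rng, n, p):
        G = _random_genotypes(rng, n, p)
        m = rng.normal(size=n) + G.dosages @ rng.normal(0.1, 0.05, p)
        cov = rng.normal(size=(n, 2))
        vec = estimate_mediator_effects(G, m, covariates=cov)
        X = sm.add_constant(np.column_stack(
            [G.dosages.astype(float), cov]))
        ref = sm.OLS(m, X).fit()
        np.testing.assert_allclose(vec.values, ref.params[1:1 + p], rtol=1e-8)
        np.testing.assert_allclose(vec.standard_errors, ref.bse[1:1 + p],
                                   rtol=1e-8)

    def test_direct_effects_match_reference_ols(self, rng):
        n, p, K = 300, 8, 3
        G = _random_genotypes(rng, n, p)
        M = rng.normal(size=(n, K))
        cov = rng.normal(size=(n, 2))
        y = rng.normal(size=n) + M @ [0.4, 0.2, 0.3]
        c_star, med_coef, cov_coef = estimate_direct_effects(G, M, cov, y)
        X = sm.add_constant(np.column_stack([G.dosages.astype(float), M, cov]))
        ref = sm.OLS(y, X).fit()
        np.testing.assert_allclose(c_star.values, ref.params[1:1 + p],
                                   rtol=1e-8)
        np.testing.assert_allclose(med_coef, ref.params[1 + p:1 + p + K],
                                   rtol=1e-8)
        np.testing.assert_allclose(cov_coef, ref.params[1 + p + K:],
                                   rtol=1e-8)

    def test_null_regression_standard_errors_calibrated(self, rng):
        n, p = 400, 6
        G = _random_genotypes(rng, n, p)
        coefs, ses = [], []
        for _ in range(200):
            m = rng.normal(size=n)
            vec = estimate_mediator_effects(G, m)
            coefs.append(vec.values)
            ses.append(vec.standard_errors)
        coefs = np.array(coefs)
        assert np.abs(coefs.mean()) < 0.01
        assert np.isclose(coefs.std(), np.mean(ses), rtol=0.15)

    def test_singular_design_raises(self, rng):
        G = _random_genotypes(rng, 10, 20)
        with pytest.raises(RankDeficiencyError, match="columns"):
            estimate_mediator_effects(G, rng.normal(size=10))


class TestOrientation:
    def test_all_positive_effects_untouched(self, small_base_dataset):
        d = small_base_dataset
        # flip any columns whose generative total effect is negative first,
        # so orientation should find nothing left to flip
        oriented = orient_snps(d.genotypes, d.outcome,
                               d.covariates.to_numpy())
        twice = orient_snps(oriented, d.outcome, d.covariates.to_numpy())
        np.testing.assert_array_equal(oriented.dosages, twice.dosages)
        np.testing.assert_array_equal(twice.signs, oriented.signs)

    def test_negated_snp_is_flipped_back(self, small_base_dataset):
        d = small_base_dataset
        oriented = orient_snps(d.genotypes, d.outcome,
                               d.covariates.to_numpy())
        # recode one SNP: its effect on Y flips sign
        j = 7
        tampered = GenotypeMatrix(oriented.dosages.copy(),
                                  list(oriented.snp_ids))
        tampered.dosages[:, j] = 2 - tampered.dosages[:, j]
        fixed = orient_snps(tampered, d.outcome, d.covariates.to_numpy())
        assert fixed.signs[j] == -1
        assert (fixed.signs[np.arange(60) != j] == 1).all()
        np.testing.assert_array_equal(fixed.dosages, oriented.dosages)

    def test_refit_coefficients_nonnegative(self, small_base_dataset):
        d = small_base_dataset
        cov = d.covariates.to_numpy()
        oriented = orient_snps(d.genotypes, d.outcome, cov)
        c_star, _, _ = estimate_direct_effects(
            oriented, d.mediators.to_numpy(), cov, d.outcome)
        X = sm.add_constant(np.column_stack(
            [oriented.dosages.astype(float), cov]))
        marginal = sm.OLS(d.outcome, X).fit().params[1:61]
        assert (marginal >= 0).all()


class TestOutlierFilter:
    def test_constant_vector_keeps_everything(self):
        kept = filter_outlier_snps([np.full(10, 3.0)])
        np.testing.assert_array_equal(kept, np.arange(10))

    def test_single_extreme_value_with_zero_iqr(self):
        # twenty 0s and one 100: Q1 = Q3 = 0, IQR = 0 -> only 100 removed
        x = np.array([0.0] * 20 + [100.0])
        kept = filter_outlier_snps([x])
        np.testing.assert_array_equal(kept, np.arange(20))

    def test_values_inside_fences_all_kept(self, rng):
        x = rng.uniform(size=50)
        np.testing.assert_array_equal(filter_outlier_snps([x]), np.arange(50))

    def test_joint_removal_across_vectors(self):
        a = np.array([0.0] * 20 + [100.0] + [0.0])
        c = np.array([0.0] * 21 + [-100.0])
        kept = filter_outlier_snps([a, c])
        np.testing.assert_array_equal(kept, np.arange(20))

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.lists(st.floats(-1e3, 1e3), min_size=5, max_size=60),
           st.randoms(use_true_random=False))
    def test_invariant_to_snp_order(self, values, pyrandom):
        x = np.array(values)
        perm = np.arange(len(x))
        pyrandom.shuffle(perm)
        kept = filter_outlier_snps([x])
        kept_perm = filter_outlier_snps([x[perm]])
        np.testing.assert_array_equal(np.sort(perm[kept_perm]), kept)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            filter_outlier_snps([])


class TestStepOneOnSimulatedTruth:
    def test_a_star_nonzero_component_centres_at_effect_mean(
            self, small_base_dataset, small_base_results):
        d = small_base_dataset
        reg = small_base_results.regression
        vals, masks = [], []
        for k, vec in enumerate(reg.a_star):
            mask = d.truth["a_masks"][k]
            vals.append(vec.values[mask] * reg.sign_flips[mask])
            masks.append(mask)
        nonzero = np.concatenate(vals)
        assert np.isclose(nonzero.mean(), 0.2, atol=0.01)

    def test_c_star_nonzero_component_reflects_product_decomposition(
            self, small_base_dataset, small_base_results):
        # c = a_H * b_H: nonzero c* entries centre near b_H * 0.2 = 0.05
        d = small_base_dataset
        reg = small_base_results.regression
        mask = d.truth["a_H_mask"]
        c_nonzero = reg.c_star.values[mask] * reg.sign_flips[mask]
        assert np.isclose(c_nonzero.mean(), 0.25 * 0.2, atol=0.01)

    def test_fully_mediated_model_gives_null_c_star(self):
        cfg = study_config("base", b_H=0.0, p=50, n=6000)
        d = simulate_dataset(cfg, seed=31)
        reg = run_step1(d.genotypes, d.mediators.to_numpy(),
                        d.covariates.to_numpy(), d.outcome)
        assert np.abs(reg.c_star.values.mean()) < 0.003

    def test_parent_adjustment_restores_child_mediator_effects(self):
        # with M1 -> M2, the child regression must adjust for the parent
        cfg = study_config("setting5", variant=1, p=50, n=8000)  # coef 0.9
        d = simulate_dataset(cfg, seed=13)
        reg_adj = run_step1(d.genotypes, d.mediators.to_numpy(),
                            d.covariates.to_numpy(), d.outcome,
                            mediator_parent_idx={1: [0]})
        reg_raw = run_step1(d.genotypes, d.mediators.to_numpy(),
                            d.covariates.to_numpy(), d.outcome)
        mask = d.truth["a_masks"][1]
        adj = reg_adj.a_star[1].values[mask] * reg_adj.sign_flips[mask]
        raw = reg_raw.a_star[1].values[mask] * reg_raw.sign_flips[mask]
        assert np.isclose(adj.mean(), 0.2, atol=0.05)
        assert raw.mean() > adj.mean() + 0.05  # inflated without adjustment


def test_per_vector_outlier_filter_returns_one_set_per_vector():
    a = np.array([0.0] * 20 + [100.0])
    c = np.zeros(21)
    per = filter_outlier_snps([a, c], joint=False)
    np.testing.assert_array_equal(per[0], np.arange(20))
    np.testing.assert_array_equal(per[1], np.arange(21))
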