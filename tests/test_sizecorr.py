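"""PGLS regression and ensemble size correction."""

import numpy as np
import pandas as pd
import pytest

import ecomorph as em
from ecomorph.sizecorr import LINEAR_VARS, RESIDUAL_COLUMNS, validate_trait_table
from ecomorph.trees import PhyloCovariance


class TestPGLS:
    def test_identity_covariance_reduces_to_ols(self):
        rng = np.random.default_rng(0)
        n = 30
        x = rng.normal(size=n)
        y = 1.5 + 0.8 * x + rng.normal(scale=0.3, size=n)
        cov = PhyloCovariance([f"s{i}" for i in range(n)], np.eye(n))
        fit = em.pgls_fit(y, x, cov)
        X = np.column_stack([np.ones(n), x])
        beta_ols = np.linalg.solve(X.T @ X, X.T @ y)
        np.testing.assert_allclose(fit.params, beta_ols, atol=1e-10)
        np.testing.assert_allclose(fit.resid, y - X @ beta_ols, atol=1e-10)

    def test_matches_external_gls_at_fixed_lambda(self, oracle_tree_data):
        """Frozen oracle: nlme::gls with corPagel(0.7, fixed) on this fixture."""
        _, cov, yv, xv = oracle_tree_data
        model = em.PGLS(yv, xv, cov)
        beta, _, _, llf = model._profile(0.7)
        np.testing.assert_allclose(beta, [0.1256673684, 1.6089362574],
                                   atol=1e-8)
        assert llf == pytest.approx(2.7090112517, abs=1e-8)

    def test_slope_and_lambda_recovery_under_brownian_noise(self):
        tree = em.simulate_tree(200, seed=7)
        cov = tree.covariance()
        rng = np.random.default_rng(3)
        x = rng.normal(0, 1, 200)
        noise = em.simulate_bm_traits(tree, 0.5, 1.0, seed=11).iloc[:, 0]
        fit = em.pgls_fit(2.0 + 0.7 * x + noise.to_numpy(), x, cov)
        assert abs(fit.params[1] - 0.7) < 0.1
        assert fit.lambda_ >= 0.8

    def test_constant_predictor_raises(self, oracle_tree_data):
        _, cov, yv, _ = oracle_tree_data
        with pytest.raises(np.linalg.LinAlgError):
            em.PGLS(yv, np.ones(8), cov).fit()

    def test_residuals_are_response_scale(self, oracle_tree_data):
        _, cov, yv, xv = oracle_tree_data
        res = em.pgls_fit(yv, xv, cov)
        np.testing.assert_allclose(
            res.resid, yv - res.model.exog @ res.params, atol=1e-12)

    def test_summary_mentions_lambda(self, oracle_tree_data):
        _, cov, yv, xv = oracle_tree_data
        assert "lambda" in em.pgls_fit(yv, xv, cov).summary()


class TestSizeCorrection:
    def test_star_tree_equals_ols_residuals(self, small_dataset):
        """On a star phylogeny the PGLS residuals are OLS residuals."""
        _, traits, _ = small_dataset
        traits = traits.iloc[:20]
        species = sorted(traits.index)
        tips = ",".join(f"{s}:1" for s in species)
        star = em.read_trees(f"({tips});")
        resid = em.size_correct_ensemble(traits, star)
        logm = np.log(traits.loc[species, "mass_g"].to_numpy())
        X = np.column_stack([np.ones(len(species)), logm])
        for var in ("HF", "LMT"):
            y = np.log(traits.loc[species, var].to_numpy())
            beta = np.linalg.lstsq(X, y, rcond=None)[0]
            np.testing.assert_allclose(resid[var].to_numpy(), y - X @ beta,
                                       atol=1e-8)

    def test_duplicated_tree_equals_single_tree(self, small_dataset):
        ensemble, traits, _ = small_dataset
        one = em.TreeEnsemble([ensemble[0]])
        two = em.TreeEnsemble([ensemble[0], ensemble[0]])
        pd.testing.assert_frame_equal(em.size_correct_ensemble(traits, one),
                                      em.size_correct_ensemble(traits, two))

    def test_tree_order_invariance(self, small_dataset):
        ensemble, traits, _ = small_dataset
        fwd = em.TreeEnsemble(list(ensemble))
        rev = em.TreeEnsemble(list(ensemble)[::-1])
        pd.testing.assert_frame_equal(em.size_correct_ensemble(traits, fwd),
                                      em.size_correct_ensemble(traits, rev))

    def test_residuals_uncorrelated_with_size(self):
        """With independent trait deviations the size signal is removed.

        (With phylogenetically correlated deviations the residuals can
        retain chance tree-level correlation with mass regardless of n —
        phylogenetic pseudo-replication — so the clean check uses
        lambda_signal = 0.)"""
        cfg = em.SimConfig(n_tips=150, n_trees=1, lambda_signal=0.0,
                           class_shift=0.0, seed=21)
        ensemble, traits, _ = em.simulate_ecomorph_dataset(cfg)
        resid = em.size_correct_ensemble(traits, ensemble)
        logm = np.log(traits["mass_g"]).reindex(resid.index)
        cors = [abs(np.corrcoef(resid[v], logm)[0, 1]) for v in LINEAR_VARS]
        assert np.mean(cors) < 0.05

    def test_column_order_and_acp_centred(self, small_residuals):
        assert list(small_residuals.columns) == RESIDUAL_COLUMNS
        assert small_residuals["ACP"].mean() == pytest.approx(0.0, abs=1e-9)

    def test_species_missing_from_tree_raises(self, small_dataset):
        ensemble, traits, _ = small_dataset
        bad = traits.rename(index={traits.index[0]: "not_a_tip"})
        with pytest.raises(ValueError, match="missing from trees"):
            em.size_correct_ensemble(bad, ensemble)


class TestTraitValidation:
    def test_nonpositive_measurement_rejected(self, small_dataset):
        _, traits, _ = small_dataset
        bad = traits.copy()
        bad.iloc[0, bad.columns.get_loc("HF")] = 0.0
        with pytest.raises(ValueError, match="onpositive"):
            validate_trait_table(bad)

    def test_acp_outside_range_rejected(self, small_dataset):
        _, traits, _ = small_dataset
        bad = traits.copy()
        bad.iloc[0, bad.columns.get_loc("ACP")] = 185.0
        with pytest.raises(ValueError, match="ACP"):
            validate_trait_table(bad)

    def test_missing_value_rejected(self, small_dataset):
        _, traits, _ = small_dataset
        bad = traits.copy()
        bad.iloc[2, 3] = np.nan
        with pytest.raises(ValueError, match="issing"):
            validate_trait_table(bad)


class TestLogShapeRatios:
    def test_equal_measurements_give_zero(self, small_dataset):
        _, traits, _ = small_dataset
        t = traits.copy()
        t[LINEAR_VARS] = 5.0
        assert np.abs(em.log_shape_ratios(t).to_numpy()).max() < 1e-12

    def test_size_invariance(self, small_dataset):
        """Doubling every measurement of a species leaves its shape unchanged."""
        _, traits, _ = small_dataset
        doubled = traits.copy()
        doubled.loc[traits.index[0], LINEAR_VARS] *= 2.0
        a = em.log_shape_ratios(traits)
        b = em.log_shape_ratios(doubled)
        np.testing.assert_allclose(a.iloc[0], b.iloc[0], atol=1e-12)

    def test_matches_geometric_mean_definition(self, small_dataset):
        _, traits, _ = small_dataset
        ratios = em.log_shape_ratios(traits)
        sp = traits.index[3]
        vals = traits.loc[sp, LINEAR_VARS].astype(float)
        g = np.exp(np.mean(np.log(vals)))
        np.testing.assert_allclose(ratios.loc[sp],
                                   np.log(vals / g), atol=1e-12)
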