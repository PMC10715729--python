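"""PGLS, allometry, effect-size conversions and phylogenetic logistic
regression."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import linalg

from phylocomp.pgls import (
    fit_allometry,
    fit_phylo_logistic,
    fit_pgls,
    profile_lambda,
    r_ci,
    r_from_t,
    t_from_r,
)
from phylocomp.phylo import apply_lambda, phylo_covariance
from phylocomp.simulate import simulate_tree
from tests.conftest import star_tree


class TestEffectSizeConversions:
    @pytest.mark.parametrize(
        "t,df,r",
        [
            (22.26, 28, 0.97),
            (28.05, 28, 0.98),
            (-3.50, 113, -0.31),
            (18.03, 28, 0.96),
            (-6.59, 114, -0.53),
        ],
    )
    def test_published_pairs(self, t, df, r):
        assert r_from_t(t, df) == pytest.approx(r, abs=0.005)

    def test_t_zero_gives_r_zero(self):
        for df in (1, 10, 1000):
            assert r_from_t(0.0, df) == 0.0

    @given(
        r=st.floats(-0.999, 0.999),
        df=st.integers(1, 500),
    )
    @settings(max_examples=200, deadline=None)
    def test_roundtrip_identity(self, r, df):
        assert r_from_t(t_from_r(r, df), df) == pytest.approx(r, abs=1e-12)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            t_from_r(1.0, 10)
        with pytest.raises(ValueError):
            r_ci(-1.0, 10)

    def test_ci_brackets_r(self):
        lo, hi = r_ci(0.5, 100)
        assert lo < 0.5 < hi
        assert -1 < lo and hi < 1


def _bm_table(tree, slope=0.5, noise=0.5, lam=1.0, seed=0):
    C = phylo_covariance(tree)
    L = linalg.cholesky(apply_lambda(C, lam).matrix + 1e-12 * np.eye(C.n), lower=True)
    rng = np.random.default_rng(seed)
    x = L @ rng.standard_normal(C.n)
    y = slope * x + noise * (L @ rng.standard_normal(C.n))
    return pd.DataFrame({"species": tree.taxa, "x": x, "y": y})


class TestFitPgls:
    def test_star_phylogeny_matches_ols(self):
        tree = star_tree(40)
        rng = np.random.default_rng(2)
        tab = pd.DataFrame(
            {
                "species": tree.taxa,
                "x": rng.standard_normal(40),
            }
        )
        tab["y"] = 0.8 * tab["x"] + rng.standard_normal(40)
        res = fit_pgls(tab, "y ~ x", tree, n_boot=0)
        X = np.column_stack([np.ones(40), tab["x"]])
        ols, *_ = np.linalg.lstsq(X, tab["y"].to_numpy(), rcond=None)
        np.testing.assert_allclose(res.fit.coefficients, ols, atol=1e-8)

    def test_response_copy_of_predictor(self, yule50):
        tab = _bm_table(yule50, slope=1.0, noise=0.0)
        res = fit_pgls(tab, "y ~ x", yule50, n_boot=0)
        assert res.std_betas.loc["x", "est"] == pytest.approx(1.0, abs=1e-8)
        assert res.r["x"] == pytest.approx(1.0, abs=1e-6)

    def test_df_matches_field_convention(self, yule50):
        """n species with p slopes leave df = n - p - 1 (t_114 at n = 116
        with one predictor; t_113 with two)."""
        tab = _bm_table(yule50)
        tab["z"] = tab["x"] ** 2
        one = fit_pgls(tab, "y ~ x", yule50, n_boot=0)
        two = fit_pgls(tab, "y ~ x + z", yule50, n_boot=0)
        assert one.fit.df == 50 - 2
        assert two.fit.df == 50 - 3

    def test_profile_grid_never_beats_optimum(self, yule50):
        tab = _bm_table(yule50, lam=0.6, seed=4)
        C = phylo_covariance(yule50)
        X = np.column_stack([np.ones(50), tab["x"]])
        y = tab["y"].to_numpy()
        lam_hat, fit, _ = profile_lambda(y, X, C)
        grid = np.arange(0, 1.001, 0.01)
        from phylocomp.phylo import gls_fit

        lls = [gls_fit(y, X, apply_lambda(C, g)).log_likelihood for g in grid]
        assert max(lls) <= fit.log_likelihood + 1e-6

    def test_standardized_beta_unit_invariance(self, yule50):
        tab = _bm_table(yule50, seed=6)
        res1 = fit_pgls(tab, "y ~ x", yule50, n_boot=0)
        tab2 = tab.copy()
        tab2["x"] = tab2["x"] * 1000.0 + 37.0  # change of units
        res2 = fit_pgls(tab2, "y ~ x", yule50, n_boot=0)
        assert res1.std_betas.loc["x", "est"] == pytest.approx(
            res2.std_betas.loc["x", "est"], rel=1e-8
        )

    def test_nonfinite_rows_reported(self, yule50):
        tab = _bm_table(yule50)
        tab.loc[3, "x"] = np.nan
        with pytest.raises(ValueError, match=tab.loc[3, "species"]):
            fit_pgls(tab, "y ~ x", yule50, n_boot=0)

    def test_too_few_species(self, three_taxon_tree):
        tab = pd.DataFrame(
            {"species": ["A", "B", "C"], "x": [1.0, 2, 3], "z": [2.0, 1, 5],
             "y": [1.0, 0, 2]}
        )
        with pytest.raises(ValueError, match="species"):
            fit_pgls(tab, "y ~ x + z", three_taxon_tree, n_boot=0)

    def test_bootstrap_ci_brackets_estimate(self, yule50):
        tab = _bm_table(yule50, seed=8)
        res = fit_pgls(tab, "y ~ x", yule50, n_boot=30, seed=1)
        lo, hi = res.std_betas.loc["x", ["ci_low", "ci_high"]]
        assert lo <= hi
        assert 0.0 <= res.lambda_ci[0] <= res.lambda_ci[1] <= 1.0


class TestAllometry:
    def test_exact_isometry(self, yule50):
        rng = np.random.default_rng(0)
        svl = np.exp(rng.normal(3.5, 0.3, 50))
        mass = 1e-3 * svl**3
        res = fit_allometry(mass, svl, yule50, species=yule50.taxa, n_boot=20, seed=0)
        assert res.slope == pytest.approx(1.0, abs=1e-9)
        assert res.classification == "proportionate"

    def test_half_power_is_shallower(self, yule50):
        rng = np.random.default_rng(1)
        svl = np.exp(rng.normal(3.5, 0.3, 50))
        mass = 1e-2 * svl**1.5  # exponent 0.5 on SVL^3
        res = fit_allometry(mass, svl, yule50, species=yule50.taxa, n_boot=20, seed=0)
        assert res.slope == pytest.approx(0.5, abs=1e-9)
        assert res.classification == "shallower"

    def test_nonpositive_mass_rejected(self, yule50):
        with pytest.raises(ValueError):
            fit_allometry(
                np.zeros(50), np.ones(50), yule50, species=yule50.taxa, n_boot=0
            )


def _firth_oracle(y, X, tol=1e-10):
    """Independent Firth-penalized logistic Newton iteration."""
    beta = np.zeros(X.shape[1])
    for _ in range(200):
        p = 1 / (1 + np.exp(-(X @ beta)))
        W = p * (1 - p)
        info = X.T @ (W[:, None] * X)
        Hd = np.einsum(
            "ij,jk,ik->i", np.sqrt(W)[:, None] * X, np.linalg.inv(info),
            np.sqrt(W)[:, None] * X,
        )
        U = X.T @ (y - p + Hd * (0.5 - p))
        step = np.linalg.solve(info, U)
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            break
    return beta


class TestPhyloLogistic:
    def test_star_tree_matches_firth_oracle(self):
        tree = star_tree(40)
        rng = np.random.default_rng(3)
        x = rng.standard_normal(40)
        y = (rng.random(40) < 1 / (1 + np.exp(-(0.5 + 1.2 * x)))).astype(float)
        fit = fit_phylo_logistic(y, x[:, None], tree, n_boot=0)
        oracle = _firth_oracle(y, np.column_stack([np.ones(40), x]))
        np.testing.assert_allclose(fit.coefficients, oracle, atol=1e-4)

    def test_antisymmetric_toy_zero_intercept(self):
        tree = star_tree(8)
        x = np.array([-4.0, -3, -2, -1, 1, 2, 3, 4])
        y = (x > 0).astype(float)
        fit = fit_phylo_logistic(y, x[:, None], tree, n_boot=0)
        assert fit.coefficients[0] == pytest.approx(0.0, abs=1e-6)
        assert fit.separation  # perfectly separated but Firth keeps it finite

    def test_constant_response_rejected(self, yule50):
        with pytest.raises(ValueError, match="variation"):
            fit_phylo_logistic(np.ones(50), np.arange(50.0)[:, None], yule50, n_boot=0)

    def test_alpha_estimated_on_structured_tree(self, yule50):
        rng = np.random.default_rng(5)
        C = phylo_covariance(yule50)
        L = linalg.cholesky(C.matrix + 1e-10 * np.eye(50), lower=True)
        latent = L @ rng.standard_normal(50)
        y = (latent > np.median(latent)).astype(float)
        x = rng.standard_normal(50)
        fit = fit_phylo_logistic(y, x[:, None], yule50, n_boot=0)
        assert np.isfinite(fit.alpha) and fit.alpha > 0
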