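"""Tree I/O, phylogenetic covariance and the GLS engine."""

import numpy as np
import pytest
from scipy import linalg

from phylocomp.phylo import (
    NewickError,
    apply_lambda,
    gls_fit,
    phylo_covariance,
    read_newick,
    write_newick,
)
from phylocomp.simulate import simulate_tree


class TestNewickIO:
    def test_three_taxon_depths(self, three_taxon_tree):
        assert three_taxon_tree.taxa == ["A", "B", "C"]
        assert three_taxon_tree.root_distances() == {"A": 2, "B": 2, "C": 2}

    def test_single_taxon_tree(self):
        phy = read_newick("(A:1);")
        C = phylo_covariance(phy)
        assert C.matrix.shape == (1, 1)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_roundtrip_random_trees(self, seed):
        phy = simulate_tree(20, seed=seed)
        again = read_newick(write_newick(phy))
        assert again.taxa == phy.taxa
        d1, d2 = phy.root_distances(), again.root_distances()
        for t in phy.taxa:
            assert d1[t] == pytest.approx(d2[t], rel=1e-9)

    def test_malformed_string_raises(self):
        with pytest.raises(NewickError):
            read_newick("((A:1,B:1:1,C;")

    def test_missing_branch_length_raises(self):
        with pytest.raises(NewickError, match="branch length"):
            read_newick("((A:1,B),C:2);")

    def test_duplicate_taxa_raise(self):
        with pytest.raises(NewickError, match="duplicate"):
            read_newick("((A:1,A:1):1,C:2);")

    def test_zero_length_tip_warns(self):
        with pytest.warns(UserWarning, match="zero-length"):
            read_newick("((A:0,B:1):1,C:2);")


class TestCovariance:
    def test_three_taxon_shared_paths(self, three_taxon_tree):
        C = phylo_covariance(three_taxon_tree)
        expect = np.array([[2.0, 1.0, 0.0], [1.0, 2.0, 0.0], [0.0, 0.0, 2.0]])
        np.testing.assert_allclose(C.matrix, expect)

    def test_star_tree_is_diagonal(self, star_tree_20):
        C = phylo_covariance(star_tree_20)
        np.testing.assert_allclose(C.matrix, np.eye(20))

    def test_unknown_taxon_raises(self, three_taxon_tree):
        with pytest.raises(KeyError):
            phylo_covariance(three_taxon_tree, ["A", "Z"])

    def test_matches_mrca_depth_oracle(self, yule50):
        """Entry (i,j) equals the MRCA depth found by explicit root-path
        intersection on the underlying tree."""
        C = phylo_covariance(yule50)
        tree = yule50.tree
        # brute force: collect the root-to-tip edge path of every leaf
        paths = {}
        for leaf in tree.leaf_node_iter():
            path = []
            nd = leaf
            while nd.parent_node is not None:
                path.append((id(nd), nd.edge.length))
                nd = nd.parent_node
            paths[leaf.taxon.label] = path
        taxa = yule50.taxa
        for i in range(0, 50, 7):
            for j in range(i, 50, 5):
                shared = 0.0
                ids_j = {k for k, _ in paths[taxa[j]]}
                if i == j:
                    shared = sum(l for _, l in paths[taxa[i]])
                else:
                    shared = sum(l for k, l in paths[taxa[i]] if k in ids_j)
                assert C.matrix[i, j] == pytest.approx(shared, abs=1e-9)

    def test_psd_for_random_trees(self):
        for seed in range(5):
            phy = simulate_tree(30, seed=100 + seed)
            C = phylo_covariance(phy)
            np.testing.assert_allclose(C.matrix, C.matrix.T)
            linalg.cholesky(C.matrix + 0 * np.eye(30), lower=True)


class TestLambda:
    def test_lambda_zero_diagonal(self, three_taxon_tree):
        C = phylo_covariance(three_taxon_tree)
        out = apply_lambda(C, 0.0)
        np.testing.assert_allclose(out.matrix, np.diag([2.0, 2.0, 2.0]))

    def test_lambda_one_identity_transform(self, yule50_cov):
        np.testing.assert_allclose(apply_lambda(yule50_cov, 1.0).matrix, yule50_cov.matrix)

    def test_lambda_half_scales_offdiag(self, three_taxon_tree):
        C = phylo_covariance(three_taxon_tree)
        out = apply_lambda(C, 0.5)
        assert out.matrix[0, 1] == pytest.approx(0.5)
        assert out.matrix[0, 0] == pytest.approx(2.0)

    @pytest.mark.parametrize("bad", [-0.1, 1.1, 2.0])
    def test_domain_error(self, yule50_cov, bad):
        with pytest.raises(ValueError):
            apply_lambda(yule50_cov, bad)


class TestGls:
    def test_identity_covariance_equals_ols(self, rng):
        for _ in range(10):
            n = 40
            X = np.column_stack([np.ones(n), rng.standard_normal((n, 2))])
            y = X @ np.array([1.0, 0.5, -2.0]) + rng.standard_normal(n)
            fit = gls_fit(y, X, np.eye(n))
            ols, *_ = np.linalg.lstsq(X, y, rcond=None)
            np.testing.assert_allclose(fit.coefficients, ols, atol=1e-10)

    def test_exact_linear_fit_zero_sigma(self, yule50, yule50_cov):
        n = 50
        x = np.linspace(0, 1, n)
        X = np.column_stack([np.ones(n), x])
        y = 2.0 + 3.0 * x
        fit = gls_fit(y, X, yule50_cov)
        assert fit.sigma2 == pytest.approx(0.0, abs=1e-20)

    def test_rank_deficient_raises(self, yule50_cov):
        n = 50
        X = np.column_stack([np.ones(n), np.ones(n)])
        with pytest.raises(np.linalg.LinAlgError):
            gls_fit(np.arange(n, dtype=float), X, yule50_cov)

    def test_slope_recovery_brownian(self, yule100):
        """A Brownian response with slope 0.5 on a Brownian predictor is
        recovered close to truth on a 100-taxon tree."""
        C = phylo_covariance(yule100)
        L = linalg.cholesky(C.matrix, lower=True)
        rng = np.random.default_rng(7)
        ests = []
        for _ in range(10):
            x = L @ rng.standard_normal(100)
            y = 0.5 * x + 0.3 * (L @ rng.standard_normal(100))
            fit = gls_fit(y, np.column_stack([np.ones(100), x]), C)
            ests.append(fit.coefficients[1])
        assert np.mean(ests) == pytest.approx(0.5, abs=0.05)

    def test_tree_scaling_moves_sigma2_not_coefficients(self, yule50, rng):
        C = phylo_covariance(yule50)
        L = linalg.cholesky(C.matrix, lower=True)
        x = L @ rng.standard_normal(50)
        y = 1.0 + 0.7 * x + L @ rng.standard_normal(50)
        X = np.column_stack([np.ones(50), x])
        f1 = gls_fit(y, X, C.matrix)
        k = 4.0
        f2 = gls_fit(y, X, C.matrix * k)
        np.testing.assert_allclose(f1.coefficients, f2.coefficients, rtol=1e-10)
        assert f2.sigma2 == pytest.approx(f1.sigma2 / k, rel=1e-10)

    def test_loglik_maximized_at_ml_sigma2(self, yule50, rng):
        """Perturbing sigma2 by +-10% around the ML value lowers the
        multivariate normal log-density."""
        C = phylo_covariance(yule50)
        L = linalg.cholesky(C.matrix, lower=True)
        y = L @ rng.standard_normal(50)
        X = np.ones((50, 1))
        fit = gls_fit(y, X, C.matrix)

        def ll(s2):
            r = y - fit.fitted
            rw = linalg.solve_triangular(L, r, lower=True)
            logdet = 2 * np.sum(np.log(np.diag(L)))
            return -0.5 * (
                50 * np.log(2 * np.pi * s2) + logdet + rw @ rw / s2
            )

        assert ll(fit.sigma2) == pytest.approx(fit.log_likelihood)
        assert ll(fit.sigma2 * 1.1) < fit.log_likelihood
        assert ll(fit.sigma2 * 0.9) < fit.log_likelihood
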