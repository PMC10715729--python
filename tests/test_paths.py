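"""Confirmatory path analysis: basis sets, Fisher's C, CICc, averaging."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from scipy import linalg

from phylocomp.paths import (
    PathFit,
    PathModel,
    average_models,
    basis_set,
    bundled_model_set,
    fishers_c,
    fit_path_model,
    rank_models,
    read_model_set,
)
from phylocomp.phylo import phylo_covariance


class TestPathModel:
    def test_cycle_rejected(self):
        with pytest.raises(ValueError, match="cyclic"):
            PathModel("bad", [("A", "B"), ("B", "C"), ("C", "A")])

    def test_param_count_includes_exogenous_pairs(self):
        m = PathModel("m", [("A", "C"), ("B", "C")])
        # 2 edges + 1 covariance among the exogenous pair (A, B)
        assert m.n_params() == 3


class TestBasisSet:
    def test_chain(self):
        m = PathModel("chain", [("X", "Y"), ("Y", "Z")])
        claims = basis_set(m)
        assert len(claims) == 1
        c = claims[0]
        assert {c.x, c.y} == {"X", "Z"} and c.given == ("Y",)
        assert c.dependent == "Z"

    def test_saturated_dag_empty(self):
        m = PathModel("sat", [("A", "B"), ("A", "C"), ("B", "C")])
        assert basis_set(m) == []

    def test_canonical_under_relabeling(self):
        m1 = PathModel("a", [("X", "Y"), ("Y", "Z"), ("X", "W")])
        mapping = {"X": "P", "Y": "Q", "Z": "R", "W": "S"}
        m2 = PathModel("b", [(mapping[a], mapping[b]) for a, b in m1.edges])
        c1 = {
            (frozenset((mapping[c.x], mapping[c.y])),
             frozenset(mapping[g] for g in c.given))
            for c in basis_set(m1)
        }
        c2 = {(frozenset((c.x, c.y)), frozenset(c.given)) for c in basis_set(m2)}
        assert c1 == c2

    @pytest.mark.parametrize("seed", range(10))
    def test_claims_are_d_separations(self, seed):
        """Every claim in the basis set is a true d-separation of the DAG
        (independent path-blocking oracle via networkx)."""
        rng = np.random.default_rng(seed)
        nodes = list("ABCDE")
        edges = [
            (nodes[i], nodes[j])
            for i in range(5)
            for j in range(i + 1, 5)
            if rng.random() < 0.4
        ]
        g = nx.DiGraph()
        g.add_nodes_from(nodes)
        g.add_edges_from(edges)
        m = PathModel("r", edges) if edges else None
        if m is None:
            return
        claims = basis_set(m)
        # one claim per non-adjacent pair of the model's node set
        present = set(m.graph.nodes)
        n_pairs = sum(
            1
            for i, a in enumerate(sorted(present))
            for b in sorted(present)[i + 1:]
            if not (g.has_edge(a, b) or g.has_edge(b, a))
        )
        assert len(claims) == n_pairs
        for c in claims:
            assert nx.is_d_separator(m.graph, {c.x}, {c.y}, set(c.given))


class TestFishersC:
    def test_all_ones(self):
        C, df, p = fishers_c([1.0, 1.0])
        assert C == 0.0 and df == 4 and p == pytest.approx(1.0)

    def test_half_half(self):
        C, df, _ = fishers_c([0.5, 0.5])
        assert C == pytest.approx(2.7726, abs=1e-4)

    @pytest.mark.parametrize("k", [1, 3, 7])
    def test_scaling_in_k(self, k):
        C, df, _ = fishers_c([0.05] * k)
        assert C == pytest.approx(k * 5.9915, abs=1e-3 * k)
        assert df == 2 * k

    def test_zero_p_clamped(self):
        with pytest.warns(UserWarning, match="clamped"):
            C, _, _ = fishers_c([0.0, 0.5])
        assert np.isfinite(C)


def _chain_data(tree, seed=0, n=None):
    C = phylo_covariance(tree)
    L = linalg.cholesky(C.matrix + 1e-10 * np.eye(C.n), lower=True)
    rng = np.random.default_rng(seed)
    x = L @ rng.standard_normal(C.n)
    y = 0.8 * x + 0.5 * (L @ rng.standard_normal(C.n))
    z = 0.8 * y + 0.5 * (L @ rng.standard_normal(C.n))
    return pd.DataFrame({"species": tree.taxa, "X": x, "Y": y, "Z": z})


class TestFitPathModel:
    def test_saturated_model_c_zero(self, yule50):
        tab = _chain_data(yule50)
        m = PathModel("sat", [("X", "Y"), ("X", "Z"), ("Y", "Z")])
        fit = fit_path_model(m, tab, yule50)
        assert fit.C == 0.0
        n, q = fit.n, fit.q
        assert fit.cicc == pytest.approx(2 * q * n / (n - 1 - q))

    def test_chain_beats_reversed_on_chain_data(self, yule50):
        tab = _chain_data(yule50, seed=3)
        chain = PathModel("chain", [("X", "Y"), ("Y", "Z")])
        wrong = PathModel("wrong", [("X", "Z"), ("Z", "Y")])
        f1 = fit_path_model(chain, tab, yule50)
        f2 = fit_path_model(wrong, tab, yule50)
        assert f1.cicc < f2.cicc

    def test_adding_edge_never_increases_C(self, yule50):
        tab = _chain_data(yule50, seed=4)
        m1 = PathModel("sparse", [("X", "Y"), ("X", "Z")])
        m2 = PathModel("denser", [("X", "Y"), ("X", "Z"), ("Y", "Z")])
        f1 = fit_path_model(m1, tab, yule50)
        f2 = fit_path_model(m2, tab, yule50)
        assert f2.C <= f1.C + 1e-9

    def test_size_control_enters_q(self, yule50):
        tab = _chain_data(yule50, seed=5)
        tab["svl"] = np.random.default_rng(0).standard_normal(50)
        m = PathModel("chain", [("X", "Y"), ("Y", "Z")])
        plain = fit_path_model(m, tab, yule50)
        ctl = fit_path_model(m, tab, yule50, size_control="svl")
        assert ctl.q == plain.q + 3  # one extra path per node

    def test_missing_node_column(self, yule50):
        tab = _chain_data(yule50)
        m = PathModel("m", [("X", "W")])
        with pytest.raises(ValueError, match="W"):
            fit_path_model(m, tab, yule50)


def _fake_fit(name, cicc, coef, n=50):
    m = PathModel(name, [("A", "B")])
    edges = pd.DataFrame(
        [{"child": "B", "parent": "A", "std_coef": coef, "se_std": 0.1,
          "ci_low": coef - 0.2, "ci_high": coef + 0.2}]
    )
    return PathFit(model=m, claim_p={}, C=0.0, df=0, p_C=1.0, q=1, n=n,
                   cicc=cicc, edges=edges)


class TestAveraging:
    def test_single_model_identity(self):
        f = _fake_fit("m", 10.0, 0.5)
        avg = average_models([f])
        assert avg.loc[0, "std_coef"] == pytest.approx(0.5)

    def test_symmetric_pair_averages_to_zero(self):
        avg = average_models([_fake_fit("a", 10.0, 0.6), _fake_fit("b", 10.0, -0.6)])
        assert avg.loc[0, "std_coef"] == pytest.approx(0.0)

    def test_delta_threshold(self):
        fits = [_fake_fit("a", 10.0, 1.0), _fake_fit("b", 11.0, 0.0),
                _fake_fit("c", 14.0, 5.0)]
        avg = average_models(fits, delta=2.0)
        assert avg.loc[0, "std_coef"] == pytest.approx(0.5)  # third excluded
        assert avg.loc[0, "n_models"] == 2

    def test_rank_table_weights(self):
        fits = [_fake_fit("a", 10.0, 1.0), _fake_fit("b", 12.0, 0.0)]
        tab = rank_models(fits)
        assert tab["weight"].sum() == pytest.approx(1.0)
        assert tab.loc[0, "model"] == "a"


class TestModelSets:
    def test_bundled_sets_load(self):
        climate = bundled_model_set("climate8")
        tissues = bundled_model_set("tissues28")
        assert len(climate) == 8
        assert len(tissues) == 28
        assert len({tuple(m.nodes) for m in climate}) == 1
        assert len({tuple(m.nodes) for m in tissues}) == 1

    def test_parser_roundtrip(self):
        text = "[m1]\nB <- A\nC <- A + B\n"
        (m,) = read_model_set(text)
        assert set(m.edges) == {("A", "B"), ("A", "C"), ("B", "C")}

    def test_parser_rejects_garbage(self):
        with pytest.raises(ValueError):
            read_model_set("[m]\nB -> A\n")
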