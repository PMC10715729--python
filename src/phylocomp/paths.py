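"""Phylogenetic confirmatory path analysis.

Candidate causal structures are directed acyclic graphs over named traits.
Each DAG implies a basis set of conditional independencies (one claim per
non-adjacent pair, conditioned on the union of both variables' parents);
every claim is tested with a lambda-ML PGLS t-test, the p-values combine
into Fisher's C = -2 sum(ln p) with df = 2k, and models are ranked by

    CICc = C + 2 q n / (n - 1 - q)

where q counts free parameters (directed edges plus covariances among
exogenous variables).  Models within Delta-CICc <= 2 of the best are
averaged edge by edge (conditional averaging: over the models that contain
the edge).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .pgls import profile_lambda
from .phylo import Phylogeny, phylo_covariance

__all__ = [
    "PathModel",
    "Claim",
    "PathFit",
    "basis_set",
    "fishers_c",
    "fit_path_model",
    "rank_models",
    "average_models",
    "read_model_set",
]


@dataclass(frozen=True)
class Claim:
    """Conditional-independence claim: x independent of y given `given`,
    tested by regressing `dependent` on the other variable plus `given`."""

    x: str
    y: str
    given: tuple[str, ...]
    dependent: str


@dataclass
class PathModel:
    name: str
    edges: list[tuple[str, str]]  # (parent, child)
    graph: nx.DiGraph = field(init=False)

    def __post_init__(self) -> None:
        g = nx.DiGraph()
        for parent, child in self.edges:
            g.add_edge(parent, child)
        if not nx.is_directed_acyclic_graph(g):
            cyc = nx.find_cycle(g)
            raise ValueError(f"model {self.name!r} is cyclic: {cyc}")
        self.graph = g

    @property
    def nodes(self) -> list[str]:
        return sorted(self.graph.nodes)

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def exogenous(self) -> list[str]:
        return sorted(n for n in self.graph.nodes if self.graph.in_degree(n) == 0)

    def n_params(self) -> int:
        """q: directed edges plus one covariance per exogenous pair."""
        k = len(self.exogenous())
        return self.n_edges + k * (k - 1) // 2


def basis_set(model: PathModel) -> list[Claim]:
    """Shipley basis set: one claim per non-adjacent pair, conditioning on
    the union of both variables' parents.

    The regression dependent is the causally downstream variable of the
    pair (the non-ancestor); for causally unordered pairs the
    lexicographically later one, making the output canonical under node
    relabeling.
    """
    g = model.graph
    ancestors = {n: nx.ancestors(g, n) for n in g.nodes}
    claims = []
    for x, y in combinations(sorted(g.nodes), 2):
        if g.has_edge(x, y) or g.has_edge(y, x):
            continue
        given = tuple(sorted(set(g.predecessors(x)) | set(g.predecessors(y))))
        if x in ancestors[y]:
            dep = y
        elif y in ancestors[x]:
            dep = x
        else:
            dep = y
        claims.append(Claim(x=x, y=y, given=given, dependent=dep))
    return claims


def fishers_c(p_values) -> tuple[float, int, float]:
    """Fisher's C over the basis-set p-values: C, df = 2k, chi^2 tail p."""
    p = np.asarray(list(p_values), dtype=float)
    if np.any(p <= 0):
        warnings.warn("p-value of 0 clamped to 1e-300", stacklevel=2)
        p = np.clip(p, 1e-300, 1.0)
    if np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    C = float(-2.0 * np.sum(np.log(p)))
    df = 2 * p.size
    p_C = float(stats.chi2.sf(C, df)) if df else 1.0
    return C, df, p_C


@dataclass
class PathFit:
    model: PathModel
    claim_p: dict[Claim, float]
    C: float
    df: int
    p_C: float
    q: int
    n: int
    cicc: float
    edges: pd.DataFrame  # child, parent, std_coef, se_std, ci_low, ci_high


def _pgls_t_p(y, X, C0) -> tuple[float, float, "object"]:
    """lambda-ML PGLS; returns (t, p) for the *last* design column."""
    _, fit, _ = profile_lambda(y, X, C0)
    t = fit.t_statistics[-1]
    p = 2 * stats.t.sf(abs(t), fit.df)
    return float(t), float(p), fit


def fit_path_model(
    model: PathModel,
    table: pd.DataFrame,
    tree: Phylogeny,
    size_control: str | None = None,
) -> PathFit:
    """Fit one candidate DAG: d-sep claims by PGLS, C, CICc, edge coefficients.

    When `size_control` names a trait column, it enters every claim's
    conditioning set and every structural regression as an extra parent of
    all nodes (body-size control), and its paths are counted in q.
    """
    missing = [v for v in model.nodes if v not in table.columns]
    if missing:
        raise ValueError(f"trait table lacks columns {missing}")
    keep = table[table["species"].isin(set(tree.taxa))]
    sub = tree.prune_to(list(keep["species"])) if len(keep) < tree.n_taxa else tree
    order = {sp: i for i, sp in enumerate(sub.taxa)}
    keep = keep.sort_values("species", key=lambda s: s.map(order)).reset_index(drop=True)
    n = len(keep)
    C0 = phylo_covariance(sub)

    def design(cols: list[str]) -> np.ndarray:
        return np.column_stack([np.ones(n)] + [keep[c].to_numpy(float) for c in cols])

    control = [size_control] if size_control else []
    claim_p: dict[Claim, float] = {}
    for cl in basis_set(model):
        other = cl.x if cl.dependent == cl.y else cl.y
        cond = [c for c in cl.given if c != cl.dependent]
        cols = list(dict.fromkeys(control + cond + [other]))
        y = keep[cl.dependent].to_numpy(float)
        _, p, _ = _pgls_t_p(y, design(cols), C0)
        claim_p[cl] = p

    Cstat, df, p_C = fishers_c(list(claim_p.values()))
    q = model.n_params() + (len(model.nodes) if size_control else 0)
    if n <= q + 1:
        raise ValueError(f"CICc undefined: n = {n} <= q + 1 = {q + 1}")
    cicc = Cstat + 2.0 * q * n / (n - 1.0 - q)

    rows = []
    tcrit = stats.t.ppf(0.975, max(n - 2, 1))
    for child in model.nodes:
        parents = sorted(model.graph.predecessors(child))
        if not parents:
            continue
        cols = list(dict.fromkeys(control + parents))
        y = keep[child].to_numpy(float)
        _, fit, _ = profile_lambda(y, design(cols), C0)
        sd_y = y.std(ddof=1)
        for j, parent in enumerate(cols):
            if parent not in parents:
                continue
            sd_x = keep[parent].to_numpy(float).std(ddof=1)
            b = fit.coefficients[1 + j] * sd_x / sd_y
            se = fit.standard_errors[1 + j] * sd_x / sd_y
            rows.append(
                {
                    "child": child,
                    "parent": parent,
                    "std_coef": b,
                    "se_std": se,
                    "ci_low": b - tcrit * se,
                    "ci_high": b + tcrit * se,
                }
            )
    edges = pd.DataFrame(rows, columns=["child", "parent", "std_coef", "se_std", "ci_low", "ci_high"])
    return PathFit(
        model=model,
        claim_p=claim_p,
        C=Cstat,
        df=df,
        p_C=p_C,
        q=q,
        n=n,
        cicc=cicc,
        edges=edges,
    )


def rank_models(fits: list[PathFit]) -> pd.DataFrame:
    """Ranked table: C, df, p, q, CICc, Delta-CICc and CICc weights."""
    df = pd.DataFrame(
        {
            "model": [f.model.name for f in fits],
            "C": [f.C for f in fits],
            "df": [f.df for f in fits],
            "p_C": [f.p_C for f in fits],
            "q": [f.q for f in fits],
            "CICc": [f.cicc for f in fits],
        }
    ).sort_values("CICc", ignore_index=True)
    df["delta_CICc"] = df["CICc"] - df["CICc"].iloc[0]
    w = np.exp(-0.5 * df["delta_CICc"])
    df["weight"] = w / w.sum()
    return df


def average_models(
    fits: list[PathFit], delta: float = 2.0, weighted: bool = False
) -> pd.DataFrame:
    """Average edge coefficients over models with Delta-CICc <= delta.

    Conditional averaging: each edge is averaged over the retained models
    that contain it.  With `weighted=True`, CICc weights (renormalized over
    the retained set, then over the models carrying each edge) are used.
    """
    if not fits:
        raise ValueError("no fits to average")
    ciccs = np.array([f.cicc for f in fits])
    keep = [f for f, c in zip(fits, ciccs) if c - ciccs.min() <= delta]
    w = np.exp(-0.5 * (np.array([f.cicc for f in keep]) - ciccs.min()))
    w = w / w.sum()
    acc: dict[tuple[str, str], list] = {}
    for f, wi in zip(keep, w):
        for _, row in f.edges.iterrows():
            key = (row["child"], row["parent"])
            acc.setdefault(key, []).append((wi, row))
    out = []
    for (child, parent), items in sorted(acc.items()):
        ws = np.array([wi for wi, _ in items])
        ws = ws / ws.sum() if weighted else np.full(len(items), 1.0 / len(items))
        coef = float(sum(wi * r["std_coef"] for wi, (_, r) in zip(ws, items)))
        lo = float(sum(wi * r["ci_low"] for wi, (_, r) in zip(ws, items)))
        hi = float(sum(wi * r["ci_high"] for wi, (_, r) in zip(ws, items)))
        out.append(
            {
                "child": child,
                "parent": parent,
                "std_coef": coef,
                "ci_low": lo,
                "ci_high": hi,
                "n_models": len(items),
            }
        )
    return pd.DataFrame(out)


def read_model_set(path_or_text: str) -> list[PathModel]:
    """Parse a plain-text candidate set.

    Format: `[model_name]` headers, then one `child <- parent1 + parent2`
    line per child; `#` starts a comment.
    """
    import os

    if os.path.exists(path_or_text):
        with open(path_or_text) as fh:
            text = fh.read()
    else:
        text = path_or_text
    models: list[PathModel] = []
    name = None
    edges: list[tuple[str, str]] = []
    for raw in text.splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if line.startswith("[") and line.endswith("]"):
            if name is not None:
                models.append(PathModel(name, edges))
            name = line[1:-1].strip()
            edges = []
            continue
        if "<-" not in line:
            raise ValueError(f"cannot parse model line: {raw!r}")
        child, _, rhs = line.partition("<-")
        child = child.strip()
        for parent in rhs.split("+"):
            parent = parent.strip()
            if parent:
                edges.append((parent, child))
    if name is not None:
        models.append(PathModel(name, edges))
    if not models:
        raise ValueError("no models found")
    return models


def bundled_model_set(which: str) -> list[PathModel]:
    """Load a shipped candidate set: 'climate8' or 'tissues28'."""
    from importlib import resources

    fname = {"climate8": "climate8.cfg", "tissues28": "tissues28.cfg"}[which]
    text = resources.files("phylocomp").joinpath("model_sets", fname).read_text()
    return read_model_set(text)
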