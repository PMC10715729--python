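"""Directional tests of correlated evolution between two binary traits.

The joint evolution of two binary characters is modeled as a 4-state
continuous-time Markov chain over (x, y) in {00, 01, 10, 11} in which only
one trait may change at an instant (dual-transition rates are 0).  Four
candidate models are compared by AIC:

    independent   x and y rates ignore the other trait          (k = 4)
    x_dep_on_y    x's gain/loss rates depend on the state of y  (k = 6)
    y_dep_on_x    y's rates depend on the state of x            (k = 6)
    mutual        all eight transition rates free               (k = 8)

Likelihoods come from Felsenstein pruning with per-branch transition
matrices obtained from the eigendecomposition of the generator; root state
frequencies are flat (1/4) by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

from .pgls import fit_pgls
from .phylo import Phylogeny

__all__ = [
    "MODELS",
    "PagelFit",
    "build_generator",
    "pagel_likelihood",
    "fit_directional",
    "binarize_residual",
    "binarize_mean_split",
    "PrunedTree",
]

# free-parameter layout of the full 8-rate vector:
# [qx01|y0, qx10|y0, qx01|y1, qx10|y1, qy01|x0, qy10|x0, qy01|x1, qy10|x1]
_PARAM_MAPS = {
    "independent": [0, 1, 0, 1, 2, 3, 2, 3],
    "x_dep_on_y": [0, 1, 2, 3, 4, 5, 4, 5],
    "y_dep_on_x": [0, 1, 0, 1, 2, 3, 4, 5],
    "mutual": [0, 1, 2, 3, 4, 5, 6, 7],
}
MODELS = tuple(_PARAM_MAPS)


def expand_rates(model: str, params: np.ndarray) -> np.ndarray:
    """Map a model's free parameters onto the full 8-rate vector."""
    try:
        mapping = _PARAM_MAPS[model]
    except KeyError:
        raise ValueError(f"unknown model {model!r}; choose from {MODELS}") from None
    params = np.asarray(params, dtype=float)
    if params.size != n_params(model):
        raise ValueError(f"{model} needs {n_params(model)} rates, got {params.size}")
    return params[mapping]


def n_params(model: str) -> int:
    return len(set(_PARAM_MAPS[model]))


def build_generator(rates8: np.ndarray) -> np.ndarray:
    """4x4 generator over states (00, 01, 10, 11); one change per instant."""
    r = np.asarray(rates8, dtype=float)
    if r.size != 8 or np.any(r < 0) or not np.all(np.isfinite(r)):
        raise ValueError("need 8 finite nonnegative rates")
    qx01_y0, qx10_y0, qx01_y1, qx10_y1, qy01_x0, qy10_x0, qy01_x1, qy10_x1 = r
    Q = np.zeros((4, 4))
    Q[0, 2] = qx01_y0  # 00 -> 10
    Q[0, 1] = qy01_x0  # 00 -> 01
    Q[1, 3] = qx01_y1  # 01 -> 11
    Q[1, 0] = qy10_x0  # 01 -> 00
    Q[2, 0] = qx10_y0  # 10 -> 00
    Q[2, 3] = qy01_x1  # 10 -> 11
    Q[3, 1] = qx10_y1  # 11 -> 01
    Q[3, 2] = qy10_x1  # 11 -> 10
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q


class PrunedTree:
    """Postorder array view of a phylogeny for fast pruning likelihoods."""

    def __init__(self, phy: Phylogeny, species: list[str] | None = None):
        tree = phy.tree
        if species is not None:
            phy = phy.prune_to(species)
            tree = phy.tree
        nodes = list(tree.postorder_node_iter())
        index = {id(nd): i for i, nd in enumerate(nodes)}
        self.n_nodes = len(nodes)
        self.tip_index: dict[str, int] = {}
        self.children: list[list[tuple[int, float]]] = [[] for _ in nodes]
        for nd in nodes:
            i = index[id(nd)]
            if nd.is_leaf():
                self.tip_index[nd.taxon.label] = i
            for ch in nd.child_nodes():
                self.children[i].append((index[id(ch)], float(ch.edge.length or 0.0)))
        self.root = index[id(tree.seed_node)]
        self.branch_lengths = np.array(
            [bl for kids in self.children for (_, bl) in kids]
        )
        self.taxa = list(phy.taxa)


def _transition_matrices(Q: np.ndarray, lengths: np.ndarray) -> np.ndarray:
    """P(t) = expm(Q t) for every branch length, via one eigendecomposition."""
    d, U = np.linalg.eig(Q)
    try:
        Uinv = np.linalg.inv(U)
    except np.linalg.LinAlgError:
        from scipy.linalg import expm

        return np.stack([expm(Q * t) for t in lengths])
    E = np.exp(np.outer(lengths, d))  # (B, k)
    P = np.einsum("ik,bk,kj->bij", U, E, Uinv)
    P = np.real(P)
    np.clip(P, 0.0, None, out=P)
    return P


def _pruning_loglik(
    pt: PrunedTree,
    Q: np.ndarray,
    tip_states: dict[str, int],
    root_freq: np.ndarray,
) -> float:
    k = Q.shape[0]
    # flatten branch list in the same order as pt.branch_lengths
    P = _transition_matrices(Q, pt.branch_lengths)
    L = np.zeros((pt.n_nodes, k))
    for label, i in pt.tip_index.items():
        s = tip_states[label]
        if s < 0:  # missing: ambiguous tip
            L[i] = 1.0
        else:
            L[i, s] = 1.0
    log_scale = 0.0
    b = 0
    for i, kids in enumerate(pt.children):
        if not kids:
            b += 0
            continue
        acc = np.ones(k)
        for child_idx, _ in kids:
            acc = acc * (P[b] @ L[child_idx])
            b += 1
        m = acc.max()
        if m <= 0:
            return -np.inf
        L[i] = acc / m
        log_scale += np.log(m)
    lik = float(root_freq @ L[pt.root])
    if lik <= 0:
        return -np.inf
    return float(np.log(lik) + log_scale)


def pagel_likelihood(
    x: np.ndarray,
    y: np.ndarray,
    tree: Phylogeny | PrunedTree,
    model: str,
    rates: np.ndarray,
    species: list[str] | None = None,
    root: str = "flat",
) -> float:
    """Log-likelihood of the joint binary data under one candidate model."""
    pt = tree if isinstance(tree, PrunedTree) else PrunedTree(tree, species)
    if species is None:
        species = pt.taxa
    x = np.asarray(x).astype(int)
    y = np.asarray(y).astype(int)
    states = {sp: 2 * xi + yi for sp, xi, yi in zip(species, x, y)}
    Q = build_generator(expand_rates(model, rates))
    if root == "flat":
        freq = np.full(4, 0.25)
    elif root == "stationary":
        freq = _stationary(Q)
    else:
        raise ValueError("root must be 'flat' or 'stationary'")
    return _pruning_loglik(pt, Q, states, freq)


def _stationary(Q: np.ndarray) -> np.ndarray:
    A = np.vstack([Q.T, np.ones(4)])
    b = np.concatenate([np.zeros(4), [1.0]])
    pi, *_ = np.linalg.lstsq(A, b, rcond=None)
    return np.clip(pi, 1e-12, None) / np.clip(pi, 1e-12, None).sum()


@dataclass
class PagelFit:
    model: str
    rates: np.ndarray  # full 8-rate vector at the optimum
    log_likelihood: float
    k: int
    aic: float
    converged: bool
    n_restarts: int
    delta_aic: float = np.nan
    w_aic: float = np.nan


def _compress_rates(model: str, rates8: np.ndarray) -> np.ndarray:
    """Project a full 8-rate vector onto a model's free parameters."""
    mapping = _PARAM_MAPS[model]
    out = np.empty(n_params(model))
    for i in range(out.size):
        out[i] = rates8[mapping.index(i)]
    return out


def _fit_one(
    pt: PrunedTree,
    states_x: np.ndarray,
    states_y: np.ndarray,
    species: list[str],
    model: str,
    seed: int,
    n_starts: int = 5,
    root: str = "flat",
    warm_starts: list[np.ndarray] | None = None,
) -> PagelFit:
    k = n_params(model)
    tree_len = float(pt.branch_lengths.sum())
    base_rate = max(1.0 / tree_len, 1e-4)
    rng = np.random.default_rng(seed)
    bounds = [(np.log(1e-6 * base_rate), np.log(1e4 * base_rate))] * k

    def nll(log_rates: np.ndarray) -> float:
        ll = pagel_likelihood(
            states_x, states_y, pt, model, np.exp(log_rates), species=species, root=root
        )
        return -ll if np.isfinite(ll) else 1e10

    starts = [np.full(k, np.log(base_rate * 2))]
    for w in warm_starts or []:
        starts.append(np.log(np.clip(_compress_rates(model, w), 1e-6 * base_rate, None)))
    while len(starts) < n_starts + len(warm_starts or []):
        starts.append(np.log(base_rate * 2) + rng.normal(0, 1.5, size=k))

    best = None
    n_done = 0
    for x0 in starts:
        x0 = np.clip(x0, bounds[0][0], bounds[0][1])
        res = optimize.minimize(
            nll, x0, method="L-BFGS-B", bounds=bounds, options={"maxiter": 300}
        )
        n_done += 1
        if best is None or res.fun < best.fun:
            best = res
    ll = -best.fun
    aic = -2.0 * ll + 2.0 * k
    return PagelFit(
        model=model,
        rates=expand_rates(model, np.exp(best.x)),
        log_likelihood=ll,
        k=k,
        aic=aic,
        converged=bool(best.success),
        n_restarts=n_done,
    )


def fit_directional(
    x,
    y,
    tree: Phylogeny,
    species: list[str] | None = None,
    seed: int | None = None,
    n_starts: int = 5,
    root: str = "flat",
) -> list[PagelFit]:
    """Fit all four dependency models and rank them by AIC.

    Returns fits sorted by AIC with delta-AIC and Akaike weights filled in.
    """
    x = np.asarray(x).astype(int)
    y = np.asarray(y).astype(int)
    if x.min() == x.max() or y.min() == y.max():
        raise ValueError("both traits must vary across species")
    pt = PrunedTree(tree, species)
    if species is None:
        species = pt.taxa
    ss = np.random.SeedSequence(seed).spawn(len(MODELS))
    seeds = [int(s.generate_state(1)[0] % 2**31) for s in ss]
    # nested warm starts: each model also begins from the optima of its
    # submodels, so optima respect the nesting ordering
    fits: dict[str, PagelFit] = {}
    fits["independent"] = _fit_one(
        pt, x, y, species, "independent", seeds[0], n_starts=n_starts, root=root
    )
    for m, sd in zip(("x_dep_on_y", "y_dep_on_x"), seeds[1:3]):
        fits[m] = _fit_one(
            pt, x, y, species, m, sd, n_starts=n_starts, root=root,
            warm_starts=[fits["independent"].rates],
        )
    fits["mutual"] = _fit_one(
        pt, x, y, species, "mutual", seeds[3], n_starts=n_starts, root=root,
        warm_starts=[fits["independent"].rates, fits["x_dep_on_y"].rates,
                     fits["y_dep_on_x"].rates],
    )
    fits = list(fits.values())
    aics = np.array([f.aic for f in fits])
    deltas = aics - aics.min()
    w = np.exp(-0.5 * deltas)
    w = w / w.sum()
    for f, d, wi in zip(fits, deltas, w):
        f.delta_aic = float(d)
        f.w_aic = float(wi)
    return sorted(fits, key=lambda f: f.aic)


def binarize_residual(
    trait,
    size,
    tree: Phylogeny,
    species: list[str] | None = None,
) -> np.ndarray:
    """1 where the lambda-ML PGLS residual of log trait on log size is
    positive ('relatively large'), else 0; zero residuals warn."""
    trait = np.asarray(trait, float)
    size = np.asarray(size, float)
    if np.any(trait <= 0) or np.any(size <= 0):
        raise ValueError("trait and size must be positive")
    if species is None:
        species = list(tree.taxa)
    table = pd.DataFrame(
        {"species": species, "lt": np.log(trait), "ls": np.log(size)}
    )
    res = fit_pgls(table, "lt ~ ls", tree, n_boot=0)
    resid = res.fit.residuals
    tol = 1e-10 * max(1.0, float(np.max(np.abs(res.fit.fitted))))
    zero = np.abs(resid) <= tol
    if np.any(zero):
        import warnings

        warnings.warn("residuals of 0 assigned to state 0", stacklevel=2)
    return ((resid > 0) & ~zero).astype(int)


def binarize_mean_split(values) -> np.ndarray:
    """1 ('short') where the value lies below the mean, else 0 ('long')."""
    v = np.asarray(values, float)
    return (v < v.mean()).astype(int)
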