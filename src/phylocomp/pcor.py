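"""Phylogenetic pairwise partial correlations between tissues.

Trait correlations are taken from the evolutionary (phylogenetic) trait
variance-covariance matrix estimated about the GLS phylogenetic mean under
Brownian motion (lambda = 1), then combined into first-order partial
correlations controlling for body size:

    r_xy.z = (r_xy - r_xz r_yz) / sqrt((1 - r_xz^2)(1 - r_yz^2))

with t = r sqrt(df) / sqrt(1 - r^2) at df = n - 3 (two focal traits and
one control beyond the mean) and CIs from the Fisher z-transform.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd
from scipy import linalg, stats

from .pgls import r_ci, t_from_r
from .phylo import PhyloCovariance, Phylogeny, apply_lambda, phylo_covariance

__all__ = ["phylo_trait_vcv", "partial_r", "all_pairwise_partials"]


def phylo_trait_vcv(
    traits: pd.DataFrame,
    tree: Phylogeny,
    lam: float = 1.0,
    species: list[str] | None = None,
) -> tuple[pd.DataFrame, pd.Series]:
    """Evolutionary trait covariance about the phylogenetic mean.

    Returns (covariance DataFrame, GLS phylogenetic means).  ML
    normalization (divide by n) so a star phylogeny reproduces the plain
    ML sample covariance.
    """
    if species is None:
        species = list(traits.index) if traits.index.dtype == object else list(tree.taxa)
    if len(traits) < 3:
        raise ValueError("need at least 3 species")
    X = traits.to_numpy(float)
    names = list(traits.columns)
    if np.any(X.std(axis=0) == 0):
        flat = [names[j] for j in range(len(names)) if X[:, j].std() == 0]
        raise ValueError(f"zero-variance traits: {flat}")
    C = apply_lambda(phylo_covariance(tree, species), lam)
    L = linalg.cholesky(C.matrix, lower=True)
    ones = np.ones(len(species))
    ow = linalg.solve_triangular(L, ones, lower=True)
    Xw = linalg.solve_triangular(L, X, lower=True)
    anc = (ow @ Xw) / (ow @ ow)  # GLS phylogenetic mean per trait
    Ew = Xw - np.outer(ow, anc)
    V = (Ew.T @ Ew) / len(species)
    return (
        pd.DataFrame(V, index=names, columns=names),
        pd.Series(anc, index=names, name="phylo_mean"),
    )


def cov2cor(V: pd.DataFrame | np.ndarray) -> pd.DataFrame | np.ndarray:
    A = np.asarray(V, float)
    d = np.sqrt(np.diag(A))
    R = A / np.outer(d, d)
    np.fill_diagonal(R, 1.0)
    if isinstance(V, pd.DataFrame):
        return pd.DataFrame(R, index=V.index, columns=V.columns)
    return R


def partial_r(r_xy: float, r_xz: float, r_yz: float) -> float:
    """First-order partial correlation of x and y controlling for z."""
    for name, val in (("r_xz", r_xz), ("r_yz", r_yz)):
        if abs(val) >= 1.0:
            raise ValueError(f"degenerate control: |{name}| >= 1")
    num = r_xy - r_xz * r_yz
    den = np.sqrt((1.0 - r_xz**2) * (1.0 - r_yz**2))
    out = float(num / den)
    return float(np.clip(out, -1.0, 1.0))


def all_pairwise_partials(
    table: pd.DataFrame,
    tissues: list[str],
    tree: Phylogeny,
    control: str = "log_svl",
    lam: float = 1.0,
) -> pd.DataFrame:
    """Partial correlations for every unordered tissue pair, controlling
    for `control` (body size) and phylogeny.

    `table` must carry a `species` column matching tree tips.  Returns one
    row per pair with r, t, df, p and the Fisher-z 95% CI.
    """
    if control not in table.columns:
        raise ValueError(f"control column {control!r} missing")
    if "species" not in table.columns:
        raise ValueError("trait table needs a 'species' column")
    keep = table[table["species"].isin(set(tree.taxa))]
    sub = tree.prune_to(list(keep["species"])) if len(keep) < tree.n_taxa else tree
    order = {sp: i for i, sp in enumerate(sub.taxa)}
    keep = keep.sort_values("species", key=lambda s: s.map(order)).reset_index(drop=True)
    n = len(keep)
    df = n - 3
    rows = []
    for x, y in combinations(tissues, 2):
        V, _ = phylo_trait_vcv(
            keep[[x, y, control]], sub, lam=lam, species=list(keep["species"])
        )
        R = cov2cor(V)
        r = partial_r(R.loc[x, y], R.loc[x, control], R.loc[y, control])
        t = t_from_r(r, df) if abs(r) < 1 else np.inf * np.sign(r)
        p = 2 * stats.t.sf(abs(t), df) if np.isfinite(t) else 0.0
        lo, hi = r_ci(r, df) if abs(r) < 1 else (np.nan, np.nan)
        rows.append(
            {
                "x": x,
                "y": y,
                "control": control,
                "r": r,
                "t": t,
                "df": df,
                "p": p,
                "ci_low": lo,
                "ci_high": hi,
            }
        )
    return pd.DataFrame(rows)
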