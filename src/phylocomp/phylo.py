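"""Tree handling, phylogenetic covariance and the GLS engine.

The phylogenetic covariance of a rooted tree with branch lengths assigns to
each pair of tips the total branch length shared by their root-to-tip paths
(the depth of their most recent common ancestor).  Under Brownian motion
this matrix is proportional to the expected trait covariance, and every
regression in this package is a generalized least-squares fit under a
(possibly lambda-rescaled) version of it.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field, replace

import dendropy
import numpy as np
from scipy import linalg

__all__ = [
    "Phylogeny",
    "PhyloCovariance",
    "GlsFit",
    "read_newick",
    "write_newick",
    "phylo_covariance",
    "apply_lambda",
    "gls_fit",
]


class NewickError(ValueError):
    """Raised when a Newick string cannot be parsed or lacks branch lengths."""


@dataclass
class Phylogeny:
    """A rooted phylogeny with branch lengths, wrapping a dendropy tree.

    Taxon labels must be unique; branch lengths must be present and
    nonnegative on every edge except the root edge.
    """

    tree: dendropy.Tree
    taxa: list[str] = field(init=False)

    def __post_init__(self) -> None:
        labels = [leaf.taxon.label for leaf in self.tree.leaf_node_iter()]
        if len(set(labels)) != len(labels):
            dupes = sorted({x for x in labels if labels.count(x) > 1})
            raise NewickError(f"duplicate taxon labels: {dupes}")
        for edge in self.tree.preorder_edge_iter():
            if edge.head_node is self.tree.seed_node:
                continue
            if edge.length is None:
                raise NewickError(
                    f"missing branch length on edge above "
                    f"{_node_label(edge.head_node)}"
                )
            if edge.length < 0:
                raise NewickError(
                    f"negative branch length ({edge.length}) above "
                    f"{_node_label(edge.head_node)}"
                )
        zero_tips = [
            leaf.taxon.label
            for leaf in self.tree.leaf_node_iter()
            if leaf.edge.length == 0
        ]
        if zero_tips:
            warnings.warn(
                f"zero-length terminal branches for {zero_tips}; "
                "lambda estimation may degenerate",
                stacklevel=3,
            )
        self.taxa = labels

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    def prune_to(self, taxa: list[str]) -> "Phylogeny":
        """Return the induced subtree on `taxa` (order of `taxa` ignored)."""
        missing = sorted(set(taxa) - set(self.taxa))
        if missing:
            raise KeyError(f"taxa not in tree: {missing}")
        sub = self.tree.extract_tree_with_taxa_labels(taxa)
        return Phylogeny(sub)

    def root_distances(self) -> dict[str, float]:
        self.tree.calc_node_root_distances()
        return {
            leaf.taxon.label: leaf.root_distance
            for leaf in self.tree.leaf_node_iter()
        }


def _node_label(node: dendropy.Node) -> str:
    if node.taxon is not None:
        return node.taxon.label
    return node.label or "<internal node>"


def read_newick(text: str) -> Phylogeny:
    """Parse a Newick string (branch lengths required) into a Phylogeny."""
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several error types
        raise NewickError(f"malformed Newick: {exc}") from exc
    if not any(tree.leaf_node_iter()):
        raise NewickError("tree has no leaves")
    return Phylogeny(tree)


def write_newick(phy: Phylogeny) -> str:
    out = io.StringIO()
    phy.tree.write(
        file=out,
        schema="newick",
        suppress_rooting=True,
        unquoted_underscores=True,
    )
    return out.getvalue().strip()


@dataclass
class PhyloCovariance:
    """Shared root-to-tip path lengths between taxa, with a Pagel lambda."""

    matrix: np.ndarray
    taxa: list[str]
    lam: float = 1.0

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = len(self.taxa)
        if self.matrix.shape != (n, n):
            raise ValueError("covariance shape does not match taxa")

    @property
    def n(self) -> int:
        return len(self.taxa)

    def reorder(self, taxa: list[str]) -> "PhyloCovariance":
        idx = [self.taxa.index(t) for t in taxa]
        return PhyloCovariance(self.matrix[np.ix_(idx, idx)], list(taxa), self.lam)


def phylo_covariance(phy: Phylogeny, taxa: list[str] | None = None) -> PhyloCovariance:
    """Brownian-motion covariance: C[i,j] = depth of the MRCA of tips i, j.

    Computed as (d_root(i) + d_root(j) - d_patristic(i,j)) / 2, which is
    exact for any rooted tree with branch lengths, ultrametric or not.
    """
    if taxa is None:
        taxa = list(phy.taxa)
    unknown = sorted(set(taxa) - set(phy.taxa))
    if unknown:
        raise KeyError(f"taxa not in tree: {unknown}")
    depths = phy.root_distances()
    n = len(taxa)
    C = np.zeros((n, n))
    if n == 1:
        C[0, 0] = depths[taxa[0]]
        return PhyloCovariance(C, list(taxa), 1.0)
    pdm = phy.tree.phylogenetic_distance_matrix()
    tax_by_label = {t.label: t for t in phy.tree.taxon_namespace}
    for i, a in enumerate(taxa):
        C[i, i] = depths[a]
        for j in range(i + 1, n):
            b = taxa[j]
            d = pdm.patristic_distance(tax_by_label[a], tax_by_label[b])
            C[i, j] = C[j, i] = 0.5 * (depths[a] + depths[b] - d)
    # guard against tiny negative round-off on shared paths
    C[np.abs(C) < 1e-12] = 0.0
    return PhyloCovariance(C, list(taxa), 1.0)


def apply_lambda(C: PhyloCovariance, lam: float) -> PhyloCovariance:
    """Multiply off-diagonal covariances by lambda, leaving the diagonal."""
    if not 0.0 <= lam <= 1.0:
        raise ValueError(f"lambda must be in [0, 1], got {lam}")
    M = C.matrix * lam
    np.fill_diagonal(M, np.diag(C.matrix))
    return PhyloCovariance(M, list(C.taxa), lam)


@dataclass
class GlsFit:
    """Generalized least-squares fit under a fixed covariance matrix."""

    coefficients: np.ndarray
    standard_errors: np.ndarray
    t_statistics: np.ndarray
    df: int
    sigma2: float  # ML residual rate
    log_likelihood: float
    fitted: np.ndarray
    residuals: np.ndarray
    names: list[str] | None = None

    @property
    def n(self) -> int:
        return len(self.fitted)


def gls_fit(
    y: np.ndarray,
    X: np.ndarray,
    C: PhyloCovariance | np.ndarray,
    names: list[str] | None = None,
) -> GlsFit:
    """Fit y = X b + e, e ~ N(0, sigma2 * C), by ML.

    Coefficients solve the generalized normal equations through a Cholesky
    factor of C (never an explicit inverse).  sigma2 is the ML estimate
    r' C^-1 r / n; standard errors use the df-corrected residual variance
    r' C^-1 r / (n - p) so that t = b / SE follows the usual t_(n-p) law.
    """
    V = C.matrix if isinstance(C, PhyloCovariance) else np.asarray(C, float)
    y = np.asarray(y, dtype=float).ravel()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != y.size:
        X = X.T
    n, p = X.shape
    if n != y.size or V.shape != (n, n):
        raise ValueError("y, X and C dimensions disagree")
    try:
        L = linalg.cholesky(V, lower=True)
    except linalg.LinAlgError as exc:
        raise linalg.LinAlgError(f"covariance not positive definite: {exc}") from exc
    yw = linalg.solve_triangular(L, y, lower=True)
    Xw = linalg.solve_triangular(L, X, lower=True)
    q, r = np.linalg.qr(Xw)
    if np.linalg.matrix_rank(r) < p:
        raise np.linalg.LinAlgError("design matrix is rank deficient")
    beta = linalg.solve_triangular(r, q.T @ yw)
    fitted = X @ beta
    resid = y - fitted
    rw = yw - Xw @ beta
    rss = float(rw @ rw)
    df = n - p
    sigma2_ml = rss / n
    sigma2_df = rss / df if df > 0 else np.nan
    XtX_inv = np.linalg.inv(r.T @ r)
    se = np.sqrt(np.maximum(np.diag(XtX_inv), 0.0) * sigma2_df)
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = np.where(se > 0, beta / se, np.inf * np.sign(beta))
    logdet = 2.0 * float(np.sum(np.log(np.diag(L))))
    if sigma2_ml > 0:
        ll = -0.5 * (n * np.log(2 * np.pi * sigma2_ml) + logdet + n)
    else:  # exact fit
        ll = np.inf
    return GlsFit(
        coefficients=beta,
        standard_errors=se,
        t_statistics=tstat,
        df=df,
        sigma2=sigma2_ml,
        log_likelihood=ll,
        fitted=fitted,
        residuals=resid,
        names=names,
    )


def align_tree_and_table(phy: Phylogeny, species: list[str]) -> tuple[Phylogeny, list[str]]:
    """Prune tree and trait rows to their common taxa, reporting drops.

    Returns the pruned tree and the retained species in tree leaf order.
    """
    common = [s for s in species if s in set(phy.taxa)]
    dropped_rows = len(species) - len(common)
    dropped_tips = phy.n_taxa - len(common)
    if not common:
        raise ValueError("no taxa shared between tree and trait table")
    if dropped_rows or dropped_tips:
        warnings.warn(
            f"alignment dropped {dropped_rows} trait rows and pruned "
            f"{dropped_tips} tree tips",
            stacklevel=2,
        )
    pruned = phy.prune_to(common) if dropped_tips else phy
    ordered = [t for t in pruned.taxa if t in set(common)]
    return pruned, ordered
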