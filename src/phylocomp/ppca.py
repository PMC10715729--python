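"""Phylogenetically informed principal component analysis.

The eigendecomposition is taken on the evolutionary trait covariance
(estimated about the GLS phylogenetic mean under Brownian motion), and
species scores are projections of the deviations from that phylogenetic
mean — so a star phylogeny reduces exactly to ordinary PCA on centered
data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .pcor import cov2cor, phylo_trait_vcv
from .phylo import Phylogeny

__all__ = ["PpcaResult", "fit_ppca"]


@dataclass
class PpcaResult:
    eigenvalues: np.ndarray
    percent_variance: np.ndarray
    loadings: pd.DataFrame  # trait x PC
    scores: pd.DataFrame  # species x PC
    mode: str

    @property
    def n_components(self) -> int:
        return len(self.eigenvalues)


def fit_ppca(
    traits: pd.DataFrame,
    tree: Phylogeny,
    species: list[str] | None = None,
    mode: str = "covariance",
    lam: float = 1.0,
) -> PpcaResult:
    """pPCA of (log) species-mean traits.

    mode="covariance" (default) decomposes the evolutionary covariance;
    mode="correlation" its correlation rescaling.  lam=1 corresponds to
    Brownian motion.  Sign convention: the largest-magnitude loading of
    each component is positive.
    """
    if mode not in ("covariance", "correlation"):
        raise ValueError("mode must be 'covariance' or 'correlation'")
    if len(traits) < 3 or traits.shape[1] < 2:
        raise ValueError("need >= 3 species and >= 2 traits")
    if mode == "correlation" and len(traits) < traits.shape[1]:
        import warnings

        warnings.warn("fewer species than traits in correlation mode", stacklevel=2)
    names = list(traits.columns)
    if species is None:
        species = list(tree.taxa)
    V, anc = phylo_trait_vcv(traits, tree, lam=lam, species=species)
    M = cov2cor(V).to_numpy() if mode == "correlation" else V.to_numpy()
    evals, evecs = np.linalg.eigh(M)
    order = np.argsort(evals)[::-1]
    evals = np.maximum(evals[order], 0.0)
    evecs = evecs[:, order]
    # deterministic sign: largest |loading| per column positive
    for j in range(evecs.shape[1]):
        k = int(np.argmax(np.abs(evecs[:, j])))
        if evecs[k, j] < 0:
            evecs[:, j] *= -1
    X = traits.to_numpy(float)
    dev = X - anc.to_numpy()
    if mode == "correlation":
        dev = dev / np.sqrt(np.diag(V.to_numpy()))
    scores = dev @ evecs
    pcs = [f"PC{j + 1}" for j in range(len(evals))]
    pct = 100.0 * evals / evals.sum()
    return PpcaResult(
        eigenvalues=evals,
        percent_variance=pct,
        loadings=pd.DataFrame(evecs, index=names, columns=pcs),
        scores=pd.DataFrame(scores, index=species, columns=pcs),
        mode=mode,
    )
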