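"""Aitchison compositional analysis of body-mass allocation.

Total body mass is partitioned into a five-part composition (brain, fat,
testes, hindlimb muscle, rest of body).  Log-ratio transforms come from
scikit-bio: clr for correlation-style analyses (keeps part identity,
components sum to 0) and ilr for full-rank multivariate models (isometric
map of the D-part simplex onto D-1 unconstrained coordinates).

`fit_mv_pgls` regresses the ilr coordinates on one predictor under a
common Pagel lambda, tests the multivariate effect with Pillai's trace and
a permutation p-value (Freedman-Lane residual permutation in the whitened
space), and back-transforms the coefficient vector onto the simplex, where
a zero effect corresponds to 1/D (= 0.20 for five parts) in every part.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats
from skbio.stats import composition as _skb

from .phylo import Phylogeny, apply_lambda, phylo_covariance

__all__ = [
    "close",
    "clr",
    "ilr",
    "ilr_inv",
    "body_composition",
    "MvPhyloFit",
    "fit_mv_pgls",
    "aitchison_distance",
]

FOCAL_PARTS = ["brain", "fat", "testes", "hindlimb", "rest"]


def _check_positive(x: np.ndarray, what: str = "composition") -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if np.any(x <= 0):
        idx = np.argwhere(x <= 0)
        raise ValueError(f"nonpositive part(s) in {what} at {idx.tolist()[:5]}")
    return x


def close(parts) -> np.ndarray:
    """Closure: rescale positive parts to proportions summing to 1."""
    return _skb.closure(_check_positive(parts))


def clr(x) -> np.ndarray:
    """Centered log-ratio transform; components sum to 0 per composition."""
    return _skb.clr(_check_positive(x))


def ilr(x) -> np.ndarray:
    """Isometric log-ratio transform to D-1 orthonormal coordinates."""
    return _skb.ilr(_check_positive(x))


def ilr_inv(y, parts: int | None = None) -> np.ndarray:
    """Inverse ilr: map D-1 coordinates back onto the D-part simplex.

    The zero vector maps to the uniform composition 1/D per part.
    """
    y = np.asarray(y, dtype=float)
    out = _skb.ilr_inv(y)
    if parts is not None and out.shape[-1] != parts:
        raise ValueError(f"expected {parts} parts, got {out.shape[-1]}")
    return out


def aitchison_distance(a, b) -> float:
    """Aitchison distance between two compositions (via clr)."""
    return float(np.linalg.norm(clr(a) - clr(b)))


def body_composition(
    table: pd.DataFrame,
    body_col: str = "body_mass",
    part_cols: tuple[str, ...] = ("brain", "fat", "testes", "hindlimb"),
    rest_name: str = "rest",
) -> pd.DataFrame:
    """Five-part closed composition per species.

    The residual part is total body mass minus the focal tissues; species
    whose focal tissues exceed body mass raise an error.
    """
    parts = table[list(part_cols)].to_numpy(float)
    rest = table[body_col].to_numpy(float) - parts.sum(axis=1)
    if np.any(rest <= 0):
        bad = table.loc[rest <= 0, "species"].tolist() if "species" in table else []
        raise ValueError(f"focal tissues exceed body mass for {bad}")
    full = np.column_stack([parts, rest])
    closed = close(full)
    out = pd.DataFrame(closed, columns=list(part_cols) + [rest_name])
    if "species" in table.columns:
        out.insert(0, "species", table["species"].to_numpy())
    return out


@dataclass
class MvPhyloFit:
    coef_ilr: np.ndarray  # (D-1,) slope vector in ilr space
    coef_simplex: np.ndarray  # (D,) back-transformed, sums to 1
    pillai: float
    xi2: float
    p_perm: float
    p_f: float
    lambda_hat: float
    n: int
    n_perm: int


def _mv_loglik(Yw: np.ndarray, Xw: np.ndarray, logdetC: float) -> float:
    n, p = Yw.shape
    B, *_ = np.linalg.lstsq(Xw, Yw, rcond=None)
    E = Yw - Xw @ B
    S = (E.T @ E) / n
    sign, logdetS = np.linalg.slogdet(S)
    if sign <= 0:
        return -np.inf
    return -0.5 * (n * logdetS + p * logdetC + n * p * (1 + np.log(2 * np.pi)))


def fit_mv_pgls(
    ilr_response: np.ndarray,
    predictor: np.ndarray,
    tree: Phylogeny,
    species: list[str] | None = None,
    n_perm: int = 999,
    seed: int | None = None,
) -> MvPhyloFit:
    """Multivariate phylogenetic regression of ilr coordinates on one
    predictor, with Pillai's trace and a permutation test.

    A single lambda is profiled for all coordinates jointly.  The
    permutation scheme permutes phylogeny-whitened residuals of the
    intercept-only model (Freedman-Lane), so the test is exact under the
    null of no predictor effect.
    """
    Y = np.atleast_2d(np.asarray(ilr_response, float))
    x = np.asarray(predictor, float).ravel()
    n, p = Y.shape
    if n <= p:
        raise ValueError(f"need n > number of ilr coordinates ({n} <= {p})")
    if not np.all(np.isfinite(x)):
        raise ValueError("predictor has non-finite values")
    if species is None:
        species = list(tree.taxa)
    C0 = phylo_covariance(tree, species)
    X = np.column_stack([np.ones(n), x])

    def whiten(lam: float):
        L = linalg.cholesky(apply_lambda(C0, lam).matrix, lower=True)
        Yw = linalg.solve_triangular(L, Y, lower=True)
        Xw = linalg.solve_triangular(L, X, lower=True)
        return Yw, Xw, 2.0 * float(np.sum(np.log(np.diag(L))))

    def nll(lam: float) -> float:
        return -_mv_loglik(*whiten(float(lam)))

    lams = np.linspace(0, 1, 21)
    vals = [nll(l) for l in lams]
    k = int(np.argmin(vals))
    res = optimize.minimize_scalar(
        nll, bounds=(lams[max(k - 1, 0)], lams[min(k + 1, 20)]), method="bounded"
    )
    lam_hat = float(res.x) if res.fun <= vals[k] else float(lams[k])

    Yw, Xw, _ = whiten(lam_hat)
    B, *_ = np.linalg.lstsq(Xw, Yw, rcond=None)
    coef_ilr = B[1]

    def pillai_of(Ywm: np.ndarray) -> float:
        Bf, *_ = np.linalg.lstsq(Xw, Ywm, rcond=None)
        Ef = Ywm - Xw @ Bf
        x0 = Xw[:, :1]
        B0, *_ = np.linalg.lstsq(x0, Ywm, rcond=None)
        E0 = Ywm - x0 @ B0
        Emat = Ef.T @ Ef
        H = E0.T @ E0 - Emat
        T = H + Emat
        try:
            sol = np.linalg.solve(T, H)
        except np.linalg.LinAlgError:
            sol = np.linalg.pinv(T) @ H  # degenerate exact fits
        return float(np.trace(sol))

    V = pillai_of(Yw)

    # permutation of whitened reduced-model residuals
    x0 = Xw[:, :1]
    B0, *_ = np.linalg.lstsq(x0, Yw, rcond=None)
    fit0 = x0 @ B0
    R0 = Yw - fit0
    rng = np.random.default_rng(seed)
    perm_stats = np.empty(n_perm)
    for i in range(n_perm):
        Yp = fit0 + R0[rng.permutation(n)]
        perm_stats[i] = pillai_of(Yp)
    p_perm = (1 + np.sum(perm_stats >= V - 1e-12)) / (n_perm + 1)
    mean_null = float(perm_stats.mean()) if n_perm else 0.0
    xi2 = float((V - mean_null) / (1 - mean_null)) if mean_null < 1 else np.nan

    # Pillai F-approximation for reference
    q_h = 1  # hypothesis rank (one predictor)
    s = min(q_h, p)
    m = (abs(p - q_h) - 1) / 2
    n2 = (n - X.shape[1] - p - 1) / 2
    df1 = s * (2 * m + s + 1)
    df2 = s * (2 * n2 + s + 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        F = (V / (s - V)) * (df2 / df1) if s > V else np.inf
    p_f = float(stats.f.sf(F, df1, df2)) if np.isfinite(F) else 0.0

    coef_simplex = ilr_inv(coef_ilr, parts=p + 1)
    return MvPhyloFit(
        coef_ilr=coef_ilr,
        coef_simplex=coef_simplex,
        pillai=V,
        xi2=xi2,
        p_perm=float(p_perm),
        p_f=p_f,
        lambda_hat=lam_hat,
        n=n,
        n_perm=n_perm,
    )
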