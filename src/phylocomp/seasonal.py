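"""Repeatability of repeated measures and symmetric percent change.

Repeatability (intraclass correlation) is the between-group share of the
total variance in a Gaussian one-way random-effects model,
R = sigma2_between / (sigma2_between + sigma2_within), with variance
components estimated by REML and a parametric-bootstrap CI.

Pre/post tissue comparisons use the symmetric log percent change
100 * ln(post / pre): zero when nothing changes, equal magnitude and
opposite sign for halving vs doubling, and additive across multiplicative
stages.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = ["RepeatabilityResult", "PercentChange", "repeatability", "percent_change"]


@dataclass
class RepeatabilityResult:
    R: float
    ci: tuple[float, float]
    sigma2_between: float
    sigma2_within: float
    n_groups: int
    n_obs: int
    n_boot: int


def _anova_components(values: np.ndarray, groups: np.ndarray) -> tuple[float, float]:
    """Method-of-moments one-way variance components (handles imbalance)."""
    labels, inv, counts = np.unique(groups, return_inverse=True, return_counts=True)
    N, k = values.size, labels.size
    means = np.bincount(inv, weights=values) / counts
    ssw = float(np.sum((values - means[inv]) ** 2))
    grand = values.mean()
    ssb = float(np.sum(counts * (means - grand) ** 2))
    msw = ssw / max(N - k, 1)
    msb = ssb / max(k - 1, 1)
    n0 = (N - np.sum(counts**2) / N) / max(k - 1, 1)
    s2b = max((msb - msw) / n0, 0.0)
    return s2b, max(msw, 1e-12)


def _fit_components(values: np.ndarray, groups: np.ndarray) -> tuple[float, float]:
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = sm.MixedLM(values, np.ones((values.size, 1)), groups=groups)
            fit = model.fit(reml=True, method="lbfgs")
        s2b = float(np.asarray(fit.cov_re)[0, 0])
        s2w = float(fit.scale)
        if not (np.isfinite(s2b) and np.isfinite(s2w)):
            raise np.linalg.LinAlgError
        return max(s2b, 0.0), max(s2w, 1e-12)
    except (np.linalg.LinAlgError, ValueError):
        # REML degenerates when the between-group variance is ~0
        return _anova_components(values, groups)


def repeatability(
    values,
    groups,
    n_boot: int = 1000,
    seed: int | None = None,
) -> RepeatabilityResult:
    """Intraclass correlation R with a parametric-bootstrap 95% CI.

    `groups` labels repeated measures of the same unit (species, year
    replicate...).  Needs >= 2 groups and replication within at least one
    group.
    """
    v = np.asarray(values, dtype=float)
    g = np.asarray(groups)
    labels, counts = np.unique(g, return_counts=True)
    if labels.size < 2:
        raise ValueError("need at least 2 groups")
    if counts.max() < 2:
        raise ValueError("all groups are singletons; R is unidentifiable")
    s2b, s2w = _fit_components(v, g)
    R = s2b / (s2b + s2w)

    lo = hi = np.nan
    if n_boot > 0:
        rng = np.random.default_rng(seed)
        draws = np.empty(n_boot)
        mu = v.mean()
        for i in range(n_boot):
            b = rng.normal(0.0, np.sqrt(s2b), size=labels.size)
            effect = dict(zip(labels, b))
            sim = mu + np.array([effect[k] for k in g]) + rng.normal(
                0.0, np.sqrt(s2w), size=v.size
            )
            bb, ww = _fit_components(sim, g)
            draws[i] = bb / (bb + ww)
        lo, hi = np.percentile(draws, [2.5, 97.5])
    return RepeatabilityResult(
        R=float(R),
        ci=(float(lo), float(hi)),
        sigma2_between=s2b,
        sigma2_within=s2w,
        n_groups=int(labels.size),
        n_obs=int(v.size),
        n_boot=n_boot,
    )


@dataclass
class PercentChange:
    per_species: pd.Series  # 100 * ln(post/pre)
    mean: float
    ci: tuple[float, float]
    ratio: float  # back-transformed mean multiplicative change

    @property
    def n(self) -> int:
        return len(self.per_species)


def percent_change(pre, post, index=None, level: float = 0.95) -> PercentChange:
    """Symmetric percent change 100 * ln(post/pre) with a t-interval mean."""
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if np.any(pre <= 0) or np.any(post <= 0):
        raise ValueError("pre and post masses must be positive")
    if pre.shape != post.shape:
        raise ValueError("pre and post differ in length")
    delta = 100.0 * np.log(post / pre)
    ser = pd.Series(delta, index=index)
    m = float(delta.mean())
    if delta.size > 1:
        se = delta.std(ddof=1) / np.sqrt(delta.size)
        tcrit = stats.t.ppf(0.5 + level / 2, delta.size - 1)
        ci = (m - tcrit * se, m + tcrit * se)
    else:
        ci = (np.nan, np.nan)
    return PercentChange(per_species=ser, mean=m, ci=ci, ratio=float(np.exp(m / 100.0)))
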