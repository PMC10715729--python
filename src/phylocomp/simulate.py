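"""Synthetic data with the statistical structure the analyses assume.

Every generator is a pure function of its arguments and a seed: pure-birth
(Yule) trees, multivariate trait evolution with per-trait Pagel lambda and
allometric scaling on snout-vent length, seasonal sinusoidal daily
temperatures with AR(1) noise, and joint binary-trait evolution under the
four dependency models of the Pagel framework.

The `paper_scale` preset mirrors the nesting of the study system this
package targets: 116 species with tissue masses, 50 of them with pre- and
post-brumation pairs, 43 with breeding data and 30 with field-validated
activity thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg

from .climate import TemperatureSeries
from .pagel import MODELS, build_generator, expand_rates
from .phylo import Phylogeny, PhyloCovariance, apply_lambda, phylo_covariance, read_newick

__all__ = [
    "simulate_tree",
    "simulate_bm",
    "TraitConfig",
    "simulate_traits",
    "simulate_temperatures",
    "simulate_binary_pair",
    "paper_scale",
]


# ---------------------------------------------------------------------------
# trees


class _Node:
    __slots__ = ("birth", "children", "length", "label")

    def __init__(self, birth: float):
        self.birth = birth
        self.children: list[_Node] = []
        self.length = 0.0
        self.label = ""


def simulate_tree(n_taxa: int, birth_rate: float = 1.0, seed: int | None = None) -> Phylogeny:
    """Pure-birth tree with `n_taxa` extant tips.

    Waiting times between speciations are Exp(k * birth_rate) with k the
    current number of lineages; a final Exp(n * birth_rate) stretch keeps
    terminal branches strictly positive.
    """
    if n_taxa < 2:
        raise ValueError("need at least 2 taxa")
    if birth_rate <= 0:
        raise ValueError("birth_rate must be positive")
    rng = np.random.default_rng(seed)
    t = 0.0
    root = _Node(0.0)
    active = [_Node(0.0), _Node(0.0)]
    root.children = list(active)
    while len(active) < n_taxa:
        k = len(active)
        t += rng.exponential(1.0 / (k * birth_rate))
        idx = rng.integers(k)
        node = active.pop(idx)
        node.length = t - node.birth
        kids = [_Node(t), _Node(t)]
        node.children = kids
        active.extend(kids)
    t += rng.exponential(1.0 / (n_taxa * birth_rate))
    labels = iter(f"sp{i + 1:03d}" for i in range(n_taxa))
    for node in active:
        node.length = t - node.birth
        node.label = next(labels)

    def newick(node: _Node) -> str:
        if not node.children:
            return f"{node.label}:{node.length:.10g}"
        inner = ",".join(newick(c) for c in node.children)
        return f"({inner}):{node.length:.10g}"

    text = "(" + ",".join(newick(c) for c in root.children) + ");"
    return read_newick(text)


def simulate_bm(
    C: PhyloCovariance,
    rng: np.random.Generator,
    sigma2: float = 1.0,
    lam: float = 1.0,
    root_value: float = 0.0,
) -> np.ndarray:
    """One Brownian (lambda-rescaled) trait on the tree covariance."""
    M = apply_lambda(C, lam).matrix * sigma2
    L = linalg.cholesky(M + 1e-12 * np.eye(len(M)), lower=True)
    return root_value + L @ rng.standard_normal(len(M))


# ---------------------------------------------------------------------------
# trait tables


@dataclass
class TraitConfig:
    """Evolutionary model for the species trait block.

    Slopes are allometric exponents on cubed SVL (1 = isometry);
    `correlation` is the evolutionary correlation matrix of the tissue
    deviations from allometry; `lam` the per-tissue Pagel lambda;
    `fractions` the rough share of body mass at the root SVL.
    """

    tissues: tuple[str, ...] = ("brain", "fat", "testes", "hindlimb", "gut")
    slopes: dict[str, float] = field(
        default_factory=lambda: {
            "brain": 0.49,
            "fat": 1.10,
            "testes": 1.00,
            "hindlimb": 1.10,
            "gut": 1.00,
        }
    )
    fractions: dict[str, float] = field(
        default_factory=lambda: {
            "brain": 0.004,
            "fat": 0.05,
            "testes": 0.01,
            "hindlimb": 0.15,
            "gut": 0.05,
        }
    )
    lam: dict[str, float] = field(
        default_factory=lambda: {
            "brain": 0.9,
            "fat": 0.6,
            "testes": 0.8,
            "hindlimb": 0.5,
            "gut": 0.5,
        }
    )
    correlation: np.ndarray | None = None  # tissue deviation correlations
    sigma_svl: float = 0.15  # BM rate of log SVL per unit depth
    sigma_dev: float = 0.25  # SD of tissue deviations at unit depth
    root_log_svl: float = np.log(45.0)  # mm


def simulate_traits(
    tree: Phylogeny,
    config: TraitConfig | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Species trait table: SVL (mm) and tissue masses (g) on natural scale.

    log SVL evolves as Brownian motion; each log tissue mass is its
    allometric slope times log SVL^3 plus a lambda-Brownian deviation with
    the configured cross-tissue correlation.  Body mass is the sum of all
    tissues plus an isometric 'other' remainder, so the five-part
    composition is always positive.
    """
    cfg = config or TraitConfig()
    C = phylo_covariance(tree)
    n = C.n
    rng = np.random.default_rng(seed)
    depth = float(np.mean(np.diag(C.matrix)))
    log_svl = simulate_bm(
        C, rng, sigma2=cfg.sigma_svl**2 / depth, root_value=cfg.root_log_svl
    )
    p = len(cfg.tissues)
    R = np.eye(p) if cfg.correlation is None else np.asarray(cfg.correlation, float)
    if not np.allclose(R, R.T) or np.any(np.linalg.eigvalsh(R) < -1e-10):
        raise ValueError("tissue correlation matrix must be symmetric PSD")
    A = linalg.cholesky(R + 1e-12 * np.eye(p), lower=True)
    Z = np.column_stack(
        [
            simulate_bm(C, rng, sigma2=1.0 / depth, lam=cfg.lam[tis])
            for tis in cfg.tissues
        ]
    )
    dev = cfg.sigma_dev * (Z @ A.T)
    size3 = 3.0 * log_svl
    mean_size3 = float(size3.mean())
    table = pd.DataFrame({"species": list(tree.taxa), "svl": np.exp(log_svl)})
    total = np.zeros(n)
    root_mass = np.exp(cfg.root_log_svl * 3) * 1e-3  # ~grams at root size
    for j, tis in enumerate(cfg.tissues):
        base = np.log(cfg.fractions[tis] * root_mass)
        logm = base + cfg.slopes[tis] * (size3 - mean_size3) + dev[:, j]
        table[tis] = np.exp(logm)
        total += table[tis].to_numpy()
    other = np.exp(np.log(root_mass * 0.73) + 1.0 * (size3 - mean_size3))
    table["other"] = other
    table["body_mass"] = total + other
    return table


# ---------------------------------------------------------------------------
# temperatures


def simulate_temperatures(
    site_id: str = "site1",
    years: tuple[int, ...] = (2012, 2013, 2014, 2015, 2016),
    mean: float = 12.0,
    amplitude: float = 12.0,
    noise_sd: float = 1.5,
    ar1: float = 0.7,
    phase_day: int = 105,
    seed: int | None = None,
) -> TemperatureSeries:
    """Daily mean temperatures: annual sinusoid plus AR(1) noise.

    temp(d) = mean + amplitude * sin(2 pi (doy - phase_day) / ndays); the
    default phase puts the coldest days in January (northern hemisphere).
    AR(1) noise produces realistic multi-day cold spells that exercise the
    5-day persistence rule of the brumation estimator.
    """
    dates, clean = [], []
    for year in years:
        start = np.datetime64(f"{year}-01-01", "D")
        stop = np.datetime64(f"{year + 1}-01-01", "D")
        days = np.arange(start, stop)
        doy = np.arange(1, days.size + 1)
        clean.append(mean + amplitude * np.sin(2 * np.pi * (doy - phase_day) / days.size))
        dates.append(days)
    dates = np.concatenate(dates)
    clean = np.concatenate(clean)
    rng = np.random.default_rng(seed)
    if noise_sd > 0:
        innov_sd = noise_sd * np.sqrt(1 - ar1**2)
        noise = np.empty(clean.size)
        noise[0] = rng.normal(0, noise_sd)
        eps = rng.normal(0, innov_sd, size=clean.size)
        for i in range(1, clean.size):
            noise[i] = ar1 * noise[i - 1] + eps[i]
    else:
        noise = np.zeros_like(clean)
    return TemperatureSeries(site_id=site_id, dates=dates, temps=clean + noise)


# ---------------------------------------------------------------------------
# discrete characters


def simulate_binary_pair(
    tree: Phylogeny,
    model: str,
    rates: np.ndarray,
    seed: int | None = None,
    root_state: int | None = None,
) -> pd.DataFrame:
    """Joint binary pair evolved tip-ward as a 4-state CTMC.

    `rates` holds the model's free parameters (see `phylocomp.pagel`);
    the root state is drawn uniformly unless given.  Returns a frame with
    species, x, y.
    """
    if model not in MODELS:
        raise ValueError(f"unknown model {model!r}; choose from {MODELS}")
    Q = build_generator(expand_rates(model, rates))
    rng = np.random.default_rng(seed)
    tree_obj = tree.tree
    states: dict[int, int] = {}
    root = tree_obj.seed_node
    states[id(root)] = int(rng.integers(4)) if root_state is None else int(root_state)
    out = {}
    for node in tree_obj.preorder_node_iter():
        if node is root:
            continue
        s = states[id(node.parent_node)]
        t_remaining = float(node.edge.length or 0.0)
        while True:
            out_rate = -Q[s, s]
            if out_rate <= 0:
                break
            wait = rng.exponential(1.0 / out_rate)
            if wait >= t_remaining:
                break
            t_remaining -= wait
            probs = np.clip(Q[s], 0, None)
            probs[s] = 0.0
            probs = probs / probs.sum()
            s = int(rng.choice(4, p=probs))
        states[id(node)] = s
        if node.is_leaf():
            out[node.taxon.label] = s
    species = list(tree.taxa)
    joint = np.array([out[sp] for sp in species])
    return pd.DataFrame({"species": species, "x": joint // 2, "y": joint % 2})


# ---------------------------------------------------------------------------
# full-study preset


def paper_scale(seed: int = 0) -> dict:
    """Synthetic study bundle at the scale of the target system.

    116 species on a Yule tree; tissue masses with allometry and
    phylogenetic signal; per-species activity thresholds and site
    temperature series (30 species flagged as field-validated); breeding
    season and aggregation data for 43 species; pre/post-brumation tissue
    pairs for 50 species; monthly climate normals per site.
    """
    rng = np.random.default_rng(seed)
    seeds = rng.integers(2**31, size=10)
    tree = simulate_tree(116, birth_rate=1.0, seed=int(seeds[0]))
    cfg = TraitConfig(
        correlation=np.array(
            [
                [1.0, -0.3, -0.3, 0.0, 0.0],
                [-0.3, 1.0, 0.1, 0.0, 0.2],
                [-0.3, 0.1, 1.0, -0.3, 0.0],
                [0.0, 0.0, -0.3, 1.0, 0.0],
                [0.0, 0.2, 0.0, 0.0, 1.0],
            ]
        )
    )
    traits = simulate_traits(tree, cfg, seed=int(seeds[1]))
    n = len(traits)
    species = list(traits["species"])

    C = phylo_covariance(tree)
    depth = float(np.mean(np.diag(C.matrix)))
    lat = 22.0 + 4.0 * simulate_bm(
        C, np.random.default_rng(int(seeds[2])), sigma2=1.0 / depth
    )
    site_mean = 24.0 - 0.55 * (lat - 22.0) + rng.normal(0, 0.5, n)
    site_amp = 8.0 + 0.9 * (lat - 22.0) + rng.normal(0, 0.5, n)

    thresholds = pd.DataFrame(
        {
            "species": species,
            "entry_c": np.round(rng.normal(10.0, 2.0, n), 1),
        }
    )
    thresholds["emergence_c"] = thresholds["entry_c"] + np.round(
        rng.normal(0.5, 0.3, n), 1
    )
    thresholds["field_validated"] = [True] * 30 + [False] * (n - 30)

    temp_series = {
        sp: simulate_temperatures(
            site_id=f"site_{sp}",
            mean=float(site_mean[i]),
            amplitude=float(max(site_amp[i], 1.0)),
            seed=int((seeds[3] + i) % 2**31),
        )
        for i, sp in enumerate(species)
    }

    months = np.arange(1, 13)
    climate = []
    for i, sp in enumerate(species):
        mtemp = site_mean[i] + site_amp[i] * np.sin(2 * np.pi * (months * 30.4 - 105) / 365)
        mprecip = np.clip(
            80 + 90 * np.sin(2 * np.pi * (months * 30.4 - 120) / 365)
            + rng.normal(0, 15, 12),
            0,
            None,
        )
        for m, t_, p_ in zip(months, mtemp, mprecip):
            climate.append(
                {"site": f"site_{sp}", "species": sp, "month": m,
                 "temp_c": t_, "precip_mm": p_}
            )
    climate = pd.DataFrame(climate)

    breeding_species = species[:43]
    season = np.clip(rng.normal(60, 25, 43), 5, 150)
    aggregation = (season < 60).astype(int)
    flip = rng.random(43) < 0.15
    aggregation[flip] = 1 - aggregation[flip]
    breeding = pd.DataFrame(
        {
            "species": breeding_species,
            "season_days": np.round(season, 0),
            "aggregation": aggregation,
        }
    )

    pre_species = species[:50]
    pre_rows = traits[traits["species"].isin(pre_species)].copy()
    change = {"brain": 0.0, "fat": -0.5, "testes": 0.3, "hindlimb": -0.1, "gut": -0.2}
    prepost = {"species": pre_species}
    for tis, lg in change.items():
        post = pre_rows[tis].to_numpy()
        pre = post * np.exp(-lg + rng.normal(0, 0.1, 50))
        prepost[f"{tis}_pre"] = pre
        prepost[f"{tis}_post"] = post
    prepost = pd.DataFrame(prepost)

    return {
        "tree": tree,
        "traits": traits,
        "latitude": pd.DataFrame({"species": species, "latitude": lat}),
        "thresholds": thresholds,
        "temperatures": temp_series,
        "climate": climate,
        "breeding": breeding,
        "prepost": prepost,
    }
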