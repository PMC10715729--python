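# phylocomp

Phylogenetic comparative analysis of cold-season dormancy (brumation) and
body-mass allocation in anurans — from temperature-threshold dormancy
estimation to phylogenetic regression, compositional MANOVA, confirmatory
path analysis and directional tests of correlated binary-trait evolution.

## Who this is for

Comparative biologists asking how the length of the inactive season shapes
investment in energetically expensive tissues (brain, body fat, testes,
hindlimb muscles) across species, while accounting for shared ancestry.
The package provides the full analytical chain as a tested Python library
with a thin CLI, plus a synthetic-data generator that reproduces the
statistical structure of such a study (a ~116-taxon tree, log-scale tissue
masses with phylogenetic signal and allometric scaling, seasonal daily
temperatures, binary breeding traits under Markov evolution), so every
stage is testable without any data download.

## What it computes

- **Brumation period** per species and year: the active season runs from
  the first ≥5-day run of daily means above the species' activity
  threshold to the last day before the terminal below-threshold run;
  brumation days = days in year − active days. Species averaging ≤27 days
  are classed non-brumating. Optional 2/4 °C threshold buffers emulate
  ground-microclimate buffering.
- **PGLS with Pagel's λ**: generalized least squares with residual
  covariance λ-scaled shared branch lengths, λ estimated by profile ML on
  [0, 1]; standardized coefficients and λ with parametric-bootstrap 95%
  CIs (100 replicates); effect sizes via r = t/√(t² + df).
- **Allometry** of log tissue mass on log SVL³ (snout–vent length cubed,
  so isometry ⇔ slope 1), classified steeper/shallower/proportionate by
  the bootstrap CI against 1.
- **Phylogenetic logistic regression** for binary outcomes (e.g. breeding
  aggregations), with tip correlations decaying in patristic distance at
  rate α and Firth-penalized estimation.
- **Partial correlations** r_xy·z = (r_xy − r_xz r_yz)/√((1−r_xz²)(1−r_yz²))
  from the evolutionary trait covariance (λ = 1), controlling for body
  size; t at df = n − 3, Fisher-z CIs.
- **Compositional analysis**: five-part Aitchison composition (brain,
  fat, testes, hindlimb, rest of body), clr/ilr transforms, multivariate
  phylogenetic regression with Pillai's trace, permutation p-value and
  inverse-ilr back-transformed coefficients (0.20 per part = no effect).
- **Phylogenetic PCA** on the evolutionary covariance with scores about
  the GLS phylogenetic mean.
- **Confirmatory path analysis**: d-separation basis sets, Fisher's
  C = −2Σln p, CICc = C + 2qn/(n − 1 − q), and coefficient averaging over
  models within ΔCICc ≤ 2 (two editable candidate sets ship as plain-text
  configs).
- **Directional tests** of correlated evolution between two binary traits
  (4-state Markov chain; independent/unilateral/mutual models compared by
  AIC weights), with the residual- and mean-split binarization rules.
- **Repeatability** (one-way random-effects ICC, REML) and the symmetric
  percent change 100·ln(post/pre) for pre/post-brumation comparisons.

## Worked example

```python
import numpy as np
from phylocomp import simulate, pgls, compositions

tree = simulate.simulate_tree(116, birth_rate=1.0, seed=42)
traits = simulate.simulate_traits(tree, seed=43)  # brain slope 0.49 by default

res = pgls.fit_allometry(
    traits["brain"].to_numpy(), traits["svl"].to_numpy(), tree,
    species=list(traits["species"]), n_boot=100, seed=0,
)
print(f"brain allometry: beta = {res.slope:.2f} "
      f"[{res.ci[0]:.2f}, {res.ci[1]:.2f}] -> {res.classification}, "
      f"lambda = {res.lambda_hat:.2f}")

comp = compositions.body_composition(traits)
parts = ["brain", "fat", "testes", "hindlimb", "rest"]
Y = compositions.ilr(comp[parts].to_numpy())
x = np.log(traits["svl"].to_numpy())
fit = compositions.fit_mv_pgls(Y, x, tree, species=list(traits["species"]),
                               n_perm=999, seed=1)
print(f"Pillai = {fit.pillai:.2f}, xi2 = {fit.xi2:.2f}, p = {fit.p_perm:.3f}")
```

prints

```
brain allometry: beta = 0.39 [0.27, 0.50] -> shallower, lambda = 0.85
Pillai = 0.43, xi2 = 0.41, p = 0.001
```

The brain slope estimate is well below 1 (negative allometry: brains grow
more slowly than body volume), and its bootstrap CI covers the generating
slope of 0.49. Log SVL genuinely shifts this synthetic composition, so
Pillai's trace is sizeable and the permutation p-value bottoms out at
1/(999 + 1).

The whole study pipeline runs from one config:

```sh
phylocomp simulate --preset paper --seed 1 --out data/
phylocomp run config.json          # writes one CSV per stage + report.txt
```

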