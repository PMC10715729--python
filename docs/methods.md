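# Methods

## Phylogenetic covariance and the GLS engine

All regressions assume a Gaussian model y = Xβ + ε with
Cov(ε) = σ²·C(λ), where C is the matrix of shared root-to-tip path
lengths of the (possibly non-ultrametric) input tree and C(λ) multiplies
the off-diagonals by Pagel's λ ∈ [0, 1] (λ = 0: star phylogeny /
independence; λ = 1: Brownian motion). Entries are computed as
(d_root(i) + d_root(j) − d_ij)/2 from root distances and patristic
distances, which is exact for any rooted tree with branch lengths.
Trees are used as given — no height standardization — because the source
trees for this kind of analysis typically omit time calibration.

Fits go through a Cholesky factor of C (never an explicit inverse) and a
QR solve of the whitened system, for stability on near-singular
ultrametric covariances. σ² is estimated by ML (r'C⁻¹r/n), the likelihood
convention used throughout so that λ-profiling and AIC comparisons are
coherent; standard errors use the df-corrected residual variance
(df = n − p, matching the t_114/t_113 bookkeeping at n = 116 with one or
two predictors). Polytomies are accepted as-is; zero-length terminal
branches raise a warning because λ estimation can degenerate there.
Trees and trait tables are aligned by pruning to the intersection of taxa
(the `species` column must match tip labels exactly), with dropped counts
reported.

λ̂ maximizes the profile likelihood on a 21-point grid followed by bounded
scalar refinement between the neighbouring grid points, with a snap to the
0/1 boundary when indistinguishable; the grid step bounds the bracketing
error and keeps the profile's frequent boundary optima exact. Bootstrap
uncertainty (standardized β and λ̂) is parametric: responses are
re-simulated from the fitted λ-model and the full model refit per
replicate; 100 replicates and percentile CIs by default (percentile rather
than normal-theory, a deliberate choice where the convention is
ambiguous). Standardization uses plain sample SDs of response and
predictors, the common reporting convention for standardized coefficients.

## Brumation estimation

The estimator mirrors the operational field definition: within a calendar
year, the active period opens on the first day of the first run of at
least `persistence` (default 5) consecutive days with mean temperature
above the emergence threshold, and closes on the last day before the
terminal run of below-threshold days that reaches December 31. Brumation
days are the complement. Consequences of following the rule literally: a
mid-year warm spell after the terminal cold run cannot re-open the active
period, and a cold snap in midsummer shortens nothing. Days exactly at the
threshold count as inactive ("below"); this tie rule is configurable
(`at_threshold`). Entry and emergence thresholds are both supported;
emergence defaults to entry when only one was measured. Buffers of 2 or
4 °C are subtracted from both thresholds to emulate ground-microclimate
buffering, and buffered estimates are necessarily ≤ unbuffered ones.
Leap years use 366 days. The species-level estimate is the arithmetic mean
over the supplied years; ≤27 mean days classifies a species as
non-brumating (short cold spells frogs can endure without dormancy).

Climate summaries: CV = sample SD/mean of monthly values (warning when the
mean is ≤ 0, where a Celsius CV is ill-defined); dry-season length is the
count of months with total precipitation strictly below twice the mean
temperature.

## Phylogenetic logistic regression

Binary responses use a correlation structure in the spirit of the
Ives–Garland model: tip correlation = (Brownian correlation) ×
exp(−α·patristic distance). Small α means strong phylogenetic dependence.
The Hadamard form is positive definite (Schur product of a PSD and a PD
kernel) and reduces exactly to the identity on a star phylogeny, where the
fit therefore coincides with ordinary logistic regression. α is profiled
on a Gaussian pseudo-likelihood of the Pearson residuals from an initial
independence fit; β is then re-estimated by Firth-penalized estimating
equations under the fitted correlation — the penalty stabilizes the small
binary samples (n ≈ 42) typical here and keeps estimates finite under
separation, which is separately detected by an unpenalized-IRLS divergence
probe and flagged. Wald z and normal p-values are reported; bootstrap CIs
simulate correlated binary tips by thresholding a latent Gaussian field
with the fitted marginals.

## Partial correlations

The evolutionary trait covariance is estimated about the GLS phylogenetic
mean under λ = 1 with ML normalization (divide by n), so a star phylogeny
reproduces the plain ML sample covariance. Pairwise partial correlations
controlling for body size use the textbook first-order formula; t uses
df = n − 3 (two focal traits and one control beyond the mean), and CIs use
the Fisher z-transform — chosen over noncentral-t where the convention was
unstated.

## Compositional analysis

Body mass is closed into a five-part composition (brain, fat, testes,
hindlimb muscle, rest-of-body = total − four focal tissues). Transforms
come from scikit-bio: clr for part-identity-preserving correlations, ilr
(Gram–Schmidt orthonormal basis) for full-rank multivariate models. No
silent zero replacement: zero parts are an error. Back-transformed
regression coefficients are basis-independent; a zero effect maps to
1/D = 0.20 per part.

The multivariate regression fits all D−1 ilr coordinates under one common
λ (profiled on the multivariate ML). Pillai's trace comes from the
hypothesis and error cross-products of the whitened model; its p-value is
a Freedman–Lane permutation test (999 permutations by default) that
permutes phylogeny-whitened residuals of the intercept-only model — exact
under the null by construction. An F-approximation is also emitted for
reference. The effect size ξ² is defined here as the chance-corrected
Pillai, (V − E[V_perm])/(1 − E[V_perm]); this is an interpretation, since
no formula is in general circulation, and it is slightly below V as
expected of a bias-corrected quantity.

## Phylogenetic PCA

Eigendecomposition of the evolutionary covariance (mode="covariance" on
log traits by default, method Brownian; a correlation mode is available),
scores are projections of deviations from the GLS phylogenetic mean — so a
star tree reduces to ordinary PCA on centered data. Deterministic sign
convention: each component's largest-magnitude loading is positive.

## Confirmatory path analysis

Candidate causal structures are DAGs (cycles rejected at construction).
The basis set contains one claim per non-adjacent pair, conditioned on the
union of both variables' parents; the regression dependent is the causally
downstream variable (lexicographic for unordered pairs), making output
canonical under relabeling. Claims are tested by the λ-ML PGLS t-test of
the focal predictor; p-values combine into C = −2Σln p with df = 2k, and
models are ranked by CICc = C + 2qn/(n − 1 − q) with q = directed edges +
covariances among exogenous-node pairs (+1 path per node when a body-size
control is supplied, since size then parents every node and is excluded
from the claims themselves). Models within ΔCICc ≤ 2 of the best are
averaged; averaging is conditional (per edge, over the models containing
it) by default, with CICc-weighted averaging as an option — the unweighted
conditional form matches the common tooling default where the convention
was unstated. Note that Markov-equivalent DAGs (e.g. a chain and its full
reversal) share a basis set and cannot be separated by this machinery;
only non-equivalent structures (e.g. chain vs collider) are.

Two editable plain-text candidate sets ship with the package: an 8-model
set linking latitude, brumation, breeding-season length and aggregation
formation, and a 28-model tissue set (brumation → digestive tract / fat /
organs with mediation variants and both brain→testes directions). The
28-model set is a reconstruction of the described model families, built on
a fixed causal order so every member is acyclic, and is meant to be edited
without code changes.

## Directional tests of binary-trait coevolution

The joint (x, y) pair evolves as a 4-state continuous-time Markov chain in
which dual transitions are forbidden. Four nested models — independent
(k = 4), x-dependent-on-y, y-dependent-on-x (k = 6) and mutual (k = 8) —
are compared by AIC and Akaike weights. Likelihoods use Felsenstein
pruning with per-branch transition matrices from one eigendecomposition of
the generator per evaluation (vectorized over branches, with an expm
fallback for defective generators); root frequencies are flat (¼) by
default with a stationary-distribution option. Optimization is bounded
L-BFGS on log rates with seeded multi-starts plus warm starts from each
submodel's optimum, which enforces the nesting order of the optimized
likelihoods up to solver tolerance. Binarization follows the field rules:
sign of the λ-ML log–log PGLS residual of testis mass on SVL ("relatively
large/small testes"; exact zeros are assigned 0 with a warning), and a
mean split for season length (below-mean = "short" = 1).

A practical identifiability caveat, measured on synthetic data: when the
mutual dependence is a symmetric coordination of the two traits, a single
unilateral model reproduces the joint tip distribution almost exactly and
AIC prefers its 6 parameters even at 300 tips. Mutual dependence is
recoverable when the two directions act through qualitatively different
channels (e.g. one trait's transition *direction* tracks the partner while
the other trait's *lability* does) and transitions are rare enough to
leave phylogenetic signal; the recovery experiments use that regime.

## Repeatability and percent change

Repeatability is the one-way random-effects intraclass correlation
R = σ²_between/(σ²_between + σ²_within), variance components by REML
(statsmodels MixedLM) with a method-of-moments fallback when REML
degenerates at σ²_between ≈ 0; CIs by parametric bootstrap. Percent change
uses natural logs, 100·ln(post/pre) (Törnqvist convention): symmetric in
direction and additive across multiplicative stages; the back-transformed
ratio is reported alongside.

## Synthetic data

Generators are pure functions of (arguments, seed). Trees are pure-birth
(Yule) with a final waiting stretch so terminal branches are strictly
positive. Trait tables: log SVL evolves as Brownian motion (root 45 mm,
rate 0.15²/unit depth); each log tissue mass is its allometric slope
(brain 0.49, fat 1.10, testes 1.00, hindlimb 1.10, gut 1.00 by default —
the brain value is the empirically characteristic negative allometry of
brains) times log SVL³ plus a per-tissue λ-Brownian deviation
(SD 0.25) with a configurable cross-tissue correlation; body mass is the
sum of all tissues plus an isometric remainder, so compositions are always
positive. Daily temperatures are an annual sinusoid (default mean 12 °C,
amplitude 12 °C, coldest in January) plus AR(1) noise (coefficient 0.7,
SD 1.5 °C): autocorrelated noise produces realistic multi-day cold spells
that genuinely exercise the 5-day persistence rule, which i.i.d. noise
would not. Binary pairs are simulated by explicit jump sampling along
branches. The `paper_scale` preset bundles 116 species with the study's
nesting (50 pre/post pairs, 43 with breeding data, 30 field-validated
thresholds).

What the generator does **not** emulate: measurement error around species
means, within-species sampling (individuals), elevation/longitude
covariates, non-sinusoidal weather (fronts, heat waves), or any attempt to
match the real deposited values. Passing tests therefore demonstrate
statistical correctness of the estimators under their own assumptions, not
agreement with any particular empirical dataset.

## Problem sizes and numerical choices

The validation experiments use: λ recovery at n = 120 (20 replicates);
allometric-slope coverage at n = 116 with 100 bootstrap fits
(10 replicates); evolutionary correlation at n = 300 (10 replicates);
repeatability with 100 groups × 5 (10 replicates); type-I calibration with
200 replicates at n = 50 (MANOVA, 199 permutations) and n = 60
(logistic); directional-test recovery at n = 300 (7 replicates). Oracle
equivalences run on ≥50 random instances each. Tolerances: algebraic
identities at 1e−8–1e−12; conversion worked examples at the printed
2-decimal precision; recovery bands as stated per experiment; calibration
within the binomial 95% band around 5%.

Degenerate inputs are handled explicitly: exact linear fits give σ² = 0
and an infinite log-likelihood ordinate (profile comparisons still work);
singular Pillai systems fall back to a pseudo-inverse; permutation
p-values use the add-one convention (1 + #{perm ≥ obs})/(n_perm + 1);
p = 0 entering Fisher's C is clamped to 1e−300 with a warning.

## Known limitations

- The multivariate GLS is a plain ML fit; no small-sample penalization, so
  results can differ from penalized implementations at small n.
- Conditional model averaging can bias averaged coefficients toward models
  that include an edge; full averaging is available via flag.
- The logistic α and the MANOVA λ are point estimates; their sampling
  uncertainty is only propagated through the bootstrap, not analytically.
- No zero-replacement for compositions, no reduced major-axis regression,
  no multi-optimum Ornstein–Uhlenbeck models, no >2-state discrete traits.
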