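# Methods

This note documents the statistical model behind `thicknet`, the numerical
conventions it fixes where the literature is silent, what the synthetic
cohort generator does and does not emulate, and the design choices that were
genuinely open.

## Group covariance networks

For a group of `n_s` subjects and a node set of `n` atlas regions, the
weighted network is `w_ij = max(0, r_ij)` where `r_ij` is the Pearson
correlation of mean cortical thickness between regions *i* and *j* across
subjects; the diagonal is zero. Negative correlations are excluded rather
than rectified or analyzed separately — their interpretation in thickness
covariance is contested, and dropping them keeps all weights in `[0, 1]`.
No covariate adjustment (age, sex, intracranial volume) is applied before
correlation; the networks are raw-correlation objects, and group contrasts
inherit whatever shared covariate structure the groups carry.

**Binarization.** At density `d` (percent), the `k = round(d/100 ·
n(n−1)/2)` largest weights become edges. Conventions fixed here:

- `round` is round-half-up (`floor(x + 0.5)`), not banker's rounding, so the
  edge count is predictable across implementations.
- Ties at the cutoff weight break by lexicographic node-pair order. With
  continuous thickness data exact ties have probability zero; the rule
  exists so that runs are bit-reproducible.
- If fewer than `k` positive weights exist, all positive weights are kept
  and a warning records the realized density.
- A sweep is computed from a single weight ranking truncated at increasing
  prefixes, which makes edge sets nested across densities by construction.

**Density range QC.** The default sweep is 10–45 % in 1 % steps, with nodal
statistics read at the median density 27 %. The QC report flags, per
density, disconnected networks (they bias path-based measures) and
random-like topology: the small-world index
`σ = (C/C_rand)/(L/L_rand)` computed against degree-preserving rewired
graphs (default 100 per density; 20 inside the pipeline for speed), where
`C` is transitivity and `L` the mean shortest path over connected pairs.
`|σ − 1| < 0.1` is flagged as random-like; the band is a pragmatic reading
of "close to 1" and is configurable.

## Graph measures

On binary networks: nodal global efficiency
`e_i = (1/(n−1)) Σ_{j≠i} 1/d_ij` (with `1/∞ = 0`, so disconnected pairs
contribute zero rather than raising an error — group networks at low
density legitimately contain isolated nodes), average global efficiency
(mean of `e_i`), nodal local efficiency (average global efficiency of the
subgraph induced by a node's neighbors, defined as 0 for nodes with fewer
than two neighbors), and transitivity `3·triangles/triples`, 0 when there
are no connected triples. On weighted networks, before binarization: nodal
strength `s_i = Σ_j w_ij` and its mean. Shortest paths are computed by
all-sources breadth-first search expressed as boolean matrix products — for
atlas-sized networks (tens of nodes) this is substantially faster inside
the permutation loop than sparse-graph library calls, and it is validated
in the tests against an independent Floyd–Warshall/triangle-enumeration
implementation to 1e−12 on hundreds of random graphs.

## Louvain modules

Modularity with resolution `γ` is
`Q = (1/2m) Σ_ij [w_ij − γ k_i k_j/(2m)] δ(c_i, c_j)` over ordered pairs,
run on the weighted (un-binarized) networks with `γ = 1` by default. The
optimizer is the two-phase Louvain heuristic (greedy local moves, then
community aggregation) with two strengthenings that matter on small, dense,
noisy networks:

- candidate moves include a fresh empty community, so a badly placed node
  can always be isolated;
- restarts alternate between singleton initialization and random initial
  partitions, which lets the search escape merge-only local optima that
  plain Louvain provably cannot leave (observed on random weighted graphs
  with n ≤ 8, where plain best-of-restarts stalls below the enumerated
  optimum).

Determinism: node order is drawn from a seeded generator per restart; ties
in move gain break toward the lowest community id; between equal-`Q`
partitions the one with fewer modules wins, then the earlier restart. The
reported `Q` is recomputed from the final partition (self-consistency is
asserted), `Q` is asserted non-decreasing across passes, and on all test
graphs with n ≤ 8 the best-of-20-restarts result matches exhaustive
partition enumeration to 1e−9. Default restarts: 100.

## Permutation inference

Group networks are functions of *sets of subjects*, so the permutation null
relabels the pooled subjects into groups of the original sizes and rebuilds
both networks from scratch on every draw — correlation, exclusion,
thresholding, measures. Nothing short of full reconstruction is valid here.

The two-tailed p-value is `p = (1 + #{|null| ≥ |obs|})/(n_perm + 1)`, which
is never zero. The "95 % confidence interval of the null used as critical
values" is implemented as the symmetric interval `(−c, +c)` with `c` the
`m`-th largest `|null|`, `m = floor(α(n_perm+1))`. This specific choice
makes the interval rule and the p-value rule *provably identical decisions*
(including tie cases), which is asserted on every output row; a percentile
interval of the signed null would disagree with the two-tailed p whenever
the null is asymmetric. When `m = 0` (too few permutations for any
rejection at α) the critical value is infinite and a warning is emitted in
the nodal path.

The draws are made label-symmetric: the pooled subjects are sorted and each
permutation assigns the first `min(n_A, n_B)` positions to the smaller
group, so swapping the contrast's group labels flips the sign of every
observed difference but reproduces the identical p-values.

Nodal comparisons at the median density are adjusted per measure family
(global efficiency, local efficiency, strength) across nodes with
Benjamini–Hochberg FDR; Hochberg's step-up adjustment is provided for post
hoc p-vectors. Both delegate to `statsmodels` behind the package's own
validated surface, and both are tested against literal quadratic-time
step-up implementations.

Under a homogeneous null the test is exact by exchangeability: the
acceptance suite verifies a rejection rate within the binomial 99 % band
around α = 0.05 for every measure at densities 10/27/45 % over 200
simulated cohorts (n_perm = 200 there purely for runtime).

## Stratification

Median splits use the midpoint-of-central-order-statistics median; values
equal to the median go to the *low* group. The rule is arbitrary — any
deterministic rule is acceptable, but one must be fixed and recorded, which
the run manifest does. Composites are unweighted means of z-scores
(`(x − mean)/sd`, `n−1` denominator); components with zero variance are an
error, and missing values are never imputed (complete-case analysis).

## Synthetic cohorts

`generate_cohort` draws, per subject: age uniform on a range (default
32–79 y); thickness of region *j* as
`baseline − slope·(age − age_min) + noise_sd · ε_j`, with `ε ~ N(0, C)` and
`C` a block correlation matrix (`r_in` within modules, `r_out` between,
shrunk minimally toward the identity if not positive definite — never
silently); and cognitive scores from
`intercept + a·(latent ability) − b·(age − age_mid) + noise`. Defaults:
baseline 2.5 mm, slope 0.005 mm/yr, noise 0.12 mm — field-typical
magnitudes for mean regional thickness and age-related thinning; score
intercepts and slopes sit on the scales of common neuropsychological
instruments so that median splits on age and performance produce four
non-trivial groups.

Two features of this model deserve emphasis:

- **The age slope induces covariance.** A shared linear age effect adds a
  uniform positive component (~0.15 at the defaults) to every region-pair
  correlation. That mirrors real structural covariance, where age is a
  major shared driver — but it means the realized correlations exceed the
  planted `r_in`/`r_out`. Tests that verify recovery of planted correlation
  targets therefore run with the slope at zero, and the planted two-group
  scenario (below) does too, so that its realized structure equals its
  nominal one.
- **Gaussianity.** The noise is multivariate normal; Pearson correlation is
  moment-based, so this is the minimal distributional assumption. Heavy
  tails, site effects, and measurement error are not modeled, so a green
  test suite demonstrates correctness of the machinery under the model's
  assumptions, not robustness of the scientific pipeline to real-data
  pathologies.

**Planted scenarios.** The packaged demo contrasts an HP group drawn from a
two-block structure (`r_in = 0.7`, `r_out = 0.1`) with an LP group from one
merged block (`r = 0.4`), 120 subjects per group. Two scenario sizes are
used deliberately: at 12 regions the merged group's best split has negative
structural modularity, so module-count recovery (2 vs 1) is unambiguous; at
16 regions (the size of a typical phonemic-fluency node set) the density
sweep resolves transitivity and efficiency contrasts well enough that their
significant-density prevalence is a stable quantity. With 16 regions an
exact modularity maximizer will occasionally split the merged group on
sampling noise alone (best `Q ≈ +0.001`), which is why module counts are
not asserted there. The prevalence of significant densities is itself a
Monte-Carlo quantity with large realization-to-realization spread at these
group sizes; tests and the acceptance script therefore average it over
replicate scenarios rather than trusting one draw.

The strength-localization scenario raises two designated nodes'
correlations to all others by `δ` and lowers the remaining pairs to keep
non-designated strengths constant; because the boosted matrix may need a
positive-definiteness repair, the reference group's uniform correlation is
chosen to match the repaired matrix's non-designated strength exactly, so
the planted elevation is confined to the designated nodes by construction.
Group size 400 is used there: strength estimates sum ~11 correlated `r̂`
terms and need that many subjects for the planted 2-σ-per-edge effect to be
a reliable ~5-σ nodal effect.

## Reproducibility

Every stochastic stage derives its seed deterministically from the config
seed and a stage name (a stable string hash fed to `SeedSequence`), and the
run manifest records the seed, a SHA-256 hash of the canonical config, the
package version and per-file content hashes. Floating-point output is
printed with 6 significant digits; cohort tables are written with full
`repr` precision and re-parsed with Python's exact `float()` so write/read
round trips are lossless. Identical (config, cohort, seed) runs are
byte-identical; manifests omit timestamps unless requested.

## Known limitations

- Raw Pearson networks only: no partial correlations, covariate-adjusted
  covariance, or single-subject networks.
- Binary measures only across the sweep; no weighted efficiency/clustering
  variants, betweenness, or participation coefficient.
- Permutations are plain relabelings; no covariate-balanced or stratified
  permutation schemes.
- The default node rosters are plausible but not canonical; they are
  configuration, and studies should supply their own.
- The demographics of the synthetic cohort (education, IQ) are not modeled;
  only age, sex and the score model.
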