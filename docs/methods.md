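# Methods

This package implements a pipeline for asking whether individuals who
score high on trait loneliness hold *idiosyncratic* multivariate
representations of shared cultural targets (e.g., widely known
celebrities), relative to the group at large and to a group-consensus
representation. It provides two complementary statistical instruments, a
group-consensus estimator, a reliability-based voxel-selection stage for
volumetric data, and a synthetic-data generator that plants (or withholds)
each effect so every stage can be validated end to end.

## The two idiosyncrasy models

**Anna Karenina (pairwise) model.** For every unordered pair of
participants and every target, the similarity between the two
participants' feature vectors (Pearson correlation for neural patterns,
cosine for embeddings, Jaccard for binary trait profiles) is regressed on
the pair's *mean* loneliness score. Modeling the pair mean — rather than
the pair difference — tests whether high scorers are dissimilar both to
each other and to low scorers ("every lonely person is lonely in their
own way"): a negative standardized slope means lonelier pairs are less
alike.

Because each participant appears in many pairs and the outcome is
symmetric in pair order, inference uses a linear mixed model with crossed
random intercepts for the first pair member, the second pair member, and
the target. Each unordered pair enters twice with roles swapped
("doubling"), which makes the two member-role intercept factors
symmetric. All variables are z-scored on the analysis sample, so slopes
are standardized coefficients.

**Consensus-similarity model.** Each participant's feature vector is
correlated with the estimated group-consensus vector for that target
(one observation per participant x target), and that similarity is
regressed on loneliness with a participant random intercept. A target
intercept is attempted first when requested and dropped automatically if
the fit degenerates.

The two models answer different questions and are statistically
dissociable; the `cluster` and `ring` synthetic scenarios (below)
demonstrate constructions in which exactly one of them detects an effect.

## Mixed-model engine

`zeitgeist.lmm.fit_crossed_lmm` is a REML fitter for Gaussian models with
crossed random intercepts, written around the low-rank (Woodbury)
identity so each objective evaluation costs O(q^3) in the total number of
random levels q (participants + targets), independent of the number of
dyadic rows. Variance ratios are profiled out and optimized by L-BFGS-B
from three starting points; zero variance is an admissible boundary
estimate. Satterthwaite degrees of freedom are computed per fixed effect
from the finite-difference gradient of the effect's sampling variance
with respect to the variance components and the inverse Hessian of the
REML deviance, with boundary components excluded. The engine is validated
in the test suite against R's lme4/lmerTest on a fixture (agreement to
~1e-4 on estimates, standard errors, variance components, and ~1% on df)
and against statsmodels' variance-components formulation.

**Doubling adjustment.** Doubling duplicates every observation, so a
naive fit sees twice the information actually present. Halving the
Satterthwaite df alone does not repair this: simulation on data generated
directly from the assumed crossed-intercepts model shows the t statistic
remains inflated by almost exactly sqrt(2) (empirical sd(beta)/model-SE =
1.41; two-tailed rejection 0.147 at alpha = 0.05). The package therefore
removes the duplicated information on both axes: the Satterthwaite df is
halved *and* the squared standard error is doubled, after which the same
simulation rejects at 0.033. Reported t statistics are correspondingly
sqrt(2) smaller than a raw doubled-fit convention would print. One-tailed
p values follow the sign rule: p_one = p_two/2 when the estimate's sign
matches the stated direction, else 1 - p_two/2.

Wald confidence intervals (beta +/- t_crit * SE at the adjusted df) are
the default for determinism; they stand in for simulation-based
intervals.

## Group-consensus estimation

The default (kernel-weighted) estimator follows four steps per target:

1. metric (stress-minimizing) MDS of the participants' pairwise
   correlation/cosine distances into the plane, best of 4 initializations
   with up to 3000 iterations each (SMACOF convergence tolerance 1e-6 by
   default; tighten `eps` for near-exact embeddings of perfectly planar
   configurations);
2. a Gaussian-kernel density evaluated on a regular 100x100 lattice over
   the bounding box, with bandwidth equal to the smaller of the two axis
   ranges; the densest grid node is the point of greatest convergence
   (ties break at the lowest row-major index). The "radius" of the kernel
   is interpreted as the Gaussian bandwidth sigma; a truncation radius
   would leave the kernel scale undefined;
3. proximity weights w_i = max_j d_j - d_i from each participant's
   Euclidean distance d_i to that point (the furthest participant gets
   exactly zero; all-equal distances fall back to uniform weights, with a
   logged note);
4. the consensus vector is the weighted mean of participants' row-z-scored
   patterns (z across features within participant, matching the
   possessive reading "their z-scored pattern"; z-scoring each feature
   across participants was rejected as inconsistent with that reading).

Two alternatives are provided: the unweighted average, and the
distance-weighted average (the same proximity recoding applied to mean
inter-participant distance, no MDS).

**Leave-one-out transform.** When a participant's similarity to the
consensus is computed, the default excludes that participant's own
contribution (their weight is zeroed and the weighted mean renormalized).
Correlating a pattern with an average that contains it inflates the
similarity roughly in proportion to the participant's weight share; with
proximity weighting the inflation is systematically larger for
central participants, which injects a spurious negative
loneliness-similarity association whenever loneliness correlates with
peripherality. Leave-one-out averaging is the standard remedy in
inter-subject-correlation analyses and is used here by default
(`exclude_self=False` reproduces the include-self variant).

## Synthetic data

`SyntheticConfig` defaults define the reference study conditions: 40
participants, 5 targets, 200 features, loneliness drawn from a truncated
normal (mean 40.73, sd 8.32, bounds 25-57 — UCLA-scale-like) by rejection
sampling, which preserves the density shape near the bounds.

**ak / null scenarios.** Patterns are `prototype + sigma(l) * eps` with
`sigma(l) = base_noise_sd + idiosyncrasy_slope * z(l)` (floored at zero
with a logged warning; z uses the realized sample mean/sd, mirroring the
analysis-side z-scoring). Two defaults deserve explanation:

- `base_noise_sd = 2.45` with `prototype_sd = 1` puts the expected
  inter-participant pattern correlation at v_p/(v_p + sigma^2) ~ 0.14,
  the order observed for multivoxel patterns in association cortex. This
  is not cosmetic: the participant-level clustering that a pattern
  correlation inherits from the noise-prototype interaction scales as
  (1+rho)^2/(rho(rho+2)^2) relative to feature-sampling noise (rho the
  noise/prototype variance ratio), so realistic low-similarity regimes
  are also the regimes where the crossed-intercepts model is
  approximately correctly specified.
- `noise_heterogeneity_sd = 0.18` multiplies each participant's noise sd
  by a mean-one lognormal draw that is stable across targets, emulating
  stable individual differences in data quality (SNR, motion,
  engagement). Without any cross-target-stable individual differences
  the participant intercepts have nothing real to absorb and the test is
  anti-conservative; with too much, power at participant-level predictors
  collapses. The default sits in the window where the null test is
  calibrated (empirically 0.050 at alpha=0.05 over 400 replicates) and a
  planted standardized effect of -0.2 is detected with ~0.9 power at
  n=40, 5 targets.

`slope_for_effect` converts a desired standardized pairwise effect into
an idiosyncrasy slope by a delta-method calculation documented in its
docstring (pairwise-similarity gradient g at the base noise level,
predictor variance 1/2, outcome variance = feature-sampling +
heterogeneity + within-target + effect-induced terms), solved by
bisection. Planted effects are recovered to first order (simulated mean
beta -0.217 at a nominal -0.2).

**Dissociation scenarios.** These are synthetic stand-ins built to
realize two stated effect patterns; they are not reconstructions of any
empirical simulation recipe.

- `cluster` (consensus effect without an AK effect): the top
  `lonely_fraction` of scorers share a "deviant prototype" — an
  independent random direction minus `cluster_repulsion` times the shared
  prototype — with small within-group noise. They are mutually similar
  (within-group r ~ 0.85) yet anti-correlated with the main mass (cross
  r ~ -0.05), so they land beyond correlation distance 1, outside the
  main cloud in the MDS plane, where the proximity weights suppress them
  and the consensus stays with the majority. The anti-correlation tilt is
  essential: a merely-orthogonal tight knot either attracts the smooth
  KDE mode or, through its coherence, dominates the weighted average even
  at a modest weight share. The within-group similarity is set high
  enough that the *linear* AK slope is non-negative (the high-mean pairs
  sit above the grand mean), so a one-tailed negative AK test does not
  reject.
- `ring` (AK effect without a consensus effect): the top scorers' noise
  vectors are column-centered within the group (pairwise correlation
  -1/(k-1), the minimum achievable for k vectors) and rescaled to the
  common marginal noise sd. They are mutually repelled — within-group
  similarity drops by sigma^2/((k-1)(v_p+sigma^2)) — while each sits at
  the same expected distance from the true prototype as everyone else.
  A caveat discovered during development: *any* consensus estimated from
  the sample correlates with the repelled members' noise (the group's
  centered noises sum to zero, so whichever members are down- or
  up-weighted leak anti-correlation), leaving a weak negative residual
  association with loneliness (about 40% one-tailed rejection at n=30, 3
  targets, versus ~96% for the planted AK effect). The dissociation is
  therefore assessed as an ordering of rejection rates, not as an exact
  null; against the noise-free prototype the planted distance gap is
  exactly zero (verified in the tests).

**Trait responses** are drawn by flipping a single group profile
independently per participant at `flip_rate` (0.5 reduces to independent
uniform responding, expected Jaccard 1/3), with missingness as NaN.
**Split-half volumes** plant a spherical blob whose condition-level
signal is shared across halves (expected voxelwise split-half reliability
s^2/(s^2+n^2)) inside independent noise.

## Reliability-based voxel selection

Voxelwise split-half reliability is the per-participant correlation of
the condition vector across halves, averaged into a group map (undefined
voxels excluded with a logged count). Peak-anchored ROIs are the
face-connected (6-neighbor; 26-neighbor optional) suprathreshold
component containing the region's peak voxel, grown across a configurable
threshold grid (default step 0.002 over a stated range); masks are
nested by construction. Multivoxel pattern reliability is the
across-voxel correlation of the two halves within the mask, per
condition, averaged over conditions then participants; curves truncate
when a mask shrinks below 33 voxels (a 3-voxel-radius searchlight). The
selected threshold maximizes the across-region average of per-region
z-scored curves, ties toward the lower threshold (larger ROI). On the
planted-blob fixture at signal_sd = 2*noise_sd the selected ROI overlaps
the truth with Jaccard >= 0.8.

## What the synthetic benchmark does and does not show

The generator reproduces the *statistical* structure the analyses assume
— a shared prototype per target, loneliness-scaled idiosyncratic noise,
stable participant differences, binary responses with missingness,
split-half volumes with a reliable region — with Gaussian features and
exact exchangeability. It does not emulate spatial autocorrelation of
volumes, non-Gaussian pattern amplitudes, target-specific familiarity
structure, or text semantics (the semantic arm consumes embedding vectors
directly; no text is generated). Passing the benchmark therefore
certifies the pipeline's numerics and inferential calibration under the
assumed structure, not the substantive neuroscience conclusions on any
real dataset.

## Numerical choices and degenerate inputs

- Undefined similarities (zero-variance vectors under Pearson, empty
  missing-data overlap under Jaccard) are flagged and excluded from fits
  with logged counts, never imputed as zero. A Jaccard pair whose shared
  features are all-zero on both sides is defined as 1 (identical
  responses).
- Binary responses are coded {0,1} internally whatever the instrument's
  labels; dissimilarity covariates are |difference| (or Euclidean
  distance over rating vectors), z-scored across pairs and sign-flipped
  to similarity ("inverse" of a z-scored dissimilarity is read as
  negation; a reciprocal breaks on zero/negative z).
- All pattern matrices are participants x features with unique ids; the
  doubled table is constructed only from an undoubled one (duplicate
  ordered pairs raise).
- Every generator and fit is deterministic given its seed; the pipeline
  expands one master seed into per-stage substreams so stages can be
  rerun in isolation.

## Problem sizes

Simulation studies in the tests and the acceptance script use 400
replicates for null calibration (n=30 participants, 3 targets, 200
features), 200 for power (n=40, 5 targets), 200 per dissociation scenario
(n=30, 3 targets), and a 10x10x10 grid with 12 participants and 16
conditions for ROI recovery — sizes chosen to hold Monte-Carlo error on a
rejection rate near or below one percentage point at desk scale.
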