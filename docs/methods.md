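# Methods

This note documents the statistical procedures, the synthetic-data
model behind the test suite, the numerical conventions, and the design
choices that were genuinely open.

## Average variation degree (AVD)

For each disturbance level, species are scoped to those with positive
total abundance at that level, so species absent from a level do not
dilute its species count n. The variation degree of species *i* in
sample *j* is

    a_ij = |x_ij − x̄_i| / δ_i

with x̄ and δ computed over the level's K samples. Conventions:

* δ uses the sample standard deviation (n − 1 denominator), the usual
  choice for plot replicates.
* δ = 0 implies x = x̄ for every sample, so a = 0 (not NaN) is the only
  consistent value.
* The level AVD is Σ a / (K·n), i.e. the plain mean of all variation
  degrees in the level's sample × species scope; stability is 1 − AVD.
* A **per-sample** stability, 1 − meanᵢ(a_ij), is exposed as the
  replicate unit for ANOVA across levels. When every sample of a level
  shares the species scope (always true here, since the scope is
  defined per level), the mean of per-sample stabilities equals the
  level stability.
* AVD is computed on raw counts. Every a is invariant under positive
  affine per-species rescaling within a level, so per-species units do
  not matter; row-normalization would not be neutral and is not
  applied.

## Cohesion

Pairwise Pearson correlations with two-sided t-test p-values are
computed once on the pooled dataset (all levels together), not per
level. The significance mask is the plain p < α rule (α = 0.05); no
multiple-testing correction is applied by default and no null-model
correction of r is performed — plain significance-filtered Pearson
means. Each species' connectedness r̄⁺/r̄⁻ is the mean of its
significant positive/negative correlations (0 if it has none); pairs
involving a zero-variance species are excluded.

Sample cohesion weights connectedness by **relative** abundance
(rows normalized to proportions first). This is what guarantees the
documented bounds C⁺ ∈ [0, 1] and C⁻ ∈ [−1, 0]; on raw counts the
bounds would not hold, so the function rejects non-proportion input.
The network-stability ratio is reported as the magnitude |C⁻|/C⁺
(undefined and flagged as missing when C⁺ = 0); the signed value
−|C⁻|/C⁺ is also emitted.

## SPEC–OCCU indicators

Specificity of species S at level H is mean_H(S) / Σ_L mean_L(S),
where the per-level mean includes zero-abundance quadrats ("all
quadrats of H"). Occupancy is the occupied fraction of the level's
quadrats, the quadrat being the sampling unit (15 per level in the
reference design). Both thresholds are inclusive (≥ 0.4 by default):
a species at exactly 0.4/0.4 is flagged. Species with zero total
abundance are excluded with a warning. Permutation significance tests
for indicator value are deliberately out of scope; the dual-threshold
rule is the whole criterion.

## Group comparison

One-way ANOVA (scipy) plus Tukey–Kramer HSD adjusted pairwise p-values
(statsmodels) at α = 0.05, rendered as a compact letter display via a
deterministic insert-and-absorb algorithm: levels are processed in
descending mean order (ties broken by the declared gradient order),
each significant pair splits the letter columns containing both
members, and columns contained in another are absorbed. Degenerate
inputs: all observations identical → F = 0, one shared letter; groups
internally constant but unequal → infinite F, unequal pairs
significant.

## Driver analysis

Pearson screens report r, p and a p < α flag per (metric, covariate,
scope), where a scope is the pooled dataset, one level, or a pooled
adjacent-level pair. Zero-variance covariates in scope yield missing
values with a warning, never a flag. No multiple-testing correction by
default, matching the α-only screening rule; a Benjamini–Hochberg
option is a possible extension.

BRT models use squared-error gradient boosting (scikit-learn) with
learning rate 0.01, interaction depth 3, bag fraction 0.75 and up to
2000 trees — conventional ecological-BRT settings. Tree count is
chosen by early stopping; the default monitors a 20 % holdout with
patience 100, which in spot checks picks essentially the same tree
counts as the classic staged 5-fold cross-validation selection (also
implemented, `early_stopping="cv"`) at a fifth of the cost. Relative
influence is Friedman's measure computed by this package from the
fitted trees: each covariate's summed squared-error reduction
(node weight × impurity decrease) over all its splits in all trees,
normalized to percentages. It is tested against hand-built single-tree
ensembles. Influence is permutation-equivariant in covariate order up
to split-gain tie-breaking inside the tree builder. "Transition"
models pool the samples of two adjacent levels (30 in the reference
design); non-adjacent pairs require an explicit flag and warn. The
cohesion metric modelled by default is total cohesion, selectable.

## Synthetic community generator

The generator emulates a five-level gradient study: 3 plots × 5 points
per level (15 quadrats, 75 samples), a 40-species regional pool with a
lognormal rank-abundance curve (quantile-spaced; meanlog 1.0, sdlog
1.1 on per-quadrat expected counts — a median species holds ~3
individuals per 0.25 m² quadrat, dominants a few tens, a realistic
density for dense alpine meadow).

Two per-level dispersion components define the planted stability
gradient:

* **Patchiness** — the probability that a member species misses a
  quadrat — defaults (0.44, 0.32, 0.20, 0.10, 0.02) from ND to ED.
  Presence instability dominates the variation degree: a species
  blinking in and out of quadrats approaches the two-point maximum of
  the standardized absolute deviation (2√(q(1−q)) at occupancy q),
  whereas pure multiplicative noise rescales spread and standard
  deviation together and moves |x − x̄|/δ only through tail shape —
  and slightly *downward* as the noise grows, since heavier tails
  concentrate mass near the mean relative to δ. Patchiness, not the
  lognormal σ, is therefore the generator's primary stability dial.
* **σ** — lognormal quadrat-to-quadrat abundance noise, defaults
  (0.35, 0.33, 0.30, 0.22, 0.10); it controls the count coefficient of
  variation and the residual variation degree near full occupancy.

Both decrease strictly toward extreme disturbance, so true stability
increases ND → ED; with the default design the realized per-level
1 − AVD is strictly ordered in ≈ 96 % of seeds. Counts are
round(lognormal) with a floor of one, multiplied by a Bernoulli
presence mask — the mask is the only zero mechanism, so community
members of a near-zero-patchiness level are consistently present and
its rare members are consistent singletons (the strongest carriers of
the stability gradient, which is why planted structure occupies middle
abundance ranks).

Planted structure, all recorded in a retrievable `GroundTruth`:

* **Indicators** (2 per level): occupancy at the planted level follows
  the target (default 0.93) exactly as a Bernoulli probability, and
  cross-level leak abundance is solved so expected specificity equals
  the target (default 0.85). Targets of 1.0/1.0 force exact realized
  values (never absent at the level, zero mean elsewhere). Leak
  presence is abundance-thinned so the species stays rare off-level.
* **Correlated pairs**: log-abundances share a latent Gaussian factor
  with loadings of the requested signs (ρ = 0.7). Positive pairs
  override the level σ with 0.5 because integer rounding at the
  near-constant ED level would otherwise destroy the injected
  correlation; negative pairs use σ = 0.8 and are restricted to the
  disturbed levels, so the within-level anticorrelation outweighs the
  joint-presence (positive) component of the pooled correlation and
  the undisturbed level carries the minimum |C⁻|.
* **Environmental covariates**: Gaussian around level-specific means;
  soil bulk density and soil water content are additionally coupled to
  a latent stability axis (the z-scored level dispersion plus
  per-sample jitter), giving driver-recovery tests an unambiguous
  causal ground truth. Richness, plant density and Camargo evenness
  are recomputed from the abundance table itself.

Reproducibility: every (level, species) pair, every pair factor and
every covariate draws from its own `SeedSequence(seed, spawn_key=…)`
stream, so outputs are bit-for-bit reproducible and appending species
to the pool does not perturb existing draws.

What the generator does **not** emulate: spatial autocorrelation within
plots (plot and point ids are labels, not locations), temporal
dynamics, zero-inflation beyond presence masks, species interactions
beyond pairwise latent factors, and any feedback of vegetation on soil.
Passing recovery tests therefore demonstrates that the estimators
retrieve the structure this model plants at the study's sample sizes —
not that field data meet the model's assumptions.

## Derived vegetation metrics

Camargo evenness uses the pairwise form E = 1 − Σ_{i<j} |p_i − p_j| / S
restricted to the S species present in the sample (so E is not deflated
by the regional pool; E = 1 exactly for an equally-abundant community,
and E = 1 for a single species, which has no pairs). Plant density is
the row total divided by the quadrat area (0.25 m² default). The
ammonium-nitrogen and belowground-biomass covariates accept the alias
labels MHN and RGB seen in some variable lists, canonicalized to NHN
and BGB.

## Numerical conventions and edge cases

* Validation rejects duplicate ids, negative or non-finite counts and
  missing covariate values (no imputation); all-zero species columns
  are dropped with a warning (strict mode rejects).
* Correlation p-values come from the t transform of r with n − 2 df;
  exactly collinear pairs get p = 0. α = 1 means "every finite pair
  passes", the continuity limit used by the oracle tests.
* Specificity sums to 1 ± 1e-12 per species; AVD oracle agreement is
  asserted at 1e-12, Pearson closed-form agreement at 1e-10.
* Influence vectors sum to 100 ± 1e-6; a model with no splits returns
  the uniform share.
* Reference problem sizes throughout the test suite (75 samples, 40
  species, 50–100 recovery seeds, 1000 calibration replicates) are the
  package's own choice of desk-scale defaults; all are scenario
  parameters.

## Known limitations

* Cohesion uses plain significance-filtered Pearson means; the
  null-model-corrected variant of the cohesion literature is not
  implemented.
* Compositional (relative-abundance) correlation biases are not
  addressed (no SparCC-style estimator).
* ANOVA assumes variance homogeneity; Welch/Games–Howell alternatives
  are out of scope.
* BRT influence inherits shared-credit behaviour for collinear
  covariates: duplicated informative covariates split their credit.
* The per-sample stability replicate unit for ANOVA is a modelling
  choice; the level-aggregate AVD itself yields one value per level
  and cannot be tested without such a unit.
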