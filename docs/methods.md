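# Methods

## Overview

`stratnet` implements a transdiagnostic connectome-analysis pipeline that
builds *stratified* cross-disorder neural factors — one for externalizing
psychopathology (ASD, ADHD, conduct disorder, oppositional defiant
disorder) and one for internalizing psychopathology (generalized anxiety,
depression, eating disorder, specific phobia) — from task-based functional
connectomes, alongside a general (NP) factor.  The unit of analysis is the
*edge*: the functional connectivity (FC) between one unordered pair of
parcellation regions under one task condition, vectorized in canonical
upper-triangular order.

The chain is:

1. **Edge-wise brain–behavior association.** For every (condition, symptom)
   pair, the partial Pearson correlation of each edge's FC with the symptom
   after residualizing both on covariates (site, sex, age by default);
   two-sided p from the t transform with df = n − 2 − n_covariates.  An edge
   *predicts* a symptom when p ≤ α (α = 0.05 by default; a
   Benjamini–Hochberg FDR mode is available).
2. **Mutually exclusive edge taxonomy.** Per condition: edges predicting at
   least one symptom from each domain (or listed in an optional prior
   general-factor mask) are *general* and removed first; remaining edges
   predicting ≥ 2 same-domain symptoms and 0 other-domain symptoms are
   *stratified*.  Stratified edges split by the uniform direction of their
   supporting associations into pos-pos, neg-neg, and mixed groups; the
   pos-pos stratified-externalizing and neg-neg stratified-internalizing
   groups define the two factors (mixed-sign edges are discarded).
3. **Permutation reliability.** The stratified-edge count per condition is
   compared with a null built by shuffling subject rows of the symptom table
   (jointly across all eight symptoms, preserving their inter-correlations)
   and re-running the full association + classification chain;
   p = (#{null ≥ observed} + 1)/(n_perm + 1).
4. **Factor scores.** A subject's factor score is the summed FC over all
   (condition, edge) members.  The same node pair under two conditions
   counts twice; the baseline-wave edge set is re-applied unchanged at later
   waves.  For resting-state external cohorts, members collapse to unique
   node pairs.
5. **Specificity.** Region degree = number of members incident to the
   region; normalized degree = raw/Σraw + 1 ∈ [1, 2].  Specificity Score of
   factor F1 at a unit = norm(F1)/norm(F2) + norm(F1)/norm(F3); the arg-max
   factor is the unit's predominant factor, and the specificity distance is
   max − min of the three scores.  At the network level the units are
   network pairs (m networks → m(m+1)/2 units, within-network pairs on the
   diagonal), so the same formulas apply to pair counts.
6. **Longitudinal analysis.** Per-subject OLS slope of factor score on age
   across available waves (≥ 2 waves required; a complete-cases switch
   restricts to subjects with all waves); group-level one-sample t with
   Cohen's d = mean/SD; covariate-adjusted partial correlation of slopes
   with baseline domain symptoms; cross-wave prediction of later symptoms
   from the baseline factor with one-tailed p in the factor's expected
   direction (positive for externalizing, negative for internalizing).
7. **Effect-size conversions.** r = t/√(t² + n − 2); two-sample
   d = t·√(1/n₁ + 1/n₂) under the pooled-variance convention (pooled t is
   the default for group comparisons, Welch by flag, so the d identity holds
   exactly); one-sample d = t/√n.  No small-sample (Hedges) correction.

## Synthetic cohort generator

Real multi-cohort imaging data of this kind are access-restricted, so the
package ships a seeded generator that emulates the statistical structure the
analysis assumes, directly at the edge level (no voxel time series or task
GLM — out of scope by design).

**Symptoms.** Two domain latents share a common component:
L_d = √ρ·G + √(1−ρ)·U_d with ρ = `cross_domain_corr` (default 0.30).  Each
of the eight symptoms loads √a_d on its domain latent plus independent
noise, so the expected within-domain symptom correlation is a_d and the
cross-domain correlation is √(a_ext·a_int)·ρ ≈ 0.10.  Defaults
a = (0.37, 0.28) reproduce the observed within-domain mean correlations of
the two symptom blocks in the cohort this design emulates.  Latents persist
across waves; symptom noise is redrawn per wave, giving stable but
imperfect symptom autocorrelation.

**Connectomes.** Edge FC = baseline (0.3) + site offset (SD 0.05 across 8
sites) + small sex effect + loading + N(0, 0.1) noise.  Planted
externalizing edges load *positively* on the domain-specific component
U_ext, planted internalizing edges *negatively* on U_int, general edges
positively on the shared component G; all other edges are pure noise.
Loading on the domain-specific component (rather than the full latent) is
what makes a "stratified" edge well-defined: an edge loading on L_ext would
genuinely correlate with internalizing symptoms through G, and no method
could recover it as externalizing-specific.  Loadings are calibrated so the
FC–latent correlation equals the configured effect size (default 0.4).
Defaults plant 40 edges of each kind per condition in a 60-node
(1,770-edge), 4-condition, 600-subject, 3-wave design chosen to keep a full
run on one CPU in minutes; 268-node runs are supported.

**Longitudinal structure.** Every edge declines by `fc_decline_rate`
(default 0.01 FC/year).  For planted edges the per-subject yearly slope
adds `slope_sd`·z where z is a standardized mix of the baseline domain
symptom composite and noise, with mixing weight `slope_symptom_coupling` —
one value per domain, defaults (−0.20, +0.12), matching the opposite-signed
baseline-symptom/slope correlations the two factors are expected to show
(under-pruning with higher externalizing load, over-pruning with higher
internalizing load).  Polygenic-score covariates mix `prs_corr` (0.3) of
the domain-specific latent with noise, so each correlates with its own
domain only.  Wave dropout is missing-completely-at-random at a
configurable rate (default 0: complete follow-up).

**What the generator does not emulate.** Spatial autocorrelation between
edges sharing a node, heavy-tailed FC distributions, scanner drift,
informative dropout, site-by-effect interactions, and discrete
questionnaire scoring (symptoms are continuous standardized severities —
the analysis only uses their linear structure).  Passing tests therefore
demonstrate correctness of the machinery and recoverability of planted
linear structure, not performance on real imaging data.

## Numerical and design choices

- **Selection threshold.** p ≤ α inclusive, for determinism at exact ties.
- **Zero-variance edges** are flagged and assigned r = 0, p = 1 (never
  selected); a zero-variance symptom is an error.
- **Degenerate slopes.** Slopes are defined only with ≥ 2 distinct ages;
  with exactly two waves the OLS slope reduces to the difference quotient.
- **Predominance ties** break by fixed factor order (NP, externalizing,
  internalizing) and are logged; with three equal normalized degrees all
  three Specificity Scores are exactly 2.
- **Permutation p-values** use the add-one convention and are therefore
  conservative for discrete count statistics: under a pure-noise generator
  (20 nodes, 200 subjects, n_perm = 99) the measured rejection rate at
  nominal 0.05 is ≈ 0.033, because ties between the observed count and its
  null are common when expected counts are single-digit.
- **Per-edge false discoveries scale with null-edge multiplicity.** At
  α = 0.05 with ~1,650 null edges per condition, roughly 10–17 noise edges
  per condition survive the stratified rules alongside ~33 recoverable
  planted ones; the factor *scores* are robust to this (noise edges
  contribute near-zero covariance), and count reliability is handled by the
  permutation test, but per-edge precision at the default scale is ~70%.
  The bounded-FDP property test therefore runs at a 30-node parcellation
  where precision is high; the acceptance script reports the measured FDP
  at the default scale as-is.
- **CPM predictions** (connectome-based predictive modeling) select edges
  per training fold at α on covariate-residualized data, summarize each
  subject as positive-sum − negative-sum network strength, and fit a
  one-dimensional linear map to the raw training symptom; folds selecting
  zero edges fall back to the training mean with a logged warning.  The
  observed-vs-predicted similarity comparison permutes, per subject and per
  symptom, which of the two values enters each correlation matrix.
- **Randomness.** Every stage takes an explicit integer seed; the pipeline
  derives named substreams from one root seed via `numpy.random.SeedSequence`,
  so end-to-end reruns are byte-identical.

## Problem sizes used by the test suite

Module tests run on 12–30-node cohorts of 80–400 subjects; the acceptance
suite uses 3,000 pure-noise replicate studies (20 nodes, 200 subjects,
n_perm = 99) for calibration and ten 60-node, 600-subject planted cohorts
for recovery, keeping the default suite in the minutes range on one CPU.

## Known limitations

- The brain-behavior step is mass-univariate + CPM; no multivariate or
  regularized predictive models, and no nested hyperparameter search.
- Growth is summarized by per-subject OLS slopes, not mixed-effects models.
- No anatomical atlas labeling or brain rendering; parcellations are
  synthetic contiguous-block schemes.
- Cross-cohort harmonization is out of scope; site enters only as a
  covariate.
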