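# Methods

`cernakit` implements a complete competing-endogenous-RNA (ceRNA) analysis
for a matched case–control study of coronary heart disease (CHD), driven by
a synthetic-study generator so that every stage can be verified against
known ground truth. This note records the models, the defaults and why they
were chosen, the numerical conventions, and the known limits of what the
simulations demonstrate.

## The analysis being modelled

The workflow mirrors a common circRNA-biomarker study design:

1. a small two-group circRNA microarray (5 CHD vs 5 controls) is quantile
   normalised and screened for differential expression at *t*-test
   p < 0.05 and linear fold change |FC| ≥ 1.5;
2. two public gene-expression cohorts (49+50 and 110+112 samples) are
   merged, batch-corrected with ComBat, and screened at p < 0.05 and
   |FC| ≥ 1.2; the differential genes are intersected with an
   immune-gene list to give differentially expressed immune-related genes
   (DEIRGs);
3. circRNA–miRNA and miRNA–gene interaction tables are joined on shared
   miRNAs into a tripartite ceRNA network, keeping only circRNA–gene pairs
   with the same expression direction (the ceRNA hypothesis: a circRNA that
   sponges a miRNA de-represses that miRNA's targets, so circRNA and target
   should co-vary);
4. a protein–protein interaction (PPI) network over the network genes
   (combined score strictly > 0.4) is analysed for betweenness, closeness
   and degree; genes strictly above the mean on **all three** are hub
   genes, and the hub-anchored sub-network nominates candidate circRNAs;
5. a 100 vs 100 cohort, 1:1 matched on sex and age (±3 years), is
   summarised (χ²; *t* or Mann–Whitney by a Shapiro–Wilk gate at 0.05),
   markers are tested by unconditional logistic regression (crude and
   adjusted for smoking, drinking, hypertension and diabetes), and the
   incremental value of each marker over that clinical model is quantified
   by AUC with the DeLong test, the integrated discrimination improvement
   (IDI) and the category-free net reclassification improvement (NRI).

## Synthetic-study generator

The generator's job is to emulate the statistical structure the analysis
assumes, with a composition designed so the pipeline's output is known in
advance.

**Expression.** Intensities are log-normal: Gaussian on the log2 scale,
per-feature baselines N(8, 2), i.i.d. within-sample noise with
`noise_sd = 0.2`, and small per-sample brightness offsets (SD 0.1) for
quantile normalisation to remove. Planted features are shifted by their
true log2 fold change in cases: 22 circRNAs at |log2FC| = 1.5 (21 up, 1
down) among 1000 features, and 439 genes at |log2FC| = 1.0 (229 up, 210
down) among 4000, of which 46 are tagged immune-related. Neither the noise
level nor the feature-panel sizes are published quantities; they were fixed
once by a Monte-Carlo power analysis so that the published screen settings
recover the planted sets essentially deterministically (probability ≈ 0.995
of exactly 22/22 circRNA hits with no false positives), which is what lets
the construction-level counts below act as an exact check of the
procedure's logic. Batches add a per-feature location effect
(N(batch shift, 0.3), default shifts 0 and +2) and a multiplicative noise
scale (1.0 and 1.5).

**Interaction tables.** The intended tripartite network has 14 circRNAs,
24 miRNAs and 15 genes connected by 56 edges; six miRNAs bridge the four
designed hub genes to five circRNAs, so the hub sub-network has the 5/6/4
composition. The emitted tables bury this truth among three decoy
families, one per pipeline filter: ~1000 miRNA–gene rows below the
"very high" confidence class (confidence filter), high-confidence rows
whose miRNA appears on only one side (miRNA-overlap step), and four
high-confidence direction-inconsistent pairings (ceRNA consistency
filter). Table sizes (110 circRNA–miRNA rows, 1087 miRNA–gene rows) match
the published prediction-table scale. The PPI table wires the 15 genes so
that 12 are connected by 23 true edges (scores in (0.45, 1)), with decoy
edges at or below the 0.4 cutoff — including one at exactly 0.4, which the
strict `> 0.4` filter must drop.

**Cohort.** Pairs are generated directly: each pair draws a sex (60%
male) and a case age N(61.7, 10.9) clipped to [35, 90]; the control age
differs by an integer in [−3, 3]. Binary covariates are Bernoulli at the
published per-group prevalences (smoking 0.36/0.50, drinking 0.18/0.30,
hypertension 0.55/0.79, diabetes 0.16/0.29). Marker levels are
equal-variance Gaussians on the log2 scale whose case–control mean shift
is ln(OR); by Bayes' rule the conditional law of case status given the
marker is then exactly a logistic model with the blueprint's odds ratio
per SD — the minimal generative law compatible with reporting odds
ratios. Defaults give two informative markers (OR 1.514 and 1.633 per SD,
the published per-unit estimates) and three null ones, mirroring the five
candidate circRNAs of which two validated. Stored marker columns are
2^z > 0 (relative-expression units); the evaluation stage log2-transforms
them before model fits, matching their multiplicative scale. Continuous
clinical indexes (PLR, NLR, MLR, hs-CRP) are log-normal around the
published group medians; they are descriptive only and carry no designed
link to the markers or outcome.

All draws come from named substreams of a single seed
(`numpy.random.SeedSequence(seed, spawn_key=(stage,))`), so outputs are
byte-reproducible and changing one stage's draws leaves the others intact.

## Numerical conventions

- **Quantile normalisation** maps every sample onto the row-wise mean of
  the column-sorted matrix; tied values receive the mean of the reference
  values across the tied rank span, so permutation-equivalent columns
  normalise identically. The transform is idempotent.
- **ComBat** is the parametric empirical-Bayes location/scale adjustment
  (via scanpy), with case/control status preserved as a model covariate
  (encoded numerically: an all-level dummy encoding would be collinear
  with the batch indicators). Batches confounded 1:1 with group are
  refused — the batch effect would be unidentifiable. The pipeline's gene
  stage applies ComBat without a preceding quantile normalisation: merged
  public expression sets arrive normalised from their source processing,
  and renormalising across batches whose case fractions differ can convert
  rank shifts into spurious fold changes.
- **DE screen**: FC = 2^(mean log2 case − mean log2 control); |FC| means
  max(FC, 1/FC) on the linear scale (1.5 and 1.2 are linear-scale
  idioms); two-sided pooled-variance *t* by default (Welch optional), no
  multiplicity correction by default (Benjamini–Hochberg behind a flag);
  an exact zero pooled variance is guarded with an epsilon and flagged.
  An exact zero fold change is reported as direction "up" with
  `passes = False`. Empirical-Bayes variance moderation (limma-style) is
  deliberately not reimplemented; on real 5 vs 5 arrays this is a known
  source of count differences relative to moderated screens.
- **Centralities**: degree is the edge count; closeness is
  (n_c − 1) / Σd within the node's connected component (≤ 1, matching the
  published table's scale); betweenness is unnormalised Brandes
  shortest-path load with each unordered pair counted once (the published
  values, e.g. 38.00, are far above the normalised range). All three are
  verified against a Floyd–Warshall path-counting oracle on every graph
  with ≤ 8 nodes. The hub rule requires strict superiority on all three
  averages: with any/all unspecified in prose descriptions, "all three"
  is the reading under which exactly four genes emerge.
- **Direction-consistency pruning** is maximal-retention: a miR–gene edge
  survives if *any* circRNA sharing that miRNA agrees in direction (and
  symmetrically for circ–miR edges); the surviving witnesses are mutually
  consistent, so one pass suffices and the result is independent of row
  order.
- **χ²** is Pearson without continuity correction — the convention that
  reproduces all four published categorical statistics (3.998, 3.947,
  13.026, 4.846) from their printed counts. **Mann–Whitney** uses
  mid-ranks, a tie-corrected variance and no continuity correction on Z
  (the common clinical-software convention). Against the exhaustive
  permutation distribution the right comparison for this statistic is the
  mid-p (half weight on the observed lattice point); the residual
  normal-approximation error is below ~0.01 in the rejection-relevant
  range at n = 8 per group, but can reach ~0.01–0.06 for n ≤ 7,
  an irreducible discreteness/Edgeworth effect at those sizes.
- **Logistic regression** is Newton/IRLS maximum likelihood (50
  iterations, tolerance 1e−8) with Wald 95% CIs on exp(coef); perfect
  separation is flagged with no estimates returned. The unconditional
  model is the default even for the matched cohort (matching the
  published adjusted-covariate analysis); a conditional (matched-pair)
  variant is provided as a clearly-labelled extension.
- **Sample size** uses the discordant-pair (Schlesselman) formula; at
  p0 = 0.2, OR = 2.6, α = 0.05, β = 0.15 it gives 97 pairs where the
  published design states 96 — a formula-variant discrepancy, so tests
  anchor the value within ±3 of the published figure rather than guessing
  the variant used.
- **AUC** is the Mann–Whitney concordance estimator with half credit for
  ties; variances and the correlated-AUC test come from DeLong structural
  components built from mid-ranks in O(n log n), checked in tests against
  an O(n²) definitional implementation and a leave-one-out jackknife.
  **NRI** is the category-free variant (range [−2, 2]; the published
  0.280–0.640 values live on this scale), with exact probability ties
  counting in neither direction. **IDI** is the difference in
  discrimination slopes with the paired-difference Wald SE. CIs are
  Wald-type on the raw index scale, clipped to each index's range.
  Probabilities are in-sample (apparent), matching a single-cohort
  design; no cross-validation is attempted, so all discrimination
  estimates are optimism-prone.

## Calibration suite: what it shows and what it does not

Under null simulations, the DE screen's *t* p-values, the DeLong test and
the NRI/IDI tests reject at 5% within [0.03, 0.07] (2000 replicates each).
The NRI/IDI null is a perturbation of predicted probabilities independent
of outcome; when instead a pure-noise covariate is added and the nested
model *refit in-sample*, the NRI test is mildly anticonservative
(measured ≈ 0.07), a known property of in-sample nested-model
reclassification tests — a reason to prefer pre-specified models or
validation data when these indexes carry the inference. With a planted
marker of OR ≈ 1.5 per SD at 100 vs 100, mean NRI and IDI across 200
simulated cohorts are positive with Monte-Carlo CIs excluding zero.

The generator emulates the *statistical* structure of the study —
log-scale Gaussian arrays, location/scale batch effects, logistic
marker–outcome links, independent covariates. It does not model
probe-level artefacts, correlated gene modules, covariate–marker
dependence (configurable but off by default, as no joint distribution is
published), miRNA expression, or any wet-lab step. Passing the
construction-level checks therefore certifies the pipeline's logic and
numerics, not the biology of any particular dataset; published
subject-level quantities (AUCs, ORs, NRI/IDI magnitudes) are reproduced
only in distribution, at the design's effect sizes.

## Problem sizes

Defaults keep a full run light: 1000 circRNA features × 10 arrays, 4000
gene features × 321 samples across two batches, 200 cohort subjects. A
complete pipeline run takes a few seconds; the calibration suite uses
2000 null replicates and 200 planted-effect replicates.
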