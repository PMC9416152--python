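# Methods

`metabotu` reimplements, as a tested pipeline, a multi-omics analysis for
moisture-perturbed wetland soils: GC-MS exometabolite profiles are used to
predict the presence or absence of 16S OTUs within each moisture treatment
(Dry-Wet, Wet-Dry, continuous Saturation), one random-forest classifier per
OTU, with out-of-bag (OOB) balanced-accuracy gating and pooled
mean-decrease-Gini importance ranking of candidate biomarker metabolites.
Because the original raw data are not publicly deposited, the package ships
a first-class synthetic-data generator that reproduces the statistical
structure the analysis assumes, with a ground-truth record of planted
metabolite -> OTU links so that recovery can be scored.

## The classification model

For each treatment and each eligible OTU, counts are binarized (present iff
count > 0) and a forest of `n_trees` CART-style trees is grown on bootstrap
samples of the treatment's samples, with the processed metabolite profiles
as predictors. At each node `mtry` candidate predictors are drawn without
replacement and the split maximizing the count-weighted Gini decrease

    n_t G(t) - n_L G(L) - n_R G(R),   G = 1 - sum_c (n_c/n)^2

over midpoint thresholds is taken. Each sample's OOB prediction is the
majority vote of the trees whose bootstrap bag excluded it. Model efficacy
is the balanced accuracy (TPR + TNR)/2 of the OOB predictions, which equals
plain accuracy when the classes are balanced. Variable importance is the
mean decrease in Gini: the summed impurity decrease of all splits on a
predictor, divided by `n_trees`.

An OTU is eligible within a treatment if it is present in at least 3 and
absent in at least 3 of that treatment's samples; models with OOB balanced
accuracy >= 0.80 are retained; all (metabolite, model) importance scores of
the retained models in a treatment are pooled, and scores at or above the
empirical 80th percentile of the pool are reported as strong-predictor
pairs. All four thresholds are configurable (`PipelineConfig`); gating
always precedes pooling (an ungated pool would let failed models dilute
the cutoff), and pooling across treatments instead of within is available
via `pooling_scope="global"`.

Forest defaults (500 trees, mtry = floor(sqrt(p)), node size 1, full-size
bootstrap with replacement) follow the standard classification-forest
conventions. Determinism: the master seed feeds a `SeedSequence` whose
spawned children drive each tree; per-OTU forests are seeded by
CRC32(master_seed, otu_id), so adding or removing OTUs does not perturb
other models. Candidate-predictor sampling and split tie-breaking (lowest
predictor ID, then lowest threshold) operate on sorted predictor IDs, so
results are invariant to column order. OOB vote ties go to "present" by
default (configurable); the downstream gate treats the classes
symmetrically, so the choice only matters at tied vote counts.

## Preprocessing

16S block: OTUs observed (nonzero) in fewer than 2 samples are removed.
Sample outliers are screened by a randomization test: the statistic for
sample i is its mean Jaccard distance (on presence profiles) to all other
samples; the null permutes each OTU column independently across samples
(preserving per-OTU prevalence) 999 times, each sample's observed statistic
is compared with its own statistic across the permuted datasets
(p = (1 + #exceedances)/(1 + permutations)), and Bonferroni-adjusted
p <= 0.05 flags a sample. Note the Bonferroni step implies permutations
must exceed n/alpha - 1 for a flag to be possible at all; 999 suffices for
n <= 49 samples. Relative-abundance screening uses upper-quartile
normalization: each sample's counts are divided by the 75th percentile of
its nonzero counts (numpy linear-interpolation percentile; the convention
is fixed in `ProcessingParams` because "75th quartile" is ambiguous across
software) and re-multiplied by the mean of those percentiles so magnitudes
stay count-like (pure division via `upper_quartile_rescale=False`). The
per-pair location test on log2(normalized + half-minimum pseudocount) is
Welch's t by default (Wilcoxon available); no specific test is canonical
for this screening step, so it is configurable. BH correction is applied
across the whole OTU x pair family at adjusted p < 0.05.

GC-MS block, two branches. For the classifier: log2 transform, then global
half-minimum imputation (every missing value becomes half the smallest
observed log2 abundance in the whole matrix; the constant is recorded),
then per-sample median centering — in that order, since the classifier
needs complete data and centering after imputation keeps every sample's
observed median at zero. For univariate testing: metabolites observed in
fewer than 2 samples in fewer than 2 treatments are dropped, then log2 and
median centering with missing values retained.

## Univariate model

Per metabolite, a linear mixed model (REML): log2-centered abundance =
treatment mean + soil-core random intercept + residual, fitted with
statsmodels MixedLM. Technical replicates enter as repeated measures within
core — that is what the random effect is for. All three pairwise treatment
contrasts are tested on the large-sample normal reference with a
single-step max-|z| adjustment: p_adj_i = 1 - P(max_j |Z_j| <= |z_i|) under
the contrasts' estimated correlation. Because three pairwise contrasts of
three means span a rank-2 space, the rectangle probability is computed
exactly by integrating the closed-form conditional interval probability
over a 2001-point grid on [-8.5, 8.5] (agrees with scipy's multivariate
normal CDF to ~2e-5, deterministic, and ~1000x faster); Bonferroni is
available as a documented fallback. If REML yields an unusable covariance
(boundary fits on sparse metabolites), the fixed-effects model (zero core
variance) is used for that metabolite and logged.

## The synthetic-data generator

Defaults are the study conditions: 41 samples split 10 (D-W) / 18 (W-D) /
13 (Sat), 4 cores per treatment with technical replicates sharing their
core's intercept, 125 metabolites, and a 250-OTU table (reduced from the
~12,600 of a real run; OTU count only changes compute, not structure).
Metabolite log2 abundance = baseline (N(10, 2)) + treatment shift (one draw
per metabolite x treatment, sd 1) + core intercept (sd 0.5, shared across
metabolites) + residual (sd 1), exponentiated to the raw scale, with
entries going missing independently at rate 0.10 — typical magnitudes for
derivatized GC-MS soil data. Target OTUs get presence probability
logistic(intercept + slope * z) with z the globally standardized observed
log2 abundance of a driver metabolite (missing observations contribute
z = 0), slope magnitude = `effect_size`, random sign, intercept ~
U(-0.5, 0.5). Background OTUs are present at a per-OTU prevalence ~
U(0.2, 0.8) thinned by a 15% zero-inflation factor; the zero-inflation is
applied to background OTUs only so the planted links remain exactly as
drawn. Present entries receive 1 + negative-binomial counts (size 0.5), so
presence always corresponds to a nonzero count, matching the binarization
semantics.

What the generator does not emulate: phylogenetic correlation among OTUs,
metabolite-metabolite correlation networks, compositionality of counts,
non-random missingness (real GC-MS missingness is abundance-dependent), and
treatment-by-core interactions. Passing tests therefore show that the
pipeline recovers the planted generative structure, not that the biological
conclusions of any particular soil study are correct.

## Power regime used by the recovery tests

The planted-link recovery tests run at 40 samples per treatment, 100
metabolites, 5 driver metabolites, 10 target OTUs. Two facts shape the
configuration used there, established by forward power analysis during
design:

* The Bernoulli-logistic link puts a hard ceiling on attainable accuracy:
  even the Bayes classifier achieves expected accuracy E[sigmoid(|logit|)],
  about 0.82 at slope 3 — at the 0.80 gate there is essentially no power.
  The recovery tests therefore use slope 20 (near-deterministic presence,
  Bayes accuracy ~0.96).
* Between-treatment shifts of a driver metabolite translate, through the
  global standardization, into per-treatment offsets of the logit; at large
  slopes these saturate presence within a treatment, leaving only
  noise-tail minority samples for the classifier. The recovery tests set
  `treatment_shift_sd = 0` and `core_sd = 0` so the planted signal lives in
  the within-treatment variation the per-treatment models actually see, and
  use missingness 0.05.
* At n = 40 with 100 predictors, mtry = sqrt(p) = 10 rarely samples the
  single informative predictor near the root; the recovery tests use
  mtry = p/3 = 33, which raises the gate pass rate of truly driven OTUs
  from ~0.65 to ~0.9 without affecting null behaviour (chance-level OOB
  balanced accuracy is insensitive to mtry).

The matching null experiment (slope 0, prevalence 1/2, same dimensions)
checks the other side: mean OOB balanced accuracy within [0.4, 0.6], gate
pass rate <= 15%, and a typically empty biomarker set — the same mechanism
that can produce an empty result for a real treatment with few samples.

## Numerical choices and degenerate inputs

* Quantiles everywhere use numpy's linear interpolation.
* Split search requires a strict impurity decrease (> 1e-12); leaf class
  ties go to "present".
* Jaccard distance of two all-absent profiles is 0 by convention, with a
  warning.
* An all-zero count sample makes upper-quartile normalization undefined and
  raises, naming the sample; likewise median centering of a sample with no
  observed values.
* The manifest is written with sorted keys and no timestamp by default, so
  identical seeds give byte-identical artifacts (timestamps are opt-in).
* Seeds are kept below 2^31; independent generator streams are derived per
  stage so regenerating one block does not perturb the others.

## Problem sizes in the shipped tests

Unit tests run at tens of samples and tens of features. The recovery and
null experiments use 20 master seeds at the dimensions above (~500 forest
fits each); the outlier-test power study uses 100 seeds at 21 samples x 60
OTUs with 999 permutations and the size study 200 seeds at 15 x 40 with
499; mixed-model recovery uses 100 seeds at 201 samples. The determinism
check runs the full pipeline twice at reduced scale (25 OTUs, 15
metabolites, 30 trees) and compares artifacts byte for byte.

## Known limitations

* The forest is binary-class only; no regression, class weights,
  permutation importance, or surrogate splits (inputs are imputed
  upstream).
* OOB-based gating reuses the training samples; with 10-18 samples per
  treatment the balanced-accuracy estimate is noisy, and the gate should be
  read as a screen, not a validated error bound.
* Importance pooling uses raw mean-decrease-Gini values without per-model
  normalization; models with larger node counts contribute larger scores.
* Technical replicates are treated as independent samples by the
  classifier (the mixed model does account for core nesting); the manifest
  carries this caveat.
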