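# Methods

## Problem setting

After hard-filtering an exome for rare variants (MAF ≤ 1%), the remaining
non-synonymous SNVs must be ranked by their probability of causing a
Mendelian phenotype. `pathologit` treats the standardized scores of up to
five upstream predictors — SIFT, PolyPhen2, LRT, MutationTaster, PhyloP —
as features and never re-trains the predictors themselves. Throughout,
*pathogenic* means affecting a Mendelian phenotype, as distinct from
*deleterious* (under purifying selection) or *damaging* (abolishing protein
function); the hard part is separating pathogenic variants from **other
rare** variants, which share most structural properties, rather than from
common polymorphisms.

## Score standardization

Each tool's raw score is min–max rescaled to [0, 1] and oriented so larger
always means more likely pathogenic. Ranges and orientations are
configuration (`ScoreScale`), not code: SIFT is flipped (low native score =
damaging); PolyPhen2, LRT and MutationTaster already live in [0, 1]; PhyloP
has no canonical bounded range, so the default scale (−14, 6) covers typical
vertebrate conservation scores and `standardize_table` can instead fit the
PhyloP range min–max over the input table. This choice only needs to be
monotone: every downstream quantity except the raw coefficient values is
invariant to monotone rescaling.

## The logistic combiner and its bias correction

On a labeled benchmark the combiner fits
P(Y=1|X) = expit(α + β·X) by IRLS/Newton iterations: convergence when the
largest coefficient update falls below 1e-8, at most 100 iterations. Under
perfect separation (or a singular weighted normal-equation step) the fit
falls back to a ridge-stabilized estimate (penalty 1e-6, working weights
floored at 1e-10) with an explicit `SeparationWarning`; posteriors then
saturate near 0/1, which preserves ranking and classification. Training is
complete-case per tool subset: variants missing any subset score are dropped
and the training positive fraction `p_disease_sample` refers to that
complete-case set. The reduced SIFT+MutationTaster model exists precisely
because it needs non-missing scores for only two tools, keeping more of an
individual's variants usable.

Benchmarks over-represent pathogenic variants relative to a genome, which
biases only the intercept of a logistic model. The unbiased posterior
divides the sample posterior odds by the sampling odds ratio
R = odds(benchmark) / odds(population): equivalently, subtracting log R from
the linear predictor. Two consequences are load-bearing and property-tested:
with prior = training fraction, R = 1 and the correction is the identity;
and rankings are invariant to the prior, so cutoff-based classification is
unaffected by R when the cutoff is chosen on the same scale.

Classification uses posterior ≥ cutoff (ties classify as pathogenic, a
deterministic documented rule); variants missing a required score are
reported `unpredicted` and excluded from denominators.

## The weighted-average comparator

The comparator re-implements a CONDEL-style weighted average of normalized
scores. Per tool, training data supply (a) the cutoff maximizing MCC over a
1001-point grid (smallest maximizer on ties) and (b) empirical complementary
cumulative distributions P(S ≥ s) per class as right-continuous step
functions. A variant's consensus score averages its available tool scores
with weight 1 − CCDF_neg(s) above the tool cutoff (confidence the score is
not from the negative class) and 1 − CCDF_pos(s) below it. The original WAS
formulation is ambiguous about whether below-cutoff tools contribute s or
1 − s; this is a selectable `strategy` ("score", the default, averages the
scores themselves; "complement" flips below-cutoff contributions). Tools
with fewer than two distinct scores in a class are excluded with a warning;
if all present tools have zero weight the unweighted mean is used so the
score stays in [0, 1].

## Evaluation

- **Cutoff sweep.** 1001 evenly spaced cutoffs on [0, 1] (1e-3 resolution
  exceeds the precision of any metric reported); predicted positive iff
  score ≥ cutoff, so cutoff 0 calls everything positive.
- **Folds.** Stratified K-fold (each fold's positive count within one of
  proportionality), shuffled deterministically by seed; stratification
  prevents degenerate folds on imbalanced benchmarks. A training fold that
  loses a class triggers one re-split with a fresh seed, then an error.
- **ROC AUC.** Trapezoidal area under sensitivity vs 1 − specificity with
  (0,0) and (1,1) appended. On tie-free data at exact score thresholds this
  equals Mann–Whitney pair counting (oracle-tested); ties receive half
  credit via the trapezoid.
- **PR AUC.** Between consecutive achievable confusion points, false
  positives are interpolated linearly in true positives, making precision a
  hyperbolic segment; the area under precision–recall is accumulated in
  closed form (∫(t dt)/(at+c) per segment) rather than by linear
  interpolation in precision, which would overstate the area. Points tied
  in TP are ordered by FP so the curve passes through the attainable corner.
- **Cross-validation.** Per fold: train on K−1 folds, score the held-out
  fold, sweep cutoffs. Confusion counts are averaged across folds at each
  grid cutoff and the primary AUCs are computed on the averaged curves;
  means of per-fold exact-threshold AUCs are also reported. The
  MCC-maximizing cutoff is selected per fold on the training folds;
  `max_mcc` averages each fold's held-out MCC at its training-optimal
  cutoff (the deployable quantity), while `max_mcc_test` averages the
  per-fold maxima of the held-out sweep (an optimistic bound; both are
  reported because "maximal MCC" is ambiguous between the two).
- **Mann–Whitney U** uses exact enumeration when both samples have ≤ 20
  tie-free observations, otherwise the normal approximation with continuity
  and tie-variance corrections (via scipy).

## Load estimation

For one individual: restrict to rare variants fully scored on the model
tools (n_used), classify at the benchmark-training MCC-optimal cutoff,
giving the predicted pathogenic fraction P\*. Since
P\* = sens·P + (1−spec)(1−P), the true fraction is
P = (P\* + spec − 1)/(sens + spec − 1), clamped to [0, 1] (the raw inversion
is negative when P\* is below the false-positive rate; the clamp is the only
defensible choice for a proportion). The inversion requires an informative
classifier, sens + spec > 1. The total load is N = round(n_used × P), half
away from zero — heterozygous-genotype counting, since homozygous derived
genotypes are rare enough that each pathogenic variant contributes one
allele. Sensitivity/specificity come from K-fold cross-validation on the
benchmark; the point estimate averages the CV repeats.

**Confidence interval.** The 10-fold cross-validation is repeated (default
200 times); each repeat yields a fold-averaged (sens, spec) pair at the
per-fold training-optimal cutoffs, hence one inverted load; the CI is the
2.5/97.5 percentile of those loads, lower bound clamped at 0. This interval
quantifies the **cross-validation variability of the classifier's operating
characteristics only** — in practice dominated by the re-selection wobble of
the MCC cutoff, whose plateau leaves the cutoff ill-determined while
specificity is steep in it. It does *not* represent the sampling noise of
the individual's own variant draw (the realized false-positive count behind
P\*), nor the mismatch between the single deployed cutoff and the fold-cutoff
distribution. Simulation with the package's own generator (individuals of
400 rare variants at a 5% true fraction) shows the realized load falls
outside the interval in roughly half of replicates, at scaled-down *and*
full benchmark sizes; coverage-style guarantees should therefore not be read
into the interval at small n. This is a property of the interval's design,
inherited deliberately for comparability, and is the package's main known
limitation.

**Consanguinity.** A child of a union with inbreeding coefficient F is
expected to be homozygous at F·N/2 of an ancestor's N pathogenic alleles.
`consanguinity_table` tabulates the eight standard relationships
(F = 1/4 siblings; 1/8 half siblings, uncle–niece/aunt–nephew, double first
cousins; 1/16 first cousins; 1/32 first cousins once removed and double
second cousins; 1/64 second cousins), rounded to one decimal, half away from
zero. `posterior_surface` tabulates the unbiased posterior over a
(prior, common score) grid with all tools set equal, showing how a small
prior caps the attainable posterior regardless of scores.

## Synthetic data

The generators emulate the statistical structure the combiner exploits, not
real genomes. Per variant a latent severity z ~ Beta(3,2) (positive class)
or Beta(2,3) (negative) is drawn; each tool's score is Beta-distributed with
concentration 8 around clip(w·z + (1−w)·μ_tool,class), w = 0.6, and per-tool
class means chosen so single-tool ROC AUCs land at ≈ 0.75–0.83 with
MutationTaster strongest and PhyloP weakest — the informative-but-imperfect
regime in which combining helps — and inter-tool correlations are weak to
moderate (Spearman ≈ 0.35) through the shared latent. Default sizes are
5,340 positive / 4,752 negative; per-tool missingness defaults to 15%,
matching the observation that a sizable minority of an individual's rare
variants lack scores for any given tool. Class-specific score ranges allow
degenerate fixtures (disjoint ranges = perfectly separable; identical class
parameters = pure noise). `generate_individual` draws round(n × f) variants
from the positive-class generator and returns truth labels separately — the
emitted table never contains them. `generate_logistic_benchmark` draws
scores i.i.d. uniform and labels from an exact logistic law, for parameter
recovery tests. All generators are deterministic given their seed.

What passing tests on these fixtures do **not** show: robustness to
miscalibrated or adversarial upstream scores, linkage or allele-frequency
structure, annotation errors (e.g. pseudogene mis-mapping), or benchmark
composition biases of real curated datasets.

## Numerical and design choices

- IRLS tolerance 1e-8 / 100 iterations / ridge 1e-6 fallback: reproducible
  fits on small fixtures; coefficients above 50 in magnitude are treated as
  separation.
- Cutoff grid ties resolve to the smallest maximizer (deterministic); the
  `classify` tie rule is ≥ at the cutoff.
- Rounding of loads (integer) and consanguinity expectations (one decimal)
  is half away from zero, matching the convention of the tabulated values.
- MAF filtering is strictly greater-than (a variant at exactly 1% is kept);
  variants absent from the frequency lookup are kept — hard filtering only
  removes variants found common in databases.
- VCF records missing DP/GQ/QUAL are excluded conservatively with a warning:
  the quality rule is an exclusion filter, and absent evidence of quality
  fails it. Only biallelic SNVs are consumed; others are counted and
  skipped.
- Study scale in tests: benchmarks of ~600–1,700 variants for CV behaviour,
  n = 50,000 for parameter recovery, n = 5,000 for the chance/perfect
  calibration checks, and 50 generator replicates × 50 CV repeats × 5 folds
  for interval coverage — sizes chosen so each property is measured at the
  smallest scale where its expected behaviour is unambiguous.
- The per-genome estimation default is the SIFT+MutationTaster model (best
  trade-off between predictive power and variant coverage under
  missingness), with the train-set MCC-max cutoff policy.

## Known limitations

- The repeated-CV load interval is anti-conservative for realized loads at
  small n (see above).
- PhyloP's [0, 1] mapping is a convention; only monotonicity matters for
  every reported metric.
- The WAS comparator follows the cited weighting scheme, not any specific
  historical implementation byte-for-byte; its below-cutoff orientation is
  an explicit strategy choice.
- `estimate_load` assumes the individual's variants are exchangeable with
  the benchmark's score distributions; systematic shifts (platform,
  annotation version) bias the inversion.
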