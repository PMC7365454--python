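# Methods

## Rank-comparison pair features

For an ordered miRNA pair (G1, G2) and sample *s* the feature is the
indicator `1{expr(G1, s) < expr(G2, s)}`; exact ties score 0 (the literal
reading of "strictly smaller → 1, otherwise 0"). For a candidate list of
*k* miRNAs the package emits one feature per unordered combination,
oriented with G1 the lexicographically smaller identifier — an arbitrary
but deterministic convention; the embedded published panel instead keeps
its printed orientation. Any strictly increasing per-sample map leaves
every indicator unchanged, which is the design argument for using these
features across array platforms; the test suite checks this invariance
property end-to-end (features *and* ensemble predictions) under random
affine, odd-power and monotone-interpolant distortions.

## Screening

Both screening stages use a two-sample t-test with the Welch
(unequal-variance) statistic by default; the pooled-variance form is
available via `equal_var=True`. The "effect" used for ranking is the
absolute difference of class means — for binary pair indicators this is
the difference in indicator frequency, a directly interpretable quantity
on [0, 1]; ranking by |t| is available via `rank_by="t"`. Selection keeps
features with p < α (default 0.05, no multiple-testing correction — the
screen is a ranking device, not an inference) and caps at the top *n* by
effect (250 for miRNAs, 80 for pairs), breaking ties by ascending p then
identifier so results are reproducible.

Degenerate features: when both classes are constant at the same value the
test is undefined and the feature is reported with t = 0, p = 1, effect 0
and a `degenerate` flag. When both classes are constant at *different*
values the feature separates the classes perfectly and is reported with
p = 0 and effect equal to the mean difference — collapsing this case to
p = 1 would silently discard the strongest possible feature.

Near-constant pairs (majority value in strictly more than 90% of
*training* samples; the boundary fraction is retained) are removed before
the pair screen: they carry almost no contrast and only inflate the
candidate universe.

## KNN imputation

Missing intensities are imputed before any filtering, from **gene**
neighbors (the convention of expression-array imputation tools): the
distance between two genes is the root-mean-square difference over the
samples where both are observed (genes sharing no sample are infinitely
distant), and a missing cell (g, s) becomes the unweighted mean, at s, of
the k = 10 genes nearest to g that are observed at s. If no neighbor is
observed at s the gene's own observed mean is used. Observed cells are
never modified, so imputation is idempotent and the identity on complete
matrices. A gene with no observed value at all is an error. k = 10 is the
conventional default of the classic KNN-imputation tools; the distance
convention is a documented choice since upstream descriptions typically
omit it. Note the imputation (and the abundance filter) run on the full
cohort before the train/test split, mirroring the original analysis
order; this is a mild information leak across the split and is accepted
deliberately for fidelity.

## Stratified split

The 3:1 split draws `round(n_class * 0.75)` samples per class
(round-half-up) into training, uniformly at random, independently of the
input row order. Round-half-up is forced by the published partition
arithmetic: 402 and 275 samples per class yield 302 + 206 = 508 training
and 169 test samples only under that rounding.

## The RGLM ensemble

Each of `n_bags = 100` bags:

1. draws a bootstrap sample of the training set (size n, with
   replacement); the samples never drawn form the bag's out-of-bag (OOB)
   set;
2. draws `features_per_bag` (default 0.3) of the candidate features
   without replacement;
3. pre-filters candidates by a point-biserial correlation test against
   the class label on the in-bag samples (two-sided, α = 0.05), keeping
   at most `corr_keep = 20` by ascending p;
4. grows a forward stepwise binomial GLM from the intercept-only model,
   admitting at each step the term with the best AIC improvement, until
   no term improves the AIC or `max_terms = 10` is reached. GLMs are fit
   by IRLS (statsmodels); when a bag separates perfectly (|log-odds|
   above 15 or a failed fit) the selected terms are refit with an
   L2-stabilized logistic regression and the bag is flagged. A bag whose
   filter keeps nothing becomes intercept-only at the in-bag log-odds.

Prediction: each bag votes positive (sarcoma) when its GLM probability
exceeds 0.5; the ensemble label is positive when the vote fraction
reaches `vote_threshold = 0.5`, ties going to sarcoma — in a screening
context the tie should favour sensitivity. OOB accuracy scores each
training sample by majority vote over only the bags that held it out.

`features_per_bag = 0.3` is deliberately small: like a random forest's
`mtry`, small bags decorrelate the members, so the occurrence counts that
drive thinning spread over *all* informative pairs instead of
concentrating on the few that happen to rank best in the training draw.
With large bags every member sees, and forward selection stops at, the
same handful of pairs. All ensemble knobs are constructor parameters.

### Thinning

Occurrence of a feature = number of member GLMs whose final model
includes it. Candidate cutoffs are the distinct occurrence counts in
descending order; for each cutoff the ensemble is refit restricted to the
features occurring at least that often — with the *same* bootstrap draws
and bag feature subsets, so only the restriction changes — and the
smallest feature set whose OOB accuracy is within `thin_tolerance` of the
full model's is returned (1 OOB misclassification per 100 training
samples by default, operationalizing "negligible loss"). With no cutoff
within tolerance the lowest cutoff (all used features) is returned.

### Determinism

All bag randomness derives from `random_state` through a spawned
`SeedSequence` stream; identical data, configuration and seed give
bit-identical models, occurrence counts and predictions. Models serialize
to a single self-describing JSON document (coefficients, bag structure,
hyperparameters, seed, format version), so a reloaded model predicts
identically and can even be re-thinned.

## Evaluation

Standard 2×2 confusion for a designated positive class, with accuracy,
sensitivity TP/(TP+FN), specificity TN/(TN+FP), PPV TP/(TP+FP) and NPV
TN/(TN+FN). A zero denominator marks the metric undefined rather than
raising. Percentages are formatted round-half-up to one decimal.
Sarcoma is the default positive class; every report can be recomputed
with healthy positive (`ConfusionCounts.swapped()` — swapping exchanges
sensitivity↔specificity and PPV↔NPV exactly). Upstream descriptions of
this metric family sometimes print "sensitivity = TP/(TP+FP)", which
duplicates PPV and cannot reproduce tables that list sensitivity and PPV
as distinct columns; the standard definition is used here.

The pipeline driver scores external cohorts with training-derived
artifacts only: the external table is imputed separately and only the
pairs of the final model are binarized from it.

When a signal-free cohort empties a significance screen, the driver falls
back to the best-ranked features regardless of significance (logged as a
fallback stage) so that a null analysis degrades to a majority-class
classifier instead of aborting.

## Synthetic cohorts

The generator emulates a two-class log2-intensity serum miRNA array
cohort. Gene axis layout: an abundant stratum (per-gene means uniform on
[9, 13]) and a low stratum (means uniform on [5, 7.5]) on either side of
the abundance threshold of 8; within the abundant stratum, the first
`n_differential` genes are shifted by `effect_size` log2 units in sarcoma
and the next `2 * n_planted_pairs` genes are consumed pairwise by the
planted pairs. Within-class noise is Gaussian (`noise_sd`, default 1.0 —
a realistic within-class spread for log2 array intensities). Missing
cells are completely at random at `missing_rate`, never leaving a gene
fully unobserved. Defaults mirror the discovery cohort's scale (275/402
samples, 362 abundant miRNAs).

**Planted pairs** are implemented by an exchangeable within-sample swap:
both members share a base mean, two iid values are drawn per sample, and
a Bernoulli(`flip_prob`) draw decides which member receives the larger
value (orientation favoured in healthy, reversed in sarcoma). The
empirical orientation frequency is therefore *exactly* binomial, which
the tests exploit. An alternative — class-conditional mean offsets on one
member — was rejected because it makes *cross pairs* (genes from
different planted pairs) carry as much class signal as the planted pairs
themselves, so "recover the planted pairs" would be an ill-posed check.
Under the swap construction each member still acquires a marginal class
shift of about ±0.5·`noise_sd` (it is the min of two draws in one class
and the max in the other), which is what lets planted genes pass the
miRNA screen; cross pairs retain a strictly weaker indicator contrast
(≤ ~0.6 versus 0.90 for planted pairs at `flip_prob` 0.95), further
damped by spacing the pair base means across [9.5, 13.5]. Differential
genes all shift in the same direction (elevated in sarcoma — the usual
picture for tumor-secreted circulating miRNAs); same-direction shifts
cancel in within-sample comparisons, so the differential stratum does not
itself plant strong pair features.

What the generator does *not* emulate: probe chemistry and normalization
artifacts, covariate structure (age, sex, stage), correlated missingness,
or inter-gene correlation beyond the planted structure. Passing tests on
synthetic cohorts demonstrate that the pipeline recovers the structure it
assumes — not that real serum cohorts contain that structure.

### Reference benchmark

`planted_benchmark_config(seed)` fixes the scaled-down benchmark used by
the acceptance script and the recovery tests: 150 samples per class, 300
miRNAs (150 abundant), 30 differential at 1.5 log2 units, 10 planted
pairs at `flip_prob = 0.95`, 2% missing cells. At these settings the
pipeline reaches perfect or near-perfect internal-test accuracy (74 test
samples) and ranks every planted pair above every decoy in ensemble
occurrence; the problem sizes keep a full run under a minute on one CPU.

## Numerical conventions and edge cases

- Abundance comparison is strict (> 8); "half of the samples" is
  inclusive (≥ 0.5).
- Near-constant filter is strict (> 0.90 removed, exactly 0.90 kept).
- Expression ties in a pair score 0.
- Vote-fraction ties go to the positive class.
- Stepwise AIC comparisons use a 1e-12 slack; exact AIC ties keep the
  candidate earlier in the (p-value, identifier) pre-filter order.
- Expression files round-trip bit-exactly: floats are written with
  shortest round-trip precision and parsed with `round_trip` precision.
- Missing-value sentinels: empty cell, `NA`, `NaN` (case-insensitive).

## Known limitations

- The pre-split imputation/abundance filtering leak (above) is inherited
  from the original analysis order.
- Thinning judges cutoffs by OOB accuracy, which saturates on strongly
  separable training data; the procedure may then keep a panel smaller
  than what maximizes held-out redundancy.
- The correlation pre-filter's in-bag p-values are computed on bootstrap
  samples, whose duplicated observations make the nominal α
  anti-conservative; this only affects how many candidates reach the
  stepwise search, which re-judges them by AIC.
- With `n_bags = 100` a training sample fails to appear in any OOB set
  with probability ≈ (1 − e⁻¹)¹⁰⁰ ≈ 10⁻³⁹; such samples are simply
  excluded from the OOB estimate.
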