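# Methods

## The problem and the model

`embryosig` mines an *interpretable rule signature* for predicting whether an
IVF embryo will reach the expanded blastocyst stage on day 5 (BL) or not
(nBL), from 30 variables recorded in clinical routine: 6 woman-related
(age, BMI, day-3 FSH, AMH, antral follicle count, years of infertility),
10 COS-related (stimulation dose and outcome variables, including the
ovarian sensitivity index OSI = retrieved COCs x 1000 / total gonadotropin
dose) and 14 embryo-related (insemination technique, the day-2 IMCS
morphology score, the time-lapse cytokinesis timings tPNa, tPNf, t2, t3,
t4, t8 in hours post-insemination, and six derived intervals).

The estimand is not a black-box classifier but a short ordered list of
threshold rules, e.g. `IF imcs > 6.5 AND t4 <= 39 THEN BL`, chosen so that
the rules' binary firing indicators, fed to a standard classifier, maximize
cross-validated AUC.  Clinically this yields explicit cut-offs a lab can
read, rather than feature weights.

The pipeline has four stages:

1. **Feature selection.**  Features are ranked by three methods — a
   univariate rank-statistic filter (standardized two-sided Mann-Whitney
   statistic), the absolute coefficients of an L1-regularized logistic
   regression, and the impurity importances of a random forest — and the
   ranks are aggregated.  Nested top-k sets (k = 3 … 30) are scored by
   repeated stratified 10-fold cross-validation with every classifier in a
   roster; per k the best mean AUC over the roster is recorded, and the
   chosen k is the smallest within one standard error of the curve maximum.
2. **Rule extraction.**  A seeded bagged ensemble of shallow CART trees
   (default 50 trees, depth 3, bootstrap resampling) is fitted on the
   selected features; every root-to-leaf path becomes a candidate rule
   predicting the leaf-majority class.  Per-feature conditions are
   simplified to their tightest interval, rules below a minimum support
   (default 5% of the training cohort) are dropped, and duplicates are
   collapsed.
3. **Rule selection.**  Each rule is scored on the training cohort by the
   Matthews correlation coefficient,
   MCC = (TP·TN − FP·FN) / √((TP+FP)(TP+FN)(TN+FP)(TN+FN)),
   which equals the phi coefficient of the binary prediction/label vectors
   and is robust to the ~36/64 class imbalance.  Rules with MCC ≤ 0 are
   unpredictive and dropped.  Two rules are redundant when the phi between
   their firing vectors exceeds 0.8 *and* they share at least one feature;
   the lower-MCC rule of such a pair is dropped.  Survivors form the
   rule-correlation graph (nodes weighted by MCC, edges at association
   > 0.8); isolated vertices are rules carrying independent information.
4. **Rule evaluation.**  Surviving rules, ordered by training MCC, are
   encoded as binary features and the k-prefix encodings are scored by
   repeated stratified CV with every roster member.  The signature is the
   smallest prefix within one standard error of the best max-over-roster
   AUC.  The frozen signature is then evaluated on an independent cohort:
   classifiers are refitted on the training encoding only and scored on
   the validation encoding; reported AUC and accuracy are maxima over the
   roster.

### AUC and the classifier roster

AUC is always computed in its Mann-Whitney form — the probability that a
random positive outranks a random negative, ties counting one half — from
mid-ranks, so it is exact for the piecewise-constant scores that binary
rule encodings induce.  The roster spans the four classical model families:
SVM and k-NN (geometric), logistic regression and Gaussian naive Bayes
(probabilistic), random forest (rule-based), gradient boosting and AdaBoost
(ensembles), all with library-default hyperparameters and a fixed seed.
The *fast* profile used for desk-scale runs restricts the roster to the two
probabilistic members and reduces CV to 10-fold x 10 repeats; the *full*
profile is 10-fold x 100 with all seven members.  Accuracy uses the 0.5
threshold on the predicted positive-class probability.

### Missing data

Missingness is first-class.  Conventional-IVF embryos structurally lack
tPNa and tPNf−tPNa (fertilization is checked only after cumulus removal),
and the schema validates that pattern rather than imputing it.  Policies
per stage: moments for z-scoring ignore missing values and propagate them;
PCA mean-imputes *for the embedding only*; CV classifier pipelines
median-impute with the imputer fitted on the training folds only (no
leakage); a rule never fires on a missing value (conservative); the
univariate filter and the Kruskal-Wallis tests use complete observations
per feature.

## Design choices where the design was open

* **One-standard-error rule, twice.**  "Balanced cut-off between set size
  and association strength" is operationalized as the smallest k within one
  SE of the maximum, both for feature-set size and for signature size.  For
  the signature a strict argmax was tried first and found to drift to
  larger k on CV sampling noise from uninformative rules; the one-SE rule
  restores parsimony without losing measurable AUC.
* **Rank aggregation by median.**  The L1 ranker has a known failure mode
  under the strong collinearity of cytokinesis timings: the lasso keeps one
  member of a correlated group and zeroes the rest, so its ranks are
  degenerate exactly where the filter and the forest agree a feature is
  informative.  The median of the three ranks is robust to one discrepant
  ranker; mean aggregation remains available via configuration.  For the
  same reason the default L1 penalty is mild (C = 10).
* **Redundancy requires both criteria.**  A rule pair is pruned only when
  firing-vector association is high *and* a feature is shared: two rules on
  disjoint features that happen to fire on similar embryos both carry
  clinically distinct cut-offs and are kept (they will appear as an edge in
  the graph instead).
* **MCC conventions.**  A confusion table with any zero marginal gets
  MCC = 0 (the usual convention for degenerate tables).
* **Split rounding.**  The stratified split assigns round-half-up of
  `train_frac x class count` per class to the training side, the rule that
  reproduces 403/172 from 210/365 at 70%.  An epsilon guards against binary
  representation error (0.7 x 365 evaluates just below 255.5).
* **Z-scores** use the sample (n−1) standard deviation.
* **Fertilization-rate denominator** is mature oocytes by default,
  configurable to retrieved COCs, so the feature is comparable across
  insemination techniques.

## The synthetic cohort generator

No public embryo-level dataset exists for this problem, so the package
ships a seeded generator that reproduces the *structure* the analysis
relies on, with defaults mirroring the study conditions: 80 cycles, 575
embryos, expected prevalence 36.5%, roughly a third of cycles inseminated
by conventional IVF.

* **Nesting.**  Woman- and COS-related variables are drawn per patient and
  repeated across that patient's embryos (a flag breaks the nesting for
  ablation tests).
* **Woman <-> COS coupling.**  A patient-level ovarian-responsiveness
  latent u drives both blocks; the COS driver is
  w = c·u + √(1−c²)·η with c = `woman_cos_coupling` (default 0.6), so the
  cross-block mean |Pearson r| rises monotonically with c and vanishes at
  c = 0.  OSI, the counts and the rates are stored exactly as derived from
  their definitions, never rounded into inconsistency.
* **Embryo block and guaranteed ordering.**  Each embryo has a
  developmental-pace latent; tPNa and the five inter-event increments are
  lognormal with that shared latent (strength `embryo_block_coupling`),
  so all event times are strictly positive and ordered by construction
  and the timing block is internally correlated.  Typical values are
  centred on tPNa ≈ 6.5 h, tPNf ≈ 23.5 h, t2 ≈ 26 h, t3 ≈ 36.5 h,
  t4 ≈ 38.5 h, t8 ≈ 55.5 h.  IMCS decreases with slower pace on a
  half-point 0–10 scale.
* **Labels.**  A logistic model in the planted rules' firing indicators.
  The intercept is calibrated by root finding so the *post-noise* expected
  prevalence equals the configured one (the pre-noise rate is
  (p − ε)/(1 − 2ε) under flip probability ε).  An infinite rule weight is
  the noiseless limit: labels equal the rule indicator exactly.  The
  ground truth records every embryo's firing indicators and Bayes-optimal
  score, so downstream recovery can be measured against the cohort's own
  information ceiling.
* **Default planted signature.**  Three single-condition rules, one per
  correlation block: `imcs > 6.5`, `t4 <= 39 h`, `osi > 5.2`, with
  log-odds weights 5.0/4.5/4.0.  With 10% label noise this yields a Bayes
  AUC around 0.85 — near the ceiling imposed by the 8-level score such a
  three-rule logistic model can produce, which is why the weights are set
  at the saturation point rather than larger.

**What the generator does not emulate:** real per-feature marginal
distributions (not published at embryo level), real within-patient embryo
correlation magnitudes (exposed as a parameter, never asserted), any
relationship between semen quality and insemination technique, and
time-varying annotation error.  Passing recovery tests therefore
demonstrates that the pipeline finds planted threshold structure under
realistic nesting, collinearity and noise — not that it would achieve any
particular AUC on real patients.

## Numerical and degenerate-input conventions

Constant features z-score to all zeros with a warning and rank last in the
filter.  Zero denominators in derived rates leave the value missing with a
warning.  Correlation entries need ≥ 3 complete pairs.  Kruskal-Wallis
uses the tie-corrected H with a χ²(1 df) reference; features missing in a
group (or with all values tied across both) are flagged untestable rather
than scored.  All stochastic components (generator, bootstrap, tree seeds,
fold assignment) derive from explicit integer seeds; the full pipeline is
byte-reproducible from its config.

## Problem sizes used for verification

The shipped verification suite runs the full pipeline on 575-embryo
synthetic cohorts with the fast profile (two-classifier roster, 10-fold CV
with 2–10 repeats, 30 trees, prefix sweep capped at 15 rules), which keeps
a five-seed recovery study under a few minutes on one core.  Unit-level
oracle checks (MCC vs phi coefficient, rank AUC vs exhaustive pair
counting) use 1,000 random confusion tables and 200 random score vectors
at tolerance 1e-12.  The full profile (seven classifiers, 100 repeats) is
the protocol-scale configuration and is exposed via `profile="full"`.

## Known limitations

* The printed rule counts of the original development cohort (71 extracted,
  23 selected, 6 in the signature) are properties of unavailable patient
  data; this implementation reproduces the procedure, and its counts on
  synthetic cohorts differ with the data-generating mechanism.
* Prefix search over MCC-ordered rules is a greedy stand-in for exhaustive
  subset search (exponential in the number of selected rules); correlated
  rule sets can in principle hide a better non-prefix combination.
* No multiple-testing correction is applied to the per-feature
  Kruskal-Wallis screen; it is descriptive, not confirmatory.
* No probability calibration of classifier outputs; accuracy at the 0.5
  threshold inherits whatever miscalibration the winning classifier has.
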