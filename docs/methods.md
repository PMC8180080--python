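# Methods

## Problem setting and data model

The pipeline operates on an untargeted GC-MS peak table: *m* compounds ×
*n* urine samples of non-negative integrated peak areas, where an exact
zero means the compound was not detected in that sample (undetected cells
in input files — empty, `NA` or `0` — are all imputed to 0 at load time;
imputation never alters an observed value).  Each sample is labelled
`case` (cancer) or `control`.  Compound metadata carry a name, nominal
mass, metabolite annotation (`unknown` allowed) and a contaminant flag for
instrument-background species.

Zero inflation is the dominant statistical feature of such tables: most
compounds are below the detection limit in many samples, so per-compound
distributions are mixtures of a point mass at zero and a heavy-tailed
positive component.  This motivates every downstream choice: a rank test
rather than a t-test, a detection-frequency filter, and threshold
classifiers on raw abundance.

## Cohort split

`split_cohorts` allocates a discovery cohort of chosen size proportionally
to group sizes with largest-remainder rounding, then draws a seeded simple
random sample within each group; the remainder is the independent test
cohort.  Proportional allocation is deterministic in the counts (63/61
into 100 always yields 51/49, and 12/12 for the remainder) while
membership is random.  A split that would empty a group in either cohort
is rejected.

## Two-phase screening

Phase 1 is a two-sided Wilcoxon rank-sum test per compound with a
Bonferroni-corrected per-test level α/*m*, where *m* is the total number of
compounds tested per round (not the survivor count): with α = 0.05 and
*m* = 922 the level is 5.42 × 10⁻⁵.  The test uses exact enumeration when
the pooled sample is ≤ 20 and untied, and the tie-corrected normal
approximation with continuity correction otherwise; a compound whose pooled
values are all tied is assigned p = 1.  Inside the leave-one-out loop the
asymptotic branch is evaluated vectorised over all compounds at once.

Phase 2 keeps phase-1 survivors whose detection fraction among *training*
case samples strictly exceeds the cutoff (default 0.6, i.e. "more than
60%").  Computing the fraction on each round's *n*−1 training cases rather
than the full discovery cohort preserves leave-one-out hygiene; the two
readings differ by at most one sample.

A Shapiro–Wilk normality gate is computed per compound and group, with a
Bonferroni-adjusted dataset verdict, but it is advisory only: strongly
zero-inflated data always fail it, and the pipeline is unconditionally
nonparametric.  Compounds constant within a group have an undefined
normality p (recorded as NaN, not fatal).

`compare_categorical` (for demographics tables) is the Pearson chi-square
on a 2×2 table without continuity correction, df = 1.  Yates' correction is
deliberately off — it is conservative for moderate samples and is not the
default of the major statistical packages for this test.

## Leave-one-out discovery loop

For a discovery cohort of *n* samples the loop runs exactly *n* rounds,
each holding out one sample.  Per round: the two-phase screen on the *n*−1
training samples produces a candidate list; each candidate receives a
training-set classifying threshold; the held-out sample is predicted case
iff its abundance ≥ that threshold.  The held-out sample contributes
nothing to its round's screen or thresholds (asserted by a mutation test).

The final marker set is the intersection of all *n* candidate lists with
contaminant-flagged compounds removed afterwards (the order of intersection
and exclusion does not affect the result).  Markers are ordered by
ascending rank-sum p on the full discovery cohort.  An empty intersection
is a warning, not an error.  Per-marker LOOCV accuracy, sensitivity and
specificity pool the *n* held-out predictions.

The per-round threshold rule is a single-compound cutoff refit per round by
maximum Youden J, with "higher abundance ⇒ case" directionality fixed:
the screen's detection filter only admits compounds strongly present in
cases, so all surviving markers are up-regulated by construction.

## Threshold selection and ROC

`roc_curve` places one operating point per distinct score plus the
predict-nothing endpoint and integrates trapezoidally; the resulting AUC
equals the Mann–Whitney concordance probability with ties counted ½ (tested
to 10⁻¹²).  `select_threshold` maximises J = sensitivity + specificity − 1,
breaking ties by higher specificity and then higher threshold, and returns
the midpoint between the adjacent distinct scores the chosen point
separates — an observed score value would be ambiguous under the ≥ rule.
If no point exceeds J = 0 the choice is flagged degenerate.

## Logistic marker panel

The panel is a logistic regression (logit link) on raw marker abundances
with an intercept and a small ridge penalty, default λ = 10⁻⁶ · *n*.  The
penalty exists for separation robustness: screened markers often separate
the discovery cohort perfectly, where the unpenalised MLE diverges.  On
non-separable data the fit with λ → 0 converges to the maximum-likelihood
solution (tested against an independent Newton–Raphson fit).  Features are
standardised internally for optimisation and coefficients mapped back to
abundance units, so the (tiny) penalty is applied on the standardised
scale; an optional `log1p` transform of the features is available behind a
flag.  Evaluation on an independent cohort converts per-sample predicted
probabilities to an ROC.

## Multivariate QC

PCA and OPLS-DA operate on the autoscaled (mean-centred, unit-variance)
samples × compounds matrix; zero-variance compounds are centred but left
unscaled, with a warning.  Autoscaling is the default of the standard
R implementations of this model family; Pareto scaling was considered and
not implemented, as the QC role here only needs a consistent convention.

PCA reports R2X, the cumulative explained-variance share of the retained
components.  OPLS-DA codes the class ±1 (centred) and extracts the
configured number of orthogonal (class-uncorrelated) components by
deflation before a single predictive component; the predictive score column
is exactly orthogonal to every orthogonal score column.  R2Y is the
explained y-variance of the training fit.  Q2 = 1 − PRESS/TSS is computed
by stratified k-fold cross-validation (default 7 folds, seeded, refitting
the scaler and model per fold); under permuted labels its mean is ≤ 0.
R2Y and Q2 on a given dataset depend on the scaling and fold convention, so
they are reported as QC descriptives, not matched against any external
reference values.

## Synthetic data generator

`generate_profile` draws every cell as Bernoulli(detection) ×
log-normal(log_mu, log_sigma), then censors values below a hard detection
limit to zero — the simplest mechanism producing the observed
zero-inflation with a detection-limit interpretation.  Defaults mirror the
motivating study's shape: 63 cases vs 61 controls, 922 compounds, 8 planted
markers, 8 contaminants.  Planted markers get a +3 log-sd abundance shift
in cases with detection probability 0.9 there and 0.02 in controls
("nearly not detected"); background compounds are identically distributed
in both groups at detection 0.5; contaminants are high-detection (0.95),
group-identical compounds flagged `is_contaminant`.  Baseline
log_mu = 8, log_sigma = 1 put abundances in the 10³–10⁵ peak-area range,
and the default detection limit of 700 censors a further ~7% of the
baseline mass, mimicking an instrument reporting cutoff.

What the generator does *not* emulate: retention-time structure and
co-elution, batch drift, correlated compounds (cells are independent given
the group), osmolality/dilution variation, and annotation noise.  Passing
recovery tests therefore shows the pipeline's statistical machinery is
correct under its own assumptions — not that real profiles carry effects
this clean.  On real data the strong planted effect (near-minimal rank
overlap) is replaced by whatever separation exists, and recovery is
correspondingly partial.

## Numerical and edge-case conventions

- Rank-sum p-values are clipped to (0, 1]; all-tied rows give p = 1.
- Detection-fraction comparison is strict (`>`), so exactly 60% fails.
- Largest-remainder ties in the split go to the larger group first.
- Threshold classifiers use `≥`; a +∞ threshold is rejected, a threshold
  below all values predicts everything case.
- The logistic fit errors (rather than warns) if L-BFGS exhausts its
  iteration budget.
- All randomness flows from explicit integer seeds (`numpy` Generator /
  scikit-learn `random_state`); same seed ⇒ bit-identical outputs,
  including written artifacts.

## Problem sizes used in the checks

The test suite exercises the study-shaped configuration (922 × 124, 100
LOOCV rounds) once as a shared fixture, a 200-replicate null study
(no planted markers) for family-wise error and spurious-marker rates, and
50 label permutations for the Q2 null; oracle equivalences (exact rank-sum
vs full enumeration, AUC vs concordance counting, Youden vs brute-force
scan) run on small instances where the oracle is exact.

## Known limitations

- The rank test's asymptotic branch is approximate in the extreme tail at
  moderate *n*; Bonferroni screening at 10⁻⁵ levels inherits that
  approximation (the continuity correction keeps it conservative in the
  null studies run here).
- OPLS-DA is implemented for a single binary response with one predictive
  component; multi-class extensions and VIP scores are out of scope.
- Contaminant identification is metadata-driven (flags or name patterns),
  not inferred from the data.
- The panel reports in-sample discovery ROC alongside the independent-test
  ROC; no nested cross-validation of the panel is performed.
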