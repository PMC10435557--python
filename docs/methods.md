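# Methods

## The screening problem

A survey cohort is a wide table of integer Likert responses (respondents
× items), per-section response times, a small demographic block, and —
for labelled data — a binary careless/regular indicator. The package
asks three questions: how well do different data sources predict
carelessness; what does the fitted classifier actually use, respondent
by respondent; and which variables are appropriate to keep in such a
model.

## Synthetic cohort model

The generator is the package's study-conditions stand-in for labelled
survey data; its defaults define the conditions every downstream test
runs under.

**Questionnaire layout.** 6 scales × 10 items on a 1–5 range. Two items
per scale (positions 3 and 8) are reverse-coded and *stored flipped*
(`min + max − value`), emulating raw data in which some responses arrive
reversed; their ids carry the `_r` suffix. Both counts, the range and
the reverse-coded set are configurable.

**Regular respondents.** One standard-normal latent trait per scale;
item response = scale midpoint + `loading`·trait + Gaussian noise,
rounded and clipped to the Likert range. Defaults `loading = 1.0`,
`noise_sd = 0.8` put within-scale inter-item correlations near 0.6 —
strong enough that the coherence-based indices (even-odd, psychometric
synonyms) have signal to detect, weak enough that responses are not
deterministic. This one-factor-per-scale model is the simplest mechanism
that produces within-scale coherence; it ignores cross-scale trait
correlations, item difficulty/discrimination differences, and acquiescence.

**Careless styles.** `random` draws uniformly over the categories;
`midpoint` puts probability 0.7 on the middle category (remaining mass
uniform); `pattern` tiles a fixed pattern across all items. The default
pattern is the length-1 constant (straightlining) — the canonical fixed
pattern in the screening literature and the one the longstring index is
built to catch; alternating patterns such as (1, 2) are supported but
produce runs of length 1 and are intentionally longstring-invisible.
The default cohort is 361 regular + 244 careless respondents with the
careless third split evenly across the three styles (largest-remainder
rounding).

**Section times.** Log-normal per section, parameterized by the group
mean (57 755.95 ms regular, 43 271.06 ms careless) and a coefficient of
variation of 0.35; the log-scale parameters are solved from these two
moments, so the group means are recovered exactly in expectation. Only
group means were available as anchors; the CV is a package choice in the
plausible range for questionnaire page times.

**Demographics.** Age ~ truncated normal (mean 43.1, SD 17.8, range
18–90); gender ≈ two-thirds female with a small diverse share;
occupation sampled from the proportions (.281 students, .028 manual,
.393 employees, .05 self-employed, .165 retired, .083 other); education
levels (primary/secondary/tertiary/postgraduate at .08/.45/.37/.10) are
the package's own choice — demographics carry no careless signal by
construction, which the benchmark confirms (chance-level balanced
accuracy).

**What passing tests do not show.** The generator's careless styles are
pure; real careless respondents mix styles and drift within a session.
Demographic independence, single-factor scales and label cleanliness are
idealizations — results on synthetic cohorts demonstrate that the
machinery works and recovers planted structure, not field performance.

## Indices

All indices are computed on the raw stored responses (including flipped
reverse-coded items), matching the raw-storage convention of the cohort
format. Details worth noting:

- **Pair selection** for synonyms/antonyms uses inter-item Pearson
  correlations with cutoffs ±0.60 (configurable), the conventional
  defaults in the index literature. On the default mixed cohort the
  careless styles attenuate negative inter-item correlations, so
  typically *no* pair reaches −0.60 and `res_psychant` is undefined for
  every respondent — reported as missing, never as 0, and median-imputed
  (to the column median, or 0 for an all-missing column) inside the
  model pipeline.
- **Undefined scores** (zero-variance respondents in psychometric
  scores or even-odd halves) are NaN with per-column counts logged.
- **Mahalanobis distance** always uses the eigendecomposition
  pseudo-inverse of the sample covariance (identical to the inverse in
  the full-rank case); rank deficiency (p ≥ n) is logged. With strictly
  singular covariance the quadratic form depends on the generalized-
  inverse convention; distances should then be read as flags, not
  metrics.
- **Even-odd consistency** correlates even- and odd-position half-scale
  means across scales; with only two scales the correlation is forced to
  ±1 and a warning is logged. Spearman–Brown step-up (2r/(1+r)) is off
  by default.
- The default table has 13 columns (`res_psycsyn`, `res_psychant`,
  `str`, `avgstr`, `res_mahad`, `res_evenodd`, `irvTotal`,
  `irv1..irv6`); `irvDiff` and `longDiff` (last section minus first) are
  derived extras used by the `all_extracted` scenario.

## Benchmark protocol

The repeated-validation design reconciles two conventions: the outer
loop is repeated stratified holdout (default 100 repeats of 420/185,
sampling without replacement, largest-remainder stratification
preserving the 361:244 ratio), and the inner loop is stratified 10-fold
cross-validation for hyperparameter tuning on balanced accuracy. Repeat
r derives its seed as `base_seed + r`, so the whole benchmark is a pure
function of (cohort, plan, grid).

The classifier is scikit-learn's `GradientBoostingClassifier` behind a
median-imputation pipeline. The default grid is interaction depth
{1, 2, 3} × min leaf observations {5, 10} × trees {50, 100, 200} ×
shrinkage {0.01, 0.1}. Careless is the positive class; the decision
threshold is 0.5. Fast paths (tests, the acceptance script, CLI
`--scale-down`) use a compact grid (depth {1, 3} × trees {50, 100} ×
shrinkage 0.1 × min leaf 10) with 3 inner folds and ~20 outer repeats —
the package's standard reduced configuration; orderings of interest
(timing beats demographics, planted features saturate) are insensitive
to the grid.

## Shapley explanations

The value function fixes variables in S at the explained instance's
values and integrates the rest over a background sample (interventional
averaging); the background is the training partition of the explained
model. Exact enumeration covers ≤ 15 variables; beyond that an unbiased
permutation estimator draws, per sample, one variable ordering and one
background row and accumulates output differences along the ordering,
reporting per-variable standard errors. Explanations are computed on
the predicted probability of the careless class, so positive φ pushes a
respondent toward "careless". Efficiency, symmetry and dummy axioms are
verified by enumeration in the test suite; the sampled estimator is
checked against enumeration within three standard errors.

## Appropriateness grading

Three criteria per variable, from contribution summaries (group mean ±
1.96·SE):

1. TP vs TN on the with-indices fit; opposite-signed means are good
   (the variable separates populations).
2. TP vs FN among careless respondents; opposite-signed means are bad
   (the variable flips exactly where the model fails).
3. Stability of the all-respondent mean between fits with and without
   the index block; rated only when the rounded |mean| reaches 0.01 in
   either fit; +1 stable, −1 significantly shifted.

Magnitude for criteria 1–2: three signs inside the influence set (union
of top-5 and bottom-5 by the reference group's mean — TP for criterion
1, FN for criterion 2) without a significant difference, two signs with
one, one sign outside. Significance defaults to 95%-CI non-overlap; a
Welch-test alternative is provided. The overall level is the clamped
signed sum over rated criteria (±3 ceiling), X when fewer than two are
rated — this formalization reproduces every unambiguous published
merge the test suite encodes. Ties in influence ranking break by
variable id.

Degenerate inputs: an empty prediction group skips its criterion for
all variables (logged); a variable absent from one summary is not rated
for that criterion.

## Numerical and design choices

- Sample statistics use ddof=1 throughout; correlations are Pearson.
- CSV round trips use pandas `float_precision="round_trip"` so rerun
  determinism is byte-exact; every pipeline CSV carries a config-hash
  and seed header comment.
- The acceptance script's problem sizes — 10 000 respondents for the
  timing-mean recovery, 20 repeats for the rt-vs-dem benchmark, 20 000
  permutation samples for the Shapley check — are chosen so each
  quantity's Monte-Carlo error is far below the margins being asserted,
  at about half a minute of runtime.

## Known limitations

- No partial attentiveness: respondents are careless for the whole
  questionnaire or not at all.
- Threshold-based classification from literature cutoffs (longstring
  > 7, even-odd < 0.3) is exposed only as a reporting utility, not in
  the pipeline's label logic.
- Only gradient boosting is benchmarked; no variable elimination or
  refitting follows from the ledger grades.
- Index computation on raw stored responses means reverse-coded items
  weaken (not corrupt) synonym and even-odd signals; recoding before
  index computation is a possible variant not implemented.
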