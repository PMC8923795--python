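# Methods

## Problem setting and model

The package targets small-sample binary classification over a fixed table
of named continuous features — canonically 70 EEG band-power features
(14 channels × 5 spectral bands) from a consumer headset, with classes
*positive* / *negative* emotion. The classifier genotype is a single
expression tree: internal nodes are `{+, −, ×, protected ÷}`, leaves are
feature references or ephemeral random constants. A sample is classified
positive iff the tree's value on it is ≥ the classification threshold
(default 0). Fitness of a tree is its training-set accuracy in [0, 1].

Evaluation is vectorized over all samples; two numerical guards keep every
output finite: protected division returns 1 whenever |denominator| < 1e−9,
and every function node's output is clipped to ±1e12 (clipping at each
node bounds all intermediates, so no overflow or NaN can arise from finite
inputs). Trees have a canonical prefix s-expression serialization
(constants at 6 significant digits) that is injective up to structural
equality; "no similar trees" during initialization means exactly: no two
identical serializations.

## The GP engine

* **Initialization** — ramped half-and-half: target depths cycle over
  [5, 10] while grow/full construction alternates; every tree must be
  structurally new, with a 200-attempt cap per slot (retries alternate the
  method and, in the second half of the attempts, deepen the target so an
  exhausted shallow stratum cannot deadlock a feasible configuration).
  In the grow method the function/terminal choice is forced to "function"
  above the minimum depth, forced to "terminal" at the maximum depth, and
  50/50 in between; constants are drawn with probability 0.1 from
  U[−1, 1] when enabled.
* **Selection** — tournament of size 7, sampled uniformly *with
  replacement*; fitness ties break toward the smaller tree, then uniformly.
* **Operators** — per generation the single best individual is copied in
  unchanged (elitism), then slots are filled by crossover / reproduction /
  mutation with probabilities 0.6 / 0.2 / 0.2. Crossover and mutation are
  hill-climbing: up to 10 retries, a child is adopted only if *strictly*
  fitter than its parent (and within the depth cap of 17); otherwise the
  parent survives. Consequently best-of-population fitness is
  non-decreasing — the one exception is the forced replacement generation
  below.

## The embedded feature selection

With G = ⌊budget / population⌋ planned generations, generations 1..⌈G/2⌉
form the weighting phase: each generation, the individuals with fitness
strictly above the population mean (the *Cgaa* set) contribute one count
per feature-terminal occurrence to a per-feature weight ledger (a feature
occurring twice in one tree adds 2; a per-tree-presence variant is a
config toggle). At generation ⌈G/2⌉ the features split at the average
weight — taken over the full feature set, zero-weight features included
(averaging over nonzero features only is a toggle) — into Fso (strictly
above) and Fno. If all weights tie, the maximal-weight features become
Fso; if the ledger is all-zero (no above-average classifier ever appeared)
the replacement step is skipped with a warning and the run continues as
plain GP.

The replacement mutation then visits every Fno terminal of every tree:
up to 10 random Fso substitutions are evaluated, the first strictly
improving one is adopted, else the best-scoring one — the Fno terminal is
replaced regardless, so after this generation no tree references an Fno
feature. To keep the purge permanent, fresh mutation subtrees afterwards
draw feature terminals from Fso only (crossover only recombines existing,
already-purged material). The run stops the moment any individual reaches
training accuracy 1.0, else at generation G. The result is the best
individual seen *since the purge* (elitism preserves it into the final
population); tracking the pre-purge best instead could return a tree
containing purged features, defeating the selection. The selected feature
set is exactly the distinct features of that tree.

## Budget accounting

One budget unit is one individual slot per generation — the classical
generational accounting in which an 80000-evaluation budget with
population 100 means 800 generations, and an evaluations-versus-accuracy
curve is generations × population. The hill-climbing retries and
replacement trials evaluate additional candidate trees internally; those
calls are tallied and reported (`total_evaluations` in every result is the
true number of fitness computations, typically ~8× the nominal budget
with the default operator probabilities) but they are not the stopping
clock. Billing them against the budget would end an 80000-budget run
after a few dozen generations, leaving the weighting phase too short to
accumulate any usable signal and starving the replacement step — the
selection mechanism only functions on the generational clock.

## Data handling

CSV in/out with a header row and one label column (default `label`);
`positive`/`negative` are recognized directly, any other two-class
alphabet maps the lexicographically larger value to the positive class
unless overridden. Hold-out splitting is stratified by default with train
size ⌊f·n + 0.5⌋ (per-class roundings reconciled to that total by largest
fractional remainder), and features are z-scored by training-set
statistics before evolution (constant columns map to 0; togglable).
Standardization matters because constants are drawn from [−1, 1] and the
sign threshold sits at 0: features must be on a commensurate scale.

## Performance measures

Accuracy, sensitivity (recall), precision and specificity from the 2×2
confusion matrix; a zero denominator yields an undefined (None) value
rather than an error. The Mann–Whitney comparison of two run-accuracy
samples uses midranks, an exact null distribution (dynamic-programming
count of rank configurations) when the combined sample size is ≤ 16 and
there are no ties, and otherwise a normal approximation with tie
correction and a 0.5 continuity correction; two-tailed p is
min(1, 2·min(lower tail, upper tail)), and a fully tied comparison (e.g. a
sample against itself) gives p = 1.

## Synthetic benchmark

The generator draws labels Bernoulli(class balance), non-informative
features N(0, σ²) independent of the label, and informative features
N(±effect/2, σ²) with the sign set by the class; optional redundant
features are corr·source + √(1−corr²)·N(0, σ²). With k independent
informative features and balanced classes the Bayes accuracy is
Φ(√k · effect / 2σ), which anchors the no-signal (Φ(0) = 0.5) and
perfectly-separable limits in tests. The generator reproduces the *shape*
of the target data — sample count, 70 named features, two classes, sparse
signal — but not participant-level clustering, channel topography,
band-power marginals or feature correlations of real EEG, so passing
tests demonstrate algorithmic correctness and recovery behaviour, not
clinical performance.

Two default study conditions are used throughout the tests and the
acceptance script:

* **Recovery benchmark** — 45 samples × 70 features, 8 informative,
  effect size 2, σ = 1, balance 0.5: the scale of a 45-participant study,
  where a per-feature signal of Φ(1) ≈ 0.84 and a joint Bayes optimum of
  Φ(2.83) ≈ 0.998 leave plenty of room for overfitting 36 training
  samples. Budget 20000 (population 100) keeps repeated runs fast; on
  these easy tables training accuracy typically reaches 1.0 before the
  midpoint, so the run ends by the early-termination rule and selection
  reduces to the best tree's features.
* **Purge benchmark** — 120 samples, effect size 1.0, population 50,
  initial depths 3–6, budget 5000 (100 generations): training accuracy
  stays below 1.0 through the midpoint, so the weighting phase completes
  and the replacement step fires in every seeded run; used for the purge,
  ledger-conservation and monotonicity checks, and for demonstrating
  selection quality (pooled precision of selected features ≈ 0.6–0.9
  versus the 8/70 ≈ 0.11 random baseline).

Problem sizes in the test suite (population 20–50, budgets in the
hundreds to low thousands, 10–20 seeds) are scaled-down versions of the
same conditions, chosen so the full suite completes in minutes.

## Known limitations

* The weighting signal needs enough generations; at very small budgets
  (or on trivially separable data) the run ends before the midpoint and
  FSGP degenerates gracefully to plain GP.
* The forced purge can momentarily lower every individual's fitness; the
  monotonicity guarantee therefore excludes the single replacement
  generation.
* Feature weights count occurrences, not marginal usefulness: a feature
  carried along inside large above-average trees accrues weight without
  necessarily contributing — the small-sample regime makes Fso noisy.
* Single-tree, two-class classification only; no multi-tree forests, no
  multi-class outputs, no semantic (beyond structural) duplicate
  detection.
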