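# fsgp

Genetic-programming classification with **embedded feature selection in a
single GP life cycle**, for two-class numeric feature tables of the kind
produced by consumer EEG headsets: 14 channels × 5 band-power summaries =
70 continuous features per sample, labelled *positive* or *negative*
(emotion classification). Most of those 70 features are redundant or
irrelevant, and with only tens of participants a classifier that uses all
of them overfits; the point of this package is to discover the informative
subset *while* training the classifier, not in a separate pass.

## The method

An individual is a single expression tree over the feature terminals,
random constants and `{+, −, ×, protected ÷}`; a sample is classified
positive iff the tree's output is ≥ 0. Fitness is training-set accuracy.
Evolution uses ramped half-and-half initialization (depths 5–10, all trees
structurally distinct), tournament selection, elitist reproduction, and
*hill-climbing* crossover and mutation: a child replaces its parent only
when strictly fitter, so the best fitness never degrades.

The selection mechanism rides on top:

1. **Weighting phase** (first half of the run). Each generation, the
   classifiers with above-average accuracy (*Cgaa*) vote for their
   features: every feature-terminal occurrence adds 1 to that feature's
   weight, starting from all-zero weights.
2. **Partition.** At the midpoint, features with weight strictly above the
   average weight form the suboptimal set *Fso*; the complement is *Fno*.
3. **Purge.** A replacement mutation rewrites every *Fno* terminal in every
   tree to a randomly drawn *Fso* feature, keeping the first
   strictly-improving substitution (or the best one found). From then on,
   fresh mutation subtrees draw features only from *Fso*, so the purge is
   never undone.
4. Evolution continues to the end of the budget (or stops as soon as any
   tree reaches 100% training accuracy). The distinct features of the
   final best tree are the selected feature set — selection and
   classification in one run.

Accuracy, sensitivity TP/(TP+FN), precision TP/(TP+FP) and specificity
TN/(TN+FP) are reported on a held-out 20% split, and repeated-run accuracy
samples can be compared with a two-tailed Mann–Whitney U test (exact null
for small samples, tie-corrected normal approximation otherwise).

Because real EEG recordings are typically private, the package ships a
synthetic generator that emulates the 45-participant, 70-feature regime
with a *known* informative subset (Gaussian class-conditional model with a
closed-form Bayes accuracy), so recovery of the informative features is
measurable.

## Worked example

Generate a synthetic table (120 samples × 70 features, 8 informative at
effect size 1.0) and run FSGP with a 5000-evaluation budget:

```sh
fsgp simulate --n-samples 120 --effect-size 1.0 --seed 3 --out demo.csv
fsgp run --data demo.csv --budget 5000 --pop-size 50 --seed 0 --out demo_run
```

which prints

```
wrote 120x70 table to demo.csv
test accuracy 0.833 with 5 features (41200 evaluations)
```

`demo_run/report.json` holds the full result; for this run the best tree is

```
(+ (+ (+ (- FC6_gamma FC5_betaL) -0.0581275) (+ F4_gamma (+ FC5_theta P8_theta))) (+ FC6_gamma FC5_theta))
```

i.e. 83.3% held-out accuracy from **5** of the 70 features — and 4 of those
5 (`F4_gamma`, `FC5_theta`, `FC6_gamma`, `P8_theta`) are in the generator's
true informative set (`demo.csv.manifest.json` lists it). The report also
snapshots the per-feature weight ledger, the Fso/Fno partition and the
per-generation history; `demo_run/best_tree.sexp` can be re-applied to any
CSV with `fsgp evaluate`.

Other subcommands: `fsgp sweep` (accuracy and feature count versus
evaluation budget), `fsgp compare` (paired FSGP vs plain-GP runs with a
Mann–Whitney p), `fsgp run --baseline` (plain GP without the selection
phase).

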