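"""Performance measures and run-comparison statistics.

Confusion-matrix construction, the standard binary measures (accuracy,
sensitivity/recall = TP/(TP+FN), precision = TP/(TP+FP), specificity =
TN/(TN+FP)), a two-tailed Mann–Whitney U test for comparing accuracy
samples from repeated runs, and the repeated-run harness itself.

The Mann–Whitney implementation uses midranks for ties, an exact null
distribution (dynamic programming over rank configurations) when the
combined sample size is at most 16 and there are no ties, and otherwise a
normal approximation with tie and continuity corrections.  Degenerate
all-tied comparisons (e.g. a sample against itself) give p = 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm, rankdata

from .data_model import FeatureTable, holdout_split, standardize
from .feature_selection import run_fsgp
from .gp_core import FSGPConfig, predict_table

__all__ = [
    "ConfusionMatrix",
    "MetricSet",
    "MannWhitneyResult",
    "TrialRecord",
    "TrialsResult",
    "confusion",
    "compute_metrics",
    "mann_whitney",
    "run_trials",
    "evaluate_split",
]

EXACT_MAX_COMBINED_N = 16


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class MetricSet:
    """Binary-classification measures; ``None`` marks a 0/0 denominator."""

    accuracy: float | None
    sensitivity: float | None
    precision: float | None
    specificity: float | None


@dataclass(frozen=True)
class MannWhitneyResult:
    u_statistic: float
    p_two_tailed: float
    method: str  # "exact" | "normal-approximation"


def confusion(true_labels, predicted, positive_class=1) -> ConfusionMatrix:
    """Standard 2x2 counts with the declared positive class."""
    t = np.asarray(true_labels)
    p = np.asarray(predicted)
    if t.shape != p.shape or t.size == 0:
        raise ValueError("label sequences must be equal-length and non-empty")
    tpos = t == positive_class
    ppos = p == positive_class
    return ConfusionMatrix(
        tp=int(np.sum(tpos & ppos)),
        fp=int(np.sum(~tpos & ppos)),
        tn=int(np.sum(~tpos & ~ppos)),
        fn=int(np.sum(tpos & ~ppos)),
    )


def _ratio(num: int, den: int) -> float | None:
    return None if den == 0 else num / den


def compute_metrics(cm: ConfusionMatrix) -> MetricSet:
    """Accuracy, recall, precision and specificity from a confusion matrix."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    return MetricSet(
        accuracy=_ratio(cm.tp + cm.tn, cm.total),
        sensitivity=_ratio(cm.tp, cm.tp + cm.fn),
        precision=_ratio(cm.tp, cm.tp + cm.fp),
        specificity=_ratio(cm.tn, cm.tn + cm.fp),
    )


# ---------------------------------------------------------------------------
# Mann–Whitney U
# ---------------------------------------------------------------------------

def _exact_u_counts(n_a: int, n_b: int) -> np.ndarray:
    """count[u] of rank configurations giving U = u (no ties), u in 0..n_a*n_b.

    Classic recurrence c(m,n,u) = c(m-1,n,u-n) + c(m,n-1,u); the total over
    u is C(m+n, m).
    """
    max_u = n_a * n_b
    c = np.zeros((n_a + 1, n_b + 1, max_u + 1))
    c[0, :, 0] = 1.0
    c[:, 0, 0] = 1.0
    for m in range(1, n_a + 1):
        for n in range(1, n_b + 1):
            c[m, n] = c[m, n - 1]
            c[m, n, n:] += c[m - 1, n, : max_u + 1 - n]
    return c[n_a, n_b]


def mann_whitney(sample_a, sample_b) -> MannWhitneyResult:
    """Two-tailed Mann–Whitney U comparison of two samples.

    Returns U for the first sample.  Exact enumeration of the null is used
    when the combined size is at most ``EXACT_MAX_COMBINED_N`` and there are
    no ties; otherwise the normal approximation with tie correction and a
    0.5 continuity correction.  ``U_A + U_B = n_a * n_b`` always holds.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    n_a, n_b = a.size, b.size
    combined = np.concatenate([a, b])
    ranks = rankdata(combined)  # midranks
    u_a = float(np.sum(ranks[:n_a]) - n_a * (n_a + 1) / 2)
    has_ties = np.unique(combined).size < combined.size
    mu = n_a * n_b / 2

    if not has_ties and n_a + n_b <= EXACT_MAX_COMBINED_N:
        counts = _exact_u_counts(n_a, n_b)
        total = counts.sum()
        u_int = int(round(u_a))
        lower = counts[: u_int + 1].sum() / total
        upper = counts[u_int:].sum() / total
        p = min(1.0, 2 * min(lower, upper))
        return MannWhitneyResult(u_a, float(p), "exact")

    n = n_a + n_b
    _, tie_counts = np.unique(combined, return_counts=True)
    tie_term = float(np.sum(tie_counts ** 3 - tie_counts))
    var = n_a * n_b / 12 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:
        # every observation tied: no evidence of a difference
        return MannWhitneyResult(u_a, 1.0, "normal-approximation")
    z = max(0.0, abs(u_a - mu) - 0.5) / np.sqrt(var)
    p = min(1.0, 2 * float(norm.sf(z)))
    return MannWhitneyResult(u_a, p, "normal-approximation")


# ---------------------------------------------------------------------------
# Repeated-run harness
# ---------------------------------------------------------------------------

@dataclass
class TrialRecord:
    seed: int
    train_accuracy: float
    test_accuracy: float
    n_selected_features: int
    selected_features: list[str]
    evaluations: int
    terminated_early: bool


@dataclass
class TrialsResult:
    records: list[TrialRecord]
    use_fs: bool

    @property
    def test_accuracies(self) -> list[float]:
        return [r.test_accuracy for r in self.records]

    @property
    def train_accuracies(self) -> list[float]:
        return [r.train_accuracy for r in self.records]

    @property
    def feature_counts(self) -> list[int]:
        return [r.n_selected_features for r in self.records]

    def summary(self) -> dict[str, float]:
        acc = np.asarray(self.test_accuracies)
        return {
            "max": float(acc.max()),
            "mean": float(acc.mean()),
            "min": float(acc.min()),
            "mean_features": float(np.mean(self.feature_counts)),
        }


def evaluate_split(dataset: FeatureTable, config: FSGPConfig, seed: int,
                   use_fs: bool = True, train_fraction: float = 0.8) -> TrialRecord:
    """One seeded run: split, (optionally) standardize, evolve, score on test."""
    pair = holdout_split(dataset, train_fraction=train_fraction,
                         stratified=True, seed=seed)
    train, test = pair.train, pair.test
    if config.standardize:
        reference = train
        train = standardize(train, reference)
        test = standardize(test, reference)
    result = run_fsgp(train, config.with_seed(seed), use_fs=use_fs)
    preds = predict_table(result.best.tree, test, config.classification_threshold)
    test_acc = compute_metrics(confusion(test.labels, preds)).accuracy
    return TrialRecord(
        seed=seed,
        train_accuracy=result.best.fitness,
        test_accuracy=float(test_acc),
        n_selected_features=len(result.selected_features),
        selected_features=result.selected_features,
        evaluations=result.total_evaluations,
        terminated_early=result.terminated_early,
    )


def run_trials(dataset: FeatureTable, config: FSGPConfig, n_runs: int,
               seeds, use_fs: bool = True,
               train_fraction: float = 0.8) -> TrialsResult:
    """Repeat seeded hold-out runs; per-run accuracies and max/mean/min summary.

    Each seed governs both the 80–20 split and the GP run, so the same seed
    list yields identical samples (reproducibility) and two strategies run
    on identical splits (paired comparison).
    """
    seeds = list(seeds)
    if n_runs != len(seeds):
        raise ValueError(f"n_runs={n_runs} but {len(seeds)} seeds supplied")
    records = [evaluate_split(dataset, config, s, use_fs, train_fraction)
               for s in seeds]
    return TrialsResult(records=records, use_fs=use_fs)
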