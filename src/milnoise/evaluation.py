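"""Metrics, cross-validation, and significance analysis for slide classification.

The central metric is the support-weighted macro F1: per-class F1 scores are
averaged with weights equal to each class's true support, which keeps the
score honest under the class imbalance typical of slides sampled from routine
pathology workflows. Model setups are compared across cross-validation folds
with the two-sided Wilcoxon rank-sum (Mann-Whitney) test, and a noise sweep
is summarized by the largest label-noise fraction whose scores remain
statistically indistinguishable from the manual-label baseline.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import f1_score

from .labels import LabelTable

CUMULATIVE = "cumulative"


def weighted_f1(predictions: LabelTable, truth: LabelTable) -> float:
    """Support-weighted macro F1 of predictions against truth.

    Per-class F1 is computed from one-vs-rest confusion counts (for
    multilabel, per-class binary F1 on the indicator columns) and averaged
    with weights proportional to each class's support in ``truth``; classes
    with zero support therefore do not contribute.
    """
    if len(truth) == 0:
        raise ValueError("empty truth table")
    if predictions.scheme != truth.scheme:
        raise ValueError("prediction/truth scheme mismatch")
    if not predictions.same_slides(truth):
        raise ValueError("prediction/truth slide sets differ")
    y_pred = predictions.aligned_y(truth.slide_ids)
    y_true = truth.y
    if truth.scheme == "multilabel":
        return float(f1_score(y_true, y_pred, average="weighted", zero_division=0))
    labels = np.arange(truth.n_classes)
    return float(
        f1_score(y_true, y_pred, labels=labels, average="weighted", zero_division=0)
    )


@dataclass
class FoldSplit:
    """Patient-grouped fold assignment: every slide of a patient shares a fold."""

    k: int
    assignment: dict  # patient_id -> fold index
    seed: int

    def fold_of_slides(self, slide_patient_pairs) -> np.ndarray:
        return np.array([self.assignment[p] for _, p in slide_patient_pairs])

    def fold_sizes(self) -> np.ndarray:
        counts = np.zeros(self.k, dtype=int)
        for f in self.assignment.values():
            counts[f] += 1
        return counts


def _slide_patient_pairs(cohort):
    if hasattr(cohort, "bags"):
        return [(b.slide_id, b.patient_id) for b in cohort.bags]
    return [(str(s), str(p)) for s, p in cohort]


def make_folds(cohort, k: int = 10, seed: int = 0) -> FoldSplit:
    """Shuffle patients by seed and deal them round-robin into k folds.

    Accepts a cohort object with ``bags`` or an iterable of
    ``(slide_id, patient_id)`` pairs. Fold sizes differ by at most one
    patient and no patient's slides ever span folds.
    """
    pairs = _slide_patient_pairs(cohort)
    patients = list(dict.fromkeys(p for _, p in pairs))  # first-seen order
    if k > len(patients):
        raise ValueError(f"k={k} exceeds the number of patients ({len(patients)})")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(patients))
    assignment = {patients[idx]: i % k for i, idx in enumerate(order)}
    return FoldSplit(k=k, assignment=assignment, seed=seed)


def wilcoxon_rank_sum(a, b) -> float:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) p-value.

    Uses the exact null distribution when both samples are small
    (n_a + n_b <= 20) and untied, otherwise the normal approximation with
    mid-rank tie correction and continuity correction.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("both samples need at least 2 values")
    pooled = np.concatenate([a, b])
    if np.ptp(pooled) == 0:
        warnings.warn("degenerate data: all values identical; p = 1.0", stacklevel=2)
        return 1.0
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (len(pooled) <= 20 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(min(res.pvalue, 1.0))


@dataclass
class RunResult:
    """Per-fold weighted-F1 scores for one experimental setup.

    ``scores`` has one row per fold and one column per source plus a
    ``cumulative`` column evaluated on the union of sources.
    """

    setup_id: str
    scores: pd.DataFrame
    noise_level: float | None = None

    def __post_init__(self):
        if CUMULATIVE not in self.scores.columns:
            raise ValueError("scores must include a 'cumulative' column")

    @property
    def mean(self) -> pd.Series:
        return self.scores.mean()

    @property
    def std(self) -> pd.Series:
        return self.scores.std(ddof=1)

    def column(self, name: str = CUMULATIVE) -> np.ndarray:
        return self.scores[name].to_numpy()


def aggregate_runs(setup_id: str, per_fold_scores, noise_level=None) -> RunResult:
    """Assemble per-fold score dicts into a :class:`RunResult`.

    ``per_fold_scores`` maps fold index to a dict of column -> weighted F1
    (must include ``cumulative``); every fold must provide the same columns.
    """
    if not per_fold_scores:
        raise ValueError("no fold scores provided")
    folds = sorted(per_fold_scores)
    columns = None
    rows = []
    for f in folds:
        row = per_fold_scores[f]
        if columns is None:
            columns = list(row)
        elif set(row) != set(columns):
            raise ValueError(f"fold {f} is missing columns")
        rows.append([row[c] for c in columns])
    frame = pd.DataFrame(rows, index=folds, columns=columns)
    return RunResult(setup_id=setup_id, scores=frame, noise_level=noise_level)


@dataclass
class SignificanceReport:
    """Pairwise Wilcoxon comparisons with a fixed significance level."""

    comparisons: dict = field(default_factory=dict)  # (setup_a, setup_b) -> p
    alpha: float = 0.05

    @property
    def flags(self) -> dict:
        return {pair: p < self.alpha for pair, p in self.comparisons.items()}

    def add(self, setup_a: str, setup_b: str, p: float) -> None:
        self.comparisons[(setup_a, setup_b)] = float(p)


def compare_to_baseline(
    results, baseline: RunResult, alpha: float = 0.05, column: str = CUMULATIVE
) -> SignificanceReport:
    report = SignificanceReport(alpha=alpha)
    base = baseline.column(column)
    for res in results:
        report.add(res.setup_id, baseline.setup_id, wilcoxon_rank_sum(res.column(column), base))
    return report


def noise_threshold(
    results, baseline: RunResult, alpha: float = 0.05, column: str = CUMULATIVE
) -> float:
    """Largest noise fraction still indistinguishable from the baseline.

    ``results`` must be ordered by strictly increasing noise level. Returns
    the largest level p such that the cumulative-F1 comparison against the
    baseline is non-significant for p and every smaller level (first-crossing
    rule); returns 0.0 if the smallest level is already significant.
    """
    levels = [r.noise_level for r in results]
    if any(lv is None for lv in levels):
        raise ValueError("every result needs a noise_level")
    if any(b <= a for a, b in zip(levels, levels[1:])):
        raise ValueError("results must be ordered by strictly increasing noise level")
    base = baseline.column(column)
    threshold = 0.0
    for res in results:
        p_value = wilcoxon_rank_sum(res.column(column), base)
        if p_value < alpha:
            break
        threshold = res.noise_level
    return float(threshold)
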