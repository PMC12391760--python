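"""Metric, fold, and rank-sum behaviour against independent oracles."""

import itertools

import numpy as np
import pytest

from milnoise.evaluation import (
    aggregate_runs,
    make_folds,
    noise_threshold,
    weighted_f1,
    wilcoxon_rank_sum,
)
from milnoise.labels import LabelTable

from conftest import random_table


def brute_force_weighted_f1(y_true, y_pred, n_classes):
    """Raw confusion-count implementation, independent of sklearn."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.ndim == 1:
        indic_true = np.stack([(y_true == c).astype(int) for c in range(n_classes)], axis=1)
        indic_pred = np.stack([(y_pred == c).astype(int) for c in range(n_classes)], axis=1)
    else:
        indic_true, indic_pred = y_true, y_pred
    total, weight_sum = 0.0, 0
    for c in range(n_classes):
        t, p = indic_true[:, c], indic_pred[:, c]
        tp = int(np.sum((t == 1) & (p == 1)))
        fp = int(np.sum((t == 0) & (p == 1)))
        fn = int(np.sum((t == 1) & (p == 0)))
        support = int(t.sum())
        if support == 0:
            continue
        f1 = 0.0 if (2 * tp + fp + fn) == 0 else 2 * tp / (2 * tp + fp + fn)
        total += support * f1
        weight_sum += support
    return total / weight_sum


def _table(scheme, names, y):
    ids = tuple(f"s{i}" for i in range(len(y)))
    return LabelTable(scheme, names, ids, np.asarray(y))


def test_weighted_f1_hand_computed_example():
    truth = _table("binary", ("a", "b"), [0, 0, 1, 1, 1])
    pred = _table("binary", ("a", "b"), [0, 1, 1, 1, 0])
    # F1(class0)=0.5, F1(class1)=2/3, support-weighted (2*0.5 + 3*2/3)/5
    assert weighted_f1(pred, truth) == pytest.approx(0.6, abs=1e-12)


def test_weighted_f1_perfect_prediction_is_one(multilabel_cohort):
    labels = multilabel_cohort.labels
    assert weighted_f1(labels, labels.copy()) == 1.0


@pytest.mark.parametrize("scheme,n_classes", [("binary", 2), ("multiclass", 5), ("multilabel", 4)])
def test_weighted_f1_matches_confusion_count_oracle(scheme, n_classes):
    rng = np.random.default_rng(42)
    for _ in range(200):
        n = int(rng.integers(5, 40))
        truth = random_table(scheme, n, n_classes, rng)
        pred = random_table(scheme, n, n_classes, rng)
        pred = LabelTable(scheme, truth.class_names, truth.slide_ids, pred.y)
        ours = weighted_f1(pred, truth)
        oracle = brute_force_weighted_f1(truth.y, pred.y, n_classes)
        assert ours == pytest.approx(oracle, abs=1e-12)


def test_weighted_f1_rejects_empty_and_mismatched():
    truth = _table("binary", ("a", "b"), [0, 1])
    other = _table("binary", ("a", "b"), [0, 1, 1])
    with pytest.raises(ValueError):
        weighted_f1(other, truth)
    empty = LabelTable("binary", ("a", "b"), (), np.zeros(0, dtype=int))
    with pytest.raises(ValueError):
        weighted_f1(empty, empty)


# --- folds -----------------------------------------------------------------


def test_make_folds_exact_division():
    pairs = [(f"s{i}", f"p{i}") for i in range(20)]
    split = make_folds(pairs, k=10, seed=0)
    assert sorted(split.fold_sizes()) == [2] * 10


def test_make_folds_groups_patient_slides():
    pairs = [("s1", "pA"), ("s2", "pA"), ("s3", "pA")] + [(f"t{i}", f"q{i}") for i in range(6)]
    split = make_folds(pairs, k=3, seed=1)
    folds = split.fold_of_slides(pairs[:3])
    assert len(set(folds)) == 1


def test_make_folds_seed_changes_assignment_not_profile():
    pairs = [(f"s{i}", f"p{i}") for i in range(23)]
    a = make_folds(pairs, k=5, seed=0)
    b = make_folds(pairs, k=5, seed=1)
    assert sorted(a.fold_sizes()) == sorted(b.fold_sizes())
    assert a.assignment != b.assignment


def test_make_folds_no_patient_leakage_across_seeds(binary_cohort):
    for seed in range(5):
        split = make_folds(binary_cohort, k=6, seed=seed)
        by_fold = {}
        for bag in binary_cohort.bags:
            by_fold.setdefault(split.assignment[bag.patient_id], set()).add(bag.patient_id)
        for f1, f2 in itertools.combinations(by_fold, 2):
            assert not (by_fold[f1] & by_fold[f2])


def test_make_folds_rejects_too_many_folds():
    pairs = [(f"s{i}", f"p{i}") for i in range(4)]
    with pytest.raises(ValueError):
        make_folds(pairs, k=5, seed=0)


# --- Wilcoxon rank-sum -----------------------------------------------------


def permutation_rank_sum_p(a, b):
    """Exact two-sided p by enumerating every split of the pooled ranks."""
    pooled = np.concatenate([a, b])
    n_a = len(a)
    ranks = np.argsort(np.argsort(pooled)) + 1.0
    observed = ranks[:n_a].sum()
    sums = [
        sum(ranks[list(comb)]) for comb in itertools.combinations(range(len(pooled)), n_a)
    ]
    sums = np.array(sums)
    mean = sums.mean()
    extreme = np.sum(np.abs(sums - mean) >= abs(observed - mean) - 1e-12)
    return extreme / len(sums)


def test_rank_sum_most_extreme_ordering():
    assert wilcoxon_rank_sum([1, 2, 3], [4, 5, 6]) == pytest.approx(0.1, abs=1e-12)


def test_rank_sum_identical_samples_warn_p_one():
    with pytest.warns(UserWarning, match="degenerate"):
        assert wilcoxon_rank_sum([2.0, 2.0], [2.0, 2.0]) == 1.0


@pytest.mark.parametrize("n_a,n_b", [(2, 2), (2, 5), (3, 4), (4, 4), (5, 3), (7, 7)])
def test_exact_rank_sum_matches_permutation_enumeration(n_a, n_b):
    rng = np.random.default_rng(100 + n_a * 10 + n_b)
    for _ in range(5):
        pooled = rng.permutation(np.arange(1.0, n_a + n_b + 1))  # untied by design
        a, b = pooled[:n_a], pooled[n_a:]
        assert wilcoxon_rank_sum(a, b) == pytest.approx(permutation_rank_sum_p(a, b), abs=1e-9)


def test_rank_sum_ten_vs_ten_close_to_monte_carlo_permutation():
    rng = np.random.default_rng(7)
    a = rng.normal(0.0, 1.0, 10)
    b = rng.normal(0.8, 1.0, 10)
    p = wilcoxon_rank_sum(a, b)
    pooled = np.concatenate([a, b])
    ranks = np.argsort(np.argsort(pooled)) + 1.0
    observed = ranks[:10].sum()
    n_mc = 10_000
    stat = np.empty(n_mc)
    for i in range(n_mc):
        perm = rng.permutation(20)
        stat[i] = ranks[perm[:10]].sum()
    mean = 10 * 21 / 2
    p_mc = np.mean(np.abs(stat - mean) >= abs(observed - mean) - 1e-12)
    se = np.sqrt(max(p_mc * (1 - p_mc), 1e-6) / n_mc)
    assert abs(p - p_mc) <= 3 * se + 1e-3


# --- aggregation and thresholds --------------------------------------------


def test_aggregate_runs_mean_and_sample_std():
    per_fold = {f: {"cumulative": 0.9} for f in range(10)}
    run = aggregate_runs("const", per_fold)
    assert run.mean["cumulative"] == pytest.approx(0.9)
    assert run.std["cumulative"] == pytest.approx(0.0)

    run2 = aggregate_runs("two", {0: {"cumulative": 0.8}, 1: {"cumulative": 1.0}})
    assert run2.mean["cumulative"] == pytest.approx(0.9)
    assert run2.std["cumulative"] == pytest.approx(np.sqrt(0.02), abs=1e-12)


def test_aggregate_runs_matches_independent_summation():
    rng = np.random.default_rng(3)
    per_fold = {
        f: {"cumulative": float(rng.random()), "catania": float(rng.random())}
        for f in range(10)
    }
    run = aggregate_runs("rand", per_fold)
    for col in ("cumulative", "catania"):
        vals = [per_fold[f][col] for f in range(10)]
        assert run.mean[col] == pytest.approx(sum(vals) / 10, abs=1e-12)
    with pytest.raises(ValueError):
        aggregate_runs("bad", {0: {"cumulative": 1.0}, 1: {"other": 1.0}})


def _fake_run(setup, values, level=None):
    return aggregate_runs(setup, {f: {"cumulative": v} for f, v in enumerate(values)}, noise_level=level)


def test_noise_threshold_first_crossing_rules():
    rng = np.random.default_rng(5)
    base_vals = 0.9 + 0.01 * rng.standard_normal(10)
    baseline = _fake_run("base", base_vals)
    same = lambda lv: _fake_run(f"n{lv}", 0.9 + 0.01 * rng.standard_normal(10), lv)
    worse = lambda lv: _fake_run(f"n{lv}", 0.5 + 0.01 * rng.standard_normal(10), lv)

    # significance first at 0.20 -> threshold 0.10
    results = [same(0.01), same(0.05), same(0.10), worse(0.20), worse(0.50)]
    assert noise_threshold(results, baseline) == 0.10
    # significance first at 0.50 -> threshold 0.20
    results = [same(0.01), same(0.10), same(0.20), worse(0.50)]
    assert noise_threshold(results, baseline) == 0.20
    # nothing significant -> largest tested level
    results = [same(0.01), same(0.10), same(0.50)]
    assert noise_threshold(results, baseline) == 0.50
    # smallest level already significant -> 0
    results = [worse(0.01), same(0.05)]
    assert noise_threshold(results, baseline) == 0.0
    with pytest.raises(ValueError, match="increasing"):
        noise_threshold([same(0.10), same(0.05)], baseline)
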