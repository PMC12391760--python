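"""Label-perturbation operators and the label-quality score.

Weak labels extracted automatically from pathology reports are noisy; the
perturbation operators here simulate that noise by corrupting a manually
curated label table at a controlled rate. Each operator corrupts exactly
``round(p * N)`` slides chosen uniformly without replacement:

* binary tables have the selected labels flipped,
* multiclass tables have a different class assigned uniformly at random,
* multilabel tables have 1..C distinct indicator bits flipped per selected
  slide, then repaired to validity (the "normal" class never co-occurs with
  a finding, and no row is left all-zero).

Label quality is scored as the support-weighted F1 of the perturbed table
treated as predictions against the original table as truth, so a table with
p = 0 noise scores 1.0 and quality decays as p grows.

Closed-form expectations of that quality under uniform perturbation are
provided for the binary and multiclass operators (ratio-of-expected-counts
approximation, accurate to a few 1e-4 at cohort sizes in the thousands).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .evaluation import weighted_f1
from .labels import SCHEMES, LabelTable

#: noise fractions used in the published sweeps; arbitrary p is allowed in library use
SWEEP_LEVELS = (0.0, 0.01, 0.02, 0.05, 0.10, 0.20, 0.50)


@dataclass(frozen=True)
class NoiseSpec:
    """Perturbation request: scheme, noise fraction p in [0, 1], RNG seed."""

    scheme: str
    p: float
    seed: int = 0

    def __post_init__(self):
        if self.scheme not in SCHEMES:
            raise ValueError(f"unknown scheme {self.scheme!r}")
        if not 0.0 <= self.p <= 1.0:
            raise ValueError(f"noise fraction must lie in [0, 1], got {self.p}")


@dataclass
class PerturbationResult:
    perturbed: LabelTable
    changed_ids: frozenset
    quality_f1: float


def _check(labels: LabelTable, spec: NoiseSpec, expected_scheme: str) -> None:
    if spec.scheme != expected_scheme or labels.scheme != expected_scheme:
        raise ValueError(
            f"operator requires scheme {expected_scheme!r}, got spec={spec.scheme!r} "
            f"table={labels.scheme!r}"
        )


def _select(labels: LabelTable, spec: NoiseSpec, rng) -> np.ndarray:
    n_changed = int(round(spec.p * len(labels)))
    return rng.choice(len(labels), size=n_changed, replace=False)


def _result(labels: LabelTable, y_new: np.ndarray, idx: np.ndarray) -> PerturbationResult:
    perturbed = LabelTable(labels.scheme, labels.class_names, labels.slide_ids, y_new)
    changed = frozenset(labels.slide_ids[i] for i in idx)
    return PerturbationResult(perturbed, changed, label_quality(perturbed, labels))


def flip_binary(labels: LabelTable, spec: NoiseSpec) -> PerturbationResult:
    """Invert the label of round(p*N) uniformly chosen slides."""
    _check(labels, spec, "binary")
    rng = np.random.default_rng(spec.seed)
    idx = _select(labels, spec, rng)
    y = labels.y.copy()
    y[idx] = 1 - y[idx]
    return _result(labels, y, idx)


def reassign_multiclass(labels: LabelTable, spec: NoiseSpec) -> PerturbationResult:
    """Reassign round(p*N) uniformly chosen slides to a uniformly drawn other class."""
    _check(labels, spec, "multiclass")
    C = labels.n_classes
    if C < 2:
        raise ValueError("multiclass reassignment needs at least 2 classes")
    rng = np.random.default_rng(spec.seed)
    idx = _select(labels, spec, rng)
    y = labels.y.copy()
    # draw from the C-1 other classes by shifting past the original label
    shifts = rng.integers(1, C, size=len(idx))
    y[idx] = (y[idx] + shifts) % C
    return _result(labels, y, idx)


def perturb_multilabel(
    labels: LabelTable, spec: NoiseSpec, normal_class: int = -1
) -> PerturbationResult:
    """Flip 1..C indicator bits on round(p*N) uniformly chosen slides.

    For each selected slide a count k is drawn uniformly from {1, ..., C} and
    k distinct classes have their bits flipped; the result is repaired to
    validity ("normal" cleared when co-active with a finding, an all-zero row
    reactivated on one uniformly chosen class) and redrawn in the rare case
    the repair restores the original row.
    """
    _check(labels, spec, "multilabel")
    C = labels.n_classes
    normal = normal_class % C
    rng = np.random.default_rng(spec.seed)
    idx = _select(labels, spec, rng)
    y = labels.y.copy()
    for i in idx:
        original = labels.y[i]
        while True:
            row = original.copy()
            k = int(rng.integers(1, C + 1))
            flip = rng.choice(C, size=k, replace=False)
            row[flip] = 1 - row[flip]
            if row[normal] == 1 and row.sum() > 1:
                row[normal] = 0
            if row.sum() == 0:
                row[rng.integers(C)] = 1
            if not np.array_equal(row, original):
                break
        y[i] = row
    return _result(labels, y, idx)


def perturb(labels: LabelTable, spec: NoiseSpec) -> PerturbationResult:
    """Dispatch to the scheme's perturbation operator."""
    op = {
        "binary": flip_binary,
        "multiclass": reassign_multiclass,
        "multilabel": perturb_multilabel,
    }[spec.scheme]
    return op(labels, spec)


def label_quality(perturbed: LabelTable, original: LabelTable) -> float:
    """Support-weighted F1 of the perturbed table against the original."""
    return weighted_f1(perturbed, original)


def mean_label_quality(labels: LabelTable, p: float, n_seeds: int, seed: int = 0) -> float:
    """Monte-Carlo mean label quality over independent perturbation seeds."""
    seeds = np.random.SeedSequence(seed).generate_state(n_seeds) % (2**31)
    vals = [perturb(labels, NoiseSpec(labels.scheme, p, int(s))).quality_f1 for s in seeds]
    return float(np.mean(vals))


def expected_quality_multiclass(supports, p: float) -> float:
    """Expected label quality under exact-count uniform class reassignment.

    Each slide is corrupted with probability q = round(p*N)/N; a corrupted
    slide of class c lands on each other class with probability q/(C-1).
    Per-class F1 is formed from the expected confusion counts and averaged
    by support.
    """
    s = np.asarray(supports, dtype=float)
    N = s.sum()
    C = len(s)
    if C < 2:
        raise ValueError("need at least 2 classes")
    q = round(p * N) / N
    if q == 0:
        return 1.0
    tp = s * (1.0 - q)
    fn = s * q
    fp = (N - s) * q / (C - 1)
    f1 = 2 * tp / (2 * tp + fp + fn)
    return float(np.average(f1, weights=s))


def expected_quality_binary(n_class0: int, n_class1: int, p: float) -> float:
    """Expected label quality under exact-count uniform binary flipping."""
    s = np.array([n_class0, n_class1], dtype=float)
    N = s.sum()
    q = round(p * N) / N
    if q == 0:
        return 1.0
    tp = s * (1.0 - q)
    fn = s * q
    fp = (N - s) * q
    f1 = 2 * tp / (2 * tp + fp + fn)
    return float(np.average(f1, weights=s))
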