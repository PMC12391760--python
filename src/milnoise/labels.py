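"""Slide-level label tables for the three weak-label schemes.

A :class:`LabelTable` maps slide identifiers to labels under one of three
schemes used in digital pathology cohorts:

``binary``
    one class index in {0, 1} per slide (e.g. celiac disease vs normal),
``multiclass``
    one class index in [0, C) per slide (e.g. lung cancer subtypes),
``multilabel``
    a 0/1 indicator vector of length C per slide with at least one active
    entry (e.g. colon findings), where a designated "normal" class is
    mutually exclusive with the disease classes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

SCHEMES = ("binary", "multiclass", "multilabel")


@dataclass
class LabelTable:
    """Per-slide labels under a scheme.

    Parameters
    ----------
    scheme:
        One of ``binary``, ``multiclass``, ``multilabel``.
    class_names:
        Ordered class names; for binary/multiclass the label is the index
        into this list, for multilabel the indicator vector is aligned to it.
    slide_ids:
        Slide identifiers, one per row, unique.
    y:
        Integer array of shape ``(N,)`` (binary/multiclass) or ``(N, C)``
        0/1 indicators (multilabel).
    """

    scheme: str
    class_names: tuple
    slide_ids: tuple
    y: np.ndarray = field(repr=False)

    def __post_init__(self):
        if self.scheme not in SCHEMES:
            raise ValueError(f"unknown scheme {self.scheme!r}; expected one of {SCHEMES}")
        self.class_names = tuple(self.class_names)
        self.slide_ids = tuple(str(s) for s in self.slide_ids)
        if len(set(self.slide_ids)) != len(self.slide_ids):
            raise ValueError("slide_ids must be unique")
        self.y = np.asarray(self.y, dtype=np.int64)
        C = len(self.class_names)
        N = len(self.slide_ids)
        if self.scheme == "multilabel":
            if self.y.shape != (N, C):
                raise ValueError(f"multilabel y must have shape ({N}, {C}), got {self.y.shape}")
            if not np.isin(self.y, (0, 1)).all():
                raise ValueError("multilabel indicators must be 0/1")
            if N and (self.y.sum(axis=1) < 1).any():
                raise ValueError("every multilabel row needs at least one active class")
        else:
            if self.y.shape != (N,):
                raise ValueError(f"{self.scheme} y must have shape ({N},), got {self.y.shape}")
            if N and (self.y.min() < 0 or self.y.max() >= C):
                raise ValueError(f"class index out of range [0, {C})")
            if self.scheme == "binary" and C != 2:
                raise ValueError("binary scheme requires exactly 2 classes")

    def __len__(self) -> int:
        return len(self.slide_ids)

    @property
    def n_classes(self) -> int:
        return len(self.class_names)

    @property
    def support(self) -> dict:
        """Count of true slides per class (multilabel: per-indicator)."""
        C = self.n_classes
        if self.scheme == "multilabel":
            counts = self.y.sum(axis=0)
        else:
            counts = np.bincount(self.y, minlength=C)
        return {name: int(c) for name, c in zip(self.class_names, counts)}

    def copy(self) -> "LabelTable":
        return LabelTable(self.scheme, self.class_names, self.slide_ids, self.y.copy())

    def same_slides(self, other: "LabelTable") -> bool:
        return set(self.slide_ids) == set(other.slide_ids)

    def aligned_y(self, slide_order) -> np.ndarray:
        """Labels reindexed to the given slide order."""
        pos = {s: i for i, s in enumerate(self.slide_ids)}
        idx = np.array([pos[s] for s in slide_order], dtype=np.intp)
        return self.y[idx]

    def to_frame(self, patient_ids=None, sources=None) -> pd.DataFrame:
        """Tidy frame: slide_id[, patient_id, source], label column(s)."""
        data = {"slide_id": list(self.slide_ids)}
        if patient_ids is not None:
            data["patient_id"] = list(patient_ids)
        if sources is not None:
            data["source"] = list(sources)
        if self.scheme == "multilabel":
            for j, name in enumerate(self.class_names):
                data[name] = self.y[:, j]
        else:
            data["label"] = [self.class_names[i] for i in self.y]
        return pd.DataFrame(data)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, scheme: str, class_names) -> "LabelTable":
        class_names = tuple(class_names)
        slide_ids = tuple(frame["slide_id"].astype(str))
        if scheme == "multilabel":
            y = frame[list(class_names)].to_numpy(dtype=np.int64)
        else:
            index = {name: i for i, name in enumerate(class_names)}
            y = np.array([index[v] for v in frame["label"]], dtype=np.int64)
        return cls(scheme, class_names, slide_ids, y)


def from_supports(
    scheme: str,
    class_names,
    supports,
    n_total: int | None = None,
    prefix: str = "s",
) -> LabelTable:
    """Build a deterministic label table with the given per-class supports.

    For binary/multiclass, ``supports[c]`` slides get class ``c``. For
    multilabel, the last class is treated as the exclusive "normal" class:
    its ``supports[-1]`` slides carry only that indicator, and the disease
    activations are wrapped sequentially over the remaining
    ``n_total - supports[-1]`` slides so each carries at least one finding.
    This is a layout for oracles and benchmarks, not a generative model.
    """
    class_names = tuple(class_names)
    supports = [int(s) for s in supports]
    if scheme == "multilabel":
        if n_total is None:
            raise ValueError("multilabel from_supports requires n_total")
        n = int(n_total)
        n_normal = supports[-1]
        n_disease_rows = n - n_normal
        disease_total = sum(supports[:-1])
        if disease_total < n_disease_rows:
            raise ValueError("disease supports cannot cover all non-normal slides")
        y = np.zeros((n, len(class_names)), dtype=np.int64)
        y[n_disease_rows:, -1] = 1
        ptr = 0
        for c, s in enumerate(supports[:-1]):
            if s > n_disease_rows:
                raise ValueError(f"support of class {class_names[c]} exceeds disease rows")
            rows = (ptr + np.arange(s)) % n_disease_rows
            y[rows, c] = 1
            ptr = (ptr + s) % n_disease_rows
    else:
        y = np.repeat(np.arange(len(class_names)), supports)
        n = len(y)
    ids = tuple(f"{prefix}{i:05d}" for i in range(n))
    return LabelTable(scheme, class_names, ids, y)
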