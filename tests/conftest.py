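import dataclasses

import numpy as np
import pytest

from milnoise.labels import LabelTable, from_supports
from milnoise.synthgen import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def binary_config():
    return CohortConfig(
        scheme="binary",
        class_names=("celiac_disease", "normal"),
        class_counts_per_source={
            "catania": {"celiac_disease": 10, "normal": 20},
            "rumc": {"celiac_disease": 14, "normal": 16},
        },
        n_instances_range=(8, 16),
        embed_dim=12,
        witness_rate=0.2,
        signal_strength=3.0,
        seed=11,
    )


@pytest.fixture(scope="session")
def binary_cohort(binary_config):
    return generate_cohort(binary_config)


@pytest.fixture(scope="session")
def multiclass_cohort():
    cfg = CohortConfig(
        scheme="multiclass",
        class_names=("sclc", "luad", "lusc", "normal"),
        class_counts_per_source={
            "catania": {"sclc": 4, "luad": 10, "lusc": 8, "normal": 8},
            "rumc": {"sclc": 2, "luad": 6, "lusc": 4, "normal": 18},
        },
        n_instances_range=(8, 16),
        embed_dim=12,
        witness_rate=0.2,
        signal_strength=3.0,
        seed=13,
    )
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def multilabel_cohort():
    cfg = CohortConfig(
        scheme="multilabel",
        class_names=("adenocarcinoma", "hgd", "lgd", "hyperplastic_polyp", "normal"),
        class_counts_per_source={
            "catania": {"adenocarcinoma": 8, "hgd": 7, "lgd": 12, "hyperplastic_polyp": 5, "normal": 6},
            "rumc": {"adenocarcinoma": 4, "hgd": 3, "lgd": 8, "hyperplastic_polyp": 9, "normal": 10},
        },
        n_slides_per_source={"catania": 30, "rumc": 30},
        n_instances_range=(8, 16),
        embed_dim=12,
        witness_rate=0.2,
        signal_strength=3.0,
        seed=17,
    )
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def lung_manual_table():
    """Multiclass table with the lung training-set manual class supports."""
    return from_supports(
        "multiclass", ("sclc", "luad", "lusc", "normal"), (51, 779, 444, 1276)
    )


def random_table(scheme, n, n_classes, rng) -> LabelTable:
    ids = tuple(f"r{i:04d}" for i in range(n))
    if scheme == "multilabel":
        y = rng.integers(0, 2, size=(n, n_classes))
        empty = y.sum(axis=1) == 0
        y[empty, rng.integers(0, n_classes, size=int(empty.sum()))] = 1
        # keep the last class exclusive, mirroring the normal-tissue rule
        y[(y[:, -1] == 1) & (y[:, :-1].sum(axis=1) > 0), -1] = 0
        names = tuple(f"c{j}" for j in range(n_classes))
        return LabelTable(scheme, names, ids, y)
    y = rng.integers(0, n_classes, size=n)
    names = tuple(f"c{j}" for j in range(n_classes))
    return LabelTable(scheme, names, ids, y)
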