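"""Cohort generator: composition, determinism, witness fractions, reports."""

import dataclasses

import numpy as np
import pytest

from milnoise.synthgen import (
    CohortConfig,
    Cohort,
    InstanceBag,
    class_signatures,
    generate_cohort,
    generate_reports,
)


def test_class_composition_matches_config_binary(binary_cohort, binary_config):
    labels = binary_cohort.labels
    by_source = {}
    for bag in binary_cohort.bags:
        by_source.setdefault(bag.source, []).append(bag.slide_id)
    pos = {s: i for i, s in enumerate(labels.slide_ids)}
    for source, want in binary_config.class_counts_per_source.items():
        y = labels.y[[pos[s] for s in by_source[source]]]
        for c, name in enumerate(labels.class_names):
            assert int(np.sum(y == c)) == want[name]


def test_class_composition_matches_config_multilabel(multilabel_cohort):
    cfg = multilabel_cohort.config
    labels = multilabel_cohort.labels
    pos = {s: i for i, s in enumerate(labels.slide_ids)}
    by_source = {}
    for bag in multilabel_cohort.bags:
        by_source.setdefault(bag.source, []).append(bag.slide_id)
    for source, want in cfg.class_counts_per_source.items():
        y = labels.y[[pos[s] for s in by_source[source]]]
        assert y.shape[0] == cfg.n_slides_per_source[source]
        for c, name in enumerate(labels.class_names):
            assert int(y[:, c].sum()) == want[name]
    # the normal class is exclusive of every finding
    y = labels.y
    assert not ((y[:, -1] == 1) & (y[:, :-1].sum(axis=1) > 0)).any()
    assert (y.sum(axis=1) >= 1).all()


def test_generation_is_deterministic_per_seed(binary_config):
    a = generate_cohort(binary_config)
    b = generate_cohort(binary_config)
    assert a.labels.slide_ids == b.labels.slide_ids
    assert np.array_equal(a.labels.y, b.labels.y)
    for ba, bb in zip(a.bags, b.bags):
        assert ba.slide_id == bb.slide_id
        assert np.array_equal(ba.features, bb.features)
        assert np.array_equal(ba.witness_mask, bb.witness_mask)
    shifted = dataclasses.replace(binary_config, seed=binary_config.seed + 1)
    c = generate_cohort(shifted)
    assert not all(
        np.array_equal(ba.features, bc.features) for ba, bc in zip(a.bags, c.bags)
    )


def test_witness_fraction_tracks_configured_rate():
    cfg = CohortConfig(
        scheme="binary",
        class_names=("disease", "normal"),
        class_counts_per_source={"site": {"disease": 100, "normal": 100}},
        n_instances_range=(40, 60),
        embed_dim=8,
        witness_rate=0.15,
        seed=3,
    )
    cohort = generate_cohort(cfg)
    n_wit = sum(int(b.witness_mask.sum()) for b in cohort.bags)
    n_inst = sum(b.n_instances for b in cohort.bags)
    assert abs(n_wit / n_inst - 0.15) < 0.01
    # per-bag: rounded count, never zero
    for bag in cohort.bags:
        assert int(bag.witness_mask.sum()) == max(1, round(0.15 * bag.n_instances))


def test_instance_counts_respect_range(binary_cohort, binary_config):
    lo, hi = binary_config.n_instances_range
    for bag in binary_cohort.bags:
        assert lo <= bag.n_instances <= hi
        assert bag.features.shape[1] == binary_config.embed_dim


def test_signatures_are_orthonormal_when_dim_allows():
    sig = class_signatures(("a", "b", "c"), embed_dim=16, seed=0)
    assert sig.shape == (3, 16)
    gram = sig @ sig.T
    assert np.allclose(gram, np.eye(3), atol=1e-10)
    again = class_signatures(("a", "b", "c"), embed_dim=16, seed=0)
    assert np.array_equal(sig, again)


def test_full_witness_cohort_is_centroid_separable():
    """With witness_rate 1 and no covariate shift, a nearest-signature
    classifier on bag means must recover nearly all labels."""
    cfg = CohortConfig(
        scheme="multiclass",
        class_names=("sclc", "luad", "lusc", "normal"),
        class_counts_per_source={
            "site": {"sclc": 25, "luad": 25, "lusc": 25, "normal": 25}
        },
        n_instances_range=(8, 16),
        embed_dim=12,
        witness_rate=1.0,
        signal_strength=3.0,
        source_shift=0.0,
        seed=5,
    )
    cohort = generate_cohort(cfg)
    sig = class_signatures(cfg.class_names, cfg.embed_dim, cfg.seed)
    pos = {s: i for i, s in enumerate(cohort.labels.slide_ids)}
    correct = 0
    for bag in cohort.bags:
        pred = int(np.argmax(sig @ bag.features.mean(axis=0)))
        correct += pred == int(cohort.labels.y[pos[bag.slide_id]])
    assert correct / len(cohort) >= 0.99


def test_source_shift_displaces_feature_means():
    base = dict(
        scheme="binary",
        class_names=("disease", "normal"),
        class_counts_per_source={
            "a": {"disease": 20, "normal": 20},
            "b": {"disease": 20, "normal": 20},
        },
        n_instances_range=(20, 30),
        embed_dim=16,
        witness_rate=0.1,
        seed=7,
    )
    shifted = generate_cohort(CohortConfig(source_shift=2.0, **base))
    means = {}
    for bag in shifted.bags:
        means.setdefault(bag.source, []).append(bag.features.mean(axis=0))
    gap = np.linalg.norm(
        np.mean(means["a"], axis=0) - np.mean(means["b"], axis=0)
    )
    assert gap > 1.0  # sources separated by order of the shift magnitude


def test_patients_never_straddle_sources():
    with pytest.raises(ValueError, match="two sources"):
        bag = lambda sid, pid, src: InstanceBag(
            sid, pid, src, np.zeros((3, 4)), np.zeros(3, dtype=bool)
        )
        from milnoise.labels import LabelTable

        labels = LabelTable(
            "binary", ("a", "b"), ("s1", "s2"), np.array([0, 1])
        )
        cfg = CohortConfig(
            scheme="binary",
            class_names=("a", "b"),
            class_counts_per_source={"x": {"a": 1}, "y": {"b": 1}},
        )
        Cohort([bag("s1", "p0", "x"), bag("s2", "p0", "y")], labels, cfg)


def test_config_validation_rejects_bad_values():
    base = dict(
        scheme="binary",
        class_names=("a", "b"),
        class_counts_per_source={"x": {"a": 1, "b": 1}},
    )
    with pytest.raises(ValueError, match="scheme"):
        CohortConfig(**{**base, "scheme": "ordinal"})
    with pytest.raises(ValueError, match="witness_rate"):
        CohortConfig(**base, witness_rate=0.0)
    with pytest.raises(ValueError, match="unknown class"):
        CohortConfig(**{**base, "class_counts_per_source": {"x": {"zz": 1}}})
    with pytest.raises(ValueError, match="n_slides_per_source"):
        CohortConfig(**{**base, "scheme": "multilabel"})
    with pytest.raises(ValueError, match="n_instances_range"):
        CohortConfig(**base, n_instances_range=(0, 5))


def test_config_yaml_roundtrip(tmp_path, binary_config):
    import yaml

    path = tmp_path / "cohort.yaml"
    raw = dataclasses.asdict(binary_config)
    raw["class_names"] = list(raw["class_names"])
    raw["n_instances_range"] = list(raw["n_instances_range"])
    path.write_text(yaml.safe_dump(raw))
    loaded = CohortConfig.from_yaml(path)
    assert loaded == binary_config
    assert np.array_equal(
        generate_cohort(loaded).labels.y, generate_cohort(binary_config).labels.y
    )


# --- pseudo-reports --------------------------------------------------------


def test_one_report_per_slide_with_matching_truth(binary_cohort):
    records = generate_reports(binary_cohort, wordy_fraction=0.2, seed=1)
    assert len(records) == len(binary_cohort)
    pos = {s: i for i, s in enumerate(binary_cohort.labels.slide_ids)}
    assert {r.slide_id for r in records} == set(binary_cohort.labels.slide_ids)
    for r in records:
        assert r.truth_concepts == int(binary_cohort.labels.y[pos[r.slide_id]])
        assert r.text.strip()


def test_wordy_fraction_boundaries_and_binomial_band(binary_cohort):
    none = generate_reports(binary_cohort, wordy_fraction=0.0, seed=2)
    assert not any(r.is_wordy for r in none)
    allw = generate_reports(binary_cohort, wordy_fraction=1.0, seed=2)
    assert all(r.is_wordy for r in allw)
    with pytest.raises(ValueError):
        generate_reports(binary_cohort, wordy_fraction=1.2, seed=2)

    # pooled over many seeds the wordy rate concentrates near the target
    n_wordy = n_total = 0
    for seed in range(30):
        recs = generate_reports(binary_cohort, wordy_fraction=0.2, seed=seed)
        n_wordy += sum(r.is_wordy for r in recs)
        n_total += len(recs)
    rate = n_wordy / n_total
    sd = np.sqrt(0.2 * 0.8 / n_total)
    assert abs(rate - 0.2) < 5 * sd


def test_concise_reports_mention_active_class(multiclass_cohort):
    records = generate_reports(multiclass_cohort, wordy_fraction=0.0, seed=3)
    mentions = {
        "sclc": "small cell carcinoma",
        "luad": "adenocarcinoma",
        "lusc": "squamous cell carcinoma",
    }
    pos = {s: i for i, s in enumerate(multiclass_cohort.labels.slide_ids)}
    names = multiclass_cohort.labels.class_names
    for r in records:
        cls = names[int(multiclass_cohort.labels.y[pos[r.slide_id]])]
        if cls in mentions:
            assert mentions[cls] in r.text.lower()


def test_reports_deterministic_per_seed(binary_cohort):
    a = generate_reports(binary_cohort, wordy_fraction=0.3, seed=9)
    b = generate_reports(binary_cohort, wordy_fraction=0.3, seed=9)
    assert [(r.slide_id, r.text, r.is_wordy) for r in a] == [
        (r.slide_id, r.text, r.is_wordy) for r in b
    ]


def test_reports_reject_unknown_classes(binary_config):
    cfg = dataclasses.replace(
        binary_config,
        class_names=("mystery_entity", "normal"),
        class_counts_per_source={
            "catania": {"mystery_entity": 10, "normal": 20},
            "rumc": {"mystery_entity": 14, "normal": 16},
        },
    )
    cohort = generate_cohort(cfg)
    with pytest.raises(ValueError, match="templates"):
        generate_reports(cohort, wordy_fraction=0.0, seed=0)
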