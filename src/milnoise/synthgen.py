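"""Synthetic weakly labeled slide cohorts.

Real whole-slide images are gigapixel scans reduced, after tiling and
self-supervised encoding, to a bag of instance feature vectors carrying a
single slide-level label. This module emulates that end product directly: a
cohort is a list of bags of Gaussian instance embeddings in which only a
small *witness* fraction of instances carries class evidence (weak labels
are typically justified by 1-2% of the tissue), drawn from two sources with
a covariate shift that stands in for inter-lab stain variability.

The generative model per bag:

* non-witness instances are background draws ``N(0, noise_sd^2 I)``;
* witness instances add a fixed unit class-signature direction scaled by
  ``signal_strength`` (default ``2 * noise_sd``); multilabel bags contain
  witnesses for each active class;
* every instance of a source is then scaled and offset by that source's
  shift (magnitude ``source_shift``).

Class compositions are taken verbatim from the config table, so generated
per-source, per-class counts match it exactly. Templated pseudo-reports pair
each slide with free text: concise templates state the findings, and a
configurable minority of wordy reports bury them among history and
immunohistochemistry clauses -- the stratum on which rule-based concept
extraction realistically fails.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import yaml

from .labels import SCHEMES, LabelTable


@dataclass
class CohortConfig:
    """Configuration of a synthetic cohort.

    ``class_counts_per_source`` maps source name -> {class name -> count}.
    For the multilabel scheme the per-class counts overlap, so
    ``n_slides_per_source`` must give the total slide count per source; for
    binary/multiclass it defaults to the row sums.
    """

    scheme: str
    class_names: tuple
    class_counts_per_source: dict
    n_slides_per_source: dict | None = None
    n_instances_range: tuple = (20, 60)
    embed_dim: int = 32
    witness_rate: float = 0.05
    signal_strength: float | None = None  # default 2 * noise_sd
    source_shift: float = 0.5
    noise_sd: float = 1.0
    slides_per_patient: int = 1
    seed: int = 0

    def __post_init__(self):
        if self.scheme not in SCHEMES:
            raise ValueError(f"unknown scheme {self.scheme!r}; expected one of {SCHEMES}")
        self.class_names = tuple(self.class_names)
        for source, row in self.class_counts_per_source.items():
            for cls, count in row.items():
                if cls not in self.class_names:
                    raise ValueError(f"count for unknown class {cls!r} in source {source!r}")
                if count < 0:
                    raise ValueError("class counts must be >= 0")
        if not 0.0 < self.witness_rate <= 1.0:
            raise ValueError("witness_rate must lie in (0, 1]")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.source_shift < 0:
            raise ValueError("source_shift must be >= 0")
        lo, hi = self.n_instances_range
        if lo < 1 or hi < lo:
            raise ValueError("n_instances_range must satisfy 1 <= lo <= hi")
        if self.slides_per_patient < 1:
            raise ValueError("slides_per_patient must be >= 1")
        if self.scheme == "multilabel" and self.n_slides_per_source is None:
            raise ValueError("multilabel configs need n_slides_per_source")

    @property
    def sources(self) -> tuple:
        return tuple(self.class_counts_per_source)

    def slides_in_source(self, source: str) -> int:
        if self.n_slides_per_source is not None:
            return int(self.n_slides_per_source[source])
        return int(sum(self.class_counts_per_source[source].values()))

    @classmethod
    def from_yaml(cls, path) -> "CohortConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        raw["class_names"] = tuple(raw["class_names"])
        if "n_instances_range" in raw:
            raw["n_instances_range"] = tuple(raw["n_instances_range"])
        return cls(**raw)


@dataclass
class InstanceBag:
    """One slide: an instance-feature matrix plus identifiers.

    ``witness_mask`` marks the instances that carry class evidence; it is
    ground truth for diagnostics (e.g. checking attention maps) and is never
    shown to a model.
    """

    slide_id: str
    patient_id: str
    source: str
    features: np.ndarray
    witness_mask: np.ndarray = field(repr=False)

    def __post_init__(self):
        self.features = np.asarray(self.features, dtype=np.float64)
        self.witness_mask = np.asarray(self.witness_mask, dtype=bool)
        if self.features.ndim != 2 or self.features.shape[0] < 1:
            raise ValueError("features must be a non-empty (n_instances, embed_dim) matrix")
        if self.witness_mask.shape != (self.features.shape[0],):
            raise ValueError("witness_mask length must equal n_instances")
        if not np.isfinite(self.features).all():
            raise ValueError("features must be finite")

    @property
    def n_instances(self) -> int:
        return self.features.shape[0]


@dataclass
class Cohort:
    bags: list
    labels: LabelTable
    config: CohortConfig

    def __post_init__(self):
        if {b.slide_id for b in self.bags} != set(self.labels.slide_ids):
            raise ValueError("labels must cover exactly the cohort's slides")
        patient_source = {}
        for b in self.bags:
            if patient_source.setdefault(b.patient_id, b.source) != b.source:
                raise ValueError(f"patient {b.patient_id} appears in two sources")

    def __len__(self) -> int:
        return len(self.bags)

    @property
    def sources(self) -> tuple:
        return tuple(dict.fromkeys(b.source for b in self.bags))

    def bag(self, slide_id: str) -> InstanceBag:
        return next(b for b in self.bags if b.slide_id == slide_id)


@dataclass
class ReportRecord:
    """Pseudo-report paired with a slide: free text plus ground-truth concepts."""

    report_id: str
    slide_id: str
    source: str
    text: str
    truth_concepts: object  # label under the cohort scheme
    is_wordy: bool

    def __post_init__(self):
        if not self.text:
            raise ValueError("report text must be non-empty")


def class_signatures(class_names, embed_dim: int, seed: int) -> np.ndarray:
    """Fixed unit signature direction per class (orthonormalized when possible)."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xC1A55]).generate_state(1)[0])
    C = len(class_names)
    raw = rng.standard_normal((embed_dim, max(C, 1)))
    if embed_dim >= C:
        q, _ = np.linalg.qr(raw)
        sig = q[:, :C].T
    else:
        sig = raw[:, :C].T
        sig /= np.linalg.norm(sig, axis=1, keepdims=True)
    return sig


def _per_source_labels(config: CohortConfig, source: str, rng) -> np.ndarray:
    """Label array for one source with exactly the configured class counts."""
    counts = config.class_counts_per_source[source]
    C = len(config.class_names)
    if config.scheme == "multilabel":
        n = config.slides_in_source(source)
        normal = C - 1
        supports = [int(counts.get(c, 0)) for c in config.class_names]
        n_normal = supports[normal]
        n_disease = n - n_normal
        if sum(supports[:normal]) < n_disease:
            raise ValueError(f"source {source!r}: finding counts cannot cover all non-normal slides")
        y = np.zeros((n, C), dtype=np.int64)
        y[n_disease:, normal] = 1
        if n_disease > 0:
            ptr = 0
            for c in range(normal):
                s = supports[c]
                if s > n_disease:
                    raise ValueError(f"source {source!r}: class {config.class_names[c]!r} support exceeds slides")
                y[(ptr + np.arange(s)) % n_disease, c] = 1
                ptr = (ptr + s) % n_disease
        rng.shuffle(y)  # shuffles rows only
        return y
    supports = [int(counts.get(c, 0)) for c in config.class_names]
    y = np.repeat(np.arange(C), supports)
    rng.shuffle(y)
    return y


def generate_cohort(config: CohortConfig) -> Cohort:
    """Generate a synthetic cohort; deterministic for a fixed config seed."""
    ss = np.random.SeedSequence(config.seed)
    rng = np.random.default_rng(ss)
    sig = class_signatures(config.class_names, config.embed_dim, config.seed)
    signal = config.signal_strength if config.signal_strength is not None else 2.0 * config.noise_sd

    bags = []
    slide_ids, rows = [], []
    lo, hi = config.n_instances_range
    for source in config.sources:
        y_src = _per_source_labels(config, source, rng)
        offset_dir = rng.standard_normal(config.embed_dim)
        norm = np.linalg.norm(offset_dir)
        offset = config.source_shift * offset_dir / norm if norm > 0 else offset_dir * 0.0
        scale = 1.0 + 0.1 * config.source_shift * rng.uniform(-1.0, 1.0)
        for i in range(len(y_src)):
            label = y_src[i]
            n = int(rng.integers(lo, hi + 1))
            feats = config.noise_sd * rng.standard_normal((n, config.embed_dim))
            n_wit = max(1, int(round(config.witness_rate * n)))
            n_wit = min(n_wit, n)
            wit_idx = rng.choice(n, size=n_wit, replace=False)
            mask = np.zeros(n, dtype=bool)
            mask[wit_idx] = True
            if config.scheme == "multilabel":
                active = np.flatnonzero(label)
            else:
                active = np.array([label])
            # witnesses split round-robin across the bag's active classes
            for j, inst in enumerate(wit_idx):
                feats[inst] += signal * sig[active[j % len(active)]]
            feats = scale * feats + offset
            slide_id = f"{source}_slide_{i:05d}"
            patient_index = i // config.slides_per_patient
            patient_id = f"{source}_patient_{patient_index:05d}"
            bags.append(InstanceBag(slide_id, patient_id, source, feats, mask))
            slide_ids.append(slide_id)
            rows.append(label)

    if rows:
        y = np.stack(rows) if config.scheme == "multilabel" else np.array(rows, dtype=np.int64)
    else:
        C = len(config.class_names)
        y = np.zeros((0, C), dtype=np.int64) if config.scheme == "multilabel" else np.zeros(0, dtype=np.int64)
    labels = LabelTable(config.scheme, config.class_names, tuple(slide_ids), y)
    return Cohort(bags=bags, labels=labels, config=config)


# ---------------------------------------------------------------------------
# pseudo-report generation


def _load_templates() -> dict:
    with resources.files("milnoise.data").joinpath("templates.yaml").open() as fh:
        return yaml.safe_load(fh)


def _default_distractor(class_names, templates) -> str:
    """Disease class whose mention seeds the misleading wordy clause.

    Prefers the lowest-severity finding of the known use cases so the
    extraction errors it induces concentrate on slides lacking that finding.
    """
    for preferred in ("luad", "adenocarcinoma", "celiac_disease"):
        if preferred in class_names:
            return preferred
    for name in class_names:
        if name != "normal":
            return name
    return class_names[0]


def generate_reports(cohort: Cohort, wordy_fraction: float = 0.2, seed: int = 0):
    """One templated pseudo-report per slide.

    Concise reports state each active class's findings in one of three
    templates. A ``wordy_fraction`` minority instead buries the findings
    among distractor clauses (family history, immunohistochemistry); half of
    the wordy frames negate a disease mention cleanly, the other half leave
    a history mention of the distractor class outside any negation scope,
    which is the stratum where rule-based extraction errs.
    """
    if not 0.0 <= wordy_fraction <= 1.0:
        raise ValueError("wordy_fraction must lie in [0, 1]")
    templates = _load_templates()
    class_names = cohort.labels.class_names
    for name in class_names:
        if name not in templates["classes"]:
            raise ValueError(f"no report templates for class {name!r}")
    mention = {name: templates["classes"][name]["mention"] for name in class_names}
    dis_cls = _default_distractor(class_names, templates)
    # frames need a short phrase so benign negation scopes actually cover it
    distractor = templates["classes"][dis_cls].get("short", mention[dis_cls])
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x5EED]).generate_state(1)[0])

    y = cohort.labels.y
    order = {s: i for i, s in enumerate(cohort.labels.slide_ids)}
    records = []
    for bag in cohort.bags:
        label = y[order[bag.slide_id]]
        if cohort.labels.scheme == "multilabel":
            active = [class_names[j] for j in np.flatnonzero(label)]
            truth = label.copy()
        else:
            active = [class_names[int(label)]]
            truth = int(label)
        sentences = []
        for name in active:
            options = templates["classes"][name]["concise"]
            t = options[int(rng.integers(len(options)))]
            sentences.append(t.format(mention=mention[name]))
        findings = " ".join(sentences)
        is_wordy = bool(rng.random() < wordy_fraction)
        if is_wordy:
            frames = templates["wordy_frames"]
            kind = "misleading" if rng.random() < 0.5 else "benign"
            frame = frames[kind][int(rng.integers(len(frames[kind])))]
            text = frame.format(findings=findings, distractor=distractor)
        else:
            text = findings
        records.append(
            ReportRecord(
                report_id=f"report_{bag.slide_id}",
                slide_id=bag.slide_id,
                source=bag.source,
                text=text,
                truth_concepts=truth,
                is_wordy=is_wordy,
            )
        )
    return records
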