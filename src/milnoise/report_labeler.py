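"""Rule-based concept extraction from pathology reports, and annotation cost.

Automatic weak labels come from scanning a report's findings text for class
trigger phrases (lexicon lookup) while discounting mentions inside a negation
scope ("no villous atrophy"). Binary and multiclass schemes resolve multiple
fired classes by a configured severity priority with diseases ranked above
normal tissue; the multilabel scheme keeps every fired class, with normal
tissue mutually exclusive of findings. A slide whose report fires nothing is
assigned the default (normal) class.

The annotation-time model compares automatic against manual labeling: an
algorithm needs fractions of a second per report while a human expert needs
tens of seconds, so automatic labeling of a realistic archive saves well over
99% of annotation time.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import yaml

from .evaluation import CUMULATIVE, weighted_f1
from .labels import LabelTable

_SENTENCE_SPLIT = re.compile(r"[.;:]")
_PUNCT = re.compile(r"[,()\[\]{}!?\"]")


@dataclass
class ConceptLexicon:
    """Trigger phrases per class plus negation rules for one use case."""

    scheme: str
    triggers: dict  # class -> list of phrases, case-insensitive
    negation_cues: list
    default_class: str
    priority: list  # classes in decreasing severity, diseases before normal
    negation_window: int = 5

    def __post_init__(self):
        seen = {}
        for cls, phrases in self.triggers.items():
            if not phrases:
                raise ValueError(f"class {cls!r} needs at least one trigger")
            for ph in phrases:
                key = ph.lower()
                if key in seen:
                    raise ValueError(f"trigger {ph!r} shared by {seen[key]!r} and {cls!r}")
                seen[key] = cls
        if self.default_class not in self.triggers:
            raise ValueError("default_class must be one of the lexicon classes")

    @property
    def class_order(self) -> list:
        return list(self.priority)


def load_lexicon(use_case: str) -> ConceptLexicon:
    """Shipped lexicon for one of the built-in use cases (celiac, lung, colon)."""
    with resources.files("milnoise.data").joinpath("lexicons.yaml").open() as fh:
        raw = yaml.safe_load(fh)
    if use_case not in raw:
        raise KeyError(f"no shipped lexicon for {use_case!r}; have {sorted(raw)}")
    entry = raw[use_case]
    return ConceptLexicon(
        scheme=entry["scheme"],
        triggers=entry["triggers"],
        negation_cues=entry["negation_cues"],
        default_class=entry["default_class"],
        priority=entry["priority"],
        negation_window=entry.get("negation_window", 5),
    )


def _tokenize(sentence: str) -> list:
    return _PUNCT.sub(" ", sentence.lower()).split()


def _phrase_positions(tokens, phrase_tokens) -> list:
    n = len(phrase_tokens)
    return [
        i
        for i in range(len(tokens) - n + 1)
        if tokens[i : i + n] == phrase_tokens
    ]


def _fired_classes(text: str, lexicon: ConceptLexicon) -> set:
    fired = set()
    cues = sorted((c.lower().split() for c in lexicon.negation_cues), key=len, reverse=True)
    for sentence in _SENTENCE_SPLIT.split(text):
        tokens = _tokenize(sentence)
        if not tokens:
            continue
        # negation scope: window of tokens after each cue, not crossing the sentence
        negated = np.zeros(len(tokens), dtype=bool)
        for cue in cues:
            for pos in _phrase_positions(tokens, cue):
                start = pos + len(cue)
                negated[start : start + lexicon.negation_window] = True
        for cls, phrases in lexicon.triggers.items():
            if cls in fired:
                continue
            for phrase in phrases:
                ptoks = phrase.lower().split()
                if any(not negated[p] for p in _phrase_positions(tokens, ptoks)):
                    fired.add(cls)
                    break
    return fired


def extract_concepts(text: str, lexicon: ConceptLexicon):
    """Extract the slide label from one report.

    Returns a class name for binary/multiclass, or the sorted list of active
    class names for multilabel (normal dropped when a finding co-fires).
    Extraction is deterministic, idempotent, and insensitive to case and
    surrounding whitespace.
    """
    if not text or not text.strip():
        raise ValueError("report text must be non-empty")
    fired = _fired_classes(text, lexicon)
    default = lexicon.default_class
    if lexicon.scheme == "multilabel":
        if fired - {default}:
            fired.discard(default)  # normal is exclusive of findings
        active = fired or {default}
        order = {c: i for i, c in enumerate(lexicon.class_order)}
        return sorted(active, key=lambda c: order.get(c, len(order)))
    for cls in lexicon.class_order:
        if cls in fired:
            return cls
    return default


def labels_from_reports(corpus, lexicon: ConceptLexicon, class_names) -> LabelTable:
    """Run extraction over a corpus and assemble a label table."""
    if not corpus:
        raise ValueError("empty corpus")
    class_names = tuple(class_names)
    index = {c: i for i, c in enumerate(class_names)}
    slide_ids, rows = [], []
    for rec in corpus:
        extracted = extract_concepts(rec.text, lexicon)
        if lexicon.scheme == "multilabel":
            row = np.zeros(len(class_names), dtype=np.int64)
            for c in extracted:
                row[index[c]] = 1
            rows.append(row)
        else:
            rows.append(index[extracted])
        slide_ids.append(rec.slide_id)
    y = np.stack(rows) if lexicon.scheme == "multilabel" else np.array(rows, dtype=np.int64)
    return LabelTable(lexicon.scheme, class_names, tuple(slide_ids), y)


def _truth_table(corpus, scheme: str, class_names) -> LabelTable:
    class_names = tuple(class_names)
    slide_ids = tuple(rec.slide_id for rec in corpus)
    if scheme == "multilabel":
        y = np.stack([np.asarray(rec.truth_concepts, dtype=np.int64) for rec in corpus])
    else:
        y = np.array([int(rec.truth_concepts) for rec in corpus], dtype=np.int64)
    return LabelTable(scheme, class_names, slide_ids, y)


def evaluate_labeler(corpus, lexicon: ConceptLexicon, class_names) -> dict:
    """Weighted F1 of extracted vs ground-truth concepts, per source and cumulative."""
    if not corpus:
        raise ValueError("empty corpus")
    extracted = labels_from_reports(corpus, lexicon, class_names)
    truth = _truth_table(corpus, lexicon.scheme, class_names)
    scores = {CUMULATIVE: weighted_f1(extracted, truth)}
    sources = sorted({rec.source for rec in corpus})
    for src in sources:
        ids = [rec.slide_id for rec in corpus if rec.source == src]
        keep = set(ids)
        sub_idx = [i for i, s in enumerate(truth.slide_ids) if s in keep]
        sub_truth = LabelTable(truth.scheme, class_names, ids, truth.y[sub_idx])
        sub_idx_e = [i for i, s in enumerate(extracted.slide_ids) if s in keep]
        sub_pred = LabelTable(truth.scheme, class_names, ids, extracted.y[sub_idx_e])
        scores[src] = weighted_f1(sub_pred, sub_truth)
    return scores


@dataclass(frozen=True)
class CostModel:
    """Per-report annotation times (seconds) for the automatic and manual route."""

    auto_seconds_per_report: float
    manual_seconds_per_report: float
    n_reports: int

    def __post_init__(self):
        if self.auto_seconds_per_report <= 0 or self.manual_seconds_per_report <= 0:
            raise ValueError("annotation times must be positive")
        if self.n_reports <= 0:
            raise ValueError("n_reports must be positive")


def annotation_cost(model: CostModel) -> tuple:
    """Total annotation minutes for each route and the percent of time saved.

    ``percent_saved`` is independent of the archive size and reported to two
    decimals, e.g. 0.03 s automatic vs 10 s manual on 10,000 reports gives
    (5.0 min, 1666.666667 min, 99.70%).
    """
    auto_minutes = model.auto_seconds_per_report * model.n_reports / 60.0
    manual_minutes = model.manual_seconds_per_report * model.n_reports / 60.0
    percent_saved = round(
        (1.0 - model.auto_seconds_per_report / model.manual_seconds_per_report) * 100.0, 2
    )
    return auto_minutes, manual_minutes, percent_saved
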