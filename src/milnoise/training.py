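"""Training loop for the MIL aggregators.

Bags are batched by padding + masking and optimized with Adam under the
scheme's loss: binary cross-entropy (binary), softmax cross-entropy
(multiclass), or the per-class binary cross-entropy mean (multilabel).
Attention families add ``instance_loss_weight`` times the top-k/bottom-k
instance clustering loss. Training is patient-grouped-fold aware: each fold's
model is fitted on the other folds' slides and validated on its own.

Decision rules at prediction time: binary/multiclass take the argmax
(binary: sigmoid threshold 0.5 on the single logit), multilabel thresholds
each sigmoid score at 0.5 and maps an all-zero prediction to the normal
class.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .autodiff import Adam, Tensor
from .labels import LabelTable
from .models import BagPrediction, ModelSpec, build_model, instance_clustering_loss, pad_bags


@dataclass
class TrainConfig:
    """Optimizer and schedule settings (defaults follow the selected grid values)."""

    batch_size: int = 4
    learning_rate: float = 1e-4
    weight_decay: float = 1e-4
    epochs: int = 15
    hidden_nodes: int | None = None  # overrides ModelSpec.hidden_nodes when set
    seed: int = 0


def batch_loss(scores: Tensor, y_batch: np.ndarray, scheme: str) -> Tensor:
    """Scheme-appropriate classification loss averaged over the batch."""
    if scheme == "binary":
        z = scores.reshape(scores.shape[0])
        return (z.softplus() - z * y_batch).mean()
    if scheme == "multiclass":
        onehot = np.eye(scores.shape[1])[y_batch]
        lse = scores.logsumexp(axis=1)
        z_y = (scores * onehot).sum(axis=1)
        return (lse - z_y).mean()
    if scheme == "multilabel":
        return (scores.softplus() - scores * y_batch).mean()
    raise ValueError(f"unknown scheme {scheme!r}")


def decide(scores: np.ndarray, scheme: str, normal_class: int = -1) -> np.ndarray:
    """Apply the scheme's decision rule to raw scores (logits)."""
    if scheme == "binary":
        return (scores.reshape(-1) > 0).astype(np.int64)
    if scheme == "multiclass":
        return scores.argmax(axis=1)
    pred = (scores > 0).astype(np.int64)
    empty = pred.sum(axis=1) == 0
    pred[empty, normal_class % scores.shape[1]] = 1
    return pred


def _forward(model, batch, mask):
    """Uniform forward over families: (scores, attention, hidden, inst_logits)."""
    if hasattr(model, "instance_head"):
        return model.forward(batch, mask)
    scores, attn = model.forward(batch, mask)
    return scores, attn, None, None


def _branch_attention(attention, y_batch, scheme) -> np.ndarray:
    """Attention of the bag's class branch, for instance pseudo-labeling."""
    attn = attention.data if isinstance(attention, Tensor) else attention
    if attn.shape[1] == 1:
        return attn[:, 0, :]
    if scheme == "multilabel":
        branch = np.argmax(y_batch, axis=1)
    else:
        branch = np.asarray(y_batch)
    return attn[np.arange(attn.shape[0]), branch, :]


def _total_loss(model, spec, batch, mask, y_batch):
    scores, attention, _, inst_logits = _forward(model, batch, mask)
    loss = batch_loss(scores, y_batch, spec.scheme)
    if inst_logits is not None and spec.instance_loss_weight > 0:
        sel = _branch_attention(attention, y_batch, spec.scheme)
        loss = loss + spec.instance_loss_weight * instance_clustering_loss(
            sel, inst_logits, mask, spec.topk
        )
    return loss


def fit(model, spec: ModelSpec, bags, y: np.ndarray, tcfg: TrainConfig, seed: int):
    """Optimize the model in place over the given bags; returns the model."""
    optimizer = Adam(
        model.params(), lr=tcfg.learning_rate, weight_decay=tcfg.weight_decay
    )
    rng = np.random.default_rng(seed)
    features = [b.features for b in bags]
    n = len(bags)
    for _ in range(tcfg.epochs):
        order = rng.permutation(n)
        for start in range(0, n, tcfg.batch_size):
            idx = order[start : start + tcfg.batch_size]
            batch, mask = pad_bags([features[i] for i in idx])
            loss = _total_loss(model, spec, batch, mask, y[idx])
            optimizer.zero_grad()
            loss.backward()
            optimizer.step()
    return model


def evaluate_loss(model, spec: ModelSpec, bags, y: np.ndarray, batch_size: int = 32) -> float:
    total, count = 0.0, 0
    for start in range(0, len(bags), batch_size):
        chunk = bags[start : start + batch_size]
        batch, mask = pad_bags([b.features for b in chunk])
        loss = _total_loss(model, spec, batch, mask, y[start : start + batch_size])
        total += float(loss.data) * len(chunk)
        count += len(chunk)
    return total / max(count, 1)


def predict_bags(model, spec: ModelSpec, bags, batch_size: int = 32):
    """Score bags and apply the scheme's decision rule."""
    out = []
    for start in range(0, len(bags), batch_size):
        chunk = bags[start : start + batch_size]
        batch, mask = pad_bags([b.features for b in chunk])
        scores, attention, _, _ = _forward(model, batch, mask)
        raw = scores.data
        labels = decide(raw, spec.scheme)
        attn = attention.data if isinstance(attention, Tensor) else attention
        for i, bag in enumerate(chunk):
            n = bag.n_instances
            a = attn[i, ..., :n]
            out.append(
                BagPrediction(
                    slide_id=bag.slide_id,
                    scores=raw[i].copy(),
                    attention=a.copy(),
                    predicted_label=labels[i].copy() if labels.ndim > 1 else int(labels[i]),
                )
            )
    return out


def predictions_to_table(predictions, labels_like: LabelTable) -> LabelTable:
    """Assemble bag predictions into a label table matching a reference table."""
    ids = tuple(p.slide_id for p in predictions)
    if labels_like.scheme == "multilabel":
        y = np.stack([p.predicted_label for p in predictions])
    else:
        y = np.array([p.predicted_label for p in predictions], dtype=np.int64)
    return LabelTable(labels_like.scheme, labels_like.class_names, ids, y)


def train_model(cohort, labels: LabelTable, spec: ModelSpec, tcfg: TrainConfig, folds):
    """Fit one model per cross-validation fold.

    Each fold's model trains on the other folds' slides and records its
    validation loss on the held-out fold. Returns ``{fold: {"model", "val_loss",
    "val_slide_ids"}}``, reproducible for fixed seeds on one thread.
    """
    if labels.scheme != spec.scheme:
        raise ValueError(f"label scheme {labels.scheme!r} does not match spec {spec.scheme!r}")
    if spec.n_classes != labels.n_classes:
        raise ValueError("spec.n_classes does not match the label table")
    if not set(labels.slide_ids) <= {b.slide_id for b in cohort.bags}:
        raise ValueError("labels refer to slides missing from the cohort")
    if tcfg.hidden_nodes is not None:
        spec = replace(spec, hidden_nodes=tcfg.hidden_nodes)

    slide_fold = {
        b.slide_id: folds.assignment[b.patient_id] for b in cohort.bags
    }
    y_all = labels.aligned_y([b.slide_id for b in cohort.bags])
    bags = cohort.bags
    results = {}
    child_seeds = np.random.SeedSequence(tcfg.seed).generate_state(2 * folds.k) % (2**31)
    for fold in range(folds.k):
        train_idx = [i for i, b in enumerate(bags) if slide_fold[b.slide_id] != fold]
        val_idx = [i for i, b in enumerate(bags) if slide_fold[b.slide_id] == fold]
        model = build_model(spec, seed=int(child_seeds[2 * fold]))
        fit(
            model,
            spec,
            [bags[i] for i in train_idx],
            y_all[train_idx],
            tcfg,
            seed=int(child_seeds[2 * fold + 1]),
        )
        val_loss = (
            evaluate_loss(model, spec, [bags[i] for i in val_idx], y_all[val_idx])
            if val_idx
            else float("nan")
        )
        results[fold] = {
            "model": model,
            "val_loss": val_loss,
            "val_slide_ids": [bags[i].slide_id for i in val_idx],
        }
    return results
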