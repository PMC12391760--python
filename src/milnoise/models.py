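"""Desk-scale MIL aggregators for bags of precomputed instance features.

Three families, mirroring the architectures commonly benchmarked for
weakly supervised slide classification:

``attention_sb`` / ``attention_mb``
    Gated-attention MIL: instances are projected to a hidden space, a gated
    attention module (tanh gate x sigmoid gate) yields normalized instance
    weights, and the bag embedding is the attention-weighted sum. The SB
    variant shares one attention branch across classes; MB gives every class
    its own branch and scoring head. An auxiliary instance head supports a
    top-k/bottom-k clustering loss (a binary cross-entropy stand-in for the
    smooth-SVM instance loss of the original design).
``transformer_mil``
    Instances as a token sequence with a prepended class token, pre-norm
    self-attention blocks with exact (not approximated) attention, optional
    sinusoidal encodings of instance grid coordinates.
``vit``
    The same transformer trunk with learned positional embeddings, standing
    in for a ViT aggregator over patch tokens.

All models consume bags padded to a common length with masked attention
(padded instances get -inf attention logits), are permutation-invariant when
no positional information is used, and report a normalized per-instance
attention vector alongside the class scores.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autodiff import Adam, Parameter, Tensor, concat

FAMILIES = ("attention_sb", "attention_mb", "transformer_mil", "vit")
_NEG = -1e9  # attention logit for padded instances


@dataclass
class ModelSpec:
    """Architecture choice and sizes for one aggregator."""

    family: str
    embed_dim: int = 128
    n_classes: int = 2
    scheme: str = "multiclass"
    hidden_nodes: int = 128
    n_layers: int | None = None  # default 2 for transformer_mil, 4 for vit
    n_heads: int = 4
    use_positional: bool | None = None
    instance_loss_weight: float = 0.3
    topk: int = 8
    max_instances: int = 512  # learned-position table size for the vit family

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}; expected one of {FAMILIES}")
        if self.n_layers is None:
            self.n_layers = {"transformer_mil": 2, "vit": 4}.get(self.family, 0)
        if self.use_positional is None:
            self.use_positional = self.family in ("transformer_mil", "vit")
        if self.family == "attention_sb" and self.scheme == "multiclass" and self.n_classes < 2:
            raise ValueError("multiclass needs n_classes >= 2")

    @property
    def n_outputs(self) -> int:
        return 1 if self.scheme == "binary" else self.n_classes


@dataclass
class BagPrediction:
    slide_id: str
    scores: np.ndarray  # per-class real scores (logits)
    attention: np.ndarray  # per-instance weights; (branches, n) for MB
    predicted_label: object


def _linear_init(rng, n_in, n_out):
    return Parameter(rng.standard_normal((n_in, n_out)) / np.sqrt(n_in))


class Linear:
    def __init__(self, rng, n_in, n_out, bias=True):
        self.W = _linear_init(rng, n_in, n_out)
        self.b = Parameter(np.zeros(n_out)) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        out = x @ self.W
        return out + self.b if self.b is not None else out

    def params(self):
        return [self.W] + ([self.b] if self.b is not None else [])


class LayerNorm:
    def __init__(self, dim):
        self.g = Parameter(np.ones(dim))
        self.b = Parameter(np.zeros(dim))

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        centered = x - mu
        var = (centered * centered).mean(axis=-1, keepdims=True)
        return centered / (var + 1e-5) ** 0.5 * self.g + self.b

    def params(self):
        return [self.g, self.b]


def pad_bags(features_list):
    """Stack variable-length bags into (B, Nmax, D) plus a validity mask."""
    if not features_list:
        raise ValueError("need at least one bag")
    if any(f.shape[0] < 1 for f in features_list):
        raise ValueError("bags must contain at least one instance")
    B = len(features_list)
    n_max = max(f.shape[0] for f in features_list)
    D = features_list[0].shape[1]
    batch = np.zeros((B, n_max, D))
    mask = np.zeros((B, n_max), dtype=bool)
    for i, f in enumerate(features_list):
        batch[i, : f.shape[0]] = f
        mask[i, : f.shape[0]] = True
    return batch, mask


def _masked_softmax(logits: Tensor, mask: np.ndarray, axis: int = -1) -> Tensor:
    bias = np.where(mask, 0.0, _NEG)
    return (logits + bias).softmax(axis=axis)


class AttentionMIL:
    """Gated-attention MIL with single (SB) or per-class (MB) branches."""

    def __init__(self, spec: ModelSpec, seed: int = 0):
        if spec.family not in ("attention_sb", "attention_mb"):
            raise ValueError("AttentionMIL requires an attention family spec")
        self.spec = spec
        rng = np.random.default_rng(seed)
        H = spec.hidden_nodes
        self.proj = Linear(rng, spec.embed_dim, H)
        # MB keeps one attention branch per output logit; for the binary
        # scheme (a single logit) it therefore coincides with SB
        self.n_branches = spec.n_outputs if spec.family == "attention_mb" else 1
        self.branches = []
        for c in range(self.n_branches):
            branch = {
                "V": Linear(rng, H, H),
                "U": Linear(rng, H, H),
                "w": Linear(rng, H, 1, bias=False),
                "head": Linear(rng, H, spec.n_outputs if self.n_branches == 1 else 1),
            }
            self.branches.append(branch)
        self.instance_head = Linear(rng, H, 1)

    def params(self):
        ps = self.proj.params() + self.instance_head.params()
        for br in self.branches:
            for layer in br.values():
                ps += layer.params()
        return ps

    def forward(self, batch: np.ndarray, mask: np.ndarray):
        """Returns (scores, attention, hidden, instance_logits).

        scores: (B, n_outputs); attention: (B, branches, Nmax) normalized
        over valid instances; hidden: (B, Nmax, H) projected instances.
        """
        x = Tensor(batch)
        h = self.proj(x).relu()
        branch_scores, branch_attn = [], []
        for br in self.branches:
            a = br["V"](h).tanh()
            g = br["U"](h).sigmoid()
            logits = br["w"](a * g).reshape(batch.shape[0], batch.shape[1])
            attn = _masked_softmax(logits, mask, axis=-1)  # (B, N)
            bag = (attn.reshape(batch.shape[0], 1, batch.shape[1]) @ h).reshape(
                batch.shape[0], -1
            )
            branch_scores.append(br["head"](bag))
            branch_attn.append(attn.reshape(batch.shape[0], 1, batch.shape[1]))
        scores = branch_scores[0] if self.n_branches == 1 else concat(branch_scores, axis=1)
        attention = branch_attn[0] if self.n_branches == 1 else concat(branch_attn, axis=1)
        inst_logits = self.instance_head(h).reshape(batch.shape[0], batch.shape[1])
        return scores, attention, h, inst_logits


def _sincos_positions(coords: np.ndarray, dim: int) -> np.ndarray:
    """Fixed sinusoidal encoding of (row, col) grid coordinates."""
    half = dim // 2
    quarter = max(half // 2, 1)
    freqs = 1.0 / (10000 ** (np.arange(quarter) / quarter))
    enc = np.zeros((coords.shape[0], dim))
    for axis in range(2):
        angle = coords[:, axis : axis + 1] * freqs
        start = axis * half
        enc[:, start : start + quarter] = np.sin(angle)
        enc[:, start + quarter : start + 2 * quarter] = np.cos(angle)
    return enc


class TransformerAggregator:
    """Pre-norm transformer over instance tokens with a class token."""

    def __init__(self, spec: ModelSpec, seed: int = 0):
        if spec.family not in ("transformer_mil", "vit"):
            raise ValueError("TransformerAggregator requires a transformer family spec")
        self.spec = spec
        rng = np.random.default_rng(seed)
        H = spec.hidden_nodes
        if H % spec.n_heads:
            raise ValueError("hidden_nodes must be divisible by n_heads")
        self.embed = Linear(rng, spec.embed_dim, H)
        self.cls_token = Parameter(rng.standard_normal((1, 1, H)) * 0.02)
        self.pos_table = None
        if spec.family == "vit" and spec.use_positional:
            self.pos_table = Parameter(rng.standard_normal((spec.max_instances + 1, H)) * 0.02)
        self.blocks = []
        for _ in range(spec.n_layers):
            self.blocks.append(
                {
                    "ln1": LayerNorm(H),
                    "qkv": Linear(rng, H, 3 * H),
                    "proj": Linear(rng, H, H),
                    "ln2": LayerNorm(H),
                    "fc1": Linear(rng, H, 2 * H),
                    "fc2": Linear(rng, 2 * H, H),
                }
            )
        self.ln_out = LayerNorm(H)
        self.head = Linear(rng, H, spec.n_outputs)

    def params(self):
        ps = self.embed.params() + [self.cls_token] + self.ln_out.params() + self.head.params()
        if self.pos_table is not None:
            ps.append(self.pos_table)
        for blk in self.blocks:
            for layer in blk.values():
                ps += layer.params()
        return ps

    def _attend(self, blk, x: Tensor, key_mask: np.ndarray):
        B, N = key_mask.shape
        H = self.spec.hidden_nodes
        nh = self.spec.n_heads
        hd = H // nh
        qkv = blk["qkv"](blk["ln1"](x))  # (B, N, 3H)
        qkv = qkv.reshape(B, N, 3, nh, hd).transpose((2, 0, 3, 1, 4))
        q, k, v = qkv[0], qkv[1], qkv[2]  # (B, nh, N, hd)
        logits = (q @ k.transpose((0, 1, 3, 2))) * (1.0 / np.sqrt(hd))
        bias = np.where(key_mask, 0.0, _NEG)[:, None, None, :]
        attn = (logits + bias).softmax(axis=-1)  # (B, nh, N, N)
        out = (attn @ v).transpose((0, 2, 1, 3)).reshape(B, N, H)
        return blk["proj"](out), attn

    def forward(self, batch: np.ndarray, mask: np.ndarray, coords=None):
        """Returns (scores, attention) where attention is the class-token
        attention of the last layer, head-averaged and renormalized over the
        real instances."""
        B, N, _ = batch.shape
        x = self.embed(Tensor(batch))
        if self.spec.family == "transformer_mil" and self.spec.use_positional and coords is not None:
            pos, _ = pad_bags([_sincos_positions(c, self.spec.hidden_nodes) for c in coords])
            x = x + pos
        if self.pos_table is not None:
            if N > self.spec.max_instances:
                raise ValueError("bag exceeds the learned-position table")
            x = x + self.pos_table[1 : N + 1].reshape(1, N, -1)
        cls = self.cls_token + np.zeros((B, 1, x.shape[-1]))
        if self.pos_table is not None:
            cls = cls + self.pos_table[0:1].reshape(1, 1, -1)
        x = concat([cls, x], axis=1)
        key_mask = np.concatenate([np.ones((B, 1), dtype=bool), mask], axis=1)
        attn_last = None
        for blk in self.blocks:
            sa, attn_last = self._attend(blk, x, key_mask)
            x = x + sa
            x = x + blk["fc2"](blk["fc1"](blk["ln2"](x)).relu())
        cls_out = self.ln_out(x[:, 0, :])
        scores = self.head(cls_out)
        # class-token attention over instance tokens, averaged over heads
        cls_attn = attn_last.data[:, :, 0, 1:].mean(axis=1) * mask
        cls_attn = cls_attn / np.maximum(cls_attn.sum(axis=1, keepdims=True), 1e-12)
        return scores, cls_attn


def build_model(spec: ModelSpec, seed: int = 0):
    if spec.family in ("attention_sb", "attention_mb"):
        return AttentionMIL(spec, seed=seed)
    return TransformerAggregator(spec, seed=seed)


def instance_clustering_loss(attention: np.ndarray, instance_logits: Tensor,
                             mask: np.ndarray, topk: int) -> Tensor:
    """Top-k/bottom-k instance pseudo-labeling loss for attention families.

    The ``topk`` highest-attention valid instances of each bag are
    pseudo-labeled positive, the ``topk`` lowest negative, and the mean
    binary cross-entropy of the instance head on those 2k instances is
    returned. Bags smaller than 2k clamp k to floor(n/2).
    """
    B = attention.shape[0]
    rows, cols, targets = [], [], []
    for i in range(B):
        valid = np.flatnonzero(mask[i])
        k = min(topk, len(valid) // 2)
        if k == 0:
            continue
        order = valid[np.argsort(attention[i, valid])]
        rows += [i] * (2 * k)
        cols += list(order[-k:]) + list(order[:k])
        targets += [1.0] * k + [0.0] * k
    if not rows:
        return Tensor(0.0)
    z = instance_logits[(np.array(rows), np.array(cols))]
    y = np.array(targets)
    # BCE with logits: softplus(z) - z*y
    return (z.softplus() - z * y).mean()
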