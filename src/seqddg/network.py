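"""The three-block sequence model for ΔΔG prediction.

A wild/mutant antigen-antibody pair enters as four (n, 40) feature matrices
(antibody/antigen × wild/mutant).  Three blocks process them:

* **embedding** — three 1-D convolution branches (one per kernel size), each
  a gated linear unit (half the channels gate the other half through a
  logistic sigmoid), concatenated to ``3·hidden_size`` channels and layer
  normalized;
* **attention** — multi-head self-attention per protein (scaled dot product,
  dropout, residual), then multi-head mutual attention across the two
  proteins of each complex variant (queries from one protein, keys/values
  from its partner; no residual, no dropout).  The head-averaged
  antigen→antibody map is retained for interpretability;
* **prediction** — mask-aware pooling of each protein over its length, the
  four pooled vectors concatenated (wild pair then mutant pair) and passed
  through three affine layers with rectifier nonlinearities to a scalar
  ΔΔG estimate in kcal/mol.

With ``use_attention=False`` (ablation) the pooled embeddings feed the head
directly; the head input width is unchanged because attention maps d → d.
All arithmetic runs on the package's autodiff core, so the same forward
graph serves training and evaluation.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .data_io import MutationRecord
from .encoders import FeatureMatrix, featurize

_NEG = -1e9  # additive bias excluding padded keys from softmax


@dataclass(frozen=True)
class ModelConfig:
    """Hyperparameters; ``3·hidden_size`` must be divisible by ``n_heads``
    and the last fully connected size must be 1 (the scalar output)."""

    hidden_size: int = 64
    kernel_sizes: tuple[int, int, int] = (3, 5, 7)
    n_heads: int = 4
    dropout_rate: float = 0.1
    use_attention: bool = True
    mutual_residual: bool = False
    pooling: str = "mean"  # or "max"
    fc_sizes: tuple[int, int, int] = (128, 64, 1)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.hidden_size < 1:
            raise ValueError("hidden_size must be positive")
        if len(self.kernel_sizes) != 3 or any(k < 1 or k % 2 == 0 for k in self.kernel_sizes):
            raise ValueError("kernel_sizes must be three odd positive ints")
        if (3 * self.hidden_size) % self.n_heads != 0:
            raise ValueError("3*hidden_size must be divisible by n_heads")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")
        if len(self.fc_sizes) != 3 or any(s < 1 for s in self.fc_sizes):
            raise ValueError("fc_sizes must be three positive ints")
        if self.fc_sizes[-1] != 1:
            raise ValueError("the last fully connected layer must have size 1")
        if self.pooling not in ("mean", "max"):
            raise ValueError("pooling must be 'mean' or 'max'")

    @property
    def d_model(self) -> int:
        return 3 * self.hidden_size

    @property
    def d_head(self) -> int:
        return self.d_model // self.n_heads


@dataclass
class AttentionMaps:
    """Head-averaged antigen×antibody mutual-attention maps for one pair."""

    w_ag_ab_wt: np.ndarray  # (len_ag, len_ab), rows sum to 1
    w_ag_ab_mt: np.ndarray


class Model:
    """Learned state: a :class:`ModelConfig` plus named parameter tensors."""

    FORMAT_TAG = "seqddg-ckpt-1"

    def __init__(self, config: ModelConfig):
        self.config = config
        self.params: dict[str, Tensor] = {}
        self._init_params(np.random.default_rng(config.seed))

    # -- parameters ---------------------------------------------------------

    def _add(self, name: str, shape: tuple[int, ...], rng, *, zeros: bool = False, ones: bool = False):
        if zeros:
            data = np.zeros(shape)
        elif ones:
            data = np.ones(shape)
        else:  # Glorot uniform on the last two dims
            fan_in, fan_out = (shape[-2], shape[-1]) if len(shape) >= 2 else (shape[0], shape[0])
            limit = np.sqrt(6.0 / (fan_in + fan_out))
            data = rng.uniform(-limit, limit, size=shape)
        self.params[name] = Tensor(data, requires_grad=True)

    def _init_params(self, rng) -> None:
        cfg = self.config
        h, d = cfg.hidden_size, cfg.d_model
        for k in cfg.kernel_sizes:
            self._add(f"conv{k}.w", (k, 40, 2 * h), rng)
            self._add(f"conv{k}.b", (2 * h,), rng, zeros=True)
        self._add("ln.gain", (d,), rng, ones=True)
        self._add("ln.bias", (d,), rng, zeros=True)
        if cfg.use_attention:
            for blk in ("self", "mutual"):
                for w in ("wq", "wk", "wv"):
                    self._add(f"{blk}.{w}", (d, d), rng)
            self._add("self.wo", (d, d), rng)
        widths = [4 * d, *cfg.fc_sizes]
        for i in range(3):
            self._add(f"fc{i}.w", (widths[i], widths[i + 1]), rng)
            self._add(f"fc{i}.b", (widths[i + 1],), rng, zeros=True)

    def parameters(self) -> list[Tensor]:
        return list(self.params.values())

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def shape_audit(self) -> dict[str, tuple[int, ...]]:
        """Named parameter shapes, and a finiteness check."""
        for name, p in self.params.items():
            if not np.isfinite(p.data).all():
                raise ValueError(f"non-finite values in parameter {name}")
        return {name: p.shape for name, p in self.params.items()}

    # -- persistence --------------------------------------------------------

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        if path.suffix != ".npz":
            path = path.with_suffix(".npz")
        arrays = {name: p.data for name, p in self.params.items()}
        meta = {"format": self.FORMAT_TAG, "config": asdict(self.config)}
        np.savez_compressed(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **arrays)
        return path

    @classmethod
    def load(cls, path: str | Path) -> "Model":
        with np.load(path) as archive:
            meta = json.loads(bytes(archive["__meta__"]).decode())
            if meta.get("format") != cls.FORMAT_TAG:
                raise ValueError(f"unknown checkpoint format {meta.get('format')!r}")
            cfg_dict = meta["config"]
            for key in ("kernel_sizes", "fc_sizes"):
                cfg_dict[key] = tuple(cfg_dict[key])
            model = cls(ModelConfig(**cfg_dict))
            for name in model.params:
                model.params[name].data = archive[name].astype(np.float64)
        return model


# ---------------------------------------------------------------------------
# Batching


@dataclass
class FeatureBatch:
    """Right-padded (B, N, 40) arrays + boolean masks for the four roles."""

    features: dict[str, np.ndarray]  # keys: ab_wt, ag_wt, ab_mt, ag_mt
    masks: dict[str, np.ndarray]  # (B, N) float, 1 = real residue
    record_ids: list[str] = field(default_factory=list)

    ROLES = ("ab_wt", "ag_wt", "ab_mt", "ag_mt")

    @property
    def size(self) -> int:
        return next(iter(self.features.values())).shape[0]


def _pad_stack(mats: Sequence[np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
    n_max = max(m.shape[0] for m in mats)
    out = np.zeros((len(mats), n_max, mats[0].shape[1]))
    mask = np.zeros((len(mats), n_max))
    for i, m in enumerate(mats):
        out[i, : m.shape[0]] = m
        mask[i, : m.shape[0]] = 1.0
    return out, mask


class Featurizer:
    """Caches per-sequence feature matrices; optionally serves precomputed
    PSSMs keyed by sequence, falling back to the substitution-table profile."""

    def __init__(self, pssms: dict[str, np.ndarray] | None = None, z_scale: bool = False):
        self.pssms = pssms or {}
        self.z_scale = z_scale
        self._cache: dict[str, np.ndarray] = {}

    def __call__(self, seq: str) -> np.ndarray:
        if seq not in self._cache:
            fm = featurize(seq, self.pssms.get(seq), z_scale=self.z_scale)
            self._cache[seq] = fm.values
        return self._cache[seq]


def batch_records(records: Sequence[MutationRecord], featurizer: Featurizer | None = None) -> FeatureBatch:
    """Featurize wild and mutant sequences of ``records`` into one padded batch."""
    featurizer = featurizer or Featurizer()
    seqs = {
        "ab_wt": [r.antibody_seq for r in records],
        "ag_wt": [r.antigen_seq for r in records],
        "ab_mt": [r.mutant_antibody_seq for r in records],
        "ag_mt": [r.mutant_antigen_seq for r in records],
    }
    features, masks = {}, {}
    for role, role_seqs in seqs.items():
        stacked, mask = _pad_stack([featurizer(s) for s in role_seqs])
        features[role], masks[role] = stacked, mask
    ids = [f"{r.complex_id}:{r.mutation_string}" for r in records]
    return FeatureBatch(features=features, masks=masks, record_ids=ids)


# ---------------------------------------------------------------------------
# Forward pass


def embed(model: Model, x: Tensor, mask: np.ndarray) -> Tensor:
    """Gated-convolution embedding: (B, N, 40) → (B, N, 3·hidden_size)."""
    cfg = model.config
    if x.shape[-1] != 40:
        raise ValueError(f"expected feature width 40, got {x.shape[-1]}")
    n = x.shape[1]
    if n == 0:
        raise ValueError("empty sequence batch")
    h = cfg.hidden_size
    branches = []
    for k in cfg.kernel_sizes:
        w, b = model.params[f"conv{k}.w"], model.params[f"conv{k}.b"]
        xp = ad.pad_axis(x, 1, k // 2, k // 2)
        y = None
        for offset in range(k):
            term = xp[:, offset : offset + n, :] @ w[offset]
            y = term if y is None else y + term
        y = y + b
        value, gate = y[:, :, :h], y[:, :, h:]
        branches.append(value * ad.sigmoid(gate))
    out = ad.concat(branches, axis=-1)
    # Layer normalization over channels.
    mu = out.mean(axis=-1, keepdims=True)
    var = ((out - mu) ** 2).mean(axis=-1, keepdims=True)
    out = (out - mu) * ((var + 1e-5) ** -0.5)
    out = out * model.params["ln.gain"] + model.params["ln.bias"]
    return out * Tensor(mask[:, :, None])  # zero padded positions


def _split_heads(t: Tensor, n_heads: int, d_head: int) -> Tensor:
    b, n, _ = t.shape
    return t.reshape((b, n, n_heads, d_head)).transpose((0, 2, 1, 3))


def _merge_heads(t: Tensor) -> Tensor:
    b, heads, n, dk = t.shape
    return t.transpose((0, 2, 1, 3)).reshape((b, n, heads * dk))


def _attend(
    model: Model,
    block: str,
    h_q: Tensor,
    h_kv: Tensor,
    mask_kv: np.ndarray,
) -> tuple[Tensor, Tensor]:
    """Scaled dot-product attention; returns (context, row-stochastic maps
    of shape (B, heads, N_q, N_kv))."""
    cfg = model.config
    if np.any(mask_kv.sum(axis=1) < 1):
        raise ValueError("a sequence in the batch has no unmasked positions")
    q = _split_heads(h_q @ model.params[f"{block}.wq"], cfg.n_heads, cfg.d_head)
    k = _split_heads(h_kv @ model.params[f"{block}.wk"], cfg.n_heads, cfg.d_head)
    v = _split_heads(h_kv @ model.params[f"{block}.wv"], cfg.n_heads, cfg.d_head)
    scores = (q @ k.transpose((0, 1, 3, 2))) * (1.0 / np.sqrt(cfg.d_head))
    bias = (1.0 - mask_kv)[:, None, None, :] * _NEG
    attn = ad.softmax(scores, axis=-1, bias=bias)
    return _merge_heads(attn @ v), attn


def _dropout(t: Tensor, rate: float, rng: np.random.Generator | None) -> Tensor:
    if rate <= 0 or rng is None:
        return t
    keep = (rng.random(t.shape) >= rate) / (1.0 - rate)
    return t * Tensor(keep)


def self_attention(
    model: Model,
    h: Tensor,
    mask: np.ndarray,
    *,
    training: bool = False,
    rng: np.random.Generator | None = None,
) -> Tensor:
    """Multi-head self-attention with dropout and a residual connection."""
    ctx, _ = _attend(model, "self", h, h, mask)
    ctx = ctx @ model.params["self.wo"]
    ctx = _dropout(ctx, model.config.dropout_rate, rng if training else None)
    return ctx + h


def mutual_attention(
    model: Model,
    h_q: Tensor,
    h_kv: Tensor,
    mask_kv: np.ndarray,
) -> tuple[Tensor, np.ndarray]:
    """Cross-protein attention (queries from one protein, keys/values from
    its partner); no residual and no dropout unless
    ``config.mutual_residual``.  Returns the context and the head-averaged
    attention map as a plain (B, N_q, N_kv) array."""
    ctx, attn = _attend(model, "mutual", h_q, h_kv, mask_kv)
    if model.config.mutual_residual:
        ctx = ctx + h_q
    return ctx, attn.data.mean(axis=1)


def _pool(model: Model, h: Tensor, mask: np.ndarray) -> Tensor:
    m = Tensor(mask[:, :, None])
    if model.config.pooling == "mean":
        lengths = mask.sum(axis=1, keepdims=True)
        return (h * m).sum(axis=1) * Tensor(1.0 / lengths)
    shifted = h * m + Tensor((1.0 - mask[:, :, None]) * _NEG)
    return ad.amax(shifted, axis=1)


def forward(
    model: Model,
    batch: FeatureBatch,
    *,
    training: bool = False,
    rng: np.random.Generator | None = None,
) -> tuple[Tensor, list[AttentionMaps]]:
    """Full pipeline on a batch; returns (B,) predictions and per-record
    antigen×antibody attention maps (empty list when attention is off)."""
    cfg = model.config
    emb = {role: embed(model, Tensor(batch.features[role]), batch.masks[role]) for role in batch.ROLES}
    maps: list[AttentionMaps] = []
    if cfg.use_attention:
        att = {
            role: self_attention(model, emb[role], batch.masks[role], training=training, rng=rng)
            for role in batch.ROLES
        }
        reps = {}
        raw_maps = {}
        for variant in ("wt", "mt"):
            ab, ag = att[f"ab_{variant}"], att[f"ag_{variant}"]
            ab_mask, ag_mask = batch.masks[f"ab_{variant}"], batch.masks[f"ag_{variant}"]
            reps[f"ag_{variant}"], raw_maps[variant] = mutual_attention(model, ag, ab, ab_mask)
            reps[f"ab_{variant}"], _ = mutual_attention(model, ab, ag, ag_mask)
        ab_len = batch.masks["ab_wt"].sum(axis=1).astype(int)
        ag_len = batch.masks["ag_wt"].sum(axis=1).astype(int)
        ab_len_mt = batch.masks["ab_mt"].sum(axis=1).astype(int)
        ag_len_mt = batch.masks["ag_mt"].sum(axis=1).astype(int)
        for i in range(batch.size):
            maps.append(
                AttentionMaps(
                    w_ag_ab_wt=raw_maps["wt"][i, : ag_len[i], : ab_len[i]].copy(),
                    w_ag_ab_mt=raw_maps["mt"][i, : ag_len_mt[i], : ab_len_mt[i]].copy(),
                )
            )
    else:
        reps = emb
    pooled = [_pool(model, reps[role], batch.masks[role]) for role in batch.ROLES]
    # wild pair first, mutant pair second: [ab_wt, ag_wt] ∥ [ab_mt, ag_mt]
    head_in = ad.concat([pooled[0], pooled[1], pooled[2], pooled[3]], axis=-1)
    out = head_in
    for i in range(3):
        out = out @ model.params[f"fc{i}.w"] + model.params[f"fc{i}.b"]
        if i < 2:
            out = ad.relu(out)
        if training and i < 2:
            out = _dropout(out, cfg.dropout_rate, rng)
    pred = out.reshape((batch.size,))
    if not np.isfinite(pred.data).all():
        raise FloatingPointError("non-finite prediction")
    return pred, maps


def predict_ddg(
    model: Model,
    records: Sequence[MutationRecord],
    featurizer: Featurizer | None = None,
) -> tuple[np.ndarray, list[AttentionMaps]]:
    """Evaluation-mode ΔΔG predictions (kcal/mol) for a list of records."""
    batch = batch_records(records, featurizer)
    pred, maps = forward(model, batch, training=False)
    return pred.data.copy(), maps
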