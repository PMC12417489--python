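"""Dual-encoder model and contrastive alignment loss.

The EEG side is a four-block convolution/max-pool network (temporal then
spatial convolution in the first block, batch norm, ReLU, dropout) flattened
into a 128-dimensional embedding. The text side is a pluggable encoder
satisfying a small contract. Both embeddings pass through 3-layer MLP
projection heads into a shared, L2-normalized space (64-d by default) where
an InfoNCE-style temperature-scaled softmax loss aligns matching pairs.
"""

from __future__ import annotations

import hashlib
import json
import re
import warnings
from dataclasses import dataclass, field

import numpy as np

from . import nn
from .autodiff import Tensor
from .preprocessing import WindowSet

__all__ = [
    "EEGEncoder",
    "ProjectionHead",
    "TextEncoderBase",
    "HashingTextEncoder",
    "EmbeddingTextEncoder",
    "PretrainedTransformerTextEncoder",
    "DualEncoderModel",
    "ContrastiveBatch",
    "l2_normalize",
    "cosine_similarity_matrix",
    "info_nce",
    "contrastive_loss",
    "eeg_encode",
    "text_encode",
    "project",
    "save_checkpoint",
    "load_checkpoint",
    "make_text_encoder",
]

_TOKEN_RE = re.compile(r"[a-z0-9]+")


def _tokenize(text: str) -> list[str]:
    return _TOKEN_RE.findall(text.lower())


def _stable_hash(token: str) -> int:
    return int.from_bytes(hashlib.blake2b(token.encode(), digest_size=8).digest(), "big")


# ---------------------------------------------------------------------------
# EEG encoder


class EEGEncoder(nn.Module):
    """Four conv-max-pool blocks (batch norm + dropout) -> flatten -> linear.

    Block 1 factorizes into a temporal convolution applied per electrode and a
    spatial convolution mixing electrodes; blocks 2-4 are standard 1-D
    convolutions. Kernel length 10 and pool size 3 throughout.
    """

    KERNEL = 10
    POOL = 3

    def __init__(self, n_channels: int = 21, window_length: int = 1200,
                 embedding_dim: int = 128,
                 widths: tuple[int, int, int, int, int] = (25, 25, 50, 100, 200),
                 dropout: float = 0.5, seed: int = 0):
        super().__init__()
        rng = np.random.default_rng(seed)
        self.n_channels = n_channels
        self.window_length = window_length
        self.embedding_dim = embedding_dim
        self.widths = tuple(widths)

        f_time, f_spat, f2, f3, f4 = self.widths
        self.w_time = Tensor(
            rng.normal(0, np.sqrt(2.0 / self.KERNEL),
                       (self.KERNEL, f_time)).astype(np.float32),
            requires_grad=True)
        self.w_spat = Tensor(
            rng.normal(0, np.sqrt(2.0 / (n_channels * f_time)),
                       (n_channels * f_time, f_spat)).astype(np.float32),
            requires_grad=True)
        self.b_spat = Tensor(np.zeros(f_spat, dtype=np.float32), requires_grad=True)
        self.bn1 = nn.BatchNorm(f_spat)

        self._dropout_rng = np.random.default_rng(seed + 1)
        self.drop = nn.Dropout(dropout, self._dropout_rng)
        self.conv2 = nn.Conv1d(f_spat, f2, self.KERNEL, rng)
        self.bn2 = nn.BatchNorm(f2)
        self.conv3 = nn.Conv1d(f2, f3, self.KERNEL, rng)
        self.bn3 = nn.BatchNorm(f3)
        self.conv4 = nn.Conv1d(f3, f4, self.KERNEL, rng)
        self.bn4 = nn.BatchNorm(f4)

        t = window_length
        for _ in range(4):
            t = (t - self.KERNEL + 1) // self.POOL
        if t < 1:
            raise ValueError("window too short for four conv-pool blocks")
        self.flat_dim = f4 * t
        self.fc = nn.Linear(self.flat_dim, embedding_dim, rng)

    def reseed_dropout(self, seed: int) -> None:
        self._dropout_rng = np.random.default_rng(seed)
        self.drop.rng = self._dropout_rng

    def forward(self, x: Tensor) -> Tensor:
        n, c, t = x.shape
        if (c, t) != (self.n_channels, self.window_length):
            raise ValueError(
                f"expected windows of shape (n, {self.n_channels}, "
                f"{self.window_length}), got (n, {c}, {t})")
        from .autodiff import im2col
        f_time, f_spat = self.widths[0], self.widths[1]
        # temporal (k x F_t) and spatial (C*F_t x F_s) filters compose into one
        # equivalent (C*k x F_s) convolution weight; composing first keeps the
        # heavy data path on a single GEMM
        ws = self.w_spat.reshape(c, f_time, f_spat)
        composite = (self.w_time @ ws).reshape(c * self.KERNEL, f_spat)
        patches = im2col(x, self.KERNEL, 1)                 # (n, T-9, C*k)
        t1 = patches.shape[1]
        h = patches.reshape(n * t1, c * self.KERNEL) @ composite
        h = (h.reshape(n, t1, f_spat) + self.b_spat).transpose(0, 2, 1)
        h = nn.max_pool1d(self.bn1(h).relu(), self.POOL)

        for conv, bn in ((self.conv2, self.bn2), (self.conv3, self.bn3),
                         (self.conv4, self.bn4)):
            h = self.drop(h)
            h = nn.max_pool1d(bn(conv(h)).relu(), self.POOL)

        h = h.reshape(n, self.flat_dim)
        return self.fc(h)


# ---------------------------------------------------------------------------
# text encoders


class TextEncoderBase(nn.Module):
    """Contract: ``encode(texts) -> (n, dim) Tensor``; trainable params via
    ``parameters()``; over-length inputs truncated at ``max_tokens``."""

    dim: int
    max_tokens: int = 256

    def _truncate(self, tokens: list[str], text: str) -> list[str]:
        if len(tokens) > self.max_tokens:
            warnings.warn(
                f"text of {len(tokens)} tokens truncated to {self.max_tokens}: "
                f"{text[:40]!r}...", stacklevel=3)
            return tokens[: self.max_tokens]
        return tokens

    def encode(self, texts: list[str]) -> Tensor:  # pragma: no cover - contract
        raise NotImplementedError

    def config(self) -> dict:
        raise NotImplementedError


class HashingTextEncoder(TextEncoderBase):
    """Frozen bag-of-words embedder: each token maps to a fixed Gaussian
    vector seeded by a stable hash; a text is the mean of its token vectors.

    Deterministic across processes and platforms; has no trainable
    parameters, so only the text projection head adapts during training.
    """

    kind = "hashing"

    def __init__(self, dim: int = 256, seed: int = 0, max_tokens: int = 256):
        super().__init__()
        self.dim = dim
        self.seed = seed
        self.max_tokens = max_tokens

    def _token_vector(self, token: str) -> np.ndarray:
        rng = np.random.default_rng((_stable_hash(token) ^ self.seed) % (2 ** 63))
        return rng.standard_normal(self.dim).astype(np.float32)

    def encode(self, texts: list[str]) -> Tensor:
        rows = np.zeros((len(texts), self.dim), dtype=np.float32)
        for i, text in enumerate(texts):
            tokens = self._truncate(_tokenize(text), text)
            if tokens:
                rows[i] = np.mean([self._token_vector(t) for t in tokens], axis=0)
        return Tensor(rows)

    def config(self) -> dict:
        return {"kind": self.kind, "dim": self.dim, "seed": self.seed,
                "max_tokens": self.max_tokens}


class EmbeddingTextEncoder(TextEncoderBase):
    """Trainable hashed-vocabulary embedding table averaged over tokens."""

    kind = "embedding"

    def __init__(self, dim: int = 64, vocab_size: int = 4096, seed: int = 0,
                 max_tokens: int = 256):
        super().__init__()
        self.dim = dim
        self.vocab_size = vocab_size
        self.seed = seed
        self.max_tokens = max_tokens
        rng = np.random.default_rng(seed)
        # last row is padding; masked out of every average
        self.table = Tensor(
            rng.normal(0, 0.1, (vocab_size + 1, dim)).astype(np.float32),
            requires_grad=True)

    def _ids(self, text: str) -> list[int]:
        tokens = self._truncate(_tokenize(text), text)
        return [_stable_hash(t) % self.vocab_size for t in tokens]

    def encode(self, texts: list[str]) -> Tensor:
        ids = [self._ids(t) for t in texts]
        n = len(texts)
        width = max((len(r) for r in ids), default=1) or 1
        index = np.full((n, width), self.vocab_size, dtype=np.int64)
        mask = np.zeros((n, width, 1), dtype=np.float32)
        counts = np.ones((n, 1), dtype=np.float32)
        for i, row in enumerate(ids):
            index[i, : len(row)] = row
            mask[i, : len(row), 0] = 1.0
            counts[i, 0] = max(len(row), 1)
        rows = self.table[index]                       # (n, width, dim)
        summed = (rows * Tensor(mask)).sum(axis=1)     # (n, dim)
        return summed * Tensor(1.0 / counts)

    def config(self) -> dict:
        return {"kind": self.kind, "dim": self.dim, "vocab_size": self.vocab_size,
                "seed": self.seed, "max_tokens": self.max_tokens}


class PretrainedTransformerTextEncoder(TextEncoderBase):
    """Adapter for BERT-family checkpoints via ``transformers`` (optional).

    Embeddings are mean-pooled final hidden states, returned as constants
    (fine-tuning the checkpoint is out of scope here; the projection head
    remains the trainable text-side component).
    """

    kind = "transformer"

    def __init__(self, model_name: str = "bert-base-uncased", max_tokens: int = 256):
        super().__init__()
        try:
            import torch  # noqa: F401
            from transformers import AutoModel, AutoTokenizer
        except ImportError as exc:  # pragma: no cover - optional dependency
            raise ImportError(
                "PretrainedTransformerTextEncoder requires the optional "
                "'torch' and 'transformers' packages") from exc
        self.model_name = model_name
        self.max_tokens = max_tokens
        self._tokenizer = AutoTokenizer.from_pretrained(model_name)
        self._model = AutoModel.from_pretrained(model_name).eval()
        self.dim = self._model.config.hidden_size

    def encode(self, texts: list[str]) -> Tensor:  # pragma: no cover - optional
        import torch
        batch = self._tokenizer(texts, return_tensors="pt", padding=True,
                                truncation=True, max_length=self.max_tokens)
        with torch.no_grad():
            hidden = self._model(**batch).last_hidden_state
        mask = batch["attention_mask"].unsqueeze(-1)
        pooled = (hidden * mask).sum(1) / mask.sum(1).clamp(min=1)
        return Tensor(pooled.numpy().astype(np.float32))

    def config(self) -> dict:
        return {"kind": self.kind, "model_name": self.model_name,
                "max_tokens": self.max_tokens}


_TEXT_ENCODERS = {
    "hashing": HashingTextEncoder,
    "embedding": EmbeddingTextEncoder,
    "transformer": PretrainedTransformerTextEncoder,
}


def make_text_encoder(config: dict) -> TextEncoderBase:
    config = dict(config)
    kind = config.pop("kind")
    return _TEXT_ENCODERS[kind](**config)


# ---------------------------------------------------------------------------
# projection + similarity + loss


class ProjectionHead(nn.Module):
    """Three fully-connected layers with ReLU activations; final width is the
    shared-space dimension."""

    def __init__(self, in_dim: int, out_dim: int = 64, hidden_dim: int | None = None,
                 seed: int = 0):
        super().__init__()
        hidden_dim = hidden_dim or max(in_dim, out_dim)
        rng = np.random.default_rng(seed)
        self.fc1 = nn.Linear(in_dim, hidden_dim, rng)
        self.fc2 = nn.Linear(hidden_dim, hidden_dim, rng)
        self.fc3 = nn.Linear(hidden_dim, out_dim, rng)

    def forward(self, x: Tensor) -> Tensor:
        return self.fc3(self.fc2(self.fc1(x).relu()).relu())


def l2_normalize(x: Tensor, warn_on_zero: bool = True) -> Tensor:
    """Row-normalize to unit L2 norm; all-zero rows map to zero with a warning."""
    sq = (x * x).sum(axis=-1, keepdims=True)
    zero_rows = sq.data <= 0.0
    if warn_on_zero and zero_rows.any():
        warnings.warn("zero-norm projection row(s) mapped to the zero vector",
                      stacklevel=2)
    return x * (sq + 1e-24) ** -0.5


def project(emb: Tensor | np.ndarray, head: ProjectionHead,
            normalize: bool = True) -> Tensor:
    emb = emb if isinstance(emb, Tensor) else Tensor(np.asarray(emb, dtype=np.float32))
    out = head(emb)
    return l2_normalize(out) if normalize else out


def cosine_similarity_matrix(x: Tensor | np.ndarray, y: Tensor | np.ndarray) -> Tensor:
    x = x if isinstance(x, Tensor) else Tensor(np.asarray(x))
    y = y if isinstance(y, Tensor) else Tensor(np.asarray(y))
    xn = l2_normalize(x, warn_on_zero=False)
    yn = l2_normalize(y, warn_on_zero=False)
    return xn @ yn.transpose(1, 0)


@dataclass
class ContrastiveBatch:
    """Paired projections with their similarity matrix and temperature."""

    x: np.ndarray                 # (n, d) EEG projections
    y: np.ndarray                 # (n, d) text projections
    tau: float = 1.0
    sim: np.ndarray = field(default=None)

    def __post_init__(self):
        self.x = np.asarray(self.x, dtype=np.float64)
        self.y = np.asarray(self.y, dtype=np.float64)
        if self.tau <= 0:
            raise ValueError("temperature must be positive")
        if self.x.shape != self.y.shape:
            raise ValueError("x and y must have matching shapes")
        if self.sim is None:
            self.sim = cosine_similarity_matrix(self.x, self.y).data


def info_nce(sim: Tensor | np.ndarray, tau: float | Tensor = 1.0,
             symmetric: bool = True) -> Tensor:
    """Temperature-scaled softmax alignment loss over a similarity matrix.

    One direction is the mean over rows i of ``-log softmax(sim[i]/tau)[i]``;
    the symmetric form averages the row-wise and column-wise directions.
    """
    sim = sim if isinstance(sim, Tensor) else Tensor(np.asarray(sim, dtype=np.float64))
    n, m = sim.shape
    if n != m:
        raise ValueError("similarity matrix must be square")
    if n < 2:
        raise ValueError("contrastive loss needs at least 2 pairs (no negatives)")
    tau_val = float(tau.data.reshape(-1)[0]) if isinstance(tau, Tensor) else float(tau)
    if tau_val <= 0:
        raise ValueError("temperature must be positive")
    z = sim * (tau ** -1.0 if isinstance(tau, Tensor) else 1.0 / tau)

    def direction(zmat: Tensor) -> Tensor:
        const_max = Tensor(zmat.data.max(axis=1, keepdims=True))  # detached
        lse = (zmat - const_max).exp().sum(axis=1).log() + const_max.reshape(n)
        idx = np.arange(n)
        diag = zmat[idx, idx]
        return (lse - diag).mean()

    loss = direction(z)
    if symmetric:
        loss = (loss + direction(z.transpose(1, 0))) * 0.5
    return loss


def contrastive_loss(batch: ContrastiveBatch, symmetric: bool = True) -> float:
    """Scalar loss for a prepared batch (non-differentiable convenience form)."""
    return float(info_nce(batch.sim, batch.tau, symmetric=symmetric).data)


# ---------------------------------------------------------------------------
# full model


class DualEncoderModel(nn.Module):
    """EEG encoder + text encoder + projection heads + learnable temperature."""

    def __init__(self, text_encoder: TextEncoderBase, n_channels: int = 21,
                 window_length: int = 1200, embedding_dim: int = 128,
                 projection_dim: int = 64, head_hidden_dim: int = 128,
                 widths: tuple[int, int, int, int, int] = (25, 25, 50, 100, 200),
                 dropout: float = 0.5, temperature_init: float = 0.07,
                 symmetric_loss: bool = True, seed: int = 0):
        super().__init__()
        self.text_encoder = text_encoder
        self.projection_dim = projection_dim
        self.symmetric_loss = symmetric_loss
        self._init_kwargs = {
            "n_channels": n_channels, "window_length": window_length,
            "embedding_dim": embedding_dim, "projection_dim": projection_dim,
            "head_hidden_dim": head_hidden_dim, "widths": list(widths),
            "dropout": dropout, "temperature_init": temperature_init,
            "symmetric_loss": symmetric_loss, "seed": seed,
        }
        self.eeg_encoder = EEGEncoder(n_channels, window_length, embedding_dim,
                                      widths, dropout, seed=seed)
        self.eeg_head = ProjectionHead(embedding_dim, projection_dim,
                                       head_hidden_dim, seed=seed + 10)
        self.text_head = ProjectionHead(text_encoder.dim, projection_dim,
                                        head_hidden_dim, seed=seed + 20)
        self.log_tau = Tensor(np.array([np.log(temperature_init)], dtype=np.float32),
                              requires_grad=True)

    @property
    def tau(self) -> float:
        return float(np.clip(np.exp(self.log_tau.data[0]), 1e-3, 100.0))

    def tau_tensor(self) -> Tensor:
        # clamp via straight-through: clip the stored value, then exponentiate
        self.log_tau.data = np.clip(self.log_tau.data, np.log(1e-3), np.log(100.0))
        return self.log_tau.exp()

    def encode_eeg(self, windows: np.ndarray | Tensor, project_out: bool = True) -> Tensor:
        x = windows if isinstance(windows, Tensor) else Tensor(
            np.asarray(windows, dtype=np.float32))
        emb = self.eeg_encoder(x)
        if not project_out:
            return emb
        return l2_normalize(self.eeg_head(emb), warn_on_zero=False)

    def encode_text(self, texts: list[str], project_out: bool = True) -> Tensor:
        emb = self.text_encoder.encode(texts)
        if not project_out:
            return emb
        return l2_normalize(self.text_head(emb), warn_on_zero=False)

    def batch_loss(self, windows: np.ndarray, texts: list[str]) -> Tensor:
        x = self.encode_eeg(windows)
        y = self.encode_text(texts)
        sim = x @ y.transpose(1, 0)
        return info_nce(sim, self.tau_tensor(), symmetric=self.symmetric_loss)


# ---------------------------------------------------------------------------
# spec-surface convenience ops


def eeg_encode(windows: WindowSet | np.ndarray, model: DualEncoderModel) -> np.ndarray:
    """Inference-mode (n, embedding_dim) embedding of a window set."""
    arr = windows.windows if isinstance(windows, WindowSet) else np.asarray(windows)
    was_training = model.training
    model.eval()
    try:
        out = model.encode_eeg(arr.astype(np.float32), project_out=False).data
    finally:
        model.train(was_training)
    return out


def text_encode(texts: list[str], encoder: TextEncoderBase) -> np.ndarray:
    """Inference-mode (n, D_t) embedding, one row per input string."""
    if not texts:
        return np.zeros((0, encoder.dim), dtype=np.float32)
    was_training = encoder.training
    encoder.eval()
    try:
        return encoder.encode(list(texts)).data
    finally:
        encoder.train(was_training)


# ---------------------------------------------------------------------------
# checkpoints

CHECKPOINT_VERSION = 1


def save_checkpoint(model: DualEncoderModel, path, extra: dict | None = None,
                    montage: tuple[str, ...] | None = None,
                    preprocessing: dict | None = None) -> None:
    """Write weights + architecture + text-encoder config to an ``.npz``.

    ``montage`` and ``preprocessing`` record the acquisition-side constants a
    checkpoint depends on (channel order, crop/clip/resample/scale/window
    settings) so a consumer can verify compatibility.
    """
    from .preprocessing import DEFAULT_MONTAGE, PreprocessConfig
    if preprocessing is None:
        cfg = PreprocessConfig()
        preprocessing = {
            "crop_start_s": cfg.crop_start_s, "crop_duration_s": cfg.crop_duration_s,
            "clip_uv": cfg.clip_uv, "target_rate": cfg.target_rate,
            "divisor": cfg.divisor, "window_length": cfg.window_length,
            "window_stride": cfg.window_stride,
        }
    meta = {
        "version": CHECKPOINT_VERSION,
        "model": model._init_kwargs,
        "text_encoder": model.text_encoder.config(),
        "montage": list(montage if montage is not None else DEFAULT_MONTAGE),
        "preprocessing": preprocessing,
        "extra": extra or {},
    }
    arrays = {f"param::{k}": v for k, v in model.state_dict().items()}
    np.savez(path, __meta__=np.frombuffer(
        json.dumps(meta).encode(), dtype=np.uint8), **arrays)


def load_checkpoint(path) -> tuple[DualEncoderModel, dict]:
    with np.load(path, allow_pickle=False) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        state = {k[len("param::"):]: data[k] for k in data.files
                 if k.startswith("param::")}
    if meta["version"] != CHECKPOINT_VERSION:
        raise ValueError(f"unsupported checkpoint version {meta['version']}")
    text_encoder = make_text_encoder(meta["text_encoder"])
    kwargs = dict(meta["model"])
    kwargs["widths"] = tuple(kwargs["widths"])
    model = DualEncoderModel(text_encoder, **kwargs)
    model.load_state_dict(state)
    return model, meta.get("extra", {})
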