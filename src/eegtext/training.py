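"""Contrastive training loop pairing EEG windows with their recording's report.

Every window of a recording is paired with the section-selected text of that
recording. By default a batch holds at most one window per recording so
in-batch negatives never share a report text. The optimizer is Adam with two
parameter groups: the main group (EEG encoder, both projection heads,
temperature) at the configured learning rate, and the text-encoder group at
``lr * text_lr_ratio`` — the ratio throttles adaptation of the pretrained
text encoder only, fresh projection heads always train at the full rate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np

from .models import DualEncoderModel, TextEncoderBase, make_text_encoder
from .nn import Adam
from .nn import recalibrate_batchnorm as nn_recalibrate
from .preprocessing import WindowSet
from .text_corpus import ClinicalReport, parse_report, select_sections

logger = logging.getLogger(__name__)

__all__ = ["TrainConfig", "PairedDataset", "make_pairs", "train", "build_model"]


@dataclass
class TrainConfig:
    lr: float = 5e-3
    weight_decay: float = 5e-4
    epochs: int = 20
    batch_size: int = 64
    text_lr_ratio: float = 1e-3
    section_selection: list | str = "all"
    seed: int = 0
    projection_dim: int = 64
    embedding_dim: int = 128
    head_hidden_dim: int = 128
    widths: tuple = (25, 25, 50, 100, 200)
    dropout: float = 0.5
    temperature_init: float = 0.07
    symmetric_loss: bool = True
    one_window_per_recording: bool = True
    text_encoder: dict = field(
        default_factory=lambda: {"kind": "hashing", "dim": 256, "seed": 0})

    def __post_init__(self):
        for name in ("lr", "weight_decay", "epochs", "batch_size"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.text_lr_ratio < 0:
            raise ValueError("text_lr_ratio must be non-negative")

    @property
    def text_lr(self) -> float:
        return self.lr * self.text_lr_ratio

    def to_dict(self) -> dict:
        d = asdict(self)
        d["widths"] = list(self.widths)
        return d


@dataclass
class PairedDataset:
    """Window tensor with one report text per window."""

    windows: np.ndarray           # (n, C, T) float32
    texts: list[str]
    recording_ids: np.ndarray     # (n,)
    n_dropped_empty: int = 0

    def __post_init__(self):
        if not (len(self.windows) == len(self.texts) == len(self.recording_ids)):
            raise ValueError("windows, texts and recording ids must align")

    def __len__(self):
        return len(self.windows)

    @property
    def n_recordings(self) -> int:
        return len(set(self.recording_ids.tolist()))


def make_pairs(windows: WindowSet, reports: dict[str, ClinicalReport | str],
               selection: list | str = "all") -> PairedDataset:
    """Pair each window with the section-selected text of its own recording.

    Pairs whose selected text is empty are dropped (count logged); a window
    whose recording has no report at all is an error.
    """
    texts_by_rec: dict[str, str] = {}
    for rec_id in dict.fromkeys(windows.recording_ids.tolist()):
        if rec_id not in reports:
            raise KeyError(f"recording {rec_id!r} has no report")
        rep = reports[rec_id]
        if isinstance(rep, str):
            rep = parse_report(rep)
        texts_by_rec[rec_id] = select_sections(rep, selection)

    keep = np.asarray([bool(texts_by_rec[r].strip())
                       for r in windows.recording_ids], dtype=bool)
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("dropped %d window-text pairs with empty selected text", n_dropped)
    return PairedDataset(
        windows=windows.windows[keep],
        texts=[texts_by_rec[r] for r in windows.recording_ids[keep]],
        recording_ids=windows.recording_ids[keep],
        n_dropped_empty=n_dropped,
    )


def build_model(cfg: TrainConfig,
                text_encoder: TextEncoderBase | None = None) -> DualEncoderModel:
    if text_encoder is None:
        text_encoder = make_text_encoder(cfg.text_encoder)
    return DualEncoderModel(
        text_encoder,
        embedding_dim=cfg.embedding_dim,
        projection_dim=cfg.projection_dim,
        head_hidden_dim=cfg.head_hidden_dim,
        widths=tuple(cfg.widths),
        dropout=cfg.dropout,
        temperature_init=cfg.temperature_init,
        symmetric_loss=cfg.symmetric_loss,
        seed=cfg.seed,
    )


def _epoch_batches(pairs: PairedDataset, cfg: TrainConfig,
                   rng: np.random.Generator) -> list[np.ndarray]:
    """Window indices per batch for one epoch under the composition policy."""
    if cfg.one_window_per_recording:
        by_rec: dict = {}
        for i, rec_id in enumerate(pairs.recording_ids.tolist()):
            by_rec.setdefault(rec_id, []).append(i)
        chosen = np.asarray([idxs[rng.integers(len(idxs))]
                             for idxs in by_rec.values()])
        rng.shuffle(chosen)
    else:
        chosen = rng.permutation(len(pairs))
    return [chosen[i:i + cfg.batch_size]
            for i in range(0, len(chosen), cfg.batch_size)]


def train(pairs: PairedDataset, cfg: TrainConfig,
          model: DualEncoderModel | None = None,
          ) -> tuple[DualEncoderModel, list[float]]:
    """Run the contrastive loop; returns the model and per-epoch mean losses."""
    if pairs.n_recordings < 2:
        raise ValueError(
            "contrastive training needs at least 2 distinct recordings "
            "(in-batch negatives)")
    seeds = np.random.SeedSequence(cfg.seed).spawn(3)
    if model is None:
        model = build_model(cfg)
    model.eeg_encoder.reseed_dropout(int(seeds[1].generate_state(1)[0]))
    shuffle_rng = np.random.default_rng(seeds[0])

    main_params, text_params = [], []
    text_ids = {id(p) for p in model.text_encoder.parameters()}
    for p in model.parameters():
        (text_params if id(p) in text_ids else main_params).append(p)
    groups = [{"params": main_params, "lr": cfg.lr, "weight_decay": cfg.weight_decay}]
    if text_params:
        groups.append({"params": text_params, "lr": cfg.text_lr,
                       "weight_decay": cfg.weight_decay})
    opt = Adam(groups)

    history: list[float] = []
    model.train()
    for epoch in range(cfg.epochs):
        batch_losses = []
        for batch_idx in _epoch_batches(pairs, cfg, shuffle_rng):
            if len(batch_idx) < 2:
                continue  # a single pair has no negatives
            windows = pairs.windows[batch_idx]
            texts = [pairs.texts[i] for i in batch_idx]
            opt.zero_grad()
            loss = model.batch_loss(windows, texts)
            loss.backward()
            opt.step()
            batch_losses.append(float(loss.data))
        mean_loss = float(np.mean(batch_losses)) if batch_losses else float("nan")
        history.append(mean_loss)
        logger.info("epoch %d/%d mean loss %.4f", epoch + 1, cfg.epochs, mean_loss)

    # dropout noise biases the running batch-norm statistics; re-estimate them
    # with clean forward passes so inference matches training geometry
    calib_batches = _epoch_batches(pairs, cfg, shuffle_rng)[:8]
    from .autodiff import Tensor
    nn_module = model.eeg_encoder
    nn_recalibrate(nn_module, lambda idx: nn_module(
        Tensor(pairs.windows[idx].astype(np.float32))),
        [b for b in calib_batches if len(b) >= 2])
    model.eval()
    return model, history
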