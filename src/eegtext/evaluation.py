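"""Evaluation regimes: frozen-encoder probing with supervised baselines,
zero-shot prompt classification, and the fractional few-shot protocol.

All scores are balanced accuracy at the recording level; a recording is
represented by the mean of its per-window embeddings (re-normalized in
cosine space). Splits are disjoint at the recording level: 60% of recordings
for contrastive pre-training, a 20% few-shot pool (from which fractions 1/2,
1/5, 1/10, 1/20, 1/50 are sampled, stratified) and a 20% evaluation split.
"""

from __future__ import annotations

import hashlib
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.neural_network import MLPClassifier

from . import nn
from .autodiff import Tensor
from .models import DualEncoderModel, EEGEncoder, eeg_encode
from .text_corpus import build_prompts

logger = logging.getLogger(__name__)

__all__ = [
    "SplitPlan",
    "EvalResult",
    "balanced_accuracy",
    "recording_embedding",
    "zero_shot_classify",
    "probe",
    "SupervisedEEGClassifier",
    "train_supervised",
    "supervised_recording_scores",
    "make_split_plan",
    "stratified_fraction",
    "subset_hash",
    "few_shot_protocol",
    "confidence_bands",
    "FEWSHOT_FRACTIONS",
]

FEWSHOT_FRACTIONS = (1 / 2, 1 / 5, 1 / 10, 1 / 20, 1 / 50)


# ---------------------------------------------------------------------------
# metric


def balanced_accuracy(preds, labels) -> float:
    """Mean of per-class recalls for binary predictions."""
    preds = np.asarray(preds).astype(bool)
    labels = np.asarray(labels).astype(bool)
    if preds.shape != labels.shape:
        raise ValueError("predictions and labels must align")
    if labels.all() or (~labels).all():
        raise ValueError("both classes must be present in the labels")
    recall_pos = (preds & labels).sum() / labels.sum()
    recall_neg = (~preds & ~labels).sum() / (~labels).sum()
    return float((recall_pos + recall_neg) / 2.0)


# ---------------------------------------------------------------------------
# embeddings and zero-shot


def recording_embedding(model: DualEncoderModel, rec_windows: np.ndarray,
                        space: str = "embedding") -> np.ndarray:
    """Aggregate one recording's windows into a single vector.

    ``space="embedding"`` averages 128-d encoder outputs; ``"projection"``
    averages the shared-space projections and re-normalizes (cosine space).
    """
    rec_windows = np.asarray(rec_windows, dtype=np.float32)
    if len(rec_windows) == 0:
        raise ValueError("recording has no windows")
    if space == "embedding":
        return eeg_encode(rec_windows, model).mean(axis=0)
    if space != "projection":
        raise ValueError("space must be 'embedding' or 'projection'")
    was_training = model.training
    model.eval()
    try:
        proj = model.encode_eeg(rec_windows, project_out=True).data
    finally:
        model.train(was_training)
    mean = proj.mean(axis=0)
    norm = np.linalg.norm(mean)
    return mean / norm if norm > 0 else mean


def zero_shot_classify(model: DualEncoderModel,
                       recordings: list[np.ndarray],
                       task: str | None = None,
                       prompts: dict[str, str] | None = None,
                       window_level: bool = False,
                       ):
    """Assign each recording the class of its most-similar prompt projection.

    Returns (boolean predictions, class names); ``True`` means the second
    (B / positive) class. Ties break to class A with a warning. With
    ``window_level=True`` a third element is returned: one array per
    recording of per-window similarity margins (classB - classA).
    """
    if prompts is None:
        if task is None:
            raise ValueError("either task or prompts must be given")
        prompts = build_prompts(task)
    class_names = list(prompts)
    if len(class_names) != 2:
        raise ValueError("zero-shot classification expects exactly two prompts")

    was_training = model.training
    model.eval()
    try:
        proto = model.encode_text([prompts[c] for c in class_names]).data
    finally:
        model.train(was_training)

    preds = np.zeros(len(recordings), dtype=bool)
    window_margins: list[np.ndarray] = []
    for i, windows in enumerate(recordings):
        emb = recording_embedding(model, windows, space="projection")
        sims = proto @ emb
        if sims[0] == sims[1]:
            warnings.warn(f"zero-shot tie for recording {i}; assigning class "
                          f"{class_names[0]!r}", stacklevel=2)
            preds[i] = False
        else:
            preds[i] = bool(sims[1] > sims[0])
        if window_level:
            was_training = model.training
            model.eval()
            try:
                proj = model.encode_eeg(
                    np.asarray(windows, dtype=np.float32), project_out=True).data
            finally:
                model.train(was_training)
            per_window = proj @ proto.T            # (n_windows, 2)
            window_margins.append(per_window[:, 1] - per_window[:, 0])
    if window_level:
        return preds, class_names, window_margins
    return preds, class_names


# ---------------------------------------------------------------------------
# probes on frozen embeddings


@dataclass(frozen=True)
class EvalResult:
    task: str
    method: str            # eegclip_logreg | eegclip_mlp | zero_shot | ...
    balanced_accuracy: float
    fraction: float | None = None
    seed: int | None = None

    def __post_init__(self):
        if not 0.0 <= self.balanced_accuracy <= 1.0:
            raise ValueError("balanced accuracy must lie in [0, 1]")


def _make_head(head: str, seed: int):
    if head == "logreg":
        return LogisticRegression(max_iter=2000, random_state=seed)
    if head == "mlp":
        # 3-layer MLP probe: two hidden ReLU layers of width 64 + readout
        return MLPClassifier(hidden_layer_sizes=(64, 64), activation="relu",
                             solver="adam", max_iter=800, random_state=seed)
    raise ValueError(f"unknown probe head {head!r}")


def probe(train_embeddings: np.ndarray, train_labels, eval_embeddings: np.ndarray,
          eval_labels, head: str = "logreg", task: str = "", seed: int = 0,
          fraction: float | None = None) -> EvalResult:
    """Train only a classification head on frozen embeddings; score the eval split."""
    clf = _make_head(head, seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # MLP convergence chatter on tiny probes
        clf.fit(np.asarray(train_embeddings), np.asarray(train_labels).astype(int))
    preds = clf.predict(np.asarray(eval_embeddings)).astype(bool)
    return EvalResult(task=task, method=f"eegclip_{head}",
                      balanced_accuracy=balanced_accuracy(preds, eval_labels),
                      fraction=fraction, seed=seed)


# ---------------------------------------------------------------------------
# supervised baselines (same EEG architecture, trained with task labels)


class SupervisedEEGClassifier(nn.Module):
    """EEG encoder + linear softmax head for binary decoding."""

    def __init__(self, widths=(25, 25, 50, 100, 200), embedding_dim: int = 128,
                 n_classes: int = 2, dropout: float = 0.5, seed: int = 0):
        super().__init__()
        self.encoder = EEGEncoder(widths=widths, embedding_dim=embedding_dim,
                                  dropout=dropout, seed=seed)
        self.head = nn.Linear(embedding_dim, n_classes,
                              np.random.default_rng(seed + 5))

    def forward(self, x: Tensor) -> Tensor:
        return self.head(self.encoder(x).relu())

    def logits(self, windows: np.ndarray, batch_size: int = 256) -> np.ndarray:
        was_training = self.training
        self.eval()
        try:
            outs = []
            for i in range(0, len(windows), batch_size):
                x = Tensor(np.asarray(windows[i:i + batch_size], dtype=np.float32))
                outs.append(self(x).data)
            return np.concatenate(outs)
        finally:
            self.train(was_training)


def train_supervised(windows: np.ndarray, labels: np.ndarray,
                     widths=(25, 25, 50, 100, 200), lr: float = 5e-3,
                     weight_decay: float = 5e-4, epochs: int = 20,
                     batch_size: int = 64, seed: int = 0,
                     freeze_encoder: bool = False,
                     model: SupervisedEEGClassifier | None = None,
                     ) -> SupervisedEEGClassifier:
    """End-to-end (or frozen-encoder) supervised training on task labels."""
    labels = np.asarray(labels).astype(int)
    seeds = np.random.SeedSequence(seed).spawn(2)
    if model is None:
        model = SupervisedEEGClassifier(widths=widths, seed=seed)
    model.encoder.reseed_dropout(int(seeds[1].generate_state(1)[0]))
    rng = np.random.default_rng(seeds[0])

    if freeze_encoder:
        params = [p for name, p in model.named_parameters()
                  if name.startswith("head.")]
    else:
        params = model.parameters()
    opt = nn.Adam([{"params": params, "lr": lr, "weight_decay": weight_decay}])

    model.train()
    if freeze_encoder:
        model.encoder.eval()  # frozen encoder also keeps running stats fixed
    for _ in range(epochs):
        order = rng.permutation(len(windows))
        for i in range(0, len(order), batch_size):
            idx = order[i:i + batch_size]
            if len(idx) < 2:
                continue
            opt.zero_grad()
            logits = model(Tensor(np.asarray(windows[idx], dtype=np.float32)))
            loss = nn.softmax_cross_entropy(logits, labels[idx])
            loss.backward()
            opt.step()

    if not freeze_encoder:
        calib = [rng.permutation(len(windows))[:batch_size] for _ in range(4)]
        nn.recalibrate_batchnorm(
            model, lambda idx: model(
                Tensor(np.asarray(windows[idx], dtype=np.float32))),
            [b for b in calib if len(b) >= 2])
    model.eval()
    return model


def supervised_recording_scores(model: SupervisedEEGClassifier,
                                recordings: list[np.ndarray]) -> np.ndarray:
    """Boolean class-1 predictions from mean per-recording logits."""
    preds = np.zeros(len(recordings), dtype=bool)
    for i, windows in enumerate(recordings):
        logit = model.logits(np.asarray(windows)).mean(axis=0)
        preds[i] = bool(logit[1] > logit[0])
    return preds


# ---------------------------------------------------------------------------
# splits and the few-shot protocol


@dataclass(frozen=True)
class SplitPlan:
    contrastive_train: tuple[str, ...]
    fewshot_pool: tuple[str, ...]
    eval: tuple[str, ...]
    fractions: tuple[float, ...] = FEWSHOT_FRACTIONS
    seed: int = 0

    def __post_init__(self):
        groups = [set(self.contrastive_train), set(self.fewshot_pool),
                  set(self.eval)]
        for i in range(3):
            for j in range(i + 1, 3):
                overlap = groups[i] & groups[j]
                if overlap:
                    raise ValueError(
                        f"splits overlap at the recording level: {sorted(overlap)[:5]}")


def make_split_plan(recording_ids, class_labels, seed: int = 0,
                    fractions=FEWSHOT_FRACTIONS) -> SplitPlan:
    """Stratified, recording-level 60/20/20 split."""
    ids = np.asarray(recording_ids)
    labels = np.asarray(class_labels)
    rng = np.random.default_rng(seed)
    train, pool, evl = [], [], []
    for value in np.unique(labels):
        members = ids[labels == value]
        members = members[rng.permutation(len(members))]
        n = len(members)
        n_train = int(round(0.6 * n))
        n_pool = int(round(0.2 * n))
        train += members[:n_train].tolist()
        pool += members[n_train:n_train + n_pool].tolist()
        evl += members[n_train + n_pool:].tolist()
    return SplitPlan(tuple(train), tuple(pool), tuple(evl),
                     tuple(fractions), seed)


def stratified_fraction(pool_ids, labels: dict, fraction: float,
                        rng: np.random.Generator) -> list[str]:
    """Sample a class-stratified fraction of the pool, at least one per class."""
    pool_ids = list(pool_ids)
    by_class: dict = {}
    for rec_id in pool_ids:
        by_class.setdefault(bool(labels[rec_id]), []).append(rec_id)
    if len(by_class) < 2:
        raise ValueError("few-shot pool must contain both classes")
    chosen: list[str] = []
    for members in by_class.values():
        k = max(1, int(round(fraction * len(members))))
        idx = rng.choice(len(members), size=k, replace=False)
        chosen += [members[i] for i in idx]
    return sorted(chosen)


def subset_hash(ids) -> str:
    """Stable digest of a sampled id set; asserts identical subsets across methods."""
    joined = "\x1f".join(sorted(map(str, ids)))
    return hashlib.sha256(joined.encode()).hexdigest()[:16]


@dataclass
class FewShotData:
    """Everything the protocol needs, keyed by recording id."""

    labels: dict                                  # id -> bool
    embeddings: dict                              # id -> frozen contrastive embedding
    windows: dict | None = None                   # id -> (n, C, T) raw windows
    alt_embeddings: dict | None = None            # id -> alternative-task embedding


def few_shot_protocol(plan: SplitPlan, data: FewShotData,
                      methods=("eegclip_logreg", "task_specific"),
                      seeds=(0, 1, 2, 3, 4), task: str = "",
                      supervised_kwargs: dict | None = None) -> pd.DataFrame:
    """Train every method on identical fractional subsets of the few-shot pool
    and score on the eval split; returns a tidy result table."""
    supervised_kwargs = supervised_kwargs or {}
    eval_ids = list(plan.eval)
    eval_labels = np.asarray([data.labels[r] for r in eval_ids], dtype=bool)
    rows = []
    for fraction in plan.fractions:
        for seed in seeds:
            rng = np.random.default_rng((plan.seed, int(seed), int(1 / fraction)))
            subset = stratified_fraction(plan.fewshot_pool, data.labels,
                                         fraction, rng)
            digest = subset_hash(subset)
            sub_labels = np.asarray([data.labels[r] for r in subset], dtype=bool)
            for method in methods:
                if method in ("eegclip_logreg", "eegclip_mlp"):
                    head = method.split("_", 1)[1]
                    result = probe(
                        np.stack([data.embeddings[r] for r in subset]), sub_labels,
                        np.stack([data.embeddings[r] for r in eval_ids]),
                        eval_labels, head=head, task=task, seed=int(seed),
                        fraction=fraction)
                    score = result.balanced_accuracy
                elif method == "task_specific":
                    if data.windows is None:
                        raise ValueError("task_specific needs raw windows")
                    windows = np.concatenate([data.windows[r] for r in subset])
                    win_labels = np.concatenate(
                        [np.full(len(data.windows[r]), data.labels[r], dtype=int)
                         for r in subset])
                    model = train_supervised(windows, win_labels, seed=int(seed),
                                             **supervised_kwargs)
                    preds = supervised_recording_scores(
                        model, [data.windows[r] for r in eval_ids])
                    score = balanced_accuracy(preds, eval_labels)
                elif method == "alternative_task":
                    if data.alt_embeddings is None:
                        raise ValueError(
                            "alternative_task needs frozen alternative-task "
                            "embeddings")
                    result = probe(
                        np.stack([data.alt_embeddings[r] for r in subset]),
                        sub_labels,
                        np.stack([data.alt_embeddings[r] for r in eval_ids]),
                        eval_labels, head="logreg", task=task, seed=int(seed),
                        fraction=fraction)
                    score = result.balanced_accuracy
                else:
                    raise ValueError(f"unknown method {method!r}")
                rows.append({"task": task, "method": method, "fraction": fraction,
                             "seed": int(seed), "subset_hash": digest,
                             "n_train": len(subset),
                             "balanced_accuracy": score})
    df = pd.DataFrame.from_records(rows)
    # identical subsets per (fraction, seed) across methods, by construction;
    # assert anyway so a regression cannot silently bias the comparison
    for (_, _), group in df.groupby(["fraction", "seed"]):
        assert group["subset_hash"].nunique() == 1
    return df


def confidence_bands(df: pd.DataFrame, level: float = 0.8) -> pd.DataFrame:
    """Percentile interval over seeds per (task, method, fraction)."""
    lo_q, hi_q = (1 - level) / 2, 1 - (1 - level) / 2
    grouped = df.groupby(["task", "method", "fraction"])["balanced_accuracy"]
    out = grouped.agg(
        mean="mean",
        lo=lambda s: float(np.quantile(s, lo_q)),
        hi=lambda s: float(np.quantile(s, hi_q)),
        n_seeds="count",
    ).reset_index()
    return out
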