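"""End-to-end orchestration helpers shared by the CLI, tests and reports.

Glue only: corpus preparation (generate -> preprocess -> label), contrastive
pre-training on the 60% split of a split plan, and recording-level embedding
extraction. The substance lives in the individual modules.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .evaluation import SplitPlan, make_split_plan
from .models import DualEncoderModel
from .preprocessing import PreprocessConfig, WindowSet, preprocess
from .synthetic import SyntheticCorpusSpec, generate_corpus
from .text_corpus import derive_labels, parse_report
from .training import PairedDataset, TrainConfig, make_pairs, train
from .evaluation import recording_embedding

__all__ = ["CorpusData", "prepare_corpus", "contrastive_pretrain",
           "embeddings_by_recording", "class_prompts", "split_corpus",
           "synthetic_train_config"]


@dataclass
class CorpusData:
    """Preprocessed corpus with per-recording windows, reports and labels."""

    manifest: pd.DataFrame
    windows: dict                   # id -> (n, C, T) float32
    reports: dict                   # id -> raw report text
    labels: dict                    # task -> {id -> bool}
    class_names: dict               # id -> class name

    @property
    def recording_ids(self) -> list[str]:
        return self.manifest["recording_id"].tolist()

    def window_set(self, ids=None) -> WindowSet:
        ids = self.recording_ids if ids is None else list(ids)
        return WindowSet.concatenate([
            WindowSet(self.windows[r],
                      np.asarray([r] * len(self.windows[r]), dtype=object),
                      rate=100.0)
            for r in ids
        ])


def prepare_corpus(spec: SyntheticCorpusSpec,
                   pre_config: PreprocessConfig = PreprocessConfig()) -> CorpusData:
    """Generate a synthetic corpus and run every recording through the chain."""
    recordings, manifest = generate_corpus(spec)
    windows, reports, class_names = {}, {}, {}
    labels: dict = {"pathological": {}, "age": {}, "gender": {}, "medication": {}}
    for rec, row in zip(recordings, manifest.itertuples()):
        ws = preprocess(rec, pre_config)
        windows[rec.recording_id] = ws.windows
        reports[rec.recording_id] = rec.report_text
        class_names[rec.recording_id] = row.class_name
        label_set = derive_labels(rec.subject_meta, parse_report(rec.report_text))
        labels["pathological"][rec.recording_id] = bool(label_set.pathological)
        labels["age"][rec.recording_id] = bool(label_set.age_over_50)
        labels["gender"][rec.recording_id] = label_set.gender == "F"
        labels["medication"][rec.recording_id] = label_set.medication
    return CorpusData(manifest=manifest, windows=windows, reports=reports,
                      labels=labels, class_names=class_names)


def class_prompts(spec: SyntheticCorpusSpec) -> dict[str, str]:
    """Zero-shot prompts from the classes' impression template sentences.

    Ordered so the pathological class is "B" (the positive class of
    :func:`eegtext.evaluation.zero_shot_classify`).
    """
    ordered = sorted(spec.class_defs, key=lambda c: bool(c.pathological))
    prompts = {}
    for key, class_def in zip(("A", "B"), ordered):
        text = class_def.report_templates.get("impression", class_def.name)
        prompts[key] = text if isinstance(text, str) else " ".join(text)
    return prompts


def synthetic_train_config(seed: int = 0, epochs: int = 30) -> TrainConfig:
    """Desk-scale contrastive config for the synthetic corpus: published
    optimizer settings with narrower convolution widths, a milder initial
    temperature and a longer epoch budget, sized for single-CPU runs (the
    tiny corpus gives only a few gradient steps per epoch; the extra epochs
    also sharpen the encoder's event reliance, which cleans up the
    gradient-attribution spectrum)."""
    return TrainConfig(
        lr=5e-3, weight_decay=5e-4, epochs=epochs, batch_size=64,
        widths=(12, 12, 25, 50, 100), head_hidden_dim=64,
        temperature_init=0.3, seed=seed,
        text_encoder={"kind": "hashing", "dim": 128, "seed": 0},
    )


def split_corpus(corpus: CorpusData, seed: int = 0) -> SplitPlan:
    classes = [corpus.class_names[r] for r in corpus.recording_ids]
    return make_split_plan(corpus.recording_ids, classes, seed=seed)


def contrastive_pretrain(corpus: CorpusData, plan: SplitPlan, cfg: TrainConfig,
                         ) -> tuple[DualEncoderModel, list[float], PairedDataset]:
    """Train the dual encoder on the contrastive (60%) split only."""
    ws = corpus.window_set(plan.contrastive_train)
    pairs = make_pairs(ws, corpus.reports, cfg.section_selection)
    model, history = train(pairs, cfg)
    return model, history, pairs


def embeddings_by_recording(model: DualEncoderModel, corpus: CorpusData,
                            ids=None, space: str = "embedding") -> dict:
    ids = corpus.recording_ids if ids is None else list(ids)
    return {r: recording_embedding(model, corpus.windows[r], space=space)
            for r in ids}
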