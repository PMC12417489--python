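# eegtext

Contrastive alignment of clinical EEG windows with medical-report text in a
shared embedding space, evaluated by zero-shot prompting, frozen-encoder
probing and a fractional few-shot protocol, with frequency-domain gradient
attribution — runnable end to end on a bundled synthetic EEG+report
generator, on one CPU, with no deep-learning framework dependency.

## What is inside

| Module | Purpose |
| --- | --- |
| `eegtext.preprocessing` | Deterministic chain: 21-electrode 10-20 montage selection (with channel-alias normalization), crop to recording seconds [60, 180), clip at ±800 µV, resample to 100 Hz, divide by 30, extract 21×1200 windows at stride 519. |
| `eegtext.text_corpus` | Clinical-report parsing into 15 canonical sections, section selection, the four task labels (pathological / age>50 / gender / medication-keyword) and the zero-shot prompt pairs. |
| `eegtext.models` | Dual encoder: four-block conv EEG encoder → 128-d embedding, pluggable text encoder (deterministic hashing embedder, trainable token-averager, optional BERT adapter), 3-layer MLP projection heads → 64-d L2-normalized space, InfoNCE-style loss with learnable temperature. |
| `eegtext.training` | Contrastive loop pairing each window with its recording's section-selected report; Adam with a reduced-lr text-encoder parameter group. |
| `eegtext.evaluation` | Balanced accuracy, recording-level embedding aggregation, zero-shot prompt classification, logreg/MLP probes, supervised task-specific and alternative-task baselines, recording-level 60/20/20 split plan, stratified fractional few-shot protocol with 80% percentile bands. |
| `eegtext.interpretability` | Gradient of EEG–prompt cosine similarity with respect to per-channel rFFT coefficients (the inverse transform sits inside the autodiff graph); channel × frequency maps, magnitude or signed. |
| `eegtext.synthetic` | Paired synthetic corpus: 1/f background noise plus oscillation-burst / sharp-wave events, templated reports with class sentences and shared distractors, metadata sampling; fully seeded. |
| `eegtext.autodiff`, `eegtext.nn` | Minimal NumPy reverse-mode autodiff and layer/optimizer library backing the model (no torch required). |
| `eegtext.edf` | Minimal plain-EDF reader/writer (16-bit, 1-second records). |

## CLI

```bash
eegtext synth --n 40 --seed 0 --out data/          # EDF + reports + manifest.csv
eegtext labels --manifest data/ --out labels.csv
eegtext preprocess --data data/ --out windows/
eegtext train --data data/ --config cfg.yaml --out model.npz
eegtext zeroshot --ckpt model.npz --data data/ --task medication
eegtext fewshot --ckpt model.npz --data data/ --task pathological --out fewshot.csv
eegtext gradients --ckpt model.npz --data data/ \
    --prompt "Excessive beta activity" --out map.npz --png
eegtext sectionsweep --data data/ --task pathological --out sweep.csv
```

`zeroshot --window-level` additionally reports per-window prompt-margin
statistics; `sectionsweep` retrains once per single report section (plus
"all") to measure how section choice affects alignment.

`cfg.yaml` holds `TrainConfig` overrides, e.g.

```yaml
lr: 0.005
epochs: 20
batch_size: 64
text_lr_ratio: 0.001
widths: [12, 12, 25, 50, 100]
temperature_init: 0.3
text_encoder: {kind: hashing, dim: 128, seed: 0}
```

## Python API sketch

```python
from eegtext.pipeline import (prepare_corpus, split_corpus, contrastive_pretrain,
                              class_prompts, synthetic_train_config)
from eegtext.synthetic import beta_vs_normal_spec
from eegtext.evaluation import zero_shot_classify, balanced_accuracy

spec = beta_vs_normal_spec(n_recordings=200, seed=7)
corpus = prepare_corpus(spec)                      # generate + preprocess + label
plan = split_corpus(corpus, seed=0)                # 60/20/20 at recording level
model, history, _ = contrastive_pretrain(corpus, plan, synthetic_train_config(0))

eval_ids = list(plan.eval)
preds, _ = zero_shot_classify(model, [corpus.windows[r] for r in eval_ids],
                              prompts=class_prompts(spec))
labels = [corpus.labels["pathological"][r] for r in eval_ids]
print(balanced_accuracy(preds, labels))
```
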