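# ethosim

Synthetic ethogram benchmark for composite animal-behavior recognition.

Automated recognition of rodent behavior from pose time-series plateaus
around 75–80% for ethologically relevant classes, and the residual errors
concentrate on specific *dynamics*: look-alike poses, class-specific
event durations, periodic movement, momentary point events, and composite
behaviors whose constituents are shared with other behaviors (a jump's
stretched pose is also part of walking; a grooming sub-pose overlaps
eating). `ethosim` isolates each of these dynamics in fully synthetic,
endlessly generatable labeled time-series, trains two representative
recognition models on them, and measures — against a closed-form
Bayes-optimal baseline — which dynamics the models actually learn.

It is aimed at researchers developing behavior-recognition
architectures: the generator gives clean features, balanced classes and
frame-accurate labels, so a failure on a confusion group cannot be blamed
on data quality.

## What is inside

* **Behavior model** (`ethosim.ethogram`) — behaviors as hierarchically
  structured constituents: *state events* (a Gaussian key pose held over
  a sampled duration, with slow wander and optional class-specific
  periodicity), *point events* (a one-sample key pose), and ordered or
  unordered composites; events joined by 2–8-sample transition ramps
  (label `b00`) plus observation noise. Two shipped presets: `state`
  (b01–b10) and `composite` (b11–b16 plus controls), each with
  deliberately constructed confusion groups.
* **Simulator** (`ethosim.simulator`) — bit-reproducible rendering of a
  repertoire into labeled series (CSV + JSON sidecar).
* **Models** — a supervised recurrent variational auto-encoder with a
  behavioral-motif layer (`ethosim.rnn_vae`) and a masked-span
  Transformer with a GRU slice-classification head
  (`ethosim.transformer`), both implemented on `ethosim.nn`, a small
  gradient-checked reverse-mode autodiff engine over NumPy.
* **Evaluation** (`ethosim.evaluation`) — per-sample confusion matrices
  at behavior and sub-event level, confusion-group summaries, and the
  Bayes-optimal single-sample classifier computed from the known
  generative densities (the formal "switching states" baseline that
  cannot use duration, periodicity or sequence context).
* **Orchestration** (`ethosim.experiment`, `ethosim` CLI) — full
  experiment protocol with reproducibility manifests and a seeded random
  hyperparameter search.

## Worked example

```python
import numpy as np
from ethosim import (generate_dataset, make_state_preset, bayes_oracle,
                     confusion_matrix, group_report, preset_confusion_groups)
from ethosim import rnn_vae

spec = make_state_preset()
train = generate_dataset(spec, n_events=600, seed=101)
test = generate_dataset(spec, n_events=150, seed=103)

# context-free upper bound: single-sample Bayes errors
oracle = bayes_oracle(spec)
print(f"Bayes error b01/b02: {oracle.pair_error('b01', 'b02'):.4f}")
print(f"Bayes error b03/b04: {oracle.pair_error('b03', 'b04'):.4f}")
print(f"Bayes error b06/b07: {oracle.pair_error('b06', 'b07'):.4f}")

cfg = rnn_vae.VAEConfig(epochs=40, seed=1)
model, curves = rnn_vae.fit(train, cfg, classes=spec.all_labels)
pred = rnn_vae.predict_series(model, test)

report = confusion_matrix(test.behavior_labels, pred, spec.all_labels)
print({k: round(report.recall(k), 2) for k in ("b01", "b02", "b03", "b04")})
groups = group_report(report, preset_confusion_groups("state"))
print({k: round(v["unweighted"], 2) for k, v in groups.items()})
```

prints (exact model recalls vary a little with the seed):

```
Bayes error b01/b02: 0.0000
Bayes error b03/b04: 0.3115
Bayes error b06/b07: 0.5000
{'b01': 0.98, 'b02': 0.99, 'b03': 0.49, 'b04': 0.93}
{'group1': 0.27, 'group2': 0.39, 'group3': 0.24}
```

Reading it: the sanity pair b01/b02 is near-perfectly separable and the
model gets it. b03 and b04 overlap in pose by construction (single-sample
Bayes error 31%) and the trained model cannot resolve them either — about
a quarter of the look-alike pair's row mass lands inside the group.
b06/b07 share an identical pose and differ only in event duration (Bayes
error 50%: a single sample carries no information), and the large
within-group confusion shows the model indeed cannot separate them from
window-scale context. The same protocol
on the `composite` preset probes point events (b11) and shared
sub-behaviors in unordered (b13/b14) and ordered (b15/b16) sequences.

From the shell:

```sh
ethosim generate --preset composite --n-events 1000 --seed 7 --out series.csv
ethosim run --preset state --model both --n-train 600 --seed 101 --out results/
ethosim tune --preset state --model transformer --budget 20 --out tuning/
```

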