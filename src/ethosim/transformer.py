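"""Masked-span Transformer for behavioral time-series.

A small attention encoder (4 layers, 4 heads, feed-forward hidden 80) is
trained on sequences of 20 samples with two objectives optimized
simultaneously:

* masked reconstruction — one *contiguous* span covering 45% of the
  sequence is replaced by a learned mask token and a linear decoder must
  regress the original feature values at the span positions only
  (contiguous masking avoids the trivial interpolation solution; features
  are continuous, so reconstruction is mean-squared error);
* supervised classification — the unmasked sequence is encoded and a
  central slice of five encoded samples is classified by a bidirectional
  GRU head (hidden 30); the target is the label of the slice's central
  sample.

Positional information is a learned per-position embedding (it can be
disabled for ablation: without it, reconstruction of periodic classes
degrades since the phase of the span cannot be located).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .nn import (Adam, BiGRU, LayerNorm, Linear, Module,
                 MultiHeadSelfAttention, Tensor, concat, cross_entropy, no_grad)
from .rnn_vae import class_weights, ramp  # shared helpers
from .simulator import GeneratedSeries
from .windows import extract_windows

__all__ = ["TransformerConfig", "mask_span", "SpanTransformer", "fit",
           "predict_series", "save_model", "load_model", "slice_positions"]


@dataclass
class TransformerConfig:
    n_layers: int = 4
    n_heads: int = 4
    ff_hidden: int = 80
    width: int = 32            # token embedding size
    seq_len: int = 20
    mask_ratio: float = 0.45
    slice_len: int = 5
    cls_hidden: int = 30
    F: int = 1
    w_cls: float = 1.0
    lr: float = 1e-3
    epochs: int = 30
    batch_size: int = 64
    batches_per_epoch: int = 60
    pretrain_epochs: int = 0   # optional two-phase mode; co-training by default
    lr_schedule: str = "cosine"  # "cosine" (with 10% warmup) or "constant"
    use_positional: bool = True
    class_weighting: str = "none"
    seed: int = 0

    def validate(self) -> None:
        if not (0.0 < self.mask_ratio < 1.0):
            raise ValueError(f"mask_ratio must be in (0, 1), got {self.mask_ratio}")
        if self.slice_len > self.seq_len:
            raise ValueError("slice_len must be <= seq_len")
        if self.span_length < 1:
            raise ValueError("mask span would be empty")

    @property
    def span_length(self) -> int:
        return int(round(self.mask_ratio * self.seq_len))


def slice_positions(seq_len: int, slice_len: int) -> np.ndarray:
    """Indices of the central classification slice (e.g. 7..11 for 20/5)."""
    start = (seq_len - slice_len) // 2
    return np.arange(start, start + slice_len)


def slice_center(seq_len: int, slice_len: int) -> int:
    pos = slice_positions(seq_len, slice_len)
    return int(pos[len(pos) // 2])


def mask_span(sequence: np.ndarray, ratio: float, rng: np.random.Generator,
              mask_token: Optional[np.ndarray] = None
              ) -> tuple[np.ndarray, int, int]:
    """Replace one contiguous span by the mask token.

    The span length is ``round(ratio * seq_len)``; its start is uniform
    over feasible positions.  Returns (masked copy, span start, span
    length).
    """
    seq = np.asarray(sequence, dtype=float)
    if not (0.0 < ratio < 1.0):
        raise ValueError(f"mask ratio must be in (0, 1), got {ratio}")
    n = seq.shape[0]
    length = int(round(ratio * n))
    if length < 1:
        raise ValueError("mask span rounds to zero samples")
    start = int(rng.integers(0, n - length + 1))
    token = (np.zeros(seq.shape[1]) if mask_token is None
             else np.asarray(mask_token, dtype=float))
    out = seq.copy()
    out[start:start + length] = token
    return out, start, length


class SpanTransformer(Module):
    def __init__(self, config: TransformerConfig, classes: Sequence[str],
                 rng: np.random.Generator):
        super().__init__()
        config.validate()
        self.config = config
        self.classes = list(classes)
        c = config
        self.in_proj = Linear(c.F, c.width, rng)
        self.pos = Tensor(0.1 * rng.standard_normal((c.seq_len, c.width)),
                          requires_grad=True)
        self.mask_token = Tensor(0.02 * rng.standard_normal(c.F),
                                 requires_grad=True)
        self.attn = [MultiHeadSelfAttention(c.width, c.n_heads, rng)
                     for _ in range(c.n_layers)]
        self.ln1 = [LayerNorm(c.width) for _ in range(c.n_layers)]
        self.ff1 = [Linear(c.width, c.ff_hidden, rng) for _ in range(c.n_layers)]
        self.ff2 = [Linear(c.ff_hidden, c.width, rng) for _ in range(c.n_layers)]
        self.ln2 = [LayerNorm(c.width) for _ in range(c.n_layers)]
        self.decoder = Linear(c.width, c.F, rng)
        self.cls_gru = BiGRU(c.width, c.cls_hidden, rng)
        self.cls_out = Linear(2 * c.cls_hidden, len(self.classes), rng)

    # -- encoder --------------------------------------------------------

    def _encode(self, x: Tensor) -> Tensor:
        h = self.in_proj(x)
        if self.config.use_positional:
            h = h + self.pos
        # pre-norm residual blocks: markedly more trainable than post-norm
        # at this scale (no warm-up needed)
        for attn, ln1, ff1, ff2, ln2 in zip(self.attn, self.ln1, self.ff1,
                                            self.ff2, self.ln2):
            h = h + attn(ln1(h))
            h = h + ff2(ff1(ln2(h)).relu())
        return h  # (B, T, width)

    def _mask_batch(self, X: np.ndarray, rng: np.random.Generator
                    ) -> tuple[Tensor, np.ndarray]:
        """Mask one span per sequence; keeps gradient flow to the token."""
        B, T, F = X.shape
        L = self.config.span_length
        starts = rng.integers(0, T - L + 1, size=B)
        m = np.zeros((B, T, 1))
        for b, s in enumerate(starts):
            m[b, s:s + L, 0] = 1.0
        masked = Tensor(X * (1.0 - m)) + self.mask_token * Tensor(m)
        return masked, m

    def reconstruction_loss(self, X: np.ndarray, rng: np.random.Generator) -> Tensor:
        """Masked-span regression: MSE restricted to the span positions."""
        masked, m = self._mask_batch(X, rng)
        recon = self.decoder(self._encode(masked))
        diff = (recon - Tensor(X)) * Tensor(m)
        return (diff * diff).sum() * (1.0 / m.sum() / X.shape[2])

    def _classify_logits(self, X: Tensor) -> Tensor:
        h = self._encode(X)
        pos = slice_positions(self.config.seq_len, self.config.slice_len)
        sl = h[:, pos, :]
        _, (hf, hb) = self.cls_gru(sl)
        return self.cls_out(concat([hf, hb], axis=1))

    def classify_slice(self, sequence: np.ndarray) -> np.ndarray:
        """Label distribution for the central slice of one full sequence."""
        seq = np.asarray(sequence, dtype=float)
        if seq.shape != (self.config.seq_len, self.config.F):
            raise ValueError(f"sequence shape {seq.shape} != "
                             f"({self.config.seq_len}, {self.config.F})")
        logits = self._classify_logits(Tensor(seq[None]))
        return logits.softmax(axis=-1).data[0]

    def reconstruct(self, sequence: np.ndarray, span_start: int,
                    span_length: int) -> np.ndarray:
        """Predicted feature values over a span, masked before encoding."""
        seq = np.asarray(sequence, dtype=float)
        masked = seq.copy()
        masked[span_start:span_start + span_length] = self.mask_token.data
        out = self.decoder(self._encode(Tensor(masked[None]))).data[0]
        return out[span_start:span_start + span_length]


# ---------------------------------------------------------------------------
# Training / prediction
# ---------------------------------------------------------------------------

def fit(series: GeneratedSeries, config: TransformerConfig,
        classes: Optional[Sequence[str]] = None,
        verbose: bool = False) -> tuple[SpanTransformer, pd.DataFrame]:
    """Joint masked-reconstruction + slice-classification training."""
    if len(series) < config.seq_len:
        raise ValueError("series shorter than seq_len")
    classes = (sorted(set(series.behavior_labels.tolist()))
               if classes is None else list(classes))
    label_index = {c: i for i, c in enumerate(classes)}
    rng = np.random.default_rng(config.seed)
    model = SpanTransformer(config, classes, rng)
    opt = Adam(model.parameters(), lr=config.lr, betas=(0.9, 0.999))
    weights = class_weights(series, classes, config.class_weighting)
    center = slice_center(config.seq_len, config.slice_len)
    total_steps = max(1, config.epochs * config.batches_per_epoch)
    warmup = max(1, int(0.1 * total_steps))
    step = 0

    curves = {k: [] for k in ("recon", "cls", "total")}
    for epoch in range(config.epochs):
        co_train = epoch >= config.pretrain_epochs
        sums = dict.fromkeys(curves, 0.0)
        for _ in range(config.batches_per_epoch):
            if config.lr_schedule == "cosine":
                if step < warmup:
                    opt.lr = config.lr * (step + 1) / warmup
                else:
                    frac = (step - warmup) / max(1, total_steps - warmup)
                    opt.lr = config.lr * 0.5 * (1.0 + np.cos(np.pi * frac))
            step += 1
            starts = rng.integers(0, len(series) - config.seq_len + 1,
                                  size=config.batch_size)
            X = extract_windows(series.features, starts, config.seq_len)
            l_recon = model.reconstruction_loss(X, rng)
            if co_train:
                y = np.asarray([label_index[series.behavior_labels[s + center]]
                                for s in starts])
                l_cls = cross_entropy(model._classify_logits(Tensor(X)), y, weights)
            else:
                l_cls = Tensor(0.0)
            total = l_recon + config.w_cls * l_cls
            model.zero_grad()
            total.backward()
            opt.step()
            for k, v in (("recon", l_recon), ("cls", l_cls), ("total", total)):
                sums[k] += float(v.data)
        for k in sums:
            curves[k].append(sums[k] / config.batches_per_epoch)
        if verbose:
            print(f"epoch {epoch:3d}  total {curves['total'][-1]:.4f}  "
                  f"recon {curves['recon'][-1]:.4f}  cls {curves['cls'][-1]:.4f}")
    model.eval()
    return model, pd.DataFrame(curves)


def predict_series(model: SpanTransformer, series: GeneratedSeries,
                   batch_size: int = 512) -> np.ndarray:
    """Per-sample predictions: each sample sits at the center of the
    classified slice of its stride-1 sequence (clamped at boundaries)."""
    model.eval()
    c = model.config
    if len(series) < c.seq_len:
        raise ValueError("series shorter than seq_len")
    center = slice_center(c.seq_len, c.slice_len)
    starts = np.clip(np.arange(len(series)) - center, 0, len(series) - c.seq_len)
    labels = np.asarray(model.classes, dtype=str)
    out = np.empty(len(series), dtype=labels.dtype)
    with no_grad():
        for a in range(0, len(series), batch_size):
            X = extract_windows(series.features, starts[a:a + batch_size], c.seq_len)
            logits = model._classify_logits(Tensor(X))
            out[a:a + len(X)] = labels[np.argmax(logits.data, axis=1)]
    return out


# ---------------------------------------------------------------------------
# Checkpointing
# ---------------------------------------------------------------------------

def save_model(model: SpanTransformer, directory) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    np.savez(directory / "weights.npz", *[p.data for p in model.parameters()])
    (directory / "config.json").write_text(json.dumps(
        {"config": asdict(model.config), "classes": model.classes,
         "kind": "transformer"}))


def load_model(directory) -> SpanTransformer:
    directory = Path(directory)
    meta = json.loads((directory / "config.json").read_text())
    config = TransformerConfig(**meta["config"])
    model = SpanTransformer(config, meta["classes"],
                            np.random.default_rng(config.seed))
    with np.load(directory / "weights.npz") as z:
        model.load_state_dict([z[f"arr_{i}"] for i in range(len(z.files))])
    model.eval()
    return model
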