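"""Realize an ethogram into labeled behavioral time-series.

The generative pipeline is: sample an i.i.d. event sequence (uniform over
behaviors, no immediate repeats, so no behavior-to-behavior sequence cue
exists), render each event from its constituents, join events — and the
constituents inside composite events — with short transition ramps of 2-8
samples, and finally add i.i.d. Gaussian observation noise to every
feature sample.

Coordinate conventions: 0-based sample indices, half-open ``[start, end)``
events.  Transition samples between events carry the transition label
(``b00``) at both the behavior and the sub-event level; transition samples
*inside* a composite event carry the parent behavior label and the
transition sub-event label.

One integer seed drives a splittable ``numpy.random.SeedSequence``
hierarchy (event sequence / event rendering / transitions / noise), so the
output is bit-reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from .ethogram import (
    Atomic,
    BehaviorDefinition,
    Constituent,
    EthogramSpec,
    FluctuationSpec,
    Ordered,
    Unordered,
    get_preset,
)

__all__ = [
    "Event",
    "GeneratedSeries",
    "sample_event_sequence",
    "realize_event",
    "make_transition",
    "apply_fluctuations",
    "add_observation_noise",
    "generate_dataset",
    "merge_transition_labels",
    "write_series",
    "read_series",
    "SeriesParseError",
]

# Scatter added to transition ramps so that transitional movements are not
# noiseless straight lines; small relative to typical key-pose spreads.
TRANSITION_SCATTER = 0.05


@dataclass
class Event:
    """One behavior event: ``[start, end)`` plus its sub-event tiling."""

    behavior_label: str
    start: int
    end: int
    subevents: list[tuple[str, int, int]] = field(default_factory=list)


@dataclass
class GeneratedSeries:
    """Labeled feature time-series with its event table and provenance."""

    features: np.ndarray            # (time, F)
    behavior_labels: np.ndarray     # (time,) str
    subevent_labels: np.ndarray     # (time,) str
    events: list[Event]
    seed: int
    spec_name: str

    def __len__(self) -> int:
        return self.features.shape[0]

    @property
    def F(self) -> int:
        return self.features.shape[1]

    def __eq__(self, other) -> bool:
        if not isinstance(other, GeneratedSeries):
            return NotImplemented
        return (np.array_equal(self.features, other.features)
                and np.array_equal(self.behavior_labels, other.behavior_labels)
                and np.array_equal(self.subevent_labels, other.subevent_labels)
                and self.events == other.events
                and self.seed == other.seed
                and self.spec_name == other.spec_name)


# ---------------------------------------------------------------------------
# Event sequence
# ---------------------------------------------------------------------------

def sample_event_sequence(spec: EthogramSpec, n_events: int,
                          rng: np.random.Generator) -> list[str]:
    """Draw ``n_events`` behavior labels i.i.d. uniform, no immediate repeats.

    Uniform event sampling guarantees that no behavior-to-behavior
    transition statistics exist for a model to exploit; repeats are
    resampled so every event boundary is a genuine behavior change.
    """
    labels = spec.labels
    if not labels:
        raise ValueError("spec has no behaviors")
    if n_events < 1:
        raise ValueError("n_events must be >= 1")
    out: list[str] = []
    for _ in range(n_events):
        lab = labels[rng.integers(len(labels))]
        while out and lab == out[-1] and len(labels) > 1:
            lab = labels[rng.integers(len(labels))]
        out.append(lab)
    return out


# ---------------------------------------------------------------------------
# Constituent rendering
# ---------------------------------------------------------------------------

def apply_fluctuations(segment: np.ndarray, fl: FluctuationSpec,
                       rng: np.random.Generator) -> np.ndarray:
    """Add within-event dynamics to a rendered segment.

    Two additive components: (a) slow wander — white Gaussian noise
    low-passed by a moving average of window ``smoothness``, normalized
    per position so its marginal std is exactly ``amount``; (b) if a
    period is configured, a sinusoid of that period and amplitude with a
    random phase per call (per event), so phase carries no class cue.
    """
    n, F = segment.shape
    out = segment.copy()
    if fl.amount > 0:
        w = int(fl.smoothness)
        eps = rng.standard_normal((n + w - 1, F))
        kernel = np.ones(w)
        for j in range(F):
            smoothed = np.convolve(eps[:, j], kernel, mode="valid")  # length n
            out[:, j] += fl.amount * smoothed / np.sqrt(w)
    if fl.period is not None:
        phase = rng.uniform(0.0, 2.0 * np.pi)
        t = np.arange(n)
        wave = fl.period_amplitude * np.sin(2.0 * np.pi * t / fl.period + phase)
        out += wave[:, None]
    return out


def _render_constituent(c: Constituent, rng: np.random.Generator) -> np.ndarray:
    dur = c.duration.sample(rng)
    mean = np.asarray(c.key_pose.mean, dtype=float)
    spread = np.asarray(c.key_pose.spread, dtype=float)
    seg = mean[None, :] + spread[None, :] * rng.standard_normal((dur, len(mean)))
    if not c.fluctuation.is_null():
        seg = apply_fluctuations(seg, c.fluctuation, rng)
    return seg


def make_transition(prev_pose: np.ndarray, next_pose: np.ndarray, length: int,
                    rng: np.random.Generator,
                    scatter: float = TRANSITION_SCATTER) -> np.ndarray:
    """Smooth ramp of ``length`` samples from ``prev_pose`` toward ``next_pose``.

    A cosine ease evaluated at interior fractions, so every sample lies
    strictly between the two boundary poses (before scatter), plus small
    Gaussian scatter.
    """
    if length < 2:
        raise ValueError(f"transition length must be >= 2, got {length}")
    prev_pose = np.atleast_1d(np.asarray(prev_pose, dtype=float))
    next_pose = np.atleast_1d(np.asarray(next_pose, dtype=float))
    t = (np.arange(length) + 1.0) / (length + 1.0)
    ease = 0.5 * (1.0 - np.cos(np.pi * t))
    seg = prev_pose[None, :] + ease[:, None] * (next_pose - prev_pose)[None, :]
    if scatter > 0:
        seg = seg + scatter * rng.standard_normal(seg.shape)
    return seg


def _draw_constituents(b: BehaviorDefinition, rng: np.random.Generator) -> list[Constituent]:
    s = b.structure
    if isinstance(s, Atomic):
        return [s.constituent]
    if isinstance(s, Ordered):
        return list(s.constituents)
    # Unordered: draw the repeat count, then constituents by mixture weight,
    # avoiding immediate repeats of the same sub-pose when possible.
    n = s.repeats.sample(rng)
    weights = (np.full(len(s.constituents), 1.0 / len(s.constituents))
               if s.weights is None else np.asarray(s.weights, dtype=float))
    idx: list[int] = []
    for _ in range(n):
        i = int(rng.choice(len(s.constituents), p=weights))
        while idx and i == idx[-1] and len(s.constituents) > 1:
            i = int(rng.choice(len(s.constituents), p=weights))
        idx.append(i)
    return [s.constituents[i] for i in idx]


def realize_event(behavior: BehaviorDefinition, spec: EthogramSpec,
                  rng: np.random.Generator) -> tuple[np.ndarray, list[tuple[str, int, int]]]:
    """Render one event: pre-noise feature segment plus its sub-event tiling.

    Consecutive constituents of composite behaviors are joined by internal
    transition ramps drawn from the same 2-8 sample range as inter-event
    transitions; those samples get the transition sub-event label but stay
    inside the event.
    """
    constituents = _draw_constituents(behavior, rng)
    lo, hi = spec.transition_range
    parts: list[np.ndarray] = []
    subevents: list[tuple[str, int, int]] = []
    pos = 0
    for k, c in enumerate(constituents):
        seg = _render_constituent(c, rng)
        if k > 0:
            tlen = int(rng.integers(lo, hi + 1))
            ramp = make_transition(parts[-1][-1], seg[0], tlen, rng)
            parts.append(ramp)
            subevents.append((spec.transition_label, pos, pos + tlen))
            pos += tlen
        parts.append(seg)
        subevents.append((c.subevent_label, pos, pos + len(seg)))
        pos += len(seg)
    return np.concatenate(parts, axis=0), subevents


# ---------------------------------------------------------------------------
# Noise and assembly
# ---------------------------------------------------------------------------

def add_observation_noise(series: np.ndarray, sigma: float,
                          rng: np.random.Generator) -> np.ndarray:
    """Add i.i.d. Gaussian observation noise of std ``sigma`` to every entry."""
    if sigma < 0:
        raise ValueError(f"noise sigma must be >= 0, got {sigma}")
    if sigma == 0:
        return series.copy()
    return series + sigma * rng.standard_normal(series.shape)


def generate_dataset(spec: EthogramSpec, n_events: int, seed: int) -> GeneratedSeries:
    """Generate a labeled series of ``n_events`` events from ``spec``.

    Deterministic: the same (spec, n_events, seed) yields bit-identical
    output.
    """
    ss = np.random.SeedSequence(seed)
    rng_seq, rng_ev, rng_tr, rng_noise = (np.random.default_rng(c)
                                          for c in ss.spawn(4))
    labels = sample_event_sequence(spec, n_events, rng_seq)
    lo, hi = spec.transition_range

    parts: list[np.ndarray] = []
    beh: list[np.ndarray] = []
    sub: list[np.ndarray] = []
    events: list[Event] = []
    pos = 0
    for i, lab in enumerate(labels):
        seg, subevents = realize_event(spec.behavior(lab), spec, rng_ev)
        if i > 0:
            tlen = int(rng_tr.integers(lo, hi + 1))
            ramp = make_transition(parts[-1][-1], seg[0], tlen, rng_tr)
            parts.append(ramp)
            beh.append(np.full(tlen, spec.transition_label, dtype=object))
            sub.append(np.full(tlen, spec.transition_label, dtype=object))
            pos += tlen
        start = pos
        parts.append(seg)
        beh.append(np.full(len(seg), lab, dtype=object))
        sub_arr = np.empty(len(seg), dtype=object)
        abs_sub = []
        for s_lab, s0, s1 in subevents:
            sub_arr[s0:s1] = s_lab
            abs_sub.append((s_lab, start + s0, start + s1))
        sub.append(sub_arr)
        pos += len(seg)
        events.append(Event(lab, start, pos, abs_sub))

    features = np.concatenate(parts, axis=0)
    features = add_observation_noise(features, spec.noise_sigma, rng_noise)
    return GeneratedSeries(
        features=features,
        behavior_labels=np.concatenate(beh).astype(str),
        subevent_labels=np.concatenate(sub).astype(str),
        events=events,
        seed=int(seed),
        spec_name=spec.name,
    )


def merge_transition_labels(series: GeneratedSeries, transition_label: str = "b00") -> GeneratedSeries:
    """Reassign inter-event transition samples to the *following* event's label.

    Mimics annotation conventions where transitional movement is absorbed
    into the next behavior bout.  Returns a relabeled copy; the feature
    matrix is shared.
    """
    beh = series.behavior_labels.copy()
    nxt = None
    for i in range(len(beh) - 1, -1, -1):
        if beh[i] != transition_label:
            nxt = beh[i]
        elif nxt is not None:
            beh[i] = nxt
    return GeneratedSeries(series.features, beh, series.subevent_labels.copy(),
                           series.events, series.seed, series.spec_name)


# ---------------------------------------------------------------------------
# I/O: CSV + JSON sidecar
# ---------------------------------------------------------------------------

class SeriesParseError(ValueError):
    pass


def _sidecar(path: Path) -> Path:
    return path.with_name(path.name + ".meta.json")


def write_series(series: GeneratedSeries, path: Union[str, Path]) -> None:
    """Write one row per sample (time, features, labels) plus a JSON sidecar."""
    path = Path(path)
    cols = {"t": np.arange(len(series))}
    for j in range(series.F):
        cols[f"f{j}"] = series.features[:, j]
    cols["behavior"] = series.behavior_labels
    cols["subevent"] = series.subevent_labels
    # %.17g guarantees float64 round-trips exactly through the text file
    pd.DataFrame(cols).to_csv(path, index=False, float_format="%.17g")
    meta = {
        "seed": series.seed,
        "spec_name": series.spec_name,
        "n_samples": len(series),
        "F": series.F,
        "events": [
            {"behavior": e.behavior_label, "start": e.start, "end": e.end,
             "subevents": [[s, a, b] for s, a, b in e.subevents]}
            for e in series.events
        ],
    }
    _sidecar(path).write_text(json.dumps(meta))


def read_series(path: Union[str, Path]) -> GeneratedSeries:
    path = Path(path)
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise SeriesParseError(f"{path}: cannot parse CSV: {exc}") from exc
    feat_cols = [c for c in df.columns if c.startswith("f") and c[1:].isdigit()]
    for col in ("behavior", "subevent"):
        if col not in df.columns:
            raise SeriesParseError(f"{path}: missing required column {col!r} (line 1)")
    if not feat_cols:
        raise SeriesParseError(f"{path}: no feature columns f0..fK found (line 1)")
    bad = df["behavior"].isna()
    if bad.any():
        raise SeriesParseError(
            f"{path}: missing behavior label at line {int(np.argmax(bad.values)) + 2}")
    meta_path = _sidecar(path)
    if not meta_path.exists():
        raise SeriesParseError(f"{meta_path}: sidecar metadata file not found")
    meta = json.loads(meta_path.read_text())
    events = [Event(e["behavior"], int(e["start"]), int(e["end"]),
                    [(s, int(a), int(b)) for s, a, b in e["subevents"]])
              for e in meta["events"]]
    return GeneratedSeries(
        features=df[sorted(feat_cols, key=lambda c: int(c[1:]))].to_numpy(dtype=float),
        behavior_labels=df["behavior"].to_numpy(dtype=str),
        subevent_labels=df["subevent"].to_numpy(dtype=str),
        events=events,
        seed=int(meta["seed"]),
        spec_name=meta["spec_name"],
    )
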