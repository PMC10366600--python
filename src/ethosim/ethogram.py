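"""Hierarchical behavior repertoires (ethograms) for synthetic time-series.

A behavior repertoire is described generatively: each behavior is built from
*constituents* — state events (a key pose held with variation over a sampled
duration) and point events (a momentary key pose, one sample) — optionally
combined into ordered sequences or unordered repeat sets.  Key poses are
Gaussian distributions in an abstract feature space; within-event dynamics
(slow wander, class-specific periodicity) and observation noise are layered
on top by the simulator.

Two presets ship with the package:

``make_state_preset``
    Ten atomic state behaviors (b01-b10) probing pose overlap, pose
    mixtures, uncommon event durations and class-specific periodicity.
``make_composite_preset``
    Structured behaviors (b11-b16 plus b01/b02/b12/b14) probing point
    events, ambiguous sub-behaviors in unordered repeats, and shared
    sub-poses in ordered sequences.

Both presets use a single abstract pose feature (F = 1) and insert
transition samples (label ``b00``) of 2-8 samples between events.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import yaml

__all__ = [
    "KeyPose",
    "DurationDistribution",
    "FluctuationSpec",
    "Constituent",
    "Atomic",
    "Ordered",
    "Unordered",
    "BehaviorDefinition",
    "EthogramSpec",
    "make_state_preset",
    "make_composite_preset",
    "get_preset",
    "PRESET_NAMES",
    "validate_spec",
    "save_spec",
    "load_spec",
]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class KeyPose:
    """A characteristic posture: a Gaussian in abstract feature space.

    ``mean`` and ``spread`` are per-feature location and scale (length F);
    ``spread`` is the per-sample scatter of poses around the mean while the
    pose is held.
    """

    id: str
    mean: tuple[float, ...]
    spread: tuple[float, ...]

    def __post_init__(self):
        object.__setattr__(self, "mean", tuple(float(m) for m in np.atleast_1d(self.mean)))
        object.__setattr__(self, "spread", tuple(float(s) for s in np.atleast_1d(self.spread)))

    @property
    def F(self) -> int:
        return len(self.mean)


@dataclass(frozen=True)
class DurationDistribution:
    """Distribution over integer event durations (in samples).

    families:
      ``fixed``         params: value
      ``uniform-int``   params: low, high (inclusive)
      ``gamma-rounded`` params: mean, shape; samples are rounded and
                        clamped at ``minimum``
    """

    family: str
    params: dict
    minimum: int = 1

    FAMILIES = ("fixed", "uniform-int", "gamma-rounded")

    def sample(self, rng: np.random.Generator, size: Optional[int] = None):
        n = 1 if size is None else size
        if self.family == "fixed":
            out = np.full(n, int(round(self.params["value"])))
        elif self.family == "uniform-int":
            out = rng.integers(int(self.params["low"]), int(self.params["high"]) + 1, size=n)
        elif self.family == "gamma-rounded":
            shape = float(self.params.get("shape", 4.0))
            scale = float(self.params["mean"]) / shape
            out = np.rint(rng.gamma(shape, scale, size=n)).astype(int)
        else:
            raise ValueError(f"unknown duration family {self.family!r}")
        out = np.maximum(out, self.minimum).astype(int)
        return int(out[0]) if size is None else out

    def mean_duration(self) -> float:
        """Expected duration, ignoring the rounding/clamping corrections."""
        if self.family == "fixed":
            return max(float(self.params["value"]), self.minimum)
        if self.family == "uniform-int":
            return (float(self.params["low"]) + float(self.params["high"])) / 2.0
        return max(float(self.params["mean"]), float(self.minimum))


def fixed_duration(value: int, minimum: int = 1) -> DurationDistribution:
    return DurationDistribution("fixed", {"value": value}, minimum=minimum)


def gamma_duration(mean: float, shape: float = 4.0, minimum: int = 2) -> DurationDistribution:
    return DurationDistribution("gamma-rounded", {"mean": mean, "shape": shape}, minimum=minimum)


@dataclass(frozen=True)
class FluctuationSpec:
    """Within-event dynamics added on top of the held key pose.

    ``amount`` is the marginal std of a slowly varying wander (low-passed
    Gaussian noise, moving-average window ``smoothness``); ``period`` /
    ``period_amplitude`` add a sinusoid with a random phase per event.
    """

    amount: float = 0.0
    smoothness: int = 1
    period: Optional[int] = None
    period_amplitude: float = 0.0

    def is_null(self) -> bool:
        return self.amount == 0.0 and self.period is None


NULL_FLUCTUATION = FluctuationSpec()


@dataclass(frozen=True)
class Constituent:
    """One sub-event: a key pose held as a state or hit as a point event."""

    kind: str  # "state" | "point"
    key_pose: KeyPose
    duration: DurationDistribution
    fluctuation: FluctuationSpec = NULL_FLUCTUATION
    subevent_label: str = ""


def state(key_pose: KeyPose, duration: DurationDistribution,
          fluctuation: FluctuationSpec = NULL_FLUCTUATION,
          subevent_label: str = "") -> Constituent:
    return Constituent("state", key_pose, duration, fluctuation,
                       subevent_label or key_pose.id)


def point(key_pose: KeyPose, subevent_label: str = "") -> Constituent:
    # Point events occupy exactly one sample: the minimal realizable
    # duration on a sampled grid.
    return Constituent("point", key_pose, fixed_duration(1, minimum=1),
                       NULL_FLUCTUATION, subevent_label or key_pose.id)


@dataclass(frozen=True)
class Atomic:
    constituent: Constituent


@dataclass(frozen=True)
class Ordered:
    constituents: tuple[Constituent, ...]

    def __post_init__(self):
        object.__setattr__(self, "constituents", tuple(self.constituents))


@dataclass(frozen=True)
class Unordered:
    constituents: tuple[Constituent, ...]
    repeats: DurationDistribution
    weights: Optional[tuple[float, ...]] = None

    def __post_init__(self):
        object.__setattr__(self, "constituents", tuple(self.constituents))
        if self.weights is not None:
            object.__setattr__(self, "weights", tuple(float(w) for w in self.weights))


Structure = Union[Atomic, Ordered, Unordered]


@dataclass(frozen=True)
class BehaviorDefinition:
    """A named behavior: atomic, ordered sequence, or unordered repeat set."""

    label: str
    structure: Structure

    def constituents(self) -> tuple[Constituent, ...]:
        s = self.structure
        if isinstance(s, Atomic):
            return (s.constituent,)
        return s.constituents


@dataclass(frozen=True)
class EthogramSpec:
    """Full generative definition of a behavior repertoire."""

    name: str
    behaviors: tuple[BehaviorDefinition, ...]
    F: int = 1
    transition_range: tuple[int, int] = (2, 8)
    noise_sigma: float = 0.1
    transition_label: str = "b00"

    def __post_init__(self):
        object.__setattr__(self, "behaviors", tuple(self.behaviors))
        object.__setattr__(self, "transition_range",
                           (int(self.transition_range[0]), int(self.transition_range[1])))

    @property
    def labels(self) -> list[str]:
        return [b.label for b in self.behaviors]

    @property
    def all_labels(self) -> list[str]:
        """Behavior labels plus the transition label, in report order."""
        return [self.transition_label] + self.labels

    def behavior(self, label: str) -> BehaviorDefinition:
        for b in self.behaviors:
            if b.label == label:
                return b
        raise KeyError(label)

    def subevent_labels(self) -> list[str]:
        out = [self.transition_label]
        for b in self.behaviors:
            for c in b.constituents():
                if c.subevent_label not in out:
                    out.append(c.subevent_label)
        return out


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

def _validate_constituent(c: Constituent, F: int, where: str, diags: list[str]) -> None:
    kp = c.key_pose
    if kp.F != F:
        diags.append(f"{where}: key pose {kp.id!r} has {kp.F} features, spec has F={F}")
    if not all(np.isfinite(kp.mean)):
        diags.append(f"{where}: key pose {kp.id!r} mean not finite")
    if not all(s > 0 for s in kp.spread):
        diags.append(f"{where}: key pose {kp.id!r} spread must be strictly positive")
    if c.kind not in ("state", "point"):
        diags.append(f"{where}: unknown constituent kind {c.kind!r}")
    if c.kind == "point":
        if not (c.duration.family == "fixed" and int(c.duration.params.get("value", 0)) == 1):
            diags.append(f"{where}: point events must have fixed duration of 1 sample")
    elif c.duration.minimum < 2:
        diags.append(f"{where}: state events need duration minimum >= 2")
    if c.duration.family not in DurationDistribution.FAMILIES:
        diags.append(f"{where}: unknown duration family {c.duration.family!r}")
    fl = c.fluctuation
    if fl.amount < 0:
        diags.append(f"{where}: fluctuation amount must be >= 0")
    if fl.smoothness < 1:
        diags.append(f"{where}: fluctuation smoothness must be >= 1")
    if (fl.period is not None) != (fl.period_amplitude > 0):
        diags.append(f"{where}: fluctuation period must be present iff period_amplitude > 0")
    if fl.period is not None and fl.period < 2:
        diags.append(f"{where}: fluctuation period must be >= 2 samples")


def validate_spec(spec: EthogramSpec) -> list[str]:
    """Check every repertoire invariant; returns diagnostics (empty = valid)."""
    diags: list[str] = []
    if spec.F < 1:
        diags.append(f"F must be >= 1, got {spec.F}")
    lo, hi = spec.transition_range
    if not (2 <= lo <= hi):
        diags.append(f"transition_range must satisfy 2 <= min <= max, got [{lo}, {hi}]")
    if spec.noise_sigma < 0:
        diags.append(f"noise_sigma must be >= 0, got {spec.noise_sigma}")
    seen: set[str] = set()
    for b in spec.behaviors:
        if b.label in seen:
            diags.append(f"duplicate behavior label {b.label!r}")
        seen.add(b.label)
        if b.label == spec.transition_label:
            diags.append(f"behavior label {b.label!r} collides with transition label")
        s = b.structure
        if isinstance(s, Atomic):
            _validate_constituent(s.constituent, spec.F, b.label, diags)
        elif isinstance(s, Ordered):
            if len(s.constituents) < 2:
                diags.append(f"{b.label}: ordered sequences need >= 2 constituents")
            for i, c in enumerate(s.constituents):
                _validate_constituent(c, spec.F, f"{b.label}[{i}]", diags)
        elif isinstance(s, Unordered):
            if len(s.constituents) < 2:
                diags.append(f"{b.label}: unordered sets need >= 2 constituents")
            if s.weights is not None:
                if len(s.weights) != len(s.constituents):
                    diags.append(f"{b.label}: weights length != number of constituents")
                elif abs(sum(s.weights) - 1.0) > 1e-9:
                    diags.append(f"{b.label}: weights must sum to 1")
            for i, c in enumerate(s.constituents):
                _validate_constituent(c, spec.F, f"{b.label}[{i}]", diags)
        else:
            diags.append(f"{b.label}: unknown structure type {type(s).__name__}")
    return diags


# ---------------------------------------------------------------------------
# Serialization (YAML/JSON round-trip)
# ---------------------------------------------------------------------------

def _duration_to_dict(d: DurationDistribution) -> dict:
    return {"family": d.family, "params": dict(d.params), "minimum": d.minimum}


def _duration_from_dict(d: dict) -> DurationDistribution:
    return DurationDistribution(d["family"], dict(d["params"]), int(d["minimum"]))


def _fluct_to_dict(f: FluctuationSpec) -> dict:
    return {"amount": f.amount, "smoothness": f.smoothness,
            "period": f.period, "period_amplitude": f.period_amplitude}


def _fluct_from_dict(d: dict) -> FluctuationSpec:
    return FluctuationSpec(float(d["amount"]), int(d["smoothness"]),
                           None if d["period"] is None else int(d["period"]),
                           float(d["period_amplitude"]))


def _constituent_to_dict(c: Constituent) -> dict:
    return {"kind": c.kind, "key_pose": c.key_pose.id,
            "duration": _duration_to_dict(c.duration),
            "fluctuation": _fluct_to_dict(c.fluctuation),
            "subevent_label": c.subevent_label}


def _constituent_from_dict(d: dict, poses: dict[str, KeyPose]) -> Constituent:
    return Constituent(d["kind"], poses[d["key_pose"]],
                       _duration_from_dict(d["duration"]),
                       _fluct_from_dict(d["fluctuation"]),
                       d["subevent_label"])


def spec_to_dict(spec: EthogramSpec) -> dict:
    poses: dict[str, KeyPose] = {}
    for b in spec.behaviors:
        for c in b.constituents():
            prev = poses.setdefault(c.key_pose.id, c.key_pose)
            if prev != c.key_pose:
                raise ValueError(f"key pose id {c.key_pose.id!r} reused with different parameters")
    behaviors = []
    for b in spec.behaviors:
        s = b.structure
        if isinstance(s, Atomic):
            sd = {"type": "atomic", "constituent": _constituent_to_dict(s.constituent)}
        elif isinstance(s, Ordered):
            sd = {"type": "ordered",
                  "constituents": [_constituent_to_dict(c) for c in s.constituents]}
        else:
            sd = {"type": "unordered",
                  "constituents": [_constituent_to_dict(c) for c in s.constituents],
                  "repeats": _duration_to_dict(s.repeats),
                  "weights": None if s.weights is None else list(s.weights)}
        behaviors.append({"label": b.label, "structure": sd})
    return {
        "name": spec.name,
        "F": spec.F,
        "transition_range": list(spec.transition_range),
        "noise_sigma": spec.noise_sigma,
        "transition_label": spec.transition_label,
        "key_poses": [{"id": p.id, "mean": list(p.mean), "spread": list(p.spread)}
                      for p in poses.values()],
        "behaviors": behaviors,
    }


def spec_from_dict(d: dict) -> EthogramSpec:
    poses = {p["id"]: KeyPose(p["id"], tuple(p["mean"]), tuple(p["spread"]))
             for p in d["key_poses"]}
    behaviors = []
    for bd in d["behaviors"]:
        sd = bd["structure"]
        if sd["type"] == "atomic":
            s: Structure = Atomic(_constituent_from_dict(sd["constituent"], poses))
        elif sd["type"] == "ordered":
            s = Ordered(tuple(_constituent_from_dict(c, poses) for c in sd["constituents"]))
        elif sd["type"] == "unordered":
            s = Unordered(tuple(_constituent_from_dict(c, poses) for c in sd["constituents"]),
                          _duration_from_dict(sd["repeats"]),
                          None if sd.get("weights") is None else tuple(sd["weights"]))
        else:
            raise ValueError(f"unknown structure type {sd['type']!r}")
        behaviors.append(BehaviorDefinition(bd["label"], s))
    return EthogramSpec(d["name"], tuple(behaviors), int(d["F"]),
                        tuple(d["transition_range"]), float(d["noise_sigma"]),
                        d["transition_label"])


def save_spec(spec: EthogramSpec, path: Union[str, Path]) -> None:
    path = Path(path)
    doc = spec_to_dict(spec)
    if path.suffix in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(doc, sort_keys=False))
    else:
        path.write_text(json.dumps(doc, indent=2))


def load_spec(path: Union[str, Path]) -> EthogramSpec:
    path = Path(path)
    text = path.read_text()
    doc = yaml.safe_load(text) if path.suffix in (".yaml", ".yml") else json.loads(text)
    return spec_from_dict(doc)


# ---------------------------------------------------------------------------
# Presets
# ---------------------------------------------------------------------------
#
# Preset constants are fixed once for the released repertoires.  They are
# chosen so that the closed-form single-sample Bayes errors realize the
# intended confusion structure: the sanity pair b01/b02 is near-perfectly
# separable (< 1% error) while the look-alike pair b03/b04 overlaps heavily
# (> 25% error), duration is the only cue separating b06 from b07, and
# periodicity is the only cue separating b08/b09 from b10.

_WANDER = FluctuationSpec(amount=0.15, smoothness=8)


def _atomic_state(label: str, pose: KeyPose, duration: DurationDistribution,
                  fluct: FluctuationSpec = _WANDER) -> BehaviorDefinition:
    return BehaviorDefinition(label, Atomic(state(pose, duration, fluct, subevent_label=label)))


def make_state_preset() -> EthogramSpec:
    """Repertoire of ten atomic state behaviors (b01-b10).

    Confusion structure on the single pose axis:

    * b01/b02 — key poses far apart relative to spread (sanity check).
    * b03/b04 — key poses ~1 spread apart (confusion group 1).
    * b05 — unordered mixture of two well-separated sub-poses.
    * b06/b07 — identical key pose; long (mean 100) vs short (mean 9)
      durations (confusion group 2): duration is the only separating cue,
      and both means exceed the models' window scale so the cue is
      invisible to windowed classification.
    * b08/b09/b10 — identical pose location; b08/b09 carry sinusoidal
      within-event periodicity (periods 6 and 12), b10 is aperiodic with a
      wider spread matching their marginal (confusion group 3): periodicity
      is the only separating cue.
    """
    dur = gamma_duration(20.0)
    p01 = KeyPose("k01", (-12.0,), (1.0,))
    p02 = KeyPose("k02", (12.0,), (1.0,))
    # look-alike pair: the overlap lives in *slow within-event wander*
    # (event-level pose variation), not in per-sample scatter, so temporal
    # averaging over a window cannot separate the two classes
    p03 = KeyPose("k03", (2.0,), (0.35,))
    p04 = KeyPose("k04", (3.0,), (0.35,))
    slow = FluctuationSpec(amount=0.95, smoothness=30)
    p05a = KeyPose("k05a", (-5.5,), (0.8,))
    p05b = KeyPose("k05b", (-7.5,), (0.8,))
    p67 = KeyPose("k67", (7.0,), (1.0,))
    # periodic pair: small scatter keeps the class-specific sinusoid
    # visible; the aperiodic b10 matches their *marginal* variance
    # (0.3^2 + amplitude^2/2) so only the dynamics separate the group
    p89 = KeyPose("k89", (-2.0,), (0.3,))
    p10 = KeyPose("k10", (-2.0,), (float(np.sqrt(0.3 ** 2 + 0.5)),))

    per6 = FluctuationSpec(amount=0.1, smoothness=8, period=6, period_amplitude=1.0)
    per12 = FluctuationSpec(amount=0.1, smoothness=8, period=12, period_amplitude=1.0)

    b05 = BehaviorDefinition("b05", Unordered(
        (state(p05a, gamma_duration(10.0), _WANDER, "b05_a"),
         state(p05b, gamma_duration(10.0), _WANDER, "b05_b")),
        repeats=DurationDistribution("uniform-int", {"low": 2, "high": 4}),
        weights=(0.5, 0.5)))

    behaviors = (
        _atomic_state("b01", p01, dur),
        _atomic_state("b02", p02, dur),
        _atomic_state("b03", p03, dur, slow),
        _atomic_state("b04", p04, dur, slow),
        b05,
        _atomic_state("b06", p67, gamma_duration(100.0)),
        _atomic_state("b07", p67, gamma_duration(9.0)),
        _atomic_state("b08", p89, dur, per6),
        _atomic_state("b09", p89, dur, per12),
        _atomic_state("b10", p10, dur, FluctuationSpec(amount=0.1, smoothness=8)),
    )
    return EthogramSpec("state", behaviors)


def make_composite_preset() -> EthogramSpec:
    """Repertoire with point events and composite behaviors (b11-b16).

    * b01/b02 — well separated atomic states (sanity check).
    * b11 — a point behavior (one-sample key pose) overlapping the state
      behavior b12; its surrounding samples are transitions.
    * b13 — an unordered repeat sequence over sub-poses {A, B, X} where X
      *is* b14's key pose, so X samples overlap both b12 and b14
      (confusion group 4).
    * b15 — an ordered point-state-point triple (take-off, stretched pose,
      landing) whose middle constituent's key pose is shared with the
      ordered state triple b16 (confusion group 5).
    """
    dur = gamma_duration(20.0)
    p01 = KeyPose("k01", (-12.0,), (1.0,))
    p02 = KeyPose("k02", (12.0,), (1.0,))
    k12 = KeyPose("k12", (0.0,), (1.0,))
    k11 = KeyPose("k11", (0.8,), (0.8,))
    kx = KeyPose("kx", (2.5,), (1.2,))       # shared by b13's X and b14
    k13a = KeyPose("k13a", (-4.5,), (0.8,))
    k13b = KeyPose("k13b", (-7.0,), (0.8,))
    kto = KeyPose("kto", (6.0,), (0.7,))     # take-off / landing pose
    kst = KeyPose("kst", (8.5,), (0.7,))     # stretched pose, shared b15/b16
    k16 = KeyPose("k16", (5.0,), (0.7,))     # walk bracketing pose

    b11 = BehaviorDefinition("b11", Atomic(point(k11, "b11_peak")))
    # shared sub-state bouts outlast both models' context windows (mean
    # 30 vs windows of 12-20 samples), so a window interior to b13's X
    # bout, to a b14 event, or to the shared stretched pose of b15/b16 is
    # identical across the group: only out-of-window context could tell
    # the parents apart
    b13 = BehaviorDefinition("b13", Unordered(
        (state(k13a, gamma_duration(30.0), _WANDER, "b13_A"),
         state(k13b, gamma_duration(30.0), _WANDER, "b13_B"),
         state(kx, gamma_duration(30.0), _WANDER, "b13_X")),
        repeats=DurationDistribution("uniform-int", {"low": 3, "high": 4}),
        weights=(0.25, 0.25, 0.5)))
    b15 = BehaviorDefinition("b15", Ordered(
        (point(kto, "b15_takeoff"),
         state(kst, gamma_duration(30.0, minimum=3), _WANDER, "b15_stretch"),
         point(kto, "b15_landing"))))
    b16 = BehaviorDefinition("b16", Ordered(
        (state(k16, gamma_duration(8.0), _WANDER, "b16_P"),
         state(kst, gamma_duration(30.0, minimum=3), _WANDER, "b16_X"),
         state(k16, gamma_duration(8.0), _WANDER, "b16_Q"))))

    behaviors = (
        _atomic_state("b01", p01, dur),
        _atomic_state("b02", p02, dur),
        b11,
        _atomic_state("b12", k12, dur),
        b13,
        _atomic_state("b14", kx, gamma_duration(30.0)),
        b15,
        b16,
    )
    return EthogramSpec("composite", behaviors)


PRESET_NAMES = ("state", "composite")


def get_preset(name: str) -> EthogramSpec:
    if name == "state":
        return make_state_preset()
    if name == "composite":
        return make_composite_preset()
    raise KeyError(f"unknown preset {name!r}; available: {PRESET_NAMES}")
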