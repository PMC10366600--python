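"""Simulator: event sampling, rendering, transitions, noise, I/O."""

import numpy as np
import pytest

from ethosim.ethogram import FluctuationSpec
from ethosim.simulator import (GeneratedSeries, SeriesParseError,
                               add_observation_noise, apply_fluctuations,
                               generate_dataset, make_transition,
                               merge_transition_labels, read_series,
                               realize_event, sample_event_sequence,
                               write_series)


def b00_run_lengths(series):
    runs, cur = [], 0
    for lab in series.behavior_labels:
        if lab == "b00":
            cur += 1
        elif cur:
            runs.append(cur)
            cur = 0
    if cur:
        runs.append(cur)
    return runs


class TestEventSequence:
    def test_single_event(self, state_spec, rng):
        seq = sample_event_sequence(state_spec, 1, rng)
        assert len(seq) == 1 and seq[0] in state_spec.labels

    def test_uniform_frequencies(self, state_spec, rng):
        """Each behavior's frequency within 3 standard errors of 1/10."""
        n = 10_000
        seq = sample_event_sequence(state_spec, n, rng)
        p = 1 / len(state_spec.labels)
        se = np.sqrt(p * (1 - p) / n)
        for lab in state_spec.labels:
            freq = seq.count(lab) / n
            assert abs(freq - p) < 3.5 * se, lab

    def test_no_immediate_repeats(self, state_spec, rng):
        seq = sample_event_sequence(state_spec, 5000, rng)
        assert all(a != b for a, b in zip(seq, seq[1:]))

    def test_empty_spec_errors(self, state_spec, rng):
        import dataclasses
        empty = dataclasses.replace(state_spec, behaviors=())
        with pytest.raises(ValueError):
            sample_event_sequence(empty, 5, rng)


class TestRealizeEvent:
    def test_point_event_single_sample(self, composite_spec, rng):
        seg, subevents = realize_event(composite_spec.behavior("b11"),
                                       composite_spec, rng)
        assert seg.shape == (1, 1)
        assert subevents == [("b11_peak", 0, 1)]

    def test_ordered_includes_internal_transitions(self, composite_spec, rng):
        seg, subevents = realize_event(composite_spec.behavior("b15"),
                                       composite_spec, rng)
        kinds = [s for s, _, _ in subevents]
        assert kinds == ["b15_takeoff", "b00", "b15_stretch", "b00", "b15_landing"]
        # tiling covers [0, len) without gaps
        assert subevents[0][1] == 0 and subevents[-1][2] == len(seg)
        for (_, _, e), (_, s, _) in zip(subevents, subevents[1:]):
            assert e == s

    def test_degenerate_state_equals_mean(self, state_spec, rng):
        """With zero spread and no fluctuation, samples sit on the mean."""
        import dataclasses
        from ethosim.ethogram import Atomic, KeyPose
        b = state_spec.behavior("b01")
        c = b.structure.constituent
        tiny = dataclasses.replace(
            c, key_pose=KeyPose("k", (3.0,), (1e-12,)),
            fluctuation=FluctuationSpec())
        beh = dataclasses.replace(b, structure=Atomic(tiny))
        seg, _ = realize_event(beh, state_spec, rng)
        assert np.allclose(seg, 3.0, atol=1e-9)

    def test_unordered_avoids_repeat_subposes(self, composite_spec, rng):
        for _ in range(20):
            _, subevents = realize_event(composite_spec.behavior("b13"),
                                         composite_spec, rng)
            labs = [s for s, _, _ in subevents if s != "b00"]
            assert all(a != b for a, b in zip(labs, labs[1:]))


class TestTransitions:
    def test_zero_displacement(self, rng):
        seg = make_transition(np.array([1.5]), np.array([1.5]), 4, rng,
                              scatter=0.0)
        assert np.allclose(seg, 1.5)

    def test_monotone_interior(self, rng):
        seg = make_transition(np.array([0.0]), np.array([1.0]), 5, rng,
                              scatter=0.0)[:, 0]
        assert np.all(np.diff(seg) > 0)
        assert np.all((seg > 0) & (seg < 1))

    def test_length_bounds_enforced(self, rng):
        with pytest.raises(ValueError):
            make_transition(np.zeros(1), np.ones(1), 1, rng)

    def test_empirical_length_bounds(self, state_spec):
        series = generate_dataset(state_spec, 1000, seed=5)
        runs = b00_run_lengths(series)
        assert min(runs) >= 2 and max(runs) <= 8


class TestFluctuations:
    def test_identity_when_null(self, rng):
        seg = np.ones((50, 1))
        out = apply_fluctuations(seg, FluctuationSpec(), rng)
        assert np.array_equal(out, seg)

    def test_periodic_spectrum_peak(self, rng):
        """A period-6 sinusoid dominates the spectrum at frequency 1/6."""
        fl = FluctuationSpec(amount=0.0, period=6, period_amplitude=1.0)
        seg = apply_fluctuations(np.zeros((600, 1)), fl, rng)[:, 0]
        spectrum = np.abs(np.fft.rfft(seg))
        freqs = np.fft.rfftfreq(600)
        assert abs(freqs[np.argmax(spectrum[1:]) + 1] - 1 / 6) < 1e-3

    def test_wander_is_smooth(self, rng):
        """Lag-1 autocorrelation of a window-10 moving average exceeds the
        closed-form value 0.9 minus sampling slack."""
        fl = FluctuationSpec(amount=1.0, smoothness=10)
        seg = apply_fluctuations(np.zeros((20_000, 1)), fl, rng)[:, 0]
        inner = seg[50:-50]
        ac1 = np.corrcoef(inner[:-1], inner[1:])[0, 1]
        assert ac1 > 0.8

    def test_wander_marginal_std(self, rng):
        fl = FluctuationSpec(amount=0.7, smoothness=8)
        seg = apply_fluctuations(np.zeros((50_000, 1)), fl, rng)[:, 0]
        assert abs(np.std(seg) - 0.7) < 0.05


class TestObservationNoise:
    def test_zero_sigma_identity(self, rng):
        x = np.arange(12.0).reshape(-1, 1)
        assert np.array_equal(add_observation_noise(x, 0.0, rng), x)

    def test_noise_std(self, rng):
        x = np.zeros((10_000, 1))
        noisy = add_observation_noise(x, 1.0, rng)
        assert 0.97 < np.std(noisy) < 1.03

    def test_negative_sigma_errors(self, rng):
        with pytest.raises(ValueError):
            add_observation_noise(np.zeros((2, 1)), -0.1, rng)


class TestGenerateDataset:
    def test_deterministic(self, state_spec):
        a = generate_dataset(state_spec, 60, seed=7)
        b = generate_dataset(state_spec, 60, seed=7)
        assert a == b

    def test_different_seeds_differ(self, state_spec):
        a = generate_dataset(state_spec, 60, seed=7)
        b = generate_dataset(state_spec, 60, seed=8)
        assert not np.array_equal(a.features, b.features)

    def test_label_partition(self, small_state_series, state_spec):
        """Every sample has exactly one behavior label; event label runs
        match the event table; transitions lie strictly between events."""
        s = small_state_series
        assert len(s.behavior_labels) == len(s.features) == len(s.subevent_labels)
        for e in s.events:
            assert np.all(s.behavior_labels[e.start:e.end] == e.behavior_label)
        # boundaries: first and last samples belong to events, not b00
        assert s.behavior_labels[0] != "b00"
        assert s.behavior_labels[-1] != "b00"

    def test_subevents_tile_events(self, small_composite_series):
        for e in small_composite_series.events:
            assert e.subevents[0][1] == e.start
            assert e.subevents[-1][2] == e.end
            for (_, _, b), (_, a, _) in zip(e.subevents, e.subevents[1:]):
                assert b == a

    def test_point_behavior_one_sample(self, composite_spec):
        series = generate_dataset(composite_spec, 1000, seed=3)
        for e in series.events:
            if e.behavior_label == "b11":
                assert e.end - e.start == 1
                assert series.subevent_labels[e.start] == "b11_peak"

    def test_duration_ratio_b06_b07(self, state_spec):
        series = generate_dataset(state_spec, 1000, seed=9)
        d6 = [e.end - e.start for e in series.events if e.behavior_label == "b06"]
        d7 = [e.end - e.start for e in series.events if e.behavior_label == "b07"]
        assert np.mean(d6) / np.mean(d7) >= 10

    def test_merge_transitions(self, small_state_series):
        merged = merge_transition_labels(small_state_series)
        assert "b00" not in merged.behavior_labels
        # non-transition samples keep their label
        keep = small_state_series.behavior_labels != "b00"
        assert np.array_equal(merged.behavior_labels[keep],
                              small_state_series.behavior_labels[keep])


class TestSeriesIO:
    def test_roundtrip(self, small_state_series, tmp_path):
        p = tmp_path / "series.csv"
        write_series(small_state_series, p)
        assert read_series(p) == small_state_series

    def test_column_count(self, small_state_series, tmp_path):
        p = tmp_path / "series.csv"
        write_series(small_state_series, p)
        header = p.read_text().splitlines()[0]
        assert header.split(",") == ["t", "f0", "behavior", "subevent"]

    def test_missing_label_column_errors(self, small_state_series, tmp_path):
        p = tmp_path / "series.csv"
        write_series(small_state_series, p)
        lines = p.read_text().splitlines()
        header = lines[0].split(",")
        keep = [i for i, c in enumerate(header) if c != "behavior"]
        broken = "\n".join(",".join(l.split(",")[i] for i in keep)
                           for l in lines)
        p.write_text(broken)
        with pytest.raises(SeriesParseError):
            read_series(p)

    def test_bytes_deterministic(self, state_spec, tmp_path):
        a, b = tmp_path / "a.csv", tmp_path / "b.csv"
        write_series(generate_dataset(state_spec, 40, seed=3), a)
        write_series(generate_dataset(state_spec, 40, seed=3), b)
        assert a.read_bytes() == b.read_bytes()


class TestPropertyBased:
    """Randomized invariants via hypothesis (derandomized)."""

    from hypothesis import given, settings, strategies as st

    @staticmethod
    @given(prev=st.floats(-20, 20), nxt=st.floats(-20, 20),
           length=st.integers(2, 8))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_transition_stays_between_endpoints(prev, nxt, length):
        import numpy as np
        from ethosim.simulator import make_transition
        rng = np.random.default_rng(0)
        seg = make_transition(np.array([prev]), np.array([nxt]), length, rng,
                              scatter=0.0)[:, 0]
        lo, hi = min(prev, nxt), max(prev, nxt)
        assert np.all(seg >= lo - 1e-9) and np.all(seg <= hi + 1e-9)
        assert len(seg) == length

    @staticmethod
    @given(mean=st.floats(1.0, 50.0), shape=st.floats(0.5, 10.0),
           minimum=st.integers(1, 5))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_sampled_durations_respect_minimum(mean, shape, minimum):
        import numpy as np
        from ethosim.ethogram import DurationDistribution
        d = DurationDistribution("gamma-rounded",
                                 {"mean": mean, "shape": shape}, minimum)
        s = d.sample(np.random.default_rng(1), size=500)
        assert s.min() >= minimum
        assert np.issubdtype(s.dtype, np.integer)
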