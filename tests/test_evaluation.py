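"""Confusion matrices, group summaries, and the Bayes oracle."""

import numpy as np
import pytest

from ethosim.evaluation import (ConfusionGroup, bayes_oracle, confusion_matrix,
                                group_report, preset_confusion_groups, recalls,
                                subevent_confusion)


class TestConfusionMatrix:
    def test_perfect_predictions_identity(self):
        labels = ["a", "b", "c"]
        t = ["a", "b", "c", "a", "b"]
        rep = confusion_matrix(t, t, labels)
        assert np.allclose(rep.matrix[:3], np.eye(3))

    def test_rows_normalized(self, rng):
        labels = ["a", "b", "c"]
        t = rng.choice(labels, 500)
        p = rng.choice(labels, 500)
        rep = confusion_matrix(t, p, labels)
        assert np.allclose(rep.matrix.sum(axis=1), 1.0, atol=1e-9)
        assert rep.support.sum() == 500

    def test_uniform_random_predictions(self, rng):
        """Single true class, uniform predictions: each column ~ 1/k."""
        labels = ["a", "b", "c", "d"]
        n = 40_000
        t = ["a"] * n
        p = rng.choice(labels, n)
        rep = confusion_matrix(t, p, labels)
        assert np.allclose(rep.matrix[0], 0.25, atol=0.01)

    def test_zero_support_row_is_zero(self):
        rep = confusion_matrix(["a"], ["a"], ["a", "b"])
        assert rep.support[1] == 0
        assert np.all(rep.matrix[1] == 0)

    def test_unknown_label_errors(self):
        with pytest.raises(ValueError):
            confusion_matrix(["x"], ["a"], ["a", "b"])

    def test_permutation_invariance(self, rng):
        labels = ["a", "b", "c"]
        t = rng.choice(labels, 300)
        p = rng.choice(labels, 300)
        r1 = confusion_matrix(t, p, labels)
        r2 = confusion_matrix(t, p, labels[::-1])
        for i, li in enumerate(labels):
            for j, lj in enumerate(labels):
                assert r1.matrix[i, j] == r2.matrix[2 - i, 2 - j]


class TestSubeventConfusion:
    def test_rows_for_ordered_composite(self, small_composite_series,
                                        composite_spec):
        pred = small_composite_series.behavior_labels  # perfect predictions
        rep = subevent_confusion(small_composite_series, pred, composite_spec)
        b15_rows = [l for l in rep.labels if l.startswith("b15")]
        assert sorted(b15_rows) == ["b15_landing", "b15_stretch", "b15_takeoff"]

    def test_perfect_predictions_concentrate_on_parent(
            self, small_composite_series, composite_spec):
        pred = small_composite_series.behavior_labels
        rep = subevent_confusion(small_composite_series, pred, composite_spec)
        i = rep.labels.index("b13_X")
        j = rep.pred_labels.index("b13")
        assert rep.matrix[i, j] == pytest.approx(1.0)

    def test_length_mismatch_errors(self, small_composite_series):
        with pytest.raises(ValueError):
            subevent_confusion(small_composite_series, ["b01"])


class TestGroupReport:
    def test_identity_matrix_zero_mass(self):
        labels = ["a", "b", "c"]
        rep = confusion_matrix(["a", "b", "c"], ["a", "b", "c"], labels)
        out = group_report(rep, [ConfusionGroup("g", frozenset({"a", "b"}))])
        assert out["g"]["weighted"] == 0.0

    def test_hand_computed_two_member_group(self):
        t = ["a", "a", "b", "b"]
        p = ["a", "b", "b", "a"]
        rep = confusion_matrix(t, p, ["a", "b"])
        out = group_report(rep, [ConfusionGroup("g", frozenset({"a", "b"}))])
        assert out["g"]["weighted"] == pytest.approx(0.5)
        assert out["g"]["unweighted"] == pytest.approx(0.5)

    def test_equals_bruteforce_sum(self, rng):
        labels = ["a", "b", "c", "d"]
        t = rng.choice(labels, 1000)
        p = rng.choice(labels, 1000)
        rep = confusion_matrix(t, p, labels)
        members = {"b", "d"}
        out = group_report(rep, [ConfusionGroup("g", frozenset(members))])
        num = den = 0.0
        for i, li in enumerate(labels):
            if li not in members:
                continue
            mass = sum(rep.matrix[i, labels.index(lj)]
                       for lj in members if lj != li)
            num += rep.support[i] * mass
            den += rep.support[i]
        assert out["g"]["weighted"] == pytest.approx(num / den)

    def test_relabeling_within_group_invariant(self, rng):
        """Swapping the two members' identities preserves the group mass."""
        labels = ["a", "b", "c"]
        t = rng.choice(labels, 500, p=[0.4, 0.4, 0.2])
        p = rng.choice(labels, 500)
        swap = {"a": "b", "b": "a", "c": "c"}
        r1 = confusion_matrix(t, p, labels)
        r2 = confusion_matrix([swap[x] for x in t], [swap[x] for x in p], labels)
        g = [ConfusionGroup("g", frozenset({"a", "b"}))]
        assert group_report(r1, g)["g"]["weighted"] == pytest.approx(
            group_report(r2, g)["g"]["weighted"])

    def test_preset_groups(self):
        state = {g.name: g.members for g in preset_confusion_groups("state")}
        assert state["group1"] == {"b03", "b04"}
        assert state["group3"] == {"b08", "b09", "b10"}
        comp = {g.name: g.members for g in preset_confusion_groups("composite")}
        assert comp["group5"] == {"b15", "b16"}


class TestBayesOracle:
    def test_pair_error_bounds(self, state_spec):
        oracle = bayes_oracle(state_spec)
        assert oracle.pair_error("b01", "b02") < 0.01
        assert oracle.pair_error("b03", "b04") > 0.25
        # identical-pose pair: error approaches the maximum 0.5
        assert oracle.pair_error("b06", "b07") > 0.45

    @pytest.mark.parametrize("pair", [("b01", "b02"), ("b03", "b04"),
                                      ("b08", "b10")])
    def test_integration_matches_monte_carlo(self, state_spec, pair, rng):
        """1-D quadrature vs simulation from the generative marginal."""
        oracle = bayes_oracle(state_spec)
        integral = oracle.pair_error(*pair)
        mc = oracle.mc_pair_error(*pair, n=200_000, rng=rng)
        assert abs(integral - mc) < 3e-3

    def test_classifier_on_easy_class(self, state_spec, rng):
        oracle = bayes_oracle(state_spec)
        x = oracle.sample("b01", 5000, rng)
        assert np.mean(oracle.classify(x) == "b01") >= 0.99

    def test_error_table_symmetry(self, composite_spec):
        tbl = bayes_oracle(composite_spec).error_table()
        assert np.allclose(tbl.values, tbl.values.T)
        assert np.all(np.diag(tbl.values) == 0)

    def test_multifeature_unsupported(self, state_spec):
        import dataclasses
        with pytest.raises(ValueError):
            bayes_oracle(dataclasses.replace(state_spec, F=2))


def test_confusion_heatmap_smoke(tmp_path, rng):
    """Heatmap export writes a file and outlines the groups."""
    pytest.importorskip("matplotlib")
    from ethosim.evaluation import plot_confusion
    labels = ["b03", "b04", "b05"]
    t = rng.choice(labels, 200)
    p = rng.choice(labels, 200)
    rep = confusion_matrix(t, p, labels)
    out = tmp_path / "cm.png"
    plot_confusion(rep, out, groups=[ConfusionGroup("g", frozenset({"b03", "b04"}))])
    assert out.stat().st_size > 0


def test_confusion_exclude_transition_rows(rng):
    labels = ["b00", "a", "b"]
    t = ["b00", "a", "a", "b", "b00"]
    p = ["a", "a", "b00", "b", "b"]
    rep = confusion_matrix(t, p, labels, exclude=("b00",))
    assert rep.labels == ["a", "b"]
    assert rep.pred_labels == labels          # b00 kept as a column
    assert rep.support.sum() == 3             # the two b00 rows dropped
    i, j = rep.labels.index("a"), rep.pred_labels.index("b00")
    assert rep.matrix[i, j] == pytest.approx(0.5)


def test_bootstrap_recall_ci_brackets_point_estimate(rng):
    from ethosim.evaluation import bootstrap_recall_ci
    t = ["x"] * 200 + ["y"] * 100
    p = ["x"] * 150 + ["y"] * 50 + ["y"] * 100
    lo, hi = bootstrap_recall_ci(t, p, "x", n_boot=500, rng=rng)
    assert lo <= 0.75 <= hi
    assert 0 <= lo < hi <= 1
    with pytest.raises(ValueError):
        bootstrap_recall_ci(t, p, "missing", rng=rng)
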