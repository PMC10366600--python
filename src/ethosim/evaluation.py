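"""Per-sample evaluation: confusion matrices, confusion groups, Bayes oracle.

The central measurement is a row-normalized per-sample confusion matrix at
the behavior level (optionally at the sub-event level), summarized over
*confusion groups*: sets of behaviors deliberately constructed to overlap
in pose, duration or structure.  A closed-form Bayes-optimal single-sample
classifier — computable because the generative pose densities are known —
provides the context-free upper bound: it cannot use duration, periodicity
or sequence context, so any model accuracy above it on those groups
demonstrates learned temporal context.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import confusion_matrix as _sk_confusion

from .ethogram import Atomic, BehaviorDefinition, EthogramSpec, Ordered, Unordered
from .simulator import GeneratedSeries

__all__ = [
    "ConfusionReport",
    "ConfusionGroup",
    "confusion_matrix",
    "subevent_confusion",
    "group_report",
    "recalls",
    "bootstrap_recall_ci",
    "BayesOracle",
    "bayes_oracle",
    "preset_confusion_groups",
    "plot_confusion",
]


# ---------------------------------------------------------------------------
# Confusion matrices
# ---------------------------------------------------------------------------

@dataclass
class ConfusionReport:
    """Row-normalized per-sample confusion matrix.

    ``labels`` index the rows (true classes), ``pred_labels`` the columns
    (predicted classes); for behavior-level reports they coincide.  Rows
    with zero support are all-zero.
    """

    labels: list[str]
    pred_labels: list[str]
    matrix: np.ndarray        # (len(labels), len(pred_labels)), rows sum to 1
    support: np.ndarray       # per-row true sample counts
    level: str = "behavior"

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.labels, columns=self.pred_labels)

    def recall(self, label: str) -> float:
        """Diagonal entry for ``label`` (requires label in both axes)."""
        i = self.labels.index(label)
        j = self.pred_labels.index(label)
        return float(self.matrix[i, j])

    def save_csv(self, path) -> None:
        df = self.to_dataframe()
        df.insert(0, "support", self.support)
        df.to_csv(path)


def _check_known(values: np.ndarray, labels: Sequence[str], what: str) -> None:
    unknown = set(np.unique(values)) - set(labels)
    if unknown:
        raise ValueError(f"unknown {what} label(s): {sorted(unknown)}")


def _row_normalize(counts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    support = counts.sum(axis=1)
    denom = np.where(support > 0, support, 1)
    return counts / denom[:, None], support


def confusion_matrix(true_labels: Iterable[str], pred_labels: Iterable[str],
                     labels: Sequence[str], level: str = "behavior",
                     exclude: Sequence[str] = ()) -> ConfusionReport:
    """Count-then-row-normalize confusion matrix over a fixed label order.

    ``exclude`` drops samples whose *true* label is in the given set
    (typically the transition class) from the rows; the excluded labels
    remain available as prediction columns.
    """
    t = np.asarray(list(true_labels), dtype=str)
    p = np.asarray(list(pred_labels), dtype=str)
    if t.shape != p.shape:
        raise ValueError("true and predicted label sequences differ in length")
    _check_known(t, labels, "true")
    _check_known(p, labels, "predicted")
    if exclude:
        keep = ~np.isin(t, list(exclude))
        t, p = t[keep], p[keep]
        row_labels = [l for l in labels if l not in set(exclude)]
    else:
        row_labels = list(labels)
    counts = _sk_confusion(t, p, labels=list(labels)).astype(float)
    rows = [list(labels).index(l) for l in row_labels]
    matrix, support = _row_normalize(counts[rows])
    return ConfusionReport(row_labels, list(labels), matrix, support, level)


def subevent_confusion(series: GeneratedSeries, pred_labels: Iterable[str],
                       spec: Optional[EthogramSpec] = None) -> ConfusionReport:
    """Confusion of true *sub-event* labels against predicted behavior labels.

    Rows are the constituent-level ground truth (e.g. a composite
    behavior's take-off / held pose / landing plus internal transitions),
    columns the behavior-level predictions — exposing which constituent of
    a composite behavior absorbs the confusion.
    """
    p = np.asarray(list(pred_labels), dtype=str)
    if len(p) != len(series):
        raise ValueError("prediction length does not match series length")
    t = series.subevent_labels
    row_labels = (spec.subevent_labels() if spec is not None
                  else sorted(set(t.tolist())))
    col_labels = (spec.all_labels if spec is not None
                  else sorted(set(p.tolist())))
    _check_known(t, row_labels, "sub-event")
    _check_known(p, col_labels, "predicted")
    r_index = {l: i for i, l in enumerate(row_labels)}
    c_index = {l: i for i, l in enumerate(col_labels)}
    counts = np.zeros((len(row_labels), len(col_labels)))
    np.add.at(counts, ([r_index[x] for x in t], [c_index[x] for x in p]), 1.0)
    matrix, support = _row_normalize(counts)
    return ConfusionReport(row_labels, col_labels, matrix, support, "subevent")


# ---------------------------------------------------------------------------
# Confusion groups
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConfusionGroup:
    name: str
    members: frozenset[str]


def preset_confusion_groups(preset: str) -> list[ConfusionGroup]:
    """The deliberately-overlapping class groups of the shipped presets."""
    if preset == "state":
        return [ConfusionGroup("group1", frozenset({"b03", "b04"})),
                ConfusionGroup("group2", frozenset({"b06", "b07"})),
                ConfusionGroup("group3", frozenset({"b08", "b09", "b10"}))]
    if preset == "composite":
        return [ConfusionGroup("group4", frozenset({"b13", "b14"})),
                ConfusionGroup("group5", frozenset({"b15", "b16"}))]
    raise KeyError(f"no confusion groups defined for preset {preset!r}")


def group_report(report: ConfusionReport, groups: Iterable[ConfusionGroup]) -> dict[str, dict]:
    """Within-group off-diagonal confusion mass, per group.

    For each member row, the off-diagonal row mass landing on *other*
    members of the same group; summarized support-weighted (primary) and
    unweighted.
    """
    out: dict[str, dict] = {}
    for g in groups:
        missing = g.members - set(report.labels)
        if missing:
            raise ValueError(f"group {g.name}: labels not in report: {sorted(missing)}")
        masses, weights = [], []
        for lab in sorted(g.members):
            i = report.labels.index(lab)
            if report.support[i] == 0:
                continue
            mass = sum(report.matrix[i, report.pred_labels.index(c)]
                       for c in g.members if c != lab and c in report.pred_labels)
            masses.append(mass)
            weights.append(report.support[i])
        if masses:
            w = np.asarray(weights, dtype=float)
            weighted = float(np.average(masses, weights=w))
            unweighted = float(np.mean(masses))
        else:
            weighted = unweighted = float("nan")
        out[g.name] = {"weighted": weighted, "unweighted": unweighted,
                       "members": sorted(g.members)}
    return out


def recalls(report: ConfusionReport) -> dict[str, float]:
    return {lab: report.recall(lab) for lab in report.labels
            if lab in report.pred_labels}


def bootstrap_recall_ci(true_labels, pred_labels, label: str,
                        n_boot: int = 1000, alpha: float = 0.05,
                        rng: Optional[np.random.Generator] = None
                        ) -> tuple[float, float]:
    """Percentile bootstrap confidence interval for one class's recall.

    Resamples the class's samples with replacement; a descriptive
    utility, not a significance test (per-sample resampling ignores the
    within-event correlation of neighboring samples).
    """
    rng = rng or np.random.default_rng(0)
    t = np.asarray(list(true_labels), dtype=str)
    p = np.asarray(list(pred_labels), dtype=str)
    hits = (p == label)[t == label]
    if hits.size == 0:
        raise ValueError(f"no samples with true label {label!r}")
    boots = rng.choice(hits, size=(n_boot, hits.size)).mean(axis=1)
    lo, hi = np.quantile(boots, [alpha / 2, 1 - alpha / 2])
    return float(lo), float(hi)


# ---------------------------------------------------------------------------
# Bayes oracle
# ---------------------------------------------------------------------------

_N_PHASE = 256  # quadrature points for the periodic component


def _constituent_mixture(b: BehaviorDefinition) -> list[tuple[float, object]]:
    """(weight, constituent) pairs ∝ expected per-sample share of each
    constituent, marginalizing over the behavior's structure (internal
    transitions excluded)."""
    s = b.structure
    if isinstance(s, Atomic):
        return [(1.0, s.constituent)]
    if isinstance(s, Ordered):
        pairs = [(c.duration.mean_duration(), c) for c in s.constituents]
    else:
        assert isinstance(s, Unordered)
        w = (np.full(len(s.constituents), 1.0 / len(s.constituents))
             if s.weights is None else np.asarray(s.weights, dtype=float))
        pairs = [(wi * c.duration.mean_duration(), c)
                 for wi, c in zip(w, s.constituents)]
    total = sum(w for w, _ in pairs)
    return [(w / total, c) for w, c in pairs]


class BayesOracle:
    """Bayes-optimal *single-sample* classifier from the known densities.

    Each behavior's marginal sample density is a mixture over its
    constituents of a Gaussian (key-pose spread ⊕ wander ⊕ observation
    noise) convolved, for periodic constituents, with the random-phase
    sinusoid's marginal.  Classification is maximum likelihood under a
    uniform class prior.  By construction the oracle sees one sample at a
    time: duration, periodicity and sequence context are invisible to it,
    making it the formal switching-states, context-free baseline.

    Supports one-dimensional feature spaces (the shipped presets).
    """

    def __init__(self, spec: EthogramSpec):
        if spec.F != 1:
            raise ValueError("Bayes oracle supports F = 1 specs only")
        self.spec = spec
        self.labels = spec.labels
        self._mixtures = {b.label: _constituent_mixture(b) for b in spec.behaviors}

    # -- densities -----------------------------------------------------

    def _component_density(self, x: np.ndarray, c) -> np.ndarray:
        mean = c.key_pose.mean[0]
        var = (c.key_pose.spread[0] ** 2 + c.fluctuation.amount ** 2
               + self.spec.noise_sigma ** 2)
        sd = np.sqrt(var)
        fl = c.fluctuation
        if fl.period is None or fl.period_amplitude == 0:
            return stats.norm.pdf(x, mean, sd)
        phases = (np.arange(_N_PHASE) + 0.5) / _N_PHASE * 2.0 * np.pi
        offsets = fl.period_amplitude * np.sin(phases)
        return stats.norm.pdf(x[:, None], mean + offsets[None, :], sd).mean(axis=1)

    def density(self, label: str, x: np.ndarray) -> np.ndarray:
        x = np.atleast_1d(np.asarray(x, dtype=float))
        out = np.zeros_like(x)
        for w, c in self._mixtures[label]:
            out += w * self._component_density(x, c)
        return out

    # -- classification ------------------------------------------------

    def classify(self, x: np.ndarray) -> np.ndarray:
        """Maximum-likelihood label per sample (uniform prior)."""
        x = np.asarray(x, dtype=float).reshape(-1)
        dens = np.stack([self.density(lab, x) for lab in self.labels])
        return np.asarray(self.labels, dtype=str)[np.argmax(dens, axis=0)]

    # -- pairwise errors -----------------------------------------------

    def _grid(self) -> np.ndarray:
        means = [c.key_pose.mean[0] for b in self.spec.behaviors
                 for _, c in self._mixtures[b.label]]
        lo, hi = min(means) - 12.0, max(means) + 12.0
        return np.linspace(lo, hi, 20001)

    def pair_error(self, a: str, b: str) -> float:
        """Two-class Bayes error 0.5 ∫ min(p_a, p_b) dx by 1-D quadrature."""
        x = self._grid()
        pa, pb = self.density(a, x), self.density(b, x)
        return float(0.5 * np.trapezoid(np.minimum(pa, pb), x))

    def error_table(self) -> pd.DataFrame:
        x = self._grid()
        dens = {lab: self.density(lab, x) for lab in self.labels}
        n = len(self.labels)
        tbl = np.zeros((n, n))
        for i, a in enumerate(self.labels):
            for j in range(i + 1, n):
                e = 0.5 * np.trapezoid(np.minimum(dens[a], dens[self.labels[j]]), x)
                tbl[i, j] = tbl[j, i] = e
        return pd.DataFrame(tbl, index=self.labels, columns=self.labels)

    # -- Monte-Carlo cross-check ---------------------------------------

    def sample(self, label: str, n: int, rng: np.random.Generator) -> np.ndarray:
        """Draw n single samples from the behavior's marginal density."""
        weights = np.asarray([w for w, _ in self._mixtures[label]])
        comps = [c for _, c in self._mixtures[label]]
        idx = rng.choice(len(comps), size=n, p=weights)
        x = np.empty(n)
        for k, c in enumerate(comps):
            m = idx == k
            cnt = int(m.sum())
            if cnt == 0:
                continue
            sd = np.sqrt(c.key_pose.spread[0] ** 2 + c.fluctuation.amount ** 2
                         + self.spec.noise_sigma ** 2)
            vals = c.key_pose.mean[0] + sd * rng.standard_normal(cnt)
            fl = c.fluctuation
            if fl.period is not None and fl.period_amplitude > 0:
                vals += fl.period_amplitude * np.sin(rng.uniform(0, 2 * np.pi, cnt))
            x[m] = vals
        return x

    def mc_pair_error(self, a: str, b: str, n: int,
                      rng: np.random.Generator) -> float:
        """Monte-Carlo estimate of the two-class Bayes error (n per class
        pair total, classes balanced)."""
        na = n // 2
        xa, xb = self.sample(a, na, rng), self.sample(b, n - na, rng)
        pa_a, pb_a = self.density(a, xa), self.density(b, xa)
        pa_b, pb_b = self.density(a, xb), self.density(b, xb)
        errors = int(np.sum(pb_a > pa_a)) + int(np.sum(pa_b >= pb_b))
        return errors / n


def bayes_oracle(spec: EthogramSpec) -> BayesOracle:
    """Build the context-free Bayes-optimal classifier for a repertoire."""
    return BayesOracle(spec)


def plot_confusion(report: ConfusionReport, path, groups=None) -> None:
    """Save a row-normalized confusion heatmap; confusion groups outlined.

    Requires matplotlib (optional dependency).
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(0.45 * len(report.pred_labels) + 2,
                                    0.45 * len(report.labels) + 2))
    im = ax.imshow(report.matrix, vmin=0, vmax=1, cmap="Blues")
    ax.set_xticks(range(len(report.pred_labels)), report.pred_labels,
                  rotation=90)
    ax.set_yticks(range(len(report.labels)), report.labels)
    ax.set_xlabel("predicted")
    ax.set_ylabel("true")
    for i in range(report.matrix.shape[0]):
        for j in range(report.matrix.shape[1]):
            v = report.matrix[i, j]
            if v >= 0.01:
                ax.text(j, i, f"{v:.2f}", ha="center", va="center",
                        fontsize=7, color="white" if v > 0.5 else "black")
    for g in groups or []:
        rows = [report.labels.index(m) for m in g.members
                if m in report.labels]
        cols = [report.pred_labels.index(m) for m in g.members
                if m in report.pred_labels]
        if rows and cols:
            r0, c0 = min(rows), min(cols)
            ax.add_patch(plt.Rectangle(
                (c0 - 0.5, r0 - 0.5), max(cols) - c0 + 1, max(rows) - r0 + 1,
                fill=False, edgecolor="red", linewidth=1.5))
    fig.colorbar(im, ax=ax, shrink=0.8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
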