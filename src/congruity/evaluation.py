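"""Congruity–accuracy evaluation workflow.

Given a lattice built on the training set and a labelled, classified test
set, the workflow (a) scores every test instance, (b) sorts the scores and
groups them into equal-frequency bins, (c) computes the classifier's
accuracy within each bin, and (d) correlates per-bin mean score against
per-bin accuracy with Pearson's r, Kendall's τ-b and Spearman's ρ.  A
positive correlation is the operational evidence that the score predicts
where the classifier can be trusted.

A mean-cosine-similarity baseline runs the identical binning-and-
correlation path with the score column replaced by the mean cosine
similarity between the instance's binary attribute-indicator vector and
every training object's vector.

The workflow is classifier-agnostic: it consumes (true, predicted) label
pairs produced elsewhere; no model is trained here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .formal_context import Instance
from .lattice import ConceptLattice
from .measure import CongruityParams, congruity_score

__all__ = [
    "BinningError",
    "ScoredInstance",
    "CongruityBin",
    "CorrelationTriple",
    "EvaluationReport",
    "score_test_set",
    "equal_frequency_bins",
    "accuracy_per_bin",
    "correlate",
    "attribute_vectors",
    "mean_cosine_similarity",
    "evaluate",
    "plot_report",
]


class BinningError(ValueError):
    """The requested bin count is infeasible for the given scores."""


@dataclass(frozen=True)
class ScoredInstance:
    id: str
    congruity: float
    y_true: object
    y_pred: object

    @property
    def correct(self) -> bool:
        return self.y_true == self.y_pred


@dataclass(frozen=True)
class CongruityBin:
    index: int
    lo: float
    hi: float
    members: tuple[str, ...]
    mean_score: float
    accuracy: float | None = None


@dataclass(frozen=True)
class CorrelationTriple:
    """Pearson/Kendall/Spearman; a coefficient is None when undefined
    (constant series), with the reason recorded."""

    pearson: float | None
    kendall: float | None
    spearman: float | None
    undefined: Mapping[str, str] = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "pearson": self.pearson,
            "kendall": self.kendall,
            "spearman": self.spearman,
            "undefined": dict(self.undefined),
        }


@dataclass(frozen=True)
class EvaluationReport:
    bins: tuple[CongruityBin, ...]
    correlations: CorrelationTriple
    overall_accuracy: float
    baseline_bins: tuple[CongruityBin, ...] | None = None
    baseline_correlations: CorrelationTriple | None = None

    def to_dict(self) -> dict:
        def bins_out(bins):
            return [
                {
                    "index": b.index,
                    "lo": b.lo,
                    "hi": b.hi,
                    "size": len(b.members),
                    "members": list(b.members),
                    "mean_score": b.mean_score,
                    "accuracy": b.accuracy,
                }
                for b in bins
            ]

        doc = {
            "overall_accuracy": self.overall_accuracy,
            "bins": bins_out(self.bins),
            "correlations": self.correlations.as_dict(),
        }
        if self.baseline_bins is not None:
            doc["baseline"] = {
                "bins": bins_out(self.baseline_bins),
                "correlations": self.baseline_correlations.as_dict(),
            }
        return doc


def score_test_set(
    lattice: ConceptLattice,
    instances: Sequence[Instance],
    labels: Mapping[str, tuple[object, object]],
    params: CongruityParams = CongruityParams(),
) -> list[ScoredInstance]:
    """Score every instance, attaching its (true, predicted) labels.

    ``labels`` maps instance id to a ``(y_true, y_pred)`` pair; a missing
    id is an error.
    """
    out = []
    for inst in instances:
        if inst.id not in labels:
            raise KeyError(f"no labels supplied for instance {inst.id!r}")
        y_true, y_pred = labels[inst.id]
        result = congruity_score(lattice, inst, params)
        out.append(ScoredInstance(inst.id, result.value, y_true, y_pred))
    return out


def equal_frequency_bins(scores: Sequence[float], k: int) -> list[list[int]]:
    """Partition score indices into ``k`` ascending equal-frequency groups.

    Returns, per bin, the positions of its members in the input sequence.
    Identical score values are never split across a boundary: the whole run
    of ties joins the lower bin.  Raises :class:`BinningError` when that
    rule would leave a bin empty (too few distinct values for ``k``).
    """
    n = len(scores)
    if k < 2:
        raise BinningError("need at least 2 bins")
    if k > n:
        raise BinningError(f"cannot form {k} bins from {n} scores; use a smaller k")
    order = sorted(range(n), key=lambda i: (scores[i], i))
    # runs of identical values are atomic: a boundary can only fall between
    # two distinct values, so a whole run always lands in a single bin
    runs: list[list[int]] = []
    for idx in order:
        if runs and scores[idx] == scores[runs[-1][-1]]:
            runs[-1].append(idx)
        else:
            runs.append([idx])
    if len(runs) < k:
        raise BinningError(
            f"only {len(runs)} distinct score values; cannot form {k} "
            "non-empty bins — use a smaller k"
        )
    bins: list[list[int]] = []
    i = 0
    placed = 0
    for b in range(k):
        rem_bins = k - b
        if b == k - 1:
            take = len(runs) - i
        else:
            # greedy equal-frequency: grow the bin while that brings its
            # size closer to an equal share of what remains, but always
            # leave one run for each later bin
            target = (n - placed) / rem_bins
            take, count = 1, len(runs[i])
            while i + take < len(runs) - (rem_bins - 1) and abs(
                count + len(runs[i + take]) - target
            ) <= abs(count - target):
                count += len(runs[i + take])
                take += 1
        members = [idx for run in runs[i : i + take] for idx in run]
        bins.append(members)
        placed += len(members)
        i += take
    return bins


def accuracy_per_bin(
    bins: Sequence[Sequence[int]], scored: Sequence[ScoredInstance]
) -> list[CongruityBin]:
    """Materialize bins with range, mean score, and classifier accuracy."""
    out = []
    for idx, members in enumerate(bins):
        if not members:
            raise BinningError(f"bin {idx} is empty")
        vals = [scored[i].congruity for i in members]
        correct = sum(scored[i].correct for i in members)
        out.append(
            CongruityBin(
                index=idx,
                lo=min(vals),
                hi=max(vals),
                members=tuple(scored[i].id for i in members),
                mean_score=float(np.mean(vals)),
                accuracy=correct / len(members),
            )
        )
    return out


def correlate(xs: Sequence[float], ys: Sequence[float]) -> CorrelationTriple:
    """Pearson r, Kendall τ-b (tie-corrected) and Spearman ρ of two series.

    A coefficient over a constant series is undefined and reported as None
    rather than raised, so a perfectly accurate classifier (accuracy 1 in
    every bin) still yields a report.
    """
    xs = np.asarray(xs, dtype=float)
    ys = np.asarray(ys, dtype=float)
    if xs.shape != ys.shape:
        raise ValueError("series must have equal length")
    if xs.size < 2:
        raise ValueError("need at least 2 points to correlate")
    undefined: dict[str, str] = {}
    x_const = np.all(xs == xs[0])
    y_const = np.all(ys == ys[0])

    def guard(name: str) -> bool:
        if x_const or y_const:
            which = "x" if x_const else "y"
            undefined[name] = f"constant {which} series"
            return True
        return False

    pearson = None if guard("pearson") else float(stats.pearsonr(xs, ys).statistic)
    kendall = None if guard("kendall") else float(stats.kendalltau(xs, ys).statistic)
    spearman = None if guard("spearman") else float(stats.spearmanr(xs, ys).statistic)
    return CorrelationTriple(pearson, kendall, spearman, undefined)


def attribute_vectors(
    attributes: Sequence[str], attr_sets: Sequence[frozenset[str]]
) -> np.ndarray:
    """Binary indicator matrix of attribute sets over the ordered M."""
    index = {a: j for j, a in enumerate(attributes)}
    mat = np.zeros((len(attr_sets), len(attributes)), dtype=float)
    for i, attrs in enumerate(attr_sets):
        for a in attrs:
            j = index.get(a)
            if j is not None:
                mat[i, j] = 1.0
    return mat


def mean_cosine_similarity(train_vectors: np.ndarray, instance_vector: np.ndarray) -> float:
    """Mean cosine similarity between one instance and every training vector."""
    train_vectors = np.asarray(train_vectors, dtype=float)
    v = np.asarray(instance_vector, dtype=float)
    v_norm = np.linalg.norm(v)
    t_norms = np.linalg.norm(train_vectors, axis=1)
    if v_norm == 0 or np.any(t_norms == 0):
        raise ValueError("cosine similarity undefined for a zero vector")
    return float(np.mean(train_vectors @ v / (t_norms * v_norm)))


def evaluate(
    lattice: ConceptLattice,
    instances: Sequence[Instance],
    labels: Mapping[str, tuple[object, object]],
    params: CongruityParams = CongruityParams(),
    k: int = 10,
    baseline: bool = False,
) -> EvaluationReport:
    """Run the full workflow: score, bin, per-bin accuracy, correlate.

    With ``baseline=True``, the mean-cosine-similarity score is pushed
    through the identical binning-and-correlation path for comparison.
    """
    scored = score_test_set(lattice, instances, labels, params)
    if not scored:
        raise ValueError("empty test set")
    overall = sum(s.correct for s in scored) / len(scored)

    def run(values: Sequence[float]):
        column = [
            ScoredInstance(s.id, v, s.y_true, s.y_pred)
            for s, v in zip(scored, values)
        ]
        bins = accuracy_per_bin(
            equal_frequency_bins([c.congruity for c in column], k), column
        )
        corr = correlate(
            [b.mean_score for b in bins], [b.accuracy for b in bins]
        )
        return tuple(bins), corr

    bins, corr = run([s.congruity for s in scored])

    baseline_bins = baseline_corr = None
    if baseline:
        M = lattice.context.attributes
        train = attribute_vectors(
            M, [lattice.context.incidence[g] for g in lattice.context.objects]
        )
        test = attribute_vectors(M, [inst.attributes for inst in instances])
        cosims = [mean_cosine_similarity(train, row) for row in test]
        baseline_bins, baseline_corr = run(cosims)

    return EvaluationReport(bins, corr, overall, baseline_bins, baseline_corr)


def plot_report(report: EvaluationReport, path) -> None:
    """Plot per-bin accuracy against the congruity range (optional output).

    Requires matplotlib (the ``plot`` extra); everything else in the
    package works without it.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4))
    xs = [b.mean_score for b in report.bins]
    ys = [b.accuracy for b in report.bins]
    labels = [f"[{b.lo:.2f},\n{b.hi:.2f}]" for b in report.bins]
    ax.plot(range(len(xs)), ys, marker="o", label="congruity bins")
    if report.baseline_bins is not None:
        ax.plot(
            range(len(report.baseline_bins)),
            [b.accuracy for b in report.baseline_bins],
            marker="s",
            linestyle="--",
            label="cosine baseline bins",
        )
    ax.set_xticks(range(len(labels)), labels, fontsize=7)
    ax.set_xlabel("congruity range (ascending bins)")
    ax.set_ylabel("accuracy")
    ax.set_ylim(0, 1.05)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
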