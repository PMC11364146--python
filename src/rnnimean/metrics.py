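"""Summary-tree quality metrics and SoS-vs-score diagnostics.

Metrics comparing a summary tree to a reference (true) tree:

* clade age error (CAE) — mean absolute height discrepancy over the
  reference tree's clades, matched by mrca in the summary;
* clade rank error (CRE) — same with heights replaced by ranks;
* RNNI distance (raw and normalised by the treespace diameter);
* rooted Robinson-Foulds (clade symmetric difference) and its weighted
  variant on clade-indexed branch lengths.

CAE/CRE are directional (reference-indexed); RF/wRF are symmetric.  A
symmetrised CAE/CRE variant (average of both directions) sits behind a
flag.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy import stats

from .mean import sos
from .rnni import diameter, distance
from .trees import RankedTree, TimeTree, TreeError, TreeSample, to_ranked

__all__ = [
    "ComparisonReport",
    "CorrelationReport",
    "clade_age_error",
    "clade_rank_error",
    "rf_distance",
    "weighted_rf",
    "rnni_normalized",
    "compare",
    "correlation_diagnostics",
    "win_counts",
]

METRIC_NAMES = ("cae", "cre", "rnni", "rnni_normalized", "rf", "wrf")

#: metrics where a smaller value is closer to the truth (all of them)
_LOWER_IS_BETTER = set(METRIC_NAMES)


@dataclass
class ComparisonReport:
    """Per-metric values comparing a summary tree to a reference tree."""

    cae: float
    cre: float
    rnni: int
    rnni_normalized: float
    rf: int
    wrf: float

    def as_dict(self) -> dict:
        return {name: getattr(self, name) for name in METRIC_NAMES}

    def tsv(self) -> str:
        head = "\t".join(METRIC_NAMES)
        row = "\t".join(f"{getattr(self, name):.12g}" for name in METRIC_NAMES)
        return f"{head}\n{row}\n"


@dataclass
class CorrelationReport:
    pearson: float
    spearman: float
    n_points: int
    mode: str  # "sos_vs_score" | "pairwise_distance_vs_score_delta"


def _check_taxa(a, b) -> None:
    if a.taxa != b.taxa:
        raise TreeError("trees are on different taxon sets")


def clade_age_error(
    summary: TimeTree, truth: TimeTree, symmetrize: bool = False
) -> float:
    """Mean absolute height discrepancy over the reference clades.

    For each of the n-1 clades C of ``truth``, the summary height of the
    mrca of C (in the summary) is compared with C's height in ``truth``.
    With ``symmetrize=True`` the average of both directions is returned.
    """
    _check_taxa(summary, truth)
    if symmetrize:
        return 0.5 * (
            clade_age_error(summary, truth) + clade_age_error(truth, summary)
        )
    total = 0.0
    for rank, clade in enumerate(truth.topology.clusters, start=1):
        h_sum = summary.height_of(summary.topology.mrca_rank(clade))
        total += abs(h_sum - truth.heights[rank - 1])
    return total / len(truth.topology.clusters)


def clade_rank_error(
    summary: RankedTree, truth: RankedTree, symmetrize: bool = False
) -> float:
    """As :func:`clade_age_error` with heights replaced by ranks."""
    summary = to_ranked(summary)
    truth = to_ranked(truth)
    _check_taxa(summary, truth)
    if symmetrize:
        return 0.5 * (
            clade_rank_error(summary, truth) + clade_rank_error(truth, summary)
        )
    total = 0
    for rank, clade in enumerate(truth.clusters, start=1):
        total += abs(summary.mrca_rank(clade) - rank)
    return total / len(truth.clusters)


def _nontrivial_clades(t: RankedTree) -> frozenset:
    """Internal clades excluding the root (and trivially the leaves)."""
    return frozenset(t.clusters[:-1])


def rf_distance(a: RankedTree, b: RankedTree) -> int:
    """Rooted Robinson-Foulds distance: size of the symmetric difference
    of the non-trivial clade sets; even, in [0, 2(n-2)]."""
    a = to_ranked(a)
    b = to_ranked(b)
    _check_taxa(a, b)
    return len(_nontrivial_clades(a) ^ _nontrivial_clades(b))


def _clade_branch_lengths(t: TimeTree) -> dict:
    """Branch length above each non-trivial clade (parent minus node height)."""
    top = t.topology
    out = {}
    for rank, clade in enumerate(top.clusters[:-1], start=1):
        parent = top.parent_rank(rank)
        out[clade] = t.heights[parent - 1] - t.heights[rank - 1]
    return out


def weighted_rf(a: TimeTree, b: TimeTree) -> float:
    """Weighted Robinson-Foulds: sum over the union of non-trivial clades
    of the absolute branch-length difference, with length 0 for clades
    absent from a tree."""
    _check_taxa(a, b)
    la = _clade_branch_lengths(a)
    lb = _clade_branch_lengths(b)
    return sum(
        abs(la.get(c, 0.0) - lb.get(c, 0.0)) for c in set(la) | set(lb)
    )


def rnni_normalized(a: RankedTree, b: RankedTree) -> float:
    """RNNI distance divided by the treespace diameter on these taxa."""
    a = to_ranked(a)
    b = to_ranked(b)
    d = diameter(a.n_leaves) if a.n_leaves > 2 else 1
    return distance(a, b) / d if d else 0.0


def compare(summary: TimeTree, truth: TimeTree) -> ComparisonReport:
    """All metrics comparing ``summary`` to ``truth`` (truth-referenced)."""
    _check_taxa(summary, truth)
    rnni = distance(summary.topology, truth.topology)
    diam = diameter(summary.n_leaves)
    return ComparisonReport(
        cae=clade_age_error(summary, truth),
        cre=clade_rank_error(summary.topology, truth.topology),
        rnni=rnni,
        rnni_normalized=rnni / diam if diam else 0.0,
        rf=rf_distance(summary.topology, truth.topology),
        wrf=weighted_rf(summary, truth),
    )


def correlation_diagnostics(
    sample: TreeSample, mode: str = "sos_vs_score"
) -> CorrelationReport:
    """Pearson/Spearman correlation between treespace geometry and scores.

    ``sos_vs_score`` pairs each tree's SoS value (against the whole
    sample) with its score.  ``pairwise`` pairs, over all tree pairs, the
    RNNI distance and the absolute score difference, each normalised by
    its largest observed value.
    """
    if sample.scores is None:
        raise TreeError("sample carries no scores")
    if len(sample) < 3:
        raise TreeError("need at least 3 trees for correlation diagnostics")
    scores = np.asarray(sample.scores, dtype=float)
    ranked = sample.ranked
    if mode == "sos_vs_score":
        x = np.array([sos(t, sample) for t in ranked], dtype=float)
        y = scores
    elif mode in ("pairwise", "pairwise_distance_vs_score_delta"):
        mode = "pairwise_distance_vs_score_delta"
        dists, deltas = [], []
        for i, j in combinations(range(len(ranked)), 2):
            dists.append(distance(ranked[i], ranked[j]))
            deltas.append(abs(scores[i] - scores[j]))
        x = np.asarray(dists, dtype=float)
        y = np.asarray(deltas, dtype=float)
        if x.max() == 0 or y.max() == 0:
            raise TreeError("constant distances or scores: correlation undefined")
        x = x / x.max()
        y = y / y.max()
    else:
        raise ValueError(f"unknown mode {mode!r}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise TreeError("zero variance in one variable: correlation undefined")
    pearson = stats.pearsonr(x, y).statistic
    spearman = stats.spearmanr(x, y).statistic
    return CorrelationReport(
        pearson=float(pearson),
        spearman=float(spearman),
        n_points=len(x),
        mode=mode,
    )


def win_counts(
    triples: Iterable[tuple[TimeTree, TimeTree, TimeTree]],
    metrics: Sequence[str] = METRIC_NAMES,
) -> dict:
    """Per-metric tallies of which summary is closer to the truth.

    ``triples`` yields ``(summary_a, summary_b, truth)``; the result maps
    each metric to ``{'a': wins_a, 'b': wins_b, 'tie': ties}``.
    """
    counts = {m: {"a": 0, "b": 0, "tie": 0} for m in metrics}
    for summary_a, summary_b, truth in triples:
        report_a = compare(summary_a, truth).as_dict()
        report_b = compare(summary_b, truth).as_dict()
        for m in metrics:
            va, vb = report_a[m], report_b[m]
            if abs(va - vb) <= 1e-12:
                counts[m]["tie"] += 1
            elif va < vb:
                counts[m]["a"] += 1
            else:
                counts[m]["b"] += 1
    return counts


def win_counts_tsv(counts: dict) -> str:
    lines = ["metric\ta\tb\ttie"]
    for m, row in counts.items():
        lines.append(f"{m}\t{row['a']}\t{row['b']}\t{row['tie']}")
    return "\n".join(lines) + "\n"
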