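"""Branch-length annotation of summary topologies.

Two schemes are provided.  Rank-height annotation assigns the node of
rank i the mean of the i-th entry of each sample tree's height vector
(its t-coordinate), which never changes the ranked topology and always
yields strictly increasing heights.  The common-ancestor scheme used with
the MCC baseline averages, over all sample trees, the height of the mrca
of each node's leaf set; it can break height monotonicity, which is
flagged rather than repaired.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

from .trees import RankedTree, TimeTree, TreeError, TreeSample, to_ranked

__all__ = [
    "AnnotatedSummary",
    "MccResult",
    "annotate_rank_heights",
    "mcc_topology",
    "common_ancestor_heights",
    "clade_frequencies",
]


@dataclass
class AnnotatedSummary:
    """A summary topology with annotated node heights.

    ``heights[i]`` belongs to the node of rank ``i + 1``.  ``monotone`` is
    False when the heights violate the strict rank order (possible only
    for the common-ancestor method); ``support`` maps each cluster to its
    frequency in the sample.
    """

    topology: RankedTree
    heights: tuple
    method: str  # "rank_heights" | "mcc_common_ancestor"
    support: dict = field(default_factory=dict)
    monotone: bool = True

    @property
    def time_tree(self) -> TimeTree:
        if not self.monotone:
            raise TreeError(
                "annotated heights violate the rank order; no valid TimeTree"
            )
        return TimeTree(self.topology, self.heights)

    def newick(self, fmt: str = "%.12g") -> str:
        """Newick with heights (monotone case) or raw branch lengths."""
        if self.monotone:
            return self.time_tree.newick(fmt=fmt)
        top = self.topology

        def h(item) -> float:
            return 0.0 if isinstance(item, str) else self.heights[item - 1]

        def render(item, parent_h: float) -> str:
            if isinstance(item, int):
                kids = ",".join(render(k, h(item)) for k in top.children(item))
                return f"({kids}):{fmt % (parent_h - h(item))}"
            return f"{item}:{fmt % parent_h}"

        root = len(top.clusters)
        kids = ",".join(render(k, h(root)) for k in top.children(root))
        return f"({kids});"

    def nexus(self) -> str:
        """NEXUS with per-node comment fields (height, posterior support)."""
        from .trees import _quote_label

        top = self.topology
        taxa = sorted(top.taxa)
        number = {label: str(i + 1) for i, label in enumerate(taxa)}

        def h(item) -> float:
            return 0.0 if isinstance(item, str) else self.heights[item - 1]

        def render(item, parent_h: float) -> str:
            if isinstance(item, int):
                kids = ",".join(render(k, h(item)) for k in top.children(item))
                freq = self.support.get(top.clusters[item - 1])
                meta = f"[&height={h(item):.12g}"
                if freq is not None:
                    meta += f",posterior={freq:.6g}"
                meta += "]"
                return f"({kids}){meta}:{(parent_h - h(item)):.12g}"
            return f"{number[item]}:{parent_h:.12g}"

        root = len(top.clusters)
        kids = ",".join(render(k, h(root)) for k in top.children(root))
        lines = ["#NEXUS", ""]
        lines.append(f"[annotation method: {self.method}]")
        lines.append("Begin taxa;")
        lines.append(f"    Dimensions ntax={len(taxa)};")
        lines.append("    Taxlabels")
        lines += [f"        {_quote_label(t)}" for t in taxa]
        lines.append("        ;")
        lines.append("End;")
        lines.append("Begin trees;")
        lines.append("    Translate")
        for i, t in enumerate(taxa):
            sep = "," if i < len(taxa) - 1 else ""
            lines.append(f"        {i + 1} {_quote_label(t)}{sep}")
        lines.append("        ;")
        root_freq = self.support.get(top.clusters[-1])
        root_meta = f"[&height={h(root):.12g}"
        if root_freq is not None:
            root_meta += f",posterior={root_freq:.6g}"
        root_meta += "]"
        lines.append(f"tree SUMMARY = [&R] ({kids}){root_meta};")
        lines.append("End;")
        return "\n".join(lines) + "\n"


def clade_frequencies(sample: TreeSample) -> dict:
    """Sample frequency of every cluster observed in the sample."""
    counts: dict = {}
    for t in sample:
        for c in to_ranked(t).clusters:
            counts[c] = counts.get(c, 0) + 1
    m = len(sample)
    return {c: k / m for c, k in counts.items()}


def annotate_rank_heights(
    topology: RankedTree, sample: TreeSample
) -> AnnotatedSummary:
    """Annotate ``topology`` with the rank-wise mean heights of the sample.

    The height of the rank-i node is the arithmetic mean of the i-th
    t-coordinate across the sample, independent of the leaf labels below
    the node.  Means of strictly increasing vectors are strictly
    increasing, so the ranked topology is preserved exactly.
    """
    topology = to_ranked(topology)
    times = sample.time_trees
    if times[0].taxa != topology.taxa:
        raise TreeError("topology and sample are on different taxon sets")
    n1 = len(topology.clusters)
    heights = tuple(
        sum(t.heights[i] for t in times) / len(times) for i in range(n1)
    )
    return AnnotatedSummary(
        topology=topology,
        heights=heights,
        method="rank_heights",
        support=clade_frequencies(sample),
        monotone=True,
    )


@dataclass
class MccResult:
    """Maximum clade credibility topology chosen from the sample.

    ``score`` is the sum of log sample frequencies over the topology's
    non-trivial clades (the root and leaves contribute nothing); the
    argmax is unchanged by the log transform.  ``tie`` is set when several
    sampled topologies share the maximal score; the earliest occurrence
    wins.
    """

    tree: RankedTree
    score: float
    sample_index: int
    tie: bool
    support: dict


def mcc_topology(sample: TreeSample) -> MccResult:
    """Topology from the sample maximising the product of clade frequencies."""
    freqs = clade_frequencies(sample)
    ranked = sample.ranked
    entries: list[tuple[float, int, RankedTree]] = []
    seen: set = set()
    for i, t in enumerate(ranked):
        key = frozenset(t.clusters[:-1])  # unranked rooted topology
        if key in seen:
            continue
        seen.add(key)
        # root clade (frequency 1) excluded; leaves are not clusters anyway
        score = sum(math.log(freqs[c]) for c in t.clusters[:-1])
        entries.append((score, i, t))
    best_score = max(score for score, _, _ in entries)
    tied = [e for e in entries if e[0] >= best_score - 1e-12]
    score, index, tree = min(tied, key=lambda e: e[1])
    return MccResult(
        tree=tree, score=score, sample_index=index, tie=len(tied) > 1, support=freqs
    )


def common_ancestor_heights(
    topology: RankedTree, sample: TreeSample
) -> AnnotatedSummary:
    """Annotate each node with the mean, over all sample trees, of the
    height of the mrca of that node's leaf set.

    The topology is not re-ranked; if the averaged heights violate the
    rank order the result is flagged (``monotone=False``).
    """
    topology = to_ranked(topology)
    times = sample.time_trees
    if times[0].taxa != topology.taxa:
        raise TreeError("topology and sample are on different taxon sets")
    heights = []
    for c in topology.clusters:
        total = 0.0
        for t in times:
            total += t.height_of(t.topology.mrca_rank(c))
        heights.append(total / len(times))
    monotone = all(a < b for a, b in zip(heights, heights[1:])) and heights[0] > 0
    return AnnotatedSummary(
        topology=topology,
        heights=tuple(heights),
        method="mcc_common_ancestor",
        support=clade_frequencies(sample),
        monotone=monotone,
    )
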