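"""Ranked and time tree data model with Newick/NEXUS input and output.

A ranked tree is a rooted binary tree whose internal nodes carry unique
ranks ``1..n-1`` increasing towards the root (leaves have rank 0).  The
canonical encoding used throughout this package is the rank-ordered
*cluster sequence*: position ``i`` (0-based) holds the set of leaf labels
descending from the node of rank ``i + 1``.  Two ranked trees are equal
iff their cluster sequences are equal, which makes equality, hashing and
cluster-based properties directly testable.

A time tree adds strictly increasing internal-node heights (times) to a
ranked topology, with all leaves at height 0.
"""

from __future__ import annotations

import io
import math
import re
import warnings
from dataclasses import dataclass, field
from typing import IO, Iterable, Sequence, Union

import dendropy

__all__ = [
    "TreeError",
    "TieError",
    "RankedTree",
    "TimeTree",
    "TreeSample",
    "parse_trees",
    "to_ranked",
    "ultrametricize",
    "ranked_from_clade_heights",
    "write_trees",
]


class TreeError(ValueError):
    """Raised for invalid trees or malformed tree input."""


class TieError(TreeError):
    """Raised when two internal nodes share a height under tie_policy='error'."""


def _cluster_key(cluster: frozenset) -> tuple:
    return tuple(sorted(cluster))


class RankedTree:
    """Immutable ranked tree encoded as its rank-ordered cluster sequence.

    Parameters
    ----------
    clusters:
        Iterable of leaf-label sets; entry ``i`` is the cluster of the node
        of rank ``i + 1``.  The last entry must be the full taxon set.
    validate:
        Verify the laminar/binary/rank invariants (default).  Skipped by
        internal constructors that build trees known to be valid.
    """

    __slots__ = ("clusters", "_hash", "_children", "_parent")

    def __init__(self, clusters: Iterable[Iterable[str]], validate: bool = True):
        object.__setattr__(self, "clusters", tuple(frozenset(c) for c in clusters))
        object.__setattr__(self, "_hash", hash(self.clusters))
        object.__setattr__(self, "_children", None)
        object.__setattr__(self, "_parent", None)
        if validate:
            self._validate()

    # -- basic protocol ---------------------------------------------------

    def __eq__(self, other):
        return isinstance(other, RankedTree) and self.clusters == other.clusters

    def __hash__(self):
        return self._hash

    def __repr__(self):
        inner = ", ".join("{" + ",".join(sorted(c)) + "}" for c in self.clusters)
        return f"RankedTree([{inner}])"

    def __setattr__(self, name, value):  # immutability guard
        raise AttributeError("RankedTree is immutable")

    @property
    def taxa(self) -> frozenset:
        return self.clusters[-1]

    @property
    def n_leaves(self) -> int:
        return len(self.clusters[-1])

    @property
    def sort_key(self) -> tuple:
        """Deterministic total-order key over trees on the same taxa."""
        return tuple(_cluster_key(c) for c in self.clusters)

    # -- validation -------------------------------------------------------

    def _validate(self) -> None:
        cl = self.clusters
        if not cl:
            raise TreeError("empty cluster sequence")
        taxa = cl[-1]
        n = len(taxa)
        if n < 2:
            raise TreeError(f"need at least 2 taxa, got {n}")
        if len(cl) != n - 1:
            raise TreeError(f"expected {n - 1} clusters for {n} taxa, got {len(cl)}")
        for i, c in enumerate(cl):
            if len(c) < 2:
                raise TreeError(f"cluster of rank {i + 1} has fewer than 2 leaves")
            if not c <= taxa:
                raise TreeError(f"cluster of rank {i + 1} contains unknown leaves")
        # laminar and "rank below parent": for i < j either disjoint or
        # cl[i] strictly inside cl[j] (a higher-ranked node can never be
        # nested inside a lower-ranked one).
        for j in range(len(cl)):
            for i in range(j):
                inter = cl[i] & cl[j]
                if inter and not cl[i] < cl[j]:
                    raise TreeError(
                        f"clusters of ranks {i + 1} and {j + 1} overlap without nesting"
                    )
        # binary: every node has exactly two children
        for rank in range(1, n):
            if len(self.children(rank)) != 2:
                raise TreeError(f"node of rank {rank} is not binary")

    # -- structure --------------------------------------------------------

    def _build_incidence(self) -> None:
        cl = self.clusters
        n1 = len(cl)
        parent = [0] * n1  # parent[i] = 1-based parent rank of node rank i+1 (0 = root)
        kids: list[list] = [[] for _ in range(n1)]
        for i in range(n1 - 1):
            for j in range(i + 1, n1):
                if cl[i] < cl[j]:
                    parent[i] = j + 1
                    kids[j].append(i + 1)
                    break
        covered = [frozenset() for _ in range(n1)]
        for j in range(n1):
            for r in kids[j]:
                covered[j] = covered[j] | cl[r - 1]
        for j in range(n1):
            for leaf in sorted(cl[j] - covered[j]):
                kids[j].append(leaf)
        object.__setattr__(self, "_children", tuple(tuple(k) for k in kids))
        object.__setattr__(self, "_parent", tuple(parent))

    def children(self, rank: int):
        """Children of the node of ``rank`` as a tuple of leaf labels (str)
        and child ranks (int)."""
        if self._children is None:
            self._build_incidence()
        return self._children[rank - 1]

    def parent_rank(self, rank: int) -> int:
        """1-based rank of the parent node; 0 for the root."""
        if self._parent is None:
            self._build_incidence()
        return self._parent[rank - 1]

    def mrca_rank(self, leaves: Iterable[str]) -> int:
        """Rank of the most recent common ancestor of ``leaves``."""
        target = frozenset(leaves)
        if not target:
            raise TreeError("mrca of an empty leaf set is undefined")
        if not target <= self.taxa:
            raise TreeError("mrca query contains unknown leaves")
        if len(target) == 1:
            # mrca of a single leaf is the leaf itself; report its parent
            # cluster rank is not meaningful, so return 0 (leaf rank).
            return 0
        for i, c in enumerate(self.clusters):
            if target <= c:
                return i + 1
        raise AssertionError("root cluster must contain every leaf set")

    def rank_of_cluster(self, cluster: Iterable[str]):
        """Rank of the exact ``cluster`` or ``None`` if absent."""
        c = frozenset(cluster)
        for i, cl in enumerate(self.clusters):
            if cl == c:
                return i + 1
        return None

    # -- conversion -------------------------------------------------------

    def as_time_tree(self) -> "TimeTree":
        """Time tree with unit rank increments as heights (rank i at time i)."""
        return TimeTree(self, tuple(float(i) for i in range(1, self.n_leaves)))

    def newick(self) -> str:
        return self.as_time_tree().newick()


class TimeTree:
    """Ranked topology plus strictly increasing internal-node heights.

    ``heights[i]`` (0-based) is the time of the node of rank ``i + 1``;
    leaves sit at height 0.
    """

    __slots__ = ("topology", "heights")

    def __init__(self, topology: RankedTree, heights: Sequence[float]):
        heights = tuple(float(h) for h in heights)
        if len(heights) != len(topology.clusters):
            raise TreeError(
                f"expected {len(topology.clusters)} heights, got {len(heights)}"
            )
        if heights[0] <= 0:
            raise TreeError("lowest internal node must be above the leaves (height > 0)")
        for a, b in zip(heights, heights[1:]):
            if not a < b:
                raise TreeError("heights must be strictly increasing with rank")
        object.__setattr__(self, "topology", topology)
        object.__setattr__(self, "heights", heights)

    def __setattr__(self, name, value):
        raise AttributeError("TimeTree is immutable")

    def __eq__(self, other):
        return (
            isinstance(other, TimeTree)
            and self.topology == other.topology
            and self.heights == other.heights
        )

    def __hash__(self):
        return hash((self.topology, self.heights))

    def __repr__(self):
        return f"TimeTree({self.topology!r}, heights={self.heights})"

    @property
    def taxa(self) -> frozenset:
        return self.topology.taxa

    @property
    def n_leaves(self) -> int:
        return self.topology.n_leaves

    def height_of(self, rank: int) -> float:
        """Height of the node of ``rank``; leaves (rank 0) are at height 0."""
        if rank == 0:
            return 0.0
        return self.heights[rank - 1]

    def approx_equal(self, other: "TimeTree", tol: float = 1e-9) -> bool:
        return self.topology == other.topology and all(
            abs(a - b) <= tol for a, b in zip(self.heights, other.heights)
        )

    def newick(self, fmt: str = "%.12g", label_map: dict | None = None) -> str:
        top = self.topology

        def render(item, parent_height: float) -> str:
            if isinstance(item, int):
                kids = ",".join(
                    render(k, self.heights[item - 1]) for k in top.children(item)
                )
                blen = parent_height - self.heights[item - 1]
                return f"({kids}):{fmt % blen}"
            label = label_map[item] if label_map else _quote_label(item)
            return f"{label}:{fmt % parent_height}"

        root = len(top.clusters)
        kids = ",".join(render(k, self.heights[root - 1]) for k in top.children(root))
        return f"({kids});"


_SAFE_LABEL = re.compile(r"^[A-Za-z0-9_.|\-]+$")


def _quote_label(label: str) -> str:
    if _SAFE_LABEL.match(label):
        return label
    return "'" + label.replace("'", "''") + "'"


@dataclass
class TreeSample:
    """Ordered collection of trees on one shared taxon set.

    ``trees`` may hold :class:`RankedTree` or :class:`TimeTree` instances;
    ``scores`` is an optional per-tree scalar vector (e.g. log-likelihoods).
    """

    trees: list
    scores: Sequence[float] | None = None

    def __post_init__(self):
        if not self.trees:
            raise TreeError("empty tree sample")
        taxa = self._taxa_of(self.trees[0])
        for i, t in enumerate(self.trees):
            if self._taxa_of(t) != taxa:
                raise TreeError(f"tree {i} has a different taxon set")
        if self.scores is not None:
            self.scores = [float(s) for s in self.scores]
            if len(self.scores) != len(self.trees):
                raise TreeError("scores length must match number of trees")

    @staticmethod
    def _taxa_of(t) -> frozenset:
        return t.taxa

    @property
    def taxa(self) -> frozenset:
        return self.trees[0].taxa

    def __len__(self) -> int:
        return len(self.trees)

    def __iter__(self):
        return iter(self.trees)

    def __getitem__(self, i):
        return self.trees[i]

    @property
    def ranked(self) -> list[RankedTree]:
        """Topologies of all trees (identity for ranked trees)."""
        return [to_ranked(t) for t in self.trees]

    @property
    def time_trees(self) -> list[TimeTree]:
        out = []
        for i, t in enumerate(self.trees):
            if not isinstance(t, TimeTree):
                raise TreeError(f"tree {i} carries no heights")
            out.append(t)
        return out


# ---------------------------------------------------------------------------
# conversions


def to_ranked(t: Union[RankedTree, TimeTree]) -> RankedTree:
    """Ranked topology of ``t`` (identity on ranked trees)."""
    if isinstance(t, RankedTree):
        return t
    if isinstance(t, TimeTree):
        return t.topology
    raise TypeError(f"cannot rank object of type {type(t).__name__}")


def ranked_from_clade_heights(
    clade_heights: dict, tie_policy: str = "error"
) -> TimeTree:
    """Build a :class:`TimeTree` from a mapping ``{clade leafset: height}``.

    Ranks are assigned by sorting heights ascending.  Equal heights abort
    under ``tie_policy='error'``; under ``'perturb'`` ties are broken by a
    deterministic total order on clusters (lexicographically smallest leaf
    label first) and tied heights are nudged apart by a tiny epsilon so the
    result satisfies the strict height ordering.  A warning is emitted.
    """
    if tie_policy not in ("error", "perturb"):
        raise ValueError(f"unknown tie_policy {tie_policy!r}")
    items = [(float(h), frozenset(c)) for c, h in clade_heights.items()]
    heights_only = sorted(h for h, _ in items)
    has_tie = any(a == b for a, b in zip(heights_only, heights_only[1:]))
    if has_tie:
        if tie_policy == "error":
            raise TieError("two internal nodes share the same height")
        warnings.warn(
            "tied internal-node heights broken deterministically "
            "(lexicographic smallest leaf label)",
            stacklevel=2,
        )
    items.sort(key=lambda hc: (hc[0], _cluster_key(hc[1])))
    tree = RankedTree([c for _, c in items])
    heights = [h for h, _ in items]
    if has_tie:  # nudge tied heights apart, preserving the chosen order
        scale = max(abs(heights[-1]), 1.0)
        eps = scale * 1e-12
        for i in range(1, len(heights)):
            if heights[i] <= heights[i - 1]:
                heights[i] = heights[i - 1] + eps
    return TimeTree(tree, heights)


# ---------------------------------------------------------------------------
# dendropy bridge


def _check_binary(tree: dendropy.Tree, index: int) -> None:
    for node in tree.preorder_node_iter():
        k = len(node.child_nodes())
        if k == 0:
            continue
        if k != 2:
            raise TreeError(
                f"tree {index}: non-binary node with {k} children "
                "(only rooted binary trees are supported)"
            )


def _timetree_from_dendropy(
    tree: dendropy.Tree, tie_policy: str, index: int
) -> TimeTree:
    """Ultrametricise a parsed tree and convert to :class:`TimeTree`.

    Internal-node heights are kept fixed relative to the root while every
    leaf branch is extended to the maximum root-to-leaf depth, so leaves
    end up at height 0.
    """
    _check_binary(tree, index)
    depth: dict = {tree.seed_node: 0.0}
    leaves = []
    for node in tree.preorder_node_iter():
        if node is not tree.seed_node:
            length = node.edge.length
            if length is None:
                raise TreeError(f"tree {index}: missing branch length")
            if length < 0:
                raise TreeError(f"tree {index}: negative branch length {length}")
            depth[node] = depth[node.parent_node] + length
        if node.is_leaf():
            if node.taxon is None or node.taxon.label is None:
                raise TreeError(f"tree {index}: unlabelled leaf")
            leaves.append(node)
    if len(leaves) < 2:
        raise TreeError(f"tree {index}: fewer than 2 leaves")
    labels = [lv.taxon.label for lv in leaves]
    if len(set(labels)) != len(labels):
        raise TreeError(f"tree {index}: duplicate leaf labels")
    max_depth = max(depth[lv] for lv in leaves)
    clade_heights: dict = {}
    leafsets: dict = {lv: frozenset({lv.taxon.label}) for lv in leaves}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            continue
        ls = frozenset().union(*(leafsets[c] for c in node.child_nodes()))
        leafsets[node] = ls
        clade_heights[ls] = max_depth - depth[node]
    for ls, h in clade_heights.items():
        if h <= 0:
            raise TreeError(f"tree {index}: internal node at or below leaf level")
    try:
        return ranked_from_clade_heights(clade_heights, tie_policy=tie_policy)
    except TieError as exc:
        raise TieError(f"tree {index}: {exc}") from exc


def ultrametricize(
    tree: Union[dendropy.Tree, str], tie_policy: str = "error"
) -> TimeTree:
    """Convert a rooted binary tree with branch lengths into an ultrametric
    :class:`TimeTree` by extending leaf branches to the deepest leaf.

    ``tree`` may be a ``dendropy.Tree`` or a Newick string.  Already
    ultrametric trees come back unchanged (up to floating tolerance).
    Negative branch lengths are rejected.
    """
    if isinstance(tree, str):
        tree = dendropy.Tree.get(
            data=tree, schema="newick", rooting="default-rooted"
        )
    return _timetree_from_dendropy(tree, tie_policy, 0)


# ---------------------------------------------------------------------------
# parsing / writing


def parse_trees(
    source: Union[str, IO[str]],
    format: str = "newick",
    burnin: float = 0.0,
    tie_policy: str = "error",
) -> TreeSample:
    """Parse a Newick or NEXUS tree file into a :class:`TreeSample` of
    :class:`TimeTree` objects.

    ``source`` is the file content (str) or a readable text stream.
    NEXUS translate tables are resolved to leaf labels.  The first
    ``floor(burnin * m)`` trees are discarded before any computation.
    """
    if hasattr(source, "read"):
        data = source.read()
    else:
        data = source
    if format not in ("newick", "nexus"):
        raise ValueError(f"unknown format {format!r}")
    if not (0.0 <= burnin < 1.0):
        raise ValueError("burnin must lie in [0, 1)")
    if not data.strip():
        raise TreeError("empty tree file")
    try:
        tlist = dendropy.TreeList.get(
            data=data,
            schema=format,
            rooting="default-rooted",
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises schema-specific errors
        raise TreeError(f"could not parse {format} input: {exc}") from exc
    if len(tlist) == 0:
        raise TreeError("no trees found in input")
    drop = math.floor(burnin * len(tlist))
    kept = list(tlist)[drop:]
    if not kept:
        raise TreeError("burn-in discarded every tree")
    trees = [
        _timetree_from_dendropy(t, tie_policy, i + drop) for i, t in enumerate(kept)
    ]
    return TreeSample(trees)


def _as_tree_list(obj) -> list:
    if isinstance(obj, TreeSample):
        return list(obj.trees)
    if isinstance(obj, (RankedTree, TimeTree)):
        return [obj]
    raise TypeError(f"cannot write object of type {type(obj).__name__}")


def write_trees(obj, format: str = "newick", comments: dict | None = None) -> str:
    """Serialise a tree or sample as Newick (one tree per line) or a NEXUS
    trees block with a translate table.

    Ranked trees without heights are written with unit rank increments as
    branch lengths; NEXUS output flags this in a comment.
    """
    trees = _as_tree_list(obj)
    any_ranked_only = any(isinstance(t, RankedTree) for t in trees)
    time_trees = [t.as_time_tree() if isinstance(t, RankedTree) else t for t in trees]
    if format == "newick":
        return "\n".join(t.newick() for t in time_trees) + "\n"
    if format != "nexus":
        raise ValueError(f"unknown format {format!r}")
    taxa = sorted(time_trees[0].taxa)
    number = {label: i + 1 for i, label in enumerate(taxa)}
    out = io.StringIO()
    out.write("#NEXUS\n\n")
    if any_ranked_only:
        out.write("[ranked trees: branch lengths are unit rank increments]\n")
    if comments:
        for key, val in comments.items():
            out.write(f"[{key}: {val}]\n")
    out.write("Begin taxa;\n")
    out.write(f"    Dimensions ntax={len(taxa)};\n    Taxlabels\n")
    for label in taxa:
        out.write(f"        {_quote_label(label)}\n")
    out.write("        ;\nEnd;\n")
    out.write("Begin trees;\n    Translate\n")
    for i, label in enumerate(taxa):
        sep = "," if i < len(taxa) - 1 else ""
        out.write(f"        {number[label]} {_quote_label(label)}{sep}\n")
    out.write("        ;\n")
    translated = {label: str(num) for label, num in number.items()}
    for i, t in enumerate(time_trees):
        out.write(f"tree STATE_{i} = [&R] {t.newick(label_map=translated)}\n")
    out.write("End;\n")
    return out.getvalue()
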