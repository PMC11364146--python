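"""RNNI treespace: moves, neighbourhoods, shortest paths and distances.

The RNNI graph has ranked trees as vertices; edges are rank moves (swap
the ranks of two non-adjacent nodes with consecutive ranks) and ranked
NNI moves (on an edge joining nodes of consecutive ranks, relocate one
sister clade of the bottom node to the other side of the top node).  The
RNNI distance is shortest-path length in this graph and is computed here
with the FindPath construction, which is exact and runs in O(n^2) per
pair.  Exhaustive enumeration and BFS oracles for small n back it up in
tests.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field
from math import factorial
from typing import Iterable, Sequence

from .trees import RankedTree, TreeError, write_trees

__all__ = [
    "Move",
    "MovePath",
    "apply_move",
    "neighbours",
    "findpath",
    "distance",
    "bfs_distance",
    "enumerate_space",
    "rnni_graph",
    "count_ranked_trees",
    "diameter",
    "MAX_EXHAUSTIVE_N",
]

#: largest leaf count for which exhaustive enumeration / BFS is permitted
#: (the space has n!(n-1)!/2^(n-1) trees: 56 700 at n = 7)
MAX_EXHAUSTIVE_N = 7


class MoveError(TreeError):
    """Raised when a move is illegal on the given tree."""


@dataclass(frozen=True)
class Move:
    """One RNNI edge, positionally encoded.

    ``lower_rank`` is the rank ``i`` of the lower of the two consecutive
    nodes the move acts on (``1 <= i <= n-2``).  For NNI moves ``variant``
    selects which child of the bottom node stays attached to it: children
    are ordered by their smallest leaf label, variant 0 keeps the first.
    ``variant`` is unused for rank moves.
    """

    kind: str  # "rank" | "nni"
    lower_rank: int
    variant: int = 0

    def __post_init__(self):
        if self.kind not in ("rank", "nni"):
            raise ValueError(f"unknown move kind {self.kind!r}")
        if self.kind == "nni" and self.variant not in (0, 1):
            raise ValueError("NNI variant must be 0 or 1")

    def __str__(self):
        if self.kind == "rank":
            return f"rank {self.lower_rank}"
        return f"nni {self.lower_rank} {self.variant}"


@dataclass
class MovePath:
    """Sequence of ranked trees in which consecutive trees differ by the
    recorded move; ``len(moves) == len(trees) - 1``."""

    trees: list[RankedTree]
    moves: list[Move] = field(default_factory=list)

    def __post_init__(self):
        if len(self.moves) != len(self.trees) - 1:
            raise ValueError("need exactly one move per consecutive tree pair")

    def __len__(self) -> int:
        """Path length = number of moves."""
        return len(self.moves)

    @property
    def src(self) -> RankedTree:
        return self.trees[0]

    @property
    def dst(self) -> RankedTree:
        return self.trees[-1]

    def validate(self) -> None:
        for t, mv, u in zip(self.trees, self.moves, self.trees[1:]):
            if apply_move(t, mv) != u:
                raise TreeError("recorded move does not produce the next tree")

    def to_nexus(self) -> str:
        return write_trees_path(self)

    def move_listing(self) -> str:
        return "\n".join(str(m) for m in self.moves) + ("\n" if self.moves else "")


def write_trees_path(path: MovePath) -> str:
    from .trees import TreeSample

    return write_trees(TreeSample(list(path.trees)), format="nexus")


# ---------------------------------------------------------------------------
# moves


def _bottom_children(cl: Sequence[frozenset], idx: int) -> tuple[frozenset, frozenset]:
    """Leaf sets of the two children of the node at cluster index ``idx``."""
    bottom = cl[idx]
    for j in range(idx - 1, -1, -1):
        if cl[j] < bottom:
            return cl[j], bottom - cl[j]
    a, b = sorted(bottom)
    return frozenset({a}), frozenset({b})


def _ordered_children(cl: Sequence[frozenset], idx: int) -> tuple[frozenset, frozenset]:
    x, y = _bottom_children(cl, idx)
    return (x, y) if min(x) < min(y) else (y, x)


def apply_move(t: RankedTree, mv: Move) -> RankedTree:
    """Apply one rank or NNI move to ``t`` and return the resulting tree."""
    cl = list(t.clusters)
    n = t.n_leaves
    i = mv.lower_rank
    if not 1 <= i <= n - 2:
        raise MoveError(f"lower_rank {i} out of range for {n} taxa")
    lo, hi = i - 1, i  # cluster indices of ranks i, i+1
    adjacent = cl[lo] < cl[hi]
    if mv.kind == "rank":
        if adjacent:
            raise MoveError(
                f"rank move illegal: nodes of ranks {i} and {i + 1} are adjacent"
            )
        cl[lo], cl[hi] = cl[hi], cl[lo]
    else:
        if not adjacent:
            raise MoveError(
                f"NNI move illegal: nodes of ranks {i} and {i + 1} are not adjacent"
            )
        sibling = cl[hi] - cl[lo]
        c0, c1 = _ordered_children(cl, lo)
        keep = c0 if mv.variant == 0 else c1
        cl[lo] = keep | sibling
    return RankedTree(cl, validate=False)


def neighbours(t: RankedTree) -> set[RankedTree]:
    """All trees at RNNI distance exactly one from ``t``.

    Size lies between ``n - 2`` and ``2(n - 2)``; empty for ``n < 3``.
    """
    cl = list(t.clusters)
    n = t.n_leaves
    out: set[RankedTree] = set()
    for i in range(1, n - 1):
        lo, hi = i - 1, i
        if cl[lo] < cl[hi]:
            sibling = cl[hi] - cl[lo]
            for child in _bottom_children(cl, lo):
                new = list(cl)
                new[lo] = child | sibling
                out.add(RankedTree(new, validate=False))
        else:
            new = list(cl)
            new[lo], new[hi] = new[hi], new[lo]
            out.add(RankedTree(new, validate=False))
    out.discard(t)
    return out


# ---------------------------------------------------------------------------
# FindPath


def _check_same_taxa(src: RankedTree, dst: RankedTree) -> None:
    if src.taxa != dst.taxa:
        raise TreeError("trees are on different taxon sets")


def _findpath_core(src: RankedTree, dst: RankedTree, collect: bool):
    """Shared FindPath loop.

    Walks from ``src`` to ``dst``: for each target rank k (ascending) the
    mrca of dst's rank-k cluster is pulled down one rank per move, via a
    rank move when the two nodes involved are non-adjacent and via the
    unique admissible NNI move otherwise.  Exactly one NNI variant can
    lower the mrca; anything else indicates a bug, hence the assertion.
    """
    cl = list(src.clusters)
    dst_cl = dst.clusters
    count = 0
    trees = [src] if collect else None
    moves: list[Move] = [] if collect else None
    for k in range(len(dst_cl) - 1):  # root cluster needs no work
        target = dst_cl[k]
        r = k
        while not target <= cl[r]:
            r += 1
        while r > k:
            bottom, top = cl[r - 1], cl[r]
            if bottom < top:
                sibling = top - bottom
                c0, c1 = _ordered_children(cl, r - 1)
                in0 = bool(target & c0)
                in1 = bool(target & c1)
                assert in0 != in1, (
                    "FindPath invariant violated: no unique NNI variant "
                    "lowers the mrca (implementation bug)"
                )
                keep, variant = (c0, 0) if in0 else (c1, 1)
                cl[r - 1] = keep | sibling
                if collect:
                    moves.append(Move("nni", r, variant))
            else:
                cl[r - 1], cl[r] = cl[r], cl[r - 1]
                if collect:
                    moves.append(Move("rank", r))
            r -= 1
            count += 1
            if collect:
                trees.append(RankedTree(cl, validate=False))
    if collect:
        return MovePath(trees, moves)
    return count


def findpath(src: RankedTree, dst: RankedTree) -> MovePath:
    """Shortest RNNI path from ``src`` to ``dst`` (FindPath construction).

    The returned path length equals the RNNI distance, and every cluster
    shared by ``src`` and ``dst`` is present in each intermediate tree
    (cluster property).
    """
    _check_same_taxa(src, dst)
    return _findpath_core(src, dst, collect=True)


def distance(src: RankedTree, dst: RankedTree) -> int:
    """RNNI distance: minimal number of rank and NNI moves between trees."""
    _check_same_taxa(src, dst)
    if src == dst:
        return 0
    return _findpath_core(src, dst, collect=False)


# ---------------------------------------------------------------------------
# exhaustive oracles (small n)


def count_ranked_trees(n: int) -> int:
    """Number of ranked trees on n labelled leaves: n!(n-1)!/2^(n-1)."""
    if n < 2:
        raise ValueError("need n >= 2")
    return factorial(n) * factorial(n - 1) // 2 ** (n - 1)


def _check_exhaustive(n: int) -> None:
    if n > MAX_EXHAUSTIVE_N:
        raise ValueError(
            f"exhaustive treespace operations refuse n = {n} > {MAX_EXHAUSTIVE_N}: "
            f"the space holds {count_ranked_trees(n)} trees"
        )


def enumerate_space(taxa: Iterable[str]) -> list[RankedTree]:
    """All ranked trees on ``taxa`` via exhaustive merge sequences.

    Each ranked tree corresponds to a unique sequence of pairwise lineage
    merges (rank k assigned at the k-th merge), so enumerating all merge
    choices yields each tree exactly once.
    """
    taxa = sorted(set(taxa))
    n = len(taxa)
    if n < 2:
        raise ValueError("need at least 2 taxa")
    _check_exhaustive(n)
    out: list[RankedTree] = []
    lineages = [frozenset({t}) for t in taxa]

    def rec(lineages: list[frozenset], clusters: list[frozenset]) -> None:
        k = len(lineages)
        if k == 1:
            out.append(RankedTree(clusters, validate=False))
            return
        for i in range(k - 1):
            for j in range(i + 1, k):
                merged = lineages[i] | lineages[j]
                rest = [
                    lin for idx, lin in enumerate(lineages) if idx not in (i, j)
                ]
                rec(rest + [merged], clusters + [merged])

    rec(lineages, [])
    assert len(out) == count_ranked_trees(n)
    return out


def rnni_graph(taxa: Iterable[str]):
    """Full RNNI graph for small n.

    Returns ``(trees, index, adjacency)`` where ``index`` maps each tree
    to its position in ``trees`` and ``adjacency[i]`` lists neighbour
    positions.
    """
    trees = enumerate_space(taxa)
    index = {t: i for i, t in enumerate(trees)}
    adjacency = [
        sorted(index[u] for u in neighbours(t)) for t in trees
    ]
    return trees, index, adjacency


def bfs_distance(src: RankedTree, dst: RankedTree, adjacency=None, index=None) -> int:
    """Exact RNNI distance by breadth-first search (test oracle, n <= 7).

    With ``adjacency``/``index`` from :func:`rnni_graph` the search runs on
    the prebuilt graph; otherwise neighbourhoods are expanded on the fly.
    """
    _check_same_taxa(src, dst)
    _check_exhaustive(src.n_leaves)
    if src == dst:
        return 0
    if adjacency is not None and index is not None:
        s, d = index[src], index[dst]
        dist = {s: 0}
        queue = deque([s])
        while queue:
            v = queue.popleft()
            for w in adjacency[v]:
                if w not in dist:
                    dist[w] = dist[v] + 1
                    if w == d:
                        return dist[w]
                    queue.append(w)
        raise AssertionError("RNNI graph must be connected")
    dist = {src: 0}
    queue = deque([src])
    while queue:
        v = queue.popleft()
        for w in neighbours(v):
            if w not in dist:
                dist[w] = dist[v] + 1
                if w == dst:
                    return dist[w]
                queue.append(w)
    raise AssertionError("RNNI graph must be connected")


def bfs_eccentricity(src: RankedTree) -> int:
    """Largest BFS distance from ``src`` to any tree in its space (n <= 7)."""
    _check_exhaustive(src.n_leaves)
    dist = {src: 0}
    queue = deque([src])
    ecc = 0
    while queue:
        v = queue.popleft()
        for w in neighbours(v):
            if w not in dist:
                dist[w] = dist[v] + 1
                ecc = max(ecc, dist[w])
                queue.append(w)
    return ecc


def diameter(n: int, method: str = "auto") -> int:
    """Maximum RNNI distance between any two ranked trees on n leaves.

    The closed form ``(n-1)(n-2)/2`` is validated against all-pairs BFS for
    n <= 5 (and spot-validated at n = 6) in the test suite; ``method='bfs'``
    forces the exhaustive computation for small n.
    """
    if n < 2:
        raise ValueError("need n >= 2")
    if method == "bfs":
        _check_exhaustive(n)
        taxa = [f"t{i}" for i in range(n)]
        trees, index, adjacency = rnni_graph(taxa)
        best = 0
        for s in range(len(trees)):
            dist = [-1] * len(trees)
            dist[s] = 0
            queue = deque([s])
            while queue:
                v = queue.popleft()
                for w in adjacency[v]:
                    if dist[w] < 0:
                        dist[w] = dist[v] + 1
                        queue.append(w)
            best = max(best, max(dist))
        return best
    if method not in ("auto", "closed_form"):
        raise ValueError(f"unknown method {method!r}")
    return (n - 1) * (n - 2) // 2
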