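"""Mean-tree estimation: sum-of-squared-distances objective and the
centroid local search with a Sturm-style starting tree.

The mean (centroid) of a tree sample is a minimiser of the Frechet
variance, i.e. the sum of squared RNNI distances (SoS) to the sample.
``centroid`` performs a strict hill descent over RNNI neighbourhoods and
stops at a local optimum; ``sturm_start`` provides a good initial tree by
iterated shrinking steps along shortest paths.
"""

from __future__ import annotations

from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .rnni import distance, findpath, neighbours
from .trees import RankedTree, TreeError, TreeSample, to_ranked

__all__ = ["CentroidResult", "sos", "centroid", "sturm_start", "summarize"]


@dataclass
class CentroidResult:
    """Outcome of a centroid run.

    ``trajectory`` records ``(iteration, sos)`` pairs starting at iteration
    0 (the start tree) and is strictly decreasing in sos.  ``tie_events``
    lists ``(iteration, n_tied)`` whenever the minimal-SoS neighbour was
    not unique and the seeded RNG broke the tie.
    """

    tree: RankedTree
    sos: int
    iterations: int
    trajectory: list[tuple[int, int]]
    seed: int
    start_tree: RankedTree
    tie_events: list[tuple[int, int]] = field(default_factory=list)

    def trajectory_tsv(self) -> str:
        lines = ["iteration\tsos"]
        lines += [f"{i}\t{s}" for i, s in self.trajectory]
        return "\n".join(lines) + "\n"


def _ranked_sample(sample: TreeSample) -> list[RankedTree]:
    ranked = sample.ranked
    return ranked


def sos(
    t: RankedTree,
    sample: TreeSample,
    cache: Optional[dict] = None,
) -> int:
    """Sum over the sample of squared RNNI distances to ``t`` (integer).

    ``cache`` may be a dict shared across calls on the same sample; it maps
    candidate trees to their SoS value.
    """
    t = to_ranked(t)
    if cache is not None and t in cache:
        return cache[t]
    ranked = _ranked_sample(sample)
    if ranked and ranked[0].taxa != t.taxa:
        raise TreeError("query tree and sample are on different taxon sets")
    value = sum(distance(t, s) ** 2 for s in ranked)
    if cache is not None:
        cache[t] = value
    return value


def _sos_of(t: RankedTree, ranked: list[RankedTree], cache: dict) -> int:
    value = cache.get(t)
    if value is None:
        value = sum(distance(t, s) ** 2 for s in ranked)
        cache[t] = value
    return value


def centroid(
    sample: TreeSample,
    start: RankedTree,
    seed: int = 0,
    workers: int = 1,
    cache: Optional[dict] = None,
) -> CentroidResult:
    """Hill descent on the SoS objective over RNNI neighbourhoods.

    Each iteration evaluates every neighbour of the current tree (in
    parallel when ``workers > 1`` — results are collected in deterministic
    order first, so the worker count never changes the outcome), moves to
    a strictly improving neighbour of minimal SoS (ties broken uniformly
    by the seeded RNG), and stops at local optimality.  Deterministic
    given (sample order, start, seed).
    """
    start = to_ranked(start)
    ranked = _ranked_sample(sample)
    if ranked[0].taxa != start.taxa:
        raise TreeError("start tree and sample are on different taxon sets")
    rng = np.random.default_rng(seed)
    if cache is None:
        cache = {}
    current = start
    current_sos = _sos_of(current, ranked, cache)
    trajectory = [(0, current_sos)]
    tie_events: list[tuple[int, int]] = []
    iteration = 0
    while True:
        nbrs = sorted(neighbours(current), key=lambda t: t.sort_key)
        if workers > 1 and len(nbrs) > 1:
            with ThreadPoolExecutor(max_workers=workers) as pool:
                values = list(
                    pool.map(lambda t: _sos_of(t, ranked, cache), nbrs)
                )
        else:
            values = [_sos_of(t, ranked, cache) for t in nbrs]
        if not values:
            break
        best = min(values)
        if best >= current_sos:
            break
        minimal = [t for t, v in zip(nbrs, values) if v == best]
        iteration += 1
        if len(minimal) > 1:
            tie_events.append((iteration, len(minimal)))
            current = minimal[rng.integers(len(minimal))]
        else:
            current = minimal[0]
        current_sos = best
        trajectory.append((iteration, current_sos))
    return CentroidResult(
        tree=current,
        sos=current_sos,
        iterations=iteration,
        trajectory=trajectory,
        seed=seed,
        start_tree=start,
        tie_events=tie_events,
    )


def sturm_start(sample: TreeSample, seed: int = 0) -> RankedTree:
    """Starting tree by iterated shrinking steps along shortest paths.

    Sample trees are drawn without replacement in a seeded random order.
    The first drawn tree initialises the estimate T; at iteration
    k = 2..m, with p the shortest path from T towards the drawn tree R,
    the estimate moves to the tree at distance ``floor(d(T, R) / k)`` from
    T along p (a step of zero leaves T unchanged).  Runs in O(m * n^2).
    """
    ranked = _ranked_sample(sample)
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(ranked))
    current = ranked[order[0]]
    for k in range(2, len(ranked) + 1):
        drawn = ranked[order[k - 1]]
        path = findpath(current, drawn)
        step = len(path) // k
        if step:
            current = path.trees[step]
    return current


def summarize(
    sample: TreeSample,
    start_policy: str = "sturm",
    seed: int = 0,
    start_tree: Optional[RankedTree] = None,
    workers: int = 1,
    cache: Optional[dict] = None,
) -> CentroidResult:
    """Compose a starting tree with the centroid descent.

    ``start_policy`` is one of ``'sturm'`` (default), ``'given'`` (requires
    ``start_tree``) or ``'random'`` (uniform ranked tree from the seeded
    generator).
    """
    if start_policy == "sturm":
        start = sturm_start(sample, seed=seed)
    elif start_policy == "given":
        if start_tree is None:
            raise ValueError("start_policy='given' requires start_tree")
        start = to_ranked(start_tree)
    elif start_policy == "random":
        from .simulate import random_ranked_tree

        start = random_ranked_tree(sample.taxa, seed=seed)
    else:
        raise ValueError(f"unknown start_policy {start_policy!r}")
    return centroid(sample, start, seed=seed, workers=workers, cache=cache)
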