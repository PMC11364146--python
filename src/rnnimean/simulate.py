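"""Synthetic tree-sample generators.

These stand in for posterior samples: a uniform generator over ranked
trees (by uniform pair merging, which puts equal mass on every merge
sequence and hence on every ranked topology), RNNI random-walk clouds
around a focal tree, and node-height jitter on a fixed topology.  All
generators are bit-reproducible under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Union

import numpy as np

from .rnni import neighbours
from .trees import RankedTree, TimeTree, TreeSample

__all__ = [
    "WalkConfig",
    "random_ranked_tree",
    "random_walk_sample",
    "jitter_heights",
]


def _rng(seed: Union[int, np.random.Generator]) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def random_ranked_tree(
    taxa: Iterable[str], seed: Union[int, np.random.Generator] = 0
) -> RankedTree:
    """Uniform random ranked tree on ``taxa``.

    At each of the n-1 merge events every unordered pair of extant
    lineages is equally likely; each ranked tree arises from exactly one
    merge sequence, so each has probability prod_k 1/C(k, 2).
    """
    rng = _rng(seed)
    lineages = [frozenset({t}) for t in sorted(set(taxa))]
    if len(lineages) < 2:
        raise ValueError("need at least 2 taxa")
    clusters = []
    while len(lineages) > 1:
        k = len(lineages)
        pick = int(rng.integers(k * (k - 1) // 2))
        # unrank the pair index: pairs (i, j), i < j, in lexicographic order
        i = 0
        while pick >= k - 1 - i:
            pick -= k - 1 - i
            i += 1
        j = i + 1 + pick
        merged = lineages[i] | lineages[j]
        del lineages[j], lineages[i]
        lineages.append(merged)
        clusters.append(merged)
    return RankedTree(clusters, validate=False)


@dataclass
class WalkConfig:
    """Configuration of an RNNI random-walk cloud around ``centre``.

    ``step_distribution`` is ``('fixed', k)`` or ``('poisson', lam)``; each
    sample tree performs that many uniform moves from the centre.  With
    ``stay_probability > 0`` the walk is lazy: each step stays put with
    that probability (the simple walk is not stationary-uniform either
    way; tests must not assume uniformity).
    """

    centre: RankedTree
    m: int
    step_distribution: tuple = ("fixed", 1)
    seed: int = 0
    stay_probability: float = 0.0

    def __post_init__(self):
        if self.m < 1:
            raise ValueError("need m >= 1")
        kind, value = self.step_distribution
        if kind not in ("fixed", "poisson") or value < 0:
            raise ValueError(f"bad step_distribution {self.step_distribution!r}")
        if not 0.0 <= self.stay_probability < 1.0:
            raise ValueError("stay_probability must lie in [0, 1)")


def random_walk_sample(cfg: WalkConfig) -> TreeSample:
    """Sample of m trees, each an independent random walk from the centre.

    Every output tree lies within RNNI distance s of the centre, where s
    is that tree's drawn step count.
    """
    rng = _rng(cfg.seed)
    kind, value = cfg.step_distribution
    trees = []
    for _ in range(cfg.m):
        steps = value if kind == "fixed" else int(rng.poisson(value))
        current = cfg.centre
        for _ in range(steps):
            if cfg.stay_probability and rng.random() < cfg.stay_probability:
                continue
            nbrs = sorted(neighbours(current), key=lambda t: t.sort_key)
            if not nbrs:
                break
            current = nbrs[int(rng.integers(len(nbrs)))]
        trees.append(current)
    return TreeSample(trees)


def jitter_heights(
    topology: RankedTree,
    m: int,
    noise_sd: float,
    seed: Union[int, np.random.Generator] = 0,
    max_tries: int = 10_000,
) -> TreeSample:
    """Sample of m TimeTrees on one topology with jittered node heights.

    Base heights are 1..n-1 by rank; Gaussian noise with standard
    deviation ``noise_sd`` is added and the whole vector is resampled
    until the strict height ordering (and positivity) holds, i.e. the
    noise is truncated to the ordering-preserving region.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    if m < 1:
        raise ValueError("need m >= 1")
    rng = _rng(seed)
    n1 = len(topology.clusters)
    base = np.arange(1, n1 + 1, dtype=float)
    trees = []
    for _ in range(m):
        for _ in range(max_tries):
            h = base + rng.normal(0.0, noise_sd, size=n1) if noise_sd else base
            if h[0] > 0 and np.all(np.diff(h) > 0):
                break
        else:
            raise RuntimeError("could not draw strictly ordered heights")
        trees.append(TimeTree(topology, tuple(h)))
    return TreeSample(trees)
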