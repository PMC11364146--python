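import collections

import pytest

from rnnimean import RankedTree, enumerate_space, rnni_graph


@pytest.fixture
def caterpillar4():
    return RankedTree([{"A", "B"}, {"A", "B", "C"}, {"A", "B", "C", "D"}])


@pytest.fixture
def balanced4():
    return RankedTree([{"A", "B"}, {"C", "D"}, {"A", "B", "C", "D"}])


@pytest.fixture(scope="session")
def taxa5():
    return [f"t{i}" for i in range(5)]


@pytest.fixture(scope="session")
def space5(taxa5):
    return enumerate_space(taxa5)


@pytest.fixture(scope="session")
def graph4():
    """(trees, index, adjacency) for the full n=4 RNNI graph."""
    return rnni_graph(["A", "B", "C", "D"])


@pytest.fixture(scope="session")
def graph5(taxa5):
    return rnni_graph(taxa5)


def all_pairs_bfs(adjacency, source):
    """Plain BFS distances from ``source`` over an adjacency list (oracle)."""
    dist = [-1] * len(adjacency)
    dist[source] = 0
    queue = collections.deque([source])
    while queue:
        v = queue.popleft()
        for w in adjacency[v]:
            if dist[w] < 0:
                dist[w] = dist[v] + 1
                queue.append(w)
    return dist
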