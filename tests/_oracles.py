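"""Independent oracles, implemented without the package's routing path.

The shortest-path oracle is a plain Bellman-Ford relaxation over the edge
list — no priority queue, no scipy/networkx graph algorithms — so it shares
nothing with the Dijkstra-based implementation it checks.
"""

import numpy as np


def bellman_ford_times(network, source: int) -> np.ndarray:
    """Exhaustive edge relaxation; minutes from source to every node."""
    n = network.n_nodes
    a = network.edges[:, 0]
    b = network.edges[:, 1]
    w = network.travel_time_min
    dist = np.full(n, np.inf)
    dist[source] = 0.0
    for _ in range(n - 1):
        nd = dist.copy()
        np.minimum.at(nd, b, dist[a] + w)
        np.minimum.at(nd, a, dist[b] + w)
        if np.array_equal(nd, dist):
            break
        dist = nd
    return dist


def brute_force_best_travel(network, event_node: int, station_pool) -> tuple[float, int]:
    """Minimum route time over every station of a service; (time, id)."""
    dist = bellman_ford_times(network, event_node)
    return min((float(dist[s.node]), s.id) for s in station_pool)


def pooled_chisquare_p(counts: np.ndarray, expected: np.ndarray) -> float:
    """Goodness-of-fit p-value, pooling cells with expected count < 5."""
    from scipy.stats import chisquare

    keep = expected >= 5
    obs, exp = counts[keep], expected[keep]
    if (~keep).any():
        obs = np.append(obs, counts[~keep].sum())
        exp = np.append(exp, expected[~keep].sum())
    return float(chisquare(obs, exp).pvalue)
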