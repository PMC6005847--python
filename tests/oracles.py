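"""Independent brute-force oracles used to check the package implementation.

Everything here is deliberately naive (triple loops, breadth-first search,
full graph enumeration) and shares no code with the library paths it
checks.
"""

from __future__ import annotations

import itertools
import math
from collections import deque

import numpy as np
from scipy.optimize import minimize
from scipy.special import logsumexp


def brute_degree(adj) -> list[int]:
    n = len(adj)
    return [sum(1 for j in range(n) if adj[i][j]) for i in range(n)]


def brute_clustering(adj) -> list[float]:
    n = len(adj)
    out = []
    for i in range(n):
        nbrs = [j for j in range(n) if adj[i][j]]
        k = len(nbrs)
        if k < 2:
            out.append(0.0)
            continue
        links = sum(
            1 for a, b in itertools.combinations(nbrs, 2) if adj[a][b]
        )
        out.append(links / (k * (k - 1) / 2))
    return out


def _bfs_dist(adj, nodes, src):
    dist = {src: 0}
    q = deque([src])
    nodeset = set(nodes)
    while q:
        u = q.popleft()
        for v in nodes:
            if adj[u][v] and v in nodeset and v not in dist:
                dist[v] = dist[u] + 1
                q.append(v)
    return dist


def brute_local_efficiency(adj) -> list[float]:
    """Mean inverse shortest-path length within each neighbor subgraph."""
    n = len(adj)
    out = []
    for i in range(n):
        nbrs = [j for j in range(n) if adj[i][j]]
        k = len(nbrs)
        if k < 2:
            out.append(0.0)
            continue
        total = 0.0
        for a, b in itertools.combinations(nbrs, 2):
            d = _bfs_dist(adj, nbrs, a).get(b)
            if d:
                total += 1.0 / d
        out.append(total / (k * (k - 1) / 2))
    return out


def brute_esp_hist(adj) -> dict[int, int]:
    n = len(adj)
    hist: dict[int, int] = {}
    for i in range(n):
        for j in range(i + 1, n):
            if adj[i][j]:
                sp = sum(1 for k in range(n) if k not in (i, j) and adj[i][k] and adj[j][k])
                hist[sp] = hist.get(sp, 0) + 1
    return hist


def brute_gwesp(adj, decay: float) -> float:
    v = 0.0
    for sp, cnt in brute_esp_hist(adj).items():
        if sp >= 1:
            v += math.exp(decay) * (1 - (1 - math.exp(-decay)) ** sp) * cnt
    return v


def brute_stats(adj, terms, x=None, codes=None, n_levels=0, cells=None) -> np.ndarray:
    """Model statistics from first principles.

    ``terms`` is a list of ("edges",) / ("nodecov",) / ("nodemix",) /
    ("gwesp", decay) tuples; ``x`` the quantitative covariate, ``codes``
    categorical codes, ``cells`` the included (a, b) code pairs.
    """
    n = len(adj)
    edges = [(i, j) for i in range(n) for j in range(i + 1, n) if adj[i][j]]
    out = []
    for term in terms:
        if term[0] == "edges":
            out.append(float(len(edges)))
        elif term[0] == "nodecov":
            out.append(float(sum(x[i] + x[j] for i, j in edges)))
        elif term[0] == "nodemix":
            for a, b in cells:
                out.append(
                    float(
                        sum(
                            1
                            for i, j in edges
                            if {codes[i], codes[j]} == ({a, b} if a != b else {a})
                        )
                    )
                )
        elif term[0] == "gwesp":
            out.append(brute_gwesp(adj, term[1]))
        else:
            raise ValueError(term)
    return np.array(out)


def all_graphs(n: int):
    """Yield every adjacency matrix (as a list of lists) on n nodes."""
    dyads = list(itertools.combinations(range(n), 2))
    for bits in itertools.product((0, 1), repeat=len(dyads)):
        adj = [[0] * n for _ in range(n)]
        for (i, j), b in zip(dyads, bits):
            adj[i][j] = adj[j][i] = b
        yield adj


def enumeration_mle(adj_obs, stat_fn, k: int):
    """Exact MLE by summing the normalizing constant over all graphs.

    ``stat_fn`` maps an adjacency list-of-lists to a statistic vector of
    length ``k``. Only feasible for n <= 5 (at most 2^10 graphs).
    """
    n = len(adj_obs)
    G = np.array([stat_fn(a) for a in all_graphs(n)])
    g_obs = np.asarray(stat_fn(adj_obs), dtype=float)

    def nll(theta):
        return -(theta @ g_obs - logsumexp(G @ theta))

    def grad(theta):
        w = G @ theta
        w = np.exp(w - logsumexp(w))
        return -(g_obs - w @ G)

    res = minimize(nll, np.zeros(k), jac=grad, method="BFGS",
                   options={"gtol": 1e-10})
    return res.x


def enumeration_logZ(stat_fn, theta, n: int) -> float:
    """Exact log normalizing constant by enumeration."""
    G = np.array([stat_fn(a) for a in all_graphs(n)])
    return float(logsumexp(G @ np.asarray(theta, dtype=float)))


def random_adj(rng, n: int, p: float = 0.5):
    adj = [[0] * n for _ in range(n)]
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p:
                adj[i][j] = adj[j][i] = 1
    return adj
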