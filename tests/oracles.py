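"""Independent brute-force reference implementations used to check the
package's graph and statistics code on small instances.  These follow
textbook definitions directly (path enumeration, triple-loop APSP,
pairwise AUC counting, hypergeometric tail summation) and share no code
with the implementations they verify."""

from __future__ import annotations

import math
from collections import deque
from itertools import combinations

import numpy as np


def bfs_distances(adj: dict, source) -> dict:
    dist = {source: 0}
    queue = deque([source])
    while queue:
        u = queue.popleft()
        for v in adj[u]:
            if v not in dist:
                dist[v] = dist[u] + 1
                queue.append(v)
    return dist


def adjacency(edges, nodes) -> dict:
    adj = {n: set() for n in nodes}
    for u, v in edges:
        adj[u].add(v)
        adj[v].add(u)
    return adj


def all_shortest_paths(adj: dict, s, t) -> list[list]:
    """Enumerate every shortest s-t path via the BFS predecessor DAG."""
    dist = bfs_distances(adj, s)
    if t not in dist:
        return []
    preds = {n: [p for p in adj[n] if dist.get(p, -2) == dist[n] - 1] for n in dist}
    paths = []

    def walk(node, suffix):
        if node == s:
            paths.append([s] + suffix)
            return
        for p in preds[node]:
            walk(p, [node] + suffix)

    walk(t, [])
    return paths


def brute_betweenness(edges, nodes) -> dict:
    """Normalized betweenness by explicit shortest-path enumeration."""
    adj = adjacency(edges, nodes)
    bet = {n: 0.0 for n in nodes}
    for s, t in combinations(nodes, 2):
        paths = all_shortest_paths(adj, s, t)
        if not paths:
            continue
        for n in nodes:
            if n in (s, t):
                continue
            through = sum(1 for p in paths if n in p)
            bet[n] += through / len(paths)
    n = len(nodes)
    norm = 2.0 / ((n - 1) * (n - 2)) if n > 2 else 1.0
    return {k: v * norm for k, v in bet.items()}


def floyd_warshall(edges, nodes) -> dict:
    """All-pairs shortest hop counts by the classic triple loop."""
    inf = math.inf
    d = {(a, b): (0 if a == b else inf) for a in nodes for b in nodes}
    for u, v in edges:
        d[(u, v)] = 1
        d[(v, u)] = 1
    for k in nodes:
        for i in nodes:
            dik = d[(i, k)]
            if dik is inf:
                continue
            for j in nodes:
                if dik + d[(k, j)] < d[(i, j)]:
                    d[(i, j)] = dik + d[(k, j)]
    return d


def katz_series(edges, nodes, alpha: float, terms: int = 400) -> np.ndarray:
    """Katz vector via the truncated power series sum_k alpha^k A^k 1
    (including the k=0 constant term), L2-normalized."""
    idx = {n: i for i, n in enumerate(nodes)}
    a = np.zeros((len(nodes), len(nodes)))
    for u, v in edges:
        a[idx[u], idx[v]] = 1.0
        a[idx[v], idx[u]] = 1.0
    x = np.ones(len(nodes))
    term = np.ones(len(nodes))
    for _ in range(terms):
        term = alpha * (a @ term)
        x = x + term
    return x / np.linalg.norm(x)


def pairwise_auc(scores, labels) -> float:
    """AUC as the midrank-corrected fraction of concordant +/- pairs."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1.0
            elif p == q:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def hypergeom_tail(a: int, b: int, c: int, d: int) -> float:
    """One-sided (greater) Fisher p for table [[a, b], [c, d]] by direct
    summation of the hypergeometric pmf over k >= a."""
    row1, col1, n = a + b, a + c, a + b + c + d
    p = 0.0
    for k in range(a, min(row1, col1) + 1):
        p += (
            math.comb(col1, k)
            * math.comb(n - col1, row1 - k)
            / math.comb(n, row1)
        )
    return p


def bh_stepup(pvalues) -> np.ndarray:
    """Benjamini-Hochberg q-values computed from the definition."""
    p = np.asarray(pvalues, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    prev = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        prev = min(prev, p[i] * m / rank_from_top)
        q[i] = prev
    return q


def paired_t_p(tumor_row, normal_row) -> float:
    """Two-sided paired t-test from the textbook formula on log2(x+1)."""
    from scipy.stats import t as tdist

    d = np.log2(np.asarray(tumor_row) + 1.0) - np.log2(np.asarray(normal_row) + 1.0)
    n = len(d)
    tstat = d.mean() / (d.std(ddof=1) / math.sqrt(n))
    return 2.0 * tdist.sf(abs(tstat), df=n - 1)
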