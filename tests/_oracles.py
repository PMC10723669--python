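"""Independent brute-force oracles used to validate the implementation.

Everything here is written from first principles on adjacency dictionaries
(no calls into the package's feature code paths) so that agreement is a
genuine two-route check.
"""

from __future__ import annotations

from collections import deque
from itertools import combinations

import numpy as np


def adjacency(net) -> dict[str, set[str]]:
    adj: dict[str, set[str]] = {n: set() for n in net.nodes}
    for a, b in net.edges:
        adj[a].add(b)
        adj[b].add(a)
    return adj


def bfs_levels(adj, s):
    dist = {s: 0}
    q = deque([s])
    while q:
        u = q.popleft()
        for v in adj[u]:
            if v not in dist:
                dist[v] = dist[u] + 1
                q.append(v)
    return dist


def enumerate_shortest_paths(adj, s, t) -> list[list[str]]:
    """All shortest s-t paths by BFS levels + backtracking."""
    dist = bfs_levels(adj, s)
    if t not in dist:
        return []
    paths = []

    def back(node, acc):
        if node == s:
            paths.append([s] + acc)
            return
        for p in adj[node]:
            if p in dist and dist[p] == dist[node] - 1:
                back(p, [node] + acc)

    back(t, [])
    return paths


def brute_betweenness(net) -> dict[str, float]:
    """Sum over unordered pairs of fractions of shortest paths through v."""
    adj = adjacency(net)
    nodes = sorted(adj)
    btw = {v: 0.0 for v in nodes}
    for s, t in combinations(nodes, 2):
        paths = enumerate_shortest_paths(adj, s, t)
        if not paths:
            continue
        sigma = len(paths)
        for v in nodes:
            if v in (s, t):
                continue
            through = sum(1 for p in paths if v in p)
            if through:
                btw[v] += through / sigma
    return btw


def dense_pagerank(net, damping=0.85) -> dict[str, float]:
    """Solve (I - d*M) x = (1-d)/n directly; dangling columns are uniform."""
    nodes = sorted(net.nodes)
    n = len(nodes)
    idx = {g: i for i, g in enumerate(nodes)}
    M = np.zeros((n, n))
    adj = adjacency(net)
    for g in nodes:
        nbrs = adj[g]
        if nbrs:
            for h in nbrs:
                M[idx[h], idx[g]] = 1.0 / len(nbrs)
        else:
            M[:, idx[g]] = 1.0 / n
    x = np.linalg.solve(np.eye(n) - damping * M, np.full(n, (1 - damping) / n))
    return dict(zip(nodes, x))


def naive_clustering(net, gene) -> float:
    adj = adjacency(net)
    nbrs = sorted(adj[gene])
    k = len(nbrs)
    if k < 2:
        return 0.0
    links = sum(1 for a, b in combinations(nbrs, 2) if b in adj[a])
    return 2.0 * links / (k * (k - 1))


def naive_mean_dist(net, gene, disease_set) -> float:
    dist = bfs_levels(adjacency(net), gene)
    ls = [dist[d] for d in disease_set if d != gene and d in dist]
    return sum(ls) / len(ls) if ls else float(len(net.nodes))


def naive_neighbor_stats(net, gene, disease_set):
    adj = adjacency(net)
    n = len({x for x in adj[gene] if x in disease_set and x != gene})
    d = len(adj[gene])
    return n, (n / d if d else 0.0)


def brute_all_min_paths(net, s, t) -> list[list[str]]:
    """All simple s-t paths by DFS, filtered to minimum length."""
    adj = adjacency(net)
    all_paths = []

    def dfs(node, seen, acc):
        if node == t:
            all_paths.append(list(acc))
            return
        for v in sorted(adj[node]):
            if v not in seen:
                seen.add(v)
                acc.append(v)
                dfs(v, seen, acc)
                acc.pop()
                seen.remove(v)

    dfs(s, {s}, [s])
    if not all_paths:
        return []
    m = min(len(p) for p in all_paths)
    return sorted(p for p in all_paths if len(p) == m)


def brute_bh(pvals) -> list[float]:
    """Step-up Benjamini-Hochberg applied literally."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    adj = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, pvals[i] * m / rank)
        adj[i] = running
    return adj


def random_net(rng, n_max=30, p_choices=(0.05, 0.15, 0.3, 0.6, 0.9)):
    """Random G(n, p) as a PPINetwork, mixed densities, isolated nodes kept."""
    from aaanet.network import PPINetwork

    n = int(rng.integers(2, n_max + 1))
    p = float(rng.choice(p_choices))
    names = [f"n{i:02d}" for i in range(n)]
    edges = [
        (names[i], names[j])
        for i in range(n)
        for j in range(i + 1, n)
        if rng.random() < p
    ]
    return PPINetwork.from_edges(edges, nodes=names)
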