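"""Brute-force oracles for network traits and small-pedigree kinship.

Everything here is deliberately naive (exhaustive simple-path enumeration,
dense eigendecomposition, direct counting) and independent of the package's
computation paths, so agreement is meaningful.
"""

import itertools

import numpy as np


def _all_simple_paths(adj, s, t, n):
    """Yield every simple path s -> t as a node tuple; adj[i][j] = weight or None."""
    stack = [(s, (s,))]
    while stack:
        node, path = stack.pop()
        if node == t:
            yield path
            continue
        for nxt in range(n):
            if adj[node][nxt] is not None and nxt not in path:
                stack.append((nxt, path + (nxt,)))


def shortest_paths_enumerated(adj, n):
    """All-pairs shortest-path costs and full sets of cheapest simple paths."""
    dist = [[np.inf] * n for _ in range(n)]
    best_paths = [[[] for _ in range(n)] for _ in range(n)]
    for s in range(n):
        dist[s][s] = 0.0
        for t in range(n):
            if t == s:
                continue
            best = np.inf
            paths = []
            for path in _all_simple_paths(adj, s, t, n):
                cost = sum(adj[path[k]][path[k + 1]] for k in range(len(path) - 1))
                if cost < best:
                    best = cost
                    paths = [path]
                elif cost == best:
                    paths.append(path)
            dist[s][t] = best
            best_paths[s][t] = paths
    return dist, best_paths


def graph_to_adj(g):
    nodes = list(g.graph.nodes)
    n = len(nodes)
    pos = {u: i for i, u in enumerate(nodes)}
    adj = [[None] * n for _ in range(n)]
    for a, b, d in g.graph.edges(data=True):
        adj[pos[a]][pos[b]] = adj[pos[b]][pos[a]] = d["weight"]
    return nodes, adj


def betweenness_oracle(g):
    """Fractional-count betweenness over enumerated cheapest paths, normalized."""
    nodes, adj = graph_to_adj(g)
    n = len(nodes)
    score = dict.fromkeys(nodes, 0.0)
    _, best = shortest_paths_enumerated(adj, n)
    for s in range(n):
        for t in range(s + 1, n):
            paths = best[s][t]
            if not paths:
                continue
            sigma = len(paths)
            for v in range(n):
                if v in (s, t):
                    continue
                through = sum(1 for p in paths if v in p)
                score[nodes[v]] += through / sigma
    norm = (n - 1) * (n - 2) / 2.0
    return {u: (s / norm if norm > 0 else 0.0) for u, s in score.items()}


def closeness_oracle(g):
    """Wasserman-Faust closeness from enumerated shortest-path costs."""
    nodes, adj = graph_to_adj(g)
    n = len(nodes)
    dist, _ = shortest_paths_enumerated(adj, n)
    out = {}
    for v in range(n):
        reach = [dist[v][u] for u in range(n) if u != v and np.isfinite(dist[v][u])]
        if not reach:
            out[nodes[v]] = 0.0
            continue
        r = len(reach)
        out[nodes[v]] = (r / sum(reach)) * (r / (n - 1))
    return out


def degree_oracle(g):
    n = g.graph.number_of_nodes()
    return {v: len(list(g.graph[v])) / (n - 1) for v in g.graph.nodes}


def weighted_degree_oracle(g):
    return {v: sum(d["weight"] for _, _, d in g.graph.edges(v, data=True))
            for v in g.graph.nodes}


def clustering_oracle(g):
    out = {}
    for v in g.graph.nodes:
        nbrs = list(g.graph[v])
        k = len(nbrs)
        if k < 2:
            out[v] = 0.0
            continue
        links = sum(1 for a, b in itertools.combinations(nbrs, 2)
                    if g.graph.has_edge(a, b))
        out[v] = links / (k * (k - 1) / 2.0)
    return out


def eigenvector_oracle(g):
    """Leading eigenvector via dense symmetric eigendecomposition, max = 1."""
    import networkx as nx

    nodes = list(g.graph.nodes)
    A = nx.to_numpy_array(g.graph, nodelist=nodes, weight="weight")
    if A.sum() == 0:
        return dict.fromkeys(nodes, 0.0)
    w, V = np.linalg.eigh(A)
    v = np.abs(V[:, -1])
    v /= v.max()
    v[v < 1e-9] = 0.0
    return {u: float(s) for u, s in zip(nodes, v)}


ORACLES = {
    "degree": degree_oracle,
    "weighted_degree": weighted_degree_oracle,
    "betweenness": betweenness_oracle,
    "closeness": closeness_oracle,
    "eigenvector": eigenvector_oracle,
    "clustering": clustering_oracle,
}


def dense_A_kinship(ped):
    """A = 2 * coancestry matrix, computed by the kinship recursion."""
    n = ped.n
    f = np.zeros((n, n))
    for i in range(n):
        si, di = ped.sire[i], ped.dam[i]
        for j in range(i):
            val = 0.0
            if si:
                val += 0.5 * f[si - 1, j]
            if di:
                val += 0.5 * f[di - 1, j]
            f[i, j] = f[j, i] = val
        fsd = f[si - 1, di - 1] if (si and di) else 0.0
        f[i, i] = 0.5 * (1.0 + fsd)
    return 2.0 * f
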