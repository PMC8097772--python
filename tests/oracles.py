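"""Independent brute-force oracles used to cross-check the implementation.

Deliberately naive: shortest paths by exhaustive simple-path enumeration,
betweenness by direct counting over enumerated shortest paths, eigenvector
by dense power iteration with a diagonal shift (the shift breaks the +/-
eigenvalue symmetry of bipartite adjacency matrices without changing
eigenvectors).  Only usable on tiny graphs.
"""

from __future__ import annotations

import numpy as np

TOL = 1e-12


def enumerate_simple_paths(adj: dict, s, t):
    """All simple paths s -> t as lists of nodes."""
    paths = []

    def walk(node, visited, path):
        if node == t:
            paths.append(list(path))
            return
        for nb in adj[node]:
            if nb not in visited:
                visited.add(nb)
                path.append(nb)
                walk(nb, visited, path)
                path.pop()
                visited.remove(nb)

    walk(s, {s}, [s])
    return paths


def brute_force_centralities(nodes, edges, lengths=None):
    """degree / closeness / betweenness / eigenvector by exhaustive search.

    ``edges`` maps frozenset({u, v}) -> weight; ``lengths`` (same keys) are
    the shortest-path edge lengths (defaults to the weights).
    """
    if lengths is None:
        lengths = edges
    adj = {n: set() for n in nodes}
    for e in edges:
        u, v = tuple(e)
        adj[u].add(v)
        adj[v].add(u)

    def path_len(path):
        return sum(lengths[frozenset((path[i], path[i + 1]))] for i in range(len(path) - 1))

    degree = {n: float(len(adj[n])) for n in nodes}

    # all-pairs shortest paths by enumeration
    shortest = {}  # (s, t) unordered -> (dist, list of shortest paths)
    node_list = sorted(nodes)
    for i, s in enumerate(node_list):
        for t in node_list[i + 1 :]:
            paths = enumerate_simple_paths(adj, s, t)
            if not paths:
                continue
            dists = [path_len(p) for p in paths]
            dmin = min(dists)
            best = [p for p, d in zip(paths, dists) if d <= dmin + TOL]
            shortest[(s, t)] = (dmin, best)

    closeness = {}
    for n in nodes:
        total = 0.0
        for (s, t), (d, _) in shortest.items():
            if n in (s, t):
                total += d
        closeness[n] = 1.0 / total if total > 0 else 0.0

    betweenness = {n: 0.0 for n in nodes}
    for (s, t), (_, best) in shortest.items():
        for v in nodes:
            if v in (s, t):
                continue
            through = sum(1 for p in best if v in p)
            if through:
                betweenness[v] += through / len(best)

    eigenvector = _power_iteration_eigenvector(node_list, adj, edges)
    return {
        "degree": degree,
        "closeness": closeness,
        "betweenness": betweenness,
        "eigenvector": eigenvector,
    }


def _power_iteration_eigenvector(node_list, adj, edges):
    idx = {n: i for i, n in enumerate(node_list)}
    n = len(node_list)
    a = np.zeros((n, n))
    for e, w in edges.items():
        u, v = tuple(e)
        a[idx[u], idx[v]] = a[idx[v], idx[u]] = w

    # connected components by flood fill
    unseen = set(node_list)
    out = {}
    while unseen:
        start = next(iter(unseen))
        comp = {start}
        frontier = [start]
        while frontier:
            x = frontier.pop()
            for y in adj[x]:
                if y not in comp:
                    comp.add(y)
                    frontier.append(y)
        unseen -= comp
        cidx = [idx[c] for c in sorted(comp)]
        sub = a[np.ix_(cidx, cidx)]
        shift = 1.0 + np.abs(sub).sum(axis=1).max()
        m = sub + shift * np.eye(len(cidx))
        v = np.ones(len(cidx))
        for _ in range(100000):
            nv = m @ v
            nv /= np.linalg.norm(nv)
            if np.linalg.norm(nv - v) < 1e-15:
                break
            v = nv
        v = np.abs(v)
        if v.max() > 0:
            v = v / v.max()
        for c, val in zip(sorted(comp), v):
            out[c] = float(val)
    return out
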