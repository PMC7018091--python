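"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own algorithms: tree topologies are
enumerated exhaustively, branch lengths are fitted by least squares on the
path-edge incidence system, and additive matrices are generated by explicit
path summation on randomly built trees.
"""

import itertools

import numpy as np


def enumerate_topologies(labels):
    """All unrooted binary tree topologies over ``labels`` as edge lists."""
    base = [("_i0", labels[0]), ("_i0", labels[1]), ("_i0", labels[2])]
    trees = [base]
    for idx, leaf in enumerate(labels[3:], start=1):
        new_trees = []
        for edges in trees:
            for k, (u, v) in enumerate(edges):
                w = f"_i{idx}_{k}"
                out = [e for m, e in enumerate(edges) if m != k]
                out += [(u, w), (w, v), (w, leaf)]
                new_trees.append(out)
        trees = new_trees
    return trees


def splits_of_edges(edges, labels):
    """Canonical non-trivial bipartitions of an edge-list tree."""
    labels = set(labels)
    adj = {}
    for u, v in edges:
        adj.setdefault(u, []).append(v)
        adj.setdefault(v, []).append(u)

    def side(u, v):
        leaves = set()
        visited = {v}
        stack = [v]
        while stack:
            node = stack.pop()
            if node in labels:
                leaves.add(node)
            for nxt in adj[node]:
                if nxt != u and nxt not in visited:
                    visited.add(nxt)
                    stack.append(nxt)
        return frozenset(leaves)

    anchor = min(labels)
    splits = set()
    for u, v in edges:
        below = side(u, v)
        s = below if anchor not in below else frozenset(labels) - below
        if 2 <= len(s) <= len(labels) - 2:
            splits.add(s)
    return splits


def lstsq_residual(edges, labels, dmat):
    """Least-squares branch-length fit residual of a topology to a matrix."""
    index = {lab: i for i, lab in enumerate(labels)}
    adj = {}
    for e, (u, v) in enumerate(edges):
        adj.setdefault(u, []).append((v, e))
        adj.setdefault(v, []).append((u, e))

    def path_edges(a, b):
        stack = [(a, [])]
        seen = {a}
        while stack:
            node, used = stack.pop()
            if node == b:
                return used
            for nxt, e in adj[node]:
                if nxt not in seen:
                    seen.add(nxt)
                    stack.append((nxt, used + [e]))
        raise AssertionError("disconnected topology")

    pairs = list(itertools.combinations(labels, 2))
    A = np.zeros((len(pairs), len(edges)))
    y = np.zeros(len(pairs))
    for row, (a, b) in enumerate(pairs):
        for e in path_edges(a, b):
            A[row, e] = 1
        y[row] = dmat[index[a], index[b]]
    x, *_ = np.linalg.lstsq(A, y, rcond=None)
    return float(np.linalg.norm(A @ x - y))


def brute_force_topology(labels, dmat):
    """Splits of the best least-squares topology over all enumerations."""
    best, best_res = None, None
    for edges in enumerate_topologies(list(labels)):
        res = lstsq_residual(edges, labels, dmat)
        if best_res is None or res < best_res:
            best, best_res = edges, res
    return splits_of_edges(best, labels)


def random_additive_matrix(labels, rng):
    """(distance matrix, true splits) from a random binary tree with
    uniform(0.5, 3) branch lengths, distances by explicit path summation."""
    topologies = enumerate_topologies(list(labels))
    topo = topologies[int(rng.integers(len(topologies)))]
    lengths = {e: float(rng.uniform(0.5, 3.0)) for e in range(len(topo))}
    index = {lab: i for i, lab in enumerate(labels)}
    adj = {}
    for e, (u, v) in enumerate(topo):
        adj.setdefault(u, []).append((v, e))
        adj.setdefault(v, []).append((u, e))
    n = len(labels)
    d = np.zeros((n, n))
    for a, b in itertools.combinations(labels, 2):
        stack = [(a, 0.0)]
        seen = {a}
        while stack:
            node, dist = stack.pop()
            if node == b:
                d[index[a], index[b]] = d[index[b], index[a]] = dist
                break
            for nxt, e in adj[node]:
                if nxt not in seen:
                    seen.add(nxt)
                    stack.append((nxt, dist + lengths[e]))
    return d, splits_of_edges(topo, labels)
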