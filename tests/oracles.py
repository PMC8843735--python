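"""Independent brute-force oracles shared by the unit and acceptance tests.

Kept deliberately naive (exhaustive enumeration, least squares) so they
cannot share a failure mode with the implementations they check.
"""

from itertools import combinations

import numpy as np


def enumerate_unrooted_topologies(leaves):
    """All unrooted binary topologies on the given leaves, built by
    sequential leaf insertion. Each topology is (edges, adjacency) with
    leaves as strings and internal nodes as ints."""
    leaves = list(leaves)
    assert len(leaves) >= 3
    star = [(0, leaves[0]), (0, leaves[1]), (0, leaves[2])]
    topologies = [star]
    next_internal = 1
    for leaf in leaves[3:]:
        grown = []
        for edges in topologies:
            for i, (a, b) in enumerate(edges):
                node = next_internal
                new_edges = edges[:i] + edges[i + 1:]
                new_edges += [(a, node), (node, b), (node, leaf)]
                grown.append(new_edges)
        next_internal += 1
        topologies = grown
    return topologies


def _adjacency(edges):
    adj = {}
    for a, b in edges:
        adj.setdefault(a, []).append(b)
        adj.setdefault(b, []).append(a)
    return adj


def _path_edges(edges, src, dst):
    adj = _adjacency(edges)
    stack = [(src, None, [])]
    while stack:
        node, prev, path = stack.pop()
        if node == dst:
            return path
        for nxt in adj[node]:
            if nxt != prev:
                e = frozenset((node, nxt))
                stack.append((nxt, node, path + [e]))
    raise AssertionError("disconnected topology")


def least_squares_fit(edges, leaves, dist):
    """Least-squares branch lengths for a topology against a distance
    matrix dict {(i, j): d}. Returns (residual_sum_sq, path_length dict)."""
    edge_keys = [frozenset(e) for e in edges]
    pairs = list(combinations(leaves, 2))
    A = np.zeros((len(pairs), len(edge_keys)))
    y = np.zeros(len(pairs))
    for r, (i, j) in enumerate(pairs):
        for e in _path_edges(edges, i, j):
            A[r, edge_keys.index(e)] = 1.0
        y[r] = dist[(i, j)] if (i, j) in dist else dist[(j, i)]
    x, *_ = np.linalg.lstsq(A, y, rcond=None)
    fitted = A @ x
    resid = float(((fitted - y) ** 2).sum())
    paths = {p: float(f) for p, f in zip(pairs, fitted)}
    return resid, paths


def best_topology_splits(leaves, dist):
    """Splits of the minimum-residual least-squares topology."""
    best = None
    for edges in enumerate_unrooted_topologies(leaves):
        resid, _ = least_squares_fit(edges, leaves, dist)
        if best is None or resid < best[0]:
            best = (resid, edges)
    return topology_splits(best[1], leaves), best[0]


def topology_splits(edges, leaves):
    """Nontrivial bipartitions induced by internal edges."""
    leafset = set(leaves)
    splits = set()
    for a, b in edges:
        if isinstance(a, str) or isinstance(b, str):
            continue  # pendant edge
        pruned = [e for e in edges if frozenset(e) != frozenset((a, b))]
        adj = _adjacency(pruned)
        side = set()
        stack = [a]
        seen = set()
        while stack:
            node = stack.pop()
            if node in seen:
                continue
            seen.add(node)
            if isinstance(node, str):
                side.add(node)
            stack.extend(adj.get(node, []))
        if 1 < len(side) < len(leafset) - 1:
            splits.add(frozenset({frozenset(side), frozenset(leafset - side)}))
    return splits


def skbio_tree_splits(root):
    """Nontrivial leaf bipartitions of an skbio TreeNode."""
    leaves = {t.name for t in root.tips()}
    splits = set()
    for node in root.traverse(include_self=False):
        if node.is_tip():
            continue
        side = {t.name for t in node.tips()}
        if 1 < len(side) < len(leaves) - 1:
            splits.add(frozenset({frozenset(side), frozenset(leaves - side)}))
    return splits


def random_additive_matrix(leaves, rng):
    """Distances realized by a random binary tree with positive lengths."""
    topos = enumerate_unrooted_topologies(leaves)
    edges = topos[int(rng.integers(0, len(topos)))]
    lengths = {frozenset(e): float(rng.uniform(0.5, 3.0)) for e in edges}
    dist = {}
    for i, j in combinations(leaves, 2):
        dist[(i, j)] = sum(lengths[e] for e in _path_edges(edges, i, j))
    return dist, edges
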