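"""Independent oracles and random-structure generators for the test suite.

Everything here deliberately avoids the package's own algorithmic paths:
distances come from BFS on an undirected adjacency graph, splits from
edge-removal component enumeration, UPGMA from a naive O(n^3) agglomerator,
and parsimony scores from exhaustive assignment of internal-node states.
"""

from __future__ import annotations

import itertools
from collections import deque

import numpy as np

from phylofunc import PhyloTree, parse_newick


# -- random trees ----------------------------------------------------------


def random_binary_newick(labels, rng, with_lengths: bool = True) -> str:
    """Random binary topology over ``labels`` by sequential random joins."""
    def blen():
        return f":{rng.uniform(0.1, 2.0):.6f}" if with_lengths else ""

    nodes = [f"{lab}{blen()}" for lab in labels]
    while len(nodes) > 2:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        nodes.append(f"({a},{b}){blen()}")
    return f"({nodes[0]},{nodes[1]});"


def random_binary_tree(n, rng, with_lengths: bool = True) -> PhyloTree:
    labels = [f"t{k}" for k in range(n)]
    return parse_newick(random_binary_newick(labels, rng, with_lengths))


def polytomize(tree: PhyloTree, rng, prob: float = 0.3) -> PhyloTree:
    """Collapse random internal edges, creating polytomies."""
    out = tree.copy()
    victims = [
        nd for nd in out.dendropy_tree.preorder_internal_node_iter()
        if nd.parent_node is not None and rng.random() < prob
    ]
    for nd in victims:
        nd.edge.collapse()
    return PhyloTree(out.dendropy_tree)


# -- graph-based distance / split oracles ----------------------------------


def _adjacency(tree: PhyloTree):
    """Undirected weighted adjacency over dendropy node ids."""
    adj: dict[int, list[tuple[int, float]]] = {}
    names: dict[int, str] = {}
    for node in tree.dendropy_tree.preorder_node_iter():
        adj.setdefault(id(node), [])
        if node.is_leaf():
            names[id(node)] = node.taxon.label
        if node.parent_node is not None:
            w = node.edge.length
            adj[id(node)].append((id(node.parent_node), w))
            adj.setdefault(id(node.parent_node), []).append((id(node), w))
    return adj, names


def bfs_path_distance(tree: PhyloTree, a: str, b: str) -> float:
    """Tip-to-tip path length via BFS over the undirected tree graph."""
    adj, names = _adjacency(tree)
    start = next(k for k, v in names.items() if v == a)
    goal = next(k for k, v in names.items() if v == b)
    dist = {start: 0.0}
    q = deque([start])
    while q:
        u = q.popleft()
        if u == goal:
            return dist[u]
        for v, w in adj[u]:
            if v not in dist:
                dist[v] = dist[u] + w
                q.append(v)
    raise AssertionError("tips not connected")


def splits_by_edge_removal(tree: PhyloTree) -> set[frozenset]:
    """Non-trivial splits by deleting each edge and flooding one side."""
    adj, names = _adjacency(tree)
    tips = frozenset(names.values())
    ref = min(tips)
    out = set()
    for u in adj:
        for v, _w in adj[u]:
            if u >= v:
                continue
            side = set()
            seen = {v}
            q = deque([u])
            seen.add(u)
            while q:
                x = q.popleft()
                if x in names:
                    side.add(names[x])
                for y, _ in adj[x]:
                    if y not in seen:
                        seen.add(y)
                        q.append(y)
            side = frozenset(side)
            if 2 <= len(side) <= len(tips) - 2:
                out.add(side if ref not in side else tips - side)
    return out


# -- naive UPGMA -----------------------------------------------------------


def naive_upgma_cophenetic(dist: np.ndarray) -> np.ndarray:
    """O(n^3) UPGMA; returns the implied cophenetic matrix."""
    n = dist.shape[0]
    d = dist.astype(float).copy()
    active = list(range(n))
    members = {i: [i] for i in range(n)}
    coph = np.zeros((n, n))
    cur = {(i, j): d[i, j] for i in range(n) for j in range(n) if i < j}
    while len(active) > 1:
        best, bd = None, np.inf
        for a, b in itertools.combinations(active, 2):
            key = (min(a, b), max(a, b))
            if cur[key] < bd:
                bd, best = cur[key], key
        a, b = best
        for i in members[a]:
            for j in members[b]:
                coph[i, j] = coph[j, i] = bd
        na, nb = len(members[a]), len(members[b])
        new = max(members) + 1 if max(members) >= n else n
        new = max(list(members)) + 1
        members[new] = members.pop(a) + members.pop(b)
        active = [x for x in active if x not in (a, b)]
        for c in active:
            da = cur.pop((min(a, c), max(a, c)))
            db = cur.pop((min(b, c), max(b, c)))
            cur[(min(new, c), max(new, c))] = (na * da + nb * db) / (na + nb)
        cur.pop((a, b))
        active.append(new)
    return coph


# -- exhaustive parsimony --------------------------------------------------


def exhaustive_parsimony(tree: PhyloTree, states: dict[str, int]) -> int:
    """Minimum state changes by brute force over internal-node assignments.

    ``states`` maps tip label to 0/1, or -1 for missing ('?'); missing tips
    are free to take either state.
    """
    nodes = list(tree.dendropy_tree.preorder_node_iter())
    free = [nd for nd in nodes
            if not nd.is_leaf() or states.get(nd.taxon.label, -1) == -1]
    fixed = {id(nd): states[nd.taxon.label] for nd in nodes
             if nd.is_leaf() and states.get(nd.taxon.label, -1) != -1}
    edges = [(id(nd.parent_node), id(nd)) for nd in nodes
             if nd.parent_node is not None]
    best = np.inf
    for assign in itertools.product((0, 1), repeat=len(free)):
        full = dict(fixed)
        for nd, s in zip(free, assign):
            full[id(nd)] = s
        changes = sum(full[u] != full[v] for u, v in edges)
        best = min(best, changes)
    return int(best)


def all_five_taxon_trees(labels=("a", "b", "c", "d", "e")) -> list[PhyloTree]:
    """All 15 unrooted binary topologies on five taxa (as rooted newicks)."""
    a, b, c, d, e = labels
    base = [((0, 1), 2)]  # the single unrooted 3-taxon tree, rooted

    def insert_everywhere(tree, leaf):
        yield (tree, leaf)
        if not isinstance(tree, int):
            left, right = tree
            for sub in insert_everywhere(left, leaf):
                yield (sub, right)
            for sub in insert_everywhere(right, leaf):
                yield (left, sub)

    four = [t for t0 in base for t in insert_everywhere(t0, 3)]
    five = [t for t0 in four for t in insert_everywhere(t0, 4)]

    def to_newick(t):
        if isinstance(t, int):
            return f"{labels[t]}:1"
        return f"({to_newick(t[0])},{to_newick(t[1])}):1"

    seen, out = set(), []
    for t in five:
        tree = parse_newick(to_newick(t) + ";")
        from phylofunc import bipartitions
        key = frozenset(bipartitions(tree))
        if key not in seen:
            seen.add(key)
            out.append(tree)
    return out
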