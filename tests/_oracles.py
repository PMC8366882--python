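"""Independent oracles used by the tests.

Everything here is deliberately naive (exhaustive enumeration, closed forms,
path sums on explicit trees) and shares no code with the package internals it
checks.
"""
from __future__ import annotations

import itertools
import random


def brute_force_align_score(
    ref: str,
    query: str,
    match: float = 1.0,
    mismatch: float = -1.0,
    gap_open: float = -5.0,
    gap_extend: float = -2.0,
) -> float:
    """Optimal semi-global score by exhaustive enumeration of alignments.

    Gap runs cost open + (L-1)*extend, except runs of reference overhang
    (gaps in the query row) touching either end, which are free. Exponential;
    only usable for sequences of length <= ~7.
    """
    best = [-float("inf")]

    def score(ops: list[str]) -> float:
        lead = 0
        while lead < len(ops) and ops[lead] == "D":
            lead += 1
        trail = 0
        while trail < len(ops) - lead and ops[len(ops) - 1 - trail] == "D":
            trail += 1
        total = 0.0
        prev = None
        i = j = 0
        for t, op in enumerate(ops):
            if op == "M":
                total += match if ref[i] == query[j] else mismatch
                i += 1
                j += 1
                prev = "M"
            elif op == "D":
                free = t < lead or t >= len(ops) - trail
                if not free:
                    total += gap_extend if prev == "D" else gap_open
                i += 1
                prev = "D" if not free else None
            else:
                total += gap_extend if prev == "I" else gap_open
                j += 1
                prev = "I"
        return total

    def rec(i: int, j: int, ops: list[str]):
        if i == len(ref) and j == len(query):
            s = score(ops)
            if s > best[0]:
                best[0] = s
            return
        if i < len(ref) and j < len(query):
            rec(i + 1, j + 1, ops + ["M"])
        if i < len(ref):
            rec(i + 1, j, ops + ["D"])
        if j < len(query):
            rec(i, j + 1, ops + ["I"])

    rec(0, 0, [])
    return best[0]


# --- random additive trees ----------------------------------------------------


class _Node:
    def __init__(self, name=None):
        self.name = name
        self.edges = []  # (other_node, length)


def random_additive_tree(n_taxa: int, rng: random.Random):
    """A random unrooted binary tree with uniform(0.05, 0.5) branch lengths.

    Returns (labels, distance matrix as dict of dicts, set of nontrivial
    bipartitions as canonical frozensets).
    """
    labels = [f"T{i}" for i in range(n_taxa)]
    nodes = [_Node(lbl) for lbl in labels]
    active = list(nodes)
    while len(active) > 3:
        i, j = sorted(rng.sample(range(len(active)), 2))
        a, b = active[i], active[j]
        parent = _Node()
        for child in (a, b):
            ln = rng.uniform(0.05, 0.5)
            parent.edges.append((child, ln))
            child.edges.append((parent, ln))
        active = [x for x in active if x not in (a, b)] + [parent]
    center = _Node()
    for child in active:
        ln = rng.uniform(0.05, 0.5)
        center.edges.append((child, ln))
        child.edges.append((center, ln))

    # path distances by DFS from every leaf
    def distances_from(start):
        out = {start: 0.0}
        stack = [start]
        while stack:
            cur = stack.pop()
            for other, ln in cur.edges:
                if other not in out:
                    out[other] = out[cur] + ln
                    stack.append(other)
        return out

    dmat = {}
    for node in nodes:
        dist = distances_from(node)
        dmat[node.name] = {other.name: dist[other] for other in nodes}

    # bipartitions: for each internal edge, leaves on one side
    all_leaves = frozenset(labels)
    anchor = min(all_leaves)
    bips = set()

    def leaves_under(node, parent):
        if node.name is not None:
            return {node.name}
        out = set()
        for other, _ in node.edges:
            if other is not parent:
                out |= leaves_under(other, node)
        return out

    seen_edges = set()
    stack = [(center, None)]
    while stack:
        cur, parent = stack.pop()
        for other, _ in cur.edges:
            if other is parent:
                continue
            key = (id(cur), id(other))
            if key in seen_edges:
                continue
            seen_edges.add(key)
            side = frozenset(leaves_under(other, cur))
            if 1 < len(side) < n_taxa - 1:
                canon = side if anchor not in side else all_leaves - side
                bips.add(canon)
            stack.append((other, cur))
    return labels, dmat, bips


def four_point_split(labels, dmat):
    """The true split of a 4-taxon additive matrix by the four-point
    condition: the pairing with the smallest sum is the cherry pair."""
    a, b, c, d = labels
    sums = {
        frozenset([frozenset([a, b]), frozenset([c, d])]): dmat[a][b] + dmat[c][d],
        frozenset([frozenset([a, c]), frozenset([b, d])]): dmat[a][c] + dmat[b][d],
        frozenset([frozenset([a, d]), frozenset([b, c])]): dmat[a][d] + dmat[b][c],
    }
    return min(sums, key=sums.get)


def tree_path_distances(node, acc=None, depth=0.0, out=None):
    """Leaf-to-leaf path distances of a package TreeNode (via recursion)."""
    # collect (leaf_name, depth) under each child, then combine through node
    def collect(nd, depth):
        if nd.is_leaf:
            return [(nd.name, depth)]
        got = []
        for c in nd.children:
            got.extend(collect(c, depth + c.branch_length))
        return got

    dists = {}
    groups = [collect(c, c.branch_length) for c in node.children]
    flat = [item for g in groups for item in g]
    # distances within one child subtree: recurse
    for c in node.children:
        if not c.is_leaf:
            sub = tree_path_distances(c)
            dists.update(sub)
    for gi, gj in itertools.combinations(range(len(groups)), 2):
        for na, da in groups[gi]:
            for nb, db in groups[gj]:
                dists[frozenset([na, nb])] = da + db
    return dists
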