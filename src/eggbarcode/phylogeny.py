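"""Distance-based verification of assignments.

Builds a K2P distance matrix over an aligned barcode set (pairwise deletion
of gap/ambiguous sites), a neighbor-joining tree with column-bootstrap
supports, and a single-linkage lineage partition at a divergence threshold —
the reproducible counterpart of counting "independent lineages" by eye on a
tree figure.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.base import BaseEstimator, ClusterMixin

from .errors import InputError
from .pairwise import align_pair, encode_sequence


@dataclass
class DistanceMatrix:
    labels: list[str]
    data: np.ndarray
    saturated: np.ndarray  # boolean mask of pairs beyond the K2P domain

    def __post_init__(self):
        n = len(self.labels)
        if self.data.shape != (n, n):
            raise InputError("distance matrix shape must match labels")
        if not np.allclose(self.data, self.data.T):
            raise InputError("distance matrix must be symmetric")
        if not np.allclose(np.diag(self.data), 0.0):
            raise InputError("distance matrix diagonal must be zero")

    def __len__(self):
        return len(self.labels)


def _k2p_from_encoded(labels: list[str], enc: np.ndarray) -> DistanceMatrix:
    """Vectorized all-pairs K2P with pairwise deletion (one row block per i)."""
    n = len(labels)
    d = np.zeros((n, n))
    sat = np.zeros((n, n), bool)
    ok = enc < 4
    for i in range(n - 1):
        a, b = enc[i], enc[i + 1 :]
        valid = ok[i] & ok[i + 1 :]
        ncmp = valid.sum(axis=1).astype(float)
        diff = valid & (a != b)
        ts = (diff & ((a ^ b) == 2)).sum(axis=1)
        tv = diff.sum(axis=1) - ts
        with np.errstate(divide="ignore", invalid="ignore"):
            P = np.where(ncmp > 0, ts / ncmp, 1.0)
            Q = np.where(ncmp > 0, tv / ncmp, 1.0)
            w1 = 1.0 - 2.0 * P - Q
            w2 = 1.0 - 2.0 * Q
            bad = (w1 <= 0) | (w2 <= 0) | (ncmp == 0)
            dij = np.where(bad, np.nan, -0.5 * np.log(
                np.where(bad, 1.0, w1 * np.sqrt(np.where(bad, 1.0, w2)))
            ))
        d[i, i + 1 :] = dij
        d[i + 1 :, i] = dij
        sat[i, i + 1 :] = bad
        sat[i + 1 :, i] = bad
    if sat.any():
        finite = d[~np.isnan(d)]
        fallback = 2.0 * float(finite.max()) if finite.size else 1.0
        d[np.isnan(d)] = fallback
    return DistanceMatrix(labels=labels, data=d, saturated=sat)


def k2p_matrix(sequences: dict[str, str] | list[tuple[str, str]]) -> DistanceMatrix:
    """Pairwise K2P distances over an equal-length aligned barcode set.

    Saturated pairs (substitution proportions outside the K2P domain) are
    flagged and assigned twice the largest finite pairwise distance, so the
    matrix stays usable for tree building while the flag records the loss of
    information.
    """
    items = list(sequences.items()) if isinstance(sequences, dict) else list(sequences)
    if len(items) < 2:
        raise InputError("need at least two sequences for a distance matrix")
    lengths = {len(s) for _, s in items}
    if len(lengths) != 1:
        raise InputError(
            f"sequences must be aligned to equal length; got lengths {sorted(lengths)}"
        )
    labels = [name for name, _ in items]
    if len(set(labels)) != len(labels):
        raise InputError("duplicate sequence labels")
    enc = np.stack([encode_sequence(s) for _, s in items])
    return _k2p_from_encoded(labels, enc)


class TreeNode:
    """A node of an (un)rooted tree; the NJ result is rooted at the final
    trifurcation for representation only."""

    __slots__ = ("name", "children", "branch_length", "support")

    def __init__(self, name: str | None = None, branch_length: float = 0.0):
        self.name = name
        self.children: list[TreeNode] = []
        self.branch_length = branch_length
        self.support: int | None = None

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf:
            return [self]
        out = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    def leaf_names(self) -> list[str]:
        return [l.name for l in self.leaves()]

    def _newick(self) -> str:
        if self.is_leaf:
            return f"{self.name}:{self.branch_length:.6f}"
        inner = ",".join(c._newick() for c in self.children)
        label = "" if self.support is None else str(int(self.support))
        return f"({inner}){label}:{self.branch_length:.6f}"

    def to_newick(self) -> str:
        inner = ",".join(c._newick() for c in self.children)
        return f"({inner});"

    def bipartitions(self) -> dict[frozenset, "TreeNode"]:
        """Map canonical leaf-set bipartitions to the internal node below
        each internal edge. Canonical side: the one NOT containing the
        lexicographically smallest leaf. Trivial splits are excluded."""
        all_leaves = frozenset(self.leaf_names())
        anchor = min(all_leaves)
        out: dict[frozenset, TreeNode] = {}

        def walk(node: TreeNode):
            for c in node.children:
                side = frozenset(c.leaf_names())
                if 1 < len(side) < len(all_leaves) - 1:
                    canon = side if anchor not in side else all_leaves - side
                    out[canon] = c
                walk(c)

        walk(self)
        return out


def nj_tree(dm: DistanceMatrix) -> TreeNode:
    """Saitou–Nei neighbor joining.

    Iteratively joins the pair minimizing Q(i,j) = (n-2) d(i,j) - r_i - r_j;
    ties break on the lowest (row, column) index pair under the current node
    ordering, so builds are deterministic. Negative branch lengths are
    clamped to zero. The returned node is the final trifurcation (the
    standard unrooted-NJ representation).
    """
    n = len(dm)
    if n < 3:
        raise InputError("neighbor joining needs at least three labels")
    nodes = [TreeNode(name=lbl) for lbl in dm.labels]
    d = dm.data.astype(float).copy()
    while len(nodes) > 3:
        m = len(nodes)
        r = d.sum(axis=1)
        q = (m - 2) * d - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        # row-major argmin -> lowest (row, col) tie-break
        flat = int(np.argmin(q))
        i, j = divmod(flat, m)
        if i > j:
            i, j = j, i
        dij = d[i, j]
        li = 0.5 * dij + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = dij - li
        li, lj = max(li, 0.0), max(lj, 0.0)
        parent = TreeNode()
        nodes[i].branch_length = li
        nodes[j].branch_length = lj
        parent.children = [nodes[i], nodes[j]]
        # distances from the new node to the rest
        dnew = 0.5 * (d[i, :] + d[j, :] - dij)
        keep = [k for k in range(m) if k not in (i, j)]
        d2 = np.empty((m - 1, m - 1))
        d2[:-1, :-1] = d[np.ix_(keep, keep)]
        d2[-1, :-1] = dnew[keep]
        d2[:-1, -1] = dnew[keep]
        d2[-1, -1] = 0.0
        nodes = [nodes[k] for k in keep] + [parent]
        d = d2
    # join the last three on a central node (closed-form lengths)
    a, b, c = nodes
    dab, dac, dbc = d[0, 1], d[0, 2], d[1, 2]
    a.branch_length = max(0.5 * (dab + dac - dbc), 0.0)
    b.branch_length = max(0.5 * (dab + dbc - dac), 0.0)
    c.branch_length = max(0.5 * (dac + dbc - dab), 0.0)
    center = TreeNode()
    center.children = [a, b, c]
    return center


def _column_matrix(sequences: list[tuple[str, str]]) -> tuple[list[str], np.ndarray]:
    labels = [name for name, _ in sequences]
    enc = np.stack([encode_sequence(s) for _, s in sequences])
    return labels, enc


def bootstrap_supports(
    sequences: dict[str, str] | list[tuple[str, str]],
    n_reps: int = 1000,
    seed: int = 0,
) -> TreeNode:
    """NJ tree with column-bootstrap supports.

    Columns of the alignment are resampled with replacement ``n_reps`` times;
    each internal edge of the tree built on the original alignment receives
    the percentage of replicate trees containing the same bipartition.
    With ``n_reps == 0`` the tree is returned without supports.
    """
    items = list(sequences.items()) if isinstance(sequences, dict) else list(sequences)
    labels, enc = _column_matrix(items)
    if enc.shape[1] < 1:
        raise InputError("alignment must have at least one column")
    dm = k2p_matrix(items)
    tree = nj_tree(dm)
    if n_reps == 0:
        return tree
    target = tree.bipartitions()
    counts = {bp: 0 for bp in target}
    rng = np.random.default_rng(seed)
    ncol = enc.shape[1]
    for _ in range(n_reps):
        cols = rng.integers(0, ncol, size=ncol)
        rep_dm = _k2p_from_encoded(labels, enc[:, cols])
        rep = nj_tree(rep_dm).bipartitions()
        for bp in counts:
            if bp in rep:
                counts[bp] += 1
    for bp, node in target.items():
        node.support = int(round(100.0 * counts[bp] / n_reps))
    return tree


@dataclass
class LineagePartition:
    """Disjoint single-linkage clusters of barcode ids at a K2P threshold."""

    clusters: list[set[str]]
    threshold: float
    labels: dict[str, int] = field(default_factory=dict)

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    def cluster_of(self, label: str) -> int:
        return self.labels[label]


def cluster_lineages(dm: DistanceMatrix, threshold: float) -> LineagePartition:
    """Single-linkage clusters: two ids share a lineage iff a chain of
    pairwise distances <= threshold connects them."""
    if threshold <= 0:
        raise InputError("threshold must be > 0")
    n = len(dm)
    if n == 1:
        return LineagePartition([{dm.labels[0]}], threshold, {dm.labels[0]: 0})
    z = linkage(squareform(dm.data, checks=False), method="single")
    flat = fcluster(z, t=threshold, criterion="distance")
    # renumber clusters by first appearance for deterministic output
    order: dict[int, int] = {}
    assign: dict[str, int] = {}
    for lbl, c in zip(dm.labels, flat):
        if c not in order:
            order[c] = len(order)
        assign[lbl] = order[c]
    clusters: list[set[str]] = [set() for _ in range(len(order))]
    for lbl, c in assign.items():
        clusters[c].add(lbl)
    return LineagePartition(clusters=clusters, threshold=threshold, labels=assign)


class LineageClusterer(ClusterMixin, BaseEstimator):
    """Single-linkage lineage delimitation at a K2P divergence threshold.

    scikit-learn style: ``fit(X)`` accepts either a square precomputed
    distance matrix or a list of equal-length aligned sequences (strings);
    cluster indices land in ``labels_``.
    """

    def __init__(self, threshold: float = 0.01):
        self.threshold = threshold

    def fit(self, X, y=None):
        if isinstance(X, DistanceMatrix):
            dm = X
        elif len(X) and isinstance(X[0], str):
            dm = k2p_matrix([(f"s{i}", s) for i, s in enumerate(X)])
        else:
            arr = np.asarray(X, dtype=float)
            dm = DistanceMatrix(
                labels=[f"s{i}" for i in range(arr.shape[0])],
                data=arr,
                saturated=np.zeros(arr.shape, bool),
            )
        part = cluster_lineages(dm, self.threshold)
        self.partition_ = part
        self.labels_ = np.array([part.cluster_of(lbl) for lbl in dm.labels])
        self.n_clusters_ = part.n_clusters
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_


def anchor_project(query: str, anchor: str, **scoring) -> str:
    """Project a query onto an anchor reference's coordinate frame.

    Semi-globally aligns the query to the anchor, drops columns inserted
    relative to the anchor, and pads unmatched anchor positions with gaps —
    yielding a string of exactly ``len(anchor)`` columns. This is the
    pipeline's stand-in for a multiple alignment: every barcode is expressed
    in the same fixed coordinate system before distance computation.
    """
    aln = align_pair(anchor, query, **scoring)
    out = []
    for ca, cb in zip(aln.aligned_a, aln.aligned_b):
        if ca == "-":
            continue  # insertion relative to the anchor: dropped
        out.append(cb)
    projected = "".join(out)
    if len(projected) != len(anchor):
        raise InputError("anchor projection failed to preserve anchor length")
    return projected
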