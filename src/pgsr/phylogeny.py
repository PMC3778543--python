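"""TUP-based phylograms.

Pearson dissimilarity (1 - r) between tetranucleotide signatures,
neighbor-joining (Saitou-Nei agglomeration with PHYLIP-style clamping of
negative branch-length estimates), and bootstrap supports obtained by
resampling the 256 tetranucleotide columns with replacement.  Supports are
annotated onto the full-data tree as the percentage of replicates whose NJ
tree contains the same leaf bipartition; no consensus tree is built.

Branch lengths are in the same arbitrary units as the dissimilarities.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .signatures import SignatureVector, correlate_signatures

__all__ = [
    "DistanceMatrix",
    "TreeNode",
    "Tree",
    "dissimilarity_from_signatures",
    "neighbor_joining",
    "bootstrap_support",
    "parse_newick",
]


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric dissimilarity matrix with a zero diagonal."""

    labels: tuple[str, ...]
    d: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise ValueError("matrix shape does not match labels")
        if len(set(self.labels)) != n:
            raise ValueError("duplicate labels")
        if not np.allclose(self.d, self.d.T, atol=1e-10):
            raise ValueError("matrix is not symmetric")
        if not np.allclose(np.diag(self.d), 0.0, atol=1e-10):
            raise ValueError("diagonal is not zero")
        if np.any(self.d < -1e-10):
            raise ValueError("negative dissimilarities")

    def value(self, a: str, b: str) -> float:
        return float(self.d[self.labels.index(a), self.labels.index(b)])


class TreeNode:
    """Node of an (effectively unrooted) phylogram.

    ``children`` holds (child, branch_length) pairs; ``support`` is the
    bootstrap percentage of the edge above this node, if annotated.
    """

    __slots__ = ("name", "children", "support")

    def __init__(self, name: str = "", children=None, support: float | None = None):
        self.name = name
        self.children: list[tuple[TreeNode, float]] = list(children or [])
        self.support = support

    def is_leaf(self) -> bool:
        return not self.children

    def leaf_names(self) -> list[str]:
        if self.is_leaf():
            return [self.name]
        out: list[str] = []
        for child, _ in self.children:
            out.extend(child.leaf_names())
        return out


class Tree:
    """Unrooted tree stored with a trifurcating (or multifurcating) root."""

    def __init__(self, root: TreeNode):
        self.root = root
        names = root.leaf_names()
        if len(set(names)) != len(names):
            raise ValueError("duplicate leaf labels")

    @property
    def leaf_names(self) -> tuple[str, ...]:
        return tuple(sorted(self.root.leaf_names()))

    def bipartitions(self) -> dict[frozenset, TreeNode]:
        """Non-trivial leaf splits keyed by the side excluding a fixed reference leaf.

        The reference leaf is the lexicographically smallest label, so keys
        are invariant to the (arbitrary) rooting of the stored tree.
        """
        all_leaves = frozenset(self.root.leaf_names())
        ref = min(all_leaves)
        out: dict[frozenset, TreeNode] = {}

        def walk(node: TreeNode) -> frozenset:
            if node.is_leaf():
                return frozenset([node.name])
            below = frozenset()
            for child, _ in node.children:
                below |= walk(child)
            if node is not self.root and 2 <= len(below) <= len(all_leaves) - 2:
                key = below if ref not in below else all_leaves - below
                out[key] = node
            return below

        walk(self.root)
        return out

    def leaf_distances(self) -> DistanceMatrix:
        """Patristic (branch-length path) distances between all leaves."""
        # per leaf: distance from the leaf to every node on its root path
        to_anc: dict[str, dict[int, float]] = {}

        def walk(node: TreeNode, trail: list[tuple[TreeNode, float]]):
            if node.is_leaf():
                cum_to_leaf = sum(bl for _, bl in trail)
                acc = {id(self.root): cum_to_leaf}
                seen = 0.0
                for anc, bl in trail:
                    seen += bl
                    acc[id(anc)] = cum_to_leaf - seen
                to_anc[node.name] = acc
            for child, bl in node.children:
                walk(child, trail + [(child, bl)])

        walk(self.root, [])
        labels = self.leaf_names
        n = len(labels)
        d = np.zeros((n, n))
        for i, a in enumerate(labels):
            for j in range(i + 1, n):
                b = labels[j]
                shared = [
                    to_anc[a][nd] + to_anc[b][nd]
                    for nd in to_anc[a]
                    if nd in to_anc[b]
                ]
                # deepest common ancestor minimizes the summed path
                d[i, j] = d[j, i] = min(shared)
        return DistanceMatrix(labels, d)

    def to_newick(self, include_support: bool = True) -> str:
        def fmt(node: TreeNode) -> str:
            if node.is_leaf():
                return node.name
            inner = ",".join(f"{fmt(c)}:{bl!r}" for c, bl in node.children)
            label = ""
            if include_support and node.support is not None:
                label = repr(float(node.support))
            elif node.name:
                label = node.name
            return f"({inner}){label}"

        return fmt(self.root) + ";"


def dissimilarity_from_signatures(sigs: list[SignatureVector]) -> DistanceMatrix:
    """Pearson dissimilarity d = 1 - r between TUPs (range [0, 2])."""
    if len(sigs) < 3:
        raise ValueError("need at least three signatures")
    corr = correlate_signatures(sigs)
    d = 1.0 - corr.r
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(corr.labels, d)


def _tie_key(node: TreeNode) -> str:
    return min(node.leaf_names())


def neighbor_joining(D: DistanceMatrix) -> Tree:
    """Classical Saitou-Nei neighbor joining.

    Negative branch-length estimates are clamped to zero with the deficit
    transferred to the sibling branch (so the pair's mutual distance is
    preserved), following the PHYLIP convention.  Equal-Q ties break on the
    lexicographically smallest pair of subtree labels.
    """
    n = len(D.labels)
    if n < 3:
        raise ValueError("need at least three taxa")
    nodes: list[TreeNode] = [TreeNode(lbl) for lbl in D.labels]
    dist: dict[tuple[int, int], float] = {}
    for i in range(n):
        for j in range(i + 1, n):
            dist[(i, j)] = float(D.d[i, j])
    active = list(range(n))
    next_id = n
    node_of: dict[int, TreeNode] = dict(enumerate(nodes))

    def d(i: int, j: int) -> float:
        return dist[(i, j) if i < j else (j, i)]

    while len(active) > 3:
        m = len(active)
        r = {i: sum(d(i, k) for k in active if k != i) for i in active}
        best = None
        for ai in range(m):
            for aj in range(ai + 1, m):
                i, j = active[ai], active[aj]
                q = (m - 2) * d(i, j) - r[i] - r[j]
                key = (q, tuple(sorted((_tie_key(node_of[i]), _tie_key(node_of[j])))))
                if best is None or key < best[0]:
                    best = (key, i, j)
        _, i, j = best
        dij = d(i, j)
        li = dij / 2.0 + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = dij - li
        if li < 0.0:
            li, lj = 0.0, dij
        elif lj < 0.0:
            li, lj = dij, 0.0
        parent = TreeNode(children=[(node_of[i], li), (node_of[j], lj)])
        node_of[next_id] = parent
        for k in active:
            if k in (i, j):
                continue
            dist[(min(k, next_id), max(k, next_id))] = max(
                0.0, (d(i, k) + d(j, k) - dij) / 2.0
            )
        active = [k for k in active if k not in (i, j)] + [next_id]
        next_id += 1

    a, b, c = sorted(active, key=lambda k: _tie_key(node_of[k]))
    la = (d(a, b) + d(a, c) - d(b, c)) / 2.0
    lb = (d(a, b) + d(b, c) - d(a, c)) / 2.0
    lc = (d(a, c) + d(b, c) - d(a, b)) / 2.0
    root = TreeNode(
        children=[
            (node_of[a], max(0.0, la)),
            (node_of[b], max(0.0, lb)),
            (node_of[c], max(0.0, lc)),
        ]
    )
    return Tree(root)


def _corr_dissimilarity(z: np.ndarray, labels: tuple[str, ...]) -> DistanceMatrix:
    r = np.corrcoef(z)
    d = np.clip(1.0 - r, 0.0, 2.0)
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2.0
    return DistanceMatrix(labels, d)


def bootstrap_support(
    sigs: list[SignatureVector], n_reps: int = 200, seed: int | None = None
) -> Tree:
    """Full-data NJ tree with column-bootstrap bipartition supports.

    Each replicate resamples the 256 tetranucleotide columns with
    replacement (reusing the already-computed Z columns), recomputes the
    Pearson dissimilarity matrix and its NJ tree, and each internal edge of
    the full-data tree is annotated with the percentage of replicates
    containing the same bipartition.
    """
    if seed is None:
        raise ValueError("a seed is required for bootstrap reproducibility")
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rng = np.random.default_rng(seed)
    labels = tuple(s.sequence_id for s in sigs)
    z = np.stack([s.z for s in sigs])
    tree = neighbor_joining(dissimilarity_from_signatures(list(sigs)))
    splits = tree.bipartitions()
    counts = {key: 0 for key in splits}
    for _ in range(n_reps):
        cols = rng.integers(0, z.shape[1], size=z.shape[1])
        zb = z[:, cols]
        # a replicate drawing an all-constant row cannot be correlated; redraw
        attempts = 0
        while np.any(zb.std(axis=1) == 0) and attempts < 100:
            cols = rng.integers(0, z.shape[1], size=z.shape[1])
            zb = z[:, cols]
            attempts += 1
        rep = neighbor_joining(_corr_dissimilarity(zb, labels))
        rep_splits = rep.bipartitions()
        for key in counts:
            if key in rep_splits:
                counts[key] += 1
    for key, node in splits.items():
        node.support = 100.0 * counts[key] / n_reps
    return tree


def parse_newick(text: str) -> Tree:
    """Parse a Newick string produced by :meth:`Tree.to_newick`.

    Numeric internal-node labels are read as bootstrap supports.
    """
    s = text.strip()
    if not s.endswith(";"):
        raise ValueError("newick string must end with ';'")
    s = s[:-1]
    pos = 0

    def parse_node() -> tuple[TreeNode, float | None]:
        nonlocal pos
        node = TreeNode()
        if s[pos] == "(":
            pos += 1
            while True:
                child, bl = parse_node()
                node.children.append((child, 0.0 if bl is None else bl))
                if s[pos] == ",":
                    pos += 1
                    continue
                if s[pos] == ")":
                    pos += 1
                    break
        start = pos
        while pos < len(s) and s[pos] not in ",():;":
            pos += 1
        label = s[start:pos]
        length: float | None = None
        if pos < len(s) and s[pos] == ":":
            pos += 1
            start = pos
            while pos < len(s) and s[pos] not in ",()":
                pos += 1
            length = float(s[start:pos])
        if node.children and label:
            try:
                node.support = float(label)
            except ValueError:
                node.name = label
        else:
            node.name = label
        return node, length

    root, _ = parse_node()
    if pos != len(s):
        raise ValueError(f"trailing characters in newick at offset {pos}")
    return Tree(root)
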