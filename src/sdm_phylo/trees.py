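"""Distance-based tree inference and tree utilities.

Three builders operate on a :class:`~sdm_phylo.sdm.DissimilarityMatrix`:

``upgma``
    Average-linkage agglomeration; produces a rooted ultrametric tree
    and serves as the initializer for the clock search.
``fm_clock``
    Fitch-Margoliash weighted least squares under a molecular clock:
    minimizes ``sum_{i<j} (d_ij - t_ij)^2 / d_ij^power`` over ultrametric
    trees, where ``t_ij`` is the leaf-to-leaf path length.  For a fixed
    topology the optimal node heights solve a weighted isotonic
    regression on the tree order (child height <= parent height,
    heights >= 0), which is computed exactly by block merging; the
    topology is improved by steepest-ascent nearest-neighbor
    interchanges from the UPGMA start.
``neighbor_joining``
    Canonical Saitou-Nei agglomeration with the Q-criterion; exactly
    recovers additive (tree-metric) matrices.

Trees serialize to and from Newick, can be cut into leaf partitions,
and are compared by the unrooted Robinson-Foulds distance.
"""

from __future__ import annotations

import itertools
import re
from typing import Iterable, Optional, Sequence

import numpy as np

from sdm_phylo.errors import FormatError, InputError
from sdm_phylo.sdm import DissimilarityMatrix

ULTRAMETRIC_TOL = 1e-6


class Node:
    __slots__ = ("label", "length", "children", "parent")

    def __init__(self, label: Optional[str] = None, length: float = 0.0,
                 children: Optional[list["Node"]] = None):
        self.label = label
        self.length = float(length)
        self.children: list[Node] = children or []
        self.parent: Optional[Node] = None
        for c in self.children:
            c.parent = self

    def add(self, child: "Node") -> None:
        child.parent = self
        self.children.append(child)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def copy(self) -> "Node":
        return Node(self.label, self.length, [c.copy() for c in self.children])


class PhyloTree:
    """Rooted or unrooted tree with branch lengths and labelled leaves."""

    def __init__(self, root: Node, rooted: bool = True):
        self.root = root
        self.rooted = rooted

    def copy(self) -> "PhyloTree":
        return PhyloTree(self.root.copy(), self.rooted)

    def postorder(self) -> Iterable[Node]:
        stack, out = [self.root], []
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(node.children)
        return reversed(out)

    def leaves(self) -> list[Node]:
        return [n for n in self.postorder() if n.is_leaf]

    def leaf_labels(self) -> list[str]:
        return [n.label for n in self.leaves()]

    def leaf_depths(self) -> dict[str, float]:
        """Root-to-leaf path lengths."""
        depths: dict[str, float] = {}

        def walk(node: Node, acc: float) -> None:
            if node.is_leaf:
                depths[node.label] = acc
            for c in node.children:
                walk(c, acc + c.length)

        walk(self.root, 0.0)
        return depths

    def is_ultrametric(self, tol: float = ULTRAMETRIC_TOL) -> bool:
        depths = list(self.leaf_depths().values())
        return max(depths) - min(depths) <= tol

    def distance_matrix(self, order: Optional[Sequence[str]] = None):
        """Leaf-to-leaf path-length matrix in the given label order."""
        labels = list(order) if order is not None else self.leaf_labels()
        index = {lab: i for i, lab in enumerate(labels)}
        n = len(labels)
        dist = np.zeros((n, n))
        # leaf sets and depths per node, accumulate cross-child pair distances
        depth_to = {lab: {} for lab in labels}  # leaf -> {id(node on root path): depth below node}

        def walk(node: Node) -> list[tuple[str, float]]:
            if node.is_leaf:
                if node.label not in index:
                    raise InputError(f"leaf {node.label!r} not in requested order")
                return [(node.label, 0.0)]
            groups = []
            for c in node.children:
                below = [(lab, d + c.length) for lab, d in walk(c)]
                groups.append(below)
            for ga, gb in itertools.combinations(groups, 2):
                for (la, da), (lb, db) in itertools.product(ga, gb):
                    i, j = index[la], index[lb]
                    dist[i, j] = dist[j, i] = da + db
            return [pair for g in groups for pair in g]

        seen = walk(self.root)
        if len(seen) != n:
            raise InputError("tree leaves do not match the requested label order")
        return labels, dist

    def bipartitions(self) -> set[frozenset]:
        """Non-trivial unrooted splits, each as the side not holding the
        lexicographically smallest leaf label."""
        all_leaves = frozenset(self.leaf_labels())
        ref = min(all_leaves)
        n = len(all_leaves)
        splits: set[frozenset] = set()

        def walk(node: Node) -> frozenset:
            if node.is_leaf:
                return frozenset([node.label])
            below = frozenset().union(*(walk(c) for c in node.children))
            if 2 <= len(below) <= n - 2:
                side = below if ref not in below else all_leaves - below
                splits.add(side)
            return below

        walk(self.root)
        return splits


# ---------------------------------------------------------------------------
# Newick serialization


_NEEDS_QUOTE = re.compile(r"[\s()\[\]':;,]")


def _format_label(label: str) -> str:
    if label and not _NEEDS_QUOTE.search(label):
        return label
    return "'" + label.replace("'", "''") + "'"


def write_newick(tree: PhyloTree) -> str:
    """Serialize a tree to Newick (branch lengths at 6 significant digits)."""

    def fmt(node: Node, top: bool) -> str:
        if node.is_leaf:
            body = _format_label(node.label or "")
        else:
            body = "(" + ",".join(fmt(c, False) for c in node.children) + ")"
            if node.label:
                body += _format_label(node.label)
        if top:
            return body
        return f"{body}:{node.length:.6g}"

    return fmt(tree.root, True) + ";"


def read_newick(text: str) -> PhyloTree:
    """Parse a Newick string (via dendropy) into a :class:`PhyloTree`."""
    import dendropy

    try:
        dtree = dendropy.Tree.get(
            data=text, schema="newick", suppress_internal_node_taxa=False,
            preserve_underscores=True,
        )
    except Exception as exc:
        raise FormatError(f"malformed Newick: {exc}") from exc

    def convert(dnode) -> Node:
        label = None
        if dnode.taxon is not None:
            label = dnode.taxon.label
        elif dnode.label:
            label = dnode.label
        node = Node(label, dnode.edge.length or 0.0)
        for child in dnode.child_nodes():
            node.add(convert(child))
        return node

    root = convert(dtree.seed_node)
    return PhyloTree(root, rooted=len(root.children) == 2)


# ---------------------------------------------------------------------------
# Agglomerative builders


def _validate(matrix: DissimilarityMatrix, min_n: int) -> np.ndarray:
    if len(matrix) < min_n:
        raise InputError(f"need at least {min_n} taxa, got {len(matrix)}")
    return matrix.values.copy()


def upgma(matrix: DissimilarityMatrix) -> PhyloTree:
    """Average-linkage rooted ultrametric tree.

    Merge ties are broken by the lowest pair of original label indices.
    Pendant heights are half the merge dissimilarity.
    """
    d = _validate(matrix, 2)
    # cluster: (node, size, height, representative original index)
    clusters: dict[int, tuple[Node, int, float, int]] = {
        i: (Node(lab), 1, 0.0, i) for i, lab in enumerate(matrix.labels)
    }
    dist = {frozenset((i, j)): d[i, j]
            for i, j in itertools.combinations(range(len(matrix)), 2)}
    next_id = len(matrix)
    while len(clusters) > 1:
        best = None
        for i, j in itertools.combinations(sorted(clusters), 2):
            key = (dist[frozenset((i, j))],
                   min(clusters[i][3], clusters[j][3]),
                   max(clusters[i][3], clusters[j][3]))
            if best is None or key < best[0]:
                best = (key, i, j)
        _, i, j = best
        node_i, size_i, h_i, rep_i = clusters[i]
        node_j, size_j, h_j, rep_j = clusters[j]
        height = dist[frozenset((i, j))] / 2.0
        node_i.length = max(0.0, height - h_i)
        node_j.length = max(0.0, height - h_j)
        merged = Node(children=[node_i, node_j])
        del clusters[i], clusters[j]
        for k in clusters:
            dij = dist.pop(frozenset((i, k)))
            djk = dist.pop(frozenset((j, k)))
            dist[frozenset((next_id, k))] = (
                (size_i * dij + size_j * djk) / (size_i + size_j)
            )
        dist.pop(frozenset((i, j)))
        clusters[next_id] = (merged, size_i + size_j, height, min(rep_i, rep_j))
        next_id += 1
    (root, _, _, _), = clusters.values()
    return PhyloTree(root, rooted=True)


def neighbor_joining(matrix: DissimilarityMatrix) -> PhyloTree:
    """Saitou-Nei neighbor joining; returns an unrooted tree.

    Q-criterion ties are broken by the lowest pair of original label
    indices.  Negative branch-length estimates are clamped to zero with
    the deficit transferred to the sister branch (their sum, the joined
    pair's mutual distance contribution, is preserved).
    """
    d = _validate(matrix, 3)
    nodes: dict[int, tuple[Node, int]] = {
        i: (Node(lab), i) for i, lab in enumerate(matrix.labels)
    }
    dist = {frozenset((i, j)): d[i, j]
            for i, j in itertools.combinations(range(len(matrix)), 2)}
    next_id = len(matrix)
    while len(nodes) > 3:
        active = sorted(nodes)
        n = len(active)
        r = {i: sum(dist[frozenset((i, k))] for k in active if k != i) for i in active}
        best = None
        for i, j in itertools.combinations(active, 2):
            q = (n - 2) * dist[frozenset((i, j))] - r[i] - r[j]
            key = (q, min(nodes[i][1], nodes[j][1]), max(nodes[i][1], nodes[j][1]))
            if best is None or key < best[0]:
                best = (key, i, j)
        _, i, j = best
        dij = dist[frozenset((i, j))]
        li = dij / 2.0 + (r[i] - r[j]) / (2.0 * (n - 2))
        lj = dij - li
        if li < 0.0:
            lj += li
            li = 0.0
        if lj < 0.0:
            li += lj
            lj = 0.0
        li, lj = max(0.0, li), max(0.0, lj)
        node_i, rep_i = nodes[i]
        node_j, rep_j = nodes[j]
        node_i.length, node_j.length = li, lj
        joined = Node(children=[node_i, node_j])
        del nodes[i], nodes[j]
        for k in nodes:
            dik = dist.pop(frozenset((i, k)))
            djk = dist.pop(frozenset((j, k)))
            dist[frozenset((next_id, k))] = max(0.0, (dik + djk - dij) / 2.0)
        dist.pop(frozenset((i, j)))
        nodes[next_id] = (joined, min(rep_i, rep_j))
        next_id += 1
    # final three-point formulas
    (a, b, c) = sorted(nodes)
    dab = dist[frozenset((a, b))]
    dac = dist[frozenset((a, c))]
    dbc = dist[frozenset((b, c))]
    la = max(0.0, (dab + dac - dbc) / 2.0)
    lb = max(0.0, (dab + dbc - dac) / 2.0)
    lc = max(0.0, (dac + dbc - dab) / 2.0)
    for key, length in ((a, la), (b, lb), (c, lc)):
        nodes[key][0].length = length
    root = Node(children=[nodes[a][0], nodes[b][0], nodes[c][0]])
    return PhyloTree(root, rooted=False)


# ---------------------------------------------------------------------------
# Clock-constrained least squares (Fitch-Margoliash with molecular clock)


def _pair_weights(d: np.ndarray, power: float) -> np.ndarray:
    with np.errstate(divide="ignore"):
        w = np.where(d > 0, d, 1.0) ** (-power)
    w[d == 0] = 1.0
    return w


def _tree_isotonic(targets: np.ndarray, weights: np.ndarray,
                   parent: list[Optional[int]]) -> np.ndarray:
    """Weighted least-squares fit of node values under tree-order
    constraints value[child] <= value[parent], values >= 0.

    The order's Hasse diagram is an in-tree (each node has one parent),
    for which pool-adjacent-violators block merging is exact; the
    non-negativity bound is applied by clamping, which preserves both
    feasibility and optimality for isotonic problems.
    """
    n = len(targets)
    block = list(range(n))

    def find(i: int) -> int:
        while block[i] != i:
            block[i] = block[block[i]]
            i = block[i]
        return i

    num = weights * targets
    bnum = num.copy()
    bden = weights.copy().astype(float)
    changed = True
    while changed:
        changed = False
        for i in range(n):
            p = parent[i]
            if p is None:
                continue
            bi, bp = find(i), find(p)
            if bi == bp:
                continue
            if bnum[bi] / bden[bi] > bnum[bp] / bden[bp] + 1e-15:
                block[bi] = bp
                bnum[bp] += bnum[bi]
                bden[bp] += bden[bi]
                changed = True
    values = np.array([bnum[find(i)] / bden[find(i)] for i in range(n)])
    return np.maximum(values, 0.0)


def _topology_stats(root: Node, index: dict[str, int], d: np.ndarray,
                    w: np.ndarray):
    """Per-internal-node sums over the leaf pairs whose MRCA is the node.

    Returns (nodes, parent_ids, A, B, C) with A = sum w, B = sum w*d,
    C = sum w*d^2 per internal node, in postorder.
    """
    internal: list[Node] = []
    parent_pos: dict[int, int] = {}
    stats_a, stats_b, stats_c = [], [], []

    def walk(node: Node) -> np.ndarray:
        if node.is_leaf:
            return np.array([index[node.label]], dtype=np.intp)
        child_sets = [walk(c) for c in node.children]
        a = b = c2 = 0.0
        for sa, sb in itertools.combinations(child_sets, 2):
            dd = d[np.ix_(sa, sb)]
            ww = w[np.ix_(sa, sb)]
            a += ww.sum()
            b += (ww * dd).sum()
            c2 += (ww * dd * dd).sum()
        internal.append(node)
        parent_pos[id(node)] = len(internal) - 1
        stats_a.append(a)
        stats_b.append(b)
        stats_c.append(c2)
        return np.concatenate(child_sets)

    walk(root)
    parents: list[Optional[int]] = []
    for node in internal:
        p = node.parent
        parents.append(parent_pos[id(p)] if p is not None and id(p) in parent_pos else None)
    return internal, parents, np.array(stats_a), np.array(stats_b), np.array(stats_c)


def fit_clock_topology(topology: PhyloTree, matrix: DissimilarityMatrix,
                       power: float = 2.0) -> tuple[PhyloTree, float]:
    """Optimal ultrametric branch lengths for a fixed rooted topology.

    Minimizes ``sum w_ij (d_ij - 2 h_mrca(i,j))^2`` with
    ``w_ij = d_ij^-power`` (weight 1 for zero distances) subject to the
    clock constraints (heights non-negative and non-decreasing toward
    the root).  Returns the height-annotated tree and the exact score.
    """
    d = matrix.values
    w = _pair_weights(d, power)
    index = {lab: i for i, lab in enumerate(matrix.labels)}
    tree = topology.copy()
    internal, parents, a, b, c = _topology_stats(tree.root, index, d, w)
    targets = np.where(a > 0, b / (2.0 * np.maximum(a, 1e-300)), 0.0)
    heights = _tree_isotonic(targets, 4.0 * a, parents)
    score = float((c - 4.0 * heights * b + 4.0 * heights ** 2 * a).sum())
    node_height = {id(n): h for n, h in zip(internal, heights)}
    for node in tree.postorder():
        if node.parent is None:
            node.length = 0.0
            continue
        h_self = 0.0 if node.is_leaf else node_height[id(node)]
        node.length = max(0.0, node_height[id(node.parent)] - h_self)
    return tree, max(0.0, score)


def clock_fit_score(tree: PhyloTree, matrix: DissimilarityMatrix,
                    power: float = 2.0) -> float:
    """Weighted least-squares score of a tree's own path lengths."""
    labels = matrix.labels
    _, t = tree.distance_matrix(labels)
    d = matrix.values
    w = _pair_weights(d, power)
    iu = np.triu_indices(len(labels), k=1)
    return float((w[iu] * (d[iu] - t[iu]) ** 2).sum())


def _nni_neighbors(tree: PhyloTree) -> Iterable[PhyloTree]:
    """Rooted nearest-neighbor interchanges: for every non-root internal
    node, swap each of its children with its sibling."""
    nodes = [n for n in tree.postorder()
             if not n.is_leaf and n.parent is not None]
    for pos, node in enumerate(nodes):
        for child_idx in range(len(node.children)):
            new_tree = tree.copy()
            new_nodes = [n for n in new_tree.postorder()
                         if not n.is_leaf and n.parent is not None]
            u = new_nodes[pos]
            p = u.parent
            siblings = [c for c in p.children if c is not u]
            if len(siblings) != 1:
                continue
            s = siblings[0]
            c = u.children[child_idx]
            u.children[u.children.index(c)] = s
            p.children[p.children.index(s)] = c
            s.parent, c.parent = u, p
            yield new_tree


def _spr_neighbors(tree: PhyloTree) -> Iterable[PhyloTree]:
    """Rooted subtree-prune-regraft moves (binary trees).

    Every non-root node is pruned (its parent is sutured out) and
    regrafted onto every remaining branch, or above the root.
    """
    n_prunable = sum(1 for n in tree.postorder() if n.parent is not None)
    for pos in range(n_prunable):
        base = tree.copy()
        with_parent = [n for n in base.postorder() if n.parent is not None]
        v = with_parent[pos]
        p = v.parent
        siblings = [c for c in p.children if c is not v]
        if len(siblings) != 1:
            continue
        s = siblings[0]
        g = p.parent
        if g is None:
            s.parent = None
            pruned_root = s
        else:
            g.children[g.children.index(p)] = s
            s.parent = g
            pruned_root = base.root
        v.parent = None
        targets = list(PhyloTree(pruned_root).postorder())
        for w in targets:
            root = pruned_root
            if w.parent is None:
                yield PhyloTree(Node(children=[root.copy(), v.copy()]), rooted=True)
            else:
                t2_root = root.copy()
                # find w's counterpart in the copy by postorder position
                orig = list(PhyloTree(root).postorder())
                copy_nodes = list(PhyloTree(t2_root).postorder())
                w2 = copy_nodes[orig.index(w)]
                pw = w2.parent
                repl = Node(children=[w2, v.copy()])
                pw.children[pw.children.index(w2)] = repl
                repl.parent = pw
                yield PhyloTree(t2_root, rooted=True)


def fm_clock(matrix: DissimilarityMatrix, power: float = 2.0,
             max_rounds: int = 200) -> tuple[PhyloTree, float]:
    """Clock-constrained Fitch-Margoliash least-squares tree.

    Starts from the UPGMA topology, optimizes node heights exactly for
    that topology, then hill-climbs with steepest-ascent NNI moves
    (re-optimizing heights for every candidate).  When no interchange
    improves the weighted least-squares score, a subtree-prune-regraft
    pass widens the neighborhood; the search stops when neither move
    type improves the score.
    """
    _validate(matrix, 3)
    current, score = fit_clock_topology(upgma(matrix), matrix, power)
    for _ in range(max_rounds):
        best_tree, best_score = None, score
        for cand in _nni_neighbors(current):
            fitted, s = fit_clock_topology(cand, matrix, power)
            if s < best_score - 1e-12:
                best_tree, best_score = fitted, s
        if best_tree is None:
            for cand in _spr_neighbors(current):
                fitted, s = fit_clock_topology(cand, matrix, power)
                if s < best_score - 1e-12:
                    best_tree, best_score = fitted, s
        if best_tree is None:
            break
        current, score = best_tree, best_score
    assert current.is_ultrametric(), "clock tree failed ultrametricity"
    return current, score


def enumerate_rooted_topologies(labels: Sequence[str]) -> Iterable[PhyloTree]:
    """All rooted binary topologies on the labels ((2n-3)!! trees).

    Built by inserting each successive leaf into every branch, including
    the branch above the current root.  Intended as an exhaustive-search
    companion to :func:`fit_clock_topology` for small n.
    """
    labels = list(labels)
    if len(labels) < 2:
        raise InputError("need at least 2 labels")

    def insertions(root: Node, leaf_label: str) -> Iterable[Node]:
        # new root above the old one
        yield Node(children=[root.copy(), Node(leaf_label)])
        # into every existing branch
        def count(n: Node) -> int:
            return 1 + sum(count(c) for c in n.children)

        total = count(root)
        for target in range(1, total):  # skip position 0 = root itself
            new_root = root.copy()
            stack = [new_root]
            order = []
            while stack:
                n = stack.pop()
                order.append(n)
                stack.extend(reversed(n.children))
            node = order[target]
            p = node.parent
            replacement = Node(children=[node, Node(leaf_label)])
            p.children[p.children.index(node)] = replacement
            replacement.parent = p
            yield new_root

    trees = [Node(children=[Node(labels[0]), Node(labels[1])])]
    for label in labels[2:]:
        trees = [t for base in trees for t in insertions(base, label)]
    for root in trees:
        yield PhyloTree(root, rooted=True)


# ---------------------------------------------------------------------------
# Tree comparison and cluster extraction


def robinson_foulds(tree_a: PhyloTree, tree_b: PhyloTree) -> int:
    """Unrooted Robinson-Foulds distance (symmetric bipartition difference)."""
    la, lb = set(tree_a.leaf_labels()), set(tree_b.leaf_labels())
    if la != lb:
        raise InputError(f"leaf sets differ: only-in-a={sorted(la - lb)}, "
                         f"only-in-b={sorted(lb - la)}")
    return len(tree_a.bipartitions() ^ tree_b.bipartitions())


def extract_clusters(tree: PhyloTree, height: Optional[float] = None,
                     k: Optional[int] = None):
    """Cut a rooted tree into a leaf partition.

    Exactly one of `height` (cut all branches crossing that height above
    the leaves; requires an ultrametric tree to be meaningful) or `k`
    (cut the k-1 longest internal branches, extending to pendant
    branches when the tree has fewer internal ones) must be given.
    Returns ``(blocks, outliers)`` where blocks is a list of sorted
    label lists and outliers the singleton labels.
    """
    if (height is None) == (k is None):
        raise InputError("give exactly one of height= or k=")
    if not tree.rooted:
        raise InputError("cluster extraction requires a rooted tree")
    leaves = tree.leaves()
    n = len(leaves)
    if k is not None and not (1 <= k <= n):
        raise InputError(f"k must be in [1, {n}], got {k}")

    def partition(cut: set[int]) -> list[list[str]]:
        groups: dict[int, list[str]] = {}

        def assign(node: Node, component: int) -> None:
            if id(node) in cut:
                component = id(node)
            if node.is_leaf:
                groups.setdefault(component, []).append(node.label)
            for c in node.children:
                assign(c, component)

        assign(tree.root, id(tree.root))
        return sorted((sorted(g) for g in groups.values()), key=lambda b: b[0])

    if height is not None:
        cut: set[int] = set()
        root_height = max(tree.leaf_depths().values())

        def mark(node: Node, depth: float) -> None:
            for c in node.children:
                top = root_height - depth
                bottom = root_height - (depth + c.length)
                if top > height >= bottom:
                    cut.add(id(c))
                mark(c, depth + c.length)

        mark(tree.root, 0.0)
        blocks = partition(cut)
    else:
        edges = [(n_, n_.length, idx) for idx, n_ in enumerate(tree.postorder())
                 if n_.parent is not None]
        internal = sorted((e for e in edges if not e[0].is_leaf),
                          key=lambda e: (-e[1], e[2]))
        pendant = sorted((e for e in edges if e[0].is_leaf),
                         key=lambda e: (-e[1], e[2]))
        # longest internal branches first; a cut near the root can strand a
        # leafless component, so keep cutting until k leaf blocks emerge
        cut = set()
        blocks = partition(cut)
        for node, _, _ in internal + pendant:
            if len(blocks) >= k:
                break
            cut.add(id(node))
            blocks = partition(cut)

    outliers = [b[0] for b in blocks if len(b) == 1]
    return blocks, outliers
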