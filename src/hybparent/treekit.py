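"""Distance and parsimony tree inference and topology comparison.

This is the in-repo inference tier used to quantify cyto-nuclear
discordance: pairwise distances (p / JC69), neighbor-joining, Fitch
parsimony with exact search at small taxon counts and NNI hill-climbing
beyond, nonparametric bootstrap support, supermatrix concatenation,
monophyly tests and Robinson-Foulds distances.

Trees are :class:`dendropy.Tree` objects; Newick serialization goes
through DendroPy.  Topology comparison uses unrooted, leaf-label
bipartitions throughout — rooting is for display only.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import dendropy
import numpy as np

from .alignment import Alignment

Tree = dendropy.Tree

#: JC69 distance assigned when p >= 0.75 (saturated pair)
SATURATION_CAP = 5.0


# ---------------------------------------------------------------------------
# distances
# ---------------------------------------------------------------------------


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distances with a zero diagonal."""

    labels: list[str]
    matrix: np.ndarray
    saturated: set[frozenset] = field(default_factory=set)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = len(self.labels)
        if self.matrix.shape != (n, n):
            raise ValueError("matrix shape does not match label count")
        if not np.allclose(self.matrix, self.matrix.T):
            raise ValueError("distance matrix is not symmetric")
        if not np.allclose(np.diag(self.matrix), 0.0):
            raise ValueError("distance matrix diagonal is not zero")
        if (self.matrix < -1e-12).any():
            raise ValueError("negative distances")

    def get(self, a: str, b: str) -> float:
        return float(
            self.matrix[self.labels.index(a), self.labels.index(b)]
        )


def pairwise_distance(aln: Alignment, model: str = "p") -> DistanceMatrix:
    """Pairwise distances under pairwise deletion of missing sites.

    ``model="p"``: proportion of differing compared sites.
    ``model="JC69"``: ``-(3/4) ln(1 - (4/3) p)``; pairs with p >= 0.75 are
    flagged saturated and capped at :data:`SATURATION_CAP`.
    """
    if model not in ("p", "JC69"):
        raise ValueError(f"unknown distance model {model!r}")
    if aln.n_rows < 2:
        raise ValueError("need >= 2 rows")
    n = aln.n_rows
    missing = aln.missing_mask()
    D = np.zeros((n, n))
    saturated: set[frozenset] = set()
    for i, j in itertools.combinations(range(n), 2):
        ok = ~(missing[i] | missing[j])
        m = int(ok.sum())
        if m == 0:
            raise ValueError(
                f"no comparable sites between {aln.labels[i]!r} "
                f"and {aln.labels[j]!r}"
            )
        p = float((aln.matrix[i, ok] != aln.matrix[j, ok]).sum()) / m
        if model == "p":
            d = p
        elif p >= 0.75:
            d = SATURATION_CAP
            saturated.add(frozenset((aln.labels[i], aln.labels[j])))
        else:
            d = -0.75 * np.log1p(-4.0 * p / 3.0)
        D[i, j] = D[j, i] = d
    return DistanceMatrix(list(aln.labels), D, saturated)


# ---------------------------------------------------------------------------
# neighbor joining
# ---------------------------------------------------------------------------


def neighbor_joining(dist: DistanceMatrix) -> Tree:
    """Saitou-Nei neighbor joining.

    Returns an unrooted tree (trifurcating seed node).  Additive input
    distances are realized exactly as path lengths.  Negative branch-length
    estimates are clamped to zero with the deficit moved to the sibling
    edge, preserving the joined pair's summed length (a warning is issued).
    """
    n = len(dist.labels)
    if n < 3:
        raise ValueError("neighbor joining requires >= 3 taxa")
    tns = dendropy.TaxonNamespace(dist.labels)
    tree = dendropy.Tree(taxon_namespace=tns)
    nodes = [
        dendropy.Node(taxon=tns.get_taxon(lbl)) for lbl in dist.labels
    ]
    d = dist.matrix.astype(float).copy()

    def _clamped(li: float, lj: float) -> tuple[float, float]:
        if li < 0:
            warnings.warn("negative NJ branch length clamped to zero")
            lj += li
            li = 0.0
        if lj < 0:
            warnings.warn("negative NJ branch length clamped to zero")
            li += lj
            lj = 0.0
        return max(li, 0.0), max(lj, 0.0)

    while len(nodes) > 3:
        m = len(nodes)
        r = d.sum(axis=1)
        q = (m - 2) * d - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        i, j = np.unravel_index(int(np.argmin(q)), q.shape)
        if i > j:
            i, j = j, i
        li = 0.5 * d[i, j] + (r[i] - r[j]) / (2 * (m - 2))
        lj = d[i, j] - li
        li, lj = _clamped(li, lj)
        parent = dendropy.Node()
        parent.add_child(nodes[i])
        nodes[i].edge.length = li
        parent.add_child(nodes[j])
        nodes[j].edge.length = lj
        dnew = 0.5 * (d[i, :] + d[j, :] - d[i, j])
        keep = [k for k in range(m) if k not in (i, j)]
        d2 = np.empty((m - 1, m - 1))
        d2[: m - 2, : m - 2] = d[np.ix_(keep, keep)]
        d2[-1, : m - 2] = d2[: m - 2, -1] = dnew[keep]
        d2[-1, -1] = 0.0
        d = d2
        nodes = [nodes[k] for k in keep] + [parent]

    # closed three-point formulas for the final trifurcation
    la = 0.5 * (d[0, 1] + d[0, 2] - d[1, 2])
    lb = 0.5 * (d[0, 1] + d[1, 2] - d[0, 2])
    lc = 0.5 * (d[0, 2] + d[1, 2] - d[0, 1])
    root = dendropy.Node()
    for node, length in zip(nodes, (la, lb, lc)):
        if length < 0:
            warnings.warn("negative NJ branch length clamped to zero")
            length = 0.0
        root.add_child(node)
        node.edge.length = length
    tree.seed_node = root
    tree.is_rooted = False
    return tree


# ---------------------------------------------------------------------------
# bipartitions, RF, monophyly
# ---------------------------------------------------------------------------


def leaf_labels(tree: Tree) -> set[str]:
    return {lf.taxon.label for lf in tree.leaf_node_iter()}


def bipartitions(tree: Tree) -> set[frozenset]:
    """Nontrivial unrooted splits, each normalized to the side that
    excludes the lexicographically smallest leaf label."""
    all_leaves = frozenset(leaf_labels(tree))
    ref = min(all_leaves)
    below: dict = {}
    splits: set[frozenset] = set()
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            below[node] = frozenset((node.taxon.label,))
        else:
            below[node] = frozenset().union(
                *(below[c] for c in node.child_nodes())
            )
        if node.parent_node is None:
            continue
        side = below[node]
        if len(side) < 2 or len(side) > len(all_leaves) - 2:
            continue
        if ref in side:
            side = all_leaves - side
        splits.add(side)
    return splits


def robinson_foulds(t1: Tree, t2: Tree) -> int:
    """Symmetric-difference (RF) distance between two unrooted trees."""
    l1, l2 = leaf_labels(t1), leaf_labels(t2)
    if l1 != l2:
        raise ValueError(
            f"leaf sets differ: only in first {sorted(l1 - l2)}, "
            f"only in second {sorted(l2 - l1)}"
        )
    return len(bipartitions(t1) ^ bipartitions(t2))


def is_monophyletic(tree: Tree, leafset) -> bool:
    """True iff one edge of the unrooted tree splits exactly ``leafset``
    from all other leaves.  Singletons, the complement of a singleton and
    the full leaf set are trivially monophyletic."""
    all_leaves = frozenset(leaf_labels(tree))
    target = frozenset(leafset)
    unknown = target - all_leaves
    if unknown:
        raise ValueError(f"labels not in tree: {sorted(unknown)}")
    n = len(all_leaves)
    if len(target) in (0, 1, n - 1, n):
        return True
    if min(all_leaves) in target:
        target = all_leaves - target
    return target in bipartitions(tree)


# ---------------------------------------------------------------------------
# Fitch parsimony
# ---------------------------------------------------------------------------

_CODE = np.full(256, 0, dtype=np.uint8)
for _b, _c in zip(b"ACGT", (1, 2, 4, 8)):
    _CODE[_b] = _c
_CODE[ord("N")] = _CODE[ord("-")] = 15  # missing: fully ambiguous


def _encode(aln: Alignment) -> np.ndarray:
    return _CODE[aln.matrix]


def _fitch_counts(postorder, codes: np.ndarray) -> np.ndarray:
    """Vectorized Fitch change counts per column.

    ``postorder`` is a list where each item is either an int (leaf: row
    index into ``codes``) or a list of positions of its children earlier
    in the list.  Multifurcations are folded child by child.
    """
    L = codes.shape[1]
    score = np.zeros(L, dtype=np.int64)
    states: list[np.ndarray] = []
    for item in postorder:
        if isinstance(item, (int, np.integer)):
            states.append(codes[item])
        else:
            acc = states[item[0]]
            for pos in item[1:]:
                inter = acc & states[pos]
                empty = inter == 0
                score += empty
                acc = np.where(empty, acc | states[pos], inter)
            states.append(acc)
    return score


def _postorder_from_dendropy(tree: Tree, row_of: dict) -> list:
    order: list = []
    pos: dict = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            order.append(row_of[node.taxon.label])
        else:
            order.append([pos[c] for c in node.child_nodes()])
        pos[node] = len(order) - 1
    return order


def fitch_score(tree: Tree, aln: Alignment) -> int:
    """Fitch small-parsimony score of ``aln`` on ``tree``.

    Missing states (N/-) are fully ambiguous and never force a change.
    """
    tree_leaves = leaf_labels(tree)
    aln_taxa = set(aln.labels)
    if tree_leaves != aln_taxa:
        raise ValueError(
            f"tree/alignment taxa differ: only in tree "
            f"{sorted(tree_leaves - aln_taxa)}, only in alignment "
            f"{sorted(aln_taxa - tree_leaves)}"
        )
    row_of = {lbl: i for i, lbl in enumerate(aln.labels)}
    postorder = _postorder_from_dendropy(tree, row_of)
    return int(_fitch_counts(postorder, _encode(aln)).sum())


# ---------------------------------------------------------------------------
# unrooted topology workspace for parsimony search
# ---------------------------------------------------------------------------


class _UTree:
    """Unrooted tree as an adjacency map; leaves are 0..n_leaves-1."""

    __slots__ = ("adj", "n_leaves")

    def __init__(self, adj: dict, n_leaves: int):
        self.adj = adj
        self.n_leaves = n_leaves

    def copy(self) -> "_UTree":
        return _UTree({k: set(v) for k, v in self.adj.items()}, self.n_leaves)

    def edges(self):
        seen = set()
        for u, nbrs in self.adj.items():
            for v in nbrs:
                if frozenset((u, v)) not in seen:
                    seen.add(frozenset((u, v)))
                    yield u, v

    def postorder(self) -> list:
        """Postorder layout for :func:`_fitch_counts`, rooted at the internal
        neighbor of the smallest present leaf (that leaf folded in as its
        child); partial trees during stepwise addition are supported."""
        first_leaf = min(k for k in self.adj if k < self.n_leaves)
        start = next(iter(self.adj[first_leaf]))
        order: list = []
        pos: dict = {}
        stack = [(start, None, False)]
        while stack:
            node, parent, done = stack.pop()
            if node < self.n_leaves:
                order.append(node)
                pos[node] = len(order) - 1
                continue
            if done:
                order.append([pos[c] for c in self.adj[node] if c != parent])
                pos[node] = len(order) - 1
            else:
                stack.append((node, parent, True))
                for c in self.adj[node]:
                    if c != parent:
                        stack.append((c, node, False))
        return order

    def splits(self, labels: list[str]) -> frozenset:
        """Canonical set of nontrivial splits (for deduplication)."""
        t = self.to_dendropy(labels)
        return frozenset(bipartitions(t))

    def to_dendropy(self, labels: list[str]) -> Tree:
        tns = dendropy.TaxonNamespace(labels)
        tree = dendropy.Tree(taxon_namespace=tns)
        start = next(iter(self.adj[0]))

        def build(node, parent):
            if node < self.n_leaves:
                return dendropy.Node(taxon=tns.get_taxon(labels[node]))
            dn = dendropy.Node()
            for c in self.adj[node]:
                if c != parent:
                    dn.add_child(build(c, node))
            return dn

        # root at leaf 0's internal neighbor, folding leaf 0 in as a child
        root = build(start, 0)
        root.add_child(dendropy.Node(taxon=tns.get_taxon(labels[0])))
        tree.seed_node = root
        tree.is_rooted = False
        return tree

    @classmethod
    def star3(cls, n_leaves: int) -> "_UTree":
        x = n_leaves
        adj = {0: {x}, 1: {x}, 2: {x}, x: {0, 1, 2}}
        return cls(adj, n_leaves)

    def insert_leaf(self, leaf: int, u: int, v: int, new_internal: int) -> "_UTree":
        t = self.copy()
        t.adj[u].discard(v)
        t.adj[v].discard(u)
        t.adj[new_internal] = {u, v, leaf}
        t.adj[u].add(new_internal)
        t.adj[v].add(new_internal)
        t.adj[leaf] = {new_internal}
        return t

    def nni_neighbors(self):
        """Both nearest-neighbor-interchange rearrangements of every
        internal edge."""
        for u, v in self.edges():
            if u < self.n_leaves or v < self.n_leaves:
                continue
            a, b = [x for x in self.adj[u] if x != v]
            c, d = [x for x in self.adj[v] if x != u]
            for x, y in ((b, c), (b, d)):
                t = self.copy()
                t.adj[u].discard(x)
                t.adj[v].discard(y)
                t.adj[u].add(y)
                t.adj[v].add(x)
                t.adj[x].discard(u)
                t.adj[x].add(v)
                t.adj[y].discard(v)
                t.adj[y].add(u)
                yield t

    @classmethod
    def from_dendropy(cls, tree: Tree, labels: list[str]) -> "_UTree":
        idx = {lbl: i for i, lbl in enumerate(labels)}
        n_leaves = len(labels)
        next_id = [n_leaves]
        adj: dict = {}

        def node_id(node):
            if node.is_leaf():
                return idx[node.taxon.label]
            i = next_id[0]
            next_id[0] += 1
            return i

        def walk(node, parent_id):
            nid = node_id(node)
            adj.setdefault(nid, set())
            if parent_id is not None:
                adj[nid].add(parent_id)
                adj[parent_id].add(nid)
            for c in node.child_nodes():
                walk(c, nid)
            return nid

        seed = tree.seed_node
        if len(seed.child_nodes()) == 2:
            # rooted binary: suppress the root so the tree is unrooted
            left, right = seed.child_nodes()
            lid = walk(left, None)
            rid = walk(right, None)
            adj[lid].add(rid)
            adj[rid].add(lid)
        else:
            walk(seed, None)
        return cls(adj, n_leaves)


def enumerate_topologies(n_leaves: int) -> list[_UTree]:
    """All (2n-5)!! unrooted binary topologies by stepwise insertion."""
    if n_leaves < 3:
        raise ValueError("need >= 3 leaves")
    trees = [_UTree.star3(n_leaves)]
    next_internal = n_leaves + 1
    for leaf in range(3, n_leaves):
        trees = [
            t.insert_leaf(leaf, u, v, next_internal)
            for t in trees
            for u, v in t.edges()
        ]
        next_internal += 1
    return trees


def parsimony_search(
    aln: Alignment,
    exhaustive_max: int = 7,
    hard_cap: int = 9,
    restarts: int = 3,
    seed: int = 0,
) -> tuple[list[Tree], int]:
    """Most-parsimonious trees under the Fitch criterion.

    At most ``exhaustive_max`` taxa: exact search over every unrooted
    topology (refused with guidance above ``hard_cap``, where the
    (2n-5)!! census explodes).  Beyond: NNI hill-climbing from the NJ
    topology plus random stepwise-addition restarts.  All co-optimal
    trees found are returned together with the best score.
    """
    labels = list(aln.labels)
    n = len(labels)
    if n < 4:
        raise ValueError("parsimony search requires >= 4 taxa")
    codes = _encode(aln)

    def score(t: _UTree) -> int:
        return int(_fitch_counts(t.postorder(), codes).sum())

    if n <= exhaustive_max:
        if n > hard_cap:
            raise ValueError(
                f"exhaustive search over {n} taxa is refused: the hard cap "
                f"is {hard_cap} because the (2n-5)!! topology census "
                "explodes; lower exhaustive_max to use the NNI heuristic"
            )
        best: list[_UTree] = []
        best_score = None
        for t in enumerate_topologies(n):
            s = score(t)
            if best_score is None or s < best_score:
                best, best_score = [t], s
            elif s == best_score:
                best.append(t)
        return [t.to_dendropy(labels) for t in best], int(best_score)

    rng = np.random.default_rng(seed)

    def hill_climb(t: _UTree) -> tuple[_UTree, int]:
        s = score(t)
        improved = True
        while improved:
            improved = False
            for nb in t.nni_neighbors():
                s2 = score(nb)
                if s2 < s:
                    t, s = nb, s2
                    improved = True
                    break
        return t, s

    starts: list[_UTree] = []
    nj = neighbor_joining(pairwise_distance(aln, "p"))
    starts.append(_UTree.from_dendropy(nj, labels))
    for _ in range(max(0, restarts - 1)):
        order = [int(x) for x in rng.permutation(n)]
        t = _UTree.star3(n)
        remap = {i: order[i] for i in range(n)}
        # random starting triple, then greedy insertion of the rest
        t = _relabel(t, remap, n)
        next_internal = n + 1
        for k in range(3, n):
            leaf = order[k]
            cands = [
                t.insert_leaf(leaf, u, v, next_internal)
                for u, v in t.edges()
            ]
            t = min(cands, key=score)
            next_internal += 1
        starts.append(t)

    best_trees: list[_UTree] = []
    best_score = None
    seen: set[frozenset] = set()
    for t0 in starts:
        t, s = hill_climb(t0)
        if best_score is None or s < best_score:
            best_trees, best_score, seen = [t], s, {t.splits(labels)}
        elif s == best_score and t.splits(labels) not in seen:
            best_trees.append(t)
            seen.add(t.splits(labels))
    return [t.to_dendropy(labels) for t in best_trees], int(best_score)


def _relabel(t: _UTree, remap: dict, n_leaves: int) -> _UTree:
    adj: dict = {}
    for u, nbrs in t.adj.items():
        uu = remap.get(u, u)
        adj[uu] = {remap.get(v, v) for v in nbrs}
    return _UTree(adj, n_leaves)


# ---------------------------------------------------------------------------
# bootstrap and concatenation
# ---------------------------------------------------------------------------


def _build_tree(aln: Alignment, builder: str, seed: int = 0) -> Tree:
    if builder == "nj":
        return neighbor_joining(pairwise_distance(aln, "JC69"))
    if builder == "mp":
        trees, _ = parsimony_search(aln, exhaustive_max=0, seed=seed)
        return trees[0]
    raise ValueError(f"unknown builder {builder!r}")


def bootstrap_support(
    aln: Alignment,
    builder: str = "nj",
    reps: int = 100,
    seed: int = 0,
) -> Tree:
    """Nonparametric bootstrap support on the tree built from ``aln``.

    Columns are resampled with replacement; support for each internal
    edge of the full-data tree is the percentage of successful replicate
    trees containing that bipartition (stored in internal-node labels and
    in ``tree.split_support``).  Replicates whose build fails are skipped
    with a warning and excluded from the denominator.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    rng = np.random.default_rng(seed)
    tree = _build_tree(aln, builder, seed=seed)
    counts: dict[frozenset, int] = {s: 0 for s in bipartitions(tree)}
    ok = 0
    skipped = 0
    for _ in range(reps):
        cols = rng.integers(0, aln.length, aln.length)
        try:
            rep_tree = _build_tree(aln.take_columns(cols), builder, seed=seed)
        except ValueError as exc:
            skipped += 1
            warnings.warn(f"bootstrap replicate skipped: {exc}")
            continue
        ok += 1
        for s in bipartitions(rep_tree):
            if s in counts:
                counts[s] += 1
    if skipped:
        warnings.warn(f"{skipped} of {reps} bootstrap replicates skipped")
    support = {
        s: (100.0 * c / ok if ok else 0.0) for s, c in counts.items()
    }
    all_leaves = frozenset(leaf_labels(tree))
    ref = min(all_leaves)
    below: dict = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            below[node] = frozenset((node.taxon.label,))
            continue
        below[node] = frozenset().union(*(below[c] for c in node.child_nodes()))
        side = below[node]
        if node.parent_node is None or not (
            2 <= len(side) <= len(all_leaves) - 2
        ):
            continue
        if ref in side:
            side = all_leaves - side
        node.label = f"{support[side]:.0f}"
    tree.split_support = support
    return tree


def concatenate(loci: list[Alignment]) -> Alignment:
    """Append loci column-wise into a supermatrix.

    Taxa are matched by exact label; a taxon absent from a locus is padded
    with ``N`` there (with a warning).  Partition boundaries are recorded
    on the result as ``(locus, start, end)`` half-open column ranges.
    """
    if not loci:
        raise ValueError("no loci to concatenate")
    labels: list[str] = []
    for aln in loci:
        for lbl in aln.labels:
            if lbl not in labels:
                labels.append(lbl)
    blocks = []
    partitions = []
    start = 0
    for aln in loci:
        block = np.full((len(labels), aln.length), ord("N"), dtype=np.uint8)
        row_of = {lbl: i for i, lbl in enumerate(aln.labels)}
        absent = [lbl for lbl in labels if lbl not in row_of]
        if absent:
            warnings.warn(
                f"locus {aln.locus!r}: taxa padded with N: {absent}"
            )
        for k, lbl in enumerate(labels):
            if lbl in row_of:
                block[k] = aln.matrix[row_of[lbl]]
        blocks.append(block)
        partitions.append((aln.locus, start, start + aln.length))
        start += aln.length
    genomes = {aln.genome for aln in loci}
    out = Alignment(
        labels,
        np.concatenate(blocks, axis=1),
        locus="concatenated",
        genome=genomes.pop() if len(genomes) == 1 else "",
    )
    out.partitions = partitions
    return out


# ---------------------------------------------------------------------------
# Newick I/O
# ---------------------------------------------------------------------------


def read_newick(path) -> Tree:
    """Read a Newick tree (underscores in labels preserved)."""
    return dendropy.Tree.get(
        path=str(path), schema="newick", preserve_underscores=True
    )


def write_newick(tree: Tree, path) -> None:
    """Write Newick with support values as internal-node labels."""
    tree.write(
        path=str(path),
        schema="newick",
        suppress_rooting=True,
        unquoted_underscores=True,
    )


def tree_from_newick_string(s: str) -> Tree:
    return dendropy.Tree.get(
        data=s, schema="newick", preserve_underscores=True
    )


def tree_to_newick_string(tree: Tree) -> str:
    return tree.as_string(
        schema="newick", suppress_rooting=True, unquoted_underscores=True
    ).strip()
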