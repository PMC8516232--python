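"""Hierarchical clustering of similarity matrices and tree comparison.

Genome dendrograms are built by agglomerative clustering with the Ward.D2
criterion (squared dissimilarities inside the Lance-Williams recurrence) and
reordered by Bar-Joseph optimal leaf ordering, which flips internal nodes to
minimise the summed dissimilarity between successive leaves.

Tree comparison uses a generalized Robinson-Foulds distance based on mutual
clustering information: each nontrivial bipartition (split) of a tree is
treated as a two-block clustering of the leaves, splits of the two trees are
matched one-to-one to maximise the total mutual information between paired
splits, and the distance is the information not shared,

    d(T1, T2) = H(T1) + H(T2) - 2 * MCI(T1, T2),

normalised by H(T1) + H(T2) so that identical trees score 0 and unrelated
trees approach 1.  Unlike the classic Robinson-Foulds metric this rewards
similar-but-not-identical splits, which is essential when comparing a binary
dendrogram against a polytomous reference taxonomy.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np
from scipy.cluster import hierarchy
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import squareform

from .similarity import SimilarityMatrix

__all__ = [
    "ClusterTree",
    "ward_cluster",
    "optimal_leaf_order",
    "adjacent_leaf_objective",
    "similarity_to_dissimilarity",
    "reference_tree",
    "generalized_rf",
    "random_tree",
    "to_newick",
    "from_newick",
]

MAJOR_RANKS: tuple[str, ...] = (
    "superkingdom",
    "phylum",
    "class",
    "order",
    "family",
    "genus",
    "species",
)


# ---------------------------------------------------------------------- #
# cluster trees (scipy linkage + labels)
# ---------------------------------------------------------------------- #
@dataclass
class ClusterTree:
    """Rooted binary dendrogram over genome leaves.

    Wraps a scipy linkage matrix together with the leaf labels.  Merge
    heights are non-decreasing from leaves to root; ``leaf_order`` is the
    left-to-right order of the current planar embedding.
    """

    labels: list[str]
    linkage: np.ndarray

    def __post_init__(self) -> None:
        self.linkage = np.asarray(self.linkage, dtype=float)
        n = len(self.labels)
        if self.linkage.shape != (n - 1, 4):
            raise ValueError("linkage shape inconsistent with number of labels")

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    @property
    def heights(self) -> np.ndarray:
        return self.linkage[:, 2]

    @property
    def leaf_order(self) -> list[str]:
        return [self.labels[i] for i in hierarchy.leaves_list(self.linkage)]

    def clusters(self) -> list[frozenset[str]]:
        """Leaf set under every internal node, in merge order."""
        n = self.n_leaves
        members: dict[int, frozenset[str]] = {
            i: frozenset([self.labels[i]]) for i in range(n)
        }
        out = []
        for m, (a, b, _h, _c) in enumerate(self.linkage):
            merged = members[int(a)] | members[int(b)]
            members[n + m] = merged
            out.append(merged)
        return out

    def to_newick(self, branch_lengths: bool = True) -> str:
        n = self.n_leaves
        node: dict[int, str] = {i: _quote(self.labels[i]) for i in range(n)}
        height: dict[int, float] = {i: 0.0 for i in range(n)}
        for m, (a, b, h, _c) in enumerate(self.linkage):
            a, b = int(a), int(b)
            if branch_lengths:
                left = f"{node[a]}:{h - height[a]:.10g}"
                right = f"{node[b]}:{h - height[b]:.10g}"
            else:
                left, right = node[a], node[b]
            node[n + m] = f"({left},{right})"
            height[n + m] = float(h)
        return node[n + (n - 1) - 1] + ";"


def _quote(label: str) -> str:
    if any(c in label for c in " (),:;[]'"):
        return "'" + label.replace("'", "''") + "'"
    return label


def _check_dissimilarity(D: np.ndarray) -> np.ndarray:
    D = np.asarray(D, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("dissimilarity matrix must be square")
    if not np.allclose(D, D.T, atol=1e-12):
        raise ValueError("dissimilarity matrix must be symmetric")
    if np.any(D < 0):
        raise ValueError("dissimilarities must be nonnegative")
    if not np.allclose(np.diag(D), 0.0):
        raise ValueError("dissimilarity diagonal must be zero")
    return D


def ward_cluster(D: np.ndarray, labels: list[str] | None = None) -> ClusterTree:
    """Agglomerative clustering with the Ward.D2 criterion.

    The Lance-Williams update operates on squared dissimilarities
    (Murtagh-Legendre "Ward2"); recorded merge heights are on the scale of
    the input dissimilarities.  Ties in the minimum-distance search resolve
    to the lowest cluster index, making the merge sequence deterministic.
    """
    D = _check_dissimilarity(D)
    n = D.shape[0]
    if labels is None:
        labels = [f"L{i}" for i in range(n)]
    if len(labels) != n:
        raise ValueError("labels length does not match matrix size")
    Z = hierarchy.linkage(squareform(D, checks=False), method="ward")
    return ClusterTree(labels=list(labels), linkage=Z)


def adjacent_leaf_objective(order: list[str], D: np.ndarray, labels: list[str]) -> float:
    """Sum of dissimilarities between successive leaves of an ordering."""
    idx = {lab: i for i, lab in enumerate(labels)}
    pos = [idx[lab] for lab in order]
    return float(sum(D[pos[i], pos[i + 1]] for i in range(len(pos) - 1)))


def optimal_leaf_order(tree: ClusterTree, D: np.ndarray) -> ClusterTree:
    """Bar-Joseph optimal leaf ordering of a dendrogram.

    Among the 2^(n-1) orderings reachable by flipping internal nodes,
    returns one minimising the adjacent-leaf dissimilarity sum.  Exact
    dynamic program over the (leftmost, rightmost) leaf pairs of every
    subtree; ties resolve deterministically via numpy argmin (first, i.e.
    lowest-index, optimum).
    """
    D = _check_dissimilarity(D)
    n = tree.n_leaves
    if D.shape[0] != n:
        raise ValueError("matrix size does not match tree leaves")
    Z = tree.linkage
    INF = np.inf
    # per node: sorted leaf array and dense cost table M[l, r] indexed by
    # position in the leaf array; invalid (l, r) pairs carry +inf
    leaves_of: dict[int, np.ndarray] = {}
    tables: dict[int, np.ndarray] = {}
    for i in range(n):
        leaves_of[i] = np.array([i])
        tables[i] = np.zeros((1, 1))
    for m in range(n - 1):
        a, b = int(Z[m, 0]), int(Z[m, 1])
        la, lb = leaves_of[a], leaves_of[b]
        Ma, Mb = tables[a], tables[b]
        Dab = D[np.ix_(la, lb)]
        # tmp[l, bl] = min_ar Ma[l, ar] + D[ar, bl]   (min-plus products)
        tmp = (Ma[:, :, None] + Dab[None, :, :]).min(axis=1)
        Mab = (tmp[:, :, None] + Mb.T[None, :, :]).min(axis=1)
        node = n + m
        leaves = np.concatenate([la, lb])
        M = np.full((leaves.size, leaves.size), INF)
        M[: la.size, la.size :] = Mab
        M[la.size :, : la.size] = Mab.T  # reversal symmetry
        leaves_of[node] = leaves
        tables[node] = M

    root = 2 * n - 2
    flat = int(np.argmin(tables[root]))
    li, ri = np.unravel_index(flat, tables[root].shape)

    def reconstruct(node: int, l: int, r: int) -> list[int]:
        if node < n:
            return [node]
        m = node - n
        a, b = int(Z[m, 0]), int(Z[m, 1])
        la, lb = leaves_of[a], leaves_of[b]
        if l in set(la.tolist()):
            first, second, lf, ls = a, b, la, lb
        else:
            first, second, lf, ls = b, a, lb, la
        Mf, Ms = tables[first], tables[second]
        lpos = int(np.where(lf == l)[0][0])
        rpos = int(np.where(ls == r)[0][0])
        inner = Mf[lpos, :][:, None] + D[np.ix_(lf, ls)] + Ms[:, rpos][None, :]
        fi, si = np.unravel_index(int(np.argmin(inner)), inner.shape)
        return reconstruct(first, l, int(lf[fi])) + reconstruct(second, int(ls[si]), r)

    order = reconstruct(root, int(leaves_of[root][li]), int(leaves_of[root][ri]))
    # realize the order by flipping children so leaves_list(Z) == order
    pos = {leaf: p for p, leaf in enumerate(order)}
    Znew = Z.copy()
    for m in range(n - 1):
        a, b = int(Z[m, 0]), int(Z[m, 1])
        if min(pos[v] for v in leaves_of[a]) > min(pos[v] for v in leaves_of[b]):
            Znew[m, 0], Znew[m, 1] = Z[m, 1], Z[m, 0]
    out = ClusterTree(labels=list(tree.labels), linkage=Znew)
    assert [tree.labels.index(x) for x in out.leaf_order] == order
    return out


def similarity_to_dissimilarity(
    S: SimilarityMatrix, mode: str = "one-minus", eps: float = 1e-8
) -> np.ndarray:
    """Turn a Jaccard similarity matrix into a clustering dissimilarity.

    mode "one-minus": d = 1 - J.  mode "neglog": d = -log10((J + eps) /
    (1 + eps)), rescaled so the diagonal is exactly zero.  Both transforms
    are strictly order-reversing in J.
    """
    if mode == "one-minus":
        D = 1.0 - S.J
    elif mode == "neglog":
        D = -np.log10((S.J + eps) / (1.0 + eps))
    else:
        raise ValueError(f"unknown dissimilarity mode: {mode!r}")
    np.fill_diagonal(D, 0.0)
    return D


# ---------------------------------------------------------------------- #
# reference trees from ranked taxonomy
# ---------------------------------------------------------------------- #
def reference_tree(taxonomy, ranks: tuple[str, ...] | None = None) -> dendropy.Tree:
    """Build the reference tree implied by a ranked taxonomy table.

    Organisms are nested by the major ranks from superkingdom down to
    species; internal nodes are named after the taxa and polytomies are
    preserved.  A lineage missing a rank label simply attaches at the
    nearest labelled ancestor (skip rule).  Passing ``ranks`` with extra
    user-supplied intermediate ranks (columns of the table) resolves
    polytomies where those labels exist.
    """
    from .lca_taxonomy import TaxonomyTable

    if isinstance(taxonomy, TaxonomyTable):
        df = taxonomy.table
    else:
        df = taxonomy
    if ranks is None:
        ranks = MAJOR_RANKS
    if df["genome_id"].duplicated().any():
        raise ValueError("duplicate genome_ids in taxonomy table")
    missing_sk = df[ranks[0]].isna()
    if missing_sk.any():
        bad = df.loc[missing_sk, "genome_id"].tolist()
        raise ValueError(f"every organism needs a {ranks[0]} label; missing for {bad}")

    def build(sub, level: int) -> str:
        if level == len(ranks):
            leaves = [_quote(g) for g in sub["genome_id"]]
            return ",".join(leaves)
        rank = ranks[level]
        parts = []
        unlabelled = sub[sub[rank].isna()]
        if len(unlabelled):
            parts.append(build(unlabelled, level + 1))
        for taxon, group in sub[sub[rank].notna()].groupby(rank, sort=True):
            inner = build(group, level + 1)
            if len(group) == 1:
                parts.append(inner)  # no uninformative unary node
            else:
                parts.append(f"({inner}){_quote(str(taxon))}")
        return ",".join(parts)

    newick = f"({build(df, 0)})root;"
    return from_newick(newick)


# ---------------------------------------------------------------------- #
# generalized Robinson-Foulds (mutual clustering information)
# ---------------------------------------------------------------------- #
def _leaf_set(tree) -> list[str]:
    if isinstance(tree, ClusterTree):
        return sorted(tree.labels)
    if isinstance(tree, dendropy.Tree):
        return sorted(leaf.taxon.label for leaf in tree.leaf_node_iter())
    raise TypeError(f"unsupported tree type: {type(tree)!r}")


def _split_masks(tree, taxa: list[str]) -> list[int]:
    """Nontrivial bipartitions of a tree as canonical bitmasks over taxa."""
    index = {t: i for i, t in enumerate(taxa)}
    n = len(taxa)
    full = (1 << n) - 1
    raw: list[int] = []
    if isinstance(tree, ClusterTree):
        for clade in tree.clusters():
            mask = 0
            for lab in clade:
                mask |= 1 << index[lab]
            raw.append(mask)
    else:
        for node in tree.preorder_node_iter():
            if node.is_leaf() or node.parent_node is None:
                continue
            mask = 0
            for leaf in node.leaf_iter():
                mask |= 1 << index[leaf.taxon.label]
            raw.append(mask)
    splits: set[int] = set()
    for mask in raw:
        size = mask.bit_count()
        if size < 2 or size > n - 2:
            continue
        splits.add(min(mask, full ^ mask))
    return sorted(splits)


def _split_entropy(mask: int, n: int) -> float:
    a = mask.bit_count()
    b = n - a
    p, q = a / n, b / n
    return -(p * np.log(p) + q * np.log(q))


def _mutual_info(m1: int, m2: int, n: int, full: int) -> float:
    cells = (
        (m1 & m2).bit_count(),
        (m1 & (full ^ m2)).bit_count(),
        ((full ^ m1) & m2).bit_count(),
        ((full ^ m1) & (full ^ m2)).bit_count(),
    )
    r1 = m1.bit_count()
    rows = (r1, r1, n - r1, n - r1)
    c1 = m2.bit_count()
    cols = (c1, n - c1, c1, n - c1)
    total = 0.0
    for nij, ri, cj in zip(cells, rows, cols):
        if nij:
            total += (nij / n) * np.log(n * nij / (ri * cj))
    return total


def generalized_rf(t1, t2) -> float:
    """Normalized generalized Robinson-Foulds distance between two trees.

    Accepts :class:`ClusterTree`, :class:`dendropy.Tree` or Newick strings.
    Based on mutual clustering information with optimal one-to-one split
    matching (solved as a linear assignment); 0 for identical trees,
    approaching 1 for unrelated trees.
    """
    t1 = from_newick(t1) if isinstance(t1, str) else t1
    t2 = from_newick(t2) if isinstance(t2, str) else t2
    taxa1, taxa2 = _leaf_set(t1), _leaf_set(t2)
    if taxa1 != taxa2:
        raise ValueError("trees must share an identical leaf set")
    taxa = taxa1
    n = len(taxa)
    full = (1 << n) - 1
    s1 = _split_masks(t1, taxa)
    s2 = _split_masks(t2, taxa)
    h1 = sum(_split_entropy(m, n) for m in s1)
    h2 = sum(_split_entropy(m, n) for m in s2)
    if h1 + h2 == 0.0:
        return 0.0
    if not s1 or not s2:
        return 1.0
    gain = np.zeros((len(s1), len(s2)))
    for i, m1 in enumerate(s1):
        for j, m2 in enumerate(s2):
            gain[i, j] = _mutual_info(m1, m2, n, full)
    rows, cols = linear_sum_assignment(gain, maximize=True)
    shared = float(gain[rows, cols].sum())
    dist = (h1 + h2 - 2.0 * shared) / (h1 + h2)
    return float(max(dist, 0.0))


# ---------------------------------------------------------------------- #
# random trees and Newick I/O
# ---------------------------------------------------------------------- #
def random_tree(
    n_leaves: int,
    rng: np.random.Generator,
    labels: list[str] | None = None,
) -> dendropy.Tree:
    """Random binary topology by recursive uniform splitting of the leaf set.

    At every internal node the current leaf set of size m is split into two
    children of sizes (a, m - a) with a drawn uniformly from 1..m-1; labels
    are shuffled before assignment.  Seeded generation is bit-reproducible.
    """
    if n_leaves < 2:
        raise ValueError("need at least 2 leaves")
    if labels is None:
        labels = [f"t{i + 1}" for i in range(n_leaves)]
    if len(labels) != n_leaves:
        raise ValueError("labels length does not match n_leaves")
    labels = list(labels)
    perm = rng.permutation(n_leaves)
    shuffled = [labels[i] for i in perm]

    def build(lo: int, hi: int) -> str:
        m = hi - lo
        if m == 1:
            return _quote(shuffled[lo])
        a = int(rng.integers(1, m))
        return f"({build(lo, lo + a)},{build(lo + a, hi)})"

    return from_newick(build(0, n_leaves) + ";")


def to_newick(tree) -> str:
    if isinstance(tree, ClusterTree):
        return tree.to_newick()
    if isinstance(tree, dendropy.Tree):
        return tree.as_string(schema="newick", suppress_rooting=True).strip()
    raise TypeError(f"unsupported tree type: {type(tree)!r}")


def from_newick(source) -> dendropy.Tree:
    """Parse Newick from a string or a file path; polytomies are preserved."""
    import os

    source = str(source)
    if "(" not in source and os.path.exists(source):
        with open(source) as fh:
            source = fh.read()
    try:
        tree = dendropy.Tree.get(
            data=source,
            schema="newick",
            suppress_internal_node_taxa=True,  # internal names are node labels
            case_sensitive_taxon_labels=True,
            preserve_underscores=True,
        )
    except Exception as exc:
        raise ValueError(f"malformed Newick: {exc}") from exc
    return tree
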