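"""Distance-matrix phylogenetics: p-distance, Neighbor-Joining, and
bootstrap supports.

Neighbor-Joining (Saitou & Nei 1987, with the Studier & Keppler Q
criterion) is exact on additive distance matrices: the path length
between any two leaves of the reconstructed tree equals the input
distance.  Bootstrap support for an internal edge is the percentage of
column-resampled replicate trees that contain the same leaf
bipartition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

from .alignment import GAP, MsAlignment


# ---------------------------------------------------------------------------
# Distances
# ---------------------------------------------------------------------------

@dataclass
class DistanceMatrix:
    """Symmetric nonnegative distances with a zero diagonal."""

    taxa: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.taxa)
        if self.d.shape != (n, n):
            raise ValueError("matrix shape does not match taxa")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("distance matrix is not symmetric")
        if np.any(np.diag(self.d) != 0):
            raise ValueError("diagonal must be zero")
        if np.any(self.d < 0):
            raise ValueError("distances must be nonnegative")
        if len(set(self.taxa)) != n:
            raise ValueError("duplicate taxon labels")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.d, index=self.taxa, columns=self.taxa)


def p_distance(aln: MsAlignment, model: str = "p-distance") -> DistanceMatrix:
    """Proportion of differing sites per pair, with pairwise deletion of
    gap columns.  ``model="jukes-cantor"`` applies the JC69 correction
    -3/4 ln(1 - 4p/3).

    A pair with no comparable (gap-free) columns is an error naming the
    pair.
    """
    if aln.n_rows < 3:
        raise ValueError("need at least 3 rows for a distance matrix")
    seqs = [s for _, s in aln.rows]
    ids = aln.ids
    n = len(seqs)
    arr = np.array([list(s) for s in seqs])
    gap = arr == GAP
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ok = ~gap[i] & ~gap[j]
            m = int(ok.sum())
            if m == 0:
                raise ValueError(
                    f"no comparable columns between {ids[i]!r} and {ids[j]!r}"
                )
            p = float((arr[i][ok] != arr[j][ok]).sum()) / m
            if model == "jukes-cantor":
                if p >= 0.75:
                    raise ValueError(
                        f"JC69 undefined for p={p:.3f} between {ids[i]!r} and {ids[j]!r}"
                    )
                p = -0.75 * np.log1p(-4.0 * p / 3.0)
            elif model != "p-distance":
                raise ValueError(f"unknown distance model {model!r}")
            d[i, j] = d[j, i] = p
    return DistanceMatrix(taxa=list(ids), d=d)


# ---------------------------------------------------------------------------
# Trees
# ---------------------------------------------------------------------------

@dataclass
class TreeNode:
    """Node of an unrooted tree stored with a trifurcating root."""

    label: str = ""
    length: float = 0.0  # branch to parent
    support: float | None = None  # bootstrap %, internal nodes only
    children: list["TreeNode"] = field(default_factory=list)

    def leaf_labels(self) -> list[str]:
        if not self.children:
            return [self.label]
        out: list[str] = []
        for c in self.children:
            out.extend(c.leaf_labels())
        return out

    def postorder(self):
        for c in self.children:
            yield from c.postorder()
        yield self


@dataclass
class PhyloTree:
    root: TreeNode

    @property
    def taxa(self) -> list[str]:
        return sorted(self.root.leaf_labels())

    def n_edges(self) -> int:
        return sum(1 for n in self.root.postorder() if n is not self.root)

    def leaf_distances(self) -> DistanceMatrix:
        """Path-length distances between all leaf pairs."""
        # accumulate root-to-node depths, then d = depth_i + depth_j - 2*depth_lca
        paths: dict[str, list[TreeNode]] = {}

        def walk(node: TreeNode, trail: list[TreeNode]) -> None:
            trail = trail + [node]
            if not node.children:
                paths[node.label] = trail
            for c in node.children:
                walk(c, trail)

        walk(self.root, [])
        taxa = sorted(paths)
        n = len(taxa)
        d = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                a, b = paths[taxa[i]], paths[taxa[j]]
                k = 0
                while k < min(len(a), len(b)) and a[k] is b[k]:
                    k += 1
                dist = sum(x.length for x in a[k:]) + sum(x.length for x in b[k:])
                d[i, j] = d[j, i] = dist
        return DistanceMatrix(taxa=taxa, d=d)

    def bipartitions(self) -> set[frozenset[str]]:
        """Internal-edge leaf bipartitions, each canonicalised as the
        side that excludes the lexicographically first taxon."""
        all_taxa = frozenset(self.root.leaf_labels())
        ref = min(all_taxa)
        out: set[frozenset[str]] = set()
        for node in self.root.postorder():
            if node is self.root or not node.children:
                continue
            side = frozenset(node.leaf_labels())
            if ref in side:
                side = all_taxa - side
            if 2 <= len(side) <= len(all_taxa) - 2:
                out.add(side)
        return out

    def to_dendropy(self) -> dendropy.Tree:
        taxa = dendropy.TaxonNamespace()
        tree = dendropy.Tree(taxon_namespace=taxa)

        def build(node: TreeNode, dnode: dendropy.Node) -> None:
            for c in node.children:
                child = dendropy.Node(edge_length=round(c.length, 10))
                if c.children:
                    if c.support is not None:
                        child.label = str(int(round(c.support)))
                else:
                    child.taxon = taxa.new_taxon(c.label)
                dnode.add_child(child)
                build(c, child)

        build(self.root, tree.seed_node)
        return tree


def neighbor_joining(D: DistanceMatrix) -> PhyloTree:
    """Saitou-Nei Neighbor-Joining with deterministic tie-breaking.

    Q-matrix ties are broken by the smallest (i, j) index pair in the
    current working matrix.  Negative branch lengths are clamped to
    zero with the deficit moved onto the sibling branch (the convention
    of mainstream phylogenetics GUIs), so total path lengths through
    the joined pair are preserved.
    """
    n = len(D.taxa)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    nodes: list[TreeNode] = [TreeNode(label=t) for t in D.taxa]
    d = D.d.astype(float).copy()
    active = list(range(n))

    while len(active) > 3:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        # smallest Q, ties -> smallest (i, j) position pair
        best = np.inf
        bi = bj = -1
        for a in range(m):
            for b in range(a + 1, m):
                if q[a, b] < best - 1e-12:
                    best = q[a, b]
                    bi, bj = a, b
        i, j = active[bi], active[bj]
        li = 0.5 * d[i, j] + (r[bi] - r[bj]) / (2.0 * (m - 2))
        lj = d[i, j] - li
        li, lj = _clamp_pair(li, lj)
        parent = TreeNode(children=[nodes[i], nodes[j]])
        nodes[i].length = li
        nodes[j].length = lj
        # distances from the new node
        new_row = 0.5 * (d[i, :] + d[j, :] - d[i, j])
        d = np.vstack([d, new_row])
        new_col = np.append(new_row, 0.0)
        d = np.column_stack([d, new_col])
        nodes.append(parent)
        k = d.shape[0] - 1
        active = [a for a in active if a not in (i, j)] + [k]

    # join the final three nodes on a trifurcating root (closed form)
    a, b, c = active
    la = 0.5 * (d[a, b] + d[a, c] - d[b, c])
    lb = 0.5 * (d[a, b] + d[b, c] - d[a, c])
    lc = 0.5 * (d[a, c] + d[b, c] - d[a, b])
    for node, ln in zip((nodes[a], nodes[b], nodes[c]), (la, lb, lc)):
        node.length = max(ln, 0.0)
    root = TreeNode(children=[nodes[a], nodes[b], nodes[c]])
    return PhyloTree(root=root)


def _clamp_pair(li: float, lj: float) -> tuple[float, float]:
    """Clamp a negative branch to 0, moving the deficit to the sibling."""
    if li < 0:
        lj += li
        li = 0.0
    if lj < 0:
        li += lj
        lj = 0.0
    return li, max(lj, 0.0)


# ---------------------------------------------------------------------------
# Bootstrap
# ---------------------------------------------------------------------------

def bootstrap_supports(
    aln: MsAlignment,
    replicates: int = 1000,
    seed: int = 0,
    model: str = "p-distance",
) -> PhyloTree:
    """NJ tree from the full alignment with bootstrap supports.

    Columns are resampled with replacement; all replicate column draws
    are taken as one (replicates x n_columns) block from a single
    seeded generator, so replicate r is reproducible regardless of how
    the work is chunked.  Support of an internal edge is the percentage
    of replicate trees containing the same leaf bipartition.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    if aln.n_columns < 2:
        raise ValueError("alignment must have at least 2 columns")
    base = neighbor_joining(p_distance(aln, model=model))
    rng = np.random.default_rng(seed)
    draws = rng.integers(0, aln.n_columns, size=(replicates, aln.n_columns))
    counts: dict[frozenset[str], int] = {bp: 0 for bp in base.bipartitions()}
    for r in range(replicates):
        cols = draws[r]
        rows = [(rid, "".join(s[c] for c in cols)) for rid, s in aln.rows]
        rep_tree = neighbor_joining(p_distance(MsAlignment(rows=rows), model=model))
        for bp in rep_tree.bipartitions():
            if bp in counts:
                counts[bp] += 1
    supports = {bp: 100.0 * k / replicates for bp, k in counts.items()}
    all_taxa = frozenset(base.root.leaf_labels())
    ref = min(all_taxa)
    for node in base.root.postorder():
        if node is base.root or not node.children:
            continue
        side = frozenset(node.leaf_labels())
        if ref in side:
            side = all_taxa - side
        if side in supports:
            node.support = supports[side]
    return base
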