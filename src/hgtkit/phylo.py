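"""Distance-based gene-tree inference and rooted-tree queries.

The built-in tree engine is canonical Saitou-Nei neighbor joining on
Poisson-corrected protein distances, with classic Felsenstein bootstrap
(column resampling) for split support.  It is a desk-scale, deterministic
stand-in for maximum-likelihood inference: the downstream transfer test is
purely topological, so externally computed newick trees (with support
values on internal nodes) are accepted as first-class input through
:meth:`GeneTree.from_newick`.

Determinism: ties in the NJ Q-matrix are broken by the lexicographic order
of cluster representative labels (the smallest leaf name in each cluster),
and negative branch lengths are clamped to zero with the deficit moved to
the sister branch.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import dendropy
import numpy as np

from .align import GAP, ProteinAlignment

log = logging.getLogger(__name__)


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distance matrix with a zero diagonal.

    Triangle-inequality violations are permitted (NJ tolerates them) but
    logged at debug level; asymmetry is an error.
    """

    labels: list[str]
    matrix: np.ndarray

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = len(self.labels)
        if self.matrix.shape != (n, n):
            raise ValueError("distance matrix shape does not match labels")
        if not np.allclose(self.matrix, self.matrix.T, atol=1e-9):
            raise ValueError("distance matrix is not symmetric")
        if not np.allclose(np.diag(self.matrix), 0, atol=1e-9):
            raise ValueError("distance matrix diagonal must be zero")

    def distance(self, a: str, b: str) -> float:
        return float(self.matrix[self.labels.index(a), self.labels.index(b)])


def _encode(aln: ProteinAlignment) -> np.ndarray:
    return np.frombuffer("".join(aln.rows).encode(), dtype=np.uint8).reshape(
        len(aln.rows), aln.n_columns
    )


def _poisson_distances(enc: np.ndarray, max_distance: float) -> np.ndarray:
    gap = ord(GAP)
    n = enc.shape[0]
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            valid = (enc[i] != gap) & (enc[j] != gap)
            shared = int(valid.sum())
            if shared == 0:
                raise ValueError("sequence pair shares zero ungapped columns")
            p = float(((enc[i] != enc[j]) & valid).sum()) / shared
            if p >= 1.0 - math.exp(-max_distance):
                log.debug("pairwise distance capped at %.2f (p=%.3f)", max_distance, p)
                dist = max_distance
            else:
                dist = -math.log(1.0 - p)
            d[i, j] = d[j, i] = dist
    return d


def protein_distance(aln: ProteinAlignment, max_distance: float = 10.0) -> DistanceMatrix:
    """Poisson-corrected distance d = -ln(1 - p) over pairwise-complete columns."""
    if len(aln.ids) < 2:
        raise ValueError("need at least 2 rows")
    return DistanceMatrix(list(aln.ids), _poisson_distances(_encode(aln), max_distance))


# ---------------------------------------------------------------------------
# Gene trees


@dataclass(frozen=True)
class Clade:
    """Leaf content of a rooted clade plus the support of its stem edge."""

    leaves: frozenset[str]
    support: float | None


@dataclass(frozen=True)
class Bipartition:
    """Split of the leaf set induced by an internal edge."""

    side_a: frozenset[str]
    side_b: frozenset[str]
    support: float | None

    def __post_init__(self):
        if not self.side_a or not self.side_b or self.side_a & self.side_b:
            raise ValueError("bipartition blocks must be non-empty and disjoint")


def _normalize_split(side: frozenset[str], all_leaves: frozenset[str]) -> frozenset[str]:
    ref = min(all_leaves)
    return all_leaves - side if ref in side else side


class GeneTree:
    """Gene-tree topology with branch lengths and percent split supports."""

    def __init__(self, tree: dendropy.Tree, rooted: bool = False):
        self._t = tree
        self._t.is_rooted = rooted
        self.rooted = rooted

    # -- construction -------------------------------------------------------

    @classmethod
    def from_newick(cls, newick: str, rooted: bool = False) -> "GeneTree":
        tree = dendropy.Tree.get(
            data=newick,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
        for node in tree:
            support = None
            if node.label is not None:
                try:
                    support = float(node.label)
                except ValueError:
                    support = None
            node.support = support
        return cls(tree, rooted=rooted)

    def to_newick(self) -> str:
        for node in self._t.preorder_node_iter():
            if not node.is_leaf():
                support = getattr(node, "support", None)
                node.label = None if support is None else f"{support:g}"
        return self._t.as_string(
            schema="newick", suppress_rooting=True, unquoted_underscores=True
        ).strip()

    # -- basic queries ------------------------------------------------------

    @property
    def leaf_names(self) -> list[str]:
        return [lf.taxon.label for lf in self._t.leaf_node_iter()]

    def _leafset(self, node) -> frozenset[str]:
        return frozenset(lf.taxon.label for lf in node.leaf_iter())

    def split_supports(self) -> dict[frozenset[str], float | None]:
        """Support per internal split, keyed by the normalized leaf-set side."""
        all_leaves = frozenset(self.leaf_names)
        out: dict[frozenset[str], float | None] = {}
        for node in self._t.preorder_node_iter():
            if node.is_leaf() or node.parent_node is None:
                continue
            side = self._leafset(node)
            if len(side) <= 1 or len(side) >= len(all_leaves) - (0 if self.rooted else 1):
                continue
            key = _normalize_split(side, all_leaves)
            support = getattr(node, "support", None)
            if key in out and out[key] is not None and support is None:
                continue
            out[key] = support
        return out

    def bipartitions(self) -> list[Bipartition]:
        all_leaves = frozenset(self.leaf_names)
        return [
            Bipartition(side, all_leaves - side, support)
            for side, support in self.split_supports().items()
        ]

    # -- rooting ------------------------------------------------------------

    def root_at_outgroup(
        self, outgroup: set[str] | list[str], focal: str | None = None
    ) -> "GeneTree":
        """Root on the edge separating the outgroup from the rest.

        If several outgroup leaves are present but not monophyletic in the
        unrooted topology, fall back to rooting on the single outgroup leaf
        farthest (patristic distance) from ``focal`` and log a warning.
        """
        og = frozenset(outgroup)
        all_leaves = frozenset(self.leaf_names)
        present = og & all_leaves
        if not present:
            raise ValueError("no outgroup leaf in tree")
        og = present
        supports = self.split_supports()
        tree = self._t.clone(depth=1)
        target = None
        for node in tree.preorder_node_iter():
            if node.parent_node is None:
                continue
            side = frozenset(lf.taxon.label for lf in node.leaf_iter())
            if side == og or side == all_leaves - og:
                target = node
                break
        if target is None:
            if len(og) == 1:
                raise ValueError("single outgroup leaf not found on an edge")
            leaf = self._farthest_outgroup_leaf(og, focal)
            log.warning(
                "outgroup %s not monophyletic; rooting on farthest outgroup leaf %s",
                sorted(og), leaf,
            )
            target = next(
                nd for nd in tree.leaf_node_iter() if nd.taxon.label == leaf
            )
        length = target.edge.length
        half = None if length is None else length / 2.0
        tree.reroot_at_edge(target.edge, length1=half, length2=half, update_bipartitions=False)
        rooted = GeneTree(tree, rooted=True)
        for node in tree.preorder_node_iter():
            if node.is_leaf() or node.parent_node is None:
                node.support = None
                continue
            side = rooted._leafset(node)
            node.support = supports.get(_normalize_split(side, all_leaves))
        return rooted

    def _farthest_outgroup_leaf(self, og: frozenset[str], focal: str | None) -> str:
        pdm = self._t.phylogenetic_distance_matrix()
        taxa = {t.label: t for t in self._t.taxon_namespace}
        if focal is None or focal not in taxa:
            return min(og)
        return max(sorted(og), key=lambda leaf: pdm.distance(taxa[leaf], taxa[focal]))

    # -- rooted queries -----------------------------------------------------

    def smallest_clade_containing(self, leaves: set[str] | list[str]) -> Clade:
        """MRCA clade of the given leaves with the support of its stem edge."""
        if not self.rooted:
            raise ValueError("smallest_clade_containing requires a rooted tree")
        want = set(leaves)
        missing = want - set(self.leaf_names)
        if missing:
            raise KeyError(f"leaves absent from tree: {sorted(missing)}")
        node = self._t.mrca(taxon_labels=list(want))
        return Clade(self._leafset(node), getattr(node, "support", None))

    def ancestor_clades(self, leaf: str) -> list[Clade]:
        """Nested chain of clades containing a leaf, smallest first."""
        if not self.rooted:
            raise ValueError("ancestor_clades requires a rooted tree")
        node = next(
            (nd for nd in self._t.leaf_node_iter() if nd.taxon.label == leaf), None
        )
        if node is None:
            raise KeyError(f"leaf absent from tree: {leaf}")
        chain = []
        node = node.parent_node
        while node is not None:
            chain.append(Clade(self._leafset(node), getattr(node, "support", None)))
            node = node.parent_node
        return chain

    def topology_key(self) -> frozenset[frozenset[str]]:
        """Unrooted topology fingerprint: the set of non-trivial normalized splits."""
        return frozenset(self.split_supports())


# ---------------------------------------------------------------------------
# Neighbor joining


def nj_tree(dm: DistanceMatrix) -> GeneTree:
    """Canonical Saitou-Nei neighbor joining; deterministic under ties."""
    n = len(dm.labels)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    D = dm.matrix.astype(float).copy()
    nodes = list(dm.labels)  # newick fragments
    reps = list(dm.labels)  # representative (min leaf label) per cluster
    active = list(range(n))

    def join(i_pos: int, j_pos: int, bl_i: float, bl_j: float) -> None:
        # clamp negatives, moving the deficit to the sister branch
        if bl_i < 0:
            bl_j += bl_i
            bl_i = 0.0
        if bl_j < 0:
            bl_i += bl_j
            bl_j = 0.0
        bl_i, bl_j = max(bl_i, 0.0), max(bl_j, 0.0)
        a, b = active[i_pos], active[j_pos]
        first, second = (a, b) if reps[a] <= reps[b] else (b, a)
        nodes.append(
            f"({nodes[first]}:{bl(a, first, bl_i, bl_j)},{nodes[second]}:{bl(a, second, bl_i, bl_j)})"
        )
        reps.append(min(reps[a], reps[b]))

    def bl(a, which, bl_i, bl_j):
        return f"{(bl_i if which == a else bl_j):.10g}"

    while len(active) > 3:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        best = None
        for i in range(m):
            for j in range(i + 1, m):
                ra, rb = reps[active[i]], reps[active[j]]
                key = (round(q[i, j], 10), min(ra, rb), max(ra, rb))
                if best is None or key < best[0]:
                    best = (key, i, j)
        _, i, j = best
        d_ij = sub[i, j]
        bl_i = 0.5 * d_ij + (r[i] - r[j]) / (2 * (m - 2))
        bl_j = d_ij - bl_i
        join(i, j, bl_i, bl_j)
        new_idx = len(nodes) - 1
        new_row = np.zeros(D.shape[0] + 1)
        D = np.pad(D, ((0, 1), (0, 1)))
        for k_pos, k in enumerate(active):
            if k_pos in (i, j):
                continue
            D[new_idx, k] = D[k, new_idx] = 0.5 * (sub[i, k_pos] + sub[j, k_pos] - d_ij)
        a, b = active[i], active[j]
        active = [k for k in active if k not in (a, b)] + [new_idx]

    a, b, c = active
    d_ab, d_ac, d_bc = D[a, b], D[a, c], D[b, c]
    bl_a = 0.5 * (d_ab + d_ac - d_bc)
    bl_b = 0.5 * (d_ab + d_bc - d_ac)
    bl_c = 0.5 * (d_ac + d_bc - d_ab)
    parts = sorted(zip((reps[a], reps[b], reps[c]), (a, b, c), (bl_a, bl_b, bl_c)))
    newick = (
        "(" + ",".join(f"{nodes[idx]}:{max(b_len, 0.0):.10g}" for _, idx, b_len in parts) + ");"
    )
    return GeneTree.from_newick(newick, rooted=False)


def bootstrap_support(
    aln: ProteinAlignment,
    n_reps: int = 100,
    seed: int = 0,
    max_distance: float = 10.0,
) -> GeneTree:
    """NJ tree from the full alignment with Felsenstein bootstrap supports.

    Columns are resampled with replacement ``n_reps`` times; the support of
    each split of the original tree is the percentage of replicate trees
    containing that split.  Deterministic given the seed.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if len(aln.ids) < 4:
        raise ValueError("bootstrap needs an alignment with at least 4 rows")
    enc = _encode(aln)
    tree = nj_tree(DistanceMatrix(list(aln.ids), _poisson_distances(enc, max_distance)))
    counts: dict[frozenset[str], int] = {split: 0 for split in tree.split_supports()}
    rng = np.random.default_rng(seed)
    n_cols = enc.shape[1]
    for _ in range(n_reps):
        cols = rng.integers(0, n_cols, n_cols)
        rep_enc = enc[:, cols]
        rep_tree = nj_tree(
            DistanceMatrix(list(aln.ids), _poisson_distances(rep_enc, max_distance))
        )
        for split in rep_tree.split_supports():
            if split in counts:
                counts[split] += 1
    supports = {split: 100.0 * c / n_reps for split, c in counts.items()}
    all_leaves = frozenset(tree.leaf_names)
    for node in tree._t.preorder_node_iter():
        if node.is_leaf() or node.parent_node is None:
            continue
        side = tree._leafset(node)
        if len(side) <= 1 or len(side) >= len(all_leaves) - 1:
            continue
        node.support = supports.get(_normalize_split(side, all_leaves))
    return tree
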