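"""Time-calibrated phylogenies and the trait covariance they induce.

Under Brownian motion, a trait evolving along a rooted tree with branch
lengths in Ma induces a covariance between tips equal to the depth (root
distance) of their most recent common ancestor.  That matrix C is the
currency of every phylogenetic computation in this package: Pagel's λ
rescales its off-diagonal, GLS regression whitens by it, and ancestral
reconstruction conditions on it.

Newick I/O is delegated to dendropy; :class:`PhyloTree` is a thin wrapper
that enforces this package's contracts (mandatory branch lengths, unique
tip names, non-negative edges) and exposes the covariance algebra.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

__all__ = [
    "NewickParseError",
    "PhyloTree",
    "PhyloCov",
    "parse_newick",
    "phylo_covariance",
    "lambda_transform",
    "attach_fossil_tip",
]


class NewickParseError(ValueError):
    """Raised when a Newick string cannot be read or violates tree contracts."""


class PhyloTree:
    """Rooted tree with branch lengths in Ma (time increases root-ward).

    Wraps a :class:`dendropy.Tree`.  Tip names must be unique; every
    non-root edge must carry a non-negative length.  Trees need not be
    ultrametric (fossil tips end above the present).
    """

    def __init__(self, dtree: dendropy.Tree):
        self._tree = dtree
        self._tree.is_rooted = True
        self._validate()

    # -- construction -------------------------------------------------

    @classmethod
    def from_newick(cls, text: str, unit_lengths: bool = False) -> "PhyloTree":
        """Parse a Newick string.

        Branch lengths are mandatory; ``unit_lengths=True`` assigns length 1
        to every edge instead (testing convenience only).
        """
        try:
            dtree = dendropy.Tree.get(
                data=text,
                schema="newick",
                preserve_underscores=True,
                suppress_internal_node_taxa=True,
            )
        except Exception as exc:  # dendropy raises several error types
            raise NewickParseError(f"malformed Newick: {exc}") from exc
        if unit_lengths:
            for node in dtree.preorder_node_iter():
                if node.parent_node is not None:
                    node.edge.length = 1.0
        return cls(dtree)

    def _validate(self) -> None:
        labels = self.tip_names
        if len(labels) != len(set(labels)):
            dupes = sorted({x for x in labels if labels.count(x) > 1})
            raise NewickParseError(f"duplicate tip names: {dupes}")
        for node in self._tree.preorder_node_iter():
            if node.parent_node is None:
                continue
            if node.edge.length is None:
                where = node.taxon.label if node.taxon else "an internal node"
                raise NewickParseError(
                    f"missing branch length on the edge above {where}"
                )
            if node.edge.length < 0:
                raise NewickParseError(
                    f"negative branch length {node.edge.length}"
                )
        if self.height <= 0:
            raise NewickParseError("all root-to-tip path lengths are zero")

    # -- basic accessors ----------------------------------------------

    @property
    def tip_names(self) -> list[str]:
        return [leaf.taxon.label for leaf in self._tree.leaf_node_iter()]

    @property
    def n_tips(self) -> int:
        return len(self.tip_names)

    def depths(self) -> dict[str, float]:
        """Root-to-tip path length per tip, in Ma."""
        self._tree.calc_node_root_distances(return_leaf_distances_only=False)
        return {
            leaf.taxon.label: leaf.root_distance
            for leaf in self._tree.leaf_node_iter()
        }

    @property
    def height(self) -> float:
        """Maximum root-to-tip depth; extant tips sit at age 0 by convention."""
        return max(
            (self._path_length(leaf) for leaf in self._tree.leaf_node_iter()),
            default=0.0,
        )

    @staticmethod
    def _path_length(node) -> float:
        d = 0.0
        while node.parent_node is not None:
            d += node.edge.length
            node = node.parent_node
        return d

    def node_ages(self) -> dict:
        """Age (Ma before present) per node keyed by dendropy node object."""
        h = self.height
        ages = {}
        for node in self._tree.preorder_node_iter():
            ages[node] = h - self._path_length(node)
        return ages

    def copy(self) -> "PhyloTree":
        return PhyloTree(self._tree.clone(depth=1))

    def to_newick(self) -> str:
        s = self._tree.as_string(
            schema="newick",
            unquoted_underscores=True,
            suppress_rooting=True,
            real_value_format_specifier=".12g",
        )
        return s.strip() + ("\n" if not s.endswith("\n") else "")

    def __repr__(self) -> str:
        return f"PhyloTree(n_tips={self.n_tips}, height={self.height:.3g} Ma)"

    # -- structure table (used by simulators and ancestral states) ----

    def node_table(self):
        """Preorder arrays: parent index (-1 at root), edge length, label, tip flag.

        Internal nodes without a label get a stable synthetic id ``node<k>``.
        """
        nodes = list(self._tree.preorder_node_iter())
        index = {id(n): i for i, n in enumerate(nodes)}
        parent = np.empty(len(nodes), dtype=int)
        length = np.empty(len(nodes), dtype=float)
        labels: list[str] = []
        is_tip = np.zeros(len(nodes), dtype=bool)
        n_internal = 0
        for i, node in enumerate(nodes):
            parent[i] = -1 if node.parent_node is None else index[id(node.parent_node)]
            length[i] = 0.0 if node.parent_node is None else float(node.edge.length)
            if node.is_leaf():
                is_tip[i] = True
                labels.append(node.taxon.label)
            else:
                labels.append(node.label if node.label else f"node{n_internal}")
                n_internal += 1
        return NodeTable(parent=parent, length=length, labels=labels, is_tip=is_tip)

    # -- covariance ----------------------------------------------------

    def covariance(self, taxa: list[str] | None = None) -> "PhyloCov":
        return phylo_covariance(self, taxa)

    def full_covariance(self) -> tuple[list[str], np.ndarray, np.ndarray]:
        """Shared-path covariance over ALL nodes (internal + tips), preorder.

        Returns (labels, C_full, is_tip).  ``C_full[u, v]`` is the depth of
        the MRCA of nodes u and v; the root row/column is zero.
        """
        tab = self.node_table()
        n = len(tab.labels)
        depth = np.zeros(n)
        for i in range(1, n):  # preorder: parent precedes child
            depth[i] = depth[tab.parent[i]] + tab.length[i]
        # ancestor chains (root -> node) for MRCA-depth lookup
        chains: list[list[int]] = [[0]]
        for i in range(1, n):
            chains.append(chains[tab.parent[i]] + [i])
        C = np.zeros((n, n))
        for i in range(n):
            C[i, i] = depth[i]
            for j in range(i + 1, n):
                a, b = chains[i], chains[j]
                k = 0
                m = min(len(a), len(b))
                while k < m and a[k] == b[k]:
                    k += 1
                C[i, j] = C[j, i] = depth[a[k - 1]]
        return tab.labels, C, tab.is_tip

    # -- editing -------------------------------------------------------

    def keep_tips(self, names: list[str]) -> "PhyloTree":
        """Subtree spanned by the named tips (unifurcations collapsed)."""
        missing = sorted(set(names) - set(self.tip_names))
        if missing:
            raise KeyError(f"tips not in tree: {missing}")
        clone = self._tree.clone(depth=1)
        clone.retain_taxa_with_labels(names)
        return PhyloTree(clone)

    def drop_tips(self, names: list[str]) -> "PhyloTree":
        keep = [t for t in self.tip_names if t not in set(names)]
        return self.keep_tips(keep)

    def attach_fossil_tip(
        self,
        name: str,
        stem_attach_age: float,
        tip_age: float,
        sister: list[str],
    ) -> "PhyloTree":
        return attach_fossil_tip(self, name, stem_attach_age, tip_age, sister)


@dataclass
class NodeTable:
    parent: np.ndarray
    length: np.ndarray
    labels: list[str]
    is_tip: np.ndarray


@dataclass
class PhyloCov:
    """Brownian-motion covariance structure: C[i, j] = MRCA depth of tips i, j."""

    taxa: list[str]
    matrix: np.ndarray = field(repr=False)

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (len(self.taxa), len(self.taxa)):
            raise ValueError("covariance shape does not match taxa list")

    def reorder(self, taxa: list[str]) -> "PhyloCov":
        missing = sorted(set(taxa) - set(self.taxa))
        if missing:
            raise KeyError(f"taxa not in covariance: {missing}")
        idx = [self.taxa.index(t) for t in taxa]
        return PhyloCov(list(taxa), self.matrix[np.ix_(idx, idx)])

    def lambda_transform(self, lam: float) -> "PhyloCov":
        return lambda_transform(self, lam)

    @property
    def min_eigenvalue(self) -> float:
        return float(np.linalg.eigvalsh(self.matrix)[0])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.taxa, columns=self.taxa)

    def write(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t")

    @classmethod
    def read(cls, path) -> "PhyloCov":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(list(df.index), df.to_numpy())


def parse_newick(text: str, unit_lengths: bool = False) -> PhyloTree:
    """Parse a Newick string with mandatory branch lengths."""
    return PhyloTree.from_newick(text, unit_lengths=unit_lengths)


def phylo_covariance(tree: PhyloTree, taxa: list[str] | None = None) -> PhyloCov:
    """Shared-path (BM) covariance among the requested tips, in their order.

    ``C[i, i]`` is the root-to-tip depth of tip i, ``C[i, j]`` the depth of
    the MRCA of tips i and j, computed as
    ``(depth_i + depth_j - patristic(i, j)) / 2``.
    """
    tips = tree.tip_names
    if taxa is None:
        taxa = tips
    missing = sorted(set(taxa) - set(tips))
    if missing:
        raise KeyError(f"taxa not in tree: {missing}")
    depths = tree.depths()
    pdm = tree._tree.phylogenetic_distance_matrix()
    tax_by_label = {t.label: t for t in tree._tree.taxon_namespace}
    n = len(taxa)
    C = np.zeros((n, n))
    for i, a in enumerate(taxa):
        C[i, i] = depths[a]
        for j in range(i + 1, n):
            b = taxa[j]
            dist = pdm.patristic_distance(tax_by_label[a], tax_by_label[b])
            C[i, j] = C[j, i] = 0.5 * (depths[a] + depths[b] - dist)
    # clip floating-point negatives on exact-zero shared paths
    C[(C < 0) & (C > -1e-9)] = 0.0
    return PhyloCov(list(taxa), C)


def lambda_transform(C: PhyloCov, lam: float) -> PhyloCov:
    """Pagel's λ transform: scale off-diagonal covariances, keep the diagonal.

    λ=1 leaves C unchanged (full phylogenetic structure); λ=0 yields the
    star-phylogeny diagonal (no shared history).
    """
    if not 0.0 <= lam <= 1.0:
        raise ValueError(f"lambda must lie in [0, 1], got {lam}")
    M = C.matrix * lam
    np.fill_diagonal(M, np.diag(C.matrix))
    return PhyloCov(list(C.taxa), M)


def attach_fossil_tip(
    tree: PhyloTree,
    name: str,
    stem_attach_age: float,
    tip_age: float,
    sister: list[str] | str,
) -> PhyloTree:
    """Graft a fossil tip onto the stem lineage of a clade.

    The stem edge above the MRCA of ``sister`` is split at ``stem_attach_age``
    (Ma before present) and a new tip is hung from the split with branch
    length ``stem_attach_age - tip_age``.  Extant tips sit at age 0; a
    fossil with ``tip_age > 0`` makes the tree non-ultrametric, which every
    downstream computation tolerates.
    """
    if isinstance(sister, str):
        sister = [sister]
    if tip_age < 0 or stem_attach_age <= tip_age:
        raise ValueError("require stem_attach_age > tip_age >= 0")
    if name in tree.tip_names:
        raise ValueError(f"tip {name!r} already present")
    missing = sorted(set(sister) - set(tree.tip_names))
    if missing:
        raise KeyError(f"sister taxa not in tree: {missing}")

    new = tree.copy()
    dtree = new._tree
    if len(sister) == 1:
        child = next(
            leaf for leaf in dtree.leaf_node_iter() if leaf.taxon.label == sister[0]
        )
    else:
        child = dtree.mrca(taxon_labels=sister)
    parent = child.parent_node
    if parent is None:
        raise ValueError("cannot attach above the root")
    ages = new.node_ages()
    child_age, parent_age = ages[child], ages[parent]
    if not child_age < stem_attach_age < parent_age:
        raise ValueError(
            f"attachment age {stem_attach_age} Ma outside the stem edge span "
            f"({child_age:.6g}, {parent_age:.6g}) Ma"
        )

    parent.remove_child(child)
    mid = parent.new_child(edge_length=parent_age - stem_attach_age)
    mid.add_child(child)
    child.edge.length = stem_attach_age - child_age
    taxon = dtree.taxon_namespace.new_taxon(label=name)
    mid.new_child(taxon=taxon, edge_length=stem_attach_age - tip_age)
    return PhyloTree(dtree)
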