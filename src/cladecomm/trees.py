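"""Dated-tree I/O, node enumeration, node ages, and patristic distances.

Trees are wrapped in :class:`DatedTree`, which assigns stable integer IDs to
internal nodes in a deterministic preorder traversal so that node-level
results are reproducible across runs and comparable across output files.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field

import dendropy
import numpy as np

__all__ = [
    "DatedTree",
    "PhyloDistanceMatrix",
    "read_tree",
    "read_trees",
    "node_ages",
    "cophenetic",
    "subtree_tips",
]

#: relative tolerance (fraction of tree height) for the ultrametricity check
ULTRAMETRIC_RTOL = 1e-6


class TreeError(ValueError):
    """Raised for malformed or unsupported input trees."""


@dataclass(frozen=True)
class PhyloDistanceMatrix:
    """Symmetric patristic (cophenetic) distance matrix over tip labels."""

    labels: tuple[str, ...]
    values: np.ndarray  # (n, n) float, symmetric, zero diagonal

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.labels), len(self.labels)):
            raise ValueError("distance matrix shape does not match labels")
        object.__setattr__(self, "values", v)

    @property
    def index(self) -> dict[str, int]:
        return {s: i for i, s in enumerate(self.labels)}

    def distance(self, a: str, b: str) -> float:
        idx = self.index
        return float(self.values[idx[a], idx[b]])

    def submatrix(self, labels) -> "PhyloDistanceMatrix":
        idx = self.index
        try:
            order = [idx[s] for s in labels]
        except KeyError as exc:
            raise KeyError(f"label not in distance matrix: {exc.args[0]!r}")
        sub = self.values[np.ix_(order, order)]
        return PhyloDistanceMatrix(tuple(labels), sub)


class DatedTree:
    """A rooted tree with branch lengths in Myr and stable internal-node IDs.

    Internal nodes receive consecutive integer IDs (0, 1, ...) in preorder;
    the root is always node 0.  Tips are addressed by their (unique) labels.
    """

    def __init__(self, tree: dendropy.Tree):
        self._tree = tree
        self._validate()
        self._assign_ids()
        self._compute_depths()

    # -- construction helpers -------------------------------------------------

    def _validate(self) -> None:
        seen: set[str] = set()
        for leaf in self._tree.leaf_node_iter():
            if leaf.taxon is None or not leaf.taxon.label:
                raise TreeError("tree contains an unlabeled tip")
            if leaf.taxon.label in seen:
                raise TreeError(f"duplicate tip label: {leaf.taxon.label!r}")
            seen.add(leaf.taxon.label)
        if len(seen) < 2:
            raise TreeError("tree must have at least 2 tips")
        for node in self._tree.preorder_node_iter():
            if node.is_leaf():
                continue
            nch = len(node.child_nodes())
            if nch < 2:
                raise TreeError("internal node with a single child (unifurcation)")
        for edge in self._tree.preorder_edge_iter():
            if edge.head_node is self._tree.seed_node:
                continue
            if edge.length is None:
                raise TreeError("tree has missing branch lengths")
            if edge.length < 0:
                raise TreeError("negative branch length")

    def _assign_ids(self) -> None:
        self._id_to_node: dict[int, dendropy.Node] = {}
        i = 0
        for node in self._tree.preorder_node_iter():
            if node.is_leaf():
                continue
            node.cladecomm_id = i
            self._id_to_node[i] = node
            i += 1
        self._tip_labels = tuple(
            leaf.taxon.label for leaf in self._tree.leaf_node_iter()
        )

    def _compute_depths(self) -> None:
        root = self._tree.seed_node
        root.cladecomm_depth = 0.0
        for node in self._tree.preorder_node_iter():
            if node is root:
                continue
            node.cladecomm_depth = (
                node.parent_node.cladecomm_depth + node.edge.length
            )
        tip_depths = np.array(
            [leaf.cladecomm_depth for leaf in self._tree.leaf_node_iter()]
        )
        self._height = float(tip_depths.max())
        self._is_ultrametric = bool(
            np.all(
                np.abs(tip_depths - self._height)
                <= ULTRAMETRIC_RTOL * max(self._height, 1e-300)
            )
        )
        if not self._is_ultrametric:
            warnings.warn(
                "tree is not ultrametric; tip 'ages' (height - depth) are "
                "nonzero and node ages are heights above the deepest tip",
                stacklevel=3,
            )

    # -- basic accessors ------------------------------------------------------

    @property
    def tip_labels(self) -> tuple[str, ...]:
        return self._tip_labels

    @property
    def n_tips(self) -> int:
        return len(self._tip_labels)

    @property
    def node_ids(self) -> tuple[int, ...]:
        """IDs of all internal nodes, in preorder (root first)."""
        return tuple(sorted(self._id_to_node))

    @property
    def root_id(self) -> int:
        return 0

    @property
    def height(self) -> float:
        """Maximum root-to-tip path length (Myr)."""
        return self._height

    @property
    def is_ultrametric(self) -> bool:
        return self._is_ultrametric

    def node(self, node_id: int) -> dendropy.Node:
        try:
            return self._id_to_node[node_id]
        except KeyError:
            raise KeyError(f"unknown internal node id: {node_id}")

    def node_age(self, node_id: int) -> float:
        return self._height - self.node(node_id).cladecomm_depth

    def subtree_tips(self, node_id: int) -> frozenset[str]:
        """Tip labels of the clade rooted at ``node_id``."""
        node = self.node(node_id)
        return frozenset(
            leaf.taxon.label for leaf in node.leaf_iter()
        )

    def mrca_id(self, labels) -> int:
        """ID of the most recent common ancestor of the given tips."""
        taxa = [self._tree.taxon_namespace.get_taxon(s) for s in labels]
        if any(t is None for t in taxa):
            raise KeyError("unknown tip label in MRCA query")
        node = self._tree.mrca(taxa=taxa)
        while node.is_leaf():
            node = node.parent_node
        return node.cladecomm_id

    # -- transformations ------------------------------------------------------

    def prune(self, labels_to_remove) -> "DatedTree":
        """Return a new tree with the given tips removed (e.g., outgroups)."""
        labels_to_remove = set(labels_to_remove)
        unknown = labels_to_remove - set(self._tip_labels)
        if unknown:
            raise KeyError(f"cannot prune unknown tips: {sorted(unknown)}")
        keep = [s for s in self._tip_labels if s not in labels_to_remove]
        if len(keep) < 2:
            raise TreeError("pruning would leave fewer than 2 tips")
        clone = dendropy.Tree.get(
            data=self.to_newick(), schema="newick",
            preserve_underscores=True, rooting="default-rooted",
        )
        clone.retain_taxa_with_labels(keep)
        return DatedTree(clone)

    # -- serialization --------------------------------------------------------

    def to_newick(self) -> str:
        return self._tree.as_string(
            schema="newick",
            suppress_rooting=True,
            unquoted_underscores=True,
            real_value_format_specifier=".12g",
        ).strip()

    def write(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_newick() + "\n")

    def write_annotated(self, path: str, node_labels: dict[int, str]) -> None:
        """Write Newick with internal-node labels taken from ``node_labels``.

        Unlisted nodes get their bare node ID as the label.
        """
        clone = dendropy.Tree.get(
            data=self.to_newick(), schema="newick",
            preserve_underscores=True, rooting="default-rooted",
        )
        ids = iter(self.node_ids)
        # clone preserves topology, so preorder enumeration matches
        for node in clone.preorder_node_iter():
            if node.is_leaf():
                continue
            nid = next(ids)
            node.label = node_labels.get(nid, str(nid))
        out = clone.as_string(
            schema="newick",
            suppress_rooting=True,
            unquoted_underscores=True,
            real_value_format_specifier=".12g",
        ).strip()
        with open(path, "w") as fh:
            fh.write(out + "\n")


# -- module-level operations (thin wrappers used by the pipeline) -------------


def _tree_from_dendropy(tree: dendropy.Tree) -> DatedTree:
    if tree.is_rooted is False:
        raise TreeError("tree is explicitly unrooted; a rooted tree is required")
    return DatedTree(tree)


def read_tree(path_or_data: str, format: str = "newick") -> DatedTree:
    """Read a single rooted tree from a file path or literal string.

    Strings containing ``(`` are treated as tree data, anything else as a
    path.  ``format`` is ``newick`` or ``nexus``.
    """
    if format not in ("newick", "nexus"):
        raise ValueError(f"unsupported tree format: {format!r}")
    kwargs = dict(schema=format, preserve_underscores=True,
                  rooting="default-rooted")
    try:
        if "(" in path_or_data:
            tree = dendropy.Tree.get(data=path_or_data, **kwargs)
        else:
            tree = dendropy.Tree.get(path=path_or_data, **kwargs)
    except dendropy.utility.error.DataParseError as exc:
        if "duplicate" in str(exc).lower():
            raise TreeError(f"duplicate tip label: {exc}") from exc
        raise TreeError(f"could not parse tree: {exc}") from exc
    return _tree_from_dendropy(tree)


def read_trees(path: str, format: str = "newick") -> list[DatedTree]:
    """Read a multi-tree file (e.g., posterior samples, one Newick per line)."""
    trees = dendropy.TreeList.get(
        path=path, schema=format, preserve_underscores=True,
        rooting="default-rooted",
    )
    if not trees:
        raise TreeError(f"no trees found in {path}")
    return [_tree_from_dendropy(t) for t in trees]


def node_ages(tree: DatedTree) -> dict[int, float]:
    """Age (Myr before present) of every internal node."""
    return {nid: tree.node_age(nid) for nid in tree.node_ids}


def cophenetic(tree: DatedTree, labels=None) -> PhyloDistanceMatrix:
    """Pairwise patristic distances among ``labels`` (default: all tips)."""
    if labels is None:
        labels = tree.tip_labels
    labels = tuple(labels)
    unknown = set(labels) - set(tree.tip_labels)
    if unknown:
        raise KeyError(f"labels not in tree: {sorted(unknown)}")
    pdm = tree._tree.phylogenetic_distance_matrix()
    ns = tree._tree.taxon_namespace
    taxa = [ns.get_taxon(s) for s in labels]
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = pdm.patristic_distance(taxa[i], taxa[j])
    return PhyloDistanceMatrix(labels, d)


def subtree_tips(tree: DatedTree, node_id: int) -> frozenset[str]:
    """Tip labels descending from an internal node."""
    return tree.subtree_tips(node_id)
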