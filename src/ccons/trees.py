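"""Rooted phylogenetic trees over OTU ids.

Trees are consumed, never inferred: newick files are read with dendropy,
polytomies are resolved deterministically into a caterpillar of zero-length
branches (in child order as read) so that leaf-to-leaf path lengths are
unchanged, and patristic distances are computed once into a dense matrix.
"""

from __future__ import annotations

import logging
from typing import Iterable

import dendropy
import numpy as np

from .errors import ParseError, ValidationError

logger = logging.getLogger("ccons.trees")


class PhyloTree:
    """A rooted, branch-length tree whose leaves are fine-level OTU ids.

    Parameters
    ----------
    tree:
        A dendropy tree.  It is validated and normalized in place: duplicate
        leaf labels raise, missing branch lengths become 0 with a logged
        warning, and polytomies are resolved into zero-length caterpillars.
    """

    def __init__(self, tree: dendropy.Tree):
        self._tree = tree
        self._normalize()
        self.leaves: list[str] = [lf.taxon.label for lf in tree.leaf_node_iter()]
        if len(self.leaves) != len(set(self.leaves)):
            seen, dup = set(), None
            for name in self.leaves:
                if name in seen:
                    dup = name
                    break
                seen.add(name)
            raise ValidationError(f"duplicate leaf id in tree: {dup!r}")
        self._leaf_index = {name: i for i, name in enumerate(self.leaves)}
        self._dist: np.ndarray | None = None

    # -- construction -----------------------------------------------------

    @classmethod
    def from_newick_file(cls, path) -> "PhyloTree":
        try:
            tree = dendropy.Tree.get(
                path=str(path), schema="newick", preserve_underscores=True
            )
        except Exception as exc:  # dendropy raises many concrete types
            if "Duplicate taxon labels" in str(exc):
                raise ValidationError(f"duplicate leaf id in {path}: {exc}") from exc
            raise ParseError(f"could not parse newick file {path}: {exc}") from exc
        return cls(tree)

    @classmethod
    def from_newick(cls, newick: str) -> "PhyloTree":
        try:
            tree = dendropy.Tree.get(
                data=newick, schema="newick", preserve_underscores=True
            )
        except Exception as exc:
            if "Duplicate taxon labels" in str(exc):
                raise ValidationError(f"duplicate leaf id: {exc}") from exc
            raise ParseError(f"could not parse newick string: {exc}") from exc
        return cls(tree)

    def to_newick(self) -> str:
        return self._tree.as_string(
            schema="newick", suppress_rooting=True, unquoted_underscores=True
        ).strip()

    # -- normalization -----------------------------------------------------

    def _normalize(self) -> None:
        missing = 0
        for node in self._tree.preorder_node_iter():
            if node is self._tree.seed_node:
                continue
            if node.edge.length is None:
                node.edge.length = 0.0
                missing += 1
            elif node.edge.length < 0:
                raise ValidationError(
                    f"negative branch length {node.edge.length} in tree"
                )
        if missing:
            logger.warning("%d missing branch lengths read as 0", missing)
        # caterpillar resolution, zero-length inner edges, child order as read
        for node in list(self._tree.preorder_node_iter()):
            children = list(node.child_nodes())
            if len(children) <= 2:
                continue
            for child in children:
                node.remove_child(child)
            cur = children[0]
            for child in children[1:-1]:
                joint = dendropy.Node()
                joint.edge.length = 0.0
                joint.add_child(cur)
                joint.add_child(child)
                cur = joint
            node.add_child(cur)
            node.add_child(children[-1])

    # -- basic queries -----------------------------------------------------

    @property
    def n_leaves(self) -> int:
        return len(self.leaves)

    def has_leaf(self, name: str) -> bool:
        return name in self._leaf_index

    def leaf_index(self, name: str) -> int:
        try:
            return self._leaf_index[name]
        except KeyError:
            raise KeyError(f"unknown leaf id: {name!r}") from None

    # -- distances ---------------------------------------------------------

    def distance_matrix(self) -> np.ndarray:
        """Dense patristic distance matrix, rows/cols in ``self.leaves`` order."""
        if self._dist is None:
            self._dist = self._compute_distances()
        return self._dist

    def _compute_distances(self) -> np.ndarray:
        n = self.n_leaves
        depth: dict[int, float] = {id(self._tree.seed_node): 0.0}
        for node in self._tree.preorder_node_iter():
            if node is self._tree.seed_node:
                continue
            depth[id(node)] = depth[id(node.parent_node)] + node.edge.length
        leaf_depth = np.zeros(n)
        below: dict[int, np.ndarray] = {}
        dist = np.zeros((n, n))
        for node in self._tree.postorder_node_iter():
            if node.is_leaf():
                idx = self._leaf_index[node.taxon.label]
                leaf_depth[idx] = depth[id(node)]
                below[id(node)] = np.array([idx], dtype=np.intp)
                continue
            child_sets = [below.pop(id(c)) for c in node.child_nodes()]
            d_node = depth[id(node)]
            for i in range(len(child_sets)):
                for j in range(i + 1, len(child_sets)):
                    a, b = child_sets[i], child_sets[j]
                    block = leaf_depth[a][:, None] + leaf_depth[b][None, :] - 2 * d_node
                    dist[np.ix_(a, b)] = block
                    dist[np.ix_(b, a)] = block.T
            below[id(node)] = np.concatenate(child_sets)
        return dist

    def distance(self, a: str, b: str) -> float:
        """Patristic (path-sum) distance between two leaves; symmetric, ≥ 0."""
        return float(self.distance_matrix()[self.leaf_index(a), self.leaf_index(b)])

    # -- clade cutting -----------------------------------------------------

    def node_ages(self) -> dict[int, float]:
        """Age of each node = max path length to any descendant leaf."""
        ages: dict[int, float] = {}
        for node in self._tree.postorder_node_iter():
            if node.is_leaf():
                ages[id(node)] = 0.0
            else:
                ages[id(node)] = max(
                    ages[id(c)] + c.edge.length for c in node.child_nodes()
                )
        return ages

    @property
    def height(self) -> float:
        """Root age (max root-to-tip path length)."""
        return self.node_ages()[id(self._tree.seed_node)]

    def leaf_groups_at_age(self, age: float) -> dict[str, int]:
        """Group leaves into the maximal clades whose stem crosses ``age``.

        Two leaves share a group iff their MRCA is younger than (or exactly
        at) ``age``.  Groups are numbered in preorder, so numbering is
        deterministic for a given tree.
        """
        ages = self.node_ages()
        groups: dict[str, int] = {}
        next_group = 0
        stack = [(self._tree.seed_node, None)]
        while stack:
            node, grp = stack.pop()
            if grp is None and ages[id(node)] <= age:
                grp = next_group
                next_group += 1
            if node.is_leaf():
                groups[node.taxon.label] = grp
            else:
                for child in reversed(node.child_nodes()):
                    stack.append((child, grp))
        return groups

    def dendropy_tree(self) -> dendropy.Tree:
        """The underlying dendropy tree (shared, not copied)."""
        return self._tree


def tree_distance(tree: PhyloTree, a: str, b: str) -> float:
    """Sum of branch lengths on the unique path between leaves ``a`` and ``b``."""
    return tree.distance(a, b)
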