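"""Phylogenetic tree handling: a thin, branch-id-aware wrapper over dendropy.

Branches are identified by stable string ids derived from the leaf set
below them: a terminal branch is named after its taxon, an internal branch
``mrca(a,b,...)`` after the sorted leaves of its subtree.  These ids are
what selection tests use to designate foreground branches and what fitted
per-branch quantities (omega, dS) are keyed by.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import dendropy
import numpy as np


def _read_dendropy(source: str | Path) -> dendropy.Tree:
    text = None
    if isinstance(source, Path) or (isinstance(source, str) and "(" not in source):
        text = Path(source).read_text()
    else:
        text = str(source)
    try:
        tree = dendropy.Tree.get(data=text, schema="newick")
    except Exception as exc:
        raise ValueError(f"could not parse newick: {exc}") from exc
    tree.suppress_unifurcations()
    tree.is_rooted = True  # treat the seed node as the root for MRCA queries
    return tree


class PhyloTree:
    """A rooted or unrooted tree with branch lengths and branch ids."""

    def __init__(self, tree: dendropy.Tree):
        self.tree = tree
        labels = self.leaf_names
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate leaf names")

    @classmethod
    def from_newick(cls, source: str | Path) -> "PhyloTree":
        return cls(_read_dendropy(source))

    def to_newick(self) -> str:
        return self.tree.as_string(schema="newick", suppress_rooting=True).strip()

    def copy(self) -> "PhyloTree":
        return PhyloTree(self.tree.clone(depth=1))

    @property
    def leaf_names(self) -> list[str]:
        return [lf.taxon.label for lf in self.tree.leaf_node_iter()]

    # ------------------------------------------------------------- branches

    @staticmethod
    def _node_branch_id(node: dendropy.Node) -> str:
        if node.is_leaf():
            return node.taxon.label
        leaves = sorted(lf.taxon.label for lf in node.leaf_iter())
        return "mrca(" + ",".join(leaves) + ")"

    def _branch_nodes(self) -> list[dendropy.Node]:
        root = self.tree.seed_node
        return [nd for nd in self.tree.postorder_node_iter() if nd is not root]

    def branch_ids(self) -> list[str]:
        return [self._node_branch_id(nd) for nd in self._branch_nodes()]

    def resolve_branch(self, foreground: str | Iterable[str]) -> str:
        """Resolve a foreground designation to a branch id.

        Accepts a leaf name, an existing branch id, or an iterable of leaf
        names (meaning the branch above their most recent common ancestor).
        """
        known = set(self.branch_ids())
        if isinstance(foreground, str):
            if foreground in known:
                return foreground
            raise KeyError(f"no branch {foreground!r}; known: {sorted(known)}")
        leaves = list(foreground)
        mrca = self.tree.mrca(taxon_labels=leaves)
        if mrca is None or mrca is self.tree.seed_node:
            raise KeyError(f"MRCA of {leaves} has no parent branch on this tree")
        return self._node_branch_id(mrca)

    @property
    def branch_lengths(self) -> dict[str, float]:
        return {
            self._node_branch_id(nd): (nd.edge.length if nd.edge.length is not None else 0.0)
            for nd in self._branch_nodes()
        }

    def set_branch_lengths(self, lengths: dict[str, float]) -> None:
        for nd in self._branch_nodes():
            bid = self._node_branch_id(nd)
            if bid in lengths:
                if lengths[bid] < 0:
                    raise ValueError(f"negative branch length for {bid}")
                nd.edge.length = float(lengths[bid])

    def with_branch_lengths(self, lengths: dict[str, float]) -> "PhyloTree":
        out = self.copy()
        out.set_branch_lengths(lengths)
        return out

    # ------------------------------------------------- structural queries

    def bipartitions(self) -> set[frozenset[str]]:
        """Non-trivial leaf bipartitions (as the smaller/canonical side sets)."""
        all_leaves = frozenset(self.leaf_names)
        out = set()
        for nd in self._branch_nodes():
            if nd.is_leaf():
                continue
            below = frozenset(lf.taxon.label for lf in nd.leaf_iter())
            if 1 < len(below) < len(all_leaves) - 1 or (
                len(below) == len(all_leaves) - 1 and len(all_leaves) > 3
            ):
                # store the canonical (lexicographically smaller) side
                other = all_leaves - below
                out.add(min(below, other, key=lambda s: (len(s), tuple(sorted(s)))))
        return out

    def patristic_matrix(self) -> tuple[list[str], np.ndarray]:
        """All-pairs leaf path-length matrix using current branch lengths."""
        pdm = self.tree.phylogenetic_distance_matrix()
        names = sorted(self.leaf_names)
        taxa = {t.label: t for t in self.tree.taxon_namespace}
        n = len(names)
        mat = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                d = pdm.patristic_distance(taxa[names[i]], taxa[names[j]])
                mat[i, j] = mat[j, i] = d
        return names, mat

    # ----------------------------------------------- engine-facing index

    def postorder_index(self) -> "TreeIndex":
        nodes = list(self.tree.postorder_node_iter())
        pos = {id(nd): k for k, nd in enumerate(nodes)}
        parent = np.full(len(nodes), -1, dtype=int)
        length = np.zeros(len(nodes))
        bids: list[str | None] = [None] * len(nodes)
        leaf_rows: dict[str, int] = {}
        for k, nd in enumerate(nodes):
            if nd.parent_node is not None:
                parent[k] = pos[id(nd.parent_node)]
                length[k] = nd.edge.length if nd.edge.length is not None else 0.0
                bids[k] = self._node_branch_id(nd)
            if nd.is_leaf():
                leaf_rows[nd.taxon.label] = k
        return TreeIndex(
            n_nodes=len(nodes),
            parent=parent,
            branch_ids=bids,
            lengths=length,
            leaf_index=leaf_rows,
        )


@dataclass
class TreeIndex:
    """Array view of a tree for the likelihood engine.

    Nodes are in postorder; the root is last and has parent -1 and no
    branch.  ``branch_ids[k]`` names the edge above node k.
    """

    n_nodes: int
    parent: np.ndarray
    branch_ids: list[str | None]
    lengths: np.ndarray
    leaf_index: dict[str, int]

    @property
    def root(self) -> int:
        return self.n_nodes - 1

    @property
    def edge_nodes(self) -> list[int]:
        return [k for k in range(self.n_nodes) if self.parent[k] >= 0]

    def children(self) -> list[list[int]]:
        out: list[list[int]] = [[] for _ in range(self.n_nodes)]
        for k in range(self.n_nodes):
            if self.parent[k] >= 0:
                out[self.parent[k]].append(k)
        return out


def topology_equal(
    t1: PhyloTree, t2: PhyloTree, taxon_map: dict[str, str] | None = None
) -> bool:
    """True iff two trees induce the same set of leaf bipartitions.

    ``taxon_map`` renames t1's leaves (e.g. sequence ids to species names)
    before comparing.  Branch lengths and rooting are ignored.
    """
    names1 = set(t1.leaf_names)
    if taxon_map:
        names1 = {taxon_map.get(n, n) for n in names1}
    if names1 != set(t2.leaf_names):
        raise ValueError("leaf sets differ after mapping")

    def mapped_biparts(t: PhyloTree, mapping: dict[str, str] | None) -> set:
        bips = t.bipartitions()
        if not mapping:
            return bips
        return {frozenset(mapping.get(n, n) for n in side) for side in bips}

    # recanonicalize t1's sides against the shared leaf universe
    all_leaves = frozenset(names1)

    def canon(bips: set) -> set:
        out = set()
        for side in bips:
            other = all_leaves - side
            out.add(min(side, other, key=lambda s: (len(s), tuple(sorted(s)))))
        return out

    return canon(mapped_biparts(t1, taxon_map)) == canon(t2.bipartitions())
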