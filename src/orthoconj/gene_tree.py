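"""Gene-tree container and Newick/NHX input-output.

Gene trees are rooted, strictly binary, and carry a species id on every
leaf. Parsing and serialisation are delegated to dendropy; NHX tags
(``S=`` species, ``D=`` duplication flag, ``ND=`` stable node id) travel in
node comment strings. :class:`ArrayTree` is the flat indexed view used by
the likelihood engine.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field

import dendropy
import numpy as np

__all__ = ["GeneTree", "ArrayTree", "read_gene_tree", "write_gene_tree"]

SPECIATION = "speciation"
DUPLICATION = "duplication"

_NHX_RE = re.compile(r"&&NHX:?(.*)")


def _parse_nhx(comments) -> dict[str, str]:
    for c in comments:
        m = _NHX_RE.match(c)
        if m:
            out = {}
            for item in m.group(1).split(":"):
                if "=" in item:
                    k, v = item.split("=", 1)
                    out[k] = v
            return out
    return {}


def _format_nhx(tags: dict[str, str]) -> str:
    return "&&NHX:" + ":".join(f"{k}={v}" for k, v in tags.items())


class GeneTree:
    """A rooted binary gene tree with per-leaf species annotations.

    Wraps a :class:`dendropy.Tree`; nodes gain the dynamic attributes
    ``species`` and ``gene_id`` (leaves), ``event`` and ``ref_event``
    (internal nodes), ``node_id`` (all nodes) and optionally ``age``.
    Branch lengths are expected codon substitutions on the branch above
    each node.
    """

    def __init__(self, tree: dendropy.Tree, tree_id: str = "tree"):
        self.tree = tree
        self.tree_id = tree_id
        self._validate()
        self._assign_node_ids()

    def _validate(self) -> None:
        root = self.tree.seed_node
        if root is None or not root.child_nodes():
            raise ValueError("empty tree")
        for node in self.tree.preorder_node_iter():
            kids = node.child_nodes()
            if kids and len(kids) != 2:
                what = "polytomy" if len(kids) > 2 else "unifurcation"
                raise ValueError(f"tree must be strictly binary; found a {what}")
            if not kids:
                sp = getattr(node, "species", None)
                if not sp:
                    label = node.taxon.label if node.taxon else "<unnamed>"
                    raise ValueError(f"leaf {label!r} lacks a species id")

    def _assign_node_ids(self) -> None:
        taken = {
            getattr(n, "node_id", None)
            for n in self.tree.preorder_node_iter()
            if not n.is_leaf()
        }
        k = 0
        for node in self.tree.preorder_node_iter():
            if node.is_leaf():
                node.node_id = node.gene_id
            elif getattr(node, "node_id", None) is None:
                while f"n{k}" in taken:
                    k += 1
                node.node_id = f"n{k}"
                taken.add(node.node_id)

    # -- traversal helpers -------------------------------------------------
    @property
    def root(self):
        return self.tree.seed_node

    def leaves(self):
        return list(self.tree.leaf_node_iter())

    def internal_nodes(self):
        """Internal nodes in preorder (root first)."""
        return [n for n in self.tree.preorder_node_iter() if not n.is_leaf()]

    def n_leaves(self) -> int:
        return sum(1 for _ in self.tree.leaf_node_iter())

    def node_by_id(self, node_id: str):
        for node in self.tree.preorder_node_iter():
            if node.node_id == node_id:
                return node
        raise KeyError(node_id)

    def leaf_species(self) -> dict[str, str]:
        return {leaf.gene_id: leaf.species for leaf in self.leaves()}

    # -- serialisation -----------------------------------------------------
    def to_newick(self, include_events: bool = True) -> str:
        for node in self.tree.preorder_node_iter():
            tags: dict[str, str] = {}
            if node.is_leaf():
                tags["S"] = node.species
            else:
                tags["ND"] = node.node_id
                event = getattr(node, "event", None)
                ref = getattr(node, "ref_event", None)
                if include_events and (event or ref):
                    # D carries the computed label when present, else the
                    # reference; RD keeps the reference alongside a computed D
                    tags["D"] = "Y" if (event or ref) == DUPLICATION else "N"
                    if event and ref:
                        tags["RD"] = "Y" if ref == DUPLICATION else "N"
            age = getattr(node, "age", None)
            if age is not None:
                tags["AGE"] = f"{age:.6g}"
            omega = getattr(node, "omega", None)
            if omega is not None:  # branch above this node
                tags["W"] = f"{omega:.6g}"
            node.comments = [_format_nhx(tags)]
        return self.tree.as_string(
            schema="newick",
            suppress_rooting=True,
            suppress_item_comments=False,
            unquoted_underscores=True,
        )

    def to_array_tree(self) -> "ArrayTree":
        return ArrayTree.from_gene_tree(self)


def read_gene_tree(
    source: str,
    species_extraction=None,
    tree_id: str = "tree",
) -> GeneTree:
    """Read a Newick/NHX gene tree from a path or a Newick string.

    Species ids are taken from NHX ``S=`` tags when present; otherwise
    ``species_extraction`` is applied to each leaf label — either a regex
    with one capture group or a callable ``label -> species``. Reference
    event labels are read from NHX ``D=`` tags (Y/N).
    """
    data = source
    if "(" not in source:  # a path, not newick text
        with open(source) as fh:
            data = fh.read()
    tree = dendropy.Tree.get(
        data=data,
        schema="newick",
        suppress_internal_node_taxa=True,
        extract_comment_metadata=False,
        preserve_underscores=True,
        rooting="force-rooted",
    )
    extractor = None
    if isinstance(species_extraction, str):
        pattern = re.compile(species_extraction)

        def extractor(label: str):
            m = pattern.search(label)
            return m.group(1) if m else None

    elif callable(species_extraction):
        extractor = species_extraction

    for node in tree.preorder_node_iter():
        tags = _parse_nhx(node.comments)
        if node.is_leaf():
            label = node.taxon.label if node.taxon else ""
            node.gene_id = label
            species = tags.get("S")
            if species is None and extractor is not None:
                species = extractor(label)
            node.species = species
        else:
            node.node_id = tags.get("ND")
            # a file's own labels serve as the reference labeling; RD (kept
            # alongside computed labels) takes precedence over D
            d = tags.get("RD", tags.get("D"))
            node.ref_event = {None: None, "Y": DUPLICATION, "N": SPECIATION}.get(d)
            node.event = None
        if "AGE" in tags:
            node.age = float(tags["AGE"])
        if "W" in tags:
            node.omega = float(tags["W"])
    return GeneTree(tree, tree_id=tree_id)


def write_gene_tree(gt: GeneTree, path: str) -> None:
    with open(path, "w") as fh:
        fh.write(gt.to_newick())


@dataclass
class ArrayTree:
    """Flat indexed tree for vectorized likelihood computation.

    Nodes are indexed 0..n-1 with leaves first (in leaf-iteration order) and
    internal nodes in postorder after them; the root is the last index.
    ``edge_length[i]`` is the branch above node i (0 for the root).
    """

    n_leaves: int
    parent: np.ndarray
    children: dict[int, tuple[int, int]]
    postorder: list[int]
    edge_length: np.ndarray
    leaf_labels: list[str]
    node_ids: list[str]
    index_of: dict[str, int] = field(repr=False)

    @classmethod
    def from_gene_tree(cls, gt: GeneTree) -> "ArrayTree":
        leaves = gt.leaves()
        internals_post = [n for n in gt.tree.postorder_node_iter() if not n.is_leaf()]
        nodes = leaves + internals_post
        idx = {id(n): i for i, n in enumerate(nodes)}
        n = len(nodes)
        parent = np.full(n, -1, dtype=np.intp)
        children: dict[int, tuple[int, int]] = {}
        edge_length = np.zeros(n)
        for node in nodes:
            i = idx[id(node)]
            edge_length[i] = node.edge.length if node.edge.length is not None else 0.0
            kids = node.child_nodes()
            if kids:
                children[i] = (idx[id(kids[0])], idx[id(kids[1])])
                for c in kids:
                    parent[idx[id(c)]] = i
        postorder = [idx[id(n)] for n in gt.tree.postorder_node_iter()]
        return cls(
            n_leaves=len(leaves),
            parent=parent,
            children=children,
            postorder=postorder,
            edge_length=edge_length,
            leaf_labels=[lf.gene_id for lf in leaves],
            node_ids=[nd.node_id for nd in nodes],
            index_of={nd.node_id: idx[id(nd)] for nd in nodes},
        )

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    @property
    def root(self) -> int:
        return self.postorder[-1]

    def edges(self) -> list[int]:
        """Child-end node indices of all branches (everything but the root)."""
        return [i for i in range(self.n_nodes) if i != self.root]
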