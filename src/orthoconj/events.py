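"""Species-overlap event labeling and paralog classification.

A node is labeled a gene duplication if and only if the species sets of its
two daughter clades intersect — i.e. at least one species is represented on
both sides. Nodes whose daughter clades carry disjoint species sets are
speciations. Duplication nodes are further split into within-species
paralog nodes (all descendant leaves from one species) and between-species
paralog nodes.
"""

from __future__ import annotations

import math

from .gene_tree import DUPLICATION, SPECIATION, GeneTree

__all__ = [
    "label_events",
    "classify_paralog_nodes",
    "label_congruence",
    "clade_species_sets",
]

WITHIN_SPECIES = "within_species"
BETWEEN_SPECIES = "between_species"


def clade_species_sets(gt: GeneTree) -> dict[str, frozenset[str]]:
    """Species set of the clade below each node, keyed by node id."""
    sets: dict[str, frozenset[str]] = {}
    for node in gt.tree.postorder_node_iter():
        if node.is_leaf():
            sets[node.node_id] = frozenset([node.species])
        else:
            left, right = node.child_nodes()
            sets[node.node_id] = sets[left.node_id] | sets[right.node_id]
    return sets


def label_events(gt: GeneTree) -> GeneTree:
    """Assign speciation/duplication labels to every internal node in place."""
    sets = clade_species_sets(gt)
    for node in gt.internal_nodes():
        left, right = node.child_nodes()
        overlap = sets[left.node_id] & sets[right.node_id]
        node.event = DUPLICATION if overlap else SPECIATION
    return gt


def classify_paralog_nodes(gt: GeneTree) -> dict[str, str]:
    """Within/between-species class for each duplication node.

    Requires a labeled tree; speciation nodes are skipped. Use
    :func:`paralog_class_of` to query a single node (raises on a
    speciation node).
    """
    sets = clade_species_sets(gt)
    out = {}
    for node in gt.internal_nodes():
        if node.event is None:
            raise ValueError("tree is not labeled; run label_events first")
        if node.event == DUPLICATION:
            cls = WITHIN_SPECIES if len(sets[node.node_id]) == 1 else BETWEEN_SPECIES
            node.paralog_class = cls
            out[node.node_id] = cls
    return out


def paralog_class_of(gt: GeneTree, node_id: str) -> str:
    """Paralog class of one duplication node; ValueError for a speciation node."""
    node = gt.node_by_id(node_id)
    if node.event != DUPLICATION:
        raise ValueError(f"node {node_id} is not a duplication node")
    species = {leaf.species for leaf in node.leaf_iter()}
    return WITHIN_SPECIES if len(species) == 1 else BETWEEN_SPECIES


def compare_labelings(labels, reference_labels) -> float:
    """Fraction of nodes on which two labelings agree.

    Both mappings must cover exactly the same node set.
    """
    if set(labels) != set(reference_labels):
        raise ValueError("labelings cover different node sets")
    if not labels:
        raise ValueError("empty labelings")
    return sum(labels[k] == reference_labels[k] for k in labels) / len(labels)


def label_congruence(gt: GeneTree) -> float:
    """Fraction of internal nodes whose species-overlap label matches the
    reference label carried by the tree (NHX ``D=`` tags or simulator truth).

    Returns NaN when no reference labels are present.
    """
    agree = total = 0
    for node in gt.internal_nodes():
        ref = getattr(node, "ref_event", None)
        if ref is None:
            continue
        if node.event is None:
            raise ValueError("tree is not labeled; run label_events first")
        total += 1
        agree += node.event == ref
    if total == 0:
        return math.nan
    return agree / total
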