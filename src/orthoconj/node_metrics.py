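"""Per-node divergence records (Δω, Δω_p) and the tree/node filters.

Each labeled internal node contributes one record holding the ω estimates
of its parent branch and its two daughter branches. Δω is the absolute
difference between the daughters' ω; Δω_p is the signed child-minus-parent
difference, summarized per node as (min, max) over the two daughters, so
Δω = Δω_p_max − Δω_p_min identically.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .gene_tree import DUPLICATION, GeneTree

__all__ = [
    "FilterThresholds",
    "build_node_records",
    "apply_node_filters",
    "apply_tree_filters",
    "NODE_RECORD_COLUMNS",
]

NODE_RECORD_COLUMNS = [
    "tree_id",
    "node_id",
    "event",
    "paralog_class",
    "omega_parent",
    "omega_left",
    "omega_right",
    "ds_left",
    "ds_right",
    "delta_omega",
    "dwp_min",
    "dwp_max",
    "age",
]


@dataclass(frozen=True)
class FilterThresholds:
    """Node- and tree-level filter settings.

    dS saturation cap (daughter dS > ds_max drops the node), minimum-signal
    floor (daughter dS < ds_min drops it), ω outlier cap, and the tree tip
    cap. Defaults follow the standard branch-model practice of discarding
    saturated (dS > 2), near-zero (dS < 0.01) and runaway (ω > 10) branch
    estimates, and capping trees at 170 tips.
    """

    ds_max: float = 2.0
    ds_min: float = 0.01
    omega_max: float = 10.0
    max_tips: int = 170

    def __post_init__(self) -> None:
        if not (0 < self.ds_min < self.ds_max):
            raise ValueError("require 0 < ds_min < ds_max")
        if self.omega_max <= 0 or self.max_tips <= 0:
            raise ValueError("omega_max and max_tips must be positive")


def build_node_records(gt: GeneTree, branch_params: pd.DataFrame) -> pd.DataFrame:
    """One record per labeled internal node of one tree.

    ``branch_params`` is the per-branch table (branch_id keyed by child-end
    node id) from the estimation step. The root lacks a parent branch: its
    Δω is defined but its Δω_p values are NaN.
    """
    bp = branch_params.set_index("branch_id")
    rows = []
    for node in gt.internal_nodes():
        if node.event is None:
            raise ValueError("tree is not labeled; run label_events first")
        left, right = node.child_nodes()
        try:
            wl = float(bp.at[left.node_id, "omega"])
            wr = float(bp.at[right.node_id, "omega"])
            dsl = float(bp.at[left.node_id, "dS"])
            dsr = float(bp.at[right.node_id, "dS"])
        except KeyError as exc:
            raise ValueError(f"missing branch estimate for daughter of {node.node_id}") from exc
        if node.parent_node is None:
            wp = np.nan
        else:
            try:
                wp = float(bp.at[node.node_id, "omega"])
            except KeyError as exc:
                raise ValueError(f"missing branch estimate for node {node.node_id}") from exc
        diffs = (wl - wp, wr - wp)
        rows.append(
            {
                "tree_id": gt.tree_id,
                "node_id": node.node_id,
                "event": node.event,
                "paralog_class": getattr(node, "paralog_class", None)
                if node.event == DUPLICATION
                else None,
                "omega_parent": wp,
                "omega_left": wl,
                "omega_right": wr,
                "ds_left": dsl,
                "ds_right": dsr,
                "delta_omega": abs(wl - wr),
                "dwp_min": min(diffs),
                "dwp_max": max(diffs),
                "age": getattr(node, "age", np.nan),
            }
        )
    return pd.DataFrame(rows, columns=NODE_RECORD_COLUMNS)


def apply_node_filters(
    records: pd.DataFrame, thresholds: FilterThresholds | None = None
) -> tuple[pd.DataFrame, dict]:
    """Sequentially drop saturated, low-signal and ω-outlier nodes.

    Rules (applied in order, each to the survivors of the previous one):

    1. dS of either daughter > ds_max (synonymous saturation);
    2. dS of either daughter < ds_min (too little signal);
    3. ω of either daughter > omega_max (outlier estimates).

    Returns the retained records and an audit of counts removed per rule.
    NaN daughter values trip none of the rules by themselves but NaN ω
    estimates are removed by a preliminary completeness rule.
    """
    th = thresholds or FilterThresholds()
    df = records
    n_input = len(df)
    complete = df.dropna(subset=["omega_left", "omega_right", "ds_left", "ds_right"])
    n_incomplete = n_input - len(complete)
    df = complete

    sat = (df["ds_left"] > th.ds_max) | (df["ds_right"] > th.ds_max)
    df1 = df[~sat]
    low = (df1["ds_left"] < th.ds_min) | (df1["ds_right"] < th.ds_min)
    df2 = df1[~low]
    out = (df2["omega_left"] > th.omega_max) | (df2["omega_right"] > th.omega_max)
    df3 = df2[~out]
    audit = {
        "n_input": n_input,
        "removed_incomplete": int(n_incomplete),
        "removed_ds_saturation": int(sat.sum()),
        "removed_ds_minimum": int(low.sum()),
        "removed_omega_outlier": int(out.sum()),
        "n_retained": len(df3),
        "thresholds": {
            "ds_max": th.ds_max,
            "ds_min": th.ds_min,
            "omega_max": th.omega_max,
        },
    }
    return df3.reset_index(drop=True), audit


def apply_tree_filters(
    trees: list[GeneTree], thresholds: FilterThresholds | None = None
) -> tuple[list[GeneTree], dict]:
    """Keep labeled trees with <= max_tips leaves and both event types.

    Trees larger than the tip cap are dropped first; the survivors must
    contain at least one duplication and at least one speciation node.
    """
    th = thresholds or FilterThresholds()
    kept_size = []
    n_too_big = 0
    for gt in trees:
        if gt.n_leaves() > th.max_tips:
            n_too_big += 1
        else:
            kept_size.append(gt)
    kept = []
    n_missing_events = 0
    for gt in kept_size:
        events = {node.event for node in gt.internal_nodes()}
        if None in events:
            raise ValueError(f"tree {gt.tree_id} is not labeled")
        if len(events) == 2:
            kept.append(gt)
        else:
            n_missing_events += 1
    audit = {
        "n_input": len(trees),
        "removed_too_many_tips": n_too_big,
        "removed_missing_event_type": n_missing_events,
        "n_retained": len(kept),
        "max_tips": th.max_tips,
    }
    return kept, audit
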