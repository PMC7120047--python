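"""Node records (Δω, Δω_p) and the sequential filters."""

import numpy as np
import pandas as pd
import pytest

from orthoconj.events import classify_paralog_nodes, label_events
from orthoconj.gene_tree import read_gene_tree
from orthoconj.node_metrics import (
    FilterThresholds,
    apply_node_filters,
    apply_tree_filters,
    build_node_records,
)


def _records(**overrides):
    base = {
        "tree_id": "t", "node_id": "n", "event": "speciation",
        "paralog_class": None, "omega_parent": 0.2, "omega_left": 0.3,
        "omega_right": 0.4, "ds_left": 0.5, "ds_right": 0.5,
        "delta_omega": 0.1, "dwp_min": 0.1, "dwp_max": 0.2, "age": np.nan,
    }
    base.update(overrides)
    return base


@pytest.fixture()
def toy_tree_records(uniform_freqs):
    gt = read_gene_tree(
        "((x1:0.1[&&NHX:S=X],x2:0.1[&&NHX:S=X]):0.2,y:0.3[&&NHX:S=Y]);"
    )
    label_events(gt)
    classify_paralog_nodes(gt)
    branch = pd.DataFrame(
        {
            "branch_id": ["x1", "x2", "n1", "y"],
            "t": [0.1, 0.1, 0.2, 0.3],
            "omega": [0.5, 0.3, 0.2, 0.9],
            "dN": [0.1, 0.1, 0.1, 0.1],
            "dS": [0.2, 0.3, 0.4, 0.5],
            "flag": [""] * 4,
        }
    )
    return build_node_records(gt, branch)


def test_record_arithmetic(toy_tree_records):
    rec = toy_tree_records.set_index("node_id")
    # duplication node n1 (x1, x2): parent branch omega 0.2
    n1 = rec.loc["n1"]
    assert n1["delta_omega"] == pytest.approx(abs(0.5 - 0.3))
    assert n1["dwp_min"] == pytest.approx(0.3 - 0.2)
    assert n1["dwp_max"] == pytest.approx(0.5 - 0.2)
    assert n1["event"] == "duplication" and n1["paralog_class"] == "within_species"
    # root: delta defined, parent differences NA
    root = rec.loc["n0"]
    assert root["delta_omega"] == pytest.approx(abs(0.2 - 0.9))
    assert np.isnan(root["dwp_min"]) and np.isnan(root["omega_parent"])


def test_delta_identity_holds(toy_tree_records):
    sub = toy_tree_records.dropna(subset=["dwp_min"])
    assert np.allclose(sub["delta_omega"], sub["dwp_max"] - sub["dwp_min"])


def test_missing_branch_estimate_raises():
    gt = read_gene_tree("((x1[&&NHX:S=X],x2[&&NHX:S=X]),y[&&NHX:S=Y]);")
    label_events(gt)
    branch = pd.DataFrame(
        {"branch_id": ["x1"], "t": [0.1], "omega": [0.5], "dN": [0.1],
         "dS": [0.2], "flag": [""]}
    )
    with pytest.raises(ValueError, match="missing branch estimate"):
        build_node_records(gt, branch)


def test_node_filters_remove_designed_records():
    records = pd.DataFrame(
        [
            _records(node_id="keep"),
            _records(node_id="sat", ds_left=2.5),
            _records(node_id="low", ds_left=0.005, ds_right=0.5),
            _records(node_id="outlier", omega_right=12.0),
            _records(node_id="keep2", ds_left=1.9, omega_right=9.9),
        ]
    )
    kept, audit = apply_node_filters(records)
    assert sorted(kept["node_id"]) == ["keep", "keep2"]
    assert audit["removed_ds_saturation"] == 1
    assert audit["removed_ds_minimum"] == 1
    assert audit["removed_omega_outlier"] == 1
    total = (
        audit["removed_incomplete"] + audit["removed_ds_saturation"]
        + audit["removed_ds_minimum"] + audit["removed_omega_outlier"]
        + audit["n_retained"]
    )
    assert total == audit["n_input"] == len(records)


def test_filters_applied_sequentially():
    # a record violating both the saturation and outlier rules counts once,
    # under the first rule in order
    records = pd.DataFrame([_records(node_id="both", ds_left=3.0, omega_left=15.0)])
    _, audit = apply_node_filters(records)
    assert audit["removed_ds_saturation"] == 1
    assert audit["removed_omega_outlier"] == 0


def test_filters_monotone_in_thresholds():
    rng = np.random.default_rng(0)
    records = pd.DataFrame(
        [
            _records(node_id=f"r{i}", ds_left=rng.uniform(0, 3),
                     ds_right=rng.uniform(0, 3), omega_left=rng.uniform(0, 15),
                     omega_right=rng.uniform(0, 15))
            for i in range(200)
        ]
    )
    loose, _ = apply_node_filters(records, FilterThresholds(ds_max=2.5, ds_min=0.005, omega_max=12))
    default, _ = apply_node_filters(records)
    tight, _ = apply_node_filters(records, FilterThresholds(ds_max=1.5, ds_min=0.05, omega_max=5))
    assert len(tight) <= len(default) <= len(loose)


def test_threshold_validation():
    with pytest.raises(ValueError):
        FilterThresholds(ds_min=3.0, ds_max=2.0)


def test_tree_filters():
    one_species = read_gene_tree("((x1[&&NHX:S=X],x2[&&NHX:S=X]),x3[&&NHX:S=X]);")
    mixed = read_gene_tree("((x1[&&NHX:S=X],x2[&&NHX:S=X]),y[&&NHX:S=Y]);")
    # a 6-tip caterpillar exceeding a max_tips of 5
    big = "(" * 5 + "s0_g[&&NHX:S=s0],s1_g[&&NHX:S=s1]),s2_g[&&NHX:S=s2])," \
        "s3_g[&&NHX:S=s3]),s4_g[&&NHX:S=s4]),s5_g[&&NHX:S=s5]);"
    trees = [read_gene_tree(t) if isinstance(t, str) else t
             for t in [big, one_species.to_newick(), mixed.to_newick()]]
    for gt in trees:
        label_events(gt)
    kept, audit = apply_tree_filters(trees, FilterThresholds(max_tips=5))
    assert len(kept) == 1
    assert audit["removed_too_many_tips"] == 1
    assert audit["removed_missing_event_type"] == 1
    assert audit["n_retained"] + audit["removed_too_many_tips"] + \
        audit["removed_missing_event_type"] == audit["n_input"]
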