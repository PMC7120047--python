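#!/usr/bin/env python
"""Assemble per-node Δω / Δω_p records and apply the quality filters.

Joins the labeled trees from 02 with the branch estimates from 03, builds
one record per internal node, then applies the sequential node filters
(synonymous saturation dS > 2, minimum signal dS < 0.01, ω > 10 outliers)
and writes the records plus the audit of what each rule removed.
"""

import json
import sys
from pathlib import Path

import pandas as pd

from orthoconj.events import classify_paralog_nodes, label_events
from orthoconj.gene_tree import read_gene_tree
from orthoconj.node_metrics import apply_node_filters, build_node_records

OUT = Path("results/analysis")
DATASET = Path("scratch/analysis_datasets") / "neofunctionalization"


def main() -> int:
    branch_path = OUT / "branch_params_neofunctionalization.tsv"
    if not branch_path.exists():
        print("run 03_estimate_omega.py first", file=sys.stderr)
        return 1
    branches = pd.read_csv(branch_path, sep="\t").fillna({"flag": ""})
    frames = []
    for tf in sorted((DATASET / "labeled_trees").glob("*.nhx")):
        gt = read_gene_tree(str(tf), tree_id=tf.stem)
        label_events(gt)
        classify_paralog_nodes(gt)
        frames.append(build_node_records(gt, branches[branches["tree_id"] == tf.stem]))
    records = pd.concat(frames, ignore_index=True)
    filtered, audit = apply_node_filters(records)
    records.to_csv(OUT / "node_records.tsv", sep="\t", index=False, float_format="%.6g")
    filtered.to_csv(OUT / "node_records_filtered.tsv", sep="\t", index=False,
                    float_format="%.6g")
    (OUT / "filter_audit.json").write_text(json.dumps(audit, indent=2) + "\n")
    print(f"{audit['n_input']} node records; removed "
          f"{audit['removed_ds_saturation']} saturated, "
          f"{audit['removed_ds_minimum']} low-signal, "
          f"{audit['removed_omega_outlier']} omega outliers; "
          f"{audit['n_retained']} retained")
    print(f"records and audit written under {OUT}/")
    return 0


if __name__ == "__main__":
    sys.exit(main())
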