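"""Orchestration: simulate -> label -> estimate -> metrics -> stats.

Every stage is a plain function over in-memory objects; :func:`run_pipeline`
chains them, logs stage timings to stderr, and (when ``out_dir`` is set)
writes each stage's artifacts: labeled NHX trees, per-branch TSV, node
records TSV, filter audits JSON, the statistical report JSON and the
permutation null draws TSV. Reruns with the same config and seed are
bit-identical.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .codon_model import CodonFrequencies, expected_substitution_partition
from .config import PipelineConfig
from .events import classify_paralog_nodes, label_congruence, label_events
from .gene_tree import GeneTree, read_gene_tree, write_gene_tree
from .alignment import CodonAlignment
from .node_metrics import apply_node_filters, apply_tree_filters, build_node_records
from .omega_estimation import (
    BRANCH_COLUMNS,
    counting_estimator,
    fit_free_ratios,
    fit_null_model,
)
from .simulate import SimulatedFamily, generate_dataset, load_species_tree
from .stats import compare_orthologs_paralogs

logger = logging.getLogger("orthoconj")

__all__ = ["run_pipeline", "PipelineResult", "estimate_branches"]


@dataclass
class PipelineResult:
    config: PipelineConfig
    records: pd.DataFrame  # all node records, pre node-filter
    filtered_records: pd.DataFrame
    report: dict
    tree_audit: dict
    node_audit: dict
    congruence: dict = field(default_factory=dict)
    branch_tables: dict = field(default_factory=dict)

    def report_json(self) -> str:
        clean = {k: v for k, v in self.report.items() if not k.startswith("_")}
        payload = {
            "report": clean,
            "tree_filter_audit": self.tree_audit,
            "node_filter_audit": self.node_audit,
            "congruence": self.congruence,
        }
        return json.dumps(payload, indent=2, sort_keys=True, default=float)


def _truth_branch_table(family: SimulatedFamily, kappa: float) -> pd.DataFrame:
    """Per-branch table taken directly from simulator truth (no estimation)."""
    gt = family.tree
    code = family.alignment.code if family.alignment is not None else None
    freqs = CodonFrequencies.uniform(code) if code else CodonFrequencies.uniform()
    atree = gt.to_array_tree()
    rows = []
    for e in atree.edges():
        bid = atree.node_ids[e]
        w = family.truth.omegas[bid]
        t = float(atree.edge_length[e])
        part = expected_substitution_partition(kappa, w, freqs, t)
        rows.append(
            {"branch_id": bid, "t": t, "omega": w, "dN": part.dN, "dS": part.dS, "flag": ""}
        )
    return pd.DataFrame(rows, columns=BRANCH_COLUMNS)


def estimate_branches(
    tree: GeneTree,
    alignment: CodonAlignment,
    estimator: str = "ml",
    seed: int = 0,
    family: SimulatedFamily | None = None,
    kappa_truth: float = 2.0,
) -> pd.DataFrame:
    """Per-branch (t, ω, dN, dS) under the configured estimator."""
    if estimator == "truth":
        if family is None:
            raise ValueError("truth estimator requires a simulated family")
        return _truth_branch_table(family, kappa_truth)
    null_fit = fit_null_model(alignment, tree, seed=seed)
    if estimator == "ml":
        table, _ = fit_free_ratios(alignment, tree, null_fit)
        return table
    if estimator == "counting":
        return counting_estimator(alignment, tree, null_fit)
    raise ValueError(f"unknown estimator {estimator!r}")


def _load_input_dir(input_dir: str) -> list[SimulatedFamily]:
    root = Path(input_dir)
    tree_files = sorted((root / "trees").glob("*.nhx")) + sorted(
        (root / "trees").glob("*.nwk")
    )
    if not tree_files:
        raise FileNotFoundError(f"no tree files under {root / 'trees'}")
    families = []
    for tf in tree_files:
        tid = tf.stem
        aln_path = root / "alignments" / f"{tid}.fasta"
        if not aln_path.exists():
            raise FileNotFoundError(f"missing alignment for {tid}: {aln_path}")
        gt = read_gene_tree(str(tf), tree_id=tid)
        aln = CodonAlignment.from_fasta(str(aln_path))
        families.append(SimulatedFamily(gt, aln, truth=None))
    return families


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run the full analysis under one config; see module docstring."""
    t_start = time.time()
    out = Path(config.out_dir) if config.out_dir else None
    if out:
        out.mkdir(parents=True, exist_ok=True)

    # -- stage 1: data ----------------------------------------------------
    t0 = time.time()
    if config.input_dir:
        families = _load_input_dir(config.input_dir)
    else:
        sp = load_species_tree(config.species_tree)
        families = generate_dataset(
            config.scenario,
            config.n_trees,
            config.seed,
            species_tree=sp,
            out_dir=str(out / "dataset") if out else None,
        )
    logger.info("stage simulate/load: %d families in %.1fs", len(families), time.time() - t0)

    # -- stage 2: label ----------------------------------------------------
    t0 = time.time()
    congruences = []
    for fam in families:
        label_events(fam.tree)
        classify_paralog_nodes(fam.tree)
        congruences.append(label_congruence(fam.tree))
    congruences = np.asarray(congruences, dtype=float)
    with_ref = congruences[~np.isnan(congruences)]
    congruence = {
        "n_trees_with_reference": int(with_ref.size),
        "mean_congruence": float(with_ref.mean()) if with_ref.size else None,
        "min_congruence": float(with_ref.min()) if with_ref.size else None,
    }
    logger.info("stage label: %.1fs", time.time() - t0)

    # -- stage 3: tree filters --------------------------------------------
    kept, tree_audit = apply_tree_filters([f.tree for f in families], config.thresholds)
    kept_ids = {gt.tree_id for gt in kept}
    families_kept = [f for f in families if f.tree.tree_id in kept_ids]
    logger.info("stage tree-filter: %d/%d retained", len(families_kept), len(families))

    # -- stage 4: estimate + node records ---------------------------------
    t0 = time.time()
    record_frames = []
    branch_tables = {}
    seed_root = np.random.SeedSequence(config.seed).spawn(1)[0]
    for i, fam in enumerate(families_kept):
        table = estimate_branches(
            fam.tree,
            fam.alignment,
            estimator=config.estimator,
            seed=int(seed_root.generate_state(1)[0] % (2**31)) + i,
            family=fam,
            kappa_truth=config.scenario.kappa,
        )
        branch_tables[fam.tree.tree_id] = table
        record_frames.append(build_node_records(fam.tree, table))
    records = (
        pd.concat(record_frames, ignore_index=True)
        if record_frames
        else pd.DataFrame()
    )
    logger.info("stage estimate(%s): %.1fs", config.estimator, time.time() - t0)

    # -- stage 5: node filters + stats ------------------------------------
    filtered, node_audit = apply_node_filters(records, config.thresholds)
    report = compare_orthologs_paralogs(
        filtered,
        b=config.b,
        seed=config.seed,
        statistic=config.statistic,
        ovl_transform=config.ovl_transform,
        epsilon=config.epsilon,
    )
    result = PipelineResult(
        config=config,
        records=records,
        filtered_records=filtered,
        report=report,
        tree_audit=tree_audit,
        node_audit=node_audit,
        congruence=congruence,
        branch_tables=branch_tables,
    )
    if out:
        _write_outputs(result, out, families_kept)
    logger.info("pipeline done in %.1fs", time.time() - t_start)
    return result


def _write_outputs(result: PipelineResult, out: Path, families) -> None:
    records_path = out / "node_records.tsv"
    result.records.to_csv(records_path, sep="\t", index=False, float_format="%.6g")
    result.filtered_records.to_csv(
        out / "node_records_filtered.tsv", sep="\t", index=False, float_format="%.6g"
    )
    branches = pd.concat(
        [t.assign(tree_id=tid) for tid, t in result.branch_tables.items()],
        ignore_index=True,
    )
    branches.to_csv(out / "branch_params.tsv", sep="\t", index=False, float_format="%.6g")
    (out / "report.json").write_text(result.report_json() + "\n")
    draws = result.report.get("_null_draws", {})
    if draws:
        pd.DataFrame(draws).to_csv(
            out / "null_draws.tsv", sep="\t", index=False, float_format="%.6g"
        )
    labeled_dir = out / "labeled_trees"
    labeled_dir.mkdir(exist_ok=True)
    for fam in families:
        table = result.branch_tables.get(fam.tree.tree_id)
        if table is not None:
            omega_of = dict(zip(table["branch_id"], table["omega"]))
            for node in fam.tree.tree.preorder_node_iter():
                if node.node_id in omega_of:
                    node.omega = float(omega_of[node.node_id])
        write_gene_tree(fam.tree, str(labeled_dir / f"{fam.tree.tree_id}.nhx"))
    import dendropy
    import scipy

    import orthoconj

    manifest = {
        "config": result.config.to_dict(),
        "versions": {
            "orthoconj": orthoconj.__version__,
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
            "dendropy": dendropy.__version__,
        },
    }
    (out / "run_manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True, default=str) + "\n"
    )
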