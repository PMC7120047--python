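"""Statistical calibration harnesses for the permutation machinery.

These run many small, sequence-free replicates of the pipeline (the
simulator's true branch ω values stand in for estimates) to measure the
permutation test's operating characteristics: the type-I error under the
null scenario, and power under an effect scenario. Sequence simulation and
ω estimation are skipped because calibration concerns the statistics layer
— labels and values — not the estimator.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .events import classify_paralog_nodes, label_events
from .node_metrics import FilterThresholds, apply_node_filters, apply_tree_filters, build_node_records
from .pipeline import _truth_branch_table
from .simulate import ScenarioConfig, SimulatedFamily, load_species_tree, simulate_family
from .stats import permutation_test

__all__ = ["truth_records", "null_pvalues"]


def truth_records(
    families: list[SimulatedFamily],
    thresholds: FilterThresholds | None = None,
    kappa: float = 2.0,
) -> pd.DataFrame:
    """Filtered node records built from simulator-truth branch parameters."""
    kept, _ = apply_tree_filters([f.tree for f in families], thresholds)
    kept_ids = {gt.tree_id for gt in kept}
    frames = []
    for fam in families:
        if fam.tree.tree_id not in kept_ids:
            continue
        frames.append(build_node_records(fam.tree, _truth_branch_table(fam, kappa)))
    if not frames:
        return pd.DataFrame()
    records = pd.concat(frames, ignore_index=True)
    filtered, _ = apply_node_filters(records, thresholds)
    return filtered


def null_pvalues(
    n_replicates: int = 200,
    n_trees: int = 6,
    b: int = 199,
    seed: int = 0,
    scenario: ScenarioConfig | None = None,
    value_column: str = "delta_omega",
) -> np.ndarray:
    """Permutation p-values over replicates of the label-uninformative null.

    Each replicate simulates ``n_trees`` gene families under the null
    scenario (event labels carry no information about branch ω), labels
    them by species overlap, assembles truth-based node records, and runs
    the within-tree permutation test on ``value_column``. Under a correct
    test the returned p-values are (sub)uniform. Replicates that end up
    with fewer than 2 records in either label class are redrawn.
    """
    scenario = scenario or ScenarioConfig(name="null")
    sp = load_species_tree()
    streams = np.random.SeedSequence(seed).spawn(2 * n_replicates + 64)
    pvals = np.empty(n_replicates)
    stream_iter = iter(streams)
    for r in range(n_replicates):
        while True:
            try:
                ss = next(stream_iter)
            except StopIteration as exc:
                raise RuntimeError("exhausted seed streams; too many degenerate replicates") from exc
            rng = np.random.default_rng(ss)
            families = [
                simulate_family(
                    scenario, rng, species_tree=sp, tree_id=f"r{r}t{i}",
                    simulate_sequences=False,
                )
                for i in range(n_trees)
            ]
            for fam in families:
                label_events(fam.tree)
                classify_paralog_nodes(fam.tree)
            records = truth_records(families, kappa=scenario.kappa)
            if len(records) and records["event"].nunique() == 2:
                n_dup = int((records["event"] == "duplication").sum())
                if min(n_dup, len(records) - n_dup) >= 2:
                    break
        res = permutation_test(
            records, value_column, b=b, rng=np.random.default_rng(ss.spawn(1)[0])
        )
        pvals[r] = res.p_value
    return pvals
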