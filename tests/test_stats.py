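"""Permutation test, effect sizes, KS and overlap coefficient."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

from orthoconj.stats import (
    compare_orthologs_paralogs,
    hedges_g,
    ks_two_sample,
    overlap_coefficient,
    permutation_test,
)


def _frame(tree_ids, events, values):
    return pd.DataFrame(
        {"tree_id": tree_ids, "event": events, "delta_omega": values}
    )


def test_constant_values_give_p_one():
    df = _frame(
        ["t1"] * 6,
        ["duplication"] * 3 + ["speciation"] * 3,
        [1.0] * 6,
    )
    res = permutation_test(df, b=200, seed=0)
    assert res.observed == 0.0
    assert res.p_value == 1.0


def test_monte_carlo_agrees_with_exhaustive_enumeration():
    # one tree, 6 nodes, 3 labels each: 20 equally likely assignments
    values = np.array([0.1, 0.7, 0.4, 1.2, 0.2, 0.9])
    df = _frame(["t1"] * 6, ["duplication"] * 3 + ["speciation"] * 3, values)
    obs = values[:3].mean() - values[3:].mean()
    stats = []
    for dup_idx in itertools.combinations(range(6), 3):
        mask = np.zeros(6, bool)
        mask[list(dup_idx)] = True
        stats.append(values[mask].mean() - values[~mask].mean())
    exact_p = np.mean(np.abs(stats) >= abs(obs) - 1e-12)
    b = 10_000
    res = permutation_test(df, b=b, seed=7)
    se = math.sqrt(exact_p * (1 - exact_p) / b)
    assert abs(res.p_value - exact_p) <= 3 * se + 1 / (b + 1)


def test_perfect_separation_reaches_smoothing_floor():
    # 10 trees, each with one dominant duplication value; no permutation can
    # match the observed statistic, so p hits the (1)/(B+1) floor
    rng = np.random.default_rng(0)
    rows = []
    for t in range(10):
        rows.append((f"t{t}", "duplication", 100.0 + rng.random()))
        rows.append((f"t{t}", "speciation", rng.random()))
        rows.append((f"t{t}", "speciation", rng.random()))
    df = _frame(*(list(c) for c in zip(*rows)))
    res = permutation_test(df, b=999, seed=1)
    assert res.p_value == pytest.approx(1 / 1000)


def test_permutation_preserves_per_tree_label_counts():
    # tree A has only duplication nodes; within-tree shuffling must keep
    # them duplications, so the null statistic can only take two values
    df = _frame(
        ["A", "A", "B", "B"],
        ["duplication", "duplication", "duplication", "speciation"],
        [5.0, 7.0, 1.0, 3.0],
    )
    res = permutation_test(df, b=500, seed=3)
    possible = {
        (5 + 7 + 1) / 3 - 3.0,  # B's duplication stays
        (5 + 7 + 3) / 3 - 1.0,  # B's labels swapped
    }
    assert set(np.round(res.null_draws, 9)) <= {round(x, 9) for x in possible}


def test_permutation_requires_both_labels():
    df = _frame(["t"] * 3, ["duplication"] * 3, [1.0, 2.0, 3.0])
    with pytest.raises(ValueError):
        permutation_test(df, b=10, seed=0)


def test_hedges_g_closed_form():
    a = [0, 0, 2, 2]
    b = [1, 1, 3, 3]
    expected = (1 - 3 / 23) * (-1.0) / math.sqrt(4 / 3)
    res = hedges_g(a, b)
    assert res.g == pytest.approx(expected, abs=1e-6)
    assert hedges_g(b, a).g == pytest.approx(-expected, abs=1e-12)


def test_hedges_g_invariances():
    rng = np.random.default_rng(2)
    a, b = rng.normal(0, 1, 30), rng.normal(1, 1, 40)
    g1 = hedges_g(a, b).g
    g2 = hedges_g(3.5 * a, 3.5 * b).g
    assert g1 == pytest.approx(g2, abs=1e-12)
    assert hedges_g(a, a).g == 0.0
    with pytest.raises(ValueError, match="variance"):
        hedges_g([1.0, 1.0], [1.0, 1.0])


def test_overlap_identical_and_disjoint():
    rng = np.random.default_rng(3)
    x = rng.normal(0, 1, 400)
    same = overlap_coefficient(x, x)
    assert same.ovl == pytest.approx(1.0, abs=0.01)
    far = overlap_coefficient(x, x + 1000.0)
    assert far.ovl < 0.01


def test_overlap_of_shifted_normals_matches_closed_form():
    rng = np.random.default_rng(4)
    a = rng.normal(0, 1, 4000)
    b = rng.normal(2, 1, 4000)
    expected = 2 * norm.cdf(-1)  # equal-variance normals, means 2 SD apart
    res = overlap_coefficient(a, b)
    assert res.ovl == pytest.approx(expected, abs=0.02)
    # symmetry and common-shift invariance
    assert overlap_coefficient(b, a).ovl == pytest.approx(res.ovl, abs=1e-9)
    shifted = overlap_coefficient(a + 5, b + 5)
    assert shifted.ovl == pytest.approx(res.ovl, abs=1e-6)


def test_overlap_degenerate_sample_rejected():
    with pytest.raises(ValueError):
        overlap_coefficient([1.0, 1.0, 1.0], [0.0, 1.0, 2.0])


def test_ks_examples():
    assert ks_two_sample([1, 2, 3], [1, 2, 3]).d == 0.0
    assert ks_two_sample([0, 1, 2], [10, 11, 12]).d == 1.0
    assert ks_two_sample([1, 2, 3], [2, 3, 4]).d == pytest.approx(1 / 3)
    with pytest.raises(ValueError):
        ks_two_sample([], [1.0])


def test_compare_report_smoke():
    rng = np.random.default_rng(9)
    n = 60
    rows = []
    for i in range(n):
        tree = f"t{i % 6}"
        event = "duplication" if i % 3 == 0 else "speciation"
        wl, wr = rng.lognormal(-1.5, 0.5, 2)
        wp = rng.lognormal(-1.5, 0.5)
        rows.append(
            {
                "tree_id": tree, "node_id": f"n{i}", "event": event,
                "paralog_class": rng.choice(["within_species", "between_species"])
                if event == "duplication" else None,
                "omega_parent": wp, "omega_left": wl, "omega_right": wr,
                "ds_left": 0.5, "ds_right": 0.5,
                "delta_omega": abs(wl - wr),
                "dwp_min": min(wl - wp, wr - wp),
                "dwp_max": max(wl - wp, wr - wp),
                "age": np.nan,
            }
        )
    records = pd.DataFrame(rows)
    report = compare_orthologs_paralogs(records, b=99, seed=0)
    d = report["delta_omega"]
    for key in ("mean_duplication", "mean_speciation"):
        assert np.isfinite(d[key])
    assert 0 < d["permutation"]["p_value"] <= 1
    assert 0 <= d["ovl"]["ovl"] <= 1
    assert np.isfinite(d["hedges_g"]["g"])
    assert "dwp_min" in report and "dwp_max" in report
    # identical report with the same seed
    report2 = compare_orthologs_paralogs(records, b=99, seed=0)
    assert report2["delta_omega"]["permutation"] == d["permutation"]
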