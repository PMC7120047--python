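"""Comparison machinery for orthologous vs paralogous lineages.

The central test is a within-tree label permutation: speciation/duplication
labels are reshuffled among the internal nodes of each gene tree (keeping
each tree's label counts fixed), which destroys any association between
event type and divergence while preserving tree-level structure. The
two-tailed p-value uses add-one smoothing, p = (1 + #{|T*| >= |T|}) / (B+1).

Also here: Hedges' g (standardized mean difference with small-sample
correction), the two-sample Kolmogorov–Smirnov test, and the overlap
coefficient (OVL) of two Gaussian kernel density estimates.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats as sps

from .gene_tree import DUPLICATION, SPECIATION

__all__ = [
    "PermutationResult",
    "EffectSize",
    "OverlapResult",
    "KSResult",
    "permutation_test",
    "hedges_g",
    "overlap_coefficient",
    "ks_two_sample",
    "compare_orthologs_paralogs",
]


# ---------------------------------------------------------------------------
@dataclass
class PermutationResult:
    observed: float
    b: int
    null_draws: np.ndarray = field(repr=False)
    p_value: float
    seed: int | None
    statistic: str

    def to_dict(self) -> dict:
        return {
            "observed": self.observed,
            "b": self.b,
            "p_value": self.p_value,
            "seed": self.seed,
            "statistic": self.statistic,
        }


def _mean_diff(values: np.ndarray, is_dup: np.ndarray) -> float:
    return float(values[is_dup].mean() - values[~is_dup].mean())


def _median_diff(values: np.ndarray, is_dup: np.ndarray) -> float:
    return float(np.median(values[is_dup]) - np.median(values[~is_dup]))


_STATISTICS = {"mean_diff": _mean_diff, "median_diff": _median_diff}


def permutation_test(
    records: pd.DataFrame,
    value_column: str = "delta_omega",
    statistic: str = "mean_diff",
    b: int = 1000,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    label_column: str = "event",
    positive_label: str = DUPLICATION,
) -> PermutationResult:
    """Two-tailed within-tree label permutation test.

    The statistic (default: duplication-minus-speciation difference in mean
    ``value_column``) is recomputed on pooled records after independently
    permuting the labels within every tree, preserving each tree's label
    counts. Records with NaN values are dropped first.
    """
    if statistic not in _STATISTICS:
        raise ValueError(f"unknown statistic {statistic!r}")
    stat_fn = _STATISTICS[statistic]
    df = records.dropna(subset=[value_column])
    values = df[value_column].to_numpy(dtype=float)
    labels = (df[label_column] == positive_label).to_numpy()
    if labels.all() or not labels.any():
        raise ValueError("need both duplication and speciation records")
    groups = [idx.to_numpy() for _, idx in df.groupby("tree_id").groups.items()]
    pos = {v: i for i, v in enumerate(df.index)}
    groups = [np.array([pos[v] for v in g]) for g in groups]

    observed = stat_fn(values, labels)
    if rng is None:
        rng = np.random.default_rng(seed)
    draws = np.empty(b)
    perm = labels.copy()
    for k in range(b):
        for g in groups:
            perm[g] = labels[g][rng.permutation(g.size)]
        draws[k] = stat_fn(values, perm)
    # small tolerance so permutations that reproduce |T_obs| up to float
    # round-off count as ties
    tol = 1e-12 * max(1.0, abs(observed))
    p = (1.0 + np.sum(np.abs(draws) >= abs(observed) - tol)) / (b + 1.0)
    return PermutationResult(observed, b, draws, float(p), seed, statistic)


# ---------------------------------------------------------------------------
@dataclass
class EffectSize:
    g: float
    n_a: int
    n_b: int
    pooled_sd: float

    def to_dict(self) -> dict:
        return asdict(self)


def hedges_g(sample_a, sample_b) -> EffectSize:
    """Hedges' g: bias-corrected standardized difference of means.

    g = J · (mean_a − mean_b) / s_pooled, with pooled SD on
    df = n_a + n_b − 2 and correction J = 1 − 3/(4·df − 1).
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("both samples need at least 2 observations")
    df = a.size + b.size - 2
    pooled_var = ((a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1)) / df
    if pooled_var <= 0:
        raise ValueError("zero pooled variance")
    j = 1.0 - 3.0 / (4.0 * df - 1.0)
    g = j * (a.mean() - b.mean()) / np.sqrt(pooled_var)
    return EffectSize(float(g), a.size, b.size, float(np.sqrt(pooled_var)))


# ---------------------------------------------------------------------------
@dataclass
class OverlapResult:
    ovl: float
    transform: str | None
    bandwidth_a: float
    bandwidth_b: float
    grid_min: float
    grid_max: float
    grid_points: int

    def to_dict(self) -> dict:
        return asdict(self)


def overlap_coefficient(
    sample_a,
    sample_b,
    transform: str | None = None,
    epsilon: float = 1e-6,
    grid_points: int = 512,
) -> OverlapResult:
    """OVL: area under the pointwise minimum of two Gaussian KDEs.

    Both samples are optionally log-transformed as log(x + epsilon) (the
    ``"log"`` transform; OVL is invariant to any common monotone transform
    only approximately, so the transform used is reported). Bandwidths
    follow Silverman's rule per sample; densities are evaluated on a shared
    512-point grid spanning the pooled range plus 3 max bandwidths and
    integrated by the trapezoidal rule.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("both samples need at least 2 observations")
    if transform == "log":
        if np.any(a + epsilon <= 0) or np.any(b + epsilon <= 0):
            raise ValueError("log transform requires x + epsilon > 0")
        a = np.log(a + epsilon)
        b = np.log(b + epsilon)
    elif transform is not None:
        raise ValueError(f"unknown transform {transform!r}")
    if a.std(ddof=1) == 0 or b.std(ddof=1) == 0:
        raise ValueError("degenerate (zero-variance) sample")
    kde_a = sps.gaussian_kde(a, bw_method="silverman")
    kde_b = sps.gaussian_kde(b, bw_method="silverman")
    bw_a = float(kde_a.factor * a.std(ddof=1))
    bw_b = float(kde_b.factor * b.std(ddof=1))
    pad = 3.0 * max(bw_a, bw_b)
    lo = min(a.min(), b.min()) - pad
    hi = max(a.max(), b.max()) + pad
    grid = np.linspace(lo, hi, grid_points)
    fa = kde_a(grid)
    fb = kde_b(grid)
    ovl = float(np.trapezoid(np.minimum(fa, fb), grid))
    return OverlapResult(
        min(ovl, 1.0), transform, bw_a, bw_b, float(lo), float(hi), grid_points
    )


def density_curves(
    sample_a, sample_b, transform: str | None = None, epsilon: float = 1e-6,
    grid_points: int = 512,
) -> pd.DataFrame:
    """Shared-grid KDE curves for the two samples (for plotting/export)."""
    res = overlap_coefficient(sample_a, sample_b, transform, epsilon, grid_points)
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if transform == "log":
        a = np.log(a + epsilon)
        b = np.log(b + epsilon)
    grid = np.linspace(res.grid_min, res.grid_max, res.grid_points)
    return pd.DataFrame(
        {
            "x": grid,
            "density_a": sps.gaussian_kde(a, bw_method="silverman")(grid),
            "density_b": sps.gaussian_kde(b, bw_method="silverman")(grid),
        }
    )


# ---------------------------------------------------------------------------
@dataclass
class KSResult:
    d: float
    p_value: float

    def to_dict(self) -> dict:
        return asdict(self)


def ks_two_sample(sample_a, sample_b) -> KSResult:
    """Two-sample Kolmogorov–Smirnov test (asymptotic p-value)."""
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("empty sample")
    res = sps.ks_2samp(a, b, method="asymp")
    return KSResult(float(res.statistic), float(res.pvalue))


# ---------------------------------------------------------------------------
def _group_values(records: pd.DataFrame, column: str):
    df = records.dropna(subset=[column])
    dup = df[df["event"] == DUPLICATION][column].to_numpy(dtype=float)
    spec = df[df["event"] == SPECIATION][column].to_numpy(dtype=float)
    return dup, spec


def _one_comparison(
    records: pd.DataFrame,
    column: str,
    b: int,
    seed: int | None,
    statistic: str,
    ovl_transform: str | None,
    epsilon: float,
) -> dict:
    dup, spec = _group_values(records, column)
    if dup.size < 2 or spec.size < 2:
        raise ValueError(f"too few records for comparison on {column!r}")
    perm = permutation_test(records, column, statistic, b=b, seed=seed)
    out = {
        "n_duplication": int(dup.size),
        "n_speciation": int(spec.size),
        "mean_duplication": float(dup.mean()),
        "sd_duplication": float(dup.std(ddof=1)),
        "mean_speciation": float(spec.mean()),
        "sd_speciation": float(spec.std(ddof=1)),
        "permutation": perm.to_dict(),
        "hedges_g": hedges_g(dup, spec).to_dict(),
        "ks": ks_two_sample(dup, spec).to_dict(),
    }
    transform = ovl_transform if np.all(dup >= 0) and np.all(spec >= 0) else None
    try:
        out["ovl"] = overlap_coefficient(
            dup, spec, transform=transform, epsilon=epsilon
        ).to_dict()
    except ValueError as exc:
        out["ovl"] = {"error": str(exc)}
    return out, perm


def compare_orthologs_paralogs(
    records: pd.DataFrame,
    b: int = 1000,
    seed: int | None = None,
    statistic: str = "mean_diff",
    ovl_transform: str | None = "log",
    epsilon: float = 1e-6,
    extra_columns: tuple[str, ...] = ("lineage_omega", "dwp_min", "dwp_max"),
    compare_paralog_classes: bool = True,
    parent_omega_max: float | None = 10.0,
) -> dict:
    """Full ortholog-vs-paralog statistical report on filtered node records.

    Runs the permutation test, Hedges' g, KS test and OVL on Δω, then on
    the per-node mean daughter ω and the signed parent differences
    (Δω_p min/max, root nodes excluded by their NaN values), and finally
    contrasts within- vs between-species paralog Δω. Δω_p comparisons use
    no log transform (values are signed) and drop nodes whose *parent*
    branch ω exceeds ``parent_omega_max``: the node filters screen runaway
    estimates on daughter branches only, and an unfiltered runaway parent
    would dominate the parent-difference means.
    """
    records = records.copy()
    records["lineage_omega"] = (records["omega_left"] + records["omega_right"]) / 2.0
    if parent_omega_max is not None:
        bad_parent = records["omega_parent"] > parent_omega_max
        records.loc[bad_parent, ["dwp_min", "dwp_max"]] = np.nan
    report: dict = {"settings": {
        "b": b, "seed": seed, "statistic": statistic,
        "ovl_transform": ovl_transform, "epsilon": epsilon,
        "parent_omega_max": parent_omega_max,
    }}
    null_draws = {}
    main, perm = _one_comparison(
        records, "delta_omega", b, seed, statistic, ovl_transform, epsilon
    )
    report["delta_omega"] = main
    null_draws["delta_omega"] = perm.null_draws
    for i, col in enumerate(extra_columns):
        transform = ovl_transform if col == "lineage_omega" else None
        sub_seed = None if seed is None else seed + 1 + i
        try:
            comp, perm = _one_comparison(
                records, col, b, sub_seed, statistic, transform, epsilon
            )
        except ValueError as exc:
            report[col] = {"error": str(exc)}
            continue
        report[col] = comp
        null_draws[col] = perm.null_draws

    if compare_paralog_classes:
        dups = records[(records["event"] == DUPLICATION)].dropna(
            subset=["delta_omega", "paralog_class"]
        )
        within = dups[dups["paralog_class"] == "within_species"]["delta_omega"]
        between = dups[dups["paralog_class"] == "between_species"]["delta_omega"]
        if len(within) >= 2 and len(between) >= 2:
            cls_seed = None if seed is None else seed + 100
            perm_cls = permutation_test(
                dups,
                "delta_omega",
                statistic,
                b=b,
                seed=cls_seed,
                label_column="paralog_class",
                positive_label="within_species",
            )
            report["paralog_classes"] = {
                "n_within": int(len(within)),
                "n_between": int(len(between)),
                "mean_within": float(within.mean()),
                "mean_between": float(between.mean()),
                "permutation": perm_cls.to_dict(),
                "hedges_g": hedges_g(within, between).to_dict(),
                "ks": ks_two_sample(within, between).to_dict(),
            }
        else:
            report["paralog_classes"] = {
                "error": "too few within/between-species paralog nodes"
            }
    report["_null_draws"] = null_draws  # stripped before JSON serialisation
    return report
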