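"""Per-branch ω (dN/dS) estimation.

Two-step maximum-likelihood procedure mirroring the standard branch-model
workflow:

1. :func:`fit_null_model` — a single ω shared by all branches is fitted
   jointly with κ and all branch lengths (coordinate sweeps over branch
   lengths using the spectral edge closures, alternating with a bounded
   quasi-Newton step on (log κ, log ω)).
2. :func:`fit_free_ratios` — holding κ and the branch lengths at their
   null-fit values, one ω per branch is fitted by repeated coordinate
   sweeps. Fixing the nuisance parameters trades a little likelihood for
   speed and identifiability; the free fit always starts from the null
   optimum so its log-likelihood can only improve.

:func:`counting_estimator` is a fast cross-check: marginal ancestral codons
are reconstructed under the null fit and each (parent, child) pair is run
through the Nei–Gojobori-style counting machinery.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize, minimize_scalar

from .alignment import CodonAlignment, decode_codons
from .codon_model import (
    CodonFrequencies,
    CodonRateMatrix,
    build_rate_matrix,
    expected_substitution_partition,
)
from .counting import pairwise_estimate
from .gene_tree import ArrayTree, GeneTree
from .likelihood import PruningEngine

__all__ = [
    "ModelFit",
    "fit_null_model",
    "fit_free_ratios",
    "counting_estimator",
    "OMEGA_BOUNDS",
    "KAPPA_BOUNDS",
]

OMEGA_BOUNDS = (1e-6, 20.0)
KAPPA_BOUNDS = (0.01, 100.0)
T_BOUNDS = (1e-8, 50.0)

BRANCH_COLUMNS = ["branch_id", "t", "omega", "dN", "dS", "flag"]


@dataclass
class ModelFit:
    """Result of a maximum-likelihood model fit on one gene tree."""

    loglik: float
    kappa: float
    omega: float | None  # single omega (null fit); None for free-ratios
    branch_lengths: np.ndarray  # indexed by child-end node index
    freqs: CodonFrequencies
    converged: bool
    n_rounds: int
    flags: list[str] = field(default_factory=list)
    omega_per_branch: np.ndarray | None = None  # free-ratios fit only

    def branch_length_of(self, atree: ArrayTree, node_id: str) -> float:
        return float(self.branch_lengths[atree.index_of[node_id]])


def _as_array_tree(tree) -> ArrayTree:
    return tree.to_array_tree() if isinstance(tree, GeneTree) else tree


def _branch_sweeps(engine, atree, model, t, pi, max_sweeps=8, tol=1e-6):
    """Coordinate-ascent sweeps over branch lengths for a fixed model.

    Partials are refreshed once per sweep; each edge's one-dimensional
    problem uses the spectral closure. The exact log-likelihood is checked
    after every sweep and the sweep is rolled back if it did not improve
    (staleness of partials within a sweep can, rarely, overshoot).
    """
    edges = atree.edges()
    P = {e: model.transition_matrix(t[e]) for e in edges}
    best = engine.loglik(P, pi)
    for _ in range(max_sweeps):
        partials = engine.full_partials(P, pi)
        t_old = t.copy()
        for e in edges:
            f = engine.edge_loglik_in_t(partials, e, model)
            res = minimize_scalar(
                lambda x: -f(x),
                bounds=T_BOUNDS,
                method="bounded",
                options={"xatol": 1e-9},
            )
            if -res.fun > f(t[e]):
                t[e] = float(res.x)
        for e in edges:
            P[e] = model.transition_matrix(t[e])
        new = engine.loglik(P, pi)
        if new < best:
            t[:] = t_old
            for e in edges:
                P[e] = model.transition_matrix(t[e])
            break
        gain, best = new - best, new
        if gain < tol:
            break
    return best


def fit_null_model(
    aln: CodonAlignment,
    tree,
    freqs: CodonFrequencies | str | None = "f3x4",
    kappa0: float = 2.0,
    omega0: float = 0.4,
    t0: float = 0.1,
    tol: float = 1e-8,
    max_rounds: int = 50,
    seed: int = 0,
) -> ModelFit:
    """ML fit of the uniform-ω model: (κ, ω, branch lengths).

    ``freqs``: a :class:`CodonFrequencies`, the string ``"f3x4"`` (estimate
    position-specific nucleotide frequencies from the alignment, the
    default), or ``"uniform"``. One jittered restart is attempted if the
    optimizer stalls without converging.
    """
    atree = _as_array_tree(tree)
    engine = PruningEngine(atree, aln)
    if freqs == "f3x4" or freqs is None:
        seqs = [aln.sequence_string(i) for i in range(aln.n_sequences)]
        freqs = CodonFrequencies.f3x4(seqs, aln.code)
    elif freqs == "uniform":
        freqs = CodonFrequencies.uniform(aln.code)
    pi = freqs.pi

    rng = np.random.default_rng(seed)

    def one_run(kappa, omega, t):
        best = -np.inf
        converged = False
        rounds = 0
        for rounds in range(1, max_rounds + 1):
            model = build_rate_matrix(kappa, omega, freqs)
            lnl = _branch_sweeps(engine, atree, model, t, pi)

            def nll(x):
                m = build_rate_matrix(np.exp(x[0]), np.exp(x[1]), freqs)
                P = {e: m.transition_matrix(t[e]) for e in atree.edges()}
                return -engine.loglik(P, pi)

            res = minimize(
                nll,
                x0=[np.log(kappa), np.log(omega)],
                method="L-BFGS-B",
                bounds=[tuple(np.log(KAPPA_BOUNDS)), tuple(np.log(OMEGA_BOUNDS))],
                options={"maxiter": 60, "ftol": 1e-12},
            )
            kappa, omega = float(np.exp(res.x[0])), float(np.exp(res.x[1]))
            lnl = -float(res.fun)
            if lnl - best < tol * (1.0 + abs(lnl)) and rounds > 1:
                best = max(best, lnl)
                converged = True
                break
            best = max(best, lnl)
        return best, kappa, omega, t, converged, rounds

    t = np.full(atree.n_nodes, t0)
    t[atree.root] = 0.0
    best, kappa, omega, t, converged, rounds = one_run(kappa0, omega0, t)
    if not converged:
        # one jittered restart
        t2 = np.clip(t * rng.lognormal(0, 0.2, t.shape), *T_BOUNDS)
        t2[atree.root] = 0.0
        res2 = one_run(kappa * rng.lognormal(0, 0.1), omega * rng.lognormal(0, 0.1), t2)
        if res2[0] > best:
            best, kappa, omega, t, converged, rounds = res2

    flags = []
    if not converged:
        flags.append("not_converged")
    n_tiny = sum(t[e] <= T_BOUNDS[0] * 10 for e in atree.edges())
    if n_tiny == len(atree.edges()):
        flags.append("all_branch_lengths_at_boundary")
    return ModelFit(
        loglik=best,
        kappa=kappa,
        omega=omega,
        branch_lengths=t,
        freqs=freqs,
        converged=converged,
        n_rounds=rounds,
        flags=flags,
    )


def _branch_table(atree, t, omegas, kappa, freqs, flags) -> pd.DataFrame:
    rows = []
    for e in atree.edges():
        part = expected_substitution_partition(kappa, omegas[e], freqs, t[e])
        rows.append(
            {
                "branch_id": atree.node_ids[e],
                "t": float(t[e]),
                "omega": float(omegas[e]),
                "dN": part.dN,
                "dS": part.dS,
                "flag": flags.get(e, ""),
            }
        )
    return pd.DataFrame(rows, columns=BRANCH_COLUMNS)


def fit_free_ratios(
    aln: CodonAlignment,
    tree,
    null_fit: ModelFit,
    max_sweeps: int = 10,
    tol: float = 1e-6,
) -> tuple[pd.DataFrame, ModelFit]:
    """One ω per branch, with κ and branch lengths fixed at the null fit.

    Returns (per-branch parameter table, free-ratios ModelFit). Branches
    whose ω lands on a bound are flagged, not fatal.
    """
    if not null_fit.converged:
        raise ValueError("null fit did not converge; refusing free-ratios fit")
    atree = _as_array_tree(tree)
    engine = PruningEngine(atree, aln)
    freqs = null_fit.freqs
    pi = freqs.pi
    kappa = null_fit.kappa
    t = null_fit.branch_lengths
    edges = atree.edges()

    omegas = np.full(atree.n_nodes, null_fit.omega, dtype=float)
    models: dict[int, CodonRateMatrix] = {}
    base = build_rate_matrix(kappa, null_fit.omega, freqs)
    P = {}
    for e in edges:
        models[e] = base
        P[e] = base.transition_matrix(t[e])
    best = engine.loglik(P, pi)

    for _ in range(max_sweeps):
        partials = engine.full_partials(P, pi)
        for e in edges:
            f = engine.edge_loglik_in_model(partials, e, t[e])

            def nll(w):
                return -f(build_rate_matrix(kappa, w, freqs))

            res = minimize_scalar(
                nll, bounds=OMEGA_BOUNDS, method="bounded", options={"xatol": 1e-6}
            )
            if -res.fun > f(models[e]):
                omegas[e] = float(res.x)
                models[e] = build_rate_matrix(kappa, omegas[e], freqs)
                P[e] = models[e].transition_matrix(t[e])
        new = engine.loglik(P, pi)
        gain = new - best
        if new > best:
            best = new
        if gain < tol:
            break

    flags = {}
    for e in edges:
        fl = []
        if omegas[e] <= OMEGA_BOUNDS[0] * 1.01 or omegas[e] >= OMEGA_BOUNDS[1] * 0.999:
            fl.append("omega_boundary")
        if t[e] <= T_BOUNDS[0] * 1.01:
            fl.append("zero_length")
        if fl:
            flags[e] = ";".join(fl)
    table = _branch_table(atree, t, omegas, kappa, freqs, flags)
    fit = ModelFit(
        loglik=best,
        kappa=kappa,
        omega=None,
        branch_lengths=t,
        freqs=freqs,
        converged=True,
        n_rounds=max_sweeps,
        omega_per_branch=omegas,
    )
    return table, fit


def counting_estimator(
    aln: CodonAlignment, tree, null_fit: ModelFit
) -> pd.DataFrame:
    """Counting-based per-branch dN/dS from marginal ancestral codons.

    Ancestral states are reconstructed under the null fit; each
    (parent, child) sequence pair is scored with pathway-averaged
    difference counts, mutational-opportunity sites and a Jukes–Cantor
    correction. Saturated or synonymous-free branches get NaN ω and a flag.
    """
    if not null_fit.converged:
        raise ValueError("null fit did not converge")
    atree = _as_array_tree(tree)
    engine = PruningEngine(atree, aln)
    model = build_rate_matrix(null_fit.kappa, null_fit.omega, null_fit.freqs)
    t = null_fit.branch_lengths
    P = {e: model.transition_matrix(t[e]) for e in atree.edges()}
    anc = engine.marginal_ancestral_states(P, null_fit.freqs.pi)

    row_of = aln.row_index()

    def seq_of(v: int) -> str:
        if v < atree.n_leaves:
            return aln.sequence_string(row_of[atree.leaf_labels[v]])
        return decode_codons(anc[v], aln.code)

    rows = []
    for e in atree.edges():
        p = int(atree.parent[e])
        est = pairwise_estimate(seq_of(p), seq_of(e), aln.code)
        flag = ""
        if est.saturated:
            flag = "saturated"
        elif est.omega is None:
            flag = "undefined_omega"
        rows.append(
            {
                "branch_id": atree.node_ids[e],
                "t": float(t[e]),
                "omega": est.omega if est.omega is not None else np.nan,
                "dN": est.dN if est.dN is not None else np.nan,
                "dS": est.dS if est.dS is not None else np.nan,
                "flag": flag,
            }
        )
    return pd.DataFrame(rows, columns=BRANCH_COLUMNS)
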