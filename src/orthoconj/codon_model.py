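"""Goldman–Yang-style sense-codon substitution model.

States are the sense codons of a :class:`~orthoconj.genetic_code.GeneticCode`
(61 under the standard code). Instantaneous rates between codons differing
at exactly one nucleotide position are

    q_ij  ∝  π_j · κ^[transition] · ω^[nonsynonymous]

with q_ij = 0 for multi-nucleotide changes. κ is the transition/transversion
rate ratio, ω = dN/dS the nonsynonymous/synonymous rate ratio, and π the
equilibrium codon frequencies. Q is scaled so that one unit of branch length
equals one expected codon substitution at that branch's ω, matching the
convention of codeml-style branch models.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

from .genetic_code import GeneticCode, is_transition, standard_code

__all__ = [
    "CodonFrequencies",
    "CodonRateMatrix",
    "SubstitutionPartition",
    "build_rate_matrix",
    "transition_probabilities",
    "expected_substitution_partition",
]

_PI_TOL = 1e-8


@lru_cache(maxsize=8)
def _single_step_structure(table_id: int):
    """Arrays describing all single-nucleotide codon changes for a code.

    Returns (i_idx, j_idx, transition_mask, nonsyn_mask) over all ordered
    sense-codon pairs differing at exactly one position.
    """
    code = standard_code(table_id)
    ii, jj, ts, ns = [], [], [], []
    for i, ci in enumerate(code.codons):
        for j, cj in enumerate(code.codons):
            if i == j:
                continue
            diffs = [p for p in range(3) if ci[p] != cj[p]]
            if len(diffs) != 1:
                continue
            p = diffs[0]
            ii.append(i)
            jj.append(j)
            ts.append(is_transition(ci[p], cj[p]))
            ns.append(not code.is_synonymous(ci, cj))
    return (
        np.asarray(ii, dtype=np.intp),
        np.asarray(jj, dtype=np.intp),
        np.asarray(ts, dtype=bool),
        np.asarray(ns, dtype=bool),
    )


@dataclass(frozen=True)
class CodonFrequencies:
    """Equilibrium codon frequencies π over the sense codons of a code."""

    pi: np.ndarray
    code: GeneticCode = field(default_factory=standard_code)

    def __post_init__(self) -> None:
        pi = np.asarray(self.pi, dtype=float)
        if pi.shape != (self.code.n_states,):
            raise ValueError(
                f"pi must have length {self.code.n_states}, got {pi.shape}"
            )
        if np.any(pi < 0):
            raise ValueError("codon frequencies must be non-negative")
        if abs(pi.sum() - 1.0) > _PI_TOL:
            raise ValueError(f"codon frequencies must sum to 1, got {pi.sum():.6g}")
        object.__setattr__(self, "pi", pi)

    @classmethod
    def uniform(cls, code: GeneticCode | None = None) -> "CodonFrequencies":
        code = code or standard_code()
        return cls(np.full(code.n_states, 1.0 / code.n_states), code)

    @classmethod
    def f3x4(cls, sequences, code: GeneticCode | None = None) -> "CodonFrequencies":
        """Position-specific nucleotide frequencies (codeml's F3x4).

        ``sequences`` is an iterable of in-frame nucleotide strings (gaps and
        ambiguity codes are skipped). Zero frequencies are floored at 1e-8 so
        the resulting π is a valid stationary distribution.
        """
        code = code or standard_code()
        counts = np.zeros((3, 4))
        order = {"A": 0, "C": 1, "G": 2, "T": 3}
        for seq in sequences:
            s = str(seq).upper().replace("U", "T")
            if len(s) % 3:
                raise ValueError("sequence length not divisible by 3")
            for k, nt in enumerate(s):
                if nt in order:
                    counts[k % 3, order[nt]] += 1
        if counts.sum() == 0:
            raise ValueError("no unambiguous nucleotides found")
        freqs = counts / counts.sum(axis=1, keepdims=True)
        pi = np.empty(code.n_states)
        for i, codon in enumerate(code.codons):
            pi[i] = np.prod([freqs[k, order[codon[k]]] for k in range(3)])
        pi = np.maximum(pi, 1e-8)
        return cls(pi / pi.sum(), code)


@dataclass(frozen=True)
class CodonRateMatrix:
    """Normalized instantaneous rate matrix Q with its spectral form.

    The symmetrizing decomposition (Q reversible w.r.t. π) is computed once
    and reused for every transition-probability evaluation:
    P(t) = L · diag(exp(λ t)) · R  with  L = Π^{-1/2} V, R = V^T Π^{1/2}.
    """

    kappa: float
    omega: float
    freqs: CodonFrequencies
    Q: np.ndarray
    eigenvalues: np.ndarray = field(repr=False)
    left: np.ndarray = field(repr=False)
    right: np.ndarray = field(repr=False)

    @property
    def pi(self) -> np.ndarray:
        return self.freqs.pi

    @property
    def code(self) -> GeneticCode:
        return self.freqs.code

    def transition_matrix(self, t: float) -> np.ndarray:
        return transition_probabilities(self, t)


def build_rate_matrix(
    kappa: float, omega: float, freqs: CodonFrequencies, normalize: bool = True
) -> CodonRateMatrix:
    """Construct the codon rate matrix Q(κ, ω, π).

    Raises ValueError for non-positive κ, negative ω, or π with zero entries
    (reversibility requires strictly positive frequencies).
    """
    if not kappa > 0:
        raise ValueError(f"kappa must be positive, got {kappa}")
    if omega < 0:
        raise ValueError(f"omega must be non-negative, got {omega}")
    pi = freqs.pi
    if np.any(pi <= 0):
        raise ValueError("rate matrix requires strictly positive codon frequencies")
    n = freqs.code.n_states
    ii, jj, ts, ns = _single_step_structure(freqs.code.table_id)
    rates = pi[jj] * np.where(ts, kappa, 1.0) * np.where(ns, omega, 1.0)
    Q = np.zeros((n, n))
    Q[ii, jj] = rates
    np.fill_diagonal(Q, -Q.sum(axis=1))
    if normalize:
        mean_rate = -float(pi @ np.diag(Q))
        if mean_rate <= 0:
            raise ValueError("degenerate model: zero total substitution rate")
        Q = Q / mean_rate
    # symmetrize: B = Pi^{1/2} Q Pi^{-1/2} is symmetric under detailed balance
    sq = np.sqrt(pi)
    B = Q * (sq[:, None] / sq[None, :])
    B = 0.5 * (B + B.T)  # guard round-off asymmetry
    lam, V = np.linalg.eigh(B)
    left = V / sq[:, None]
    right = V.T * sq[None, :]
    return CodonRateMatrix(float(kappa), float(omega), freqs, Q, lam, left, right)


def transition_probabilities(model: CodonRateMatrix, t: float) -> np.ndarray:
    """P(t) = exp(Qt); rows sum to 1, entries clipped at 0 for round-off."""
    if t < 0:
        raise ValueError(f"branch length must be non-negative, got {t}")
    P = (model.left * np.exp(model.eigenvalues * t)) @ model.right
    np.clip(P, 0.0, None, out=P)
    P /= P.sum(axis=1, keepdims=True)
    return P


@dataclass(frozen=True)
class SubstitutionPartition:
    """Expected substitutions over a branch split into syn/nonsyn classes.

    dN and dS are per-site expectations (per nonsynonymous and synonymous
    site respectively); N_sites and S_sites are the mutational-opportunity
    site counts per codon (N_sites + S_sites = 3).
    """

    dN: float
    dS: float
    N_sites: float
    S_sites: float


def expected_substitution_partition(
    kappa: float, omega: float, freqs: CodonFrequencies, t: float
) -> SubstitutionPartition:
    """Partition the expected substitution flux π_i q_ij t into dN and dS.

    Site opportunities follow the mutational-opportunity convention: the
    synonymous site fraction is the synonymous share of the neutral (ω = 1)
    flux, which makes dN/dS = ω an exact identity whenever dS > 0.
    """
    if t < 0:
        raise ValueError(f"t must be non-negative, got {t}")
    pi = freqs.pi
    ii, jj, ts, ns = _single_step_structure(freqs.code.table_id)
    base = pi[ii] * pi[jj] * np.where(ts, kappa, 1.0)  # neutral flux terms
    a_syn = float(base[~ns].sum())
    a_nonsyn = float(base[ns].sum())
    if a_syn <= 0:
        raise ValueError("degenerate model: zero synonymous flux")
    rho_s = a_syn / (a_syn + a_nonsyn)
    s_sites = 3.0 * rho_s
    n_sites = 3.0 - s_sites
    # realized (normalized) flux at this omega
    total = a_syn + omega * a_nonsyn
    flux_syn = a_syn / total
    flux_nonsyn = omega * a_nonsyn / total
    return SubstitutionPartition(
        dN=flux_nonsyn * t / n_sites,
        dS=flux_syn * t / s_sites,
        N_sites=n_sites,
        S_sites=s_sites,
    )
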