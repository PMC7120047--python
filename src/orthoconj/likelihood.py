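"""Felsenstein pruning over codon alignments, with edge-wise machinery.

The engine computes the site-independent phylogenetic likelihood by
post-order pruning with per-node log scaling. Beyond the plain likelihood
it exposes the two ingredients the optimizers need:

* *down* (conditional) partials D_v — probability of the data below node v
  given the state at v — and *top* partials T_v — probability of all data
  outside the subtree of v given the state at v's parent. Together they
  give, for any single edge, the likelihood as a cheap one-dimensional
  function of that edge's length or ω (via the spectral form of Q), which
  is what makes coordinate-wise fitting fast.
* marginal ancestral-state posteriors, used by the counting estimator.

Missing codons (gaps/ambiguity) contribute a partial of ones, i.e. are
summed over all states; the root is weighted by the equilibrium π.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .alignment import CodonAlignment
from .codon_model import CodonRateMatrix
from .gene_tree import ArrayTree

__all__ = ["PruningEngine", "Partials", "pruning_loglik"]


@dataclass
class Partials:
    """Per-node partial likelihood arrays over site patterns.

    All arrays are indexed by node; D/T have shape (n_nodes, n_patterns,
    n_states) and the ls_* arrays carry the accumulated log scalers,
    shape (n_nodes, n_patterns).
    """

    D: np.ndarray
    ls_D: np.ndarray
    T: np.ndarray
    ls_T: np.ndarray
    loglik: float


class PruningEngine:
    """Likelihood machinery bound to one tree and one alignment."""

    def __init__(self, atree: ArrayTree, aln: CodonAlignment):
        self.atree = atree
        self.n_states = aln.code.n_states
        row_of = aln.row_index()
        missing = set(atree.leaf_labels) - set(aln.names)
        if missing:
            raise ValueError(f"alignment lacks sequences for leaves: {sorted(missing)}")
        if aln.n_codons == 0:
            raise ValueError("zero-width alignment")
        cols = np.stack(
            [aln.codes[row_of[label]] for label in atree.leaf_labels], axis=0
        )  # (n_leaves, n_sites)
        patterns, weights = np.unique(cols, axis=1, return_counts=True)
        self.patterns = patterns  # (n_leaves, n_patterns)
        self.weights = weights.astype(float)
        self.site_pattern_index = None  # computed lazily when needed
        self._cols = cols

    @property
    def n_patterns(self) -> int:
        return self.patterns.shape[1]

    # -- core passes -------------------------------------------------------
    def _leaf_partial(self, leaf: int) -> np.ndarray:
        obs = self.patterns[leaf]  # (n_pat,)
        D = np.zeros((self.n_patterns, self.n_states))
        seen = obs >= 0
        D[seen, obs[seen]] = 1.0
        D[~seen, :] = 1.0
        return D

    def down_pass(self, P: dict[int, np.ndarray]):
        """Conditional partials D and log scalers for every node.

        ``P`` maps child-end node index -> transition matrix for the branch
        above that node (the root needs no entry).
        """
        at = self.atree
        n = at.n_nodes
        D = np.empty((n, self.n_patterns, self.n_states))
        ls = np.zeros((n, self.n_patterns))
        for v in at.postorder:
            if v < at.n_leaves:
                D[v] = self._leaf_partial(v)
                continue
            l, r = at.children[v]
            Dv = (D[l] @ P[l].T) * (D[r] @ P[r].T)
            sc = Dv.max(axis=1)
            sc[sc == 0] = 1.0
            D[v] = Dv / sc[:, None]
            ls[v] = ls[l] + ls[r] + np.log(sc)
        return D, ls

    def loglik_from_down(self, D, ls, pi) -> float:
        root = self.atree.root
        site = D[root] @ pi
        return float(self.weights @ (np.log(site) + ls[root]))

    def loglik(self, P: dict[int, np.ndarray], pi: np.ndarray) -> float:
        D, ls = self.down_pass(P)
        return self.loglik_from_down(D, ls, pi)

    def full_partials(self, P: dict[int, np.ndarray], pi: np.ndarray) -> Partials:
        """Down and top partials plus the exact log-likelihood."""
        at = self.atree
        D, ls_D = self.down_pass(P)
        n = at.n_nodes
        T = np.empty((n, self.n_patterns, self.n_states))
        ls_T = np.zeros((n, self.n_patterns))
        root = at.root
        # "A" at a node = prob of data outside its subtree given its own state;
        # for the root that is just the prior pi.
        A = {root: np.broadcast_to(pi, (self.n_patterns, self.n_states))}
        ls_A = {root: np.zeros(self.n_patterns)}
        order = [v for v in reversed(at.postorder) if v in at.children]
        for p in order:
            l, r = at.children[p]
            Ml = D[l] @ P[l].T
            Mr = D[r] @ P[r].T
            for c, Msib, ls_sib in ((l, Mr, ls_D[r]), (r, Ml, ls_D[l])):
                Tc = A[p] * Msib
                sc = Tc.max(axis=1)
                sc[sc == 0] = 1.0
                T[c] = Tc / sc[:, None]
                ls_T[c] = ls_A[p] + ls_sib + np.log(sc)
                if c in at.children:
                    A[c] = T[c] @ P[c]
                    ls_A[c] = ls_T[c]
        loglik = self.loglik_from_down(D, ls_D, pi)
        return Partials(D=D, ls_D=ls_D, T=T, ls_T=ls_T, loglik=loglik)

    # -- edge-wise closures ------------------------------------------------
    def edge_loglik_in_t(self, partials: Partials, edge: int, model: CodonRateMatrix):
        """Return f(t) -> log-likelihood as a function of one edge's length.

        Uses the spectral form P(t) = L e^{Λt} R: per pattern s,
        lik_s(t) = Σ_k (T_s L)_k (R D_s)_k e^{λ_k t}.
        """
        a = (partials.T[edge] @ model.left) * (partials.D[edge] @ model.right.T)
        lam = model.eigenvalues
        const = partials.ls_T[edge] + partials.ls_D[edge]
        w = self.weights

        def f(t: float) -> float:
            site = a @ np.exp(lam * t)
            site = np.maximum(site, 1e-300)
            return float(w @ (np.log(site) + const))

        return f

    def edge_loglik_in_model(self, partials: Partials, edge: int, t: float):
        """Return f(model) -> log-likelihood as a function of one edge's Q."""
        const = partials.ls_T[edge] + partials.ls_D[edge]
        w = self.weights
        Te, De = partials.T[edge], partials.D[edge]

        def f(model: CodonRateMatrix) -> float:
            a = (Te @ model.left) * (De @ model.right.T)
            site = a @ np.exp(model.eigenvalues * t)
            site = np.maximum(site, 1e-300)
            return float(w @ (np.log(site) + const))

        return f

    # -- ancestral states --------------------------------------------------
    def marginal_ancestral_states(
        self, P: dict[int, np.ndarray], pi: np.ndarray
    ) -> dict[int, np.ndarray]:
        """Marginal (posterior-argmax) codon state per internal node and site."""
        partials = self.full_partials(P, pi)
        at = self.atree
        if self.site_pattern_index is None:
            # map alignment columns back to pattern columns
            _, idx = np.unique(self._cols, axis=1, return_inverse=True)
            self.site_pattern_index = idx
        out = {}
        root = at.root
        for v in at.children:
            if v == root:
                post = partials.D[v] * pi
            else:
                post = partials.D[v] * (partials.T[v] @ P[v])
            states = post.argmax(axis=1)
            out[v] = states[self.site_pattern_index]
        return out


def pruning_loglik(
    aln: CodonAlignment,
    atree: ArrayTree,
    models: dict[int, CodonRateMatrix],
    branch_lengths: dict[int, float] | np.ndarray,
    pi: np.ndarray,
) -> float:
    """Log-likelihood of an alignment on a tree with per-branch models.

    ``models`` and ``branch_lengths`` are keyed by child-end node index.
    """
    engine = PruningEngine(atree, aln)
    P = {}
    for e in atree.edges():
        t = branch_lengths[e]
        if t < 0:
            raise ValueError(f"negative branch length on edge {e}")
        P[e] = models[e].transition_matrix(t)
    return engine.loglik(P, pi)
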