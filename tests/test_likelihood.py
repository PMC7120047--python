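"""Pruning likelihood vs exhaustive ancestral-state summation."""

import numpy as np
import pytest

from orthoconj.alignment import CodonAlignment
from orthoconj.codon_model import build_rate_matrix
from orthoconj.gene_tree import read_gene_tree
from orthoconj.likelihood import PruningEngine, pruning_loglik

THREE_LEAF = "((A:{t1}[&&NHX:S=a],B:{t2}[&&NHX:S=b]):{t3},C:{t4}[&&NHX:S=c]);"


def brute_force_three_leaf(aln, at, P, pi, code):
    """Sum over both ancestral codon states explicitly (61^2 terms/site)."""
    row = aln.row_index()
    root = at.root
    inner = next(v for v in at.children if v != root)
    l_in, r_in = at.children[inner]
    other = next(c for c in at.children[root] if c != inner)
    total = 0.0
    for s in range(aln.n_codons):
        acc = 0.0
        obs = {v: aln.codes[row[at.leaf_labels[v]], s] for v in range(at.n_leaves)}

        def leaf_p(P_leaf, state, leaf):
            o = obs[leaf]
            return P_leaf[state].sum() if o < 0 else P_leaf[state, o]

        for r_state in range(code.n_states):
            for v_state in range(code.n_states):
                p = pi[r_state] * P[inner][r_state, v_state]
                p *= leaf_p(P[l_in], v_state, l_in) * leaf_p(P[r_in], v_state, r_in)
                p *= leaf_p(P[other], r_state, other)
                acc += p
        total += np.log(acc)
    return total


@pytest.mark.parametrize("seed", range(5))
def test_pruning_matches_bruteforce(seed, code, uniform_freqs, random_codon_string):
    rng = np.random.default_rng(seed)
    t = rng.uniform(0.05, 0.6, 4)
    gt = read_gene_tree(THREE_LEAF.format(t1=t[0], t2=t[1], t3=t[2], t4=t[3]))
    at = gt.to_array_tree()
    aln = CodonAlignment.from_sequences(
        [(n, random_codon_string(5, seed * 10 + k)) for k, n in enumerate("ABC")]
    )
    m = build_rate_matrix(rng.uniform(1, 4), rng.uniform(0.05, 2.0), uniform_freqs)
    models = {e: m for e in at.edges()}
    bl = {e: at.edge_length[e] for e in at.edges()}
    lnl = pruning_loglik(aln, at, models, bl, uniform_freqs.pi)
    P = {e: m.transition_matrix(bl[e]) for e in at.edges()}
    expected = brute_force_three_leaf(aln, at, P, uniform_freqs.pi, code)
    assert lnl == pytest.approx(expected, abs=1e-8)


def test_zero_branch_lengths_identical_sequences(code, uniform_freqs):
    gt = read_gene_tree("(A:0[&&NHX:S=a],B:0[&&NHX:S=b]);")
    at = gt.to_array_tree()
    aln = CodonAlignment.from_sequences([("A", "TTT"), ("B", "TTT")])
    m = build_rate_matrix(2.0, 0.5, uniform_freqs)
    lnl = pruning_loglik(
        aln, at, {e: m for e in at.edges()}, {e: 0.0 for e in at.edges()},
        uniform_freqs.pi,
    )
    assert lnl == pytest.approx(np.log(uniform_freqs.pi[code.index("TTT")]))


def test_saturated_branches_factorize_into_prior(code, uniform_freqs, random_codon_string):
    # at t -> infinity leaves decouple: per-site likelihood = prod pi(leaf)
    gt = read_gene_tree("((A:50[&&NHX:S=a],B:50[&&NHX:S=b]):50,C:50[&&NHX:S=c]);")
    at = gt.to_array_tree()
    seqs = [(n, random_codon_string(4, 99 + k)) for k, n in enumerate("ABC")]
    aln = CodonAlignment.from_sequences(seqs)
    m = build_rate_matrix(2.0, 0.5, uniform_freqs)
    lnl = pruning_loglik(
        aln, at, {e: m for e in at.edges()},
        {e: at.edge_length[e] for e in at.edges()}, uniform_freqs.pi,
    )
    expected = sum(
        np.log(uniform_freqs.pi[aln.codes[i, s]])
        for i in range(3)
        for s in range(4)
    )
    assert lnl == pytest.approx(expected, abs=1e-6)


def test_missing_data_sums_over_states(uniform_freqs):
    gt = read_gene_tree("(A:0.1[&&NHX:S=a],B:0.2[&&NHX:S=b]);")
    at = gt.to_array_tree()
    with_gap = CodonAlignment.from_sequences([("A", "TTTAAA"), ("B", "TTT---")])
    without = CodonAlignment.from_sequences([("A", "TTT"), ("B", "TTT")])
    m = build_rate_matrix(2.0, 0.5, uniform_freqs)
    bl = {e: at.edge_length[e] for e in at.edges()}
    lnl_gap = pruning_loglik(with_gap, at, {e: m for e in at.edges()}, bl, uniform_freqs.pi)
    lnl_ref = pruning_loglik(without, at, {e: m for e in at.edges()}, bl, uniform_freqs.pi)
    # gapped column: B missing, so that site reduces to the marginal of A's codon
    assert lnl_gap == pytest.approx(lnl_ref + np.log(uniform_freqs.pi[0] * 0 + uniform_freqs.pi[with_gap.codes[0, 1]]))


def test_engine_rejects_mismatched_leaves(uniform_freqs):
    gt = read_gene_tree("(A:0.1[&&NHX:S=a],B:0.2[&&NHX:S=b]);")
    at = gt.to_array_tree()
    aln = CodonAlignment.from_sequences([("A", "TTT"), ("X", "TTT")])
    with pytest.raises(ValueError, match="lacks sequences"):
        PruningEngine(at, aln)


def test_edge_closure_consistent_with_full_likelihood(uniform_freqs, eight_taxon_tree, random_codon_string):
    at = eight_taxon_tree.to_array_tree()
    aln = CodonAlignment.from_sequences(
        [(n, random_codon_string(20, 7 + k)) for k, n in enumerate("abcdefgh")]
    )
    engine = PruningEngine(at, aln)
    m = build_rate_matrix(2.0, 0.4, uniform_freqs)
    P = {e: m.transition_matrix(at.edge_length[e]) for e in at.edges()}
    partials = engine.full_partials(P, uniform_freqs.pi)
    for e in at.edges():
        f = engine.edge_loglik_in_t(partials, e, m)
        assert f(at.edge_length[e]) == pytest.approx(partials.loglik, abs=1e-8)
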