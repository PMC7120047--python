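"""Simulator: birth-death gene trees, ω assignment, forward evolution."""

import json

import numpy as np
import pytest
from scipy.stats import chisquare, ks_2samp

from orthoconj.codon_model import CodonFrequencies, build_rate_matrix
from orthoconj.events import label_events
from orthoconj.gene_tree import DUPLICATION, SPECIATION, read_gene_tree
from orthoconj.simulate import (
    ScenarioConfig,
    assign_branch_omegas,
    generate_dataset,
    load_species_tree,
    simulate_alignment,
    simulate_family,
    simulate_gene_tree,
)


@pytest.fixture(scope="module")
def species_tree():
    return load_species_tree()


def test_species_tree_is_ultrametric_and_dated(species_tree):
    assert species_tree.seed_node.age == pytest.approx(430.0)
    for node in species_tree.preorder_node_iter():
        for child in node.child_nodes():
            assert child.age < node.age


def test_no_duplication_reproduces_species_tree(species_tree):
    rng = np.random.default_rng(0)
    gt, truth = simulate_gene_tree(species_tree, 0.0, 0.0, rng)
    assert gt.n_leaves() == 16
    species = sorted(leaf.species for leaf in gt.leaves())
    assert species == sorted(t.label for t in species_tree.taxon_namespace)
    assert set(truth.events.values()) == {SPECIATION}
    label_events(gt)
    assert all(n.event == SPECIATION for n in gt.internal_nodes())


def test_same_seed_same_tree(species_tree):
    trees = []
    for _ in range(2):
        rng = np.random.default_rng(42)
        gt, _ = simulate_gene_tree(species_tree, 0.003, 0.001, rng)
        trees.append(gt.to_newick())
    assert trees[0] == trees[1]


def test_duplication_fraction_increases_with_rate(species_tree):
    fractions = []
    for lam in (0.001, 0.004):
        counts = [0, 0]
        rng = np.random.default_rng(77)
        for _ in range(40):
            _, truth = simulate_gene_tree(species_tree, lam, 0.0005, rng)
            for ev in truth.events.values():
                counts[ev == DUPLICATION] += 1
        fractions.append(counts[1] / sum(counts))
    assert 0 < fractions[0] < fractions[1] < 1


def test_neofunctionalization_effect_exact_without_noise(species_tree):
    scen = ScenarioConfig(
        name="neofunctionalization", duplication_factor=3.0,
        base_omega=0.2, omega_log_sd=0.0,
    )
    rng = np.random.default_rng(1)
    for _ in range(10):
        gt, truth = simulate_gene_tree(species_tree, 0.004, 0.0, rng)
        omegas = assign_branch_omegas(gt, truth, scen, rng)
        assert all(w > 0 for w in omegas.values())
        for node in gt.internal_nodes():
            kids = node.child_nodes()
            vals = sorted(omegas[k.node_id] for k in kids)
            parent = (
                0.2 if node.parent_node is None else omegas[node.node_id]
            )
            if parent >= 2.5:
                continue  # nested duplications can hit the simulator's ω caps
            if truth.events[node.node_id] == DUPLICATION:
                assert vals == pytest.approx([parent, 3.0 * parent])
            else:
                assert vals == pytest.approx([parent, parent])


def test_null_scenario_omega_independent_of_labels(species_tree):
    scen = ScenarioConfig(name="null", omega_log_sd=0.3)
    rng = np.random.default_rng(8)
    dup_w, spec_w = [], []
    for _ in range(150):
        gt, truth = simulate_gene_tree(species_tree, 0.003, 0.001, rng)
        omegas = assign_branch_omegas(gt, truth, scen, rng)
        for node in gt.internal_nodes():
            target = dup_w if truth.events[node.node_id] == DUPLICATION else spec_w
            for kid in node.child_nodes():
                target.append(omegas[kid.node_id])
    assert ks_2samp(dup_w, spec_w).pvalue > 0.01


def test_zero_length_branch_copies_parent(uniform_freqs):
    gt = read_gene_tree("(A:0[&&NHX:S=a],B:0[&&NHX:S=b]);")
    aln = simulate_alignment(
        gt, {"A": 0.5, "B": 0.5}, 2.0, uniform_freqs, 50, np.random.default_rng(0)
    )
    assert aln.sequence_string(0) == aln.sequence_string(1)


def test_omega_zero_branch_yields_no_amino_acid_changes(uniform_freqs, code):
    gt = read_gene_tree("(A:1.5[&&NHX:S=a],B:1.5[&&NHX:S=b]);")
    aln = simulate_alignment(
        gt, {"A": 0.0, "B": 0.0}, 2.0, uniform_freqs, 200, np.random.default_rng(3)
    )
    pa = [code.translate(aln.code.codons[c]) for c in aln.codes[0]]
    pb = [code.translate(aln.code.codons[c]) for c in aln.codes[1]]
    assert pa == pb
    # but synonymous changes did occur on a branch this long
    assert (aln.codes[0] != aln.codes[1]).any()


def test_long_branch_reaches_stationarity(uniform_freqs):
    gt = read_gene_tree("(A:0.0001[&&NHX:S=a],B:20[&&NHX:S=b]);")
    aln = simulate_alignment(
        gt, {"A": 0.5, "B": 0.5}, 2.0, uniform_freqs, 5000, np.random.default_rng(5)
    )
    counts = np.bincount(aln.codes[1], minlength=61)
    res = chisquare(counts, f_exp=np.full(61, 5000 / 61))
    assert res.pvalue > 0.001


def test_generate_dataset_deterministic_and_complete(tmp_path):
    scen = ScenarioConfig(name="conservation", n_codons=30)
    outs = []
    for run in ("a", "b"):
        out = tmp_path / run
        generate_dataset(scen, 5, seed=9, out_dir=str(out))
        outs.append(out)
    for fname in ("manifest.json", "truth.tsv"):
        assert (outs[0] / fname).read_text() == (outs[1] / fname).read_text()
    assert len(list((outs[0] / "trees").glob("*.nhx"))) == 5
    assert len(list((outs[0] / "alignments").glob("*.fasta"))) == 5
    manifest = json.loads((outs[0] / "manifest.json").read_text())
    assert manifest["scenario"]["name"] == "conservation"
    assert manifest["n_trees"] == 5


def test_default_generator_mostly_passes_tree_filters(species_tree):
    from orthoconj.node_metrics import apply_tree_filters

    scen = ScenarioConfig(name="null")
    rng = np.random.default_rng(21)
    fams = [
        simulate_family(scen, rng, species_tree=species_tree, simulate_sequences=False)
        for _ in range(40)
    ]
    for fam in fams:
        label_events(fam.tree)
    kept, audit = apply_tree_filters([f.tree for f in fams])
    assert audit["n_retained"] / audit["n_input"] >= 0.5


def test_unknown_scenario_rejected():
    with pytest.raises(ValueError, match="unknown scenario"):
        ScenarioConfig(name="bogus")
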