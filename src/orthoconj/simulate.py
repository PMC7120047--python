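"""Synthetic gene families with known events and branch-specific ω.

Gene families are generated in three layers, each with its own ground
truth, so every downstream stage (labeling, estimation, node metrics,
statistics) can be tested for recovery:

1. **Gene trees** evolve inside a dated ultrametric species tree by a
   birth–death process: gene lineages duplicate at rate λ_d and are lost
   at rate λ_l (both per Myr) along species-tree branches, and split at
   every species-tree node they survive to. True speciation/duplication
   labels and node ages are recorded; lineages with no surviving
   descendants are pruned (which silently removes the events above them,
   exactly as gene loss hides history in real families).
2. **Branch ω values** follow a multiplicative random walk down the tree
   (each daughter branch draws log-normally around its parent branch's ω).
   At true duplication nodes a scenario-specific effect applies:
   *neofunctionalization* multiplies one randomly chosen daughter's ω by
   the factor f, *subfunctionalization* multiplies both, *conservation*
   and *null* leave the draw untouched (the null scenario ignores event
   labels entirely, so labels carry no information about ω).
3. **Codon alignments** evolve forward from a root sequence drawn from π,
   site by site, under the branch-specific rate matrices. No indels, so
   alignments are exact by construction.

The packaged species tree has 16 vertebrate taxa with a 430-Myr root.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from importlib import resources
from pathlib import Path

import dendropy
import numpy as np

from .alignment import CodonAlignment, decode_codons
from .codon_model import CodonFrequencies, build_rate_matrix
from .gene_tree import DUPLICATION, SPECIATION, GeneTree, write_gene_tree

__all__ = [
    "ScenarioConfig",
    "SimulationTruth",
    "SimulatedFamily",
    "load_species_tree",
    "simulate_gene_tree",
    "assign_branch_omegas",
    "simulate_alignment",
    "simulate_family",
    "generate_dataset",
]

SCENARIOS = ("null", "conservation", "neofunctionalization", "subfunctionalization")

OMEGA_FLOOR = 0.005
OMEGA_CEIL = 8.0
OMEGA_HARD_CEIL = 15.0  # after the duplication effect multiplier


@dataclass(frozen=True)
class ScenarioConfig:
    """Generative settings for one simulation scenario.

    ``duplication_factor`` (f >= 1) is the ω multiplier applied at true
    duplication nodes per the scenario; ``lambda_dup``/``lambda_loss`` are
    per-Myr gene birth/death rates; ``base_omega`` centres the root branch
    ω; ``rate_median`` converts Myr to expected codon substitutions
    (per-tree rates scatter log-normally around it so families differ in
    depth as real ones do).
    """

    name: str = "null"
    duplication_factor: float = 3.0
    kappa: float = 2.0
    n_codons: int = 300
    lambda_dup: float = 0.002
    lambda_loss: float = 0.001
    base_omega: float = 0.2
    omega_log_sd: float = 0.2
    rate_median: float = 0.002
    rate_log_sd: float = 0.3

    def __post_init__(self) -> None:
        if self.name not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.name!r}; choose from {SCENARIOS}")
        if self.duplication_factor < 1:
            raise ValueError("duplication_factor must be >= 1")
        if self.lambda_dup < 0 or self.lambda_loss < 0:
            raise ValueError("rates must be non-negative")
        if self.n_codons < 1:
            raise ValueError("n_codons must be >= 1")


@dataclass
class SimulationTruth:
    """Ground truth emitted by the simulator for one gene family."""

    tree_id: str
    events: dict[str, str]  # internal node id -> speciation/duplication
    ages: dict[str, float]  # node id -> age in Myr
    omegas: dict[str, float] = field(default_factory=dict)  # branch id -> true ω
    paralog_classes: dict[str, str] = field(default_factory=dict)
    rate: float = float("nan")  # substitutions per codon per Myr


@dataclass
class SimulatedFamily:
    tree: GeneTree
    alignment: CodonAlignment | None
    truth: SimulationTruth | None


# ---------------------------------------------------------------------------
def load_species_tree(path: str | None = None) -> dendropy.Tree:
    """Load an ultrametric species tree (Newick, branch lengths in Myr).

    Defaults to the packaged 16-taxon vertebrate tree. Node ages are
    computed from tip depths and attached as ``node.age``; the tree must be
    ultrametric within a 1e-6 relative tolerance.
    """
    if path is None:
        ref = resources.files("orthoconj.data") / "species_tree_vertebrate16.nwk"
        data = ref.read_text()
    else:
        data = Path(path).read_text()
    tree = dendropy.Tree.get(
        data=data,
        schema="newick",
        preserve_underscores=True,
        rooting="force-rooted",
        suppress_internal_node_taxa=True,
    )
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            node.age = 0.0
        else:
            ages = [
                c.age + (c.edge.length or 0.0) for c in node.child_nodes()
            ]
            if max(ages) - min(ages) > 1e-6 * max(max(ages), 1.0):
                raise ValueError("species tree is not ultrametric")
            node.age = float(np.mean(ages))
    return tree


# ---------------------------------------------------------------------------
class _SimNode:
    __slots__ = ("children", "event", "age", "species")

    def __init__(self, event=None, age=0.0, species=None, children=()):
        self.children = list(children)
        self.event = event
        self.age = age
        self.species = species


def _evolve(sp_node, entry_age, lam_d, lam_l, rng):
    """Evolve one gene lineage toward ``sp_node``, entering at ``entry_age``."""
    total = lam_d + lam_l
    age = entry_age
    while True:
        wait = rng.exponential(1.0 / total) if total > 0 else np.inf
        event_age = age - wait
        if event_age <= sp_node.age:
            if sp_node.is_leaf():
                return _SimNode(age=0.0, species=sp_node.taxon.label)
            kids = [
                _evolve(c, sp_node.age, lam_d, lam_l, rng)
                for c in sp_node.child_nodes()
            ]
            kids = [k for k in kids if k is not None]
            if not kids:
                return None
            if len(kids) == 1:
                return kids[0]  # speciation node hidden by loss
            return _SimNode(event=SPECIATION, age=sp_node.age, children=kids)
        if rng.random() < lam_d / total:
            kids = [
                _evolve(sp_node, event_age, lam_d, lam_l, rng) for _ in range(2)
            ]
            kids = [k for k in kids if k is not None]
            if not kids:
                return None
            if len(kids) == 1:
                return kids[0]  # duplication hidden by loss of one copy
            return _SimNode(event=DUPLICATION, age=event_age, children=kids)
        return None  # lineage lost
    # unreachable


def simulate_gene_tree(
    species_tree: dendropy.Tree,
    lambda_dup: float,
    lambda_loss: float,
    rng: np.random.Generator,
    tree_id: str = "tree",
    rate: float = 1.0,
    max_attempts: int = 1000,
) -> tuple[GeneTree, SimulationTruth]:
    """Birth–death gene-family simulation inside a dated species tree.

    Branch lengths of the returned gene tree are time spans (Myr) times
    ``rate`` (expected codon substitutions per Myr). Families with fewer
    than two surviving copies are discarded and redrawn; exhausting
    ``max_attempts`` raises RuntimeError.
    """
    root_sp = species_tree.seed_node
    for _ in range(max_attempts):
        sim_root = _evolve(root_sp, root_sp.age, lambda_dup, lambda_loss, rng)
        if sim_root is not None and sim_root.children:
            break
    else:
        raise RuntimeError(f"no surviving family in {max_attempts} attempts")

    taxa = dendropy.TaxonNamespace()
    counts: dict[str, int] = {}

    def build(sim: _SimNode) -> dendropy.Node:
        node = dendropy.Node()
        node.age = sim.age
        if not sim.children:
            counts[sim.species] = counts.get(sim.species, 0) + 1
            label = f"{sim.species}_g{counts[sim.species]}"
            node.taxon = taxa.new_taxon(label)
            node.gene_id = label
            node.species = sim.species
            node.ref_event = None
        else:
            node.ref_event = sim.event
            node.event = None
            for kid in sim.children:
                child = build(kid)
                child.edge.length = (sim.age - kid.age) * rate
                node.add_child(child)
        return node

    droot = build(sim_root)
    tree = dendropy.Tree(taxon_namespace=taxa)
    tree.seed_node = droot
    gt = GeneTree(tree, tree_id=tree_id)

    events, ages = {}, {}
    for node in gt.tree.preorder_node_iter():
        ages[node.node_id] = node.age
        if not node.is_leaf():
            events[node.node_id] = node.ref_event
    truth = SimulationTruth(tree_id=tree_id, events=events, ages=ages, rate=rate)
    # paralog classes from true labels and descendant species sets
    for node in gt.internal_nodes():
        if node.ref_event == DUPLICATION:
            species = {leaf.species for leaf in node.leaf_iter()}
            truth.paralog_classes[node.node_id] = (
                "within_species" if len(species) == 1 else "between_species"
            )
    return gt, truth


# ---------------------------------------------------------------------------
def _clamp(x: float, lo: float = OMEGA_FLOOR, hi: float = OMEGA_CEIL) -> float:
    return float(min(max(x, lo), hi))


def assign_branch_omegas(
    gt: GeneTree,
    truth: SimulationTruth,
    scenario: ScenarioConfig,
    rng: np.random.Generator,
) -> dict[str, float]:
    """Draw a true ω for every branch according to the scenario.

    Daughter branches draw log-normally around the parent branch's ω
    (``omega_log_sd`` on the log scale); at a true duplication node the
    scenario effect multiplies one (neofunctionalization) or both
    (subfunctionalization) daughters by ``duplication_factor``. The null
    and conservation scenarios apply no effect. Results are stored in
    ``truth.omegas`` keyed by child-end node id.
    """
    if scenario.name not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario.name!r}")
    omegas: dict[str, float] = {}
    root = gt.root
    family_base = _clamp(
        rng.lognormal(np.log(scenario.base_omega), scenario.omega_log_sd)
    )
    for node in gt.tree.preorder_node_iter():
        if node.is_leaf():
            continue
        parent_omega = family_base if node is root else omegas[node.node_id]
        kids = node.child_nodes()
        draws = [
            _clamp(rng.lognormal(np.log(parent_omega), scenario.omega_log_sd))
            for _ in kids
        ]
        event = truth.events.get(node.node_id)
        if event == DUPLICATION and scenario.name in (
            "neofunctionalization",
            "subfunctionalization",
        ):
            if scenario.name == "neofunctionalization":
                which = int(rng.integers(len(kids)))
                draws[which] = min(
                    draws[which] * scenario.duplication_factor, OMEGA_HARD_CEIL
                )
            else:
                draws = [
                    min(d * scenario.duplication_factor, OMEGA_HARD_CEIL)
                    for d in draws
                ]
        for kid, w in zip(kids, draws):
            omegas[kid.node_id] = w
    truth.omegas = omegas
    return omegas


# ---------------------------------------------------------------------------
def simulate_alignment(
    gt: GeneTree,
    omegas: dict[str, float],
    kappa: float,
    freqs: CodonFrequencies,
    n_codons: int,
    rng: np.random.Generator,
) -> CodonAlignment:
    """Forward-simulate a codon alignment along the gene tree.

    The root sequence is drawn from π; each branch evolves every site by
    the transition probabilities of its own (κ, ω) rate matrix over the
    branch length (expected substitutions per codon). No indels, so the
    output is aligned by construction.
    """
    n_states = freqs.code.n_states
    root_seq = rng.choice(n_states, size=n_codons, p=freqs.pi)
    seqs: dict[str, np.ndarray] = {}

    def walk(node, seq):
        if node.is_leaf():
            seqs[node.gene_id] = seq
            return
        for kid in node.child_nodes():
            t = kid.edge.length or 0.0
            if t <= 0:
                child_seq = seq.copy()
            else:
                model = build_rate_matrix(kappa, omegas[kid.node_id], freqs)
                P = model.transition_matrix(t)
                cum = np.cumsum(P[seq], axis=1)
                u = rng.random(n_codons)
                child_seq = (u[:, None] > cum).sum(axis=1).astype(np.int16)
                np.clip(child_seq, 0, n_states - 1, out=child_seq)
            walk(kid, child_seq)

    walk(gt.root, root_seq.astype(np.int16))
    named = [
        (leaf.gene_id, decode_codons(seqs[leaf.gene_id], freqs.code))
        for leaf in gt.leaves()
    ]
    return CodonAlignment.from_sequences(named, freqs.code)


# ---------------------------------------------------------------------------
def simulate_family(
    scenario: ScenarioConfig,
    rng: np.random.Generator,
    species_tree: dendropy.Tree | None = None,
    tree_id: str = "tree",
    freqs: CodonFrequencies | None = None,
    simulate_sequences: bool = True,
) -> SimulatedFamily:
    """Simulate one gene family end to end under a scenario.

    ``simulate_sequences=False`` skips the alignment (family.alignment is
    None) for statistics-only harnesses that work from truth ω directly.
    """
    sp = species_tree if species_tree is not None else load_species_tree()
    freqs = freqs or CodonFrequencies.uniform()
    rate = scenario.rate_median * rng.lognormal(0.0, scenario.rate_log_sd)
    gt, truth = simulate_gene_tree(
        sp, scenario.lambda_dup, scenario.lambda_loss, rng, tree_id=tree_id, rate=rate
    )
    omegas = assign_branch_omegas(gt, truth, scenario, rng)
    aln = None
    if simulate_sequences:
        aln = simulate_alignment(gt, omegas, scenario.kappa, freqs, scenario.n_codons, rng)
    return SimulatedFamily(gt, aln, truth)


def generate_dataset(
    scenario: ScenarioConfig,
    n_trees: int,
    seed: int,
    species_tree: dendropy.Tree | None = None,
    out_dir: str | None = None,
) -> list[SimulatedFamily]:
    """Simulate ``n_trees`` families with deterministic per-tree seed streams.

    When ``out_dir`` is given, writes per-family NHX trees and FASTA
    alignments, one truth TSV covering all branches, and a manifest JSON
    recording every generative parameter.
    """
    sp = species_tree if species_tree is not None else load_species_tree()
    streams = np.random.SeedSequence(seed).spawn(n_trees)
    families = []
    for i, ss in enumerate(streams):
        rng = np.random.default_rng(ss)
        families.append(
            simulate_family(scenario, rng, species_tree=sp, tree_id=f"tree{i:04d}")
        )
    if out_dir is not None:
        _write_dataset(families, scenario, n_trees, seed, Path(out_dir))
    return families


def _write_dataset(families, scenario, n_trees, seed, out: Path) -> None:
    trees_dir = out / "trees"
    aln_dir = out / "alignments"
    trees_dir.mkdir(parents=True, exist_ok=True)
    aln_dir.mkdir(parents=True, exist_ok=True)
    truth_rows = ["tree_id\tbranch_id\ttrue_omega\ttrue_event\tage"]
    for fam in families:
        tid = fam.tree.tree_id
        write_gene_tree(fam.tree, str(trees_dir / f"{tid}.nhx"))
        fam.alignment.to_fasta(str(aln_dir / f"{tid}.fasta"))
        for branch_id, w in sorted(fam.truth.omegas.items()):
            event = fam.truth.events.get(branch_id, "")
            age = fam.truth.ages.get(branch_id, float("nan"))
            truth_rows.append(f"{tid}\t{branch_id}\t{w:.6g}\t{event}\t{age:.6g}")
    (out / "truth.tsv").write_text("\n".join(truth_rows) + "\n")
    manifest = {
        "n_trees": n_trees,
        "seed": seed,
        "scenario": asdict(scenario),
        "tree_ids": [fam.tree.tree_id for fam in families],
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
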