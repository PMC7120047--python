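import numpy as np
import pytest

from orthoconj.codon_model import CodonFrequencies
from orthoconj.gene_tree import read_gene_tree
from orthoconj.genetic_code import standard_code
from orthoconj.simulate import simulate_alignment

EIGHT_TAXON_NEWICK = (
    "((((a:0.1[&&NHX:S=a],b:0.1[&&NHX:S=b]):0.05,"
    "(c:0.08[&&NHX:S=c],d:0.12[&&NHX:S=d]):0.07):0.1,"
    "(e:0.15[&&NHX:S=e],f:0.1[&&NHX:S=f]):0.1):0.08,"
    "(g:0.2[&&NHX:S=g],h:0.18[&&NHX:S=h]):0.1);"
)


@pytest.fixture(scope="session")
def code():
    return standard_code()


@pytest.fixture(scope="session")
def uniform_freqs(code):
    return CodonFrequencies.uniform(code)


@pytest.fixture()
def eight_taxon_tree():
    return read_gene_tree(EIGHT_TAXON_NEWICK)


def make_alignment(gt, omega, kappa, freqs, n_codons, seed, omega_overrides=None):
    """Simulate an alignment on ``gt`` with a constant ω (plus overrides)."""
    atree = gt.to_array_tree()
    omap = {atree.node_ids[e]: omega for e in atree.edges()}
    if omega_overrides:
        omap.update(omega_overrides)
    rng = np.random.default_rng(seed)
    return simulate_alignment(gt, omap, kappa, freqs, n_codons, rng)


@pytest.fixture(scope="session")
def random_codon_string(code):
    def _make(n_codons, seed):
        rng = np.random.default_rng(seed)
        return "".join(code.codons[i] for i in rng.integers(0, code.n_states, n_codons))

    return _make
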