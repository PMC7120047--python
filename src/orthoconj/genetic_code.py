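"""Genetic-code tables and the sense-codon state space.

The codon substitution machinery works on the set of *sense* codons (61
under the standard nuclear code): stop codons are excluded from the state
space, so every model state translates to exactly one amino acid.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from itertools import product

from Bio.Data import CodonTable

NUCLEOTIDES = "ACGT"
PURINES = frozenset("AG")
PYRIMIDINES = frozenset("CT")


def is_transition(a: str, b: str) -> bool:
    """True if the single-nucleotide change a->b is a transition."""
    return (a in PURINES and b in PURINES) or (a in PYRIMIDINES and b in PYRIMIDINES)


@dataclass(frozen=True)
class GeneticCode:
    """A codon -> amino-acid map restricted to sense codons.

    Parameters
    ----------
    table_id
        NCBI translation-table id (1 = standard nuclear code).

    Attributes
    ----------
    codons
        Sense codons in a fixed (alphabetical) order; this order defines
        the state indexing used by every rate and probability matrix.
    stop_codons
        Codons excluded from the state space.
    """

    table_id: int = 1
    codons: tuple[str, ...] = field(init=False)
    stop_codons: frozenset[str] = field(init=False)
    _aa: dict = field(init=False, repr=False)
    _index: dict = field(init=False, repr=False)

    def __post_init__(self) -> None:
        try:
            table = CodonTable.unambiguous_dna_by_id[self.table_id]
        except KeyError as exc:
            raise ValueError(f"unknown NCBI translation table id {self.table_id}") from exc
        stops = frozenset(table.stop_codons)
        aa = dict(table.forward_table)
        all_codons = ["".join(p) for p in product(NUCLEOTIDES, repeat=3)]
        sense = tuple(sorted(c for c in all_codons if c not in stops))
        if set(sense) != set(aa):
            raise ValueError(f"table {self.table_id}: sense/stop partition inconsistent")
        object.__setattr__(self, "codons", sense)
        object.__setattr__(self, "stop_codons", stops)
        object.__setattr__(self, "_aa", aa)
        object.__setattr__(self, "_index", {c: i for i, c in enumerate(sense)})

    @property
    def n_states(self) -> int:
        return len(self.codons)

    def translate(self, codon: str) -> str:
        return self._aa[codon]

    def is_stop(self, codon: str) -> bool:
        return codon in self.stop_codons

    def is_sense(self, codon: str) -> bool:
        return codon in self._index

    def index(self, codon: str) -> int:
        """State index of a sense codon; KeyError for stops/invalid codons."""
        return self._index[codon]

    def is_synonymous(self, codon_a: str, codon_b: str) -> bool:
        """True if two sense codons encode the same amino acid."""
        return self._aa[codon_a] == self._aa[codon_b]


@lru_cache(maxsize=8)
def standard_code(table_id: int = 1) -> GeneticCode:
    """Cached accessor for a GeneticCode by NCBI table id."""
    return GeneticCode(table_id)
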