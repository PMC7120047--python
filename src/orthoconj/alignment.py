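"""In-frame codon alignment container with FASTA I/O."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .genetic_code import GeneticCode, standard_code

MISSING = -1


@dataclass
class CodonAlignment:
    """Aligned in-frame coding sequences encoded as sense-codon indices.

    ``codes`` has shape (n_sequences, n_codon_columns); entries are state
    indices into ``code.codons`` or -1 for codons containing gaps or
    ambiguity characters (treated as fully missing downstream). Stop codons
    are also encoded as missing — curated CDS alignments should not contain
    them, and the state space excludes them.
    """

    names: list[str]
    codes: np.ndarray
    code: GeneticCode = field(default_factory=standard_code)

    def __post_init__(self) -> None:
        if len(self.names) != self.codes.shape[0]:
            raise ValueError("names/codes row mismatch")
        if len(set(self.names)) != len(self.names):
            raise ValueError("duplicate sequence names")

    @property
    def n_sequences(self) -> int:
        return self.codes.shape[0]

    @property
    def n_codons(self) -> int:
        return self.codes.shape[1]

    @classmethod
    def from_sequences(
        cls, named_seqs, code: GeneticCode | None = None
    ) -> "CodonAlignment":
        """Build from an iterable of (name, nucleotide-string) pairs."""
        code = code or standard_code()
        names, rows = [], []
        length = None
        for name, seq in named_seqs:
            s = str(seq).upper().replace("U", "T")
            if length is None:
                length = len(s)
                if length % 3:
                    raise ValueError(f"alignment length {length} not divisible by 3")
                if length == 0:
                    raise ValueError("zero-width alignment")
            elif len(s) != length:
                raise ValueError(f"sequence {name!r} length differs from alignment")
            row = np.full(length // 3, MISSING, dtype=np.int16)
            for k in range(0, length, 3):
                codon = s[k : k + 3]
                if code.is_sense(codon):
                    row[k // 3] = code.index(codon)
            names.append(name)
            rows.append(row)
        if not rows:
            raise ValueError("empty alignment")
        return cls(names, np.vstack(rows), code)

    @classmethod
    def from_fasta(cls, path: str, code: GeneticCode | None = None) -> "CodonAlignment":
        records = [(r.id, str(r.seq)) for r in SeqIO.parse(path, "fasta")]
        return cls.from_sequences(records, code)

    def to_fasta(self, path: str) -> None:
        records = [
            SeqRecord(Seq(self.sequence_string(i)), id=name, description="")
            for i, name in enumerate(self.names)
        ]
        SeqIO.write(records, path, "fasta")

    def sequence_string(self, row: int) -> str:
        return decode_codons(self.codes[row], self.code)

    def row_index(self) -> dict[str, int]:
        return {name: i for i, name in enumerate(self.names)}


def decode_codons(codes: np.ndarray, code: GeneticCode | None = None) -> str:
    """Decode a vector of state indices to a nucleotide string (gaps for -1)."""
    code = code or standard_code()
    return "".join(code.codons[c] if c >= 0 else "---" for c in codes)
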