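"""Counting-based synonymous/nonsynonymous machinery (Nei–Gojobori style).

Provides the mutational-opportunity site counts, pathway-averaged difference
counts between codon pairs, the Jukes–Cantor multiple-hit correction, and a
pairwise dN/dS estimator built from them. Used as a fast cross-check of the
likelihood-based branch estimates.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations
from math import log

from .genetic_code import GeneticCode, NUCLEOTIDES, standard_code

__all__ = [
    "SaturationError",
    "UnresolvablePairError",
    "count_sites",
    "count_differences",
    "jukes_cantor_correct",
    "pairwise_estimate",
    "PairwiseCounts",
]


class SaturationError(ValueError):
    """Observed difference proportion at or beyond the correctable limit (3/4)."""


class UnresolvablePairError(ValueError):
    """All minimal mutational pathways between two codons pass through a stop."""


def count_sites(sequence: str, code: GeneticCode | None = None) -> tuple[float, float]:
    """Nonsynonymous and synonymous site counts (N, S) of a codon sequence.

    Each codon position contributes (synonymous single-nucleotide mutants)/3
    synonymous sites; mutants that create stop codons count as nonsynonymous,
    so N + S = 3 × (number of codons) exactly.
    """
    code = code or standard_code()
    seq = str(sequence).upper().replace("U", "T")
    if len(seq) % 3:
        raise ValueError(f"sequence length {len(seq)} not divisible by 3")
    s_total = 0.0
    n_codons = 0
    for k in range(0, len(seq), 3):
        codon = seq[k : k + 3]
        if code.is_stop(codon):
            raise ValueError(f"stop codon {codon} at position {k}")
        if not code.is_sense(codon):
            raise ValueError(f"invalid codon {codon!r} at position {k}")
        n_codons += 1
        for pos in range(3):
            syn = sum(
                1
                for nt in NUCLEOTIDES
                if nt != codon[pos]
                and code.is_sense(m := codon[:pos] + nt + codon[pos + 1 :])
                and code.is_synonymous(codon, m)
            )
            s_total += syn / 3.0
    return 3.0 * n_codons - s_total, s_total


def count_differences(
    codon_a: str, codon_b: str, code: GeneticCode | None = None
) -> tuple[float, float]:
    """Pathway-averaged (N_diff, S_diff) between two sense codons.

    Changes are counted along every minimal single-step mutational pathway
    between the codons; pathways passing through a stop codon are excluded
    and the remainder averaged with equal weight. N_diff + S_diff equals the
    number of differing positions.
    """
    code = code or standard_code()
    a, b = str(codon_a).upper(), str(codon_b).upper()
    for c in (a, b):
        if not code.is_sense(c):
            raise ValueError(f"{c!r} is not a sense codon")
    diff_positions = [p for p in range(3) if a[p] != b[p]]
    if not diff_positions:
        return 0.0, 0.0
    path_counts = []
    for order in permutations(diff_positions):
        current = a
        n_d = s_d = 0
        ok = True
        for pos in order:
            nxt = current[:pos] + b[pos] + current[pos + 1 :]
            if code.is_stop(nxt):
                ok = False
                break
            if code.is_synonymous(current, nxt):
                s_d += 1
            else:
                n_d += 1
            current = nxt
        if ok:
            path_counts.append((n_d, s_d))
    if not path_counts:
        raise UnresolvablePairError(f"all pathways {a}->{b} traverse a stop codon")
    n_mean = sum(p[0] for p in path_counts) / len(path_counts)
    s_mean = sum(p[1] for p in path_counts) / len(path_counts)
    return n_mean, s_mean


def jukes_cantor_correct(p: float) -> float:
    """Jukes–Cantor distance d = -(3/4)·ln(1 - 4p/3) for 0 <= p < 3/4."""
    if p < 0:
        raise ValueError(f"proportion must be non-negative, got {p}")
    if p >= 0.75:
        raise SaturationError(f"proportion {p} at or beyond saturation (3/4)")
    return -0.75 * log(1.0 - 4.0 * p / 3.0)


@dataclass(frozen=True)
class PairwiseCounts:
    """Counting-estimator summary for one sequence pair."""

    N_sites: float
    S_sites: float
    N_diff: float
    S_diff: float
    dN: float | None
    dS: float | None
    omega: float | None
    saturated: bool
    n_codons_used: int


def pairwise_estimate(
    seq_a: str, seq_b: str, code: GeneticCode | None = None
) -> PairwiseCounts:
    """Counting-based dN/dS between two aligned in-frame sequences.

    Codon columns where either sequence carries a gap, ambiguity code or stop
    are skipped pairwise; unresolvable codon pairs (all pathways through a
    stop) are likewise skipped. Sites are averaged between the two sequences,
    differences summed, and proportions Jukes–Cantor corrected. Saturated
    proportions (>= 3/4) yield ``dN``/``dS``/``omega`` of None with
    ``saturated`` set; dS = 0 yields omega None.
    """
    code = code or standard_code()
    a = str(seq_a).upper().replace("U", "T")
    b = str(seq_b).upper().replace("U", "T")
    if len(a) != len(b):
        raise ValueError("sequences must be aligned (equal lengths)")
    if len(a) % 3:
        raise ValueError("alignment length not divisible by 3")
    n_sites = s_sites = n_diff = s_diff = 0.0
    used = 0
    for k in range(0, len(a), 3):
        ca, cb = a[k : k + 3], b[k : k + 3]
        if not (code.is_sense(ca) and code.is_sense(cb)):
            continue
        try:
            nd, sd = count_differences(ca, cb, code)
        except UnresolvablePairError:
            continue
        na, sa = count_sites(ca, code)
        nb, sb = count_sites(cb, code)
        n_sites += (na + nb) / 2.0
        s_sites += (sa + sb) / 2.0
        n_diff += nd
        s_diff += sd
        used += 1
    if used == 0:
        raise ValueError("no comparable codon columns")
    try:
        dn = jukes_cantor_correct(n_diff / n_sites) if n_sites > 0 else None
        ds = jukes_cantor_correct(s_diff / s_sites) if s_sites > 0 else None
        saturated = False
    except SaturationError:
        dn = ds = None
        saturated = True
    omega = dn / ds if (dn is not None and ds is not None and ds > 0) else None
    return PairwiseCounts(n_sites, s_sites, n_diff, s_diff, dn, ds, omega, saturated, used)
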