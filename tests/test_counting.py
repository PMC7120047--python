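"""Counting machinery vs independent brute-force enumeration."""

import math
from itertools import permutations, product

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from orthoconj.counting import (
    SaturationError,
    count_differences,
    count_sites,
    jukes_cantor_correct,
    pairwise_estimate,
)
from orthoconj.genetic_code import standard_code

CODE = standard_code()


# -- independent oracles (deliberately naive re-derivations) ----------------
def oracle_sites(codon):
    s = 0.0
    for pos, base in enumerate(codon):
        for nt in "ACGT":
            if nt == base:
                continue
            mut = codon[:pos] + nt + codon[pos + 1 :]
            if mut not in CODE.stop_codons and CODE.translate(mut) == CODE.translate(codon):
                s += 1 / 3
    return 3 - s, s


def oracle_differences(a, b):
    positions = [p for p in range(3) if a[p] != b[p]]
    results = []
    for order in permutations(positions):
        cur, nd, sd, ok = a, 0, 0, True
        for p in order:
            nxt = cur[:p] + b[p] + cur[p + 1 :]
            if nxt in CODE.stop_codons:
                ok = False
                break
            if CODE.translate(cur) == CODE.translate(nxt):
                sd += 1
            else:
                nd += 1
            cur = nxt
        if ok:
            results.append((nd, sd))
    if not results:
        return None
    return (
        sum(r[0] for r in results) / len(results),
        sum(r[1] for r in results) / len(results),
    )


def test_count_sites_examples():
    n, s = count_sites("TTT")
    assert math.isclose(s, 1 / 3) and math.isclose(n, 8 / 3)
    assert count_sites("") == (0.0, 0.0)


def test_count_sites_matches_oracle_on_all_sense_codons():
    for codon in CODE.codons:
        assert count_sites(codon) == pytest.approx(oracle_sites(codon), abs=1e-12)


def test_count_sites_rejects_bad_input():
    with pytest.raises(ValueError):
        count_sites("TTTA")
    with pytest.raises(ValueError):
        count_sites("TAA")


def test_count_differences_examples():
    assert count_differences("TTT", "TTT") == (0.0, 0.0)
    assert count_differences("TTT", "TTC") == (0.0, 1.0)
    assert count_differences("TTT", "GTA") == (1.5, 0.5)


def test_count_differences_matches_pathway_oracle_on_random_pairs():
    rng = np.random.default_rng(42)
    for _ in range(500):
        a, b = (CODE.codons[i] for i in rng.integers(0, 61, 2))
        expected = oracle_differences(a, b)
        nd, sd = count_differences(a, b)
        assert (nd, sd) == pytest.approx(expected, abs=1e-12)
        n_pos = sum(x != y for x, y in zip(a, b))
        assert nd + sd == pytest.approx(n_pos)


def test_count_differences_rejects_stop_codons():
    with pytest.raises(ValueError):
        count_differences("TAA", "TTT")


def test_jukes_cantor():
    assert jukes_cantor_correct(0.0) == 0.0
    assert jukes_cantor_correct(0.3) == pytest.approx(-0.75 * math.log(0.6))
    with pytest.raises(SaturationError):
        jukes_cantor_correct(0.75)
    with pytest.raises(ValueError):
        jukes_cantor_correct(-0.01)


@settings(deadline=None, max_examples=30, derandomize=True)
@given(st.lists(st.sampled_from(CODE.codons), min_size=0, max_size=30))
def test_sites_sum_to_three_per_codon(codons):
    n, s = count_sites("".join(codons))
    assert n + s == pytest.approx(3 * len(codons))


def test_pairwise_estimate_single_synonymous_transition():
    est = pairwise_estimate("TTT", "TTC")
    assert est.S_diff == 1.0 and est.N_diff == 0.0
    # one codon cannot support a corrected rate (p_S = 3 >= 3/4): saturated
    assert est.saturated and est.omega is None
    # in a longer context the same single change gives dN = 0, dS > 0
    est10 = pairwise_estimate("TTT" * 10, "TTC" + "TTT" * 9)
    assert est10.S_diff == 1.0 and est10.N_diff == 0.0
    assert est10.dN == 0.0 and est10.dS > 0 and est10.omega == 0.0


def test_pairwise_estimate_identical_sequences_has_undefined_omega():
    est = pairwise_estimate("TTTGGA", "TTTGGA")
    assert est.dN == 0.0 and est.dS == 0.0
    assert est.omega is None and not est.saturated


def test_pairwise_estimate_skips_gapped_columns():
    est = pairwise_estimate("TTT---GGA", "TTTAAAGGA")
    assert est.n_codons_used == 2
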