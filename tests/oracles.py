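"""Independent brute-force oracles for the NG86 machinery.

Deliberately written against Biopython's translation tables and plain
itertools enumeration, sharing no code with the package implementation:
these stay the reference the fast path is checked against.
"""

from __future__ import annotations

import itertools

from Bio.Data.CodonTable import unambiguous_dna_by_id

NUCLEOTIDES = "ACGT"


def _aa(codon: str, code: int = 1) -> str | None:
    """Residue for a codon, None for a stop."""
    table = unambiguous_dna_by_id[code]
    if codon in table.stop_codons:
        return None
    return table.forward_table[codon]


def site_counts_oracle(codon: str, code: int = 1) -> tuple[float, float]:
    """Enumerate all 9 single-nucleotide mutants; stop mutants are
    nonsynonymous so the fractions sum to exactly 3."""
    ref = _aa(codon, code)
    assert ref is not None
    syn = 0
    for pos, alt in itertools.product(range(3), NUCLEOTIDES):
        if alt == codon[pos]:
            continue
        mutant = codon[:pos] + alt + codon[pos + 1:]
        if _aa(mutant, code) == ref:
            syn += 1
    return syn / 3.0, 3.0 - syn / 3.0


def path_differences_oracle(a: str, b: str, code: int = 1) -> tuple[float, float] | None:
    """Average syn/nonsyn step counts over all k! single-step orderings
    from codon a to codon b, discarding orderings that visit a stop.
    Returns None when every ordering is blocked."""
    positions = [i for i in range(3) if a[i] != b[i]]
    if not positions:
        return (0.0, 0.0)
    outcomes = []
    for order in itertools.permutations(positions):
        codon = a
        steps = []
        for pos in order:
            nxt = codon[:pos] + b[pos] + codon[pos + 1:]
            if _aa(nxt, code) is None:
                steps = None
                break
            steps.append(_aa(nxt, code) == _aa(codon, code))
            codon = nxt
        if steps is not None:
            outcomes.append((sum(steps), len(steps) - sum(steps)))
    if not outcomes:
        return None
    n = len(outcomes)
    return (sum(s for s, _ in outcomes) / n, sum(ns for _, ns in outcomes) / n)


def ng86_pair_oracle(codons_a: list[str], codons_b: list[str], code: int = 1):
    """Whole-pair NG86 counts from the two oracles above, skipping
    columns with gaps/N/stops or fully blocked pathways.

    Returns (S, N, Sd, Nd)."""
    table = unambiguous_dna_by_id[code]
    S = N = Sd = Nd = 0.0
    for x, y in zip(codons_a, codons_b):
        if any(c not in NUCLEOTIDES for c in x + y):
            continue
        if x in table.stop_codons or y in table.stop_codons:
            continue
        d = path_differences_oracle(x, y, code)
        if d is None:
            continue
        sx, nx = site_counts_oracle(x, code)
        sy, ny = site_counts_oracle(y, code)
        S += (sx + sy) / 2
        N += (nx + ny) / 2
        Sd += d[0]
        Nd += d[1]
    return S, N, Sd, Nd
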