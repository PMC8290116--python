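"""Independent reference computations used by the test suite.

These deliberately share no code with the package: degeneracy classes are
brute-forced over the Biopython codon table and the Kimura/Li formulas are
evaluated directly.
"""

import math

from Bio.Data.CodonTable import standard_dna_table

_FW = dict(standard_dna_table.forward_table)
for _s in standard_dna_table.stop_codons:
    _FW[_s] = "*"
_BASES = "ACGT"
_PURINES = {"A", "G"}


def oracle_degeneracy(codon):
    out = []
    for pos in range(3):
        aa = _FW[codon]
        n = sum(
            1
            for b in _BASES
            if b != codon[pos] and _FW[codon[:pos] + b + codon[pos + 1:]] == aa
        )
        out.append(4 if n == 3 else (0 if n == 0 else 2))
    return out


def oracle_kaks_single_diffs(ref, copy):
    """Li-1993 by direct evaluation; valid when codons differ at <=1 position."""
    L = {0: 0.0, 2: 0.0, 4: 0.0}
    S = {0: 0.0, 2: 0.0, 4: 0.0}
    V = {0: 0.0, 2: 0.0, 4: 0.0}
    for i in range(len(ref) // 3):
        c1, c2 = ref[3 * i: 3 * i + 3], copy[3 * i: 3 * i + 3]
        assert sum(a != b for a, b in zip(c1, c2)) <= 1
        d1, d2 = oracle_degeneracy(c1), oracle_degeneracy(c2)
        for pos in range(3):
            L[d1[pos]] += 0.5
            L[d2[pos]] += 0.5
            if c1[pos] != c2[pos]:
                kind = S if (c1[pos] in _PURINES) == (c2[pos] in _PURINES) else V
                kind[d1[pos]] += 0.5
                kind[d2[pos]] += 0.5
    A, B = {}, {}
    for cls in (0, 2, 4):
        P, Q = S[cls] / L[cls], V[cls] / L[cls]
        A[cls] = 0.5 * math.log(1 / (1 - 2 * P - Q)) - 0.25 * math.log(1 / (1 - 2 * Q))
        B[cls] = 0.5 * math.log(1 / (1 - 2 * Q))
    ks = (L[2] * A[2] + L[4] * A[4]) / (L[2] + L[4]) + B[4]
    ka = A[0] + (L[0] * B[0] + L[2] * B[2]) / (L[0] + L[2])
    return ka, ks
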