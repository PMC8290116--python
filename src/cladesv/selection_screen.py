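"""Pseudogenization screen over exon-copy alignments.

Each putative exon copy, aligned against the reference exon, is trimmed to
the reference frame, subjected to two hygiene rules (a run of >=10 Ns, or a
frame-shifting gap pattern, excludes the copy), scanned for internal stop
codons, and compared to the reference by Li's (1993) pairwise Ka/Ks.

Li's method partitions codon sites into nondegenerate (0-fold), twofold
and fourfold degenerate classes, tallies transitional and transversional
differences per class (averaging uniformly over minimal substitution
pathways for multi-hit codons, and half-counting a site whose class
differs between the two sequences), applies Kimura two-parameter
corrections per class (A_i for transitions, B_i for transversions), and
combines:

    Ks = (L2*A2 + L4*A4) / (L2 + L4) + B4
    Ka = A0 + (L0*B0 + L2*B2) / (L0 + L2)
"""

from __future__ import annotations

import math
import re
import warnings
from dataclasses import dataclass, field
from itertools import permutations
from typing import Dict, List, Optional, Tuple

__all__ = [
    "CodonAlignment",
    "KaKsResult",
    "prepare_copy",
    "scan_stop_codons",
    "kaks_li93",
    "STOP_CODONS",
    "codon_degeneracy",
]

STOP_CODONS = {"TAA", "TAG", "TGA"}

_CODON_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}

_BASES = "ACGT"
_PURINES = {"A", "G"}


@dataclass
class CodonAlignment:
    """Frame-anchored pairwise alignment of an exon copy vs the reference.

    ``ref`` and ``copy`` are equal-length strings over ACGTN- with the
    reference frame starting at column 0 (after trimming); reference-gap
    columns (insertions in the copy) have been removed, so every column
    index maps to a reference coordinate.
    """

    ref: str
    copy: str
    gene: str = ""
    exon: str = ""
    copy_id: str = ""
    final_exon: bool = False
    excluded_reason: Optional[str] = None


@dataclass
class KaKsResult:
    L0: float
    L2: float
    L4: float
    A0: float
    A2: float
    A4: float
    B0: float
    B2: float
    B4: float
    Ka: Optional[float]
    Ks: Optional[float]
    ratio: Optional[float]
    n_codons: int = 0


def codon_degeneracy(codon: str) -> Tuple[int, int, int]:
    """Degeneracy class (0, 2 or 4) of each position of a sense codon.

    A position is 4-fold when every nucleotide change is synonymous,
    0-fold when none is, and 2-fold otherwise (Li's convention: the
    3-fold isoleucine site counts as 2-fold).
    """
    aa = _CODON_TABLE[codon]
    classes = []
    for pos in range(3):
        n_syn = sum(
            1
            for b in _BASES
            if b != codon[pos] and _CODON_TABLE[codon[:pos] + b + codon[pos + 1:]] == aa
        )
        classes.append(4 if n_syn == 3 else (0 if n_syn == 0 else 2))
    return tuple(classes)


def _is_transition(a: str, b: str) -> bool:
    return (a in _PURINES) == (b in _PURINES)


def prepare_copy(
    copy_seq: str,
    ref_seq: str,
    gene: str = "",
    exon: str = "",
    copy_id: str = "",
    final_exon: bool = False,
    max_n_run: int = 10,
) -> CodonAlignment:
    """Trim an aligned copy to the reference frame and apply exclusion rules.

    Columns before the reference's first base and after its last are
    removed (they may be artifacts of coordinate extension).  A copy whose
    ungapped sequence contains a run of ``max_n_run`` or more Ns is
    excluded (``n_run``); a copy whose gap pattern shifts the reference
    frame — any insertion or deletion of length not a multiple of three —
    is excluded (``frameshift``).  Reference-gap columns are removed after
    the frameshift check so that columns index reference coordinates.
    """
    if len(copy_seq) != len(ref_seq):
        raise ValueError("aligned sequences differ in length")
    copy_seq = copy_seq.upper()
    ref_seq = ref_seq.upper()
    first = len(ref_seq) - len(ref_seq.lstrip("-"))
    last = len(ref_seq.rstrip("-"))
    ref_t, copy_t = ref_seq[first:last], copy_seq[first:last]
    if not ref_t or "-" in (ref_t[0], ref_t[-1]):
        raise ValueError("reference has gaps at the frame anchor after trimming")

    aln = CodonAlignment(ref="", copy="", gene=gene, exon=exon, copy_id=copy_id, final_exon=final_exon)

    if re.search("N" * max_n_run, copy_t.replace("-", "")):
        aln.excluded_reason = "n_run"
        return aln

    for run in re.finditer(r"-+", ref_t):  # insertions in the copy
        if run.end() - run.start() != 0 and (run.end() - run.start()) % 3 != 0:
            aln.excluded_reason = "frameshift"
            return aln
    for run in re.finditer(r"-+", copy_t):  # deletions in the copy
        if (run.end() - run.start()) % 3 != 0:
            aln.excluded_reason = "frameshift"
            return aln

    cols = [(r, c) for r, c in zip(ref_t, copy_t) if r != "-"]
    n_codons = len(cols) // 3
    cols = cols[: n_codons * 3]  # trim a trailing partial codon
    aln.ref = "".join(r for r, _ in cols)
    aln.copy = "".join(c for _, c in cols)
    return aln


def scan_stop_codons(alignment: CodonAlignment) -> Tuple[int, List[int]]:
    """Count internal stop codons of the copy, read in the reference frame.

    Codons containing gaps or ambiguous bases are skipped.  The terminal
    stop is exempt only when the exon is annotated as the final coding
    exon.  Returns (count, codon indices).
    """
    positions = []
    seq = alignment.copy
    n_codons = len(seq) // 3
    for i in range(n_codons):
        codon = seq[3 * i: 3 * i + 3]
        if set(codon) - set(_BASES):
            continue
        if codon in STOP_CODONS:
            if alignment.final_exon and i == n_codons - 1:
                continue
            positions.append(i)
    return len(positions), positions


def _pathway_steps(c1: str, c2: str) -> List[List[Tuple[str, str, str]]]:
    """Minimal substitution pathways between two codons.

    Each pathway is a list of steps (codon_before, codon_after, position);
    pathways passing through a stop codon are discarded unless all do.
    """
    diff = [i for i in range(3) if c1[i] != c2[i]]
    pathways = []
    for order in permutations(diff):
        cur = c1
        steps = []
        ok = True
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
            steps.append((cur, nxt, pos))
            if nxt in STOP_CODONS and nxt != c2:
                ok = False
            cur = nxt
        pathways.append((ok, steps))
    valid = [s for ok, s in pathways if ok]
    return valid if valid else [s for _, s in pathways]


def kaks_li93(alignment: CodonAlignment, return_counts: bool = False) -> KaKsResult:
    """Pairwise Ka/Ks by Li's (1993) method.

    Only codon columns in which both sequences are gap-free and
    unambiguous are compared.  Saturated per-class distances (a
    non-positive logarithm argument in the Kimura correction) yield
    missing Ka/Ks with a warning rather than an exception.  The statistic
    is symmetric in its two sequences.
    """
    L = {0: 0.0, 2: 0.0, 4: 0.0}   # site counts, averaged over the two sequences
    S = {0: 0.0, 2: 0.0, 4: 0.0}   # transitional differences per class
    V = {0: 0.0, 2: 0.0, 4: 0.0}   # transversional differences per class
    n_codons = 0
    for i in range(len(alignment.ref) // 3):
        c1 = alignment.ref[3 * i: 3 * i + 3]
        c2 = alignment.copy[3 * i: 3 * i + 3]
        if (set(c1) | set(c2)) - set(_BASES):
            continue
        if c1 in STOP_CODONS or c2 in STOP_CODONS:
            continue
        n_codons += 1
        deg1, deg2 = codon_degeneracy(c1), codon_degeneracy(c2)
        for pos in range(3):
            L[deg1[pos]] += 0.5
            L[deg2[pos]] += 0.5
        if c1 == c2:
            continue
        pathways = _pathway_steps(c1, c2)
        w = 1.0 / len(pathways)
        for steps in pathways:
            for before, after, pos in steps:
                if before in STOP_CODONS or after in STOP_CODONS:
                    # degeneracy undefined for stops; classify by the sense codon
                    sense = before if before not in STOP_CODONS else after
                    classes = (codon_degeneracy(sense)[pos],) * 2
                else:
                    classes = (codon_degeneracy(before)[pos], codon_degeneracy(after)[pos])
                kind = S if _is_transition(before[pos], after[pos]) else V
                for cls in classes:
                    kind[cls] += 0.5 * w

    A: Dict[int, float] = {}
    B: Dict[int, float] = {}
    saturated = False
    for cls in (0, 2, 4):
        if L[cls] > 0:
            P = S[cls] / L[cls]
            Q = V[cls] / L[cls]
        else:
            P = Q = 0.0
        arg_a = 1.0 - 2.0 * P - Q
        arg_b = 1.0 - 2.0 * Q
        if arg_a <= 0 or arg_b <= 0:
            saturated = True
            A[cls] = B[cls] = math.nan
            continue
        A[cls] = 0.5 * math.log(1.0 / arg_a) - 0.25 * math.log(1.0 / arg_b)
        B[cls] = 0.5 * math.log(1.0 / arg_b)

    if saturated:
        warnings.warn("saturated Kimura distance; Ka/Ks reported as missing")
        Ka = Ks = ratio = None
    else:
        Ks = (L[2] * A[2] + L[4] * A[4]) / (L[2] + L[4]) + B[4] if (L[2] + L[4]) > 0 else None
        Ka = A[0] + (L[0] * B[0] + L[2] * B[2]) / (L[0] + L[2]) if (L[0] + L[2]) > 0 else None
        ratio = Ka / Ks if (Ka is not None and Ks is not None and Ks > 0) else None
    return KaKsResult(
        L0=L[0], L2=L[2], L4=L[4],
        A0=A.get(0, math.nan), A2=A.get(2, math.nan), A4=A.get(4, math.nan),
        B0=B.get(0, math.nan), B2=B.get(2, math.nan), B4=B.get(4, math.nan),
        Ka=Ka, Ks=Ks, ratio=ratio, n_codons=n_codons,
    )
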