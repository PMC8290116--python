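"""Synthetic genomes, alignments, coverage, site patterns and codon data.

Every input the pipeline consumes can be generated here, with planted
truth, so all stages are testable without any external dataset.  All
generators are pure functions of (config, seed): the same seed always
reproduces the same output.

The default study conditions: two clades of species whose genomes differ
by a configurable set of inversions (50 kb – 2 Mb) on a desk-scale
reference of 4 chromosomes × 5 Mb; draft-like scaffold fragmentation in
the 20–150 kb range (the scale of short-read draft assemblies); deep
short-read coverage (60× base depth, 250-bp reads) summarized in 25-kb
windows; and four-taxon site patterns with symmetric discordance
(E[D] = 0) outside planted introgressed tracts.

Coordinate-only simulation is the default for the inversion path: PAF
records are emitted directly from the fragmentation geometry, with no
sequence materialized.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .alignment_io import AlignmentRecord
from .selection_screen import STOP_CODONS, _CODON_TABLE, codon_degeneracy

__all__ = [
    "TruthTable",
    "CladeMap",
    "Fragment",
    "PafNoise",
    "make_clade_genomes",
    "fragment_scaffolds",
    "emit_truth_paf",
    "simulate_coverage",
    "simulate_sites",
    "make_reference_cds",
    "mutate_codons",
    "evolve_codon_pair",
    "DEFAULT_CHROMOSOMES",
]

#: desk-scale default genome: accommodates 50 kb – 2 Mb inversions and the
#: 50-kb boundary rule without rescaling
DEFAULT_CHROMOSOMES: Dict[str, int] = {
    "chr1": 5_000_000,
    "chr2": 5_000_000,
    "chr3": 5_000_000,
    "chr4": 5_000_000,
}


@dataclass
class TruthTable:
    """Planted truth accompanying every generated dataset."""

    inversions: List[dict] = field(default_factory=list)
    amplifications: List[dict] = field(default_factory=list)
    tracts: List[dict] = field(default_factory=list)
    codon_edits: List[dict] = field(default_factory=list)
    fragmentation: List["Fragment"] = field(default_factory=list)
    seeds: Dict[str, int] = field(default_factory=dict)


@dataclass
class CladeMap:
    """Two clade coordinate systems differing by planted rearrangements.

    Clade-B coordinates equal clade-A coordinates except that each planted
    inversion interval is strand-flipped in place (an involution: applying
    the plan twice restores clade A).  Optional translocation decoys move
    a clade-B segment to a different reference location on the forward
    strand.
    """

    chromosomes: Dict[str, int]
    inversions: List[Tuple[str, int, int]] = field(default_factory=list)
    translocations: List[Tuple[str, int, int, str, int]] = field(default_factory=list)

    def __post_init__(self):
        by_chrom: Dict[str, List[Tuple[int, int]]] = {}
        for chrom, start, end in self.inversions:
            if chrom not in self.chromosomes:
                raise ValueError(f"inversion on unknown chromosome {chrom}")
            if not 0 <= start < end <= self.chromosomes[chrom]:
                raise ValueError(f"inversion [{start},{end}) outside {chrom}")
            by_chrom.setdefault(chrom, []).append((start, end))
        for chrom, ivals in by_chrom.items():
            ivals.sort()
            for (s1, e1), (s2, e2) in zip(ivals, ivals[1:]):
                if s2 < e1:
                    raise ValueError(f"overlapping planted inversions on {chrom}")

    def map_interval(self, chrom: str, start: int, end: int) -> List[Tuple[str, int, int, str]]:
        """Map a clade-B interval onto clade-A (reference) coordinates.

        Returns maximal collinear pieces in clade-B order, each as
        (ref_chrom, ref_start, ref_end, strand).
        """
        events: List[Tuple[int, int, str]] = []  # (start, end, kind-index)
        inv = sorted((s, e) for c, s, e in self.inversions if c == chrom)
        trans = sorted((s, e, dc, ds) for c, s, e, dc, ds in self.translocations if c == chrom)
        cuts = {start, end}
        for s, e in inv:
            cuts.update(x for x in (s, e) if start < x < end)
        for s, e, _, _ in trans:
            cuts.update(x for x in (s, e) if start < x < end)
        bounds = sorted(cuts)
        pieces = []
        for s, e in zip(bounds, bounds[1:]):
            placed = False
            for a, b in inv:
                if a <= s and e <= b:
                    pieces.append((chrom, a + b - e, a + b - s, "-"))
                    placed = True
                    break
            if placed:
                continue
            for a, b, dest_chrom, dest_start in trans:
                if a <= s and e <= b:
                    pieces.append((dest_chrom, dest_start + (s - a), dest_start + (e - a), "+"))
                    placed = True
                    break
            if not placed:
                pieces.append((chrom, s, e, "+"))
        return pieces


def make_clade_genomes(
    chromosomes: Optional[Dict[str, int]] = None,
    inversions: Sequence[Tuple[str, int, int]] = (),
    translocations: Sequence[Tuple[str, int, int, str, int]] = (),
    derived_clade: str = "B",
    seed: int = 0,
) -> Tuple[CladeMap, TruthTable]:
    """Two clade reference coordinate systems plus the planted truth.

    Overlapping planted inversions raise an error.  With an empty plan the
    two coordinate systems are identical.
    """
    chroms = dict(chromosomes or DEFAULT_CHROMOSOMES)
    clade_map = CladeMap(chroms, list(inversions), list(translocations))
    truth = TruthTable(seeds={"genomes": seed})
    for chrom, start, end in inversions:
        truth.inversions.append(
            {"chrom": chrom, "start": start, "end": end, "length": end - start, "derived_clade": derived_clade}
        )
    for chrom, start, end, dchrom, dstart in translocations:
        truth.tracts.append(
            {"kind": "translocation", "chrom": chrom, "start": start, "end": end,
             "dest_chrom": dchrom, "dest_start": dstart}
        )
    return clade_map, truth


@dataclass
class Fragment:
    """One draft scaffold: a contiguous source interval of a species genome."""

    scaffold: str
    species: str
    chrom: str
    start: int
    end: int
    reversed: bool = False  # scaffold stored in reverse-complement orientation

    @property
    def length(self) -> int:
        return self.end - self.start


def fragment_scaffolds(
    chromosomes: Dict[str, int],
    species: str,
    seed: int,
    length_range: Tuple[int, int] = (20_000, 150_000),
    span_breakpoints: Optional[Sequence[Tuple[str, int]]] = None,
    min_flank: int = 10_000,
    random_orientation: bool = True,
) -> List[Fragment]:
    """Tile each chromosome with random-length fragments (no gaps/overlaps).

    With ``span_breakpoints`` set, any fragment boundary falling within
    ``min_flank`` of a required breakpoint is removed (merging the two
    fragments), so at least one fragment spans each breakpoint with
    ``min_flank`` of sequence on both sides.  Concatenating fragments in
    map order restores the source chromosome.
    """
    rng = np.random.default_rng(seed)
    lo, hi = length_range
    if lo <= 0 or hi < lo:
        raise ValueError("bad fragment length range")
    fragments: List[Fragment] = []
    required = {}
    for chrom, pos in span_breakpoints or []:
        required.setdefault(chrom, []).append(pos)
    for chrom in sorted(chromosomes):
        length = chromosomes[chrom]
        cuts = []
        pos = 0
        while pos < length:
            pos += int(rng.integers(lo, hi + 1))
            if pos < length:
                cuts.append(pos)
        for bp in required.get(chrom, []):
            cuts = [c for c in cuts if not (bp - min_flank < c < bp + min_flank)]
        bounds = [0] + cuts + [length]
        for i, (s, e) in enumerate(zip(bounds, bounds[1:])):
            fragments.append(
                Fragment(
                    scaffold=f"{species}_{chrom}_f{i:04d}",
                    species=species,
                    chrom=chrom,
                    start=s,
                    end=e,
                    reversed=bool(rng.random() < 0.5) if random_orientation else False,
                )
            )
    return fragments


@dataclass
class PafNoise:
    """Tag/quality noise applied to emitted truth alignments."""

    dv_range: Tuple[float, float] = (0.01, 0.10)
    mapq: int = 60
    low_mapq_frac: float = 0.0
    low_mapq_value: int = 40
    secondary_frac: float = 0.0


def emit_truth_paf(
    fragments: Sequence[Fragment],
    clade_map: CladeMap,
    seed: int = 0,
    noise: Optional[PafNoise] = None,
    collinear: bool = False,
) -> List[AlignmentRecord]:
    """PAF records reflecting each scaffold's true source intervals.

    A fragment of a derived-clade (clade-B) genome splits at inversion
    breakpoints into collinear pieces with strand flips; ``collinear=True``
    emits the fragment's clade-A identity mapping instead (for species
    carrying the reference arrangement, e.g. the outgroup).
    """
    rng = np.random.default_rng(seed)
    noise = noise or PafNoise()
    records: List[AlignmentRecord] = []
    for frag in fragments:
        if collinear:
            pieces = [(frag.chrom, frag.start, frag.end, "+")]
        else:
            pieces = clade_map.map_interval(frag.chrom, frag.start, frag.end)
        offset = 0
        for ref_chrom, ref_start, ref_end, strand in pieces:
            span = ref_end - ref_start
            q_start, q_end = offset, offset + span
            if frag.reversed:
                q_start, q_end = frag.length - q_end, frag.length - q_start
                strand = "-" if strand == "+" else "+"
            dv = float(rng.uniform(*noise.dv_range))
            mapq = noise.mapq
            if noise.low_mapq_frac > 0 and rng.random() < noise.low_mapq_frac:
                mapq = noise.low_mapq_value
            tp = "P"
            if noise.secondary_frac > 0 and rng.random() < noise.secondary_frac:
                tp = "S"
            rec = AlignmentRecord(
                query_name=frag.scaffold,
                query_len=frag.length,
                query_start=q_start,
                query_end=q_end,
                strand=strand,
                target_name=ref_chrom,
                target_len=clade_map.chromosomes[ref_chrom],
                target_start=ref_start,
                target_end=ref_end,
                residue_matches=max(1, int(span * (1 - dv))),
                block_len=span,
                mapq=mapq,
                tags={"tp": tp, "dv": round(dv, 4)},
                tag_types={"tp": "A", "dv": "f"},
            )
            records.append(rec)
            offset += span
    return records


def simulate_coverage(
    species: Sequence[str],
    chromosomes: Optional[Dict[str, int]] = None,
    amplifications: Sequence[dict] = (),
    seed: int = 0,
    base_depth: float = 60.0,
    window_size: int = 25_000,
    read_length: int = 250,
    dispersion: Optional[float] = None,
) -> Tuple[pd.DataFrame, TruthTable]:
    """Per-species window depth tables with planted fold amplifications.

    Each amplification is ``{"chrom", "start", "end", "fold", "species"}``
    (``species`` a collection).  Window depth is the depth implied by a
    Poisson read count at the window's expected coverage (reads of
    ``read_length`` bases), i.e. mean depth with sampling noise at the
    scale short-read data actually shows in 25-kb windows.  With
    ``dispersion=0`` depths are deterministic; a positive value switches
    to a negative binomial on the read count with that dispersion
    (var = mu + dispersion * mu^2).
    """
    chroms = dict(chromosomes or DEFAULT_CHROMOSOMES)
    rng = np.random.default_rng(seed)
    truth = TruthTable(seeds={"coverage": seed})
    for amp in amplifications:
        truth.amplifications.append(dict(amp))
    rows = []
    for sp in species:
        for chrom in sorted(chroms):
            length = chroms[chrom]
            starts = np.arange(0, length, window_size)
            for ws in starts:
                we = min(ws + window_size, length)
                fold = 1.0
                for amp in amplifications:
                    if (
                        sp in amp["species"]
                        and amp["chrom"] == chrom
                        and ws < amp["end"]
                        and we > amp["start"]
                    ):
                        fold = float(amp["fold"])
                        break
                mu_reads = base_depth * fold * (we - ws) / read_length
                if dispersion == 0:
                    n_reads = mu_reads
                elif dispersion:
                    # NB with var = mu + d*mu^2
                    p = 1.0 / (1.0 + dispersion * mu_reads)
                    n = mu_reads * p / (1.0 - p)
                    n_reads = rng.negative_binomial(n, p)
                else:
                    n_reads = rng.poisson(mu_reads)
                depth = n_reads * read_length / (we - ws)
                rows.append({"species": sp, "chrom": chrom, "start": int(ws), "end": int(we), "depth": depth})
    return pd.DataFrame(rows), truth


def simulate_sites(
    chromosomes: Optional[Dict[str, int]] = None,
    sites_per_mb: float = 2_000.0,
    tracts: Sequence[dict] = (),
    seed: int = 0,
    ils_frac: float = 0.30,
    internal_frac: float = 0.10,
    outgroup_poly_frac: float = 0.0,
) -> Tuple[pd.DataFrame, TruthTable]:
    """Four-taxon site-frequency table with optional introgressed tracts.

    Outside tracts, derived alleles arise on terminal branches or as
    discordant ABBA/BABA patterns with equal probability (so E[D] = 0 by
    construction).  Inside a tract ``{"chrom","start","end","gamma",
    "donor","recipient"}`` each site has its recipient frequency copied
    from the donor lineage with probability gamma (default donor "p3",
    recipient "p2").  Positions are 1-based; sites are uniform per
    chromosome with expected density ``sites_per_mb``.
    """
    chroms = dict(chromosomes or DEFAULT_CHROMOSOMES)
    rng = np.random.default_rng(seed)
    for tract in tracts:
        g = tract.get("gamma", 1.0)
        if not 0.0 <= g <= 1.0:
            raise ValueError(f"gamma {g} outside [0,1]")
    truth = TruthTable(seeds={"sites": seed})
    for tract in tracts:
        truth.tracts.append({"kind": "introgression", "donor": "p3", "recipient": "p2", **dict(tract)})

    term_frac = 1.0 - ils_frac - internal_frac
    if term_frac < 0:
        raise ValueError("ils_frac + internal_frac exceeds 1")
    # categories: P1-only, P2-only, P3-only, P1+P2 (concordant), ABBA, BABA
    probs = np.array(
        [term_frac / 3, term_frac / 3, term_frac / 3, internal_frac, ils_frac / 2, ils_frac / 2]
    )
    patterns = np.array(
        [
            [1, 0, 0, 0],
            [0, 1, 0, 0],
            [0, 0, 1, 0],
            [1, 1, 0, 0],
            [0, 1, 1, 0],  # ABBA
            [1, 0, 1, 0],  # BABA
        ],
        dtype=float,
    )
    frames = []
    for chrom in sorted(chroms):
        length = chroms[chrom]
        n_sites = rng.poisson(sites_per_mb * length / 1e6)
        pos = np.sort(rng.integers(1, length + 1, size=n_sites))
        cat = rng.choice(len(probs), size=n_sites, p=probs)
        freqs = patterns[cat].copy()
        if outgroup_poly_frac > 0:
            poly = rng.random(n_sites) < outgroup_poly_frac
            freqs[poly, 3] = rng.uniform(0.0, 0.5, size=int(poly.sum()))
        for tract in tracts:
            if tract["chrom"] != chrom:
                continue
            inside = (pos > tract["start"]) & (pos <= tract["end"])
            gamma = float(tract.get("gamma", 1.0))
            copied = inside & (rng.random(n_sites) < gamma)
            donor = {"p1": 0, "p2": 1, "p3": 2}[tract.get("donor", "p3")]
            recip = {"p1": 0, "p2": 1, "p3": 2}[tract.get("recipient", "p2")]
            freqs[copied, recip] = freqs[copied, donor]
        frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "pos": pos,
                    "p1": freqs[:, 0],
                    "p2": freqs[:, 1],
                    "p3": freqs[:, 2],
                    "p4": freqs[:, 3],
                }
            )
        )
    return pd.concat(frames, ignore_index=True), truth


# ---------------------------------------------------------------------------
# Codon sequences

_SENSE_CODONS = sorted(c for c in _CODON_TABLE if c not in STOP_CODONS)
_BASES = "ACGT"
_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}


def make_reference_cds(n_codons: int, seed: int = 0) -> str:
    """A random in-frame coding sequence of sense codons (no stops)."""
    rng = np.random.default_rng(seed)
    return "".join(rng.choice(_SENSE_CODONS) for _ in range(n_codons))


def mutate_codons(
    reference: str,
    n_syn: int = 0,
    n_nonsyn: int = 0,
    n_stops: int = 0,
    n_run: bool = False,
    seed: int = 0,
) -> Tuple[str, TruthTable]:
    """Plant controlled edits into a copy of a reference CDS.

    Synonymous changes are placed at fourfold-degenerate sites,
    nonsynonymous changes at nondegenerate sites (never creating a stop),
    stops replace whole codons, and ``n_run`` splices a 10-N run in.  At
    most one edit per codon; impossible requests raise ``ValueError``.
    """
    if len(reference) % 3:
        raise ValueError("reference length must be a multiple of 3")
    rng = np.random.default_rng(seed)
    codons = [reference[i: i + 3] for i in range(0, len(reference), 3)]
    truth = TruthTable(seeds={"codons": seed})

    four_fold = []
    zero_fold = []
    for ci, codon in enumerate(codons):
        if codon in STOP_CODONS:
            continue
        deg = codon_degeneracy(codon)
        for pos in range(3):
            if deg[pos] == 4:
                four_fold.append((ci, pos))
            elif deg[pos] == 0:
                zero_fold.append((ci, pos))

    used_codons: set = set()

    def _pick(candidates, n, kind):
        chosen = []
        order = rng.permutation(len(candidates))
        for idx in order:
            ci, pos = candidates[idx]
            if ci in used_codons:
                continue
            chosen.append((ci, pos))
            used_codons.add(ci)
            if len(chosen) == n:
                return chosen
        raise ValueError(f"not enough free {kind} sites for {n} edits")

    for ci, pos in _pick(four_fold, n_syn, "fourfold") if n_syn else []:
        old = codons[ci]
        new_base = _TRANSITION[old[pos]]
        codons[ci] = old[:pos] + new_base + old[pos + 1:]
        truth.codon_edits.append({"kind": "synonymous", "codon": ci, "pos": pos, "from": old, "to": codons[ci]})

    for ci, pos in _pick(zero_fold, n_nonsyn, "nondegenerate") if n_nonsyn else []:
        old = codons[ci]
        choices = [
            b for b in _BASES
            if b != old[pos] and (old[:pos] + b + old[pos + 1:]) not in STOP_CODONS
        ]
        new_base = str(rng.choice(choices))
        codons[ci] = old[:pos] + new_base + old[pos + 1:]
        truth.codon_edits.append({"kind": "nonsynonymous", "codon": ci, "pos": pos, "from": old, "to": codons[ci]})

    if n_stops:
        free = [ci for ci in range(len(codons)) if ci not in used_codons and ci != len(codons) - 1]
        if len(free) < n_stops:
            raise ValueError("not enough free codons for requested stops")
        for ci in rng.permutation(free)[:n_stops]:
            old = codons[ci]
            codons[ci] = str(rng.choice(sorted(STOP_CODONS)))
            used_codons.add(ci)
            truth.codon_edits.append({"kind": "stop", "codon": int(ci), "from": old, "to": codons[ci]})

    seq = "".join(codons)
    if n_run:
        free_start = next(
            (3 * ci for ci in range(len(codons) - 4) if all(c not in used_codons for c in range(ci, ci + 4))),
            None,
        )
        if free_start is None:
            raise ValueError("no room for an N run")
        seq = seq[:free_start] + "N" * 10 + seq[free_start + 10:]
        truth.codon_edits.append({"kind": "n_run", "offset": free_start, "length": 10})
    return seq, truth


def evolve_codon_pair(
    n_codons: int,
    omega: float,
    n_events: int = 60,
    seed: int = 0,
) -> Tuple[str, str]:
    """A (reference, copy) pair evolved under a target dN/dS ratio.

    Substitutions are proposed uniformly over positions and alternative
    bases; synonymous proposals are always accepted, nonsynonymous ones
    with probability ``omega``, and proposals creating stops are rejected,
    so the realized nonsynonymous/synonymous rate ratio per site is
    ``omega``.
    """
    rng = np.random.default_rng(seed)
    ref = make_reference_cds(n_codons, seed=int(rng.integers(2**31)))
    seq = list(ref)
    accepted = 0
    while accepted < n_events:
        i = int(rng.integers(len(seq)))
        b = str(rng.choice([x for x in _BASES if x != seq[i]]))
        ci = i // 3
        old_codon = "".join(seq[3 * ci: 3 * ci + 3])
        new_codon = old_codon[: i % 3] + b + old_codon[i % 3 + 1:]
        if new_codon in STOP_CODONS:
            continue
        syn = _CODON_TABLE[new_codon] == _CODON_TABLE[old_codon]
        if syn or rng.random() < omega:
            seq[i] = b
            accepted += 1
    return ref, "".join(seq)
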