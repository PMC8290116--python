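"""Canonical synthetic study scenarios.

These fix the conditions under which the pipeline is exercised end-to-end:
the same configurations drive the analysis scripts, the test suite and the
acceptance evaluation, so the recovery metrics all refer to one set of
planted truths.

* Inversion scenario: two clades of 4 species each on a 4×5-Mb genome
  differing by five inversions, two of them in tandem on one chromosome,
  plus a translocation decoy; every inversion is at least 3× the maximum
  scaffold length (see docs/methods.md on the clustering resolution
  limit) and at least 50 kb from chromosome ends.
* Coverage scenario: 16 species, a focal trio carrying four amplified
  regions (2–13 windows, 6–12 fold), plus three decoys the detection rule
  must reject (a single-window spike, an amplification shared with a
  non-focal species, and a non-focal-only amplification).
* Introgression scenario: a four-taxon genome with one tract in which the
  recipient (P2) lineage is fully replaced from the donor (P3) lineage.
"""

from __future__ import annotations

from typing import Dict, List, Tuple

import pandas as pd

from . import alignment_io as aio
from . import synthetic_data as sd

__all__ = [
    "INVERSION_PLAN",
    "TRANSLOCATION_PLAN",
    "CLADE_A_SPECIES",
    "CLADE_B_SPECIES",
    "COVERAGE_SPECIES",
    "FOCAL_TRIO",
    "AMPLIFICATION_PLAN",
    "INTROGRESSION_TRACT",
    "inversion_scenario",
    "coverage_scenario",
    "introgression_scenario",
]

#: five planted inversions, the two on chr2 in tandem (sharing a breakpoint)
INVERSION_PLAN: List[Tuple[str, int, int]] = [
    ("chr1", 1_000_000, 1_800_000),
    ("chr2", 500_000, 1_100_000),
    ("chr2", 1_100_000, 1_700_000),
    ("chr3", 2_000_000, 3_500_000),
    ("chr4", 3_000_000, 3_600_000),
]

#: decoy: a 300-kb segment of chr1 relocated onto chr3 (forward strand)
TRANSLOCATION_PLAN: List[Tuple[str, int, int, str, int]] = [
    ("chr1", 3_500_000, 3_800_000, "chr3", 4_200_000),
]

CLADE_A_SPECIES = ["a1", "a2", "a3", "a4"]   # reference arrangement
CLADE_B_SPECIES = ["b1", "b2", "b3", "b4"]   # carry the inverted arrangement

COVERAGE_SPECIES = [f"s{i:02d}" for i in range(1, 17)]
FOCAL_TRIO = ["s06", "s07", "s08"]

#: four true amplified regions (trio-specific, >=2 windows) + three decoys
AMPLIFICATION_PLAN: List[dict] = [
    {"chrom": "chr1", "start": 1_000_000, "end": 1_050_000, "fold": 10, "species": FOCAL_TRIO, "truth": True},
    {"chrom": "chr2", "start": 2_000_000, "end": 2_225_000, "fold": 6, "species": FOCAL_TRIO, "truth": True},
    {"chrom": "chr3", "start": 500_000, "end": 675_000, "fold": 8, "species": FOCAL_TRIO, "truth": True},
    {"chrom": "chr4", "start": 3_000_000, "end": 3_325_000, "fold": 12, "species": FOCAL_TRIO, "truth": True},
    {"chrom": "chr1", "start": 4_000_000, "end": 4_025_000, "fold": 9, "species": FOCAL_TRIO, "truth": False},
    {"chrom": "chr2", "start": 4_000_000, "end": 4_100_000, "fold": 7, "species": FOCAL_TRIO + ["s01"], "truth": False},
    {"chrom": "chr3", "start": 4_000_000, "end": 4_100_000, "fold": 7, "species": ["s02"], "truth": False},
]

INTROGRESSION_TRACT = {"chrom": "chr2", "start": 2_000_000, "end": 2_500_000, "gamma": 1.0}


def inversion_scenario(seed: int, with_outgroup: bool = True):
    """Generate filtered alignments for both clades (+ outgroup).

    Returns (records_by_species, clade_map, truth, genome_index).  The
    outgroup (``out``) carries the reference (ancestral) arrangement, so
    for every planted inversion the inverted state is derived.  Clade-B
    fragmentations guarantee breakpoint-spanning scaffolds.
    """
    cmap, truth = sd.make_clade_genomes(
        inversions=INVERSION_PLAN, translocations=TRANSLOCATION_PLAN, seed=seed
    )
    breakpoints = [(c, s) for c, s, _ in INVERSION_PLAN] + [(c, e) for c, _, e in INVERSION_PLAN]
    breakpoints += [(c, s) for c, s, e, _, _ in TRANSLOCATION_PLAN] + [
        (c, e) for c, _, e, _, _ in TRANSLOCATION_PLAN
    ]
    records = {}
    for k, sp in enumerate(CLADE_B_SPECIES):
        frags = sd.fragment_scaffolds(cmap.chromosomes, sp, seed=seed * 1009 + k, span_breakpoints=breakpoints)
        recs = sd.emit_truth_paf(frags, cmap, seed=seed * 2003 + k)
        records[sp] = list(aio.filter_primary(recs))
        truth.fragmentation.extend(frags)
    for k, sp in enumerate(CLADE_A_SPECIES):
        frags = sd.fragment_scaffolds(cmap.chromosomes, sp, seed=seed * 3001 + k)
        recs = sd.emit_truth_paf(frags, cmap, seed=seed * 4001 + k, collinear=True)
        records[sp] = list(aio.filter_primary(recs))
    if with_outgroup:
        frags = sd.fragment_scaffolds(cmap.chromosomes, "out", seed=seed * 5003)
        recs = sd.emit_truth_paf(frags, cmap, seed=seed * 6007, collinear=True)
        records["out"] = list(aio.filter_primary(recs))
    return records, cmap, truth, aio.GenomeIndex(dict(cmap.chromosomes))


def coverage_scenario(seed: int):
    """Window depth tables for 16 species with the planted amplifications."""
    windows, truth = sd.simulate_coverage(COVERAGE_SPECIES, amplifications=AMPLIFICATION_PLAN, seed=seed)
    return windows, truth


def introgression_scenario(seed: int, sites_per_mb: float = 3_000.0):
    """Four-taxon sites with one full-replacement donor-P3→P2 tract."""
    chroms = {"chr1": 5_000_000, "chr2": 5_000_000}
    sites, truth = sd.simulate_sites(chroms, sites_per_mb=sites_per_mb, tracts=[INTROGRESSION_TRACT], seed=seed)
    return sites, truth
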