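"""Windowed depth, repeat-region detection, exon copy number, repeat enrichment.

Depth is consumed as nonoverlapping 25-kb window tables (species, chrom,
start, end, depth).  All "fold" quantities are on median-normalized depth
(window depth / genome-wide species median), the only scale on which
fold thresholds are comparable across species.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .alignment_io import AlignmentRecord

__all__ = [
    "normalize_profile",
    "detect_repeat_regions",
    "copy_number_by_alignments",
    "copy_number_by_coverage",
    "transcript_copy_number",
    "repeat_enrichment",
    "repeat_enrichment_table",
    "ExonCopyEstimate",
]


@dataclass
class ExonCopyEstimate:
    gene: str
    exon: str
    exon_length: int
    n_alignments: Optional[int] = None   # estimator 1: valid alignment count
    coverage_ratio: Optional[float] = None  # estimator 2: depth / median


def normalize_profile(windows: pd.DataFrame) -> pd.DataFrame:
    """Add ``normalized_depth`` = depth / genome-wide per-species median.

    The median is taken over all windows of each species (never per
    chromosome), so a uniformly doubled chromosome normalizes to 2 there.
    """
    df = windows.copy()
    if (df.groupby("species")["depth"].max() <= 0).any():
        raise ValueError("all-zero depth profile for at least one species")
    med = df.groupby("species")["depth"].transform("median")
    df["normalized_depth"] = df["depth"] / med
    return df


def detect_repeat_regions(
    windows: pd.DataFrame,
    focal_species: Sequence[str],
    fold_focal: float = 5.0,
    fold_other: float = 2.0,
    min_consecutive: int = 2,
    window_size: int = 25_000,
) -> pd.DataFrame:
    """Regions of clade-specific local depth amplification.

    A region is a maximal run of at least ``min_consecutive`` consecutive
    windows in which normalized depth is >= ``fold_focal`` in *every* focal
    species and < ``fold_other`` in every other species with data at that
    window.  All species must share the same window grid.  Windows
    truncated at chromosome ends participate, but a region may not consist
    solely of truncated windows.

    Returns a BED-like frame (chrom, start, end, n_windows).
    """
    df = windows if "normalized_depth" in windows.columns else normalize_profile(windows)
    focal = set(focal_species)
    missing = focal - set(df["species"].unique())
    if missing:
        raise ValueError(f"focal species without coverage data: {sorted(missing)}")
    pivot = df.pivot_table(
        index=["chrom", "start", "end"], columns="species", values="normalized_depth"
    )
    grids = df.groupby("species").apply(
        lambda g: frozenset(zip(g["chrom"], g["start"])), include_groups=False
    )
    if grids.nunique() != 1:
        raise ValueError("species do not share the same window grid")
    others = [s for s in pivot.columns if s not in focal]
    focal_ok = (pivot[list(focal)] >= fold_focal).all(axis=1)
    if others:
        # "every other species with data": NaN does not veto
        other_ok = ((pivot[others] < fold_other) | pivot[others].isna()).all(axis=1)
    else:
        other_ok = pd.Series(True, index=pivot.index)
    ok = (focal_ok & other_ok).reset_index()
    ok.columns = ["chrom", "start", "end", "pass"]
    ok = ok.sort_values(["chrom", "start"]).reset_index(drop=True)

    regions: List[dict] = []
    for chrom, sub in ok.groupby("chrom", sort=True):
        run: List[pd.Series] = []
        prev_end = None
        for _, row in sub.iterrows():
            contiguous = prev_end is not None and row["start"] == prev_end
            if row["pass"] and (not run or contiguous):
                run.append(row)
            elif row["pass"]:
                _flush_run(run, regions, min_consecutive, window_size)
                run = [row]
            else:
                _flush_run(run, regions, min_consecutive, window_size)
                run = []
            prev_end = row["end"]
        _flush_run(run, regions, min_consecutive, window_size)
    return pd.DataFrame(regions, columns=["chrom", "start", "end", "n_windows"])


def _flush_run(run: List[pd.Series], regions: List[dict], min_consecutive: int, window_size: int) -> None:
    if len(run) < min_consecutive:
        run.clear()
        return
    full_width = any((r["end"] - r["start"]) == window_size for r in run)
    if full_width:
        regions.append(
            {
                "chrom": run[0]["chrom"],
                "start": int(run[0]["start"]),
                "end": int(run[-1]["end"]),
                "n_windows": len(run),
            }
        )
    run.clear()


def copy_number_by_alignments(
    exon_hits: Iterable[AlignmentRecord],
    exon_length: Optional[int] = None,
    min_cov_frac: float = 0.5,
    max_hits: int = 1_000,
    gene: str = "",
    exon: str = "",
) -> ExonCopyEstimate:
    """Copy number as the count of valid exon-sequence alignments.

    A hit is valid when at least ``min_cov_frac`` of the exon length is
    aligned (aligned exon span / exon length); the count is capped at
    ``max_hits``, the mapper's reporting ceiling.
    """
    hits = list(exon_hits)
    if exon_length is None:
        if not hits:
            raise ValueError("exon_length required when no hits are given")
        exon_length = hits[0].query_len
    n = 0
    for h in hits:
        if h.query_span >= min_cov_frac * exon_length:
            n += 1
    return ExonCopyEstimate(gene, exon, exon_length, n_alignments=min(n, max_hits))


def copy_number_by_coverage(
    exon_start: int,
    exon_end: int,
    depth: pd.DataFrame,
    species_median: float,
    chrom: Optional[str] = None,
    gene: str = "",
    exon: str = "",
) -> ExonCopyEstimate:
    """Copy number as mean exon depth over the species' median genomic depth.

    ``depth`` is a per-base or windowed table with columns (chrom,) start,
    end, depth.  An exon outside covered territory yields a missing value,
    not zero.
    """
    d = depth
    if chrom is not None and "chrom" in d.columns:
        d = d[d["chrom"] == chrom]
    ov_start = np.maximum(d["start"].to_numpy(), exon_start)
    ov_end = np.minimum(d["end"].to_numpy(), exon_end)
    ov = np.clip(ov_end - ov_start, 0, None)
    covered = ov.sum()
    est = ExonCopyEstimate(gene, exon, exon_end - exon_start)
    if covered == 0:
        est.coverage_ratio = None
        return est
    mean_depth = float((d["depth"].to_numpy() * ov).sum() / covered)
    est.coverage_ratio = mean_depth / species_median
    return est


def transcript_copy_number(exon_estimates: Sequence[float]) -> float:
    """Transcript copy number = median across its exons' estimates."""
    if len(exon_estimates) == 0:
        raise ValueError("no exon estimates")
    return float(np.median(np.asarray(exon_estimates, dtype=float)))


def repeat_enrichment(r_i: int, r_total: int, m_i: int, m_total: int):
    """Fold change and Fisher's exact test for one repeat family.

    fold = (R_i/R) / (M_i/M) against either the homologous reference
    region (M_i, M) or the species' own genomic background (B_i, B);
    p is from a two-sided Fisher's exact test on
    [[R_i, R−R_i], [M_i, M−M_i]].
    """
    if not (0 <= r_i <= r_total and 0 <= m_i <= m_total):
        raise ValueError("family counts exceed totals or are negative")
    if r_total <= 0 or m_total <= 0:
        raise ValueError("totals must be positive")
    if m_i == 0:
        fold = math.inf if r_i > 0 else math.nan
    else:
        fold = (r_i / r_total) / (m_i / m_total)
    _, p = stats.fisher_exact([[r_i, r_total - r_i], [m_i, m_total - m_i]], alternative="two-sided")
    return fold, float(p)


def repeat_enrichment_table(counts: pd.DataFrame) -> pd.DataFrame:
    """Per-family enrichment over a counts frame (family, r_i, r, m_i, m).

    Adds fold_change, p and a Benjamini–Hochberg q column.  The q column
    is a convenience addition: the per-family tests are otherwise reported
    uncorrected.
    """
    rows = []
    for _, row in counts.iterrows():
        fold, p = repeat_enrichment(int(row["r_i"]), int(row["r"]), int(row["m_i"]), int(row["m"]))
        rows.append({"family": row["family"], "fold_change": fold, "p": p})
    out = pd.DataFrame(rows)
    if len(out):
        out["q"] = multipletests(out["p"].to_numpy(), method="fdr_bh")[1]
    else:
        out["q"] = []
    return out
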