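"""Configuration and end-to-end orchestration.

A single YAML config drives every stage; each CLI flag overrides its
config key.  Every run writes a machine-readable manifest (version, seed,
config hash, per-stage record counts) next to its outputs, and the log
records record counts at every filter step of the inversion cascade.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import yaml

from . import __version__
from . import alignment_io as aio
from . import coverage_cnv as cnv
from . import introgression_stats as ist
from . import inversion_detection as inv

logger = logging.getLogger("cladesv")

__all__ = ["PipelineConfig", "ConfigError", "DataError", "run_pipeline", "write_manifest"]


class ConfigError(ValueError):
    """Invalid or incomplete configuration (CLI exit code 2)."""


class DataError(ValueError):
    """Malformed or missing input data (CLI exit code 3)."""


@dataclass
class PipelineConfig:
    """All tunable thresholds, defaulting to the published screen's values."""

    species: List[str] = field(default_factory=list)
    clades: Dict[str, List[str]] = field(default_factory=dict)
    focal_species: List[str] = field(default_factory=list)
    populations: Dict[str, str] = field(default_factory=dict)  # role (p1..p4) → name
    seed: int = 0
    # alignment entry filters
    min_scaffold_len: int = 5_000
    min_aln_len: int = 1_000
    min_mapq: int = 60
    max_dv: float = 0.25
    keep_missing_dv: bool = False
    # inversion cascade
    merge_gap: int = 50_000
    min_aligned_frac: float = 0.20
    max_pair_overlap: int = 5_000
    min_inversion_len: int = 50_000
    max_inversion_len: int = 2_000_000
    min_boundary_dist: int = 50_000
    cluster_overlap: float = 0.75
    ref_vs_ref_min_mapq: int = 10
    # coverage / CNV
    coverage_window: int = 25_000
    fold_focal: float = 5.0
    fold_other: float = 2.0
    min_consecutive_windows: int = 2
    min_exon_cov_frac: float = 0.5
    max_exon_hits: int = 1_000
    # introgression
    d_window: int = 1_000_000
    fdm_window: int = 100_000
    jackknife_block: int = 1_000_000
    min_informative_sites: int = 100
    outlier_sd: float = 3.0

    @classmethod
    def from_yaml(cls, path, **overrides) -> "PipelineConfig":
        try:
            with open(path) as fh:
                data = yaml.safe_load(fh) or {}
        except OSError as exc:
            raise ConfigError(f"cannot read config: {exc}") from exc
        if not isinstance(data, dict):
            raise ConfigError("config must be a YAML mapping")
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def digest(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def write_manifest(outdir: Path, config: PipelineConfig, stages: Dict[str, dict]) -> Path:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "tool": "clade-sv",
        "version": __version__,
        "seed": config.seed,
        "config_hash": config.digest(),
        "config": asdict(config),
        "stages": stages,
    }
    path = outdir / "run_manifest.json"
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return path


def candidates_to_frame(clusters) -> "object":
    import pandas as pd

    rows = []
    for c in clusters:
        rows.append(
            {
                "chrom": c.chromosome,
                "start": c.start,
                "end": c.end,
                "length": c.length,
                "union_start": c.union_start,
                "union_end": c.union_end,
                "n_scaffolds": c.n_members,
                "species": ",".join(sorted(c.species_set)),
                "orientation": ";".join(
                    f"{sp}={state}" for sp, state in sorted(c.orientation.items()) if sp != "__ancestral__"
                ),
                "ancestral_state": c.orientation.get("__ancestral__", ""),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "chrom", "start", "end", "length", "union_start", "union_end",
            "n_scaffolds", "species", "orientation", "ancestral_state",
        ],
    )


def run_pipeline(
    config: PipelineConfig,
    paf_by_species: Dict[str, str],
    genome_index: aio.GenomeIndex,
    outdir: Path,
    outgroup: Optional[str] = None,
    window_table: Optional[str] = None,
    site_table: Optional[str] = None,
) -> Dict[str, object]:
    """Run the requested stages; write stable filenames + a manifest.

    Inversion detection always runs (PAF inputs are mandatory); the
    coverage and introgression stages run when their inputs are given.
    Filter-step counts are logged and recorded in the manifest.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stages: Dict[str, dict] = {}
    results: Dict[str, object] = {}

    records = {}
    n_raw = {}
    for sp, path in paf_by_species.items():
        try:
            raw = list(aio.read_paf(path))
        except (OSError, aio.PafFormatError) as exc:
            raise DataError(f"{sp}: {exc}") from exc
        n_raw[sp] = len(raw)
        records[sp] = list(
            aio.filter_primary(
                raw,
                min_scaffold_len=config.min_scaffold_len,
                min_aln_len=config.min_aln_len,
                min_mapq=config.min_mapq,
                max_dv=config.max_dv,
                keep_missing_dv=config.keep_missing_dv,
            )
        )
        logger.info("%s: %d records, %d pass entry filters", sp, n_raw[sp], len(records[sp]))

    og_records = records.pop(outgroup, None) if outgroup else None
    stats: dict = {}
    clusters = inv.detect_candidates(
        records,
        genome_index,
        max_gap=config.merge_gap,
        min_len=config.min_inversion_len,
        max_len=config.max_inversion_len,
        min_boundary_dist=config.min_boundary_dist,
        min_overlap_frac=config.cluster_overlap,
        stats=stats,
    )
    logger.info("inversion cascade counts: %s", stats)
    if og_records is not None:
        og_clusters = inv.detect_candidates({outgroup: og_records}, genome_index)
        og_cov = [
            (r.target_name, r.target_start, r.target_end) for r in og_records
        ]
        for cluster in clusters:
            inv.polarize(cluster, og_clusters, outgroup_coverage=og_cov, species=config.species)
    frame = candidates_to_frame(clusters)
    frame.to_csv(outdir / "inversion_candidates.tsv", sep="\t", index=False)
    stages["inversions"] = {"input_records": n_raw, **stats, "clusters": len(clusters)}
    results["inversions"] = clusters

    if window_table is not None:
        windows = aio.read_window_table(window_table)
        if not config.focal_species:
            raise ConfigError("coverage stage requires focal_species")
        regions = cnv.detect_repeat_regions(
            windows,
            config.focal_species,
            fold_focal=config.fold_focal,
            fold_other=config.fold_other,
            min_consecutive=config.min_consecutive_windows,
            window_size=config.coverage_window,
        )
        regions.to_csv(outdir / "repeat_regions.tsv", sep="\t", index=False)
        stages["coverage"] = {"windows": len(windows), "regions": len(regions)}
        results["repeat_regions"] = regions

    if site_table is not None:
        sites = aio.read_site_table(site_table)
        win = ist.window_statistics(
            sites,
            d_window=config.d_window,
            fdm_window=config.fdm_window,
            min_sites=config.min_informative_sites,
            outlier_sd=config.outlier_sd,
        )
        jk = ist.block_jackknife(sites, block_size=config.jackknife_block)
        win["d_windows"].to_csv(outdir / "d_windows.tsv", sep="\t", index=False)
        win["fdm_windows"].to_csv(outdir / "fdm_windows.tsv", sep="\t", index=False)
        with open(outdir / "jackknife.json", "w") as fh:
            json.dump(asdict(jk), fh, indent=2)
        stages["introgression"] = {
            "sites": len(sites),
            "d_windows": len(win["d_windows"]),
            "fdm_windows": len(win["fdm_windows"]),
            "D": jk.D,
            "Z": jk.z,
        }
        results["window_stats"] = win
        results["jackknife"] = jk

    write_manifest(outdir, config, stages)
    return results
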