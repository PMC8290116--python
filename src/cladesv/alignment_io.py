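"""PAF alignment records and the simple tabular formats the pipeline exchanges.

All coordinates are 0-based half-open internally (the PAF convention).
GFF3 exon intervals (1-based inclusive) are converted at the boundary.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, TextIO, Union

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "AlignmentRecord",
    "GenomeIndex",
    "PafFormatError",
    "read_paf",
    "write_paf",
    "filter_primary",
    "read_bed",
    "write_bed",
    "read_gff3_exons",
    "read_window_table",
    "write_window_table",
    "read_site_table",
    "write_site_table",
]

#: SAM-style tag type codes → python converters
_TAG_PARSERS = {"A": str, "i": int, "f": float, "Z": str}


class PafFormatError(ValueError):
    """Raised for a malformed PAF line; message names the offending line."""


@dataclass
class AlignmentRecord:
    """One PAF line.

    Mandatory columns are stored as typed attributes; optional SAM-style
    typed tags (e.g. ``tp:A:P``, ``dv:f:0.08``) are kept in :attr:`tags`
    with their original type code so round-trips are byte-faithful.
    """

    query_name: str
    query_len: int
    query_start: int
    query_end: int
    strand: str
    target_name: str
    target_len: int
    target_start: int
    target_end: int
    residue_matches: int
    block_len: int
    mapq: int
    tags: dict = field(default_factory=dict)
    tag_types: dict = field(default_factory=dict)

    def validate(self) -> None:
        """Raise ``ValueError`` on any violated record invariant."""
        if not (0 <= self.query_start < self.query_end <= self.query_len):
            raise ValueError(
                f"query interval [{self.query_start},{self.query_end}) "
                f"invalid for length {self.query_len}"
            )
        if not (0 <= self.target_start < self.target_end <= self.target_len):
            raise ValueError(
                f"target interval [{self.target_start},{self.target_end}) "
                f"invalid for length {self.target_len}"
            )
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")
        if not 0 <= self.mapq <= 255:
            raise ValueError(f"mapq {self.mapq} outside [0,255]")
        if self.residue_matches > self.block_len:
            raise ValueError("residue_matches exceeds block_len")
        dv = self.tags.get("dv")
        if dv is not None and not 0.0 <= dv <= 1.0:
            raise ValueError(f"dv {dv} outside [0,1]")

    @property
    def target_span(self) -> int:
        return self.target_end - self.target_start

    @property
    def query_span(self) -> int:
        return self.query_end - self.query_start

    def to_paf_line(self) -> str:
        cols = [
            self.query_name,
            str(self.query_len),
            str(self.query_start),
            str(self.query_end),
            self.strand,
            self.target_name,
            str(self.target_len),
            str(self.target_start),
            str(self.target_end),
            str(self.residue_matches),
            str(self.block_len),
            str(self.mapq),
        ]
        for key, value in self.tags.items():
            code = self.tag_types.get(key, "Z")
            if code == "f":
                sval = format(value, "g")
            else:
                sval = str(value)
            cols.append(f"{key}:{code}:{sval}")
        return "\t".join(cols)


@dataclass
class GenomeIndex:
    """Reference sequence lengths plus chromosome assignment.

    Houses the scaffold boundaries used by the breakpoint-distance filter.
    Sequences without an assignment map to ``"unplaced"``.
    """

    lengths: dict
    chromosomes: dict = field(default_factory=dict)

    def __post_init__(self):
        for name, length in self.lengths.items():
            if length <= 0:
                raise ValueError(f"non-positive length for {name}")

    def chromosome_of(self, name: str) -> str:
        return self.chromosomes.get(name, name if name in self.lengths else "unplaced")

    def length_of(self, name: str) -> int:
        try:
            return self.lengths[name]
        except KeyError:
            raise KeyError(f"sequence {name!r} absent from genome index") from None

    @classmethod
    def from_fai(cls, path: Union[str, Path], chrom_table: Union[str, Path, None] = None) -> "GenomeIndex":
        """Build from a FASTA index dialect file (name, length, ...).

        ``chrom_table``, if given, is a two-column tab file mapping sequence
        name → chromosome.
        """
        lengths = {}
        with open(path) as fh:
            for line in fh:
                if not line.strip():
                    continue
                parts = line.rstrip("\n").split("\t")
                lengths[parts[0]] = int(parts[1])
        chroms = {}
        if chrom_table is not None:
            with open(chrom_table) as fh:
                for line in fh:
                    if not line.strip() or line.startswith("#"):
                        continue
                    name, chrom = line.rstrip("\n").split("\t")[:2]
                    chroms[name] = chrom
        return cls(lengths, chroms)


def _parse_tag(token: str, lineno: int):
    parts = token.split(":", 2)
    if len(parts) != 3 or len(parts[0]) != 2:
        raise PafFormatError(f"line {lineno}: malformed tag {token!r}")
    key, code, raw = parts
    conv = _TAG_PARSERS.get(code)
    if conv is None:
        return key, code, raw
    try:
        return key, code, conv(raw)
    except ValueError:
        raise PafFormatError(f"line {lineno}: bad {code}-typed tag value {raw!r}") from None


def read_paf(path_or_handle: Union[str, Path, TextIO]) -> Iterator[AlignmentRecord]:
    """Stream :class:`AlignmentRecord` from a PAF file.

    Malformed lines (wrong column count, unparsable integers) raise
    :class:`PafFormatError` naming the line number.  Records violating the
    coordinate invariants (e.g. start ≥ end) are skipped with a warning
    rather than aborting the stream.
    """
    if hasattr(path_or_handle, "read"):
        yield from _read_paf_handle(path_or_handle)
    else:
        with open(path_or_handle) as fh:
            yield from _read_paf_handle(fh)


def _read_paf_handle(fh: TextIO) -> Iterator[AlignmentRecord]:
    for lineno, line in enumerate(fh, start=1):
        line = line.rstrip("\n")
        if not line:
            continue
        cols = line.split("\t")
        if len(cols) < 12:
            raise PafFormatError(f"line {lineno}: expected >=12 columns, got {len(cols)}")
        try:
            rec = AlignmentRecord(
                query_name=cols[0],
                query_len=int(cols[1]),
                query_start=int(cols[2]),
                query_end=int(cols[3]),
                strand=cols[4],
                target_name=cols[5],
                target_len=int(cols[6]),
                target_start=int(cols[7]),
                target_end=int(cols[8]),
                residue_matches=int(cols[9]),
                block_len=int(cols[10]),
                mapq=int(cols[11]),
            )
        except ValueError:
            raise PafFormatError(f"line {lineno}: unparsable mandatory column") from None
        for token in cols[12:]:
            key, code, value = _parse_tag(token, lineno)
            rec.tags[key] = value
            rec.tag_types[key] = code
        try:
            rec.validate()
        except ValueError as exc:
            warnings.warn(f"line {lineno}: skipping invalid record ({exc})")
            continue
        yield rec


def write_paf(records: Iterable[AlignmentRecord], path_or_handle: Union[str, Path, TextIO]) -> None:
    if hasattr(path_or_handle, "write"):
        for rec in records:
            path_or_handle.write(rec.to_paf_line() + "\n")
    else:
        with open(path_or_handle, "w") as fh:
            for rec in records:
                fh.write(rec.to_paf_line() + "\n")


def filter_primary(
    records: Iterable[AlignmentRecord],
    min_scaffold_len: int = 5_000,
    min_aln_len: int = 1_000,
    min_mapq: int = 60,
    max_dv: float = 0.25,
    keep_missing_dv: bool = False,
) -> Iterator[AlignmentRecord]:
    """Keep primary alignments passing the inversion-screen entry filters.

    A record is kept iff it is a primary alignment (``tp:A:P``), its target
    span is at least ``min_aln_len``, its mapping quality at least
    ``min_mapq``, its approximate per-base divergence strictly below
    ``max_dv``, and its query scaffold at least ``min_scaffold_len`` long.
    Records lacking a ``dv`` tag are dropped with a warning unless
    ``keep_missing_dv`` is set (the divergence filter cannot be evaluated).
    The filter is pure and idempotent.
    """
    for rec in records:
        if rec.tags.get("tp") != "P":
            continue
        if rec.query_len < min_scaffold_len:
            continue
        if rec.target_span < min_aln_len:
            continue
        if rec.mapq < min_mapq:
            continue
        dv = rec.tags.get("dv")
        if dv is None:
            if not keep_missing_dv:
                warnings.warn(
                    f"record {rec.query_name}→{rec.target_name} lacks dv tag; dropped"
                )
                continue
        elif dv >= max_dv:  # strict "less than"
            continue
        yield rec


# ---------------------------------------------------------------------------
# Tabular formats


def read_bed(path) -> pd.DataFrame:
    """BED dialect: chrom, start, end[, name]; 0-based half-open."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df = df.iloc[:, : min(4, df.shape[1])]
    df.columns = ["chrom", "start", "end", "name"][: df.shape[1]]
    return df


def write_bed(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", header=False, index=False)


def read_gff3_exons(path) -> pd.DataFrame:
    """Exon intervals from GFF3, converted to 0-based half-open.

    Returns columns chrom, start, end, strand, gene, exon_id.
    """
    rows = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 8 or cols[2].lower() != "exon":
                continue
            attrs = {}
            if len(cols) > 8:
                for item in cols[8].split(";"):
                    if "=" in item:
                        k, v = item.split("=", 1)
                        attrs[k.strip()] = v.strip()
            rows.append(
                {
                    "chrom": cols[0],
                    "start": int(cols[3]) - 1,  # 1-based inclusive → half-open
                    "end": int(cols[4]),
                    "strand": cols[6],
                    "gene": attrs.get("gene_id", attrs.get("Parent", "")),
                    "exon_id": attrs.get("ID", ""),
                }
            )
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "strand", "gene", "exon_id"])


_WINDOW_COLS = ["species", "chrom", "start", "end", "depth"]


def read_window_table(path) -> pd.DataFrame:
    """Tab-delimited per-window depth table (species, chrom, start, end, depth)."""
    df = pd.read_csv(path, sep="\t")
    missing = set(_WINDOW_COLS) - set(df.columns)
    if missing:
        raise ValueError(f"window table missing columns: {sorted(missing)}")
    return df


def write_window_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


_SITE_COLS = ["chrom", "pos", "p1", "p2", "p3", "p4"]


def read_site_table(path) -> pd.DataFrame:
    """Per-site derived-allele frequency table for the four-taxon tests.

    Columns: chrom, pos (1-based, VCF convention), p1..p4 in [0,1].
    """
    df = pd.read_csv(path, sep="\t")
    missing = set(_SITE_COLS) - set(df.columns)
    if missing:
        raise ValueError(f"site table missing columns: {sorted(missing)}")
    freqs = df[["p1", "p2", "p3", "p4"]].to_numpy()
    if ((freqs < 0) | (freqs > 1)).any():
        raise ValueError("allele frequencies outside [0,1]")
    return df


def write_site_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)
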