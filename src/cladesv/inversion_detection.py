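"""Inversion discovery from strand-discordant split alignments.

A draft scaffold spanning an inversion breakpoint in the reference produces
split alignments to opposite strands of the same chromosome.  The cascade:

1. per scaffold, merge same-strand alignments that overlap or lie within
   50 kb of each other on the reference (``merge_same_strand``);
2. drop scaffolds that align poorly or whose opposite-strand alignments
   look repeat-driven (``apply_scaffold_filters``);
3. call scaffolds informative when one chromosome carries >=2 merged
   segments with both strands represented (``call_informative``);
4. size- and boundary-filter the per-scaffold candidate intervals
   (``filter_candidates``);
5. single-linkage cluster candidates that reciprocally overlap by >=75%
   of the longer of the two (``cluster_candidates``);
6. polarize orientations against an outgroup processed through the same
   cascade (``polarize``).

A second, coarser mode (``ref_vs_ref_candidates``) screens one chromosomal
assembly mapped onto another for reverse-strand blocks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

from .alignment_io import AlignmentRecord, GenomeIndex

logger = logging.getLogger(__name__)

__all__ = [
    "StrandSegment",
    "InformativeScaffold",
    "InversionCandidate",
    "segments_from_records",
    "merge_same_strand",
    "apply_scaffold_filters",
    "call_informative",
    "filter_candidates",
    "cluster_candidates",
    "polarize",
    "ref_vs_ref_candidates",
    "detect_candidates",
    "ScaffoldDecision",
]


@dataclass
class StrandSegment:
    """A (merged) alignment block of one scaffold on one reference strand."""

    scaffold: str
    chromosome: str
    target_start: int
    target_end: int
    query_start: int
    query_end: int
    strand: str

    @property
    def target_span(self) -> int:
        return self.target_end - self.target_start

    @property
    def query_span(self) -> int:
        return self.query_end - self.query_start


@dataclass
class InformativeScaffold:
    """A scaffold whose split alignments straddle an inversion breakpoint."""

    scaffold: str
    chromosome: str
    segments: List[StrandSegment]
    candidate_interval: Tuple[int, int]
    species: str = ""


@dataclass
class ScaffoldDecision:
    scaffold: str
    kept: bool
    reason: str = ""


@dataclass
class InversionCandidate:
    """A reference interval supported by strand-discordant scaffolds."""

    chromosome: str
    start: int
    end: int
    supporting_scaffolds: Dict[str, List[str]] = field(default_factory=dict)
    orientation: Dict[str, str] = field(default_factory=dict)
    union_start: Optional[int] = None
    union_end: Optional[int] = None
    n_members: int = 1

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def species_set(self) -> frozenset:
        return frozenset(self.supporting_scaffolds)


def segments_from_records(records: Iterable[AlignmentRecord]) -> Dict[str, List[StrandSegment]]:
    """Group alignment records into per-scaffold segment lists."""
    by_scaffold: Dict[str, List[StrandSegment]] = {}
    lengths: Dict[str, int] = {}
    for rec in records:
        seg = StrandSegment(
            scaffold=rec.query_name,
            chromosome=rec.target_name,
            target_start=rec.target_start,
            target_end=rec.target_end,
            query_start=rec.query_start,
            query_end=rec.query_end,
            strand=rec.strand,
        )
        by_scaffold.setdefault(rec.query_name, []).append(seg)
        lengths[rec.query_name] = rec.query_len
    for segs in by_scaffold.values():
        segs.sort(key=lambda s: (s.chromosome, s.target_start))
    return by_scaffold


def merge_same_strand(segments: Sequence[StrandSegment], max_gap: int = 50_000) -> List[StrandSegment]:
    """Concatenate same-scaffold, same-chromosome, same-strand alignments
    that overlap or lie not more than ``max_gap`` apart on the reference.

    Merged target and query intervals are union spans.
    """
    out: List[StrandSegment] = []
    groups: Dict[Tuple[str, str], List[StrandSegment]] = {}
    for seg in segments:
        groups.setdefault((seg.chromosome, seg.strand), []).append(seg)
    for (chrom, strand), group in sorted(groups.items()):
        group = sorted(group, key=lambda s: s.target_start)
        current = None
        for seg in group:
            if current is None:
                current = StrandSegment(
                    seg.scaffold, chrom, seg.target_start, seg.target_end,
                    seg.query_start, seg.query_end, strand,
                )
                continue
            gap = seg.target_start - current.target_end
            if gap <= max_gap:  # overlap (gap<0) or within max_gap
                current.target_end = max(current.target_end, seg.target_end)
                current.target_start = min(current.target_start, seg.target_start)
                current.query_start = min(current.query_start, seg.query_start)
                current.query_end = max(current.query_end, seg.query_end)
            else:
                out.append(current)
                current = StrandSegment(
                    seg.scaffold, chrom, seg.target_start, seg.target_end,
                    seg.query_start, seg.query_end, strand,
                )
        if current is not None:
            out.append(current)
    out.sort(key=lambda s: (s.chromosome, s.target_start))
    return out


def _interval_overlap(s1: int, e1: int, s2: int, e2: int) -> int:
    return min(e1, e2) - max(s1, s2)


def apply_scaffold_filters(
    scaffold: str,
    segments: Sequence[StrandSegment],
    query_len: int,
    min_aligned_frac: float = 0.20,
    max_pair_overlap: int = 5_000,
) -> ScaffoldDecision:
    """Exclude scaffolds with weak or repeat-like alignment signatures.

    Drop reasons:

    * ``low-aligned-fraction`` — summed query span of the (merged) segments
      is below 20% of the scaffold length;
    * ``query-overlap`` — a forward and a reverse alignment come from
      overlapping scaffold regions (overlap > 5 kb);
    * ``reference-overlap`` — they overlap in the reference by > 5 kb;
    * ``containment`` — the alignment on one strand lies completely within
      the alignment on the other strand (on the reference).
    """
    aligned = sum(s.query_span for s in segments)
    if aligned < min_aligned_frac * query_len:
        return ScaffoldDecision(scaffold, False, "low-aligned-fraction")
    fwd = [s for s in segments if s.strand == "+"]
    rev = [s for s in segments if s.strand == "-"]
    for f in fwd:
        for r in rev:
            if f.chromosome != r.chromosome:
                continue
            if _interval_overlap(f.query_start, f.query_end, r.query_start, r.query_end) > max_pair_overlap:
                return ScaffoldDecision(scaffold, False, "query-overlap")
            if (f.target_start <= r.target_start and r.target_end <= f.target_end) or (
                r.target_start <= f.target_start and f.target_end <= r.target_end
            ):
                return ScaffoldDecision(scaffold, False, "containment")
            if _interval_overlap(f.target_start, f.target_end, r.target_start, r.target_end) > max_pair_overlap:
                return ScaffoldDecision(scaffold, False, "reference-overlap")
    return ScaffoldDecision(scaffold, True)


def _candidate_interval(segments: Sequence[StrandSegment]) -> Tuple[int, int]:
    """Candidate inversion extent from one scaffold's discordant segments.

    The minority strand is the one with the smaller summed target span
    (ties toward "-", the reference-forward convention).  If a minority
    segment is flanked by opposite-strand segments on both sides, the
    scaffold spans the whole inversion and the minority segment's target
    span is the candidate.  Otherwise the scaffold spans one breakpoint and
    the candidate is the union span of the minority segment and its nearest
    opposite-strand neighbour.
    """
    ordered = sorted(segments, key=lambda s: s.target_start)
    # a segment flanked on both sides by opposite-strand segments is the
    # inversion interior itself: use its target span directly
    flanked = [
        s
        for i, s in enumerate(ordered)
        if any(o.strand != s.strand for o in ordered[:i])
        and any(o.strand != s.strand for o in ordered[i + 1:])
    ]
    if flanked:
        seg = max(flanked, key=lambda s: (s.target_span, -s.target_start))
        return seg.target_start, seg.target_end
    spans = {"+": 0, "-": 0}
    for s in segments:
        spans[s.strand] += s.target_span
    minority = "-" if spans["-"] <= spans["+"] else "+"
    minority_segs = [s for s in ordered if s.strand == minority]
    # take the minority segment of maximal span (deterministic tie-break)
    seg = max(minority_segs, key=lambda s: (s.target_span, -s.target_start))
    idx = ordered.index(seg)
    left = next((ordered[i] for i in range(idx - 1, -1, -1) if ordered[i].strand != minority), None)
    right = next((ordered[i] for i in range(idx + 1, len(ordered)) if ordered[i].strand != minority), None)
    neighbours = [n for n in (left, right) if n is not None]
    near = min(
        neighbours,
        key=lambda n: max(n.target_start - seg.target_end, seg.target_start - n.target_end),
    )
    return min(seg.target_start, near.target_start), max(seg.target_end, near.target_end)


def call_informative(
    scaffold: str,
    segments: Sequence[StrandSegment],
    species: str = "",
) -> Optional[InformativeScaffold]:
    """A scaffold is informative iff some chromosome carries at least two
    of its merged segments with both strands represented."""
    by_chrom: Dict[str, List[StrandSegment]] = {}
    for s in segments:
        by_chrom.setdefault(s.chromosome, []).append(s)
    best = None
    for chrom in sorted(by_chrom):
        group = by_chrom[chrom]
        strands = {s.strand for s in group}
        if len(group) >= 2 and strands == {"+", "-"}:
            interval = _candidate_interval(group)
            cand = InformativeScaffold(scaffold, chrom, sorted(group, key=lambda s: s.target_start), interval, species)
            if best is None or (interval[1] - interval[0]) > (
                best.candidate_interval[1] - best.candidate_interval[0]
            ):
                best = cand
    return best


def filter_candidates(
    candidates: Iterable[InformativeScaffold],
    genome_index: GenomeIndex,
    min_len: int = 50_000,
    max_len: int = 2_000_000,
    min_boundary_dist: int = 50_000,
) -> List[InformativeScaffold]:
    """Keep candidates 50 kb–2 Mb long with both endpoints at least 50 kb
    from the ends of the containing reference scaffold."""
    kept = []
    for cand in candidates:
        start, end = cand.candidate_interval
        ref_len = genome_index.length_of(cand.chromosome)
        length = end - start
        if not min_len <= length <= max_len:
            continue
        if start < min_boundary_dist or (ref_len - end) < min_boundary_dist:
            continue
        kept.append(cand)
    return kept


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[max(ri, rj)] = min(ri, rj)


def cluster_candidates(
    candidates: Sequence[InformativeScaffold],
    min_overlap_frac: float = 0.75,
) -> List[InversionCandidate]:
    """Single-linkage clustering of per-scaffold candidate intervals.

    Two candidates on the same chromosome support the same inversion iff
    their intervals overlap by at least ``min_overlap_frac`` of the longer
    of the two.  Clustering is joint across species; per-species support
    lists are retained.  The cluster's representative interval is the
    member interval of maximal length (the union span is also reported).
    Input order never changes the partition: candidates are first sorted
    deterministically.
    """
    cands = sorted(
        candidates,
        key=lambda c: (c.chromosome, c.candidate_interval[0], c.candidate_interval[1], c.scaffold, c.species),
    )
    uf = _UnionFind(len(cands))
    for i in range(len(cands)):
        ci = cands[i]
        si, ei = ci.candidate_interval
        for j in range(i + 1, len(cands)):
            cj = cands[j]
            if cj.chromosome != ci.chromosome:
                break
            sj, ej = cj.candidate_interval
            if sj >= ei:  # sorted by start, so no later j overlaps i either
                break
            ov = _interval_overlap(si, ei, sj, ej)
            if ov <= 0:
                continue
            if ov / max(ei - si, ej - sj) >= min_overlap_frac:
                uf.union(i, j)
    clusters: Dict[int, List[InformativeScaffold]] = {}
    for i, cand in enumerate(cands):
        clusters.setdefault(uf.find(i), []).append(cand)
    out: List[InversionCandidate] = []
    for root in sorted(clusters):
        members = clusters[root]
        rep = max(members, key=lambda c: (c.candidate_interval[1] - c.candidate_interval[0], -c.candidate_interval[0]))
        start, end = rep.candidate_interval
        union_start = min(c.candidate_interval[0] for c in members)
        union_end = max(c.candidate_interval[1] for c in members)
        support: Dict[str, List[str]] = {}
        for m in members:
            support.setdefault(m.species, []).append(m.scaffold)
        inv = InversionCandidate(
            chromosome=rep.chromosome,
            start=start,
            end=end,
            supporting_scaffolds={sp: sorted(scafs) for sp, scafs in sorted(support.items())},
            union_start=union_start,
            union_end=union_end,
            n_members=len(members),
        )
        for sp in inv.supporting_scaffolds:
            inv.orientation[sp] = "inverted"
        out.append(inv)
    out.sort(key=lambda c: (c.chromosome, c.start, c.end))
    return out


def polarize(
    cluster: InversionCandidate,
    outgroup_candidates: Sequence[InversionCandidate],
    outgroup_coverage: Optional[Sequence[Tuple[str, int, int]]] = None,
    min_overlap_frac: float = 0.75,
    species: Optional[Sequence[str]] = None,
) -> Dict[str, str]:
    """Label ancestral/derived orientations against an outgroup.

    Species whose scaffolds support the cluster are inverted relative to
    the reference.  If the outgroup (processed through the same cascade
    against the same reference) also supports the interval, the inverted
    state is ancestral and the reference orientation derived; if the
    outgroup has informative alignment coverage over the locus but no
    supporting candidate, it is collinear with the reference and the
    inverted state is derived; with no outgroup information the ancestral
    state is unknown.

    Returns a map species → {"inverted-ancestral", "inverted-derived",
    "reference-ancestral", "reference-derived", "unknown"} and records an
    ``ancestral_state`` entry on the cluster's orientation map.
    """
    og_supports = any(
        c.chromosome == cluster.chromosome
        and _interval_overlap(cluster.start, cluster.end, c.start, c.end)
        / max(cluster.length, c.length)
        >= min_overlap_frac
        for c in outgroup_candidates
    )
    og_covers = og_supports
    if not og_covers and outgroup_coverage is not None:
        og_covers = any(
            chrom == cluster.chromosome and _interval_overlap(cluster.start, cluster.end, s, e) > 0
            for chrom, s, e in outgroup_coverage
        )
    if og_supports:
        inv_label, ref_label = "inverted-ancestral", "reference-derived"
    elif og_covers:
        inv_label, ref_label = "inverted-derived", "reference-ancestral"
    else:
        inv_label = ref_label = "unknown"
    result: Dict[str, str] = {}
    supporters = set(cluster.supporting_scaffolds)
    for sp in sorted(supporters | set(species or [])):
        result[sp] = inv_label if sp in supporters else ref_label
    cluster.orientation = dict(result)
    cluster.orientation["__ancestral__"] = (
        "inverted" if og_supports else ("reference" if og_covers else "unknown")
    )
    return result


def ref_vs_ref_candidates(
    records: Iterable[AlignmentRecord],
    min_mapq: int = 10,
    merge_gap: int = 50_000,
) -> Tuple[List[InversionCandidate], List[str]]:
    """Reference-vs-reference inversion screen.

    Reverse-strand alignment blocks within a query scaffold yield
    candidates; only alignments with mapping quality >= ``min_mapq`` and to
    the scaffold's single reference chromosome are considered.  Query
    scaffolds whose every alignment is reverse-strand are possibly
    misoriented: they are flagged and yield no candidate.

    Returns (candidates, misoriented scaffold names).
    """
    by_scaffold: Dict[str, List[AlignmentRecord]] = {}
    for rec in records:
        if rec.mapq < min_mapq:
            continue
        by_scaffold.setdefault(rec.query_name, []).append(rec)
    candidates: List[InversionCandidate] = []
    misoriented: List[str] = []
    for scaffold in sorted(by_scaffold):
        recs = by_scaffold[scaffold]
        # restrict to the scaffold's modal chromosome ("to the same chromosome")
        span_by_chrom: Dict[str, int] = {}
        for r in recs:
            span_by_chrom[r.target_name] = span_by_chrom.get(r.target_name, 0) + r.target_span
        chrom = max(sorted(span_by_chrom), key=lambda c: span_by_chrom[c])
        recs = [r for r in recs if r.target_name == chrom]
        if all(r.strand == "-" for r in recs):
            misoriented.append(scaffold)
            continue
        rev = [
            StrandSegment(scaffold, chrom, r.target_start, r.target_end, r.query_start, r.query_end, "-")
            for r in recs
            if r.strand == "-"
        ]
        for seg in merge_same_strand(rev, max_gap=merge_gap):
            cand = InversionCandidate(chromosome=chrom, start=seg.target_start, end=seg.target_end)
            cand.supporting_scaffolds = {"": [scaffold]}
            candidates.append(cand)
    candidates.sort(key=lambda c: (c.chromosome, c.start, c.end))
    return candidates, misoriented


def detect_candidates(
    records_by_species: Dict[str, Iterable[AlignmentRecord]],
    genome_index: GenomeIndex,
    max_gap: int = 50_000,
    min_len: int = 50_000,
    max_len: int = 2_000_000,
    min_boundary_dist: int = 50_000,
    min_overlap_frac: float = 0.75,
    stats: Optional[dict] = None,
) -> List[InversionCandidate]:
    """Run the full cascade over pre-filtered records of several species.

    ``records_by_species`` maps species name → records already passed
    through :func:`cladesv.alignment_io.filter_primary`.  ``stats``, if
    given, collects per-step record counts (monotonically nonincreasing).
    """
    informative: List[InformativeScaffold] = []
    counts = {"scaffolds": 0, "post_filters": 0, "informative": 0, "post_size": 0}
    for species in sorted(records_by_species):
        by_scaffold: Dict[str, List[StrandSegment]] = {}
        qlens: Dict[str, int] = {}
        for rec in records_by_species[species]:
            seg = StrandSegment(
                rec.query_name, rec.target_name, rec.target_start, rec.target_end,
                rec.query_start, rec.query_end, rec.strand,
            )
            by_scaffold.setdefault(rec.query_name, []).append(seg)
            qlens[rec.query_name] = rec.query_len
        for scaffold in sorted(by_scaffold):
            counts["scaffolds"] += 1
            merged = merge_same_strand(by_scaffold[scaffold], max_gap=max_gap)
            decision = apply_scaffold_filters(scaffold, merged, qlens[scaffold])
            if not decision.kept:
                continue
            counts["post_filters"] += 1
            info = call_informative(scaffold, merged, species=species)
            if info is None:
                continue
            counts["informative"] += 1
            informative.append(info)
    sized = filter_candidates(
        informative, genome_index, min_len=min_len, max_len=max_len, min_boundary_dist=min_boundary_dist
    )
    counts["post_size"] = len(sized)
    if stats is not None:
        stats.update(counts)
    return cluster_candidates(sized, min_overlap_frac=min_overlap_frac)
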