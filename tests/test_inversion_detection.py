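"""The split-alignment cascade: merging, filters, clustering, polarization."""

import random

import pytest

from cladesv import scenarios
from cladesv.alignment_io import GenomeIndex
from cladesv.inversion_detection import (
    InformativeScaffold,
    StrandSegment,
    apply_scaffold_filters,
    call_informative,
    cluster_candidates,
    detect_candidates,
    filter_candidates,
    merge_same_strand,
    polarize,
    ref_vs_ref_candidates,
)

GI = GenomeIndex({"chr1": 5_000_000, "chr2": 5_000_000, "chr13": 5_000_000})


def seg(tstart, tend, strand="+", qstart=None, qend=None, chrom="chr13", scaffold="s"):
    span = tend - tstart
    if qstart is None:
        qstart, qend = 0, span
    return StrandSegment(scaffold, chrom, tstart, tend, qstart, qend, strand)


class TestMergeSameStrand:
    @pytest.mark.parametrize(
        "gap, n_expected",
        [(30_000, 1), (50_000, 1), (50_001, 2)],  # "not more than 50 kb apart"
    )
    def test_gap_boundary(self, gap, n_expected):
        a = seg(100_000, 150_000)
        b = seg(150_000 + gap, 240_000 + gap)
        merged = merge_same_strand([a, b])
        assert len(merged) == n_expected
        if n_expected == 1:
            assert (merged[0].target_start, merged[0].target_end) == (100_000, 240_000 + gap)

    def test_partially_overlapping_merged(self):
        merged = merge_same_strand([seg(100_000, 150_000), seg(140_000, 200_000)])
        assert len(merged) == 1
        assert (merged[0].target_start, merged[0].target_end) == (100_000, 200_000)

    def test_opposite_strands_never_merge(self):
        merged = merge_same_strand([seg(0, 50_000, "+"), seg(60_000, 100_000, "-")])
        assert len(merged) == 2

    def test_merged_query_interval_is_union_span(self):
        a = seg(0, 50_000, qstart=0, qend=50_000)
        b = seg(60_000, 100_000, qstart=55_000, qend=95_000)
        (m,) = merge_same_strand([a, b])
        assert (m.query_start, m.query_end) == (0, 95_000)


class TestScaffoldFilters:
    def test_low_aligned_fraction(self):
        segments = [seg(0, 19_000, qstart=0, qend=19_000)]
        decision = apply_scaffold_filters("s", segments, query_len=100_000)
        assert not decision.kept and decision.reason == "low-aligned-fraction"

    @pytest.mark.parametrize("rev_qstart, kept", [(25_001, True), (24_999, False)])
    def test_query_overlap_boundary(self, rev_qstart, kept):
        # forward query span [0,30000); overlap 4,999 kept, 5,001 dropped
        fwd = seg(100_000, 130_000, "+", qstart=0, qend=30_000)
        rev = seg(400_000, 435_000, "-", qstart=rev_qstart, qend=rev_qstart + 35_000)
        decision = apply_scaffold_filters("s", [fwd, rev], query_len=70_000)
        assert decision.kept is kept
        if not kept:
            assert decision.reason == "query-overlap"

    def test_reference_overlap(self):
        fwd = seg(100_000, 130_000, "+", qstart=0, qend=30_000)
        rev = seg(124_000, 160_000, "-", qstart=40_000, qend=76_000)
        decision = apply_scaffold_filters("s", [fwd, rev], query_len=80_000)
        assert not decision.kept and decision.reason == "reference-overlap"

    def test_containment(self):
        fwd = seg(100_000, 200_000, "+", qstart=0, qend=100_000)
        rev = seg(120_000, 140_000, "-", qstart=110_000, qend=130_000)
        decision = apply_scaffold_filters("s", [fwd, rev], query_len=500_000)
        assert not decision.kept and decision.reason == "containment"


class TestCallInformative:
    def test_both_strands_same_chromosome_informative(self):
        info = call_informative("s", [seg(100_000, 150_000, "+"), seg(150_000, 220_000, "-")])
        assert info is not None and info.chromosome == "chr13"

    def test_single_strand_not_informative(self):
        assert call_informative("s", [seg(0, 50_000, "+"), seg(100_000, 150_000, "+")]) is None

    def test_strands_on_different_chromosomes_not_informative(self):
        segments = [seg(0, 50_000, "+", chrom="chr2"), seg(0, 50_000, "-", chrom="chr13")]
        assert call_informative("s", segments) is None

    def test_whole_inversion_span_uses_reverse_segment(self):
        segments = [
            seg(100_000, 150_000, "+", qstart=0, qend=50_000),
            seg(150_000, 400_000, "-", qstart=50_000, qend=300_000),
            seg(400_000, 430_000, "+", qstart=300_000, qend=330_000),
        ]
        info = call_informative("s", segments)
        assert info.candidate_interval == (150_000, 400_000)

    def test_single_breakpoint_uses_union_span(self):
        segments = [
            seg(100_000, 150_000, "+", qstart=0, qend=50_000),
            seg(700_000, 800_000, "-", qstart=50_000, qend=150_000),
        ]
        info = call_informative("s", segments)
        assert info.candidate_interval == (100_000, 800_000)


class TestFilterCandidates:
    def make(self, start, end, chrom="chr13"):
        return InformativeScaffold("s", chrom, [], (start, end))

    @pytest.mark.parametrize(
        "start, end, kept",
        [
            (1_000_000, 1_049_999, False),  # length 49,999
            (1_000_000, 1_050_000, True),   # length 50,000
            (1_000_000, 3_000_000, True),   # length 2,000,000
            (1_000_000, 3_000_001, False),  # length 2,000,001
            (30_000, 90_000, False),        # endpoint 30 kb from scaffold start
            (50_000, 110_000, True),        # exactly 50 kb from the boundary
            (4_940_000, 4_990_000, False),  # 10 kb from scaffold end
        ],
    )
    def test_size_and_boundary_rules(self, start, end, kept):
        out = filter_candidates([self.make(start, end)], GI)
        assert (len(out) == 1) is kept

    def test_unknown_scaffold_errors(self):
        with pytest.raises(KeyError):
            filter_candidates([self.make(100_000, 200_000, chrom="chrX")], GI)


class TestClusterCandidates:
    def make(self, start, end, scaffold="s", species="sp"):
        return InformativeScaffold(scaffold, "chr13", [], (start, end), species)

    def test_seventy_five_percent_rule(self):
        # overlap 400 kb / max len 500 kb = 0.8 → one cluster
        a = self.make(1_000_000, 1_500_000, "a")
        b = self.make(1_100_000, 1_550_000, "b")
        assert len(cluster_candidates([a, b])) == 1

    def test_below_threshold_stays_split(self):
        # overlap 370 kb / max len 500 kb = 0.74 → two clusters
        a = self.make(1_000_000, 1_500_000, "a")
        b = self.make(1_130_000, 1_630_000, "b")
        assert len(cluster_candidates([a, b])) == 2

    def test_single_linkage_chains(self):
        a = self.make(1_000_000, 1_500_000, "a")
        b = self.make(1_100_000, 1_600_000, "b")
        c = self.make(1_200_000, 1_700_000, "c")
        # a~b and b~c at 0.8; a–c only 0.6, but the chain joins all three
        clusters = cluster_candidates([a, b, c])
        assert len(clusters) == 1
        assert clusters[0].n_members == 3

    def test_permutation_invariant(self):
        members = [self.make(1_000_000 + 7_000 * i, 1_500_000 + 11_000 * i, f"s{i}") for i in range(8)]
        reference = cluster_candidates(members)
        rnd = random.Random(7)
        for _ in range(5):
            shuffled = members[:]
            rnd.shuffle(shuffled)
            result = cluster_candidates(shuffled)
            assert [(c.chromosome, c.start, c.end, c.n_members) for c in result] == [
                (c.chromosome, c.start, c.end, c.n_members) for c in reference
            ]

    def test_representative_is_longest_member_and_union_reported(self):
        a = self.make(1_000_000, 1_500_000, "a")
        b = self.make(1_050_000, 1_600_000, "b")
        (cluster,) = cluster_candidates([a, b])
        assert (cluster.start, cluster.end) == (1_050_000, 1_600_000)
        assert (cluster.union_start, cluster.union_end) == (1_000_000, 1_600_000)


class TestPolarize:
    def cluster(self):
        scaf = InformativeScaffold("s1", "chr13", [], (1_000_000, 1_500_000), "spB")
        (c,) = cluster_candidates([scaf])
        return c

    def test_outgroup_supporting_makes_reference_derived(self):
        og = cluster_candidates([InformativeScaffold("o1", "chr13", [], (1_010_000, 1_510_000), "out")])
        result = polarize(self.cluster(), og, species=["spA", "spB"])
        assert result["spB"] == "inverted-ancestral"
        assert result["spA"] == "reference-derived"

    def test_outgroup_collinear_makes_inverted_derived(self):
        coverage = [("chr13", 900_000, 1_600_000)]
        result = polarize(self.cluster(), [], outgroup_coverage=coverage, species=["spA", "spB"])
        assert result["spB"] == "inverted-derived"
        assert result["spA"] == "reference-ancestral"

    def test_uninformative_outgroup_gives_unknown(self):
        result = polarize(self.cluster(), [], outgroup_coverage=[("chr2", 0, 5_000_000)], species=["spA"])
        assert set(result.values()) == {"unknown"}


class TestRefVsRef:
    def make_rec(self, record_factory, **kw):
        return record_factory(**kw)

    def test_mixed_strand_reverse_block_yields_candidate(self, record_factory):
        recs = [
            record_factory(query_name="q", query_start=0, query_end=300_000,
                           target_start=1_000_000, target_end=1_300_000, strand="+", mapq=50),
            record_factory(query_name="q", query_start=300_000, query_end=600_000, query_len=700_000,
                           target_start=1_300_000, target_end=1_600_000, strand="-", mapq=50),
        ]
        cands, flagged = ref_vs_ref_candidates(recs)
        assert len(cands) == 1 and not flagged
        assert (cands[0].start, cands[0].end) == (1_300_000, 1_600_000)

    def test_fully_reverse_scaffold_flagged_not_candidate(self, record_factory):
        recs = [record_factory(query_name="q", strand="-", mapq=50)]
        cands, flagged = ref_vs_ref_candidates(recs)
        assert cands == [] and flagged == ["q"]

    def test_mapq_boundary(self, record_factory):
        low = record_factory(query_name="q", strand="-", mapq=9)
        ok = record_factory(query_name="q", strand="+", mapq=10,
                            target_start=2_000_000, target_end=2_001_500)
        cands, flagged = ref_vs_ref_candidates([low, ok])
        assert cands == [] and flagged == []  # mapq 9 alignment is invisible


class TestPlantedRecovery:
    """Cascade + clustering against the generator's planted truth."""

    @staticmethod
    def matches(cluster, inv, min_overlap_frac=0.75):
        ov = min(cluster.end, inv["end"]) - max(cluster.start, inv["start"])
        return (
            cluster.chromosome == inv["chrom"]
            and ov > 0
            and ov / max(cluster.length, inv["length"]) >= min_overlap_frac
        )

    @pytest.mark.parametrize("seed", range(1, 21))
    def test_each_planted_inversion_is_exactly_one_clade_fixed_cluster(self, seed):
        records, cmap, truth, gi = scenarios.inversion_scenario(seed, with_outgroup=False)
        clusters = detect_candidates(records, gi)
        for inv in truth.inversions:
            hits = [c for c in clusters if self.matches(c, inv)]
            assert len(hits) == 1, f"inversion {inv} recovered by {len(hits)} clusters"
            assert hits[0].species_set == frozenset(scenarios.CLADE_B_SPECIES)
        # specificity: nothing beyond the planted inversions
        assert len(clusters) == len(truth.inversions)

    def test_translocation_and_strand_flip_decoys_rejected(self):
        records, cmap, truth, gi = scenarios.inversion_scenario(3, with_outgroup=False)
        clusters = detect_candidates(records, gi)
        for tract in truth.tracts:
            if tract["kind"] != "translocation":
                continue
            for c in clusters:
                if c.chromosome == tract["dest_chrom"]:
                    dest_end = tract["dest_start"] + (tract["end"] - tract["start"])
                    assert min(c.end, dest_end) - max(c.start, tract["dest_start"]) <= 0

    def test_self_alignment_yields_zero_candidates(self):
        records, cmap, truth, gi = scenarios.inversion_scenario(5, with_outgroup=False)
        collinear_only = {sp: records[sp] for sp in scenarios.CLADE_A_SPECIES}
        assert detect_candidates(collinear_only, gi) == []
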