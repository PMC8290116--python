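# Methods

`cladesv` re-implements, as a tested and reusable pipeline, a set of
comparative-genomics screens for a radiation of closely related species
with two chromosome-level reference genomes and many short-read draft
assemblies: inversion discovery from split scaffold-to-reference
alignments, repeat-region and copy-number detection from windowed read
depth, a pseudogenization screen (stop codons + pairwise Ka/Ks), and
windowed four-taxon introgression statistics. Everything runs end-to-end
on synthetic genomes with planted truth, so each stage's recovery
behaviour is measurable.

## Inversion detection from split alignments

A draft scaffold spanning an inversion breakpoint aligns to the reference
in two pieces on opposite strands of one chromosome. The cascade takes
minimap2-style PAF and applies, in order:

1. **Entry filters.** Scaffolds ≥ 5 kb; primary alignments only
   (`tp:A:P`); alignment length ≥ 1 kb, measured as the target span
   (reference-space length is what drives all downstream interval logic);
   mapping quality ≥ 60; approximate per-base divergence `dv` strictly
   below 0.25. Records without a `dv` tag are dropped with a warning (the
   divergence filter cannot be evaluated on them); `keep_missing_dv`
   inverts this. Where an aligner distinguishes gap-compressed (`de`)
   from uncompressed (`dv`) divergence, the uncompressed tag is the one
   consumed.
2. **Same-strand concatenation.** Per scaffold, alignments on the same
   chromosome and strand that overlap or lie ≤ 50 kb apart are merged;
   merged target and query intervals are union spans.
3. **Scaffold hygiene.** A scaffold is excluded when < 20% of its length
   aligns, or when a forward/reverse alignment pair comes from
   overlapping scaffold regions (> 5 kb), overlaps in the reference by
   > 5 kb, or one strand's alignment lies completely within the other's —
   all signatures of repeat-driven spurious splits rather than
   breakpoints.
4. **Informative call.** A scaffold is informative when one chromosome
   carries ≥ 2 of its merged segments with both strands represented.
5. **Candidate interval.** A segment flanked on both sides by
   opposite-strand segments (the `+,−,+` pattern) is the inversion
   interior and is used directly. Otherwise the scaffold spans a single
   breakpoint: the candidate is the union span of the minority-strand
   segment (smaller summed target span; ties resolved toward `−`, the
   reference-forward convention) and its nearest opposite-strand
   neighbour. For a scaffold crossing the left breakpoint of inversion
   `[a, b)` this yields `[a − u, b)` where `u` is the scaffold's forward
   overhang — conservative, and the quantity on which the overlap
   clustering is meaningful.
6. **Size and boundary filters.** Candidates 50 kb – 2 Mb long, with both
   endpoints ≥ 50 kb from the containing reference scaffold's ends.
7. **Clustering.** Two candidates on one chromosome support the same
   inversion when their intervals overlap by ≥ 75% of the longer of the
   two; clusters are single-linkage connected components, computed
   jointly across species with per-species support lists retained, after
   a deterministic sort so input order can never change the partition.
   The reported cluster interval is the longest member interval (so
   chained clusters cannot silently grow past 2 Mb); the union span is
   reported alongside.
8. **Polarization.** An outgroup processed through the identical cascade
   decides ancestry: if the outgroup supports the candidate the inverted
   state is ancestral; if the outgroup aligns collinearly over the locus
   the reference state is ancestral; with no informative outgroup
   coverage the orientation is unknown. A candidate is *fixed between
   clades* when every species of one configured clade supports it and no
   species of the other does — clade membership is configuration, never
   inference.

A second mode screens one chromosomal assembly mapped onto another:
reverse-strand blocks within a query scaffold (MQ ≥ 10, single
chromosome) become candidates, except query scaffolds whose every
alignment is reverse-strand, which are flagged as possible misorientations
and excluded.

**Resolution limit.** With the union-span candidate convention, the two
breakpoint-spanning scaffolds of inversion `[a, b)` produce intervals
`[a − u, b)` and `[a, b + w)` with overhangs `u, w` bounded by scaffold
length. Their reciprocal overlap is `L / (L + max(u, w))`, so the 75%
rule links them only when the inversion is at least ~3× the scaffold
length. This is a property of the method, not of the implementation: the
planted-truth scenarios therefore use inversions ≥ 3× the maximum
scaffold length (600 kb – 1.5 Mb against 20–150 kb scaffolds), and
recovery of inversions near the scaffold scale should not be expected on
real data either.

## Repeat regions and copy number from windowed depth

Mean read depth in nonoverlapping 25-kb windows is normalized per species
by the genome-wide median window depth — the only scale on which fold
thresholds compare across species with different sequencing depth. A
repeat region is a maximal run of ≥ 2 consecutive windows with
normalized depth ≥ 5 in *every* focal species and < 2 in every other
species with data at that window. Windows truncated at chromosome ends
count toward medians and may join a region, but a region cannot consist
solely of truncated windows.

Exon copy number is estimated two ways, deliberately kept independent:

* **Alignment counting** — the number of alignments of the reference exon
  sequence against a target assembly covering ≥ 50% of the exon length,
  capped at the mapper's reporting ceiling (1,000).
* **Coverage ratio** — mean read depth over the exon divided by the
  species' median genomic coverage. An exon outside covered territory is
  missing, never zero.

Transcript copy number is the median across its exons' estimates
(midpoint for even counts). Repeat-family enrichment uses the fold change
`(R_i/R)/(M_i/M)` (region vs homologous reference region) or
`(R_i/R)/(B_i/B)` (region vs the species' own genomic background) with a
two-sided Fisher's exact test on `[[R_i, R−R_i], [M_i, M−M_i]]` —
two-sided because depletion and enrichment are both reported as fold
changes. No multiple-testing correction is applied to the per-family
tests; the output carries raw p-values plus a Benjamini–Hochberg `q`
column, clearly an addition for convenience.

## Selection screen

Each putative exon copy is aligned against the reference exon (upstream,
or by the simulator). Alignment columns before the reference's first base
and after its last are trimmed (they can be artifacts of coordinate
extension). A copy is excluded when its sequence contains ≥ 10
consecutive Ns (assembly gap-fill; would fabricate frameshifts) or when
any insertion/deletion relative to the reference has length not a
multiple of three (a true frameshift makes codon comparison meaningless).
Reference-gap columns are then removed so every retained column indexes a
reference codon position.

Internal stop codons (TAA/TAG/TGA in the reference frame; gap- or
N-containing codons skipped) are counted, with the terminal codon exempt
only when the exon is annotated as the final coding exon.

Pairwise Ka/Ks follows Li (1993): each codon position is classified
nondegenerate / twofold / fourfold (the threefold isoleucine site counts
as twofold); site counts are averaged over the two sequences, and a
differing site whose class differs between the sequences is half-counted
to each class. Codons differing at multiple positions are resolved by
uniform averaging over minimal substitution pathways, discarding pathways
through stop codons unless all are blocked. Per class, transition and
transversion proportions get Kimura two-parameter corrections
(`A_i` transitions, `B_i` transversions), combined as

    Ks = (L2·A2 + L4·A4)/(L2 + L4) + B4
    Ka = A0 + (L0·B0 + L2·B2)/(L0 + L2)

Saturation (a non-positive logarithm argument) yields missing values with
a warning, never an exception; `Ks = 0` leaves the ratio undefined. The
statistic is exactly symmetric in its two sequences. The implementation
was verified against the R `seqinr::kaks` implementation of the same
estimator; the test-suite oracle is an independent direct-formula
evaluation. The Pamilo–Bianchi weighting variant is not implemented.

## Introgression statistics

Sites carry derived-allele frequencies `p1..p4` for populations P1, P2,
P3 and the outgroup under the topology `(((P1,P2),P3),O)`. All statistics
use frequency (not count) weights, so a polymorphic outgroup enters
naturally; the derived allele is the outgroup-minor allele, ties broken
toward the reference allele. Sites with a wholly missing population are
skipped; there is no imputation.

* **Patterson's D** = Σ(ABBA−BABA)/Σ(ABBA+BABA) with
  ABBA = (1−p1)p2p3(1−p4), BABA = p1(1−p2)p3(1−p4); undefined (not zero)
  on an empty denominator. Computed in 1-Mb windows discarding windows
  with < 100 informative sites (sites with positive ABBA+BABA weight).
* **Block jackknife.** Genome-wide D gets a standard error from
  delete-one estimates over contiguous 1-Mb blocks, weighted by per-block
  denominator mass (the standard weighting for a ratio statistic), using
  the weighted-jackknife variance formulas; Z = D/SE and a two-sided
  normal p. Identical blocks degenerate to SE = 0, reported with a
  warning as p = 0 (D ≠ 0) or 1.
* **f_dM** shares the D numerator; its denominator substitutes the donor
  frequency max(p2,p3) for both p2 and p3 when the site favours P2–P3
  sharing (p2 ≥ p1), and max(p1,p3) for both p1 and p3 — contribution
  negated — when it favours P1–P3 sharing. Bounded in [−1, 1]; positive
  means excess P3–P2 sharing. Default window 100 kb (configurable; the
  source analyses used both 100-kb and 25-kb grids and the package does
  not privilege either beyond the default).
* **D_XY** = mean over sites of `p_A(1−p_B) + p_B(1−p_A)`; a window with
  no genotyped sites is missing.
* **RND** (relative node depth) controls D_XY for substitution-rate
  variation: divergence of an ingroup to P3 normalized by the
  between-ingroup divergence. Both orientations are emitted (`rnd_p2` =
  dxy(P2,P3)/dxy(P1,P2), `rnd_p1` = dxy(P1,P3)/dxy(P1,P2)) since the
  focal lineage is an analysis choice.
* **Outliers**: windows strictly outside mean ± 3 SD of all retained
  windows are flagged, for f_dM and RND.

Window grids anchor at coordinate 0 of each chromosome; the trailing
partial window is retained subject to the informative-site minimum
(≥ 100; a 99-site window is absent, a 100-site window present).

## Synthetic data generator

Every input format the pipeline consumes can be generated with planted
truth; each generator is a pure function of (config, seed).

* **Clade genomes** are coordinate systems: clade B equals clade A with
  each planted inversion strand-flipped in place (an involution), plus
  optional translocation decoys. The desk-scale default is 4 chromosomes
  × 5 Mb, which accommodates 50 kb – 2 Mb inversions and the 50-kb
  boundary rule without rescaling. Coordinate-only simulation is the
  default: PAF is emitted from geometry with no sequence materialized
  (a full-sequence path would only be needed to run a real aligner).
* **Fragmentation** tiles each chromosome with random 20–150 kb
  fragments — the scaffold scale of short-read draft assemblies — with
  optional random scaffold orientation and a guarantee that required
  breakpoints are spanned with ≥ 10 kb flanks (fragment boundaries
  falling closer are removed, merging the neighbours).
* **Coverage** draws per-window read counts from a Poisson at the
  window's expected count for 250-bp reads at 60× base depth, times the
  planted fold — giving the ~2% window-level noise deep short-read data
  actually shows, rather than per-base Poisson noise. A dispersion
  parameter switches to a negative binomial; dispersion 0 is
  deterministic.
* **Site patterns** come from a pattern-probability model, not a
  coalescent: derived alleles arise on terminal branches (60%), the
  concordant internal branch (10%), or as ABBA/BABA discordance split
  equally (30%), so E[D] = 0 holds by construction outside tracts. Inside
  a planted tract the recipient's frequency is copied from the donor
  lineage with probability γ. Only the statistics' expectations matter
  for testing the estimators; users wanting linkage, drift and real
  coalescent noise can feed an externally simulated VCF-derived site
  table through the same interface.
* **Codon data**: random sense-codon references; copies with exact
  numbers of synonymous changes (at fourfold sites), nonsynonymous
  changes (at nondegenerate sites, never creating stops), whole-codon
  stop replacements, and 10-N runs; and an evolver that accepts
  synonymous proposals always and nonsynonymous ones with probability ω,
  so the realized rate ratio equals the target.

What the generator does **not** emulate — and what passing tests
therefore cannot show about real data: alignment error and repeat-driven
mismapping (hygiene-filter decoys are geometric, not sequence-derived);
linked selection and recombination-rate structure in the site patterns;
GC-biased or context-dependent mutation in the codon model; scaffold
misassembly beyond clean fragmentation.

## Problem sizes and numerical choices

The canonical scenarios run in seconds: 8 ingroup species + outgroup,
~1,900 scaffolds, 5 planted inversions; 16 species × 800 windows; 30k
sites over two 5-Mb chromosomes (tract scenario) or 100 replicates of
32k sites over 40 Mb (null calibration of the jackknife test); 100
replicate codon pairs of 300 codons per ω. These sizes were chosen so
the full suite and the acceptance script each complete in well under the
time a desk check should take, while every estimator still sits in its
asymptotic regime (≥ 10 jackknife blocks, ≥ 100 informative sites per
retained window, ≥ 60 substitutions per codon pair).

Ties and degeneracies are resolved deterministically throughout:
candidates sort by (chromosome, start, end, scaffold, species) before
clustering; the minority strand ties toward `−`; the cluster
representative ties toward the earlier interval; all simulator RNG flows
through per-call `numpy` generators seeded from explicit arguments.

## Known limitations

* Breakpoints are resolved only to scaffold-overhang precision; there is
  no base-level refinement and no read-pair genotyping of inversions.
* The clustering resolution limit above: inversions smaller than ~3× the
  scaffold length can split into two single-breakpoint clusters.
* Li's method is a counting estimator; for saturated or highly divergent
  pairs a maximum-likelihood codon model should be preferred, and none is
  provided here.
* Whether amplified copies are tandem or dispersed is not resolvable from
  windowed depth or exon-alignment counts.
* The jackknife normal approximation is anti-conservative below ~20
  blocks; the block count is reported so users can judge.
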