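# Methods

## The problem and the design

Two-sample subtractive designs detect somatic structural variants that are
present in one cell population (here: replicatively senescent, the
*tester*) and absent from its matched control (proliferating, the
*driver*). `senomob` implements two such readouts — de novo SVA
retrotransposon insertions from RDA-enriched amplicons, and de novo numts
from reads chimeric for mtDNA and nuclear sequence — together with the
annotation and quantification steps around them, and a simulator that
generates the whole design with planted truth so every pipeline stage can
be scored against known events.

## Alignment model

Both callers rest on exact and near-exact **ungapped** matching
(`senomob.align`), the package's stand-in for BLAT/blastn at toy scale.
The screens the pipelines need are 100%-identity (mt segments, flank
placement on error-free reads) and ≥ 95%-identity (subfamily queries);
neither requires gapped hits. Gapped alignments from an external aligner
can be supplied as PSL and pass through the same filter chain
(`placements_from_psl`).

* `align_exact` reports every *maximal* exact substring match of length
  ≥ `min_len` between query (both strands) and target, k-mer seeded
  (k = min(16, min_len)) with bidirectional extension and per-diagonal
  deduplication. Output ordering is fixed; there is no randomness.
* `align_near` aligns the full query at every offset reaching the
  requested identity. Candidate offsets come from the pigeonhole
  principle: with at most e mismatches allowed, one of e+1 query chunks
  must occur exactly; chunks shorter than 8 nt trigger a brute-force scan
  of all offsets instead.
* Circular targets (mtDNA) are searched on a doubled linearization
  (length 2L) with hits deduplicated modulo L; a hit at doubled-position 0
  that could extend left across the origin is dropped as the shadow of the
  origin-spanning hit found elsewhere. PSL records for circular targets
  carry `tSize = 2L` so origin-spanning hits remain valid PSL rows; BED
  output splits them into two lines sharing a name.
* `N` never matches anything, including another `N`; reads with > 10% N
  are dropped up front with a logged count.
* `pslScore = matches + repMatches − misMatches − qNumInsert − tNumInsert`;
  percent identity follows the milliBad convention (DNA/DNA variant), so
  identity is 1.0 exactly when an alignment has no mismatches and no gap
  openings.

## numt scanner

Filter chain, per read: (1) maximal 100%-identity mtDNA segments of
≥ `min_mt_len` (default 30 nt — shorter perfect matches to a 16.6 kb
mtDNA arise by chance against genome-scale backgrounds); (2) segments
longer than `max_mt_len` = 130 nt are discarded and the leftover flank
must be ≥ `min_flank` = 20 nt, both boundaries inclusive (a 130 nt segment
and a 20 nt flank pass — "exceeding 130" is discarded, "minimum 20" is
kept); (3) the flank must place gapless at ≥ 95% query coverage with a
unique best pslScore (any tie rejects) and carry no residual mtDNA
segment. Reads with two disjoint mt segments are processed per segment; a
read whose segment leaves flanks on both sides can contribute both.

Two-sample calling removes every senescent placement overlapping (≥ 1 bp,
whole-member semantics, as `bedtools intersect -v` would) a proliferating
placement or a known-numt interval, then merges survivors: placements
within `merge_window` = 100 nt whose mtDNA intervals overlap (modulo the
circle) support one call. The window absorbs the varying read offsets of
junction reads; without it one event would be multi-counted. Junction
reads from the *two ends* of a long segment carry non-overlapping mtDNA
intervals and are deliberately not merged — they are two junction
observations of one insertion, and both sit at the truth locus.

**Microhomology** is measured in read space: at an NHEJ-style junction
with microhomology m, the m bases on the nuclear side equal the m proximal
bases of the mt segment, so the longest such shared word (capped at 10 nt)
is reported. A call's value is the mode over its supporting placements;
since right-hand junction reads of a left-microhomology event contribute
only chance values, the mode can understate the planted value — the
per-placement values are retained for anyone who needs the distribution.

Per-mito-gene composition assigns each call's mtDNA interval to every
feature it overlaps on a bundled mtDNA feature map (genes, D-Loop, filler
for the tRNA clusters; human-layout coordinates scaled to the configured
mt length); percentages are over all assignments and sum to 100.

## SVA flank readout

An informative amplicon read is `adaptor + upstream flank + (CCCTCT)n +
SVA 5' head`. Parsing requires the adaptor as an exact prefix in either
orientation and a run of ≥ 3 exact hexamer units (degenerate units
terminate the run); the flank between the landmarks must be ≥ 20 nt.
Flank placement reuses the numt contract (unique, gapless, ≥ 95%
coverage). The insertion point is the flank end adjacent to the hexamer;
placements within `exclusion_window` = 100 nt of an annotated SVA are
germline-derived by construction and discarded (the annotation filter has
no published window; placements abutting an annotated element cannot be
distinguished from its own flank). Surviving points within 20 nt collapse
into one call with summed support — RDA fragmentation shifts read starts,
so exact-coordinate de-duplication would undercount. "Total" counts are
read-level support; "unique" counts distinct collapsed coordinates.
Replicate overlap links coordinates within the same 20 nt tolerance,
counts transitive clusters once, and reports exact per-subset (Venn)
counts, which satisfy inclusion–exclusion by construction.

## Annotation and the cleavage consensus

One label per site under the fixed precedence Promoter > 3UTR > Exon >
TTS > SINE > LINE > LTR > Satellite > DNA > Intron > Intergenic, with
Promoter = TSS −1000..+100 and TTS = −100..+1000 encoded in the gene
sub-feature track. Repeat classes outrank Intron because repeat and
intron fractions are reported side by side as disjoint categories. The
midpoint rule (a site is annotated by the features containing its
midpoint) avoids double-labelling wide sites; an any-overlap switch
exists. The L1 endonuclease consensus scan is deterministic: a site
matches if either strand within ± 10 nt of the insertion point contains
TTTT immediately followed by AA, allowing one mismatch inside the TTTT
tract. It replaces de novo motif discovery, which is out of scope; its
matched fraction is not comparable to discovered-motif site percentages.

## Abundance

A read counts toward a query when it has ≥ 1 ungapped alignment at the
requested identity, with read and query in either role (the shorter
sequence is aligned within the longer), once per query; a read matching
two queries counts toward both. RPM = count / (total reads / 10⁶);
`FC = log2((RPM_t / rate_t) / (RPM_r / rate_r))` with per-sample overall
alignment rates as correction factors; a zero reference RPM reports as
missing, never ± infinity. Fold changes are always reported on the log2
scale. Note that because RPM normalizes by total library size, a k-fold
mtDNA copy-number change produces a per-tile RPM ratio below k whenever
mtDNA is a non-negligible library fraction — pronounced on toy genomes,
negligible at genome scale.

## Synthetic data: what it emulates, and what it does not

The simulator builds random-background chromosomes with planted germline
features (SVAs with 30–50 hexamer repeats, numts, Alu/LINE/LTR/Satellite
copies at 5% divergence, genes with promoter/exon/intron/3UTR/TTS
sub-features), then inserts de novo events into the senescent copy only:
numts as mtDNA substrings (default 40–400 nt, so the truth contains both
detectable and — beyond 130 nt per-read segments — partially undetectable
events; possibly origin-spanning) with a *genuinely planted* junction
microhomology of 0–5 nt (the mtDNA start is chosen so its first m bases
equal the m reference bases left of the insertion point), and SVAs as
hexamer-headed subfamily elements with 4–20 nt target-site duplications.
Elements are planted on the + strand; strand diversity enters through
read orientation. Insertion points default to unbiased
(`repeat_target_bias = 0`); the bias knob relocates them into annotated
repeats.

Reads are single-end 150 nt: the scanners operate on single continuous
reads, so paired ends would add nothing to the detection logic. WGS reads
are uniform with mtDNA at a configurable copy-number weight and are
error-free by default (the pipelines demand 100% identity; an error-rate
switch exists to measure sensitivity loss). RDA is modeled as per-locus
Bernoulli suppression (default efficiency 0.99) of driver-shared loci
plus multiplicative amplification (default 50×) of tester-unique loci —
an enrichment black box, not hybridization kinetics. AluScan emits
amplicons between inward-facing Alu pairs within 5 kb. The six SVA
subfamily sequences and the RDA adaptor are synthetic stand-ins bundled
so nothing is downloaded; real sequences can be substituted via
parameters. Not emulated: base-quality models, PCR duplicates, chimeric
artifacts other than planted events, diploidy/heterozygosity — so passing
recovery tests demonstrate the *logic* of the filter chains under the
stated read geometry, not robustness to sequencing noise or repeat-driven
mismapping at genome scale.

## Problem sizes and seeds

Spike-in experiments run on 2 × 50 kb genomes: numts with 10 de novo
(50–130 nt segments) vs 5 germline events at 50× coverage and mtDNA copy
number 2 (mt depth is irrelevant to numt detection, which keys on nuclear
junction reads), SVAs with 10 de novo vs 50 germline loci under perfect
subtraction; both are seed-swept (20 seeds in the test suite). An event
counts as *geometrically detectable* when the simulated read set contains
at least one junction read satisfying the scanner's own length contract,
computed from the chance-extended effective segment; sensitivity is scored
over those events, since no read-based method can call an event no read
covers informatively. All randomness flows from explicit integer seeds
through `numpy.random.default_rng`; fixed seeds give byte-identical
outputs, including the end-to-end pipeline report.

## Known limitations

The internal matcher is a functional stand-in for BLAT, not a replica
(tile size, minScore and the like are not modeled); the uniqueness notion
is "single best pslScore, no tie". Full-length numts longer than a read
are observed only through their two junctions and are not assembled.
Subfamily assignment of an inserted SVA from the amplicon is not
attempted (the 5' head is too short), and the readout is by design
unsuitable for 5'-truncated LINE-1 insertions. Composition percentages
for a handful of calls are coarse (one assignment per overlapped
feature). The capacity allocator rejects feature sets that do not fit the
requested genome with its minimum spacing rather than silently packing
them.
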