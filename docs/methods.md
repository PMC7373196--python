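# Methods

This note documents the models and procedures implemented in `dcscan`, the
defaults and why they were chosen, what the synthetic-data generator does and
does not emulate, and the numerical conventions used throughout.

## Coordinates and normalisation

All internal coordinates are 0-based half-open; 1-based inclusive appears
only in exported report tables (cluster and cleavage-site TSVs). RPM (reads
per million) uses the number of genome-aligned reads as its denominator —
not the raw read count — so normalisation is unaffected by unmappable noise;
RPKM for an interval counts reads by 5′-end containment, so each read
contributes to exactly one position, times 10⁹/(library · interval length).

## Read processing and mapping

Adapter trimming removes the read suffix at the leftmost exact match of the
adapter's first k ≥ 3 bases running to the read 3′ end (or a full internal
adapter occurrence); no error tolerance is applied, and reads shorter than
15 nt after trimming are discarded. The mapper reports a read iff its
sequence, or its reverse complement, occurs exactly once in the reference
considering both orientations jointly; multi-occurring reads are dropped and
counted. This exact-unique contract is deliberate: duplex detection
identifies reads with the genomic substrings they came from, and a read
whose sequence is ambiguous in the genome cannot be assigned a duplex
partner. General-purpose aligners (bwa, minimap2) tolerate mismatches and
report multi-mappers under their own policies, which would silently break
that contract, so they are not used; alignments produced externally can be
supplied as SAM or BED6 instead and enter the pipeline unchanged.

## Cluster calling

A cluster is seeded by any 200-bp window (evaluated at every base offset,
implemented as a cumulative-sum sweep that is exactly equivalent to
enumeration) containing at least 2,000 read 5′ ends, both strands pooled;
the threshold is strict in the sense that 1,999 reads never qualify, and can
alternatively be given in RPM. Maximal runs of qualifying offsets (optionally
bridging gaps ≤ `merge_gap`) become clusters. Reads are localised by their
5′ end because cleavage products are anchored by the cut that created them;
the reported interval is the tight span of the contributing 5′ ends rather
than the window union, which is why a cluster can span a few dozen
coordinates despite the 200-bp window. Deciles are assigned by total RPM,
most abundant first; when the cluster count is not divisible by 10 the top
deciles take the extra members, and RPM ties are broken by genomic
coordinate so the assignment is deterministic.

## Duplex (cleavage-site) detection

RNase III leaves a 2-nt 3′ overhang at each end of its products, so a
duplex appears in the data as a plus-strand unique read `[a, a+L)` paired
with a minus-strand unique read `[a−2, a+L−2)`, both of the same length
L ∈ {21, 22} and both at ≥ 1 RPM. The abundance bound is inclusive
(`min_rpm_strict` switches to strict), equal strand lengths are required by
default (a flag admits 21/22 mixed pairs for exploration, where only the
left-end offset is then exact), and chained duplexes sharing a cut are all
reported. The paired region is `[a, a+L−2)`; the overhang dinucleotides are
`[a+L−2, a+L)` on the plus strand and `[a−2, a)` read on the minus strand.

A structural property worth noting: with a 2-nt overhang the minus read's
coordinates uniquely encode its own product's plus interval, so a detected
pair always corresponds to a single real duplex product — false pairs
cannot be assembled from reads of two different products. With blunt
(overhang-0) products that encoding is lost, and in dense data two products
from *different* molecules lying exactly 2 nt apart with equal length can
coincidentally satisfy the detector geometry. The blunt-end control in the
verification suite therefore digests one molecule per locus: a single
digestion pattern tiles the overlap disjointly, an offset-2 equal-length
pair would have to overlap, and emptiness of the duplex set becomes a
theorem of the geometry rather than a sampling accident.

## Composition profiling

Reads of fixed length L are profiled per position together with 10-nt
genomic flanks taken in read orientation (reverse complemented for
minus-strand records), positions numbered −10..−1, 1..L, L+1..L+10. The
position set is partitioned exactly into: body 4..L−5 (4..17 for 22-mers,
4..16 for 21-mers); the read's own overhang {L−1, L}; the partner-strand
overhang {−2, −1}; four 3-nt cleavage-flank windows {−5..−3}, {1..3},
{L−4..L−2}, {L+1..L+3} placed immediately inside and outside each modeled
scissile bond (half of these positions lie outside the read, which is what
makes the AU signal attributable to the enzyme rather than to cloning bias);
and background (the remaining flank positions). Profiles can weight each
unique sequence once or by read count — unique weighting suits
cleavage-site collections, abundance weighting suits whole-library views;
both are exposed. Body-GC comparisons between read sets use the difference
of per-sequence means and a two-sided Mann–Whitney U test, chosen because
per-sequence GC fractions are bounded, discrete and not remotely normal;
when every value is tied the p-value is reported as 1.

## Gene quantification and overlap statistics

A read is assigned to every gene whose interval contains the read midpoint
(`floor((start+end)/2)`); same strand counts as sense, opposite as
antisense; reads hitting no gene are tallied as intergenic. Midpoint
assignment keeps a ~21-nt read's contribution unambiguous at gene edges; an
any-overlap mode is available behind a flag. Library correlations are
Pearson on `log10(x + 0.1)`-transformed per-gene values (pseudocount
configurable). Cluster/feature overlap requires ≥ 1 shared base (strand
ignored); TSS proximity accepts a TSS within 50 nt of either cluster edge,
`start − 50 ≤ t < end + 50`. Read-density comparisons between two interval
groups report the arithmetic-mean RPKM ratio as the headline fold change
(the geometric-mean ratio, with a half-minimum pseudocount for zeros, is
also reported since densities are compared on a log scale), a two-sided
Mann–Whitney U p-value between the groups, and an empirical p-value for each
group against `n_control_sets` random interval sets with the identical
length multiset placed uniformly on the reference:
`p = (1 + #{controls with mean ≥ observed}) / (n + 1)`, which is bounded
below by `1/(n+1)` by construction.

## The synthetic-data generator

The generator emulates the statistical structure the analysis assumes, stage
by stage, all driven by one seed (per-stage generators are derived
deterministically from it, so fixed config ⇒ byte-identical outputs).

**Genome.** I.i.d. bases with P(G)=P(C)=gc/2; default GC 0.508, the GC
content of the E. coli K-12 chromosome.

**Loci.** Planned loci are placed left to right with 60-bp margins (a
placement error names the first locus that does not fit). Architectures:
`divergent5` (overlap at the two 5′ ends, transcription pointing apart),
`convergent3` (overlap at the 3′ ends), `full_overlap` (antisense gene
contained in the sense transcript) and `novel_as` (same geometry, but the
asRNA is deliberately absent from the emitted annotation, since it models an
unannotated antisense transcript). Transcripts default to the overlap plus a
150-nt extension. The overlap region is the dsRNA substrate and must exceed
the product length by ≥ 4 nt.

**Digestion.** Each of the locus's `abundance` dsRNA molecules is cut
sequentially 5′→3′ along the overlap: spacing is drawn as
`round(Normal(mean, sd))` clamped to ≥ 6, with the mode-dependent mean
(14 bp for Mg²⁺ buffer, 21 bp for Mn²⁺; sd 1.5). The realised cut is chosen
among the seven offsets within ±3 of the sampled spacing with probability
proportional to a triangular prior `(4 − |offset|)` times
`exp(β_site · score)`, where the score is the AU fraction of the 3-nt
windows on either side of the scissile bonds plus the GC fraction of the
2-nt overhang (each term scaled to [0, 1]). The triangular prior keeps the
product-length mode pinned at the buffer-mode mean — a uniform prior over
the seven offsets flattens the length distribution enough that the modal
length becomes a coin flip between neighbouring values at realistic sample
sizes, which would contradict the clearly modal ~14 vs ~21 bp behaviour the
model is meant to reproduce. Each cut severs the minus strand 2 nt to the
left of the plus-strand cut, so every internal product is a perfect duplex
with 2-nt 3′ overhangs; the two terminal fragments of each molecule have
only one cut end, are flagged non-duplex and are never captured. β_site
defaults to 2.0: the enzyme's preference strength is not quantified anywhere
we know of, and this value reproduces roughly the observed ~60% GC in
overhangs and ~60% AU in cleavage flanks of captured products.

**p19 capture.** Each duplex product is retained with probability
`w(L) · exp(β_body · bodyGC) / (max w · exp(max(β_body, 0)))` — a proper
Bernoulli probability independent of pool composition — with length weights
defaulting to mass on {21, 22} and bodyGC the GC fraction of plus-strand
positions 4..L−5. β_body defaults to 3.0; under the selection model the
expected body-GC shift of the captured pool is ≈ β_body · Var(bodyGC) ≈
3 × 0.13² ≈ 0.05, matching the ~5-percentage-point body-GC elevation that
capture produces relative to raw digestion products. It is a free parameter,
not a fitted value.

**Read emission.** Per captured duplex with molecule count n, strand read
counts are `Poisson(n·b)` and `Poisson(n/b)` with `log b ~ Normal(0,
strand_bias_sd)` drawn once per duplex (cloning strand bias; default sd
0.25). Reads are exact genomic substrings at Q40 — no sequencing errors are
simulated because the mapper is exact-match by design. Background noise
reads are single-stranded, 18–30 nt, uniformly placed; they stand in for
RNase III products of structured single-stranded RNA that escape p19
capture, without modelling RNA secondary structure. The truth tables record
captured duplex coordinates with counts, and `expected_clusters` is computed
by running the cluster caller's own window rule on the emitted duplex-derived
reads (noise excluded) rather than on expected counts, so the truth is
exactly consistent with the written FASTQ and cluster recovery is a sharp
check instead of a probabilistic one.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: imperfect duplexes, stem-loops and rRNA
precursors; sequencing errors and quality variation; platform-specific
composition bias (real SOLiD and Illumina libraries of the same material
differ markedly in apparent body GC); adapter chemistry beyond an optional
fixed 3′ adapter; transcription-level correlation structure between
neighbouring loci; and any RNA secondary structure. Results on real
libraries additionally depend on the upstream aligner's mismatch and
multi-mapping policy, which the exact-match mapper side-steps.

**Calibration fixture.** `plant_composition_reads` is a separate generator
used to verify the profiler itself: it writes reads plus flanks into a
synthetic genome with *exactly* planted per-region base probabilities
(overhang positions G/C with probability g, cleavage-flank positions A/T
with probability f, everything else at background GC). The digestion model
cannot plant exact probabilities — β_site only tilts cut choice — so
profiler recovery is tested against this fixture (±0.03 at 5,000 sequences),
independent of the digestion model.

## Problem sizes used in tests and the verification script

Simulations run on 15–80-kb genomes with 1–40 loci and molecule counts from
1 (the geometry-isolating blunt control) to 3,500 per locus (cluster-calling
at the full 2,000-read threshold); the duplex-finder oracle comparison uses
200 random instances of 20–2,000 unique records including five at the
2,000-record bound; composition recovery uses 5,000 planted sequences;
density comparisons use 20 + 20 loci at a 30:1 planted abundance ratio with
100 length-matched control sets. These sizes make every stochastic check
well-resolved (the quantities under test have standard errors several times
smaller than the asserted tolerances) while the full suite runs in well
under a minute per test.

## Known limitations

* The duplex detector cannot identify cleavage sites in structured
  single-stranded RNA — only perfectly paired duplexes carry the 2-nt
  overhang signature in trans.
* At very high coverage of blunt-ended (non-RNase III) duplex material,
  coincidental offset-2 pairs across molecules can mimic the signature (see
  the duplex-detection section); the 1-RPM abundance filter suppresses this
  in deep real libraries but is weak in tiny ones.
* The exact-match mapper is only suitable for small references (it scans
  per unique read sequence); bacterial genomes and plasmids are fine,
  large genomes are not the target.
* Cluster intervals are reported as tight spans of read 5′ ends; other
  reasonable reporting conventions (window unions) would give systematically
  wider intervals.
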