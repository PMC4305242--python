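# Methods

## The measurement model

Drones are haploid gametes of their queen. At a marker site — a position
where the queen is heterozygous — each drone carries exactly one of the
queen's two alleles, so a chromosome-length drone genotype is a mosaic of
the queen's two haplotypes. Two observations follow:

1. **Phasing.** For two adjacent markers, drones vote for one of the two
   possible allele linkages; since the chance of a crossover between
   markers a few hundred bp apart is ~10⁻⁴ per meiosis, the majority
   linkage is the queen's and the minority drones are recombinants.
   Chaining the pairwise majorities left to right phases the chromosome.
2. **Event calling.** Comparing a drone with the phased haplotypes
   segments it into maximal blocks of one haplotype label. Block *span*
   is the distance between the block's end markers. Almost all directly
   observed gene-conversion tracts are far below 10 kb, so interior
   blocks spanning ≤ 10 kb are conversion tracts and longer blocks are
   the crossover backbone; each transition between consecutive backbone
   blocks is one crossover, located between the two flanking markers.

Two adjacent short blocks immediately upstream of a crossover block, with
the distal block starting within 10 kb of the crossover block's edge, are
the single-gamete signature of one *complex CO-associated conversion* and
are merged into one event. *Simple* CO-associated tracts merge invisibly
into the crossover breakpoint; single-gamete typing cannot recover them,
which is why the CO-associated conversion rate is a lower bound. All
other short blocks are non-crossover (NCO) conversions.

Workers are diploid (queen gamete + foreign drone-father haplotype). The
queen-derived allele is resolved where the worker is homozygous, or
heterozygous with exactly one allele in the queen's pair; sites where the
worker's het equals the queen's pair are uninformative (~45% at these
heterozygosities). Only crossovers are called in workers — het/hom
miscalls mimic short tracts, so conversions are not.

## Marker filters and multi-copy regions

Heterozygous calls in a haploid drone are impossible except through
copy-number variation (reads from two diverged copies piling onto one
locus), mapping artifacts or genotyping error. Marker filtering therefore
(1) starts from queen-het biallelic SNVs (indels ignored), (2) discards
any site heterozygous in at least one drone, (3) discards sites where a
drone shows an allele outside the queen's pair, and (4) requires call
quality ≥ 30. Pooled drone het sites are chained into multi-copy regions
(≥ 2 consecutive sites, every gap ≤ 2 kb, boundaries at the outermost
member sites); chaining is pooled rather than per-drone because the
duplication-bearing haplotype segregates among drones, and most het sites
recur in two or more of them. Conversion-sized event candidates
overlapping these regions are masked; an isolated crossover spanning a
masked region is kept, because its haplotype switch is still witnessed by
clean flanking markers.

Inside a multi-copy region the duplication is linked to one queen
haplotype, so drones split into a constantly-heterozygous and a
constantly-homozygous pattern. A drone whose pattern switches het↔hom
across at least two consecutive member sites (and shows no coverage-drop
evidence, when provided) is a conversion candidate in the multi-copy
fraction of the genome. Two sites are required — rather than one, as for
standard conversions — because these calls ride on the noisiest part of
the alignment.

## Simulator

The generator's defaults are the study conditions: a 16-chromosome,
219.6 Mb genome (scaled versions keep chromosome proportions); marker
spacing geometric with mean 314 bp; crossovers uniform per bp at
0.371/Mb/meiosis (37.1 cM/Mb; a gamma-interference hook exists but is off
— the calling model assumes none); NCO tracts Poisson with mean 5.1 per
meiosis (the distribution of counts is not constrained by the study;
Poisson is the natural choice for independent events) and geometric tract
lengths with mean 700 bp ("well under 2 kb" but configurable); 8% of
crossovers carry a conversion tract of which 10% are complex — making
complex CO-associated conversions ~0.8% of crossovers, the observed
fraction, while the simple remainder is invisible by construction;
multi-copy regions covering 13.5% of the genome with geometric lengths of
mean 4 kb (most regions below 10 kb; long enough that the 2-kb chaining
rule can recover them at 314 bp marker spacing); genotyping errors at
10⁻⁵ per drone-site, split evenly between allele flips and spurious het
calls (the error model is not specified by the study; symmetric is the
neutral choice); assembly gaps as runs of 50,000 N. Worker foreign
haplotypes carry either queen allele with probability 0.45 each and a
third nucleotide otherwise, approximating an independent haplotype at
segregating sites. Queen calls are treated as error-free (queens are
sequenced at twice the drone depth). Everything is reconstructible from
the truth set: gamete labels per marker, event list, CNV intervals and
error masks.

What the simulator does *not* emulate: read-level artifacts (coverage,
mapping quality, indel confusion), linkage disequilibrium structure in
the foreign haplotypes, interference, and non-uniform marker density
(real heterozygosity clusters). Passing recovery tests therefore
demonstrates correctness of the calling logic under the stated
conditions, not robustness to alignment pathologies — those enter only
through the pluggable read-evidence filters.

## Numerical and design choices

* Coordinates are 1-based inclusive (VCF convention); landscape windows
  are half-open 0-based internally and exported 1-based.
* Breakpoint point estimate = midpoint of the flanking-marker interval;
  the interval itself is retained for all proximity logic.
* Tie votes during phasing (possible with even drone counts or
  missingness) carry the running phase forward unchanged and are flagged;
  this minimizes spurious switches and matches the conservative
  gap-site rule. Drones missing at either of two adjacent markers do not
  vote. Chaining is strictly sequential; no global optimization.
* Block segmentation tolerates isolated discordant sites: a 1-marker run
  flanked by ≥ e consistent markers on both sides is treated as a
  genotyping error (default e = 2). On error-free data e = 0 reproduces
  the literal method and keeps single-marker tracts; the validation suite
  and acceptance script use e = 0 on error-free simulations so that
  conversion detection can be compared with its information-theoretic
  bound, P(tract contains ≥ 1 marker).
* Crossover *sensitivity* is measured over callable breakpoints: those
  further than the span cutoff from a chromosome end (a closer one gives
  a terminal short block, which generates no event) and without a second
  crossover of the same meiosis within the cutoff (such pairs collapse
  into a short interior block that the span rule reads, by design, as a
  conversion). At full genome scale both exclusions are ~0.2% of events;
  at 1/11 test scale they are ~3% and would otherwise dominate the
  measurement.
* The Poisson hot/cold test uses the genome-wide crossover density per bp
  times each window's length as that window's null mean, so partial
  chromosome-end windows are not spuriously cold; raw one-tailed
  p-values (the study's procedure) and Benjamini–Hochberg calls are both
  emitted. At ~3.2 expected crossovers per 200 kb window the realized
  type-I rate of the raw P < 0.05 hot call is ~0.043 — below nominal
  because of Poisson discreteness.
* Empirical permutation p-values are (M + 1)/(reps + 1) and floor at
  1/(reps + 1). Motif shuffles are uniform letter permutations drawn with
  replacement, so a shuffle can reproduce the motif itself; the
  attainable floor for a low-entropy motif is correspondingly higher
  (e.g. ~1/7 for a 7-letter motif with only 7 distinct arrangements).
  For the same reason, calibration of the shuffle test is demonstrated
  with a composition-rich motif (GATCGAT, 630 distinct arrangements):
  low-entropy motifs make the p lattice too coarse for any finite-sample
  uniformity check. Homopolymers are rejected outright.
* The u/v statistic counts AT→GC conversions per A/T recipient allele and
  GC→AT conversions per G/C recipient allele over converted marker sites.
  The null flips each direction-informative site's polarity with
  probability 1/2; because the within-class recipient counts shift the
  null ratio away from 1, the two-sided p is the doubled smaller tail of
  the null distribution around its own centre, not around 1.
* Worker/drone crossover concordance is tested with the exact
  Mann–Whitney rank test. The Brunner–Munzel statistic is also exposed,
  but its t-approximation is anticonservative below ~10 samples per
  group (type-I ≈ 6.5–7% at 6 workers), so the calibrated exact test is
  the default check at these sample sizes.
* Gene-set proximity enrichment uses a 2×2 chi-square without continuity
  correction; a density-matched background can be supplied via
  `background_ids`.

## Problem sizes

The validation suite runs on 1/11-scale genomes (~20 Mb, ~64,000
markers, 15 drones, 6 workers): 20 colonies for phasing/event recovery
and threshold robustness, 1,000 uniform null genomes at full scale for
hotspot calibration, 200 null runs at 500 permutation replicates for the
randomization statistics, and 100 simulations each for u/v power
(250 planted tracts, 60:40 bias) and worker/drone concordance
(1/20-scale colonies). These sizes were chosen so the whole suite
completes in a few minutes while keeping every estimate's Monte-Carlo
error well inside the asserted bands.

## Known limitations

* Simple CO-associated conversions are invisible in single gametes; the
  package reports the complex-fraction extrapolation but cannot validate
  it.
* The read-evidence exclusion filters (uninterrupted mapping, insert
  size) are contract-level predicates; the package does not process
  alignments.
* Multi-copy conversion candidates assume the region's het/hom patterns
  are faithfully genotyped; real CNV loci violate this in ways the
  simulator does not model.
* Marker-downsampling estimates share the phasing stage, so at very low
  marker counts the curve mixes detection loss with phasing noise — as
  it does in the real procedure.
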