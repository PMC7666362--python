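# Methods

## The measurement model

A CLIP library reduces each usable read to its 5′ start, taken as the
protein–RNA crosslink position. All coordinates in this package are
0-based half-open; strand is carried on every read and never mixed
within a cluster. Abundances are RPM — reads per million genome-mapped
reads of the read's own library — so libraries of different depth are
comparable.

The central contrast is between wild-type AGO2 and slicer-dead AGO2
(D597A or D669A; the two behave as replicates and are pooled by
concatenating reads and summing the RPM denominators). Cleavage
destroys the wild-type footprint together with its RNA, so the
(mutant + c)/(WT + c) abundance ratio of a binding site measures its
cleavage susceptibility. AGO1, which cannot slice, plays the same role
as the mutant in the endogenous-miRNA analysis.

## Pipeline stages and thresholds

**Cluster calling.** Single-linkage merging of 5′ positions with gap
≤ *window* (default 6 nt), per chromosome and strand; a gap of exactly
the window still links. The interval spans [min pos, max pos + 1);
the count includes duplicate positions. This is the standard iCLIP
clustering semantics; the window is exposed as a flag.

**Input noise filter.** A cluster is protein-specific iff its RPM
strictly exceeds `min_rpm` (default 5) and is at least `min_fold`
(default 15) times the input abundance. The input side is recounted
positionally — input read starts inside the cluster interval, same
strand — rather than by calling input clusters, because the
comparison is per-interval relative abundance. Zero-input intervals
take a pseudocount (default 0.1 RPM, configurable) so the ratio stays
defined.

**Cluster universe.** Filtered clusters of all libraries are merged
strand-specifically (any overlap, touching ends included) and each
library's reads are recounted on the merged intervals, so a library
whose own clusters missed an interval still contributes its (possibly
zero) abundance there. The universe deliberately includes the
mutant-condition clusters: a strongly cleaved site can be so depleted
in wild type that it fails the input filter there, yet it must remain
in the comparison set — it is the most interesting class.

**siRNA enrichment (the k cutoff).** Fold enrichment per universe
interval is (RPM with shRNA + c)/(RPM without shRNA + c) in the
wild-type libraries. Clusters strictly above *k* are siRNA-enriched.
*k* can be fixed, or estimated from the data: a Gaussian kernel
density (Silverman bandwidth) of the log2 fold ratios is scanned above
its mode; the crossing where density first falls below
`density_alpha` (default 0.05) × peak marks where clusters become far
rarer than the unenriched bulk. If the data mass beyond the crossing
is negligible (< 1%; the extreme tail of a unimodal distribution
carries ~0.7% at α = 0.05) or the density never rises again, the
distribution is declared unimodal and a no-threshold error instructs
the caller to supply a fixed k. Otherwise k is placed a quarter of the
way, in log space, from the crossing toward the mode of the enriched
component — near the bulk edge of the inter-mode valley. The placement
is deliberately conservative (sensitivity-first): the subsequent
mutant/WT classification, not this cutoff, provides specificity.

**Classification.** Over the enriched set, ratio_norm =
ratio_mut_wt / median(ratio_mut_wt); an even-sized set uses the mean
of the two central values. Bands, both edges closed on the
cleaved/noncleaved side: cleaved iff ratio_norm ≥ 2.0; noncleaved iff
1.4 ≤ ratio_norm < 2.0; otherwise unclassified. Median normalization
(rather than the raw ratio) follows from defining the bands as
enrichment *over the median*; a raw-ratio mode is available as a flag
for sensitivity analysis. The on-target site is identified by
sequence, not by rank: an enriched interval whose ±10-nt-extended
sequence contains the full reverse complement of the guide. Ranking
top by ratio_norm is an expected *outcome*, not the definition.

**Endogenous cleavage.** Over a universe of AGO1, pooled-mutant and
wild-type libraries, a site is an endogenous miRNA-mediated cleavage
target iff both (AGO1 + c)/(WT + c) ≥ 2 and (mut + c)/(WT + c) ≥ 2.
The conjunction is what gives the call its robustness: stray signal in
a single library cannot produce a call.

**Region annotation.** A site's region is the one containing its
midpoint; ties across overlapping transcript models resolve by
precedence CDS > 3′UTR > 5′UTR; sites outside any model are "other";
multi-isoform loci use the longest model per gene. The size-corrected
distribution is (count_i/length_i) / Σ_j(count_j/length_j) — the share
each region would have were all regions the same size.

**7-mer pairing profiles.** For every successive guide 7-mer (start
positions 1…L−6), the fraction of site sequences containing its exact
reverse complement. Matching is exact Watson–Crick after T→U
normalization; G:U wobble does not count. Site sequences are taken
from the cluster interval extended ±10 nt on the cluster's sense
strand (flag-controlled). Aggregation over several guides is an
unweighted per-position mean within each site class and requires a
common position grid.

All ratio pseudocounts default to c = 0.1 RPM on numerator and
denominator; sources are silent on zero handling, and a small constant
keeps ratios bounded without moving well-covered intervals.

## The synthetic study

The generator emulates the statistical structure the analysis assumes
— clustered crosslink starts whose mutant/WT ratio differs by site
class, over a sparse transcript-proportional background, plus a dense
position-uniform input library. One transcript = one reference
sequence on the "+" strand, with 5′UTR/CDS/3′UTR at configurable
fractions (default 0.15/0.45/0.40 of the transcript).

Planted site classes and their true log2 mutant/WT ratios
(mean ± sd, truncated to the class definition):

| class                | ratio (log2)      | shRNA-dependent | planted pairing |
|----------------------|-------------------|-----------------|-----------------|
| on_target            | 3.5 ± 0.3 (≥2.5)  | yes             | full guide      |
| cleaved              | 2.0 ± 0.2 (≥1.0)  | yes             | guide nt 8–21   |
| noncleaved           | 0.75 ± 0.10 (log2 1.4…1.0) | yes    | guide nt 2–8    |
| background           | 0.0 ± 0.05        | yes             | none            |
| constitutive         | 0.0 ± 0.05        | no              | none            |
| endogenous_cleavage  | 2.0 ± 0.2 (≥1.5)  | no              | none            |

The siRNA scenario plants 1/20/20/200 sites of the first four classes
plus 2,000 constitutive sites; the endogenous scenario plants 30
cleavage and 300 constitutive sites. Cleaved sites deliberately carry
central + 3′ pairing *without* a complete seed 7-mer — the
experimentally validated cleaved off-targets include sites that break
the seed rule while pairing extensively in the middle and 3′ region,
and this is the contrast the 7-mer profile must recover. The single
on-target site is the full reverse complement of the guide.

Sites are placed uniformly per nt across the transcriptome (so the
size-corrected region distribution of planted sites is flat by
construction), never overlapping within a transcript. Each site draws
a binding strength — its expected mutant-library read count — from a
log-normal with median `reads_per_site_mean` (default 200; the
endogenous scenario uses 1,200, see below) and log2 sd 1.0: real
cluster abundances span orders of magnitude, and without shared
strength variation a replicate correlation across clusters would
measure nothing but noise.

Reads per library are multinomial at the library depth: expected count
at a site is its strength in mutant/AGO1 libraries and
strength × 2^(−true ratio) in wild type; shRNA-dependent sites emit
nothing in the control condition; the uniform background absorbs the
remaining probability mass, so library totals are exact. Site reads
start within ±2 nt of the site midpoint (the crosslink sits at the
center of the footprint), guaranteeing that 6-nt clustering reunites
them and that the ±10-nt sequence flank covers the whole 21-nt planted
motif.

**Depth and density scales.** Derived depths keep two desk-scale
constraints that real data satisfy automatically:

1. *The per-read RPM quantum sits well below the 5-RPM cluster floor.*
   At 20M-read depth, 5 RPM is a hundred reads; at a desk-scale depth
   of 100k, a single stray background read would be 10 RPM and pass as
   a "cluster". Each CLIP library's depth is therefore derived as
   (its expected site reads)/(1 − background_read_fraction), which at
   the default site complement lands above 500k reads, putting 1–3
   stacked background reads safely under the floor. This is also why
   the endogenous scenario (only 330 sites) raises per-site reads to
   1,200.
2. *The background stays well below the chaining density.* Single
   linkage at 6 nt chains any background denser than ~1 read/6 nt into
   transcript-sized pseudo-clusters. The default
   background_read_fraction 0.01 over a ~1-Mnt transcriptome (1,000
   transcripts of 600–1,400 nt) keeps background at ~0.006 reads/nt.

The input libraries are position-uniform at `input_reads_per_nt`
(default 4/nt): dense enough that zero input reads in an interval
reflects genuine absence rather than shallow sampling — the property
that makes the 15-fold input filter meaningful. Note that input RPM
inside a w-nt cluster is w × 10⁶/transcriptome_nt regardless of input
depth, so the input-fold scale is set by the transcriptome-to-depth
ratio, as in real data.

The constitutive class doubles as the unenriched bulk for the
density-based k estimate. It defaults to 2,000 sites — an order of
magnitude more than the siRNA-dependent complement — because the
density rule presumes the unenriched mode dominates, as it does in
real AGO CLIP where endogenous binding sites vastly outnumber
siRNA-dependent ones.

**What the generator does not emulate.** No sequencing errors, PCR
duplicates, mapping ambiguity, crosslink-induced mutations, non-uniform
crosslink efficiency, expression-level variation between transcripts
in the input, antisense transcription, or isoform structure (one model
per transcript; no introns). Passing recovery tests therefore shows
the inference machinery is correct under the stated statistical model,
not that the thresholds are optimal for any particular real dataset.

## Numerical choices and degenerate inputs

- Ratios use pseudocount 0.1 RPM on both sides; correlations use
  log2(RPM + 0.1); Pearson on constant vectors returns 1 for
  identical profiles.
- Median over an even-sized enriched set = mean of the two central
  values; the normalized median is then exactly 1 only for odd sets,
  within float tolerance otherwise.
- Empty read input to cluster calling returns an empty frame, not an
  error; an empty universe yields an empty enriched set; an empty
  enriched set is a classification error (there is nothing to take a
  median over).
- The density k estimate requires ≥ 50 ratios; below that it raises
  and the caller must fix k. Grid: 2,048 points padded 4 bandwidths
  beyond the data range.
- Site placement and ratio draws are deterministic given the seed;
  every per-library read draw uses an independent seeded stream, so
  adding a library never perturbs the others.

## Problem sizes

Default test and acceptance runs use the full default scenarios:
~1-Mnt transcriptome, 2,241 (siRNA) / 330 (endogenous) planted sites,
0.5–1.3M reads per CLIP library, 4M reads per input library, three
seeds per scenario. A complete two-scenario acceptance run takes
roughly one to two minutes on a single CPU.

## Known limitations

- The k-density rule needs a dominant unenriched mode; on data where
  enriched clusters rival the bulk it will (correctly) refuse and ask
  for a fixed k.
- The on-target flag requires the guide's full reverse complement
  within the extended interval; near-perfect on-targets (single
  mismatch) would rank top but not be flagged.
- Region annotation is midpoint-based; a site straddling a junction
  gets a single label.
- Wobble-tolerant or mismatch-tolerant 7-mer matching is out of scope;
  the profile measures exact complementarity only.
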