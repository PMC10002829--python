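# Methods

This note documents the models, parameter choices and numerical decisions
behind `dnmosaic`, and what the synthetic data does and does not emulate.

## De novo candidate selection

A trio variant/alt-allele pair survives the cascade only if every rule
holds; rules are conjunctive, so the survivor set does not depend on
evaluation order. The audit records rules in the order evaluated (record
usability, parental genotype presence, parental homozygous-reference,
depth, proband alternate reads, parental alternate reads, VAF ceiling,
population blacklist, excluded regions, hard filters) and stops at the
first failure, so each rejected allele is charged to exactly one rule.

Defaults: depth ≥ 20 in all three samples; ≥ 2 proband alternate reads;
0 parental alternate reads (configurable, since real pileups show stray
reads); VAF ≤ 0.70; hard filters per variant class — SNV: MQ > 30,
ReadPosRankSum > −8, FS < 60, QD > 2; indel: ReadPosRankSum > −20,
FS < 200, QD > 2. Missing annotations pass (a record without an annotation
cannot be hard-filtered) and the pass is logged as `missing`. Missing
parental genotypes are rejected conservatively and logged distinctly.

The VAF denominator is the total site depth, matching allelic-depth
semantics, so at a multiallelic site each alt allele gets its own candidate
with its own fraction. Pileup re-inspection is modeled as reading the
VCF's allelic depths; re-genotyping from alignments is out of scope.
Interactive curation is replaced by the audit table and an exportable
per-candidate TSV.

Survivors with VAF in [0.3741, 0.6259] are called germline, below 0.3741
mosaic; the leftover interval (0.6259, 0.70] is reported as a separate
"above-germline" bucket rather than silently merged, since the cascade
retains it but the germline range does not claim it.

## VAF timing model

Components are (germline 0.5, first mitosis 0.25, second mitosis 0.125,
third division 0.0625). Each is given the continuous binomial density at
the working depth: CDF F(x) = I_{1−p}(n+1−x, x) on x ∈ [0, n+1], which
equals the discrete binomial CDF at integer x = k+1 (this identity is the
unit-test oracle). The density is obtained by central differencing of the
CDF (h = 1e−5 on the count axis) and rescaled to the VAF axis; it
integrates to 1 within 1e−3 by quadrature. Sampling uses inverse-CDF
interpolation on a 4096-point grid, accurate to ~2.5e−4 VAF at depth 50.

Boundary estimation draws 10,000 values per component, evaluates Gaussian
KDEs for the two adjacent components on an 801-point grid between their
means, and takes the crossing closest to the midpoint. The bandwidth is
Silverman's rule computed on the pooled two-component sample and applied
to both KDEs, so neither lobe is smoothed more than the other. An analytic
dense-grid crossing of the exact densities serves as the sampling-free
oracle; at 10,000 draws the two agree to ~0.002, and 10k-vs-100k draw
drift is below 0.005. Degenerate inputs (non-decreasing component
fractions, densities that never cross between the means) raise errors
rather than returning extrapolations.

The depth behind the published boundary values is not stated in the
source material; the default working depth of 50 is the package's choice
(mid-range of typical 42–58x genome coverage). At depth 50 the estimated
crossings (≈0.379, 0.192, 0.099) fall near the published cuts (0.3741,
0.1869, 0.0955), but tabulated output never depends on estimation: the
printed bins are available as a preset and are the default for
classification.

Bin edges are lower-inclusive. The printed bins leave the gap
(18.69%, 18.7%) unassigned; values in the gap go to the upper bin. Where
two bins share an edge (37.41%), the edge belongs to the upper bin, which
also keeps the germline/mosaic split (mosaic strictly below 0.3741)
consistent. The third-division component participates in boundary
estimation — it produces the ≈9.55% lower cut — but is reported as
"sub-threshold", because typical genome coverage cannot support calls at
VAF 0.0625 with confidence.

## Substitution taxonomy and Ti/Tv

Equal-length multi-base calls are decomposed into per-base substitutions
before grouping, so a called dinucleotide variant and two adjacent
single-base calls are treated identically; indels are excluded from the
taxonomy. Precedence: two alternate alleles at one position form a
biallelic event (BBS); remaining substitutions chain into maximal clusters
wherever consecutive gaps are strictly below 50 bp; a cluster that is
exactly an adjacent pair is a doublet (DBS); any other cluster of ≥ 2 is a
clustered event (CBS) — a run of three mutually close members containing
an adjacent pair is CBS, not DBS + SBS, i.e. clusters absorb their
members; singletons are SBS. Cluster distance is measured between
consecutive members (gap chaining), not first-to-last span. Events never
mix origin bins: germline and somatic members are grouped separately,
since the reporting tables are stratified by bin. BBS members are kept out
of neighbourhood clustering.

Ti/Tv tables count every member base of SBS/DBS/CBS events (transition =
A↔G or C↔T); BBS rows carry the event count with Ti/Tv marked NA, and
enter the per-origin total column but not its Ti/Tv sums. Display ratios
are rounded half-up to two decimals via exact decimal arithmetic (27/40 is
0.675 exactly and must print 0.68, which naive float rounding gets wrong);
full precision is retained internally. Event counts and member-base counts
are both reported and are not forced to agree with per-bin variant counts
— multi-member events and biallelic sites make the two accountings
legitimately different, and the run report carries a warning saying so.

## Signature profiles and refitting

Profiles are counts over the 96 pyrimidine-centred trinucleotide classes
(purine-reference substitutions are reverse-complemented with their
flanks); variants with N in a flank are excluded with a warning, and a
reference-base mismatch is an error naming the position. The ±2 bp
extended context is tallied and serialized for descriptive use only; it
plays no role in fitting.

Fitting is non-negative least squares on raw counts against a
column-normalized catalog, so contributions are absolute mutation counts.
Backwards elimination removes the currently lowest-contribution signature,
refits, and stops before a removal that would drop the reconstruction
cosine more than `max_delta` below the initial full-catalog cosine. The
elimination procedure's stopping criterion is not specified in the source
description; the default `max_delta` = 0.004 is this package's choice and
is exposed as a parameter (with `max_delta = ∞` the procedure reduces to
the single highest-contribution signature). Since removing a signature
shrinks the feasible set, the cosine trajectory is non-increasing, which
is asserted in tests. The pipeline fits the somatic SBS-event members
only; doublet/clustered/biallelic members are counted in the pattern
tables but not fitted. No third-party catalog is bundled: tests and
examples use small synthetic fixture catalogs (two signatures uniform over
disjoint halves of the 96 contexts, which make NNLS contributions exactly
identifiable), and a real COSMIC-format TSV can be supplied by the user.

## Synthetic data

The generator emulates the statistical structure the analysis assumes:
per-sample depth is negative-binomial around a configurable mean (default
50, dispersion 80, truncated at ≥ 1, optionally fixed), proband alternate
reads are Binomial(depth, p) with p the class VAF parameter, parents carry
zero alternate reads for de novo classes (a switch injects single-read
parental contamination), and inherited variants give one parent a
heterozygous genotype with Binomial(depth, 0.5) support. Default class
counts are 400 first-mitosis, 400 second-mitosis, 45 germline, 100
inherited and 60 sub-threshold noise variants at p = 0.0625, so the lower
boundary behaviour is exercised. Planted events default to 9 doublets, 13
clusters (2–3 members, gaps < 50 bp, members share one read-support draw
so a cluster is not split across timing bins) and 3 biallelic sites (each
alt at p = 0.125, jointly bounded by depth). Decoys are planted to be
caught by exactly one rule each: population-blacklist hits, excluded-region
hits, single-alternate-read sites, and one failing hard-filter annotation.

Somatic substitution contexts are drawn from a configurable signature
mixture; positions are chosen so the drawn trinucleotide context matches
the reference on either strand, which makes the planted truth context
exactly recoverable from the FASTA. Variants are kept ≥ 101 bp apart
unless they belong to one planted event, so no accidental clusters form.
All randomness flows from a single seed and outputs are byte-identical
across reruns.

What the generator does not emulate: sequencing error, mapping artifacts,
GC-dependent coverage, real segmental-duplication sequence (excluded
regions are just intervals), linked reads, or indel-specific error modes
(planted variants are substitutions; indel handling is exercised with
hand-built records in the unit tests). Passing tests therefore demonstrate
the correctness of the analysis logic under the stated read-sampling
model, not robustness to alignment artifacts in real genomes.

Because adjacent binomial lobes overlap, bin counts cannot equal truth
counts: at depth 50 about 13% of second-mitosis draws fall outside the
9.55–18.69% bin, and the 45-variant germline bin gains ~11 spillover
variants from 400 first-mitosis draws. Recovery tests therefore compare
observed bin counts against the exact binomial-tail expectation (computed
per variant at its realized depth), which they match to a few percent;
problem sizes in the tests (≈1,000 variants on a 0.5 Mb two-chromosome
genome, five seeds for recovery checks) keep the full suite under a
minute while leaving every class populated.

## Pipeline and reporting

Stages run simulate → filter → timing → patterns → signatures under one
run directory with per-stage TSV/JSON outputs, a SHA-256 digest of every
input, and a report whose numbers are all recomputable from the stage
files; reruns are byte-identical (nothing timestamped). `compare_runs`
places two reports side by side with fold differences and refuses to
compare runs made with different bin definitions.
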