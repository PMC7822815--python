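# Methods

spliceforge implements a pipeline for detecting and explaining
transcription-factor-driven differential splicing from RNA-seq, of the kind
used to characterise the RUNX1/RUNX1T1 (t(8;21)) fusion's effect on the
Kasumi-1 transcriptome: exon bins and exon–exon junctions (EEJs) are
quantified per condition, tested for gene-relative differential usage,
classified by alternative-splicing mode, linked to epigenetic peaks and
splicing-factor motifs through a random-forest meta-classifier with partial
dependence, compared between nascent and total RNA, and translated in
silico to assess coding consequences.  Because the original study's inputs
(deposited sequencing runs, a specific aligner, a specific Ensembl release)
are not reproducible at desk scale, the package pairs every stage with a
synthetic-data generator that plants a fully known truth, and the tests
measure recovery of that truth.

## Gene models and counting units

Coordinates are 0-based half-open internally; GTF I/O converts from the
1-based inclusive convention.  Transcript exons of a gene are flattened
into bins by splitting at every change in the set of covering transcripts
(the DEXSeq-style rule): bins are disjoint, tile the per-base exon union,
and are numbered 5'→3' on the gene strand.  Each bin receives one
functional type — 5'-UTR, CDS, 3'-UTR, noncoding — by letting every
(transcript, base) pair covering the bin vote and labelling mixed bins
`multi_type`; genes without a coding transcript are `noncoding`
throughout.  The junction catalog holds one record per distinct
consecutive-exon pair over all transcripts of a gene; junctions flanked by
an exon shorter than 25 bp or spanning an intron shorter than 50 bp are
excluded.  The donor is the last transcribed base of the 5' exon and the
acceptor the first transcribed base of the 3' exon, strand-aware, so "5'
splice site" always maps to the donor.

Retained-intron candidates are the gaps in a gene's exon union.  An intron
counts as detected in a condition when, in at least k = 2 of that
condition's replicates, its mean coverage is ≥ 5 (absolute floor) and
≥ 0.1 × the smaller flanking exon-bin coverage.  These thresholds are
package choices exposed in the API; condition specificity
(knockdown-specific / control-specific / shared) follows directly from the
per-condition flags.

## The usage statistic

For feature f of gene g in sample s with count c and gene total T, the
usage value is the within-gene log-odds

    u = log2(c + 0.5) − log2(T − c + 0.5),

which cancels gene-level expression changes: multiplying all counts of a
gene by a common factor leaves u unchanged up to pseudocount effects.  The
effect estimate is the difference of condition means of u; the test
statistic divides it by a moderated standard error and refers to a t
distribution with residual-plus-prior degrees of freedom.  The variance
prior is a scaled inverse chi-squared fitted by the method of moments on
log residual variances, with the prior scale following a lowess trend on
the feature's delta-method count variance (low-count features are
intrinsically noisier on the log-odds scale, so an exchangeable prior
mis-fits; the trend absorbs that structure).  On a 10,000-feature null
simulation this calibrates the test to a 5.0% type-I rate at p < 0.05 with
p-values indistinguishable from uniform by a Kolmogorov–Smirnov test; a
fixed-prior variant (`prior_df=`) is retained for comparison but is
conservative.  A label-permutation variant of the same effect statistic
provides a second "method" so the multi-method consensus bookkeeping
(union/intersection with method tags) can be exercised; the original study
intersected three external callers, which are out of scope here.

Calls use the published thresholds: more than 2-fold usage change and
BH-adjusted q < 0.1, both strict inequalities, with BH applied within each
feature family (bins, junctions, TSS expression, TSS usage) separately.
The TSS analysis groups transcripts whose start sites fall within 10 bp,
tests per-group expression (moderated t on log-CPM, called at ≥ 2-fold,
p < 0.005, q < 0.1) and per-group usage within genes (called at p < 0.0007
with the same fold and q rules); single-TSS genes appear only in the
expression arm.  The 3'-terminal-exon check counts peak-overlapping
3'-terminal bins that pass (fold > 2, q < 1e-4).

## Splicing-mode classification

A junction is compared with its gene's annotated boundaries in a fixed
decision order: annotated (donor, acceptor) pair → canonical; both sites
annotated but the pair novel with ≥ 1 annotated exon inside the spanned
intron → cassette skipping, upgraded to mutually-exclusive when the
skipped exons contain a pair that co-occur in no transcript; one novel
site → alternative 5' or 3' splice site (strand-aware); two or more
simultaneous deviations (both sites novel, or skipping combined with a
site shift) → complex.  Intron retention is a property of retained-intron
bins, never of junctions.  Category enrichment between differential and
non-differential features uses a per-label 2×2 table with the odds ratio
(Haldane 0.5 correction when any cell is zero) and a two-sided Fisher
exact or uncorrected chi-squared p, BH-adjusted across labels.

## Feature integration

Each junction's predictor vector holds, per splicing factor × region,
motif frequency (hits/kb at a threshold of 80% of the maximal attainable
score) and motif strength (maximal log-odds score; sentinel −50 for empty
windows), over four windows: the last 100 nt of the donor exon, the first
and last 100 nt of the intron, and the first 100 nt of the acceptor exon
(window widths are package defaults; short introns split the available
length).  PWMs are read from JASPAR-style count matrices and converted to
log2-odds with a 0.25-per-base pseudocount.  Per epigenetic mark the
vector holds the unsigned distance of donor and acceptor to the nearest
peak edge (0 inside a peak; a large finite sentinel when the chromosome is
absent from the track), plus intron length and mean gene log-CPM.

The meta-classifier addresses the strong class imbalance (hundreds of
differential junctions against ~10^5 others in the original data) with
repeated balanced runs: each run keeps every minority example, draws an
equal-size majority sample, and fits a random forest (sqrt-features per
split).  Run-level AUROC is measured on the untouched majority remainder
plus out-of-bag predictions for the minority, and averaged.  Partial
dependence is evaluated at deduplicated deciles of the observed feature
(avoiding extrapolation on heavy-tailed distance features), averaging
predicted probabilities over samples, trees and runs.  Permutation
importance measures the held-out AUROC drop per feature per run, using
per-tree out-of-bag masks for the minority rows so that memorised in-bag
fits do not bias the drops; features are ranked by the mean drop.  The
default configuration mirrors the published 1,000 runs × 1,000 trees; the
tests and the pipeline default run a scaled 50 × 100 configuration, which
reproduces the full profile shapes.  All runs derive their RNG streams
from (seed, run index), so results are deterministic and independent of
execution order.

## Nascent vs total RNA and cohort analyses

Delayed splicing compares replicate-averaged junction log-CPM between the
nascent and total fractions for differential vs non-differential
junctions, on junctions shared by both matrices.  Nascent values are
recentered so the median nascent−total difference over all shared
junctions is zero (median-ratio size-factor anchoring); without this,
depleting one class would masquerade as a global shift of the other class
through the library sizes.  Group differences use two-sided Mann–Whitney
tests; a bimodality score is the log-likelihood gain of a two- over a
one-component Gaussian mixture.

ICA signatures decompose a junction × sample log-CPM matrix with FastICA
(fixed seed); components are ranked by the Mann–Whitney separation of
their sample weights between groups, and a component's signature is the
junction set with |z-scored loading| > 2.5.  Overlap between junction sets
is scored by Fisher's exact test on the shared universe.  Co-expression
edges are signed Pearson correlations from a seed gene with |r| ≥ 0.5 and
BH-adjusted correlation p-values.

## Coding consequences

Transcript sequences are spliced from the genome with exon-junction
positions recorded in transcript coordinates.  The main ORF is the longest
ATG-initiated, stop-terminated reading frame (ties to the 5'-most start);
transcripts whose best ORF encodes fewer than 100 residues are
non-coding — an ORF-length proxy for coding potential, declared as such.
A stop codon starting more than 50 nt upstream of the final exon–exon
junction marks a premature termination codon (the standard exon-junction
complex model of NMD); junction-free transcripts are always mature.  PTC
fractions are compared between differential and non-differential isoforms
among coding transcripts only, with an odds ratio and Fisher p.  Identity
against a user-supplied reference protein set uses global alignment
(match +1, mismatch −1, gap open −2 / extend −0.5), reporting matched
columns over alignment length.

## The synthetic-data generator

`synthetic_data` is the package's study-condition definition, not a test
fixture.  Defaults: 200 genes on one synthetic chromosome, 4–7 exons per
gene (lognormal exon ≈ 150 bp and intron ≈ 740 bp lengths), three
replicates per condition (siMM control vs siRR knockdown), mean depth 300
fragments per gene with negative-binomial dispersion 0.05, and
Dirichlet-multinomial isoform allocation with concentration 20 for
realistic usage overdispersion.  Every gene has an inclusion transcript
and a cassette-skipping transcript; 30% of genes add an alternative-TSS
variant of the skipping isoform (truncated first exon), so the flanking
junctions stay exclusive to the inclusion isoform.  In the 15% of genes
planted differential, the inclusion proportion swings between
1/(1 + 2^Δ) and its complement with Δ = 2, which realises a ≈ Δ log2-odds
usage change per isoform-discriminating junction after accounting for the
gene's shared junctions.  Junction and bin counts arise by binomial
thinning of isoform fragments, so planted proportions propagate exactly in
expectation.  Planted retained introns read at 0.5 × flanking coverage in
their conditions (background 0.01×); peaks of four marks are placed within
500 bp of differential-junction donors with probability 0.8 against a
0.1/kb background; consensus motifs of three factors (RBFOX2 in the
5' intron, YBX1 in the 3' intron, SRSF7 in the downstream exon) are
planted at 0.8 vs 0.1 around differential vs other junctions, while the
remaining three factors are planted at background rate in both classes and
serve as null predictors.  The planted TSS activation (4-fold on the
alternative TSS in the knockdown) is applied to the transcript count
matrix only, so the junction-usage truth stays independent of it.  The
nascent matrix repeats the total counts with the differential class
binomially thinned 4-fold — the generator's statement of the delayed-
splicing phenomenon.  The six factor consensus matrices are synthetic
stand-ins built for these simulations; only RBFOX2's (U)GCAUG core follows
its well-known element.

What the generator does not emulate: read-level errors and mapping
ambiguity (counts are drawn directly), correlated peak tracks, motif
context beyond a single consensus per factor, kinetic coupling between
nascent and total abundances, and overlapping genes.  Passing tests
therefore demonstrate that the statistical machinery recovers planted
structure under the stated model, not that the thresholds are optimal for
any particular real dataset.

## Numerical choices and problem sizes

Pseudocount 0.5 throughout count log-ratios; strict inequalities at all
call thresholds; chi-squared tests without Yates correction; FastICA
with tolerance 1e-4 and up to 2,000 iterations; lowess span 0.5 for the
variance-prior trend.  The test suite runs the recovery analyses at 200
genes × 3v3, the calibration null at 1,800 genes (≈ 10,000 features), the
importance-stability experiment over 20 generator seeds at a 10 × 50
forest configuration, and the end-to-end determinism check at the default
200-gene pipeline with the 50 × 100 forest — sizes chosen so the whole
suite completes on a single CPU while leaving the measured quantities
stable.

## Known limitations

The single usage statistic stands in for the original three-caller
consensus, so "methods" in the consensus output are statistic variants,
not independent algorithms.  Mutually-exclusive-exon detection requires
annotation evidence and misses data-driven MXE pairs.  The classifier
treats each junction in isolation; coordinated multi-junction events
appear as `complex`.  PD profiles are associational — no causal reading.
KS-based uniformity checks treat within-gene features as independent,
which they are not; the acceptance check therefore reports, and the tests
assert, calibration at the full-family scale where the dependence effect
is small.
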