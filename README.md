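# spliceforge

Detecting and explaining transcription-factor-driven differential splicing
from RNA-seq.  The package implements, as a tested and reusable library,
the computational pipeline used to characterise how a chromatin-bound
fusion protein (the t(8;21) RUNX1/RUNX1T1 oncoprotein, knocked down with
an siRNA against a mismatch control) reshapes a leukemia transcriptome:

* **genemodel** — Ensembl-dialect GTF I/O, DEXSeq-style flattening of
  transcript exons into disjoint typed bins, and a donor/acceptor junction
  catalog with the standard short-exon (<25 bp) and short-intron (<50 bp)
  filters;
* **quantify** — bin and junction counting from spliced BAM alignments,
  log-CPM normalisation, and coverage-based retained-intron detection with
  condition specificity;
* **diffusage** — a gene-relative usage statistic
  `u = log2(c+0.5) − log2(T−c+0.5)` with trended empirical-Bayes variance
  moderation, BH FDR, the published call thresholds (fold > 2, q < 0.1),
  multi-method consensus bookkeeping, differential TSS expression/usage,
  and the 3'-terminal-exon check;
* **events** — classification of junctions into canonical / cassette
  skipping / alt 5'ss / alt 3'ss / mutually exclusive / complex, and
  Fisher/χ² categorical enrichment;
* **features + integrate** — splicing-factor PWM scanning in four windows
  around each junction, distances to epigenetic peak tracks (fusion-TF
  ChIP, RNA pol II, H3K9Ac, DNase HS), and a class-balanced repeated-run
  random-forest meta-classifier with partial dependence and permutation
  importance;
* **consequences** — ORF finding, in-silico translation, the 50-nt NMD
  rule for premature termination codons, and PTC-fraction comparison;
* **cohort** — ICA junction signatures, overlap odds ratios, the
  nascent-vs-total delayed-splicing comparison, and signed co-expression
  edges;
* **synthetic_data** — a generator of genomes, gene models, counts, peaks
  and sequences with fully-known planted truth, defining the study
  conditions every test measures recovery against.

## Worked example

Run the full synthetic study end to end (simulation → counting →
differential usage → event classes → feature integration → consequences →
delayed splicing), then inspect the recovery numbers:

```python
from spliceforge import PipelineConfig, SimConfig, run_pipeline

cfg = PipelineConfig(sim=SimConfig(n_genes=200, seed=1),
                     rf_runs=50, rf_trees=100,
                     outdir="spliceforge_out", seed=1)
res = run_pipeline(cfg)
print(res["diff_usage"])
print(res["rf"]["auroc"])
print(res["delayed_splicing"]["median_diff_nascent"],
      res["delayed_splicing"]["median_diff_total"])
```

which prints

```
{'n_tested': 1107, 'n_called': 83, 'sensitivity': 0.9222222222222223,
 'fdr': 0.0, 'n_consensus_union': 83}
0.9998318350713172
6.632353461514499 8.557709251082645
```

Reading: of 1,107 testable junctions, 83 were called differentially used
at fold > 2 and q < 0.1, recovering 92% of the 90 planted differential
junctions with no false calls; the random forest separates planted
differential from non-differential junctions with AUROC 0.9998 from their
peak-distance and motif features; and the planted 4-fold nascent deficit
of the differential class shows up as a ~2 log2-unit drop of its nascent
median against total RNA.  `spliceforge_out/` holds the usage table,
feature matrix, partial-dependence profiles, retained-intron BED and a
manifest with parameters and checksums.  The same stages are available
from the shell via the `spliceforge` command (`spliceforge pipeline
--n-genes 200 --seed 1`, `spliceforge flatten --gtf ...`, `spliceforge
diffusage --counts ...`).

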