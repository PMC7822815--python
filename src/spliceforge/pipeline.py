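"""End-to-end orchestration of the synthetic study: simulate, quantify,
call differential usage, classify events, integrate features with the
random-forest meta-classifier, annotate isoform consequences, and run the
nascent-vs-total comparison.  Writes plain-text outputs plus a manifest
with parameter and checksum records."""

from __future__ import annotations

import hashlib
import json
import logging
import os
import time
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import cohort as co
from . import consequences as cq
from . import diffusage as du
from . import events as ev
from . import features as ft
from . import integrate as it
from . import synthetic_data as sd
from .genemodel import GenomeSource, catalog_junctions, flatten_exons, write_gtf
from .quantify import cpm_normalize, detect_retained_introns, write_count_table, write_ri_bed

log = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    sim: sd.SimConfig = field(default_factory=sd.SimConfig)
    fc: float = 2.0
    q_max: float = 0.1
    min_count: int = 10
    permutations: int = 200
    rf_runs: int = 50
    rf_trees: int = 100
    rf_grid_points: int = 10
    run_rf: bool = True
    outdir: str = "spliceforge_out"
    seed: int = 0

    def __post_init__(self) -> None:
        # one global seed fans out to stage-level streams
        self.sim.seed = self.seed


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run every stage on synthetic data with planted truth.

    Returns a result dict (also dumped as JSON) whose numbers are all
    recomputed at run time; the manifest lists per-stage parameters and
    sha256 checksums of the written files.
    """
    os.makedirs(cfg.outdir, exist_ok=True)
    manifest: dict = {"stages": {}, "config": {
        "fc": cfg.fc, "q_max": cfg.q_max, "seed": cfg.seed,
        "rf_runs": cfg.rf_runs, "rf_trees": cfg.rf_trees,
        "sim": asdict(cfg.sim),
    }}
    results: dict = {}

    def record(stage: str, files: list[str], **params) -> None:
        manifest["stages"][stage] = {
            "params": params,
            "files": {os.path.basename(f): _sha256(f) for f in files},
        }

    t0 = time.time()
    # -- simulate -----------------------------------------------------
    genome, genes, truth = sd.simulate_annotation(cfg.sim)
    counts = sd.simulate_counts(genes, truth, cfg.sim)
    peaks = sd.simulate_peaks(genes, truth, cfg.sim)
    gtf = os.path.join(cfg.outdir, "annotation.gtf")
    fa = os.path.join(cfg.outdir, "genome.fa")
    truth_json = os.path.join(cfg.outdir, "truth.json")
    write_gtf(genes, gtf)
    sd.write_fasta(genome, fa)
    sd.write_truth(truth, truth_json)
    bed_paths = sd.write_peaks_bed(peaks, os.path.join(cfg.outdir, "peaks"))
    jc_tsv = os.path.join(cfg.outdir, "junction_counts.tsv")
    write_count_table(counts.junctions, jc_tsv)
    record("simulate", [gtf, fa, truth_json, jc_tsv, *bed_paths],
           seed=cfg.seed, n_genes=cfg.sim.n_genes)
    log.info("simulate done (%.1fs)", time.time() - t0)

    # -- gene models / catalog ---------------------------------------
    catalog = [j for g in genes for j in catalog_junctions(g)]
    bins = [b for g in genes for b in flatten_exons(g)]
    grouping = {j.junction_id: j.gene_id for j in catalog}

    # -- retained introns --------------------------------------------
    ri_calls = detect_retained_introns(
        counts.intron_coverage, counts.flank_coverage, counts.samples,
        counts.introns,
    )
    ri_bed = os.path.join(cfg.outdir, "retained_introns.bed")
    write_ri_bed(ri_calls, ri_bed)
    detected = [c for c in ri_calls if c.specificity != "none"]
    results["retained_introns"] = {
        "n_candidates": len(ri_calls),
        "n_detected": len(detected),
        "by_specificity": pd.Series(
            [c.specificity for c in detected]
        ).value_counts().to_dict(),
    }
    record("retained_introns", [ri_bed])

    # -- differential usage ------------------------------------------
    stats = du.usage_statistic(
        counts.junctions, grouping, counts.samples, min_count=cfg.min_count
    )
    calls_t = du.call_differential(stats, fc=cfg.fc, q_max=cfg.q_max)
    perm = du.permutation_usage(
        counts.junctions, grouping, counts.samples,
        min_count=cfg.min_count, permutations=cfg.permutations, seed=cfg.seed,
    )
    calls_p = du.call_differential(perm, fc=cfg.fc, q_max=cfg.q_max,
                                   method="permutation")
    cons = du.consensus(
        {"moderated_t": calls_t, "permutation": calls_p}, mode="union"
    )
    usage_tsv = os.path.join(cfg.outdir, "junction_usage.tsv")
    du.usage_table(stats, cons).to_csv(usage_tsv, sep="\t")
    called = {c.feature_id for c in calls_t if c.is_differential}
    tested = {c.feature_id for c in calls_t}
    true_set = {j for j in truth.diff_junctions if j in tested}
    tp = len(called & true_set)
    results["diff_usage"] = {
        "n_tested": len(tested),
        "n_called": len(called),
        "sensitivity": tp / len(true_set) if true_set else float("nan"),
        "fdr": (len(called) - tp) / len(called) if called else 0.0,
        "n_consensus_union": sum(c.is_differential for c in cons),
    }
    record("diff_usage", [usage_tsv], fc=cfg.fc, q_max=cfg.q_max,
           min_count=cfg.min_count)

    # -- event classes & site-type enrichment ------------------------
    genes_by_id = {g.gene_id: g for g in genes}
    modes = [
        ev.classify_junction(j, genes_by_id[j.gene_id],
                             [c for c in catalog if c.gene_id == j.gene_id])
        for j in catalog
    ]
    bins_by_gene: dict[str, list] = {}
    for b in bins:
        bins_by_gene.setdefault(b.gene_id, []).append(b)
    site_types = [
        ev.splice_site_types(j, bins_by_gene[j.gene_id]) for j in catalog
    ]
    site_lab = {
        a.junction_id: f"{a.donor_exon_type}|{a.acceptor_exon_type}"
        for a in site_types
    }
    enr = ev.categorical_enrichment(
        called & set(site_lab), set(site_lab), site_lab, test="chi2"
    )
    enr_tsv = os.path.join(cfg.outdir, "site_type_enrichment.tsv")
    enr.to_csv(enr_tsv, sep="\t")
    results["events"] = {
        "mode_counts": pd.Series([m.mode for m in modes]).value_counts().to_dict(),
    }
    record("events", [enr_tsv])

    # -- features + open-chromatin association ------------------------
    gsrc = GenomeSource(genome)
    pwms = sd.default_pwms()
    logcpm = cpm_normalize(counts.junctions)
    gene_expr_full = logcpm.mean(axis=1).groupby(grouping).mean()
    labels = {
        j.junction_id: ("diff" if j.junction_id in truth.diff_junctions
                        else "nondiff")
        for j in catalog
    }
    fm = ft.build_feature_matrix(
        catalog, gsrc, pwms, peaks, gene_expr_full.to_dict(), labels
    )
    fm_tsv = os.path.join(cfg.outdir, "feature_matrix.tsv")
    fm.to_csv(fm_tsv, sep="\t")
    diff_sites = [(j.chrom, j.donor) for j in catalog
                  if labels[j.junction_id] == "diff"]
    nondiff_sites = [(j.chrom, j.donor) for j in catalog
                     if labels[j.junction_id] == "nondiff"]
    orr, p = ft.open_chromatin_association(
        diff_sites, nondiff_sites, peaks["fusion_TF"],
        max_dist=cfg.sim.assoc_window,
    )
    results["open_chromatin"] = {"odds_ratio": orr, "p": p}
    record("features", [fm_tsv])

    # -- random-forest integration ------------------------------------
    if cfg.run_rf:
        rf_cfg = it.RFConfig(n_runs=cfg.rf_runs, n_trees=cfg.rf_trees,
                             seed=cfg.seed)
        model = it.train_meta_classifier(fm, rf_cfg)
        imp = it.rank_features(model)
        pd_feats = ["fusion_TF_donor_dist"] + [
            f"{f}_{r}_strength" for f, r in sd.EFFECT_FACTORS.items()
        ]
        profiles = {
            f: it.partial_dependence(model, f, grid_points=cfg.rf_grid_points)
            for f in pd_feats
        }
        imp_tsv = os.path.join(cfg.outdir, "rf_importance.tsv")
        imp.to_csv(imp_tsv, sep="\t")
        pd_tsv = os.path.join(cfg.outdir, "rf_partial_dependence.tsv")
        pd.concat(
            {
                f: pd.DataFrame(
                    {"grid": pr.grid, "prob": pr.prob, "sd": pr.dispersion}
                )
                for f, pr in profiles.items()
            },
            names=["feature", "i"],
        ).to_csv(pd_tsv, sep="\t")
        results["rf"] = {
            "auroc": model.auroc,
            "top_features": imp.head(8).index.tolist(),
        }
        record("rf", [imp_tsv, pd_tsv], n_runs=cfg.rf_runs,
               n_trees=cfg.rf_trees)
    else:
        manifest["stages"]["rf"] = {"skipped": True}

    # -- isoform consequences -----------------------------------------
    tseqs = []
    for g in genes:
        for t in g.transcripts:
            seq_parts, junc_pos, acc = [], [], 0
            for e in t.exons:
                seq_parts.append(gsrc.fetch(e.chrom, e.start, e.end, t.strand))
                acc += len(e)
                junc_pos.append(acc)
            junc_pos = junc_pos[:-1]
            jset = {
                j.junction_id for j in catalog_junctions(g)
                if sd._junction_in_transcript(j, t, g.strand)
            }
            status = ("differential"
                      if jset & set(truth.diff_junctions) else "nondifferential")
            tseqs.append(
                cq.TranscriptSequence(t.transcript_id, "".join(seq_parts),
                                      junc_pos, status)
            )
    calls_by_group: dict[str, list[str]] = {"differential": [],
                                            "nondifferential": []}
    n_noncoding = 0
    for ts in tseqs:
        orf = cq.find_main_orf(ts)
        if orf is None:
            n_noncoding += 1
            continue
        calls_by_group[ts.diff_status].append(cq.classify_termination(ts, orf))
    ptc = cq.ptc_fraction_test(calls_by_group)
    results["consequences"] = {"n_noncoding": n_noncoding, **ptc}

    # -- delayed splicing ----------------------------------------------
    delayed = co.delayed_splicing(
        counts.nascent_junctions, counts.junctions, labels, seed=cfg.seed
    )
    results["delayed_splicing"] = {
        "median_diff_nascent": delayed.medians[("diff", "nascent")],
        "median_diff_total": delayed.medians[("diff", "total")],
        "median_nondiff_nascent": delayed.medians[("nondiff", "nascent")],
        "median_nondiff_total": delayed.medians[("nondiff", "total")],
        "p_diff_nascent_vs_total": delayed.p_nascent_vs_total["diff"],
        "p_nondiff_nascent_vs_total": delayed.p_nascent_vs_total["nondiff"],
    }

    # -- TSS arms ------------------------------------------------------
    tss_map = du.group_tss(
        {
            t.transcript_id: (g.gene_id, t.tss)
            for g in genes
            for t in g.transcripts
        }
    )
    expr_arm, usage_arm = du.tss_differential(
        counts.transcripts, tss_map, counts.samples
    )
    activated_groups = {
        tss_map[tid] for tid in truth.tss_activated if tid in tss_map
    }
    results["tss"] = {
        "n_groups": int(expr_arm.shape[0]),
        "n_expr_called": int(expr_arm["called"].sum()),
        "n_usage_called": int(usage_arm["called"].sum())
        if not usage_arm.empty else 0,
        "n_activated_recovered_expr": int(
            expr_arm.loc[expr_arm.index.isin(activated_groups), "called"].sum()
        ),
        "n_activated": len(activated_groups),
    }

    results["wall_seconds"] = round(time.time() - t0, 2)
    res_path = os.path.join(cfg.outdir, "results.json")
    with open(res_path, "w") as fh:
        json.dump(results, fh, indent=1, sort_keys=True, default=float)
    man_path = os.path.join(cfg.outdir, "manifest.json")
    with open(man_path, "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return results
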