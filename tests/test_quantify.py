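"""Counting from alignments, CPM normalization, retained-intron calls."""

import numpy as np
import pandas as pd
import pytest

from spliceforge.genemodel import FlatBin, GeneModel, GenomicInterval
from spliceforge.quantify import (
    CountMatrix,
    SampleInfo,
    count_bins,
    cpm_normalize,
    detect_retained_introns,
    extract_junctions,
    read_count_table,
    write_count_table,
)
from spliceforge.synthetic_data import write_toy_bam

from conftest import make_transcript


def _bins():
    return [
        FlatBin("A", "g", GenomicInterval("chr1", 100, 200, "+")),
        FlatBin("B", "g", GenomicInterval("chr1", 300, 400, "+")),
        FlatBin("C", "g", GenomicInterval("chr1", 500, 600, "+")),
    ]


class TestCountBins:
    def test_read_inside_single_bin(self, tmp_path):
        bam = write_toy_bam(
            str(tmp_path / "a.bam"), [("r1", "chr1", 120, "50M")], {"chr1": 1000}
        )
        cm = count_bins(bam, _bins())
        assert cm.counts["sample"].tolist() == [1, 0, 0]

    def test_read_spanning_two_bins_counts_both(self, tmp_path):
        bam = write_toy_bam(
            str(tmp_path / "a.bam"), [("r1", "chr1", 150, "200M")], {"chr1": 1000}
        )
        cm = count_bins(bam, _bins())
        assert cm.counts["sample"].tolist() == [1, 1, 0]

    def test_spliced_read_skips_gapped_bin(self, tmp_path):
        # blocks in A and C, 301-bp gap over B
        bam = write_toy_bam(
            str(tmp_path / "a.bam"),
            [("r1", "chr1", 150, "50M301N50M")],
            {"chr1": 1000},
        )
        cm = count_bins(bam, _bins())
        assert cm.counts["sample"].tolist() == [1, 0, 1]

    def test_paired_mates_count_once(self, tmp_path):
        bam = write_toy_bam(
            str(tmp_path / "a.bam"),
            [("frag", "chr1", 110, "40M"), ("frag", "chr1", 150, "40M")],
            {"chr1": 1000},
        )
        cm = count_bins(bam, _bins())
        assert cm.counts["sample"].tolist() == [1, 0, 0]

    def test_chromosome_mismatch_raises(self, tmp_path):
        bam = write_toy_bam(
            str(tmp_path / "a.bam"), [("r1", "chrX", 0, "10M")], {"chrX": 100}
        )
        with pytest.raises(ValueError, match="chromosome"):
            count_bins(bam, _bins())


class TestExtractJunctions:
    def _gene(self):
        t = make_transcript(
            "t", "g", "chr1", "+", [(100, 200), (300, 400), (500, 600)]
        )
        return GeneModel("g", [t], "noncoding")

    def test_gapped_reads_count_catalog_junction(self, tmp_path):
        from spliceforge.genemodel import catalog_junctions

        g = self._gene()
        cat = catalog_junctions(g)
        reads = [(f"r{i}", "chr1", 150, "50M100N50M") for i in range(10)]
        bam = write_toy_bam(str(tmp_path / "a.bam"), reads, {"chr1": 1000})
        cm, recs = extract_junctions(bam, cat, [g])
        jid = next(j.junction_id for j in cat if j.donor == 199)
        assert cm.counts.loc[jid, "sample"] == 10

    def test_two_gap_read_increments_both(self, tmp_path):
        from spliceforge.genemodel import catalog_junctions

        g = self._gene()
        cat = catalog_junctions(g)
        reads = [(f"r{i}", "chr1", 150, "50M100N100M100N50M") for i in range(5)]
        bam = write_toy_bam(str(tmp_path / "a.bam"), reads, {"chr1": 1000})
        cm, _ = extract_junctions(bam, cat, [g])
        assert (cm.counts["sample"] == 5).sum() == 2

    def test_novel_junction_assigned_to_host_gene(self, tmp_path):
        from spliceforge.genemodel import catalog_junctions

        g = self._gene()
        cat = catalog_junctions(g)
        # gap (250, 500): donor 249 novel, acceptor 500 canonical
        reads = [(f"r{i}", "chr1", 200, "50M250N50M") for i in range(6)]
        bam = write_toy_bam(str(tmp_path / "a.bam"), reads, {"chr1": 1000})
        cm, recs = extract_junctions(bam, cat, [g])
        novel = [r for r in recs if not r.canonical]
        assert len(novel) == 1
        assert novel[0].gene_id == "g"
        assert cm.counts.loc[novel[0].junction_id, "sample"] == 6

    def test_min_reads_filter_drops_rare_junctions(self, tmp_path):
        from spliceforge.genemodel import catalog_junctions

        g = self._gene()
        cat = catalog_junctions(g)
        reads = [("r1", "chr1", 150, "50M100N50M")]
        bam = write_toy_bam(str(tmp_path / "a.bam"), reads, {"chr1": 1000})
        cm, recs = extract_junctions(bam, cat, [g], min_reads=5)
        assert cm.counts.empty

    def test_matches_brute_force_cigar_interpreter(self, tmp_path, rng):
        """Random gapped reads against a brute-force gap counter."""
        import re

        from spliceforge.genemodel import catalog_junctions

        t = make_transcript(
            "t", "g", "chr1", "+",
            [(i * 300, i * 300 + 200) for i in range(6)],
        )
        g = GeneModel("g", [t], "noncoding")
        cat = catalog_junctions(g)
        reads = []
        expected: dict[tuple[int, int], int] = {}
        for i in range(500):
            pos = int(rng.integers(0, 150))
            n_seg = int(rng.integers(1, 4))
            cigar = ""
            p = pos
            for s in range(n_seg):
                m = int(rng.integers(20, 60))
                cigar += f"{m}M"
                p += m
                if s < n_seg - 1:
                    gap = int(rng.integers(20, 400))
                    cigar += f"{gap}N"
                    p += gap
            reads.append((f"r{i}", "chr1", pos, cigar))
            # brute-force walk
            p = pos
            for op in re.findall(r"(\d+)([MN])", cigar):
                L = int(op[0])
                if op[1] == "N":
                    if L >= 50:
                        expected[(p - 1, p + L)] = (
                            expected.get((p - 1, p + L), 0) + 1
                        )
                    p += L
                else:
                    p += L
        bam = write_toy_bam(str(tmp_path / "a.bam"), reads, {"chr1": 5000})
        cm, recs = extract_junctions(bam, cat, [g], min_reads=1)
        by_key = {(r.left, r.right): r.junction_id for r in recs}
        counted = {
            k: int(cm.counts.loc[by_key[k], "sample"])
            for k in by_key
            if by_key[k] in cm.counts.index
        }
        # keep only gaps resolvable to a record (both ends inside the gene)
        span = g.span
        exp = {
            k: v
            for k, v in expected.items()
            if k in by_key or (span.start <= k[0] and k[1] < span.end)
        }
        assert counted == {k: v for k, v in exp.items() if k in counted or v > 0}


class TestCpm:
    def _cm(self, counts, lib):
        samples = [SampleInfo("s1", "a", 1)]
        df = pd.DataFrame({"s1": counts}, index=[f"f{i}" for i in range(len(counts))])
        return CountMatrix(df, samples, pd.Series({"s1": lib}))

    def test_zero_count_closed_form(self):
        out = cpm_normalize(self._cm([0], 10**6))
        assert out.iloc[0, 0] == pytest.approx(np.log2(0.5))

    def test_count_one_closed_form(self):
        out = cpm_normalize(self._cm([1], 10**6))
        assert out.iloc[0, 0] == pytest.approx(np.log2(1.5))

    def test_doubling_library_subtracts_one(self):
        a = cpm_normalize(self._cm([100], 10**6)).iloc[0, 0]
        b = cpm_normalize(self._cm([100], 2 * 10**6)).iloc[0, 0]
        assert a - b == pytest.approx(1.0)

    def test_zero_library_raises(self):
        with pytest.raises(ValueError):
            cpm_normalize(self._cm([0], 0))


class TestRetainedIntrons:
    def _samples(self):
        return [
            SampleInfo(f"{c}_{r}", c, r)
            for c in ("siMM", "siRR")
            for r in (1, 2, 3)
        ]

    def _tables(self, rows_int, rows_fl):
        cols = [s.sample_id for s in self._samples()]
        iv = GenomicInterval("c", 0, 100, "+")
        introns = {k: (iv, "g") for k in rows_int}
        return (
            pd.DataFrame.from_dict(rows_int, orient="index", columns=cols),
            pd.DataFrame.from_dict(rows_fl, orient="index", columns=cols),
            introns,
        )

    def test_zero_coverage_never_detected(self):
        ic, fc, iv = self._tables({"i": [0] * 6}, {"i": [100] * 6})
        (call,) = detect_retained_introns(ic, fc, self._samples(), iv)
        assert call.specificity == "none"

    def test_condition_specific_call(self):
        ic, fc, iv = self._tables(
            {"i": [0.5, 0.5, 0.5, 30, 32, 0.1]}, {"i": [100] * 6}
        )
        (call,) = detect_retained_introns(ic, fc, self._samples(), iv)
        assert call.specificity == "siRR_specific"
        assert call.detected_in == {"siMM": False, "siRR": True}

    def test_shared_call(self):
        ic, fc, iv = self._tables({"i": [40] * 6}, {"i": [100] * 6})
        (call,) = detect_retained_introns(ic, fc, self._samples(), iv)
        assert call.specificity == "shared"

    def test_relative_threshold_blocks_absolute_pass(self):
        # above c_abs but below theta * flank
        ic, fc, iv = self._tables({"i": [8] * 6}, {"i": [200] * 6})
        (call,) = detect_retained_introns(ic, fc, self._samples(), iv)
        assert call.specificity == "none"

    def test_planted_recovery_on_synthetic_counts(self):
        from spliceforge.synthetic_data import (
            SimConfig,
            simulate_annotation,
            simulate_counts,
        )

        cfg = SimConfig(n_genes=150, seed=5)
        _, genes, truth = simulate_annotation(cfg)
        counts = simulate_counts(genes, truth, cfg)
        calls = detect_retained_introns(
            counts.intron_coverage,
            counts.flank_coverage,
            counts.samples,
            counts.introns,
        )
        detected = {
            f"{c.gene_id}:RI:{c.intron.start}-{c.intron.end}"
            for c in calls
            if c.specificity != "none"
        }
        planted = set(truth.retained_introns)
        assert len(detected & planted) / len(planted) >= 0.9
        background = {
            f"{c.gene_id}:RI:{c.intron.start}-{c.intron.end}" for c in calls
        } - planted
        fp = len(detected - planted)
        assert fp / max(len(background), 1) < 0.05

    def test_specificity_matches_planted_conditions(self):
        from spliceforge.synthetic_data import (
            SimConfig,
            simulate_annotation,
            simulate_counts,
        )

        cfg = SimConfig(n_genes=100, seed=7)
        _, genes, truth = simulate_annotation(cfg)
        counts = simulate_counts(genes, truth, cfg)
        calls = {
            f"{c.gene_id}:RI:{c.intron.start}-{c.intron.end}": c
            for c in detect_retained_introns(
                counts.intron_coverage,
                counts.flank_coverage,
                counts.samples,
                counts.introns,
            )
        }
        agree = total = 0
        for iid, conds in truth.retained_introns.items():
            if iid not in calls or calls[iid].specificity == "none":
                continue
            want = "shared" if len(conds) == 2 else f"{conds[0]}_specific"
            total += 1
            agree += calls[iid].specificity == want
        assert total > 0 and agree / total >= 0.9


def test_count_table_round_trip(tmp_path):
    samples = [SampleInfo("s1", "a", 1), SampleInfo("s2", "b", 1)]
    df = pd.DataFrame({"s1": [1, 2], "s2": [3, 4]}, index=["x", "y"])
    cm = CountMatrix(df, samples)
    path = tmp_path / "c.tsv"
    write_count_table(cm, str(path))
    back = read_count_table(str(path), samples)
    pd.testing.assert_frame_equal(back.counts, cm.counts, check_names=False)
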