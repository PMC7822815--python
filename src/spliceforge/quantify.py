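"""Counting: bin/junction count matrices from spliced alignments, CPM
normalization, and coverage-based retained-intron detection."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import pysam

from .genemodel import FlatBin, GeneModel, GenomicInterval, JunctionRecord

log = logging.getLogger(__name__)

__all__ = [
    "SampleInfo",
    "CountMatrix",
    "RetainedIntronCall",
    "count_bins",
    "extract_junctions",
    "cpm_normalize",
    "detect_retained_introns",
    "read_count_table",
    "write_count_table",
    "write_ri_bed",
    "DEFAULT_MAPQ",
    "DEFAULT_MIN_READS",
]

DEFAULT_MAPQ = 10
DEFAULT_MIN_READS = 5


@dataclass(frozen=True)
class SampleInfo:
    sample_id: str
    condition: str
    replicate: int
    fraction: str = "total"


@dataclass
class CountMatrix:
    """Feature-by-sample count table with per-sample library sizes.

    ``counts`` is a pandas DataFrame indexed by feature id with one column
    per sample id; library sizes default to column sums.
    """

    counts: pd.DataFrame
    samples: list[SampleInfo]
    library_sizes: pd.Series | None = None

    def __post_init__(self) -> None:
        ids = [s.sample_id for s in self.samples]
        if list(self.counts.columns) != ids:
            self.counts = self.counts[ids]
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative counts")
        if self.library_sizes is None:
            self.library_sizes = self.counts.sum(axis=0).astype(float)
        keys = {(s.condition, s.replicate, s.fraction) for s in self.samples}
        if len(keys) != len(self.samples):
            raise ValueError("duplicate (condition, replicate, fraction)")

    def condition_samples(self, condition: str) -> list[str]:
        return [s.sample_id for s in self.samples if s.condition == condition]

    def subset(self, feature_ids: Sequence[str]) -> "CountMatrix":
        return CountMatrix(
            self.counts.loc[list(feature_ids)].copy(),
            list(self.samples),
            self.library_sizes.copy(),
        )


def _fragment_blocks(bam: pysam.AlignmentFile, mapq: int):
    """Yield (qname-unique) merged aligned blocks per fragment.

    Paired mates share a qname and are merged so a fragment counts once.
    """
    frags: dict[str, list[tuple[str, int, int]]] = {}
    for read in bam.fetch(until_eof=True):
        if (
            read.is_unmapped
            or read.is_secondary
            or read.is_supplementary
            or read.is_duplicate
            or read.mapping_quality < mapq
        ):
            continue
        chrom = read.reference_name
        frags.setdefault(read.query_name, []).extend(
            (chrom, s, e) for s, e in read.get_blocks()
        )
    return frags


def count_bins(
    alignments: "str | Mapping[str, str]",
    bins: Sequence[FlatBin],
    samples: Sequence[SampleInfo] | None = None,
    mapq: int = DEFAULT_MAPQ,
) -> CountMatrix:
    """Count fragments overlapping each bin by >= 1 bp of an aligned block.

    ``alignments`` is one BAM path or a {sample_id: path} mapping; paired
    mates are merged by query name so each fragment increments a bin at
    most once.
    """
    if isinstance(alignments, str):
        alignments = {"sample": alignments}
        if samples is None:
            samples = [SampleInfo("sample", "na", 1)]
    if samples is None:
        samples = [SampleInfo(sid, "na", i + 1) for i, sid in enumerate(alignments)]

    bin_index: dict[str, list[FlatBin]] = {}
    for b in bins:
        bin_index.setdefault(b.interval.chrom, []).append(b)

    table = pd.DataFrame(
        0, index=[b.bin_id for b in bins], columns=[s.sample_id for s in samples]
    )
    for s in samples:
        path = alignments[s.sample_id]
        with pysam.AlignmentFile(path) as bam:
            bam_chroms = set(bam.references)
            gtf_chroms = set(bin_index)
            if gtf_chroms and not (gtf_chroms & bam_chroms):
                raise ValueError(
                    "no shared chromosome names between alignments and "
                    f"annotation: BAM={sorted(bam_chroms)} GTF={sorted(gtf_chroms)}"
                )
            frags = _fragment_blocks(bam, mapq)
        for blocks in frags.values():
            hit: set[str] = set()
            for chrom, bs, be in blocks:
                for b in bin_index.get(chrom, ()):
                    if b.interval.start < be and bs < b.interval.end:
                        hit.add(b.bin_id)
            for bid in hit:
                table.loc[bid, s.sample_id] += 1
    return CountMatrix(table, list(samples))


def _read_gaps(read: pysam.AlignedSegment) -> list[tuple[int, int]]:
    """Reference-skip (N) gaps of an alignment as half-open intervals."""
    gaps = []
    pos = read.reference_start
    for op, length in read.cigartuples or ():
        if op in (0, 7, 8, 2):  # M, =, X, D consume reference
            pos += length
        elif op == 3:  # N
            gaps.append((pos, pos + length))
            pos += length
    return gaps


def extract_junctions(
    alignments: "str | Mapping[str, str]",
    catalog: Sequence[JunctionRecord],
    genes: Sequence[GeneModel] | None = None,
    samples: Sequence[SampleInfo] | None = None,
    min_reads: int = DEFAULT_MIN_READS,
    min_intron: int = 50,
    mapq: int = DEFAULT_MAPQ,
) -> tuple[CountMatrix, list[JunctionRecord]]:
    """Count gapped alignments per junction; emit novel junctions.

    Each N-gap whose flanking exonic bases match a catalog record
    increments that junction.  Gaps inside exactly one gene but absent
    from the catalog become non-canonical records; gaps contained in more
    than one gene are tagged ambiguous and excluded.  Junctions with fewer
    than ``min_reads`` total counts across samples are dropped.  Gaps
    shorter than ``min_intron`` are ignored (tally logged).
    """
    if isinstance(alignments, str):
        alignments = {"sample": alignments}
        if samples is None:
            samples = [SampleInfo("sample", "na", 1)]
    if samples is None:
        samples = [SampleInfo(sid, "na", i + 1) for i, sid in enumerate(alignments)]

    by_key: dict[tuple[str, int, int], JunctionRecord] = {
        (j.chrom, j.left, j.right): j for j in catalog
    }
    novel: dict[tuple[str, int, int], JunctionRecord] = {}
    counts: dict[tuple[str, int, int], dict[str, int]] = {}
    short_gaps = 0

    for s in samples:
        with pysam.AlignmentFile(alignments[s.sample_id]) as bam:
            for read in bam.fetch(until_eof=True):
                if (
                    read.is_unmapped
                    or read.is_secondary
                    or read.is_supplementary
                    or read.is_duplicate
                    or read.mapping_quality < mapq
                ):
                    continue
                for gs, ge in _read_gaps(read):
                    if ge - gs < min_intron:
                        short_gaps += 1
                        continue
                    key = (read.reference_name, gs - 1, ge)
                    if key not in by_key and key not in novel:
                        rec = _novel_record(key, genes or ())
                        if rec is None:
                            continue
                        novel[key] = rec
                    counts.setdefault(key, {}).setdefault(s.sample_id, 0)
                    counts[key][s.sample_id] += 1
    if short_gaps:
        log.info("ignored %d gaps shorter than min_intron=%d", short_gaps, min_intron)

    records = list(catalog) + list(novel.values())
    ids = [j.junction_id for j in records]
    table = pd.DataFrame(0, index=ids, columns=[s.sample_id for s in samples])
    for key, per_sample in counts.items():
        rec = by_key.get(key) or novel.get(key)
        for sid, n in per_sample.items():
            table.loc[rec.junction_id, sid] = n
    keep = table.sum(axis=1) >= min_reads
    table = table.loc[keep]
    kept = {jid for jid in table.index}
    records = [j for j in records if j.junction_id in kept]
    return CountMatrix(table, list(samples)), records


def _novel_record(
    key: tuple[str, int, int], genes: Sequence[GeneModel]
) -> JunctionRecord | None:
    chrom, left, right = key
    hosts = [
        g
        for g in genes
        if g.chrom == chrom and g.span.start <= left and right < g.span.end
    ]
    if len(hosts) != 1:
        if len(hosts) > 1:
            log.info("junction %s ambiguous between %d genes; excluded", key, len(hosts))
        return None
    g = hosts[0]
    donor, acceptor = (left, right) if g.strand == "+" else (right, left)
    return JunctionRecord(
        junction_id=f"{g.gene_id}:{left}-{right}",
        gene_id=g.gene_id,
        chrom=chrom,
        donor=donor,
        acceptor=acceptor,
        strand=g.strand,
        canonical=False,
    )


def cpm_normalize(m: CountMatrix, pseudocount: float = 0.5) -> pd.DataFrame:
    """log2 counts-per-million: log2((count + pc) / library_size * 1e6)."""
    lib = m.library_sizes
    if (lib <= 0).any():
        raise ValueError("zero library size")
    return np.log2((m.counts + pseudocount).div(lib, axis=1) * 1e6)


@dataclass
class RetainedIntronCall:
    intron: GenomicInterval
    gene_id: str
    detected_in: dict[str, bool] = field(default_factory=dict)

    @property
    def specificity(self) -> str:
        hits = [c for c, d in self.detected_in.items() if d]
        if len(hits) == 1:
            return f"{hits[0]}_specific"
        if len(hits) > 1:
            return "shared"
        return "none"


def detect_retained_introns(
    intron_coverage: pd.DataFrame,
    flank_coverage: pd.DataFrame,
    samples: Sequence[SampleInfo],
    introns: Mapping[str, tuple[GenomicInterval, str]],
    c_abs: float = 5.0,
    theta: float = 0.1,
    k: int = 2,
) -> list[RetainedIntronCall]:
    """Call retained introns from per-base coverage tables.

    An intron is detected in a condition when, in at least ``k`` of its
    replicates, mean intron coverage is >= ``c_abs`` and >= ``theta``
    times the smaller flanking exon-bin coverage.  ``intron_coverage`` and
    ``flank_coverage`` (the min of the two flanks) are intron-by-sample;
    ``introns`` maps intron id to (interval, gene_id).  Introns missing
    from ``flank_coverage`` are skipped with a log entry.
    """
    conditions = sorted({s.condition for s in samples})
    calls = []
    for iid in intron_coverage.index:
        if iid not in flank_coverage.index:
            log.info("intron %s lacks two flanking exon bins; skipped", iid)
            continue
        iv, gene_id = introns[iid]
        detected: dict[str, bool] = {}
        for cond in conditions:
            cols = [s.sample_id for s in samples if s.condition == cond]
            ic = intron_coverage.loc[iid, cols].to_numpy(dtype=float)
            fc = flank_coverage.loc[iid, cols].to_numpy(dtype=float)
            ok = (ic >= c_abs) & (ic >= theta * fc)
            detected[cond] = int(ok.sum()) >= k
        calls.append(RetainedIntronCall(iv, gene_id, detected))
    return calls


# ---------------------------------------------------------------------------
# Plain-text plumbing
# ---------------------------------------------------------------------------

def write_count_table(m: CountMatrix, path: str) -> None:
    df = m.counts.copy()
    df.index.name = "feature_id"
    df.to_csv(path, sep="\t")


def read_count_table(path: str, samples: Sequence[SampleInfo]) -> CountMatrix:
    df = pd.read_csv(path, sep="\t", index_col="feature_id")
    return CountMatrix(df, list(samples))


def write_ri_bed(calls: Sequence[RetainedIntronCall], path: str) -> None:
    with open(path, "w") as fh:
        for c in calls:
            if c.specificity == "none":
                continue
            fh.write(
                f"{c.intron.chrom}\t{c.intron.start}\t{c.intron.end}\t"
                f"{c.gene_id}|{c.specificity}\t0\t{c.intron.strand}\n"
            )
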