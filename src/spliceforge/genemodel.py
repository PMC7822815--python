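"""Gene models: GTF I/O, exon-bin flattening, functional typing, junction catalog.

Coordinates are 0-based half-open internally; GTF is converted from its
1-based inclusive convention at the I/O boundary.  Donor and acceptor of a
junction are the genomic positions of the exonic bases flanking the intron,
strand-aware: the donor is the last transcribed base of the 5' exon and the
acceptor the first transcribed base of the 3' exon.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import gffutils

__all__ = [
    "GenomicInterval",
    "TranscriptModel",
    "GeneModel",
    "FlatBin",
    "JunctionRecord",
    "GenomeSource",
    "GtfParseError",
    "GtfValidationError",
    "read_gtf",
    "write_gtf",
    "flatten_exons",
    "intron_intervals",
    "assign_functional_type",
    "catalog_junctions",
    "DEFAULT_MIN_EXON",
    "DEFAULT_MIN_INTRON",
]

DEFAULT_MIN_EXON = 25
DEFAULT_MIN_INTRON = 50

FUNCTIONAL_TYPES = (
    "five_prime_utr",
    "cds",
    "three_prime_utr",
    "multi_type",
    "noncoding",
)


class GtfParseError(ValueError):
    pass


class GtfValidationError(ValueError):
    pass


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open genomic interval."""

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"empty interval {self.chrom}:{self.start}-{self.end}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"bad strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass
class TranscriptModel:
    """A transcript: exons ordered 5'->3' along transcription."""

    transcript_id: str
    gene_id: str
    exons: list[GenomicInterval]
    cds: GenomicInterval | None = None

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError(f"{self.transcript_id}: no exons")
        strand = self.exons[0].strand
        genomic = sorted(self.exons, key=lambda e: e.start)
        for a, b in zip(genomic, genomic[1:]):
            if a.end > b.start:
                raise ValueError(f"{self.transcript_id}: overlapping exons")
        self.exons = genomic if strand == "+" else genomic[::-1]

    @property
    def strand(self) -> str:
        return self.exons[0].strand

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def tss(self) -> int:
        """Genomic position of the first transcribed base."""
        e = self.exons[0]
        return e.start if self.strand == "+" else e.end - 1

    @property
    def span(self) -> GenomicInterval:
        starts = [e.start for e in self.exons]
        ends = [e.end for e in self.exons]
        return GenomicInterval(self.chrom, min(starts), max(ends), self.strand)


@dataclass
class GeneModel:
    gene_id: str
    transcripts: list[TranscriptModel]
    biotype: str = "protein_coding"

    def __post_init__(self) -> None:
        if not self.transcripts:
            raise ValueError(f"{self.gene_id}: no transcripts")
        chroms = {t.chrom for t in self.transcripts}
        strands = {t.strand for t in self.transcripts}
        if len(chroms) > 1 or len(strands) > 1:
            raise ValueError(f"{self.gene_id}: transcripts on mixed chrom/strand")

    @property
    def chrom(self) -> str:
        return self.transcripts[0].chrom

    @property
    def strand(self) -> str:
        return self.transcripts[0].strand

    @property
    def span(self) -> GenomicInterval:
        starts = [t.span.start for t in self.transcripts]
        ends = [t.span.end for t in self.transcripts]
        return GenomicInterval(self.chrom, min(starts), max(ends), self.strand)

    @property
    def is_coding(self) -> bool:
        return any(t.cds is not None for t in self.transcripts)


@dataclass
class FlatBin:
    """Disjoint counting unit from flattened exons or a retained intron."""

    bin_id: str
    gene_id: str
    interval: GenomicInterval
    origin: str = "canonical_exon"  # or "retained_intron"
    functional_type: str | None = None
    is_three_prime_terminal: bool = False


@dataclass
class JunctionRecord:
    """Donor/acceptor pair. ``left``/``right`` are the strand-agnostic
    genomic flanking exonic bases used for matching gapped alignments."""

    junction_id: str
    gene_id: str
    chrom: str
    donor: int
    acceptor: int
    strand: str
    canonical: bool = True
    donor_exon: GenomicInterval | None = None
    acceptor_exon: GenomicInterval | None = None

    @property
    def left(self) -> int:
        return min(self.donor, self.acceptor)

    @property
    def right(self) -> int:
        return max(self.donor, self.acceptor)

    @property
    def intron(self) -> GenomicInterval:
        """The spanned intron as a half-open interval."""
        return GenomicInterval(self.chrom, self.left + 1, self.right, self.strand)

    @property
    def intron_length(self) -> int:
        return self.right - self.left - 1


class GenomeSource:
    """Strand-aware sequence access over a FASTA file or an in-memory dict."""

    _RC = str.maketrans("ACGTNacgtn", "TGCANtgcan")

    def __init__(self, source: "str | Mapping[str, str]"):
        if isinstance(source, (str,)):
            import pyfaidx

            self._fa = pyfaidx.Fasta(source)
            self._mem = None
        else:
            self._fa = None
            self._mem = dict(source)

    def __contains__(self, chrom: str) -> bool:
        if self._mem is not None:
            return chrom in self._mem
        return chrom in self._fa

    def length(self, chrom: str) -> int:
        if self._mem is not None:
            return len(self._mem[chrom])
        return len(self._fa[chrom])

    def fetch(self, chrom: str, start: int, end: int, strand: str = "+") -> str:
        start = max(0, start)
        end = min(end, self.length(chrom))
        if start >= end:
            return ""
        if self._mem is not None:
            seq = self._mem[chrom][start:end]
        else:
            seq = str(self._fa[chrom][start:end])
        seq = seq.upper()
        if strand == "-":
            seq = seq.translate(self._RC)[::-1]
        return seq


# ---------------------------------------------------------------------------
# GTF I/O
# ---------------------------------------------------------------------------

def read_gtf(path: str, dialect: str = "ensembl") -> list[GeneModel]:
    """Read an Ensembl-dialect GTF into gene models.

    Coordinates are converted to 0-based half-open.  CDS segments of a
    transcript are collapsed to their genomic span.  Raises
    :class:`GtfParseError` on malformed attribute strings and
    :class:`GtfValidationError` when an exon falls outside its declared
    gene span.
    """
    if dialect != "ensembl":
        raise ValueError(f"unsupported dialect {dialect!r}")
    try:
        db = gffutils.create_db(
            path,
            dbfn=":memory:",
            force=True,
            keep_order=True,
            merge_strategy="create_unique",
            disable_infer_genes=True,
            disable_infer_transcripts=True,
        )
    except Exception as exc:  # gffutils raises various types on bad input
        raise GtfParseError(f"failed to parse GTF {path}: {exc}") from exc

    genes: list[GeneModel] = []
    for g in db.features_of_type("gene", order_by="start"):
        gene_id = g.attributes["gene_id"][0]
        biotype = (g.attributes.get("gene_biotype") or ["protein_coding"])[0]
        transcripts = []
        for t in db.children(g, featuretype="transcript", order_by="start"):
            tid = t.attributes["transcript_id"][0]
            exons = []
            for e in db.children(t, featuretype="exon", order_by="start"):
                if e.start - 1 < g.start - 1 or e.end > g.end:
                    raise GtfValidationError(
                        f"exon of {tid} at {e.start}-{e.end} outside gene "
                        f"{gene_id} span {g.start}-{g.end}"
                    )
                exons.append(
                    GenomicInterval(e.seqid, e.start - 1, e.end, e.strand)
                )
            cds_parts = list(db.children(t, featuretype="CDS", order_by="start"))
            cds = None
            if cds_parts:
                cds = GenomicInterval(
                    t.seqid,
                    min(c.start for c in cds_parts) - 1,
                    max(c.end for c in cds_parts),
                    t.strand,
                )
            transcripts.append(TranscriptModel(tid, gene_id, exons, cds))
        if transcripts:
            bt = "protein_coding" if biotype == "protein_coding" else "noncoding"
            genes.append(GeneModel(gene_id, transcripts, bt))
    return genes


def write_gtf(genes: Sequence[GeneModel], path: str) -> None:
    """Write gene models as Ensembl-dialect GTF (1-based inclusive)."""
    with open(path, "w") as fh:
        for g in genes:
            sp = g.span
            attrs = f'gene_id "{g.gene_id}"; gene_biotype "{g.biotype}";'
            fh.write(
                f"{g.chrom}\tspliceforge\tgene\t{sp.start + 1}\t{sp.end}\t.\t"
                f"{g.strand}\t.\t{attrs}\n"
            )
            for t in g.transcripts:
                ts = t.span
                tattrs = (
                    f'gene_id "{g.gene_id}"; transcript_id "{t.transcript_id}"; '
                    f'gene_biotype "{g.biotype}";'
                )
                fh.write(
                    f"{g.chrom}\tspliceforge\ttranscript\t{ts.start + 1}\t{ts.end}"
                    f"\t.\t{g.strand}\t.\t{tattrs}\n"
                )
                for e in sorted(t.exons, key=lambda x: x.start):
                    fh.write(
                        f"{g.chrom}\tspliceforge\texon\t{e.start + 1}\t{e.end}\t.\t"
                        f"{g.strand}\t.\t{tattrs}\n"
                    )
                if t.cds is not None:
                    # emit the CDS span clipped to each overlapping exon
                    for e in sorted(t.exons, key=lambda x: x.start):
                        s = max(e.start, t.cds.start)
                        en = min(e.end, t.cds.end)
                        if s < en:
                            fh.write(
                                f"{g.chrom}\tspliceforge\tCDS\t{s + 1}\t{en}\t.\t"
                                f"{g.strand}\t0\t{tattrs}\n"
                            )


# ---------------------------------------------------------------------------
# Flattening
# ---------------------------------------------------------------------------

def flatten_exons(gene: GeneModel) -> list[FlatBin]:
    """Flatten transcript exons into maximal bins of constant covering set.

    Bins are split wherever the set of transcripts covering a base changes,
    are pairwise disjoint, and together tile the per-base union of the
    gene's exons.  Numbering runs 5'->3' on the gene strand.  Bins that
    contain the 3'-terminal base of at least one transcript are flagged.
    """
    boundaries: set[int] = set()
    for t in gene.transcripts:
        for e in t.exons:
            boundaries.add(e.start)
            boundaries.add(e.end)
    cuts = sorted(boundaries)

    segs: list[tuple[int, int, frozenset[str]]] = []
    for s, e in zip(cuts, cuts[1:]):
        cover = frozenset(
            t.transcript_id
            for t in gene.transcripts
            if any(x.start <= s and e <= x.end for x in t.exons)
        )
        if cover:
            segs.append((s, e, cover))

    merged: list[tuple[int, int, frozenset[str]]] = []
    for s, e, cov in segs:
        if merged and merged[-1][1] == s and merged[-1][2] == cov:
            merged[-1] = (merged[-1][0], e, cov)
        else:
            merged.append((s, e, cov))

    term_bases = {
        (t.exons[-1].end - 1) if gene.strand == "+" else t.exons[-1].start
        for t in gene.transcripts
    }

    ordered = merged if gene.strand == "+" else merged[::-1]
    bins = []
    for i, (s, e, _cov) in enumerate(ordered, start=1):
        iv = GenomicInterval(gene.chrom, s, e, gene.strand)
        bins.append(
            FlatBin(
                bin_id=f"{gene.gene_id}:{i:03d}",
                gene_id=gene.gene_id,
                interval=iv,
                origin="canonical_exon",
                is_three_prime_terminal=any(iv.contains(b) for b in term_bases),
            )
        )
    for b in bins:
        b.functional_type = assign_functional_type(b, gene)
    return bins


def intron_intervals(gene: GeneModel) -> list[GenomicInterval]:
    """Gaps in the per-base exon union: candidate retained introns."""
    ivs = sorted(
        ((e.start, e.end) for t in gene.transcripts for e in t.exons)
    )
    merged: list[list[int]] = []
    for s, e in ivs:
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    out = []
    for (s1, e1), (s2, e2) in zip(merged, merged[1:]):
        if e1 < s2:
            out.append(GenomicInterval(gene.chrom, e1, s2, gene.strand))
    return out


def _classify_base_ranges(
    lo: int, hi: int, t: TranscriptModel
) -> set[str]:
    """Functional categories contributed by transcript ``t`` over [lo, hi)."""
    if t.cds is None:
        return {"noncoding"}
    cats: set[str] = set()
    cs, ce = t.cds.start, t.cds.end
    if lo < cs:  # genomic-left of CDS
        cats.add("five_prime_utr" if t.strand == "+" else "three_prime_utr")
    if max(lo, cs) < min(hi, ce):
        cats.add("cds")
    if hi > ce:
        cats.add("three_prime_utr" if t.strand == "+" else "five_prime_utr")
    return cats


def assign_functional_type(bin: FlatBin, gene: GeneModel) -> str:
    """Classify a bin as UTR/CDS/noncoding, or multi_type when mixed.

    Every (transcript, base) pair covering the bin votes; a single
    unanimous category wins, otherwise the bin is multi_type.  Genes with
    no coding transcript are noncoding throughout.
    """
    if not gene.is_coding:
        return "noncoding"
    iv = bin.interval
    cats: set[str] = set()
    for t in gene.transcripts:
        for e in t.exons:
            lo, hi = max(iv.start, e.start), min(iv.end, e.end)
            if lo < hi:
                cats |= _classify_base_ranges(lo, hi, t)
    if not cats:
        raise GtfValidationError(
            f"bin {bin.bin_id} not contained in exon union of {gene.gene_id}"
        )
    if len(cats) == 1:
        return next(iter(cats))
    return "multi_type"


# ---------------------------------------------------------------------------
# Junction catalog
# ---------------------------------------------------------------------------

def catalog_junctions(
    gene: GeneModel,
    min_exon: int = DEFAULT_MIN_EXON,
    min_intron: int = DEFAULT_MIN_INTRON,
) -> list[JunctionRecord]:
    """Canonical junctions: distinct consecutive exon pairs over transcripts.

    Junctions flanked by an exon shorter than ``min_exon`` or spanning an
    intron shorter than ``min_intron`` are excluded; records are
    deduplicated by (donor, acceptor).
    """
    seen: dict[tuple[int, int], JunctionRecord] = {}
    for t in gene.transcripts:
        for up, down in zip(t.exons, t.exons[1:]):
            if len(up) < min_exon or len(down) < min_exon:
                continue
            if gene.strand == "+":
                donor, acceptor = up.end - 1, down.start
            else:
                donor, acceptor = up.start, down.end - 1
            gap = abs(acceptor - donor) - 1
            if gap < min_intron:
                continue
            key = (donor, acceptor)
            if key not in seen:
                left, right = min(key), max(key)
                seen[key] = JunctionRecord(
                    junction_id=f"{gene.gene_id}:{left}-{right}",
                    gene_id=gene.gene_id,
                    chrom=gene.chrom,
                    donor=donor,
                    acceptor=acceptor,
                    strand=gene.strand,
                    canonical=True,
                    donor_exon=up,
                    acceptor_exon=down,
                )
            else:
                rec = seen[key]
                if rec.donor_exon is not None and len(up) > len(rec.donor_exon):
                    rec.donor_exon = up
                if rec.acceptor_exon is not None and len(down) > len(
                    rec.acceptor_exon
                ):
                    rec.acceptor_exon = down
    return list(seen.values())
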