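"""Shared fixtures and random-model builders for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from spliceforge.genemodel import GeneModel, GenomicInterval, TranscriptModel


def make_transcript(tid, gid, chrom, strand, exon_coords, cds=None):
    exons = [GenomicInterval(chrom, s, e, strand) for s, e in exon_coords]
    cds_iv = GenomicInterval(chrom, *cds, strand) if cds else None
    return TranscriptModel(tid, gid, exons, cds_iv)


def random_gene(
    rng: np.random.Generator,
    gene_id: str = "G",
    max_transcripts: int = 4,
    max_exons: int = 8,
    coding: bool = True,
) -> GeneModel:
    """A random multi-transcript gene built from a shared exon skeleton
    with per-transcript exon subsets and occasional boundary shifts."""
    strand = "+" if rng.random() < 0.5 else "-"
    chrom = "chrT"
    n_ex = int(rng.integers(2, max_exons + 1))
    pos = int(rng.integers(0, 50))
    skeleton = []
    for _ in range(n_ex):
        length = int(rng.integers(30, 200))
        skeleton.append((pos, pos + length))
        pos += length + int(rng.integers(60, 400))

    n_t = int(rng.integers(1, max_transcripts + 1))
    transcripts = []
    for ti in range(n_t):
        keep = sorted(
            rng.choice(n_ex, size=int(rng.integers(1, n_ex + 1)), replace=False)
        )
        exons = []
        for k in keep:
            s, e = skeleton[k]
            # occasional alternative 5'/3' boundary inside the intron gap
            if rng.random() < 0.2 and e - s > 40:
                s += int(rng.integers(0, 20))
            if rng.random() < 0.2 and e - s > 40:
                e -= int(rng.integers(0, 20))
            exons.append((s, e))
        cds = None
        if coding and rng.random() < 0.8:
            union = [p for s, e in exons for p in (s, e)]
            lo, hi = union[0], union[-1]
            if hi - lo > 20:
                a = int(rng.integers(lo, hi - 10))
                b = int(rng.integers(a + 6, hi))
                cds = (a, b)
        transcripts.append(
            make_transcript(f"{gene_id}.t{ti}", gene_id, chrom, strand, exons, cds)
        )
    biotype = (
        "protein_coding"
        if any(t.cds is not None for t in transcripts)
        else "noncoding"
    )
    return GeneModel(gene_id, transcripts, biotype)


def flatten_oracle(gene: GeneModel) -> list[tuple[int, int]]:
    """Brute-force per-base flattening: maximal runs of constant covering
    transcript set within the exon union."""
    cover: dict[int, frozenset] = {}
    for t in gene.transcripts:
        for e in t.exons:
            for p in range(e.start, e.end):
                cover[p] = cover.get(p, frozenset()) | {t.transcript_id}
    merged = []
    for p in sorted(cover):
        if merged and merged[-1][1] == p and merged[-1][2] == cover[p]:
            merged[-1] = (merged[-1][0], p + 1, cover[p])
        else:
            merged.append((p, p + 1, cover[p]))
    return [(s, e) for s, e, _ in merged]


def functional_type_oracle(gene: GeneModel, start: int, end: int) -> str:
    """Per-base, per-transcript classification of a bin."""
    if not any(t.cds is not None for t in gene.transcripts):
        return "noncoding"
    cats = set()
    for t in gene.transcripts:
        for e in t.exons:
            for p in range(max(start, e.start), min(end, e.end)):
                if t.cds is None:
                    cats.add("noncoding")
                elif p < t.cds.start:
                    cats.add(
                        "five_prime_utr" if t.strand == "+" else "three_prime_utr"
                    )
                elif p >= t.cds.end:
                    cats.add(
                        "three_prime_utr" if t.strand == "+" else "five_prime_utr"
                    )
                else:
                    cats.add("cds")
    return next(iter(cats)) if len(cats) == 1 else "multi_type"


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
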