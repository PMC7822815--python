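"""Alternative-splicing mode classification and categorical enrichment.

A junction is assigned exactly one mode by comparing its donor/acceptor to
the annotated exon boundaries of its gene:

1. annotated (donor, acceptor) pair -> canonical;
2. both sites annotated but the pair is novel and the spanned intron fully
   contains >= 1 annotated exon -> cassette_skipping, or
   mutually_exclusive when the skipped exons include a pair that never
   co-occur in any transcript;
3. one annotated site and one novel site -> alt_5ss (novel donor) or
   alt_3ss (novel acceptor), strand-aware;
4. two or more simultaneous deviations (both sites novel, or skipping
   combined with a shifted site) -> complex.

Intron retention is a property of retained-intron bins, never of
junctions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .diffusage import bh_fdr
from .genemodel import FlatBin, GeneModel, GenomicInterval, JunctionRecord

__all__ = [
    "SpliceEventClass",
    "SpliceSiteAnnotation",
    "classify_junction",
    "splice_site_types",
    "categorical_enrichment",
    "MODES",
]

MODES = (
    "canonical",
    "cassette_skipping",
    "alt_5ss",
    "alt_3ss",
    "mutually_exclusive",
    "intron_retention",
    "complex",
)


@dataclass
class SpliceEventClass:
    junction_id: str
    mode: str
    evidence: list[str] = field(default_factory=list)


@dataclass
class SpliceSiteAnnotation:
    junction_id: str
    donor_exon_type: str
    acceptor_exon_type: str


def _boundary_sets(gene: GeneModel) -> tuple[set[int], set[int]]:
    """Annotated donor-side and acceptor-side exonic boundary bases."""
    donors: set[int] = set()
    acceptors: set[int] = set()
    for t in gene.transcripts:
        for i, e in enumerate(t.exons):
            if gene.strand == "+":
                if i < len(t.exons) - 1:
                    donors.add(e.end - 1)
                if i > 0:
                    acceptors.add(e.start)
            else:
                if i < len(t.exons) - 1:
                    donors.add(e.start)
                if i > 0:
                    acceptors.add(e.end - 1)
    return donors, acceptors


def _skipped_exons(j: JunctionRecord, gene: GeneModel) -> list[GenomicInterval]:
    """Distinct annotated exons fully inside the spanned intron."""
    lo, hi = j.left + 1, j.right  # half-open intron
    seen: set[tuple[int, int]] = set()
    out = []
    for t in gene.transcripts:
        for e in t.exons:
            if lo <= e.start and e.end <= hi and (e.start, e.end) not in seen:
                seen.add((e.start, e.end))
                out.append(e)
    return out


def _never_cooccur(a: GenomicInterval, b: GenomicInterval, gene: GeneModel) -> bool:
    for t in gene.transcripts:
        keys = {(e.start, e.end) for e in t.exons}
        if (a.start, a.end) in keys and (b.start, b.end) in keys:
            return False
    return True


def classify_junction(
    j: JunctionRecord,
    gene: GeneModel,
    catalog: Sequence[JunctionRecord],
) -> SpliceEventClass:
    """Assign one splicing mode to a junction (see module docstring)."""
    span = gene.span
    if not (span.start <= j.left and j.right < span.end):
        raise ValueError(f"junction {j.junction_id} outside gene {gene.gene_id}")

    pairs = {(c.donor, c.acceptor) for c in catalog if c.gene_id == gene.gene_id}
    if (j.donor, j.acceptor) in pairs:
        return SpliceEventClass(j.junction_id, "canonical")

    donors, acceptors = _boundary_sets(gene)
    donor_known = j.donor in donors
    acceptor_known = j.acceptor in acceptors
    skipped = _skipped_exons(j, gene)

    if donor_known and acceptor_known:
        if skipped:
            for i in range(len(skipped)):
                for k in range(i + 1, len(skipped)):
                    if _never_cooccur(skipped[i], skipped[k], gene):
                        return SpliceEventClass(
                            j.junction_id,
                            "mutually_exclusive",
                            [_exon_key(e) for e in (skipped[i], skipped[k])],
                        )
            return SpliceEventClass(
                j.junction_id, "cassette_skipping", [_exon_key(e) for e in skipped]
            )
        # both boundaries annotated, pair novel, nothing skipped: treated as
        # a compound deviation from any single annotated event
        return SpliceEventClass(j.junction_id, "complex")

    if not donor_known and not acceptor_known:
        return SpliceEventClass(j.junction_id, "complex")

    if skipped:  # shifted site combined with skipping
        return SpliceEventClass(
            j.junction_id, "complex", [_exon_key(e) for e in skipped]
        )
    if not donor_known:
        return SpliceEventClass(j.junction_id, "alt_5ss")
    return SpliceEventClass(j.junction_id, "alt_3ss")


def _exon_key(e: GenomicInterval) -> str:
    return f"{e.chrom}:{e.start}-{e.end}"


def splice_site_types(
    j: JunctionRecord, bins: Sequence[FlatBin]
) -> SpliceSiteAnnotation:
    """Functional type of the flattened bin hosting each splice site.

    Sites landing outside every bin (purely intronic, no retained-intron
    bin) are typed ``intergenic_intronic`` and excluded from enrichment
    tables downstream.
    """

    def site_type(pos: int) -> str:
        for b in bins:
            if b.interval.contains(pos):
                return b.functional_type or "noncoding"
        return "intergenic_intronic"

    return SpliceSiteAnnotation(j.junction_id, site_type(j.donor), site_type(j.acceptor))


def categorical_enrichment(
    diff: Iterable[str],
    universe: Iterable[str],
    category: Mapping[str, str],
    test: str = "fisher",
) -> pd.DataFrame:
    """Per-label over/under-representation among differential features.

    For each label L the 2x2 table [diff&L, diff&!L; nondiff&L,
    nondiff&!L] yields an odds ratio (Haldane 0.5 correction applied to
    every cell when any cell is zero) and a two-sided p-value from
    Fisher's exact test or the chi-square test without Yates correction;
    q is BH across labels.
    """
    diff = set(diff)
    universe = set(universe)
    if not diff <= universe:
        raise ValueError("diff set not contained in universe")
    labels = sorted({category[f] for f in universe if f in category})
    if len(labels) < 2:
        raise ValueError("need >= 2 category labels")
    nondiff = universe - diff
    rows = []
    for lab in labels:
        a = sum(1 for f in diff if category.get(f) == lab)
        b = len(diff) - a
        c = sum(1 for f in nondiff if category.get(f) == lab)
        d = len(nondiff) - c
        if min(a, b, c, d) == 0:
            orr = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
        else:
            orr = (a * d) / (b * c)
        if len(diff) == 0:
            p = np.nan
            orr = np.nan
        elif test == "fisher":
            _, p = sps.fisher_exact([[a, b], [c, d]], alternative="two-sided")
        elif test == "chi2":
            _, p, _, _ = sps.chi2_contingency([[a, b], [c, d]], correction=False)
        else:
            raise ValueError(f"unknown test {test!r}")
        rows.append(
            {"label": lab, "diff_with": a, "diff_without": b,
             "nondiff_with": c, "nondiff_without": d, "odds_ratio": orr, "p": p}
        )
    out = pd.DataFrame(rows).set_index("label")
    valid = out["p"].notna()
    out["q"] = np.nan
    if valid.any():
        out.loc[valid, "q"] = bh_fdr(out.loc[valid, "p"].tolist())
    return out
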