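"""Isoform consequences: ORF finding, in-silico translation, premature
termination (NMD 50-nt rule), identity vs reference proteins, and the
PTC-fraction comparison between differential and non-differential isoforms.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from Bio.Align import PairwiseAligner
from Bio.Seq import Seq
from scipy import stats as sps

__all__ = [
    "TranscriptSequence",
    "OrfCall",
    "find_main_orf",
    "translate",
    "classify_termination",
    "identity_vs_reference",
    "read_protein_fasta",
    "ptc_fraction_test",
    "DEFAULT_MIN_CODONS",
    "DEFAULT_NMD_RULE_NT",
]

DEFAULT_MIN_CODONS = 100
DEFAULT_NMD_RULE_NT = 50

STOPS = {"TAA", "TAG", "TGA"}


@dataclass
class TranscriptSequence:
    """Spliced transcript sequence with exon-junction positions.

    ``junctions`` hold transcript coordinates of the first base of each
    downstream exon, strictly increasing.
    """

    transcript_id: str
    seq: str
    junctions: list[int] = field(default_factory=list)
    diff_status: str = "nondifferential"

    def __post_init__(self) -> None:
        self.seq = self.seq.upper().replace("U", "T")
        if any(b <= a for a, b in zip(self.junctions, self.junctions[1:])):
            raise ValueError("junction positions must be strictly increasing")
        if self.junctions and self.junctions[-1] >= len(self.seq):
            raise ValueError("junction position beyond sequence end")


@dataclass
class OrfCall:
    start: int  # transcript coordinate of the A of ATG
    stop: int  # exclusive end of the stop codon
    protein: str
    coding_class: str = "coding"  # refined by classify_termination

    def __post_init__(self) -> None:
        if (self.stop - self.start) % 3 != 0:
            raise ValueError("ORF length not divisible by 3")


def _codon_ok(codon: str) -> bool:
    return all(c in "ACGT" for c in codon)


def find_main_orf(
    t: TranscriptSequence, min_codons: int = DEFAULT_MIN_CODONS
) -> OrfCall | None:
    """Longest ATG-initiated ORF terminating at an in-frame stop.

    Returns None (non-coding) when no stop-terminated ORF reaches
    ``min_codons`` protein residues.  Ties in length are broken by the
    5'-most start.  Codons containing ambiguous bases neither initiate
    nor terminate.
    """
    seq = t.seq
    best: OrfCall | None = None
    for i in range(len(seq) - 2):
        codon = seq[i : i + 3]
        if codon != "ATG" or not _codon_ok(codon):
            continue
        j = i + 3
        while j + 3 <= len(seq):
            c = seq[j : j + 3]
            if c in STOPS and _codon_ok(c):
                n_protein = (j - i) // 3
                if n_protein >= min_codons and (
                    best is None or n_protein > len(best.protein)
                ):
                    best = OrfCall(i, j + 3, translate(seq[i:j]))
                break
            j += 3
    return best


def translate(orf_seq: str) -> str:
    """Standard-code translation of an in-frame coding sequence.

    The input excludes (or may include) the stop codon; a single trailing
    stop is stripped, while an internal stop raises (it signals a frame
    bug upstream).  Ambiguous codons translate to X.
    """
    orf_seq = orf_seq.upper().replace("U", "T")
    if len(orf_seq) % 3 != 0:
        raise ValueError("ORF length not divisible by 3")
    protein = str(Seq(orf_seq).translate())
    if protein.endswith("*"):
        protein = protein[:-1]
    if "*" in protein:
        raise ValueError("internal stop codon in ORF")
    return protein


def classify_termination(
    t: TranscriptSequence,
    orf: OrfCall,
    nmd_rule_nt: int = DEFAULT_NMD_RULE_NT,
) -> str:
    """coding_PTC when the stop codon starts more than ``nmd_rule_nt`` nt
    upstream of the last exon-exon junction; otherwise
    coding_mature_stop.  Junction-free (single-exon) transcripts are
    always mature."""
    if not t.junctions:
        return "coding_mature_stop"
    stop_codon_start = orf.stop - 3
    dist = t.junctions[-1] - stop_codon_start
    return "coding_PTC" if dist > nmd_rule_nt else "coding_mature_stop"


def read_protein_fasta(path: str) -> dict[str, str]:
    """Reference protein set from a FASTA file, id -> sequence."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(path, "fasta")}


def identity_vs_reference(
    protein: str, reference_proteins: Mapping[str, str]
) -> tuple[str, float]:
    """Best global-alignment identity (%) against a reference protein set.

    Identity = matched columns / alignment length; the best-scoring
    reference is retained.
    """
    if not protein:
        raise ValueError("empty query protein")
    if not reference_proteins:
        raise ValueError("empty reference set")
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = -1.0
    aligner.open_gap_score = -2.0
    aligner.extend_gap_score = -0.5
    best_name, best_ident = "", -1.0
    for name, ref in reference_proteins.items():
        aln = aligner.align(protein, ref)[0]
        matches = 0
        length = 0
        for (qs, qe), (ts, te) in zip(*aln.aligned):
            for a, b in zip(protein[qs:qe], ref[ts:te]):
                if a == b:
                    matches += 1
            length += qe - qs
        # alignment length includes gapped columns
        aln_len = max(len(str(aln[0])), 1)
        ident = 100.0 * matches / aln_len
        if ident > best_ident:
            best_name, best_ident = name, ident
    return best_name, best_ident


def ptc_fraction_test(
    calls: Mapping[str, Sequence[str]],
) -> dict[str, float]:
    """PTC fraction among coding transcripts per diff group, with odds
    ratio and two-sided Fisher p.

    ``calls`` maps {"differential": [...], "nondifferential": [...]} to
    lists of coding_class strings (non-coding entries, if present, are
    excluded from the denominators).
    """
    table = {}
    for grp in ("differential", "nondifferential"):
        classes = [c for c in calls.get(grp, ()) if c.startswith("coding")]
        if not classes:
            raise ValueError(f"group {grp!r} has no coding transcripts")
        ptc = sum(1 for c in classes if c == "coding_PTC")
        table[grp] = (ptc, len(classes) - ptc)
    (a, b), (c, d) = table["differential"], table["nondifferential"]
    orr, p = sps.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return {
        "frac_ptc_differential": a / (a + b),
        "frac_ptc_nondifferential": c / (c + d),
        "odds_ratio": float(orr),
        "p": float(p),
    }
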