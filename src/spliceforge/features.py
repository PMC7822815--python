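"""Per-junction predictors: splicing-factor PWM motifs in four windows
around the splice sites, and distances to epigenetic peak tracks."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .events import categorical_enrichment
from .genemodel import GenomeSource, JunctionRecord

log = logging.getLogger(__name__)

__all__ = [
    "PWM",
    "RegionSpec",
    "read_jaspar_pwms",
    "scan_pwm",
    "junction_windows",
    "motif_features",
    "read_bed",
    "peak_distances",
    "open_chromatin_association",
    "compare_site_distances",
    "build_feature_matrix",
    "STRENGTH_SENTINEL",
    "DISTANCE_SENTINEL",
]

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}
STRENGTH_SENTINEL = -50.0
DISTANCE_SENTINEL = 1e9  # finite stand-in for "no peak on this chromosome"


@dataclass
class PWM:
    """Log-odds position weight matrix over A/C/G/T.

    ``matrix`` has shape (width, 4).  ``hit_threshold`` defaults to 80% of
    the maximum attainable score.
    """

    factor: str
    matrix: np.ndarray
    background: np.ndarray = field(
        default_factory=lambda: np.full(4, 0.25)
    )
    hit_threshold: float | None = None

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4:
            raise ValueError("matrix must be width x 4")
        if self.hit_threshold is None:
            self.hit_threshold = 0.8 * self.max_score
        if self.hit_threshold > self.max_score + 1e-9:
            raise ValueError("hit_threshold above maximum attainable score")

    @property
    def width(self) -> int:
        return self.matrix.shape[0]

    @property
    def max_score(self) -> float:
        return float(self.matrix.max(axis=1).sum())

    @classmethod
    def from_counts(
        cls,
        factor: str,
        counts: np.ndarray,
        background: np.ndarray | None = None,
        pseudocount: float = 0.25,
    ) -> "PWM":
        """Counts (width x 4) -> log2-odds with per-base pseudocount."""
        counts = np.asarray(counts, dtype=float)
        bg = np.full(4, 0.25) if background is None else np.asarray(background)
        freq = (counts + pseudocount) / (
            counts.sum(axis=1, keepdims=True) + 4 * pseudocount
        )
        return cls(factor, np.log2(freq / bg), bg)


def read_jaspar_pwms(path: str) -> list[PWM]:
    """Read a JASPAR-format count-matrix file into log-odds PWMs."""
    from Bio import motifs

    with open(path) as fh:
        parsed = motifs.parse(fh, "jaspar")
    out = []
    for m in parsed:
        counts = np.array([[m.counts[b][i] for b in BASES] for i in range(m.length)])
        out.append(PWM.from_counts(m.name or m.matrix_id, counts))
    return out


def scan_pwm(seq: str, pwm: PWM) -> list[tuple[int, float]]:
    """Log-odds score at every offset; N bases contribute 0.

    Returns an empty list when the sequence is shorter than the motif.
    """
    seq = seq.upper().replace("U", "T")
    w = pwm.width
    n = len(seq)
    if n < w:
        return []
    idx = np.array([BASE_INDEX.get(c, -1) for c in seq])
    scores = np.zeros(n - w + 1)
    for j in range(w):
        col = idx[j : j + n - w + 1]
        contrib = np.where(col >= 0, pwm.matrix[j][np.clip(col, 0, 3)], 0.0)
        scores += contrib
    return [(i, float(s)) for i, s in enumerate(scores)]


@dataclass
class RegionSpec:
    """Window widths for the four junction-centred scanning regions."""

    exon_width: int = 100
    intron_width: int = 100


def junction_windows(
    j: JunctionRecord, regions: RegionSpec
) -> dict[str, tuple[int, int]]:
    """Genomic half-open windows for the four regions, strand-aware.

    upstream_exon: last ``exon_width`` nt of the donor exon (clipped to the
    exon when its extent is known); intron_5p / intron_3p: first / last
    ``intron_width`` nt of the intron; downstream_exon: first
    ``exon_width`` nt of the acceptor exon.
    """
    we, wi = regions.exon_width, regions.intron_width
    il = j.intron_length
    wi = min(wi, max(il // 2, 1)) if il < 2 * wi else wi
    if j.strand == "+":
        up_lo = j.donor - we + 1
        if j.donor_exon is not None:
            up_lo = max(up_lo, j.donor_exon.start)
        down_hi = j.acceptor + we
        if j.acceptor_exon is not None:
            down_hi = min(down_hi, j.acceptor_exon.end)
        return {
            "upstream_exon": (up_lo, j.donor + 1),
            "intron_5p": (j.donor + 1, j.donor + 1 + wi),
            "intron_3p": (j.acceptor - wi, j.acceptor),
            "downstream_exon": (j.acceptor, down_hi),
        }
    up_hi = j.donor + we
    if j.donor_exon is not None:
        up_hi = min(up_hi, j.donor_exon.end)
    down_lo = j.acceptor - we + 1
    if j.acceptor_exon is not None:
        down_lo = max(down_lo, j.acceptor_exon.start)
    return {
        "upstream_exon": (j.donor, up_hi),
        "intron_5p": (j.donor - wi, j.donor),
        "intron_3p": (j.acceptor + 1, j.acceptor + 1 + wi),
        "downstream_exon": (down_lo, j.acceptor + 1),
    }


def motif_features(
    j: JunctionRecord,
    genome: GenomeSource,
    pwms: Sequence[PWM],
    regions: RegionSpec | None = None,
) -> dict[str, float]:
    """Motif frequency (hits/kb) and strength (max score) per factor x region."""
    regions = regions or RegionSpec()
    windows = junction_windows(j, regions)
    out: dict[str, float] = {}
    for name, (lo, hi) in windows.items():
        seq = genome.fetch(j.chrom, lo, hi, j.strand)
        for pwm in pwms:
            hits = scan_pwm(seq, pwm)
            key = f"{pwm.factor}_{name}"
            if not hits:
                out[f"{key}_freq"] = 0.0
                out[f"{key}_strength"] = STRENGTH_SENTINEL
                continue
            n_hits = sum(1 for _, s in hits if s >= pwm.hit_threshold)
            out[f"{key}_freq"] = n_hits / (len(seq) / 1000.0)
            out[f"{key}_strength"] = max(s for _, s in hits)
    return out


def read_bed(path: str) -> dict[str, np.ndarray]:
    """Read a BED (3+ columns, 0-based half-open) into per-chromosome
    sorted (N, 2) interval arrays."""
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        usecols=[0, 1, 2], names=["chrom", "start", "end"],
    )
    out = {}
    for chrom, grp in df.groupby("chrom"):
        arr = grp[["start", "end"]].to_numpy(dtype=np.int64)
        out[str(chrom)] = arr[np.argsort(arr[:, 0])]
    return out


def _nearest_distance(
    pos: int, intervals: np.ndarray, signed: bool = False
) -> float:
    """Bp distance from a position to the nearest interval edge, 0 when
    the position lies inside an interval.

    Unsigned by default; with ``signed=True`` the distance is negative
    when the nearest peak lies genomically left of the position.
    """
    if intervals.size == 0:
        return DISTANCE_SENTINEL
    starts, ends = intervals[:, 0], intervals[:, 1]
    inside = (starts <= pos) & (pos < ends)
    if inside.any():
        return 0.0
    d = np.minimum(np.abs(starts - pos), np.abs(ends - 1 - pos))
    i = int(d.argmin())
    dist = float(d[i])
    if signed and ends[i] - 1 < pos:
        return -dist
    return dist


def peak_distances(
    j: JunctionRecord,
    peaks: Mapping[str, Mapping[str, np.ndarray]],
    signed: bool = False,
) -> dict[str, float]:
    """Per-mark distance of donor and acceptor to the nearest peak.

    ``peaks`` maps mark name -> {chrom: (N, 2) sorted intervals}.
    Chromosomes absent from a track yield the finite sentinel distance.
    Distances are unsigned edge distances by default; ``signed=True``
    marks peaks genomically left of the site with a negative sign.
    """
    out = {}
    for mark, track in peaks.items():
        ivs = track.get(j.chrom)
        if ivs is None:
            log.info("mark %s has no intervals on %s", mark, j.chrom)
            ivs = np.empty((0, 2), dtype=np.int64)
        out[f"{mark}_donor_dist"] = _nearest_distance(j.donor, ivs, signed)
        out[f"{mark}_acceptor_dist"] = _nearest_distance(
            j.acceptor, ivs, signed
        )
    return out


def open_chromatin_association(
    diff_sites: Sequence[tuple[str, int]],
    nondiff_sites: Sequence[tuple[str, int]],
    peaks: Mapping[str, np.ndarray],
    max_dist: float = 0.0,
) -> tuple[float, float]:
    """Fisher 2x2 of peak overlap (distance <= max_dist) vs diff status."""
    if not diff_sites or not nondiff_sites:
        raise ValueError("empty site set")

    def flags(sites):
        return [
            _nearest_distance(pos, peaks.get(chrom, np.empty((0, 2), np.int64)))
            <= max_dist
            for chrom, pos in sites
        ]

    fd = flags(diff_sites)
    fn = flags(nondiff_sites)
    diff_ids = [f"d{i}" for i in range(len(fd))]
    nd_ids = [f"n{i}" for i in range(len(fn))]
    category = {
        **{i: ("in_peak" if f else "out") for i, f in zip(diff_ids, fd)},
        **{i: ("in_peak" if f else "out") for i, f in zip(nd_ids, fn)},
    }
    table = categorical_enrichment(diff_ids, diff_ids + nd_ids, category)
    row = table.loc["in_peak"]
    return float(row["odds_ratio"]), float(row["p"])


def compare_site_distances(
    dist_a: Sequence[float], dist_b: Sequence[float]
) -> tuple[float, float]:
    """Two-sided Mann-Whitney U on two distance samples (e.g. canonical vs
    alternative 5' splice sites)."""
    u, p = sps.mannwhitneyu(dist_a, dist_b, alternative="two-sided")
    return float(u), float(p)


def build_feature_matrix(
    junctions: Sequence[JunctionRecord],
    genome: GenomeSource,
    pwms: Sequence[PWM],
    peaks: Mapping[str, Mapping[str, np.ndarray]],
    gene_expression: Mapping[str, float],
    labels: Mapping[str, str],
    regions: RegionSpec | None = None,
) -> pd.DataFrame:
    """Assemble the per-junction predictor table with a diff/nondiff label."""
    rows = []
    for j in junctions:
        row: dict[str, float | str] = {"junction_id": j.junction_id}
        row.update(motif_features(j, genome, pwms, regions))
        row.update(peak_distances(j, peaks))
        row["intron_length"] = float(j.intron_length)
        row["gene_expression"] = float(gene_expression.get(j.gene_id, 0.0))
        row["label"] = labels.get(j.junction_id, "nondiff")
        rows.append(row)
    return pd.DataFrame(rows).set_index("junction_id")
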