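"""Synthetic genomes, gene models, counts, peaks and sequences with
fully-known planted truth.

The generator emulates the statistical structure the pipeline assumes:

* multi-transcript genes whose isoforms differ by a cassette exon and,
  in a subset of genes, by an alternative TSS;
* negative-binomial per-gene fragment counts allocated to isoforms by
  Dirichlet-multinomial proportions, with a condition-dependent shift of
  the cassette-inclusion proportion for planted differential genes;
* retained-intron coverage for planted introns, condition-specific or
  shared;
* peak tracks spatially associated with planted differential-junction
  donors at a higher rate than background;
* splicing-factor motif consensus strings planted near differential
  junctions at a higher rate than background;
* a nascent-RNA count matrix in which planted "delayed" junctions are
  depleted by a fixed factor relative to total RNA.

Everything is deterministic under the config seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genemodel import (
    GeneModel,
    GenomicInterval,
    JunctionRecord,
    TranscriptModel,
    catalog_junctions,
    flatten_exons,
    intron_intervals,
)
from .features import PWM, junction_windows, RegionSpec
from .quantify import CountMatrix, SampleInfo

__all__ = [
    "SimConfig",
    "SimTruth",
    "SimCounts",
    "default_pwms",
    "simulate_annotation",
    "simulate_counts",
    "simulate_peaks",
    "simulate_transcript_set",
    "write_fasta",
    "write_truth",
    "write_toy_bam",
]

# Synthetic consensus sites, one per splicing factor.  These are in-house
# stand-ins built for planted-truth simulations, not measured binding
# models; only RBFOX2's (U)GCAUG core follows its well-known element.
FACTOR_CONSENSUS = {
    "RBFOX2": "TGCATG",
    "YBX1": "CATCACC",
    "SRSF7": "GACGACG",
    "HNRNPA3": "TAGGGTT",
    "MBNL1": "TGCTGCT",
    "PTBP1": "TCTTTCT",
}

# factor -> window with a planted class effect; the remaining factors are
# planted at background rate in both classes (null predictors)
EFFECT_FACTORS = {
    "RBFOX2": "intron_5p",
    "YBX1": "intron_3p",
    "SRSF7": "downstream_exon",
}

MARKS = ("fusion_TF", "pol2", "H3K9Ac", "DHS")


@dataclass
class SimConfig:
    n_genes: int = 200
    transcripts_per_gene: tuple[int, int] = (2, 3)
    exon_len_log_mean: float = 5.0  # lognormal, ~150 bp
    exon_len_log_sd: float = 0.35
    intron_len_log_mean: float = 6.6  # ~740 bp
    intron_len_log_sd: float = 0.5
    n_replicates: int = 3
    depth: float = 300.0  # mean fragments per gene
    dispersion: float = 0.05  # NB overdispersion
    frac_diff_genes: float = 0.15
    usage_effect: float = 2.0  # planted |delta log2 usage-odds|
    concentration: float = 20.0  # Dirichlet-multinomial
    frac_retained_introns: float = 0.1
    peak_assoc_prob: float = 0.8
    peak_background_prob: float = 0.1  # peaks per kb
    assoc_window: int = 500
    motif_assoc_prob: float = 0.8
    motif_background_prob: float = 0.1
    frac_tss_genes: float = 0.3
    tss_activation_fold: float = 4.0
    frac_tss_activated: float = 0.5
    delayed_frac: float = 1.0  # the differential class is the delayed class
    delayed_factor: float = 4.0
    conditions: tuple[str, str] = ("siMM", "siRR")
    chrom: str = "chrS"
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (
            self.frac_diff_genes,
            self.frac_retained_introns,
            self.peak_assoc_prob,
            self.motif_assoc_prob,
            self.delayed_frac,
        ):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability {p} outside [0, 1]")
        if self.exon_len_log_mean <= 0 or self.intron_len_log_mean <= 0:
            raise ValueError("infeasible length parameters")


@dataclass
class SimTruth:
    diff_genes: list[str] = field(default_factory=list)
    diff_junctions: dict[str, float] = field(default_factory=dict)  # id -> effect
    inclusion_shift: dict[str, float] = field(default_factory=dict)  # gene -> signed
    retained_introns: dict[str, list[str]] = field(default_factory=dict)
    delayed_junctions: list[str] = field(default_factory=list)
    tss_activated: dict[str, float] = field(default_factory=dict)  # tss group -> fold
    motif_planted: dict[str, list[str]] = field(default_factory=dict)
    cassette_exon: dict[str, str] = field(default_factory=dict)  # gene -> exon key


@dataclass
class SimCounts:
    junctions: CountMatrix
    transcripts: CountMatrix
    bins: CountMatrix
    nascent_junctions: CountMatrix
    intron_coverage: pd.DataFrame
    flank_coverage: pd.DataFrame
    introns: dict[str, tuple[GenomicInterval, str]]
    samples: list[SampleInfo]
    nascent_samples: list[SampleInfo]


def default_pwms() -> list[PWM]:
    """Sharply-peaked count PWMs for the six factors' consensus strings."""
    pwms = []
    for factor, cons in FACTOR_CONSENSUS.items():
        counts = np.zeros((len(cons), 4))
        for i, base in enumerate(cons):
            counts[i, "ACGT".index(base)] = 18.0
        pwms.append(PWM.from_counts(factor, counts))
    return pwms


def _derived_seed(seed: int, k: int) -> int:
    return int((seed * 1_000_003 + 97 * k + 13) % (2**31 - 1))


def _lognormal_int(rng, mu, sd, lo, hi, size=None):
    v = np.exp(rng.normal(mu, sd, size=size))
    return np.clip(np.round(v).astype(int), lo, hi)


def simulate_annotation(
    cfg: SimConfig,
) -> tuple[dict[str, str], list[GeneModel], SimTruth]:
    """Generate genome, gene models and planted truth.

    Every gene has an inclusion transcript (all exons) and a skipping
    transcript lacking one internal cassette exon; a fraction of genes
    additionally carries an alternative-TSS transcript whose first exon is
    truncated.  A fraction of genes is planted differential: the
    cassette-inclusion proportion shifts between conditions by
    ``usage_effect`` on the log2-odds scale, making the three
    isoform-discriminating junctions truly differentially used.  Motif
    consensus strings are planted in junction windows with class-dependent
    probability.
    """
    rng = np.random.default_rng(_derived_seed(cfg.seed, 0))
    genes: list[GeneModel] = []
    truth = SimTruth()
    pos = 1000
    spacing = 2000
    gene_layouts = []

    for gi in range(cfg.n_genes):
        gid = f"G{gi:04d}"
        strand = "+" if rng.random() < 0.5 else "-"
        n_exons = int(rng.integers(4, 8))
        elens = _lognormal_int(
            rng, cfg.exon_len_log_mean, cfg.exon_len_log_sd, 40, 400, n_exons
        )
        ilens = _lognormal_int(
            rng, cfg.intron_len_log_mean, cfg.intron_len_log_sd, 80, 3000, n_exons - 1
        )
        exons = []
        p = pos
        for k in range(n_exons):
            exons.append(GenomicInterval(cfg.chrom, p, p + int(elens[k]), strand))
            p += int(elens[k])
            if k < n_exons - 1:
                p += int(ilens[k])
        gene_end = p
        pos = gene_end + spacing

        # cassette = one internal exon
        cass_idx = int(rng.integers(1, n_exons - 1))
        genomic_exons = exons  # left-to-right
        t1_ex = list(genomic_exons)
        t2_ex = [e for k, e in enumerate(genomic_exons) if k != cass_idx]

        # CDS spans from mid of first to mid of last exon (genomic)
        cs = genomic_exons[0].start + len(genomic_exons[0]) // 2
        ce = genomic_exons[-1].start + len(genomic_exons[-1]) // 2
        cds = GenomicInterval(cfg.chrom, cs, ce, strand)

        transcripts = [
            TranscriptModel(f"{gid}.t1", gid, t1_ex, cds),
            TranscriptModel(f"{gid}.t2", gid, t2_ex, cds),
        ]
        has_tss = rng.random() < cfg.frac_tss_genes
        if has_tss:
            # alternative TSS: skipping transcript with a truncated
            # 5'-most exon (keeps flanking junctions exclusive to t1)
            if strand == "+":
                first = t2_ex[0]
                alt_first = GenomicInterval(
                    cfg.chrom, first.start + min(150, len(first) - 40), first.end,
                    strand,
                )
                t3_ex = [alt_first] + list(t2_ex[1:])
            else:
                first = t2_ex[-1]
                alt_first = GenomicInterval(
                    cfg.chrom, first.start, first.end - min(150, len(first) - 40),
                    strand,
                )
                t3_ex = list(t2_ex[:-1]) + [alt_first]
            alt_cs = max(cs, alt_first.start)
            alt_ce = min(ce, t3_ex[-1].end if strand == "+" else ce)
            alt_cds = (
                GenomicInterval(cfg.chrom, alt_cs, ce, strand)
                if alt_cs < ce
                else None
            )
            transcripts.append(TranscriptModel(f"{gid}.t3", gid, t3_ex, alt_cds))

        gene = GeneModel(gid, transcripts, "protein_coding")
        genes.append(gene)
        truth.cassette_exon[gid] = (
            f"{cfg.chrom}:{genomic_exons[cass_idx].start}-"
            f"{genomic_exons[cass_idx].end}"
        )
        gene_layouts.append((gene, has_tss))

    # planted differential genes and their effect sign
    n_diff = int(round(cfg.frac_diff_genes * cfg.n_genes))
    diff_idx = set(rng.choice(cfg.n_genes, size=n_diff, replace=False).tolist())
    for gi, (gene, _) in enumerate(gene_layouts):
        if gi in diff_idx:
            sign = 1.0 if rng.random() < 0.5 else -1.0
            truth.diff_genes.append(gene.gene_id)
            truth.inclusion_shift[gene.gene_id] = sign * cfg.usage_effect
            for j in catalog_junctions(gene):
                t1 = gene.transcripts[0]
                t2 = gene.transcripts[1]
                in_t1 = _junction_in_transcript(j, t1, gene.strand)
                in_t2 = _junction_in_transcript(j, t2, gene.strand)
                if in_t1 != in_t2:  # isoform-discriminating
                    eff = cfg.usage_effect * (sign if in_t1 else -sign)
                    truth.diff_junctions[j.junction_id] = eff

    # delayed junctions: a fraction of the planted differential junctions
    dj = sorted(truth.diff_junctions)
    n_delay = int(round(cfg.delayed_frac * len(dj)))
    if n_delay:
        truth.delayed_junctions = sorted(
            rng.choice(dj, size=n_delay, replace=False).tolist()
        )

    # TSS activation: half of the alt-TSS genes get a 4-fold boost of TSS2
    for gene, has_tss in gene_layouts:
        if has_tss and rng.random() < cfg.frac_tss_activated:
            truth.tss_activated[f"{gene.gene_id}.t3"] = cfg.tss_activation_fold

    # retained introns
    ri_genes = rng.choice(
        cfg.n_genes,
        size=int(round(cfg.frac_retained_introns * cfg.n_genes)),
        replace=False,
    )
    for gi in sorted(ri_genes.tolist()):
        gene = genes[gi]
        ivs = intron_intervals(gene)
        if not ivs:
            continue
        iv = ivs[int(rng.integers(0, len(ivs)))]
        iid = f"{gene.gene_id}:RI:{iv.start}-{iv.end}"
        r = rng.random()
        if r < 0.4:
            conds = [cfg.conditions[1]]  # knockdown-specific
        elif r < 0.6:
            conds = [cfg.conditions[0]]
        else:
            conds = list(cfg.conditions)
        truth.retained_introns[iid] = conds

    genome = _build_genome(genes, gene_layouts, truth, cfg, rng)
    return genome, genes, truth


def _junction_in_transcript(
    j: JunctionRecord, t: TranscriptModel, strand: str
) -> bool:
    for up, down in zip(t.exons, t.exons[1:]):
        if strand == "+":
            if up.end - 1 == j.donor and down.start == j.acceptor:
                return True
        else:
            if up.start == j.donor and down.end - 1 == j.acceptor:
                return True
    return False


def _build_genome(
    genes: Sequence[GeneModel],
    gene_layouts,
    truth: SimTruth,
    cfg: SimConfig,
    rng: np.random.Generator,
) -> dict[str, str]:
    size = max(g.span.end for g in genes) + 1000
    seq = bytearray(
        rng.choice(np.frombuffer(b"ACGT", dtype="S1"), size=size).tobytes()
    )

    # plant splicing-factor consensus strings around junctions; the ORF
    # pass below only rewrites stop codons, which none of the consensus
    # strings can form inside a coding exon window
    regions = RegionSpec()
    for gene in genes:
        for j in catalog_junctions(gene):
            is_diff = j.junction_id in truth.diff_junctions
            windows = junction_windows(j, regions)
            for factor, cons in FACTOR_CONSENSUS.items():
                region = EFFECT_FACTORS.get(factor)
                if region is None:
                    # null predictor: same background rate in both classes
                    region = "intron_3p"
                    prob = cfg.motif_background_prob
                else:
                    prob = (
                        cfg.motif_assoc_prob
                        if is_diff
                        else cfg.motif_background_prob
                    )
                if rng.random() >= prob:
                    continue
                lo, hi = windows[region]
                _plant_string(seq, lo, hi, cons, j.strand, rng)
                truth.motif_planted.setdefault(factor, []).append(j.junction_id)

    # design a clean ORF along each gene's inclusion transcript
    for gene in genes:
        _plant_orf(seq, gene.transcripts[0])
    return {cfg.chrom: seq.decode()}


_RC = bytes.maketrans(b"ACGT", b"TGCA")


def _plant_string(
    seq: bytearray, lo: int, hi: int, cons: str, strand: str, rng
) -> None:
    width = len(cons)
    lo, hi = max(0, lo), min(len(seq), hi)
    if hi - lo < width:
        return
    off = int(rng.integers(lo, hi - width + 1))
    payload = cons.encode()
    if strand == "-":
        payload = payload.translate(_RC)[::-1]
    seq[off : off + width] = payload


def _transcript_coords(t: TranscriptModel) -> list[int]:
    """Genomic coordinate of each transcript base, 5'->3'."""
    coords: list[int] = []
    for e in t.exons:
        rng_ = range(e.start, e.end) if t.strand == "+" else range(e.end - 1, e.start - 1, -1)
        coords.extend(rng_)
    return coords


_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def _plant_orf(seq: bytearray, t: TranscriptModel) -> None:
    """Rewrite the genome so the transcript's CDS is a stop-free ORF."""
    if t.cds is None:
        return
    coords = _transcript_coords(t)
    base_at = {}
    for i, g in enumerate(coords):
        b = chr(seq[g])
        base_at[i] = b if t.strand == "+" else _COMP.get(b, "N")
    in_cds = [
        i
        for i, g in enumerate(coords)
        if t.cds.start <= g < t.cds.end
    ]
    if len(in_cds) < 9:
        return
    c0 = in_cds[0]
    n_codons = len(in_cds) // 3
    tx = [base_at[i] for i in range(len(coords))]
    tx[c0 : c0 + 3] = list("ATG")
    for ci in range(1, n_codons - 1):
        codon = "".join(tx[c0 + 3 * ci : c0 + 3 * ci + 3])
        if codon in ("TAA", "TAG", "TGA"):
            tx[c0 + 3 * ci + 2] = "C"
    tx[c0 + 3 * (n_codons - 1) : c0 + 3 * n_codons] = list("TAA")
    for i, g in enumerate(coords):
        b = tx[i]
        seq[g] = ord(b if t.strand == "+" else _COMP.get(b, "N"))


# ---------------------------------------------------------------------------
# Counts
# ---------------------------------------------------------------------------

def _nb(rng, mean, dispersion, size=None):
    mean = np.maximum(np.asarray(mean, dtype=float), 1e-9)
    n = 1.0 / dispersion
    p = n / (n + mean)
    return rng.negative_binomial(n, p, size=size)


def simulate_counts(
    genes: Sequence[GeneModel],
    truth: SimTruth,
    cfg: SimConfig,
) -> SimCounts:
    """Generate junction, transcript, bin and nascent count matrices.

    Per gene and sample: fragments ~ NB(depth x gene factor, dispersion),
    split across isoforms by Dirichlet-multinomial proportions whose
    cassette-inclusion share is shifted by the planted usage effect in the
    second condition; junction and bin counts arise by binomial thinning
    of the fragments of the isoforms containing them.  The nascent matrix
    repeats the total counts with planted delayed junctions thinned by
    1/delayed_factor.
    """
    rng = np.random.default_rng(_derived_seed(cfg.seed, 1))
    samples = [
        SampleInfo(f"{cond}_{r}", cond, r, "total")
        for cond in cfg.conditions
        for r in range(1, cfg.n_replicates + 1)
    ]
    nascent_samples = [
        SampleInfo(f"{s.condition}_{s.replicate}_nasc", s.condition, s.replicate,
                   "nascent")
        for s in samples
    ]

    # lognormal expression factors, normalized so E[factor] = 1 and the
    # mean fragment count per gene equals cfg.depth
    gene_factor = {
        g.gene_id: float(np.exp(rng.normal(0.0, 0.5) - 0.125)) for g in genes
    }

    jrows: dict[str, list[int]] = {}
    trows: dict[str, list[int]] = {}
    brows: dict[str, list[int]] = {}
    icov: dict[str, list[float]] = {}
    fcov: dict[str, list[float]] = {}
    introns_out: dict[str, tuple[GenomicInterval, str]] = {}

    cond2 = cfg.conditions[1]
    for gene in genes:
        cat = catalog_junctions(gene)
        tmodels = gene.transcripts
        junc_in_t = {
            t.transcript_id: {
                j.junction_id
                for j in cat
                if _junction_in_transcript(j, t, gene.strand)
            }
            for t in tmodels
        }
        bins = flatten_exons(gene)
        bin_cover = {
            b.bin_id: [
                t.transcript_id
                for t in tmodels
                if any(
                    e.start <= b.interval.start and b.interval.end <= e.end
                    for e in t.exons
                )
            ]
            for b in bins
        }

        # inclusion share: constant 0.5 for null genes; for planted genes
        # it swings between 1/(1+2^effect) and its complement, which
        # realizes ~|effect| log2-odds of usage change per
        # isoform-discriminating junction once shared junctions are
        # accounted for
        shift = truth.inclusion_shift.get(gene.gene_id, 0.0)
        if shift != 0.0:
            p_lo = 1.0 / (1.0 + 2.0 ** abs(shift))
            p_inc1 = p_lo if shift > 0 else 1.0 - p_lo
            p_inc2 = 1.0 - p_inc1
        else:
            p_inc1 = p_inc2 = 0.5
        base_props = _isoform_props(len(tmodels), p_inc1)

        for si, s in enumerate(samples):
            mu = cfg.depth * gene_factor[gene.gene_id]
            frags = int(_nb(rng, mu, cfg.dispersion))
            props = base_props.copy()
            if s.condition == cond2 and shift != 0.0:
                props = _isoform_props(len(tmodels), p_inc2)
            alpha = props * cfg.concentration
            pvec = rng.dirichlet(alpha)
            iso = rng.multinomial(frags, pvec)
            iso_by_t = dict(zip((t.transcript_id for t in tmodels), iso))
            # planted TSS activation is applied to the transcript matrix
            # only, keeping junction/bin usage truth independent of it
            iso_tss = dict(iso_by_t)
            for t in tmodels:
                fold = truth.tss_activated.get(t.transcript_id)
                if fold and s.condition == cond2:
                    iso_tss[t.transcript_id] = int(iso_tss[t.transcript_id] * fold)
            for j in cat:
                pool = sum(
                    iso_by_t[tid]
                    for tid, jset in junc_in_t.items()
                    if j.junction_id in jset
                )
                c = int(rng.binomial(pool, 0.6)) if pool > 0 else 0
                jrows.setdefault(j.junction_id, [0] * len(samples))[si] = c
            for t in tmodels:
                trows.setdefault(t.transcript_id, [0] * len(samples))[si] = int(
                    iso_tss[t.transcript_id]
                )
            for b in bins:
                pool = sum(iso_by_t[tid] for tid in bin_cover[b.bin_id])
                pcap = min(0.9, len(b.interval) / 400.0)
                c = int(rng.binomial(pool, pcap)) if pool > 0 else 0
                brows.setdefault(b.bin_id, [0] * len(samples))[si] = c

        # intron coverage rows: planted retained introns read like exons
        # in their conditions, all other introns carry faint background
        for iv in intron_intervals(gene):
            iid = f"{gene.gene_id}:RI:{iv.start}-{iv.end}"
            conds = truth.retained_introns.get(iid, [])
            introns_out[iid] = (iv, gene.gene_id)
            ic_row, fc_row = [], []
            for s in samples:
                flank = max(
                    1.0,
                    rng.gamma(10.0, cfg.depth * gene_factor[gene.gene_id] / 30.0),
                )
                theta_true = 0.5 if s.condition in conds else 0.01
                ic = rng.gamma(10.0, theta_true * flank / 10.0)
                ic_row.append(float(ic))
                fc_row.append(float(flank))
            icov[iid] = ic_row
            fcov[iid] = fc_row

    cols = [s.sample_id for s in samples]
    jdf = pd.DataFrame.from_dict(jrows, orient="index", columns=cols).sort_index()
    tdf = pd.DataFrame.from_dict(trows, orient="index", columns=cols).sort_index()
    bdf = pd.DataFrame.from_dict(brows, orient="index", columns=cols).sort_index()

    # nascent: thin delayed junctions by 1/delayed_factor
    ndf = jdf.copy()
    thin = 1.0 / cfg.delayed_factor
    for jid in truth.delayed_junctions:
        if jid in ndf.index:
            ndf.loc[jid] = rng.binomial(ndf.loc[jid].to_numpy(), thin)
    ndf.columns = [s.sample_id for s in nascent_samples]

    icov_df = (
        pd.DataFrame.from_dict(icov, orient="index", columns=cols).sort_index()
        if icov
        else pd.DataFrame(columns=cols)
    )
    fcov_df = (
        pd.DataFrame.from_dict(fcov, orient="index", columns=cols).sort_index()
        if fcov
        else pd.DataFrame(columns=cols)
    )

    return SimCounts(
        junctions=CountMatrix(jdf, list(samples)),
        transcripts=CountMatrix(tdf, list(samples)),
        bins=CountMatrix(bdf, list(samples)),
        nascent_junctions=CountMatrix(ndf, list(nascent_samples)),
        intron_coverage=icov_df,
        flank_coverage=fcov_df,
        introns=introns_out,
        samples=list(samples),
        nascent_samples=list(nascent_samples),
    )


def _isoform_props(n_iso: int, p_inc: float) -> np.ndarray:
    """Inclusion isoform gets p_inc; remaining isoforms share the rest."""
    props = np.empty(n_iso)
    props[0] = p_inc
    props[1:] = (1.0 - p_inc) / (n_iso - 1)
    return props


# ---------------------------------------------------------------------------
# Peaks
# ---------------------------------------------------------------------------

def simulate_peaks(
    genes: Sequence[GeneModel],
    truth: SimTruth,
    cfg: SimConfig,
    genome_size: int | None = None,
) -> dict[str, dict[str, np.ndarray]]:
    """Per-mark peak tracks associated with planted differential donors.

    Each mark places a 200-bp peak within ``assoc_window`` of every
    differential-junction donor with probability ``peak_assoc_prob``, plus
    uniform background peaks at ``peak_background_prob`` per kb.
    """
    rng = np.random.default_rng(_derived_seed(cfg.seed, 2))
    if genome_size is None:
        genome_size = max(g.span.end for g in genes) + 1000
    donors = []
    for gene in genes:
        for j in catalog_junctions(gene):
            if j.junction_id in truth.diff_junctions:
                donors.append(j.donor)
    tracks: dict[str, dict[str, np.ndarray]] = {}
    width = 200
    for mark in MARKS:
        ivs = []
        for d in donors:
            if rng.random() < cfg.peak_assoc_prob:
                center = d + int(rng.integers(-cfg.assoc_window + width // 2,
                                              cfg.assoc_window - width // 2))
                s = max(0, center - width // 2)
                ivs.append((s, s + width))
        n_bg = rng.poisson(cfg.peak_background_prob * genome_size / 1000.0)
        for _ in range(n_bg):
            s = int(rng.integers(0, genome_size - width))
            ivs.append((s, s + width))
        arr = np.array(sorted(ivs), dtype=np.int64).reshape(-1, 2)
        tracks[mark] = {cfg.chrom: arr}
    return tracks


def write_peaks_bed(
    tracks: Mapping[str, Mapping[str, np.ndarray]], prefix: str
) -> list[str]:
    paths = []
    for mark, track in tracks.items():
        path = f"{prefix}_{mark}.bed"
        with open(path, "w") as fh:
            for chrom in sorted(track):
                for s, e in track[chrom]:
                    fh.write(f"{chrom}\t{s}\t{e}\t{mark}\n")
        paths.append(path)
    return paths


# ---------------------------------------------------------------------------
# Transcript-level generator for termination-class recovery
# ---------------------------------------------------------------------------

def simulate_transcript_set(
    n: int, ptc_rate: float, seed: int = 0, n_codons: int = 120
):
    """Constructed transcripts with a known PTC rate.

    Each transcript carries one clean ORF; with probability ``ptc_rate``
    the final exon-exon junction is placed well downstream (> 50 nt) of
    the stop codon, making the transcript a planted PTC case.  Returns
    (TranscriptSequence list, planted flags).
    """
    from .consequences import TranscriptSequence

    rng = np.random.default_rng(seed)
    bases = np.frombuffer(b"ACGT", dtype="S1")
    out, flags = [], []
    sense = [a + b + c
             for a in "ACGT" for b in "ACGT" for c in "ACGT"
             if a + b + c not in ("TAA", "TAG", "TGA") and a + b + c != "ATG"]
    for i in range(n):
        utr5 = "".join(rng.choice(["C", "A", "G"], size=30))
        body = "".join(rng.choice(sense, size=n_codons - 1))
        orf = "ATG" + body + "TAA"
        is_ptc = bool(rng.random() < ptc_rate)
        stop_codon_start = len(utr5) + len(orf) - 3
        # a stop in all three frames right after the ORF, so no shifted
        # frame can read through into the UTR and outgrow the planted ORF
        utr3_guard = "TAAATAAATAA"
        if is_ptc:
            utr3 = utr3_guard + "".join(rng.choice(bases, size=289).astype(str))
            junctions = [len(utr5) + 10, stop_codon_start + 200]
        else:
            utr3 = utr3_guard + "".join(rng.choice(bases, size=109).astype(str))
            junctions = [len(utr5) + 10, stop_codon_start + 20]
        seq = utr5 + orf + utr3
        out.append(
            TranscriptSequence(f"T{i:04d}", seq, junctions,
                               "differential" if i % 2 else "nondifferential")
        )
        flags.append(is_ptc)
    return out, flags


# ---------------------------------------------------------------------------
# Writers & toy alignments
# ---------------------------------------------------------------------------

def write_fasta(genome: Mapping[str, str], path: str, width: int = 70) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(genome):
            fh.write(f">{chrom}\n")
            seq = genome[chrom]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_truth(truth: SimTruth, path: str) -> None:
    with open(path, "w") as fh:
        json.dump(asdict(truth), fh, indent=1, sort_keys=True)


def write_toy_bam(
    path: str,
    reads: Sequence[tuple[str, str, int, str]],
    chrom_lengths: Mapping[str, int],
    mapq: int = 60,
) -> str:
    """Write (qname, chrom, 0-based pos, cigar) tuples as a sorted,
    indexed BAM for counting tests."""
    import pysam

    chroms = sorted(chrom_lengths)
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": c, "LN": int(chrom_lengths[c])} for c in chroms],
    }
    recs = []
    for qname, chrom, pos, cigar in reads:
        a = pysam.AlignedSegment()
        a.query_name = qname
        a.reference_id = chroms.index(chrom)
        a.reference_start = pos
        a.cigarstring = cigar
        a.mapping_quality = mapq
        a.flag = 0
        qlen = sum(
            length
            for op, length in a.cigartuples
            if op in (0, 1, 4, 7, 8)
        )
        a.query_sequence = "A" * qlen
        recs.append(a)
    recs.sort(key=lambda r: (r.reference_id, r.reference_start))
    with pysam.AlignmentFile(path, "wb", header=header) as bam:
        for r in recs:
            bam.write(r)
    pysam.index(path)
    return path
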