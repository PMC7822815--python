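"""Gene-relative differential usage: moderated log-odds statistic, BH FDR,
threshold calls, multi-method consensus, TSS arms, 3'-terminal-exon check.

The usage statistic for feature f of gene g in sample s is

    u_fs = log2(c_fs + pc) - log2(T_gs - c_fs + pc)

(the within-gene log-odds of the feature against the rest of its gene),
with pc = 0.5.  The effect is the difference of condition means of u; the
test statistic divides it by a moderated standard error whose variance
prior is fitted empirically with an abundance trend (see
``_fit_variance_prior``).  The statistic deliberately isolates usage
shifts from gene-level expression changes: scaling every feature of a
gene by a common factor leaves u invariant up to pseudocount effects.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import special as spsp
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .genemodel import FlatBin
from .quantify import CountMatrix, SampleInfo, cpm_normalize

log = logging.getLogger(__name__)

__all__ = [
    "UsageStat",
    "DiffCall",
    "usage_statistic",
    "permutation_usage",
    "bh_fdr",
    "call_differential",
    "consensus",
    "group_tss",
    "tss_differential",
    "terminal_exon_check",
    "usage_table",
    "DEFAULT_FC",
    "DEFAULT_QMAX",
]

DEFAULT_FC = 2.0
DEFAULT_QMAX = 0.1
PSEUDOCOUNT = 0.5
LOWESS_FRAC = 0.5  # span of the variance-prior trend fit


@dataclass
class UsageStat:
    feature_id: str
    gene_id: str
    usage_log2fc: float
    stat: float
    p: float
    q: float = float("nan")

    @property
    def direction(self) -> str:
        return "up" if self.usage_log2fc > 0 else "down"


@dataclass
class DiffCall:
    feature_id: str
    is_differential: bool
    methods: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if self.is_differential != bool(self.methods):
            raise ValueError("is_differential inconsistent with methods")


def _condition_order(design: Sequence[SampleInfo]) -> list[str]:
    seen: list[str] = []
    for s in design:
        if s.condition not in seen:
            seen.append(s.condition)
    return seen


def _usage_matrix(
    m: CountMatrix,
    grouping: Mapping[str, str],
    min_count: int,
) -> tuple[pd.DataFrame, pd.Series]:
    """Per-sample within-gene log-odds u for surviving features."""
    counts = m.counts
    total = counts.sum(axis=1)
    keep = counts.index[(total >= min_count) & counts.index.isin(grouping)]
    counts = counts.loc[keep]
    gene = pd.Series({f: grouping[f] for f in counts.index}, name="gene")
    sizes = gene.groupby(gene).size()
    multi = sizes.index[sizes >= 2]
    counts = counts.loc[gene.isin(multi)]
    gene = gene.loc[counts.index]
    gene_tot = counts.groupby(gene).transform("sum")
    rest = gene_tot - counts
    u = np.log2(counts + PSEUDOCOUNT) - np.log2(rest + PSEUDOCOUNT)
    # delta-method scale of var(u): shrinks with abundance; used as the
    # trend covariate for the variance prior
    cov = np.log(
        (1.0 / (counts + PSEUDOCOUNT) + 1.0 / (rest + PSEUDOCOUNT)).mean(axis=1)
    )
    return u, gene, cov


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x by Newton iteration (monotone decreasing)."""
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = spsp.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / spsp.polygamma(2, y)
        y += dif
        if abs(dif) < 1e-8 * y:
            break
    return float(y)


def _fit_variance_prior(
    s2: np.ndarray, df_res: int, covariate: np.ndarray | None = None
) -> tuple[np.ndarray, float]:
    """Moment estimate of the scaled-inverse-chi2 variance prior from
    observed residual variances.

    Returns (per-feature prior scale s0^2, prior df d0); d0 may be inf.
    When ``covariate`` is given the prior scale follows a lowess trend on
    it (variances of count-derived log-odds shrink with abundance, so an
    exchangeable prior mis-fits; the trend absorbs that structure).
    """
    s2 = np.asarray(s2, dtype=float)
    floor = max(s2[s2 > 0].min() if (s2 > 0).any() else 1e-8, 1e-10)
    z = np.log(np.maximum(s2, floor * 1e-2))
    e = z - spsp.digamma(df_res / 2.0) + np.log(df_res / 2.0)
    if covariate is not None and np.ptp(covariate) > 0 and s2.size >= 10:
        import statsmodels.api as sm

        trend = sm.nonparametric.lowess(
            e, covariate, frac=LOWESS_FRAC, return_sorted=False
        )
    else:
        trend = np.full_like(e, e.mean())
    resid = e - trend
    evar = float(np.var(resid, ddof=1)) - float(spsp.polygamma(1, df_res / 2.0))
    if evar <= 0 or s2.size < 2:
        return np.exp(trend), np.inf
    d0 = 2.0 * _trigamma_inverse(evar)
    s0 = np.exp(trend + spsp.digamma(d0 / 2.0) - np.log(d0 / 2.0))
    return s0, d0


def usage_statistic(
    m: CountMatrix,
    grouping: Mapping[str, str],
    design: Sequence[SampleInfo],
    min_count: int = 10,
    prior_df: float | None = None,
) -> list[UsageStat]:
    """Moderated within-gene usage test per feature.

    Features with total count below ``min_count`` and genes left with a
    single feature are excluded.  The effect is mean(u, condition 2) -
    mean(u, condition 1) in design order.  Residual variances are shrunk
    toward a scaled-inverse-chi2 prior fitted to the family by the method
    of moments on log variances (empirical-Bayes moderation); the p-value
    is two-sided from a t distribution with residual + prior df.  Passing
    ``prior_df`` skips the fit and shrinks toward the family mean variance
    with that fixed prior weight instead.
    """
    conds = _condition_order(design)
    if len(conds) != 2:
        raise ValueError(f"need exactly 2 conditions, got {conds}")
    g1 = [s.sample_id for s in design if s.condition == conds[0]]
    g2 = [s.sample_id for s in design if s.condition == conds[1]]
    if min(len(g1), len(g2)) < 2:
        raise ValueError("need >=2 replicates per condition")

    u, gene, cov = _usage_matrix(m, grouping, min_count)
    if u.empty:
        return []
    u1, u2 = u[g1], u[g2]
    lfc = u2.mean(axis=1) - u1.mean(axis=1)
    n1, n2 = len(g1), len(g2)
    df_res = n1 + n2 - 2
    ss = ((u1.sub(u1.mean(axis=1), axis=0)) ** 2).sum(axis=1) + (
        (u2.sub(u2.mean(axis=1), axis=0)) ** 2
    ).sum(axis=1)
    s2 = ss / df_res
    if prior_df is None:
        s0, d0 = _fit_variance_prior(s2.to_numpy(), df_res, cov.to_numpy())
    else:
        s0, d0 = np.full(s2.size, float(s2.mean())), float(prior_df)
    if np.isinf(d0):
        s2_mod = pd.Series(s0, index=s2.index)
        df_total = np.inf
    else:
        s2_mod = (d0 * s0 + df_res * s2.to_numpy()) / (d0 + df_res)
        s2_mod = pd.Series(s2_mod, index=s2.index)
        df_total = df_res + d0
    se = np.sqrt(s2_mod * (1.0 / n1 + 1.0 / n2))
    tstat = lfc / se
    if np.isinf(df_total):
        p = 2.0 * sps.norm.sf(np.abs(tstat))
    else:
        p = 2.0 * sps.t.sf(np.abs(tstat), df=df_total)

    stats_list = [
        UsageStat(f, gene[f], float(lfc[f]), float(tstat[f]), float(pv))
        for f, pv in zip(u.index, p)
    ]
    q = bh_fdr([s.p for s in stats_list])
    for s, qv in zip(stats_list, q):
        s.q = qv
    return stats_list


def permutation_usage(
    m: CountMatrix,
    grouping: Mapping[str, str],
    design: Sequence[SampleInfo],
    min_count: int = 10,
    permutations: int = 200,
    seed: int = 0,
) -> list[UsageStat]:
    """Label-permutation variant: same effect, p from the permutation null.

    Serves as a second 'method' for the consensus bookkeeping.  With few
    replicates the permutation space is enumerated exhaustively when it is
    smaller than ``permutations``.
    """
    conds = _condition_order(design)
    g1 = [s.sample_id for s in design if s.condition == conds[0]]
    u, gene, _cov = _usage_matrix(m, grouping, min_count)
    if u.empty:
        return []
    cols = list(u.columns)
    n1 = len(g1)
    arr = u.to_numpy()
    mask1 = np.array([c in g1 for c in cols])
    obs = arr[:, ~mask1].mean(axis=1) - arr[:, mask1].mean(axis=1)

    from itertools import combinations

    all_splits = list(combinations(range(len(cols)), n1))
    rng = np.random.default_rng(seed)
    if len(all_splits) > permutations:
        idx = rng.choice(len(all_splits), size=permutations, replace=False)
        splits = [all_splits[i] for i in idx]
    else:
        splits = all_splits
    exceed = np.zeros(arr.shape[0])
    for split in splits:
        m1 = np.zeros(len(cols), dtype=bool)
        m1[list(split)] = True
        perm = arr[:, ~m1].mean(axis=1) - arr[:, m1].mean(axis=1)
        exceed += np.abs(perm) >= np.abs(obs) - 1e-12
    p = exceed / len(splits)
    stats_list = [
        UsageStat(f, gene[f], float(o), float("nan"), float(pv))
        for f, o, pv in zip(u.index, obs, p)
    ]
    q = bh_fdr([s.p for s in stats_list])
    for s, qv in zip(stats_list, q):
        s.q = qv
    return stats_list


def bh_fdr(p: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return []
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values outside [0, 1]")
    return list(multipletests(p, method="fdr_bh")[1])


def call_differential(
    stats: Sequence[UsageStat],
    fc: float = DEFAULT_FC,
    q_max: float = DEFAULT_QMAX,
    method: str = "moderated_t",
) -> list[DiffCall]:
    """Differential iff |usage_log2fc| > log2(fc) AND q < q_max (strict)."""
    thr = np.log2(fc)
    out = []
    for s in stats:
        hit = abs(s.usage_log2fc) > thr and s.q < q_max
        out.append(DiffCall(s.feature_id, hit, {method} if hit else set()))
    return out


def consensus(
    calls_by_method: Mapping[str, Sequence[DiffCall]],
    mode: str = "union",
) -> list[DiffCall]:
    """Merge per-method calls over an identical feature universe."""
    universes = [
        tuple(sorted(c.feature_id for c in calls))
        for calls in calls_by_method.values()
    ]
    if len(set(universes)) != 1:
        raise ValueError("methods tested different feature universes")
    features = universes[0]
    out = []
    for f in features:
        methods = {
            m
            for m, calls in calls_by_method.items()
            if any(c.feature_id == f and c.is_differential for c in calls)
        }
        if mode == "union":
            hit = bool(methods)
        elif mode == "intersection":
            hit = len(methods) == len(calls_by_method)
            if not hit:
                methods = set()
        else:
            raise ValueError(f"unknown mode {mode!r}")
        out.append(DiffCall(f, hit, methods))
    return out


# ---------------------------------------------------------------------------
# TSS arms
# ---------------------------------------------------------------------------

def group_tss(
    transcripts: Mapping[str, tuple[str, int]],
    window: int = 10,
) -> dict[str, str]:
    """Cluster transcripts of a gene whose TSS lie within ``window`` bp.

    ``transcripts`` maps transcript_id -> (gene_id, tss position).  Returns
    transcript_id -> TSS-group id ("gene@k", k ordered by position).
    """
    by_gene: dict[str, list[tuple[int, str]]] = {}
    for tid, (gid, pos) in transcripts.items():
        by_gene.setdefault(gid, []).append((pos, tid))
    mapping: dict[str, str] = {}
    for gid, items in by_gene.items():
        items.sort()
        k = 0
        anchor = None
        for pos, tid in items:
            if anchor is None or pos - anchor > window:
                k += 1
                anchor = pos
            mapping[tid] = f"{gid}@{k}"
    return mapping


def _moderated_t_expression(
    logcpm: pd.DataFrame,
    design: Sequence[SampleInfo],
) -> pd.DataFrame:
    """Two-group moderated t on log-CPM with the fitted variance prior."""
    conds = _condition_order(design)
    g1 = [s.sample_id for s in design if s.condition == conds[0]]
    g2 = [s.sample_id for s in design if s.condition == conds[1]]
    x1, x2 = logcpm[g1], logcpm[g2]
    lfc = x2.mean(axis=1) - x1.mean(axis=1)
    n1, n2 = len(g1), len(g2)
    df_res = n1 + n2 - 2
    ss = ((x1.sub(x1.mean(axis=1), axis=0)) ** 2).sum(axis=1) + (
        (x2.sub(x2.mean(axis=1), axis=0)) ** 2
    ).sum(axis=1)
    s2 = ss / df_res
    s0, d0 = _fit_variance_prior(s2.to_numpy(), df_res)
    if np.isinf(d0):
        s2_mod = pd.Series(s0, index=s2.index)
        t = lfc / np.sqrt(s2_mod * (1 / n1 + 1 / n2))
        p = 2 * sps.norm.sf(np.abs(t))
    else:
        s2_mod = pd.Series(
            (d0 * s0 + df_res * s2.to_numpy()) / (d0 + df_res), index=s2.index
        )
        t = lfc / np.sqrt(s2_mod * (1 / n1 + 1 / n2))
        p = 2 * sps.t.sf(np.abs(t), df=df_res + d0)
    return pd.DataFrame({"log2fc": lfc, "stat": t, "p": p, "q": bh_fdr(p)})


def tss_differential(
    transcript_counts: CountMatrix,
    tss_grouping: Mapping[str, str],
    design: Sequence[SampleInfo],
    expr_fc: float = 2.0,
    expr_p: float = 0.005,
    usage_p: float = 0.0007,
    q_max: float = DEFAULT_QMAX,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Differential TSS expression and usage.

    Expression arm: per-TSS-group total counts compared between conditions
    by moderated t on log-CPM; called at >= ``expr_fc`` fold, p <
    ``expr_p``, q < ``q_max``.  Usage arm: the within-gene usage statistic
    with TSS groups as features, called at p < ``usage_p`` and the same
    fold/q rules.  Genes with a single TSS group are absent from the usage
    arm but present in the expression arm.
    """
    counts = transcript_counts.counts
    groups = pd.Series(
        {t: tss_grouping[t] for t in counts.index if t in tss_grouping}
    )
    tss_counts = counts.loc[groups.index].groupby(groups).sum()
    tss_cm = CountMatrix(
        tss_counts, list(transcript_counts.samples),
        transcript_counts.library_sizes.copy(),
    )
    expr = _moderated_t_expression(cpm_normalize(tss_cm), design)
    thr = np.log2(expr_fc)
    expr["called"] = (
        (expr["log2fc"].abs() >= thr) & (expr["p"] < expr_p) & (expr["q"] < q_max)
    )

    gene_of = {g: g.split("@")[0] for g in tss_counts.index}
    usage = usage_statistic(tss_cm, gene_of, design, min_count=1)
    udf = pd.DataFrame(
        {
            "feature_id": [s.feature_id for s in usage],
            "gene_id": [s.gene_id for s in usage],
            "log2fc": [s.usage_log2fc for s in usage],
            "stat": [s.stat for s in usage],
            "p": [s.p for s in usage],
            "q": [s.q for s in usage],
        }
    ).set_index("feature_id")
    if not udf.empty:
        udf["called"] = (
            (udf["log2fc"].abs() >= thr) & (udf["p"] < usage_p) & (udf["q"] < q_max)
        )
    return expr, udf


def terminal_exon_check(
    stats: Sequence[UsageStat],
    bins: Sequence[FlatBin],
    peak_overlap: Mapping[str, bool],
    fc: float = 2.0,
    q_max: float = 1e-4,
) -> dict[str, int]:
    """Count peak-overlapping 3'-terminal bins and those differential at
    (fold > ``fc``, q < ``q_max``)."""
    by_id = {s.feature_id: s for s in stats}
    thr = np.log2(fc)
    n_overlap = 0
    n_diff = 0
    for b in bins:
        if not b.is_three_prime_terminal or not peak_overlap.get(b.bin_id, False):
            continue
        n_overlap += 1
        s = by_id.get(b.bin_id)
        if s is not None and abs(s.usage_log2fc) >= thr and s.q < q_max:
            n_diff += 1
    return {"peak_overlapping_terminal_bins": n_overlap, "differential": n_diff}


def usage_table(stats: Sequence[UsageStat], calls: Sequence[DiffCall]) -> pd.DataFrame:
    call_by_id = {c.feature_id: c for c in calls}
    rows = []
    for s in stats:
        c = call_by_id.get(s.feature_id)
        rows.append(
            {
                "feature_id": s.feature_id,
                "gene_id": s.gene_id,
                "usage_log2fc": s.usage_log2fc,
                "stat": s.stat,
                "p": s.p,
                "q": s.q,
                "called": bool(c and c.is_differential),
                "methods": ",".join(sorted(c.methods)) if c else "",
            }
        )
    return pd.DataFrame(rows).set_index("feature_id")
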