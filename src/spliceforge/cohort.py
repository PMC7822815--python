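"""Cross-sample analyses: ICA junction signatures, overlap odds ratios,
nascent-vs-total delayed splicing, and signed co-expression edges."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.decomposition import FastICA
from sklearn.mixture import GaussianMixture

from .diffusage import bh_fdr
from .events import categorical_enrichment
from .quantify import CountMatrix, cpm_normalize

__all__ = [
    "SignatureComponent",
    "DelayedSplicingSummary",
    "ica_signatures",
    "overlap_odds",
    "delayed_splicing",
    "bimodality_score",
    "coexpression_edges",
]


@dataclass
class SignatureComponent:
    component: int
    loadings: pd.Series  # per junction, unit norm
    weights: pd.Series  # per sample
    separation_p: float
    signature: list[str] = field(default_factory=list)


def ica_signatures(
    junction_logcpm: pd.DataFrame,
    groups: Mapping[str, str],
    k: int | None = None,
    seed: int = 0,
    z_threshold: float = 2.5,
) -> list[SignatureComponent]:
    """ICA decomposition of a junction-by-sample log-CPM matrix.

    Components are ranked by the two-sided Mann-Whitney p of their sample
    weights between the two groups; the signature of a component is the
    junction set with |z-scored loading| above ``z_threshold``.  ``k``
    defaults to the number of groups plus three.
    """
    if k is None:
        k = len(set(groups.values())) + 3
    X = junction_logcpm.to_numpy(dtype=float)
    n_junc, n_samp = X.shape
    if k >= min(n_junc, n_samp):
        raise ValueError(f"k={k} must be < min(junctions, samples)")
    labels = [groups[c] for c in junction_logcpm.columns]
    uniq = sorted(set(labels))
    if len(uniq) != 2 or min(labels.count(u) for u in uniq) < 3:
        raise ValueError("need two groups with >= 3 samples each")

    Xc = X - X.mean(axis=1, keepdims=True)
    ica = FastICA(n_components=k, random_state=seed, whiten="unit-variance",
                  max_iter=2000, tol=1e-4)
    S = ica.fit_transform(Xc)  # junctions x k (loadings)
    A = ica.mixing_  # samples x k (weights)

    comps = []
    for c in range(k):
        load = S[:, c].astype(float)
        norm = np.linalg.norm(load)
        w = A[:, c].astype(float) * norm
        load = load / norm
        g1 = [wi for wi, lab in zip(w, labels) if lab == uniq[0]]
        g2 = [wi for wi, lab in zip(w, labels) if lab == uniq[1]]
        _, p = sps.mannwhitneyu(g1, g2, alternative="two-sided")
        z = (load - load.mean()) / load.std()
        sig = [j for j, zi in zip(junction_logcpm.index, z) if abs(zi) > z_threshold]
        comps.append(
            SignatureComponent(
                c,
                pd.Series(load, index=junction_logcpm.index),
                pd.Series(w, index=junction_logcpm.columns),
                float(p),
                sig,
            )
        )
    comps.sort(key=lambda c: c.separation_p)
    return comps


def overlap_odds(
    set_a: Iterable[str], set_b: Iterable[str], universe: Iterable[str]
) -> tuple[float, float]:
    """Fisher odds ratio and p for the overlap of two feature sets."""
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    set_a, set_b = set(set_a), set(set_b)
    category = {f: ("in_b" if f in set_b else "out_b") for f in universe}
    table = categorical_enrichment(set_a, universe, category)
    row = table.loc["in_b"]
    return float(row["odds_ratio"]), float(row["p"])


@dataclass
class DelayedSplicingSummary:
    values: dict[tuple[str, str], np.ndarray]  # (class, fraction) -> log-CPM
    medians: dict[tuple[str, str], float]
    p_diff_vs_nondiff: dict[str, float]  # per fraction
    p_nascent_vs_total: dict[str, float]  # per class
    bimodality: dict[tuple[str, str], float]
    unstable: bool = False


def bimodality_score(x: np.ndarray, seed: int = 0) -> float:
    """Log-likelihood improvement of a 2- over a 1-component Gaussian
    mixture fit; larger means more bimodal."""
    x = np.asarray(x, dtype=float).reshape(-1, 1)
    if x.shape[0] < 4:
        return 0.0
    ll = {}
    for ncomp in (1, 2):
        gm = GaussianMixture(n_components=ncomp, random_state=seed, n_init=3)
        gm.fit(x)
        ll[ncomp] = gm.score(x) * x.shape[0]
    return float(ll[2] - ll[1])


def delayed_splicing(
    nascent: CountMatrix,
    total: CountMatrix,
    diff_labels: Mapping[str, str],
    seed: int = 0,
) -> DelayedSplicingSummary:
    """Compare replicate-averaged junction abundance between nascent and
    total RNA for differential vs non-differential junctions.

    Only junctions shared between the two matrices enter.  Medians and
    two-sided Mann-Whitney tests are computed on log-CPM.  The nascent
    values are recentered so the median nascent-total difference over all
    shared junctions is zero (median-ratio size-factor anchoring); without
    this, depleting one class would masquerade as a global shift of the
    other through the library sizes.
    """
    shared = nascent.counts.index.intersection(total.counts.index)
    nas = cpm_normalize(nascent.subset(shared)).mean(axis=1)
    tot = cpm_normalize(total.subset(shared)).mean(axis=1)
    nas = nas - float(np.median(nas - tot))

    values: dict[tuple[str, str], np.ndarray] = {}
    unstable = False
    for cls in ("diff", "nondiff"):
        ids = [j for j in shared if diff_labels.get(j, "nondiff") == cls]
        if len(ids) < 10:
            unstable = True
        values[(cls, "nascent")] = nas.loc[ids].to_numpy()
        values[(cls, "total")] = tot.loc[ids].to_numpy()

    medians = {k: float(np.median(v)) if v.size else float("nan")
               for k, v in values.items()}
    p_frac = {}
    for frac in ("nascent", "total"):
        a, b = values[("diff", frac)], values[("nondiff", frac)]
        p_frac[frac] = (
            float(sps.mannwhitneyu(a, b, alternative="two-sided")[1])
            if a.size and b.size else float("nan")
        )
    p_cls = {}
    for cls in ("diff", "nondiff"):
        a, b = values[(cls, "nascent")], values[(cls, "total")]
        p_cls[cls] = (
            float(sps.mannwhitneyu(a, b, alternative="two-sided")[1])
            if a.size and b.size else float("nan")
        )
    bim = {k: bimodality_score(v, seed=seed) for k, v in values.items()}
    return DelayedSplicingSummary(values, medians, p_frac, p_cls, bim, unstable)


def coexpression_edges(
    expr: pd.DataFrame,
    seed_gene: str,
    candidates: Sequence[str],
    r_min: float = 0.5,
) -> pd.DataFrame:
    """Signed Pearson co-expression edges from a seed gene.

    ``expr`` is gene-by-sample.  Zero-variance candidates are excluded.
    Edges require |r| >= ``r_min``; BH-adjusted correlation-test p values
    are attached.
    """
    if expr.shape[1] < 5:
        raise ValueError("need >= 5 samples")
    x = expr.loc[seed_gene].to_numpy(dtype=float)
    rows = []
    for g in candidates:
        if g == seed_gene:
            continue
        yv = expr.loc[g].to_numpy(dtype=float)
        if np.std(yv) == 0 or np.std(x) == 0:
            continue
        r, p = sps.pearsonr(x, yv)
        rows.append({"gene": g, "r": float(r), "p": float(p)})
    df = pd.DataFrame(rows)
    if df.empty:
        return df
    df["q"] = bh_fdr(df["p"].tolist())
    df["sign"] = np.where(df["r"] > 0, "positive", "negative")
    return df[df["r"].abs() >= r_min].reset_index(drop=True)
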