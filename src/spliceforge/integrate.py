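"""Random-forest meta-classifier over junction feature vectors.

The two classes (differentially vs non-differentially used junctions) are
heavily imbalanced in practice, so the classifier is an ensemble of
independently seeded runs: each run keeps every minority example, draws an
equal-size sample of the majority class, fits a random forest, and is
evaluated on the untouched majority remainder plus the out-of-bag minority
predictions.  AUROC, permutation importances and partial-dependence
profiles are averaged over runs; everything is deterministic given the
seed, with per-run RNG streams derived from (seed, run index).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score

__all__ = [
    "RFConfig",
    "MetaClassifier",
    "PartialDependenceProfile",
    "train_meta_classifier",
    "partial_dependence",
    "rank_features",
]


@dataclass
class RFConfig:
    n_runs: int = 1000
    n_trees: int = 1000
    balance: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_runs < 1 or self.n_trees < 1:
            raise ValueError("n_runs and n_trees must be >= 1")

    def run_seed(self, run: int) -> int:
        return int((self.seed * 1_000_003 + 7919 * run + 1) % (2**31 - 1))


@dataclass
class MetaClassifier:
    config: RFConfig
    feature_names: list[str]
    forests: list[RandomForestClassifier]
    run_minority: list[np.ndarray]  # training (minority) row indices per run
    run_rest: list[np.ndarray]  # untouched majority row indices per run
    run_auroc: list[float]
    X: np.ndarray
    y: np.ndarray

    @property
    def auroc(self) -> float:
        return float(np.mean(self.run_auroc))


@dataclass
class PartialDependenceProfile:
    feature: str
    grid: np.ndarray
    prob: np.ndarray
    dispersion: np.ndarray


def _as_xy(X: pd.DataFrame, label_col: str = "label"):
    y = (X[label_col] == "diff").to_numpy().astype(int)
    feats = X.drop(columns=[label_col])
    return feats.to_numpy(dtype=float), y, list(feats.columns)


def train_meta_classifier(
    X: "pd.DataFrame | np.ndarray",
    cfg: RFConfig,
    y: np.ndarray | None = None,
    feature_names: Sequence[str] | None = None,
) -> MetaClassifier:
    """Fit the balanced repeated-run ensemble.

    ``X`` may be the feature DataFrame carrying a ``label`` column with
    values diff/nondiff, or a numeric array with ``y`` given separately.
    Requires >= 20 minority-class examples and both classes present.
    """
    if isinstance(X, pd.DataFrame):
        Xa, ya, names = _as_xy(X)
    else:
        Xa = np.asarray(X, dtype=float)
        ya = np.asarray(y, dtype=int)
        names = list(feature_names or (f"f{i}" for i in range(Xa.shape[1])))
    classes = np.unique(ya)
    if classes.size < 2:
        raise ValueError("single-class input")
    n1 = int(ya.sum())
    minority = 1 if n1 <= ya.size - n1 else 0
    n_min = int((ya == minority).sum())
    if n_min < 20:
        raise ValueError(f"need >= 20 minority-class examples, got {n_min}")

    min_idx = np.flatnonzero(ya == minority)
    maj_idx = np.flatnonzero(ya != minority)

    forests, run_min, run_rest, aurocs = [], [], [], []
    for run in range(cfg.n_runs):
        rs = cfg.run_seed(run)
        rng = np.random.default_rng(rs)
        if cfg.balance and maj_idx.size > min_idx.size:
            take = rng.choice(maj_idx, size=min_idx.size, replace=False)
        else:
            take = maj_idx
        train = np.concatenate([min_idx, take])
        rest = np.setdiff1d(maj_idx, take)
        rf = RandomForestClassifier(
            n_estimators=cfg.n_trees,
            max_features="sqrt",
            oob_score=True,
            bootstrap=True,
            random_state=rs,
            n_jobs=1,
        )
        rf.fit(Xa[train], ya[train])
        diff_col = int(np.flatnonzero(rf.classes_ == 1)[0])
        # held-out = untouched majority remainder + OOB minority predictions
        oob = rf.oob_decision_function_[: min_idx.size, diff_col]
        oob = np.nan_to_num(oob, nan=0.5)
        if rest.size:
            rest_p = rf.predict_proba(Xa[rest])[:, diff_col]
            pr = np.concatenate([oob, rest_p])
            yt = np.concatenate([ya[min_idx], ya[rest]])
        else:
            pr, yt = oob, ya[min_idx]
        aurocs.append(float(roc_auc_score(yt, pr)))
        forests.append(rf)
        run_min.append(min_idx)
        run_rest.append(rest)
        rf._spliceforge_n_train = train.size
    return MetaClassifier(cfg, names, forests, run_min, run_rest, aurocs, Xa, ya)


def _ensemble_prob(model: MetaClassifier, X: np.ndarray) -> float:
    """Mean diff-class probability over samples, trees and runs."""
    probs = []
    for rf in model.forests:
        diff_col = int(np.flatnonzero(rf.classes_ == 1)[0])
        probs.append(rf.predict_proba(X)[:, diff_col].mean())
    return float(np.mean(probs))


def partial_dependence(
    model: MetaClassifier, feature: str, grid_points: int = 10
) -> PartialDependenceProfile:
    """Partial dependence at deduplicated deciles of the observed feature."""
    fi = model.feature_names.index(feature)
    values = model.X[:, fi]
    qs = np.linspace(0, 1, grid_points + 1)[1:-1] if grid_points > 1 else [0.5]
    grid = np.unique(np.quantile(values, np.concatenate([[0.0], qs, [1.0]])))
    probs = np.zeros(grid.size)
    disp = np.zeros(grid.size)
    for gi, v in enumerate(grid):
        Xv = model.X.copy()
        Xv[:, fi] = v
        per_run = []
        for rf in model.forests:
            diff_col = int(np.flatnonzero(rf.classes_ == 1)[0])
            per_run.append(rf.predict_proba(Xv)[:, diff_col].mean())
        probs[gi] = float(np.mean(per_run))
        disp[gi] = float(np.std(per_run))
    return PartialDependenceProfile(feature, grid, probs, disp)


def _minority_oob_masks(rf: RandomForestClassifier, n_min: int) -> np.ndarray:
    """Boolean (n_trees, n_min) matrix: tree t did not sample minority row
    i (rows 0..n_min-1 of the training matrix are the minority class)."""
    from sklearn.ensemble._forest import (
        _generate_unsampled_indices,
        _get_n_samples_bootstrap,
    )

    n_train = rf._spliceforge_n_train
    n_boot = _get_n_samples_bootstrap(n_train, rf.max_samples, None)
    masks = np.zeros((len(rf.estimators_), n_min), dtype=bool)
    for t, tree in enumerate(rf.estimators_):
        oob = _generate_unsampled_indices(
            tree.random_state, n_train, n_boot, None
        )
        masks[t, oob[oob < n_min]] = True
    return masks


def _heldout_probs(
    rf: RandomForestClassifier,
    Xm: np.ndarray,
    Xr: np.ndarray,
    masks: np.ndarray,
) -> np.ndarray:
    """Diff-class probabilities: OOB-averaged for minority rows, full
    forest for the untouched majority remainder."""
    diff_col = int(np.flatnonzero(rf.classes_ == 1)[0])
    tree_p = np.stack(
        [t.predict_proba(Xm)[:, diff_col] for t in rf.estimators_]
    )
    denom = masks.sum(axis=0)
    prob_m = np.where(
        denom > 0, (tree_p * masks).sum(axis=0) / np.maximum(denom, 1), 0.5
    )
    if Xr.shape[0]:
        prob_r = rf.predict_proba(Xr)[:, diff_col]
        return np.concatenate([prob_m, prob_r])
    return prob_m


def rank_features(model: MetaClassifier) -> pd.DataFrame:
    """Permutation importance: per-run held-out AUROC drop, averaged.

    Held-out predictions use out-of-bag trees for the minority rows (which
    are in every training set) and the whole forest for the untouched
    majority remainder, so memorized in-bag fits do not bias the drops.
    Returns a DataFrame indexed by feature with mean importance and rank
    (1 = most important).
    """
    p = len(model.feature_names)
    drops = np.zeros((len(model.forests), p))
    for ri, (rf, min_idx, rest) in enumerate(
        zip(model.forests, model.run_minority, model.run_rest)
    ):
        Xm, Xr = model.X[min_idx], model.X[rest]
        yh = np.concatenate([model.y[min_idx], model.y[rest]])
        masks = _minority_oob_masks(rf, min_idx.size)
        base = roc_auc_score(yh, _heldout_probs(rf, Xm, Xr, masks))
        rng = np.random.default_rng(model.config.run_seed(ri) + 10_007)
        n_m = Xm.shape[0]
        for fi in range(p):
            col = np.concatenate([Xm[:, fi], Xr[:, fi]])
            perm = rng.permutation(col)
            Xmp, Xrp = Xm.copy(), Xr.copy()
            Xmp[:, fi] = perm[:n_m]
            Xrp[:, fi] = perm[n_m:]
            auc = roc_auc_score(yh, _heldout_probs(rf, Xmp, Xrp, masks))
            drops[ri, fi] = base - auc
    mean_drop = drops.mean(axis=0)
    order = np.argsort(-mean_drop)
    ranks = np.empty(p, dtype=int)
    ranks[order] = np.arange(1, p + 1)
    return pd.DataFrame(
        {"importance": mean_drop, "rank": ranks}, index=model.feature_names
    ).sort_values("rank")
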