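"""Ensemble feature selection: ANOVA F, random-forest importance, RFE.

Each method produces an integer rank per feature (1 = most important, a
permutation of 1..p); the ensemble rank is the arithmetic mean of the
three, and the top N features by ensemble rank are selected. Ranking is
performed on the full sample by design — importance estimation, not
generalization, is the goal of this stage; a leakage-safe variant that
refits selection inside each training fold is available in the
cross-validation driver.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.feature_selection import f_classif
from sklearn.svm import SVC

from .io import LABEL_COLUMN

logger = logging.getLogger(__name__)

POSITIVE_LABEL = "IPD"


@dataclasses.dataclass
class RankTable:
    """Per-method and ensemble feature ranks."""

    feature_names: List[str]
    anova: np.ndarray  # rank per feature, permutation of 1..p
    random_forest: np.ndarray
    rfe: np.ndarray
    ensemble: np.ndarray  # float average of the three
    order: List[str]  # feature names sorted by ensemble rank
    rfe_curve: List[Tuple[int, float]]  # (n_features, training accuracy)

    def to_dict(self) -> dict:
        return {
            "features": self.feature_names,
            "anova_rank": self.anova.tolist(),
            "random_forest_rank": self.random_forest.tolist(),
            "rfe_rank": self.rfe.tolist(),
            "ensemble_rank": self.ensemble.tolist(),
            "order": self.order,
            "rfe_curve": [[int(n), float(a)] for n, a in self.rfe_curve],
        }


def _split_xy(table: pd.DataFrame, feature_names: Optional[List[str]] = None):
    from .features import FEATURE_NAMES

    names = feature_names or [c for c in FEATURE_NAMES if c in table.columns]
    X = table[names].to_numpy(dtype=np.float64)
    y = (table[LABEL_COLUMN].to_numpy() == POSITIVE_LABEL).astype(int)
    return X, y, names


def _scores_to_ranks(scores: np.ndarray) -> np.ndarray:
    """Descending-score ranks 1..p, ties broken by canonical column order."""
    order = np.argsort(-scores, kind="stable")
    ranks = np.empty(len(scores), dtype=int)
    ranks[order] = np.arange(1, len(scores) + 1)
    return ranks


def anova_rank(table: pd.DataFrame,
               feature_names: Optional[List[str]] = None) -> np.ndarray:
    """Rank features by the one-way (two-group) ANOVA F statistic.

    For two groups F equals the square of the unpaired equal-variance t
    statistic. A feature with zero between- and within-group variability
    gets F = 0 and the worst rank.
    """
    X, y, _ = _split_xy(table, feature_names)
    with np.errstate(divide="ignore", invalid="ignore"):
        f_vals, _ = f_classif(X, y)
    f_vals = np.nan_to_num(f_vals, nan=0.0, posinf=np.finfo(float).max)
    return _scores_to_ranks(f_vals)


def rf_rank(table: pd.DataFrame, n_trees: int = 10, seed: int = 0,
            feature_names: Optional[List[str]] = None) -> np.ndarray:
    """Rank features by mean impurity-decrease importance of a small forest.

    Ten trees, unlimited depth, sqrt(p) candidate features per split; fully
    determined by ``seed``. All-constant features yield zero importances and
    fall back to canonical order.
    """
    X, y, _ = _split_xy(table, feature_names)
    forest = RandomForestClassifier(
        n_estimators=n_trees, random_state=seed, max_features="sqrt"
    )
    forest.fit(X, y)
    return _scores_to_ranks(forest.feature_importances_)


def _standardize_columns(X: np.ndarray) -> np.ndarray:
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd_safe = np.where(sd > 0, sd, 1.0)
    return (X - mu) / sd_safe


def rfe_rank(table: pd.DataFrame, C: float = 1.0,
             feature_names: Optional[List[str]] = None
             ) -> Tuple[np.ndarray, List[Tuple[int, float]]]:
    """Recursive feature elimination with a linear SVM estimator.

    One feature is pruned per round (smallest squared weight; ties drop the
    later canonical column). The rank is the reverse elimination order —
    the survivor of the last round has rank 1. The returned curve records
    the estimator's training accuracy at every retained-set size, p points
    in total.
    """
    X, y, names = _split_xy(table, feature_names)
    X = _standardize_columns(X)
    p = X.shape[1]
    remaining = list(range(p))
    ranks = np.zeros(p, dtype=int)
    curve: List[Tuple[int, float]] = []
    next_rank = p
    while remaining:
        est = SVC(kernel="linear", C=C)
        est.fit(X[:, remaining], y)
        acc = float(est.score(X[:, remaining], y))
        curve.append((len(remaining), acc))
        if len(remaining) == 1:
            ranks[remaining[0]] = 1
            break
        w2 = np.asarray(est.coef_).ravel() ** 2
        # ties: prefer dropping the later canonical column
        drop_local = max(
            range(len(remaining)),
            key=lambda k: (-w2[k], remaining[k]),
        )
        ranks[remaining[drop_local]] = next_rank
        next_rank -= 1
        remaining.pop(drop_local)
    curve.sort(key=lambda t: t[0])
    return ranks, curve


def ensemble_select(
    table: pd.DataFrame,
    n_select: int = 40,
    seed: int = 0,
    n_trees: int = 10,
    feature_names: Optional[List[str]] = None,
) -> Tuple[RankTable, pd.DataFrame]:
    """Average the three method ranks and keep the top ``n_select`` features.

    Ties in the average rank are broken by the best single-method rank,
    then by canonical column order. Returns the rank table and the reduced
    feature table (metadata columns plus the selected features, in
    ensemble order).
    """
    _, _, names = _split_xy(table, feature_names)
    if n_select > len(names):
        raise ValueError("n_select exceeds the number of features")
    a = anova_rank(table, names)
    f = rf_rank(table, n_trees=n_trees, seed=seed, feature_names=names)
    r, curve = rfe_rank(table, feature_names=names)
    ensemble = (a + f + r) / 3.0
    best = np.minimum(np.minimum(a, f), r)
    order_idx = sorted(
        range(len(names)), key=lambda k: (ensemble[k], best[k], k)
    )
    order = [names[k] for k in order_idx]
    rank_table = RankTable(
        feature_names=names, anova=a, random_forest=f, rfe=r,
        ensemble=ensemble, order=order, rfe_curve=curve,
    )
    meta_cols = [c for c in table.columns if c not in names]
    reduced = table[meta_cols + order[:n_select]].copy()
    return rank_table, reduced
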