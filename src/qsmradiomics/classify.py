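"""RBF-SVM classification under repeated stratified k-fold cross-validation.

Per training fold the pipeline is: standardize to zero mean / unit
variance, rotate into the PCA basis (all components kept), then fit an
RBF-kernel SVM (default C = 30, gamma = 0.001). Metrics are computed on
the held-out fold with the patient class (IPD) positive: rank-based AUC
from the continuous margin, plus accuracy, sensitivity and specificity at
the SVM's decision threshold 0. The default protocol is 3 folds x 10
repetitions, i.e. 30 fold-level records pooled as mean +/- SD.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.decomposition import PCA
from sklearn.model_selection import KFold, StratifiedKFold
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .config import StudyConfig
from .io import LABEL_COLUMN
from .selection import POSITIVE_LABEL, _split_xy, ensemble_select

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class FoldRecord:
    repetition: int
    fold: int
    n_train: int
    n_test: int
    auc: Optional[float]
    accuracy: float
    sensitivity: float
    specificity: float
    roc_fpr: List[float]
    roc_tpr: List[float]


@dataclasses.dataclass
class CvReport:
    """All fold-level records plus pooled summaries."""

    records: List[FoldRecord]
    seed: int
    config: StudyConfig

    def pooled(self) -> Dict[str, Tuple[float, float]]:
        """Mean +/- sample SD of each metric over all fold records."""
        out = {}
        for metric in ("auc", "accuracy", "sensitivity", "specificity"):
            vals = [getattr(r, metric) for r in self.records
                    if getattr(r, metric) is not None]
            arr = np.asarray(vals, dtype=float)
            out[metric] = (float(arr.mean()), float(arr.std(ddof=1)))
        return out

    def per_repetition(self) -> pd.DataFrame:
        rows = [dataclasses.asdict(r) for r in self.records]
        df = pd.DataFrame(rows).drop(columns=["roc_fpr", "roc_tpr"])
        return df.groupby("repetition")[
            ["auc", "accuracy", "sensitivity", "specificity"]
        ].mean()

    def to_dict(self) -> dict:
        pooled = {k: {"mean": m, "sd": s} for k, (m, s) in self.pooled().items()}
        return {
            "seed": self.seed,
            "folds": self.config.cv_folds,
            "repetitions": self.config.cv_repetitions,
            "pooled": pooled,
            "records": [dataclasses.asdict(r) for r in self.records],
        }


def standardize(train: np.ndarray, test: np.ndarray):
    """Zero-mean / unit-variance scaling fitted on the training block only.

    Uses the population SD; constant training columns map to 0 everywhere.
    """
    scaler = StandardScaler()
    train_s = scaler.fit_transform(train)
    if np.any(scaler.scale_ == 1.0):
        const = np.flatnonzero(np.asarray(scaler.var_) == 0.0)
        if const.size:
            logger.debug("constant training columns mapped to 0: %s", const)
    test_s = scaler.transform(test)
    return train_s, test_s, scaler


def pca_transform(train: np.ndarray, test: np.ndarray):
    """PCA rotation fitted on the training block; all components retained."""
    pca = PCA(n_components=None, svd_solver="full")
    train_t = pca.fit_transform(train)
    test_t = pca.transform(test)
    if pca.n_components_ < train.shape[1]:
        logger.debug(
            "rank-deficient training block: %d of %d components",
            pca.n_components_, train.shape[1],
        )
    return train_t, test_t, pca


def train_svm(train: np.ndarray, y_train: np.ndarray,
              C: float = 30.0, gamma: float = 0.001) -> SVC:
    """Fit the RBF-kernel SVM; requires both classes in the training set."""
    if len(np.unique(y_train)) < 2:
        raise ValueError("training set contains a single class")
    model = SVC(kernel="rbf", C=C, gamma=gamma)
    model.fit(train, y_train)
    return model


def rank_auc(scores: np.ndarray, truth: np.ndarray) -> float:
    """Mann-Whitney AUC with half credit for tied scores."""
    truth = np.asarray(truth)
    scores = np.asarray(scores, dtype=float)
    n_pos = int((truth == 1).sum())
    n_neg = int((truth == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC undefined: one class absent from truth")
    ranks = rankdata(scores)  # average ranks handle ties
    u = ranks[truth == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def roc_points(scores: np.ndarray, truth: np.ndarray):
    """ROC polyline (FPR, TPR) over the distinct score thresholds."""
    order = np.argsort(-scores, kind="stable")
    t = np.asarray(truth)[order]
    s = np.asarray(scores, dtype=float)[order]
    n_pos = max(int((t == 1).sum()), 1)
    n_neg = max(int((t == 0).sum()), 1)
    tp = np.cumsum(t == 1)
    fp = np.cumsum(t == 0)
    keep = np.r_[np.diff(s) != 0, True]  # last point of each tie block
    fpr = np.r_[0.0, fp[keep] / n_neg]
    tpr = np.r_[0.0, tp[keep] / n_pos]
    return fpr, tpr


def compute_metrics(scores: np.ndarray, preds: np.ndarray,
                    truth: np.ndarray) -> Dict[str, object]:
    """AUC / accuracy / sensitivity / specificity with IPD (1) positive."""
    truth = np.asarray(truth)
    preds = np.asarray(preds)
    pos = truth == 1
    neg = truth == 0
    auc = rank_auc(scores, truth) if pos.any() and neg.any() else None
    sens = float((preds[pos] == 1).mean()) if pos.any() else float("nan")
    spec = float((preds[neg] == 0).mean()) if neg.any() else float("nan")
    fpr, tpr = roc_points(scores, truth)
    return {
        "auc": auc,
        "accuracy": float((preds == truth).mean()),
        "sensitivity": sens,
        "specificity": spec,
        "roc": (fpr, tpr),
    }


def cross_validate(
    table: pd.DataFrame,
    config: Optional[StudyConfig] = None,
    feature_names: Optional[List[str]] = None,
) -> CvReport:
    """Repeated k-fold evaluation of the standardize->PCA->SVM pipeline.

    Fold shuffling is re-seeded per repetition from the config seed. With
    ``config.leakage_safe_selection`` the ensemble selector is refit on
    each training fold; otherwise the table is expected to already hold the
    selected features. ``config.paper_mode`` fits the scaler and PCA once
    on the full sample before splitting, mirroring a selection-outside-CV
    protocol.
    """
    config = config or StudyConfig()
    X, y, names = _split_xy(table, feature_names)
    if len(np.unique(y)) < 2:
        raise ValueError("cohort must contain both classes")

    global_scaler_pca = None
    if config.paper_mode:
        Xs = StandardScaler().fit_transform(X)
        pca = PCA(n_components=None, svd_solver="full").fit(Xs)
        global_scaler_pca = (StandardScaler().fit(X), pca)

    records: List[FoldRecord] = []
    for rep in range(config.cv_repetitions):
        rep_seed = config.seed * 1000 + rep
        if config.stratified:
            splitter = StratifiedKFold(
                n_splits=config.cv_folds, shuffle=True, random_state=rep_seed
            )
        else:
            splitter = KFold(
                n_splits=config.cv_folds, shuffle=True, random_state=rep_seed
            )
        for fold, (tr, te) in enumerate(splitter.split(X, y)):
            if config.leakage_safe_selection:
                _, reduced = ensemble_select(
                    table.iloc[tr], n_select=config.n_select, seed=rep_seed
                )
                sel = [c for c in reduced.columns if c in names]
                cols = [names.index(c) for c in sel]
            else:
                cols = list(range(X.shape[1]))
            Xtr, Xte = X[np.ix_(tr, cols)], X[np.ix_(te, cols)]
            if global_scaler_pca is not None and not config.leakage_safe_selection:
                scaler, pca = global_scaler_pca
                Xtr_t = pca.transform(scaler.transform(Xtr))
                Xte_t = pca.transform(scaler.transform(Xte))
            else:
                Xtr_s, Xte_s, _ = standardize(Xtr, Xte)
                Xtr_t, Xte_t, _ = pca_transform(Xtr_s, Xte_s)
            model = train_svm(Xtr_t, y[tr], C=config.svm_c, gamma=config.svm_gamma)
            scores = model.decision_function(Xte_t)
            preds = model.predict(Xte_t)
            truth = y[te]
            try:
                metrics = compute_metrics(scores, preds, truth)
            except ValueError:
                logger.warning(
                    "repetition %d fold %d: single-class test fold, AUC missing",
                    rep, fold,
                )
                metrics = {
                    "auc": None,
                    "accuracy": float((preds == truth).mean()),
                    "sensitivity": float("nan"),
                    "specificity": float("nan"),
                    "roc": (np.array([0.0, 1.0]), np.array([0.0, 1.0])),
                }
            fpr, tpr = metrics["roc"]
            records.append(
                FoldRecord(
                    repetition=rep, fold=fold,
                    n_train=len(tr), n_test=len(te),
                    auc=metrics["auc"],
                    accuracy=metrics["accuracy"],
                    sensitivity=metrics["sensitivity"],
                    specificity=metrics["specificity"],
                    roc_fpr=np.asarray(fpr).tolist(),
                    roc_tpr=np.asarray(tpr).tolist(),
                )
            )
    return CvReport(records=records, seed=config.seed, config=config)
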