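"""Group-level statistics on the selected radiomic features.

Covers the four analyses reported alongside the classifier: unpaired
two-tailed t-tests with Bonferroni correction across the selected feature
family, per-feature ROC AUC (rank-based, reported on the >= 0.5 side with
a direction flag), Pearson correlation of features with a motor score, and
plain contingency arithmetic on radiologist swallow-tail-sign readings.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io import LABEL_COLUMN, MOTOR_COLUMN
from .selection import POSITIVE_LABEL

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class FeatureStat:
    """Per-feature group comparison row."""

    name: str
    mean_ipd: float
    sd_ipd: float
    mean_hc: float
    sd_hc: float
    t_statistic: float
    p_value: float
    significant: bool  # p < alpha / family_n
    auc: float  # reported on the >= 0.5 side
    auc_direction: str  # "IPD>HC" or "HC>IPD"


@dataclasses.dataclass
class ContingencyTable:
    """Sign-present counts per class from a visual reading."""

    hc_present: int
    hc_total: int
    ipd_present: int
    ipd_total: int

    def __post_init__(self) -> None:
        for v in dataclasses.astuple(self):
            if v < 0 or int(v) != v:
                raise ValueError("counts must be nonnegative integers")
        if self.hc_present > self.hc_total or self.ipd_present > self.ipd_total:
            raise ValueError("present counts cannot exceed class totals")


def feature_auc(values: Sequence[float], labels: Sequence[str],
                orient: bool = True) -> Tuple[float, str]:
    """Rank-based AUC of one feature for IPD vs HC.

    With ``orient`` the value is reported as max(AUC, 1 - AUC) — the
    convention of the group-comparison table, which prints all AUCs on the
    >= 0.5 side regardless of effect direction — together with a flag for
    which class has the higher values.
    """
    from .classify import rank_auc

    labels = np.asarray(labels)
    truth = (labels == POSITIVE_LABEL).astype(int)
    auc = rank_auc(np.asarray(values, dtype=float), truth)
    direction = "IPD>HC" if auc >= 0.5 else "HC>IPD"
    if orient:
        auc = max(auc, 1.0 - auc)
    return float(auc), direction


def feature_ttests(
    table: pd.DataFrame,
    feature_names: Sequence[str],
    family_n: int = 40,
    alpha: float = 0.05,
    welch: bool = False,
) -> List[FeatureStat]:
    """Unpaired two-tailed t-test per feature with Bonferroni threshold.

    The classical equal-variance test is the default; Welch's correction is
    available by flag. Significance means p < alpha / family_n. Zero pooled
    variance degenerates to p = 1 for equal means and p = 0 otherwise.
    """
    labels = table[LABEL_COLUMN].to_numpy()
    ipd = labels == POSITIVE_LABEL
    hc = ~ipd
    if ipd.sum() < 2 or hc.sum() < 2:
        raise ValueError("need >= 2 subjects per class")
    threshold = alpha / family_n
    out: List[FeatureStat] = []
    for name in feature_names:
        a = table.loc[ipd, name].to_numpy(dtype=float)
        b = table.loc[hc, name].to_numpy(dtype=float)
        if a.var(ddof=1) == 0.0 and b.var(ddof=1) == 0.0:
            equal = a.mean() == b.mean()
            t_stat, p = 0.0 if equal else np.inf, 1.0 if equal else 0.0
            logger.debug("zero-variance feature %s: p set to %g", name, p)
        else:
            t_stat, p = sps.ttest_ind(a, b, equal_var=not welch)
        auc, direction = feature_auc(table[name], labels)
        out.append(
            FeatureStat(
                name=name,
                mean_ipd=float(a.mean()), sd_ipd=float(a.std(ddof=1)),
                mean_hc=float(b.mean()), sd_hc=float(b.std(ddof=1)),
                t_statistic=float(t_stat), p_value=float(p),
                significant=bool(p < threshold),
                auc=auc, auc_direction=direction,
            )
        )
    return out


def bonferroni_threshold(family_n: int, alpha: float = 0.05) -> float:
    """Adjusted per-comparison significance level alpha / n."""
    if family_n < 1:
        raise ValueError("family size must be >= 1")
    return alpha / family_n


def motor_correlation(values: Sequence[float],
                      scores: Sequence[float]) -> Tuple[float, float]:
    """Two-tailed Pearson correlation of a feature with the motor score."""
    x = np.asarray(values, dtype=float)
    y = np.asarray(scores, dtype=float)
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if len(x) < 3:
        raise ValueError("need >= 3 paired observations")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("correlation undefined for a constant vector")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)


def contingency_metrics(table: ContingencyTable) -> Dict[str, float]:
    """Accuracy / sensitivity / specificity of a sign-based HC-vs-IPD call.

    The presence of the sign calls the subject HC, so sensitivity is the
    fraction of HC correctly showing the sign and specificity the fraction
    of IPD lacking it. Fractions in [0, 1].
    """
    if table.hc_total == 0 or table.ipd_total == 0:
        raise ValueError("both class totals must be positive")
    sens = table.hc_present / table.hc_total
    spec = (table.ipd_total - table.ipd_present) / table.ipd_total
    correct = table.hc_present + (table.ipd_total - table.ipd_present)
    acc = correct / (table.hc_total + table.ipd_total)
    return {
        "accuracy": float(acc),
        "sensitivity": float(sens),
        "specificity": float(spec),
        "ipd_sign_present_rate": float(table.ipd_present / table.ipd_total),
        "hc_sign_present_rate": float(table.hc_present / table.hc_total),
    }


def group_report(
    table: pd.DataFrame,
    feature_names: Sequence[str],
    family_n: int = 40,
    welch: bool = False,
    sts_counts: Optional[ContingencyTable] = None,
) -> dict:
    """Full group-statistics report as a JSON-serializable dict."""
    stats_rows = feature_ttests(table, feature_names, family_n=family_n,
                                welch=welch)
    report: dict = {
        "bonferroni_threshold": bonferroni_threshold(family_n),
        "n_significant": sum(s.significant for s in stats_rows),
        "features": [dataclasses.asdict(s) for s in stats_rows],
    }
    if MOTOR_COLUMN in table.columns:
        ipd = table[table[LABEL_COLUMN] == POSITIVE_LABEL]
        corr = {}
        for name in feature_names:
            try:
                r, p = motor_correlation(ipd[name], ipd[MOTOR_COLUMN])
                corr[name] = {"r": r, "p": p}
            except ValueError:
                corr[name] = {"r": None, "p": None}
        report["motor_correlation"] = corr
    if sts_counts is not None:
        report["sts_reading"] = contingency_metrics(sts_counts)
    return report
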