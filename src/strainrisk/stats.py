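"""Cohort-level statistics: group comparisons, ROC/AUC and the Youden cut-off.

The rupture-risk score is the normalized area (NA) of each aneurysm's
critical curve.  Diagnostic performance is summarised the standard way:
an ROC curve of NA against the rupture label, the trapezoid AUC (equal to
the Mann-Whitney pair probability with ties counted 1/2), and the operating
point maximising Youden's J = sensitivity + specificity - 1, with the
prediction rule "ruptured if NA >= cutoff".
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .cohort import AneurysmRecord, lognormal_params

__all__ = [
    "RocResult",
    "YoudenResult",
    "analytic_baseline_auc",
    "condition_summary",
    "confusion_metrics",
    "roc_and_auc",
    "student_t_test",
    "youden_cutoff",
]


def student_t_test(group_a, group_b, equal_var: bool = True
                   ) -> tuple[float, float]:
    """Two-sided two-sample t-test; returns (t statistic, p value).

    Equal-variance (pooled) Student's t by default, with
    df = n_a + n_b - 2; ``equal_var=False`` gives Welch's variant.
    Degenerate zero-variance groups are resolved explicitly: equal means
    give p = 1, unequal means give p = 0 (infinite separation).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 observations")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("non-finite strain values")
    if np.ptp(a) == 0.0 and np.ptp(b) == 0.0:
        if a[0] == b[0]:
            return 0.0, 1.0
        return (np.inf if a[0] > b[0] else -np.inf), 0.0
    res = sps.ttest_ind(a, b, equal_var=equal_var)
    return float(res.statistic), float(res.pvalue)


@dataclass(frozen=True)
class RocResult:
    """ROC curve of a score against binary labels.

    ``thresholds`` are descending, starting at +inf (nothing predicted
    positive); ``points`` are the matching (1 - specificity, sensitivity)
    pairs from (0, 0) to (1, 1); ``tp/fp/tn/fn`` the confusion counts per
    threshold under the rule "positive if score >= threshold".
    """

    thresholds: np.ndarray
    points: np.ndarray
    auc: float
    tp: np.ndarray
    fp: np.ndarray
    tn: np.ndarray
    fn: np.ndarray

    @property
    def fpr(self) -> np.ndarray:
        return self.points[:, 0]

    @property
    def tpr(self) -> np.ndarray:
        return self.points[:, 1]


def roc_and_auc(scores, labels) -> RocResult:
    """ROC points and trapezoid AUC of scores (e.g. NA values) vs labels.

    Thresholds are all unique score values plus a +inf sentinel; tied
    scores move together.  The trapezoid AUC equals the Mann-Whitney
    statistic P(score_pos > score_neg) + P(tie)/2.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be equal-length 1-D")
    n_pos = int(labels.sum())
    n_neg = int(labels.size - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("need at least one ruptured and one unruptured case")
    order = np.argsort(-scores, kind="stable")
    s, y = scores[order], labels[order]
    # group tied scores: last index of each distinct value
    distinct = np.nonzero(np.r_[s[1:] != s[:-1], True])[0]
    tp = np.r_[0, np.cumsum(y)[distinct]]
    fp = np.r_[0, np.cumsum(~y)[distinct]]
    thresholds = np.r_[np.inf, s[distinct]]
    points = np.column_stack([fp / n_neg, tp / n_pos])
    auc = float(np.trapezoid(points[:, 1], points[:, 0]))
    return RocResult(thresholds=thresholds, points=points, auc=auc,
                     tp=tp, fp=fp, tn=n_neg - fp, fn=n_pos - tp)


@dataclass(frozen=True)
class YoudenResult:
    """Optimal cut-off by Youden's index and its operating point."""

    cutoff: float
    youden_j: float
    sensitivity: float  # percent
    specificity: float  # percent
    tp: int
    fp: int
    tn: int
    fn: int


def youden_cutoff(roc: RocResult) -> YoudenResult:
    """Cut-off maximising J = sensitivity + specificity - 1.

    Ties on J are broken toward the larger threshold, i.e. the more
    specific operating point.  The returned cutoff is an observed score
    value (or +inf in the degenerate case where no threshold beats J = 0).
    """
    j = roc.tpr - roc.fpr
    k = int(np.argmax(j))  # thresholds descend, so first max = largest cutoff
    tp, fp = int(roc.tp[k]), int(roc.fp[k])
    tn, fn = int(roc.tn[k]), int(roc.fn[k])
    metrics = confusion_metrics(tp=tp, fn=fn, tn=tn, fp=fp)
    return YoudenResult(cutoff=float(roc.thresholds[k]),
                        youden_j=float(j[k]),
                        sensitivity=metrics["sensitivity"],
                        specificity=metrics["specificity"],
                        tp=tp, fp=fp, tn=tn, fn=fn)


def confusion_metrics(tp: int, fn: int, tn: int, fp: int) -> dict[str, float]:
    """Sensitivity/specificity (percent) and Youden's J from a confusion table."""
    if min(tp, fn, tn, fp) < 0:
        raise ValueError("confusion counts must be non-negative")
    if tp + fn == 0 or tn + fp == 0:
        raise ValueError("both classes must be represented")
    sens = 100.0 * tp / (tp + fn)
    spec = 100.0 * tn / (tn + fp)
    return {"sensitivity": sens, "specificity": spec,
            "youden_j": sens / 100.0 + spec / 100.0 - 1.0}


def condition_summary(records: list[AneurysmRecord],
                      equal_var: bool = True) -> pd.DataFrame:
    """Per-condition group comparison of the sweep strains.

    One row per (thickness fraction, modulus fraction): group mean and
    sample SD (n-1 denominator) of the highest TWA equivalent strain for
    unruptured and ruptured aneurysms, and the two-sided t-test p value.
    Raw p values are reported; no multiplicity correction across the 16
    conditions.
    """
    unrupt = [r for r in records if not r.ruptured]
    rupt = [r for r in records if r.ruptured]
    if len(unrupt) < 2 or len(rupt) < 2:
        raise ValueError("each group needs at least 2 aneurysms")
    cond = records[0].strain_grid.conditions
    rows = []
    for tau, eta in cond.conditions():
        a = np.array([r.strain_grid[tau, eta] for r in unrupt])
        b = np.array([r.strain_grid[tau, eta] for r in rupt])
        t, p = student_t_test(a, b, equal_var=equal_var)
        rows.append({
            "thickness_fraction": tau,
            "modulus_fraction": eta,
            "mean_unruptured": a.mean(),
            "sd_unruptured": a.std(ddof=1),
            "mean_ruptured": b.mean(),
            "sd_ruptured": b.std(ddof=1),
            "t_statistic": t,
            "p_value": p,
        })
    return pd.DataFrame(rows)


def analytic_baseline_auc(mean_neg: float, sd_neg: float,
                          mean_pos: float, sd_pos: float) -> float:
    """Closed-form AUC of two moment-matched lognormal score distributions.

    For X ~ LogNormal(mu_n, s_n), Y ~ LogNormal(mu_p, s_p),
    P(Y > X) = Phi((mu_p - mu_n) / sqrt(s_n^2 + s_p^2)).  Used as the
    convergence target for simulated baseline-strain AUCs.
    """
    mu_n, s_n = lognormal_params(mean_neg, sd_neg)
    mu_p, s_p = lognormal_params(mean_pos, sd_pos)
    return float(sps.norm.cdf((mu_p - mu_n) / np.hypot(s_n, s_p)))
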