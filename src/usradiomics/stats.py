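"""Evaluation statistics for classifier and reader performance.

Confusion-matrix metrics with exact (Clopper-Pearson) 95% binomial
confidence intervals, the no-information-rate (NIR) exact binomial test,
McNemar's paired test, ROC/AUC with a DeLong confidence interval, the Brier
score and a binned calibration curve.  Malignant is the positive class
throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.calibration import calibration_curve as _sk_calibration_curve
from sklearn.metrics import brier_score_loss, roc_curve


@dataclass(frozen=True)
class ConfusionTable:
    """TP/FN/TN/FP counts; malignant = positive."""

    tp: int
    fn: int
    tn: int
    fp: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.tn, self.fp) < 0:
            raise ValueError("counts must be non-negative")
        if self.total < 1:
            raise ValueError("confusion table is empty")

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.tn + self.fp

    @property
    def correct(self) -> int:
        return self.tp + self.tn

    @classmethod
    def from_calls(cls, truth, calls) -> "ConfusionTable":
        """Build from boolean arrays (True = malignant)."""
        truth = np.asarray(truth, bool)
        calls = np.asarray(calls, bool)
        if truth.shape != calls.shape:
            raise ValueError("truth and calls must align")
        return cls(
            tp=int((calls & truth).sum()),
            fn=int((~calls & truth).sum()),
            tn=int((~calls & ~truth).sum()),
            fp=int((calls & ~truth).sum()),
        )


@dataclass
class Proportion:
    """A ratio metric as a percentage with its 95% CI (None if undefined)."""

    percent: float | None
    ci_low: float | None
    ci_high: float | None


def _binomial_proportion(k: int, n: int, method: str = "exact") -> Proportion:
    if n == 0:
        return Proportion(None, None, None)
    ci_method = {"exact": "exact", "wilson": "wilson"}[method]
    ci = sps.binomtest(k, n).proportion_ci(confidence_level=0.95, method=ci_method)
    return Proportion(100.0 * k / n, 100.0 * ci.low, 100.0 * ci.high)


@dataclass
class MetricsReport:
    """Point estimates (percent) with 95% CIs for the five ratio metrics."""

    accuracy: Proportion
    sensitivity: Proportion
    specificity: Proportion
    ppv: Proportion
    npv: Proportion
    confusion: ConfusionTable

    def to_dict(self) -> dict:
        out: dict = {}
        for name in ("accuracy", "sensitivity", "specificity", "ppv", "npv"):
            p: Proportion = getattr(self, name)
            out[name] = {"percent": p.percent, "ci95": [p.ci_low, p.ci_high]}
        out["counts"] = {
            "TP": self.confusion.tp,
            "FN": self.confusion.fn,
            "TN": self.confusion.tn,
            "FP": self.confusion.fp,
        }
        return out


def confusion_metrics(ct: ConfusionTable, ci_method: str = "exact") -> MetricsReport:
    """Accuracy, sensitivity, specificity, PPV, NPV as percentages with
    exact binomial 95% CIs (Wilson intervals via ``ci_method='wilson'``).
    Metrics with a zero denominator are reported as undefined (None)."""
    return MetricsReport(
        accuracy=_binomial_proportion(ct.correct, ct.total, ci_method),
        sensitivity=_binomial_proportion(ct.tp, ct.tp + ct.fn, ci_method),
        specificity=_binomial_proportion(ct.tn, ct.tn + ct.fp, ci_method),
        ppv=_binomial_proportion(ct.tp, ct.tp + ct.fp, ci_method),
        npv=_binomial_proportion(ct.tn, ct.tn + ct.fn, ci_method),
        confusion=ct,
    )


def nir_test(ct: ConfusionTable) -> tuple[float, float]:
    """No-information rate and the one-sided exact binomial p-value.

    NIR = max(class prevalence); p = P[X >= observed correct] with
    X ~ Binomial(total, NIR) — the probability that always guessing the
    majority class (or luck at that rate) does at least as well.
    """
    n_pos = ct.tp + ct.fn
    n_neg = ct.tn + ct.fp
    nir = max(n_pos, n_neg) / ct.total
    p = float(sps.binom.sf(ct.correct - 1, ct.total, nir))
    return nir, p


@dataclass
class McNemarResult:
    p_value: float
    b: int  #: A correct, B wrong
    c: int  #: A wrong, B correct
    method: str
    no_discordance: bool = False


def mcnemar_test(b: int, c: int, exact_threshold: int = 25) -> McNemarResult:
    """McNemar's paired test from the discordant counts.

    Exact two-sided binomial test of b against Binomial(b+c, 1/2) when
    b + c < ``exact_threshold``; otherwise the chi-square statistic with
    continuity correction.  b + c = 0 returns p = 1 with a flag.
    """
    if b < 0 or c < 0:
        raise ValueError("discordant counts must be non-negative")
    n = b + c
    if n == 0:
        return McNemarResult(1.0, b, c, method="degenerate", no_discordance=True)
    if n < exact_threshold:
        p = float(sps.binomtest(b, n, 0.5).pvalue)
        return McNemarResult(p, b, c, method="exact-binomial")
    chi2 = (abs(b - c) - 1) ** 2 / n
    return McNemarResult(float(sps.chi2.sf(chi2, df=1)), b, c, method="chi2-cc")


def mcnemar_from_readings(truth, calls_a, calls_b) -> McNemarResult:
    """McNemar's test between two readings of the same lesions.

    b counts lesions A got right and B got wrong; c the reverse.
    """
    truth = np.asarray(truth, bool)
    a_ok = np.asarray(calls_a, bool) == truth
    b_ok = np.asarray(calls_b, bool) == truth
    if truth.shape != a_ok.shape or truth.shape != b_ok.shape:
        raise ValueError("readings must align with truth")
    return mcnemar_test(int((a_ok & ~b_ok).sum()), int((~a_ok & b_ok).sum()))


def _delong_variance(truth: np.ndarray, scores: np.ndarray) -> tuple[float, float]:
    """AUC and its DeLong variance (midrank formulation)."""
    pos = scores[truth]
    neg = scores[~truth]
    m, n = len(pos), len(neg)
    all_scores = np.concatenate([pos, neg])
    rank_all = sps.rankdata(all_scores)
    rank_pos = sps.rankdata(pos)
    rank_neg = sps.rankdata(neg)
    auc = (rank_all[:m].sum() - m * (m + 1) / 2) / (m * n)
    v10 = (rank_all[:m] - rank_pos) / n - auc  # structural components, positives
    v01 = 1.0 - (rank_all[m:] - rank_neg) / m - auc  # negatives
    if m < 2 or n < 2:  # variance undefined with a single case in a class
        return float(auc), float("nan")
    var = v10.var(ddof=1) / m + v01.var(ddof=1) / n
    return float(auc), float(var)


@dataclass
class RocResult:
    auc: float
    ci_low: float
    ci_high: float
    curve: pd.DataFrame = field(repr=False)  # columns fpr, tpr, threshold


def roc_auc(truth, probabilities, alpha: float = 0.95) -> RocResult:
    """AUC (rank/trapezoidal; equals the concordance probability) with a
    DeLong 95% CI, plus the ROC curve points for plotting."""
    truth = np.asarray(truth, bool)
    scores = np.asarray(probabilities, float)
    if truth.all() or not truth.any():
        raise ValueError("AUC needs both classes in the truth vector")
    auc, var = _delong_variance(truth, scores)
    z = sps.norm.ppf(0.5 + alpha / 2)
    half = z * np.sqrt(var) if np.isfinite(var) else 1.0
    fpr, tpr, thr = roc_curve(truth, scores)
    curve = pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr})
    return RocResult(
        auc=auc,
        ci_low=float(max(0.0, auc - half)),
        ci_high=float(min(1.0, auc + half)),
        curve=curve,
    )


def brier_score(truth, probabilities) -> float:
    """Mean squared difference between predicted probability and outcome."""
    truth = np.asarray(truth, bool)
    return float(brier_score_loss(truth, np.asarray(probabilities, float)))


def calibration_table(truth, probabilities, n_bins: int = 10) -> pd.DataFrame:
    """Equal-width calibration bins (empty bins omitted): per-bin mean
    predicted probability vs observed malignant fraction."""
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    truth = np.asarray(truth, bool)
    prob_true, prob_pred = _sk_calibration_curve(
        truth, np.asarray(probabilities, float), n_bins=n_bins, strategy="uniform"
    )
    return pd.DataFrame({"mean_predicted": prob_pred, "observed_fraction": prob_true})
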