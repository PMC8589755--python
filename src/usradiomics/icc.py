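"""Inter-reader feature stability via ICC(2,1) and the stability filter.

ICC(2,1) is the two-way random-effects, single-rater, absolute-agreement
intraclass correlation.  From the two-way ANOVA decomposition of an
n-subjects x k-readers ratings matrix (MSR between subjects, MSC between
readers, MSE residual):

    ICC = (MSR - MSE) / (MSR + (k-1) MSE + (k/n) (MSC - MSE))

Features whose ICC across readers falls below the threshold (0.75 by
default, inclusive: ICC >= 0.75 is retained) are considered unstable to
segmentation variability and dropped before any model sees them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .features.extract import ID_COLUMNS, feature_columns

DEFAULT_ICC_THRESHOLD = 0.75


def icc_2_1(ratings: np.ndarray) -> float | np.ndarray:
    """ICC(2,1) of an (n, k) ratings matrix, or per-feature for (n, k, F).

    A matrix with zero total variance (all cells equal) returns 1 by
    convention — identical ratings are perfectly reproducible.
    """
    x = np.asarray(ratings, dtype=float)
    squeeze = x.ndim == 2
    if squeeze:
        x = x[:, :, None]
    n, k, _ = x.shape
    if n < 2 or k < 2:
        raise ValueError(f"need at least 2 subjects and 2 readers, got {n}x{k}")
    if not np.all(np.isfinite(x)):
        raise ValueError("ratings contain missing or non-finite cells")
    grand = x.mean(axis=(0, 1))
    row_means = x.mean(axis=1)  # (n, F)
    col_means = x.mean(axis=0)  # (k, F)
    ssr = k * ((row_means - grand) ** 2).sum(axis=0)
    ssc = n * ((col_means - grand) ** 2).sum(axis=0)
    sst = ((x - grand) ** 2).sum(axis=(0, 1))
    sse = sst - ssr - ssc
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    with np.errstate(divide="ignore", invalid="ignore"):
        icc = np.where(denom > 0, (msr - mse) / np.where(denom > 0, denom, 1.0), 1.0)
    icc = np.where(sst == 0, 1.0, icc)
    return float(icc[0]) if squeeze else icc


@dataclass
class StabilityReport:
    """Per-feature ICC values with the keep/drop decision."""

    table: pd.DataFrame  # columns: feature, icc, kept
    threshold: float

    @property
    def retained(self) -> list[str]:
        return self.table.loc[self.table["kept"], "feature"].tolist()

    @property
    def dropped(self) -> list[str]:
        return self.table.loc[~self.table["kept"], "feature"].tolist()


def stability_filter(
    multi_reader_table: pd.DataFrame, threshold: float = DEFAULT_ICC_THRESHOLD
) -> StabilityReport:
    """Score every feature's ICC(2,1) across readers and flag unstable ones.

    ``multi_reader_table`` is a feature table restricted to the lesions that
    were annotated by every reader (rows keyed by lesion_id and reader_id).
    All readers must cover the same lesions with the same feature manifest.
    """
    readers = sorted(multi_reader_table["reader_id"].unique())
    if len(readers) < 2:
        raise ValueError("stability filtering needs at least 2 readers")
    features = feature_columns(multi_reader_table)
    per_reader = {}
    lesion_order = None
    for reader in readers:
        sub = (
            multi_reader_table[multi_reader_table["reader_id"] == reader]
            .sort_values("lesion_id")
            .reset_index(drop=True)
        )
        if lesion_order is None:
            lesion_order = sub["lesion_id"].tolist()
        elif sub["lesion_id"].tolist() != lesion_order:
            raise ValueError("readers do not cover the same lesions")
        per_reader[reader] = sub[features].to_numpy(float)
    ratings = np.stack([per_reader[r] for r in readers], axis=1)  # (n, k, F)
    icc = np.asarray(icc_2_1(ratings))
    report = pd.DataFrame(
        {"feature": features, "icc": icc, "kept": icc >= threshold}
    )
    return StabilityReport(table=report, threshold=threshold)


class ICCStabilityFilter:
    """Sklearn-style transformer around :func:`stability_filter`.

    ``fit`` consumes the multi-reader ratings table; ``transform`` restricts
    any feature table to the stable columns (id columns are preserved).
    """

    def __init__(self, threshold: float = DEFAULT_ICC_THRESHOLD):
        self.threshold = threshold

    def fit(self, multi_reader_table: pd.DataFrame, y=None) -> "ICCStabilityFilter":
        self.report_ = stability_filter(multi_reader_table, self.threshold)
        self.retained_ = self.report_.retained
        return self

    def transform(self, table: pd.DataFrame) -> pd.DataFrame:
        keep = [c for c in table.columns if c in ID_COLUMNS or c == "split"]
        return table[keep + self.retained_]

    def get_params(self, deep: bool = True) -> dict:
        return {"threshold": self.threshold}

    def set_params(self, **params) -> "ICCStabilityFilter":
        for key, val in params.items():
            setattr(self, key, val)
        return self
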