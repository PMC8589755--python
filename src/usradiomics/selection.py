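"""The feature-selection cascade.

Stage order is fixed: ICC stability (see :mod:`usradiomics.icc`) ->
train-fitted MinMax scaling -> low-variance pruning (variance <= 0.01
dropped) -> pairwise-correlation pruning (|r| >= 0.8) -> SMOTE class
balancing (k = 5) -> stratified 10-fold recursive feature elimination with
a logistic-regression estimator.  Every data-dependent decision is fitted
on training rows only; test rows are transformed with frozen parameters.

SMOTE is implemented here directly: each synthetic minority row is
``x + u * (x_nn - x)`` with ``u ~ Uniform(0, 1)``, ``x`` a minority row and
``x_nn`` one of its k nearest minority neighbors (Euclidean distance on the
scaled features), repeated until the classes are exactly balanced.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.feature_selection import RFECV
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import MinMaxScaler

from .datatypes import POSITIVE_CLASS

DEFAULT_VARIANCE_THRESHOLD = 0.01
DEFAULT_CORRELATION_THRESHOLD = 0.8
DEFAULT_SMOTE_K = 5
DEFAULT_RFECV_FOLDS = 10


# ---------------------------------------------------------------------------
# MinMax scaling
# ---------------------------------------------------------------------------

@dataclass
class ScalerParams:
    """Per-feature training minimum/maximum (fitted once, on training rows)."""

    feature_names: list[str]
    data_min: np.ndarray
    data_max: np.ndarray


def fit_minmax(train_table: pd.DataFrame, feature_names: list[str]) -> ScalerParams:
    """Learn the 0-1 MinMax mapping from training rows only."""
    if train_table.empty:
        raise ValueError("cannot fit a scaler on an empty training table")
    scaler = MinMaxScaler().fit(train_table[feature_names].to_numpy(float))
    return ScalerParams(
        feature_names=list(feature_names),
        data_min=scaler.data_min_,
        data_max=scaler.data_max_,
    )


def apply_minmax(table: pd.DataFrame, params: ScalerParams) -> pd.DataFrame:
    """x -> (x - min) / (max - min).  Values outside the training range map
    outside [0, 1] and are deliberately not clipped; constant training
    columns map to 0 (they fall to the variance filter next)."""
    out = table.copy()
    x = out[params.feature_names].to_numpy(float)
    span = params.data_max - params.data_min
    safe_span = np.where(span == 0, 1.0, span)
    out[params.feature_names] = (x - params.data_min) / safe_span
    return out


# ---------------------------------------------------------------------------
# Variance and correlation pruning
# ---------------------------------------------------------------------------

def variance_filter(
    train_table: pd.DataFrame,
    feature_names: list[str],
    threshold: float = DEFAULT_VARIANCE_THRESHOLD,
) -> tuple[list[str], pd.Series]:
    """Drop features whose training variance is <= threshold (inclusive).

    Returns (retained names, per-feature variance).  Uses the population
    variance, matching the convention of standard variance-threshold
    selectors.
    """
    x = train_table[feature_names].to_numpy(float)
    variances = pd.Series(x.var(axis=0), index=feature_names)
    retained = [name for name in feature_names if variances[name] > threshold]
    return retained, variances


def correlation_filter(
    train_table: pd.DataFrame,
    feature_names: list[str],
    r_threshold: float = DEFAULT_CORRELATION_THRESHOLD,
) -> tuple[list[str], list[tuple[str, float]]]:
    """Greedily remove features until no pair has |Pearson r| >= threshold.

    At each step, among all features still involved in a violating pair, the
    one with the largest mean absolute correlation against the remaining
    features is dropped (the most redundant goes first); ties break by
    manifest order, dropping the later feature.  Deterministic.

    Returns (retained names, [(dropped name, triggering |r|), ...]).
    """
    x = train_table[feature_names].to_numpy(float)
    if np.any(x.var(axis=0) == 0):
        bad = [f for f, v in zip(feature_names, x.var(axis=0)) if v == 0]
        raise ValueError(
            f"zero-variance features reached the correlation filter: {bad[:5]} "
            "(they must be removed by the variance filter first)"
        )
    corr = np.abs(np.corrcoef(x, rowvar=False))
    np.fill_diagonal(corr, 0.0)
    alive = np.ones(len(feature_names), dtype=bool)
    dropped: list[tuple[str, float]] = []
    while True:
        sub = corr[np.ix_(alive, alive)]
        if sub.size == 0 or sub.max() < r_threshold:
            break
        idx_alive = np.flatnonzero(alive)
        violating = np.flatnonzero((sub >= r_threshold).any(axis=1))
        mean_corr = sub[violating].mean(axis=1)
        # argmax with ties broken toward the later manifest position
        best = violating[np.lexsort((idx_alive[violating], mean_corr))[-1]]
        victim = idx_alive[best]
        trigger = float(corr[victim, alive].max())
        alive[victim] = False
        dropped.append((feature_names[victim], trigger))
    retained = [f for f, a in zip(feature_names, alive) if a]
    return retained, dropped


# ---------------------------------------------------------------------------
# SMOTE
# ---------------------------------------------------------------------------

def smote(
    minority_rows: np.ndarray,
    n_synthetic: int,
    rng_seed,
    k_neighbors: int = DEFAULT_SMOTE_K,
) -> np.ndarray:
    """Generate ``n_synthetic`` interpolated minority rows.

    Each synthetic row is base + u * (neighbor - base) with u ~ U(0,1) and
    the neighbor drawn uniformly from the base row's k nearest minority
    neighbors (Euclidean, self excluded).
    """
    x = np.asarray(minority_rows, dtype=float)
    n = x.shape[0]
    if n <= k_neighbors:
        raise ValueError(
            f"SMOTE needs more minority rows ({n}) than neighbors "
            f"(k={k_neighbors}); lower k_neighbors"
        )
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    d2 = ((x[:, None, :] - x[None, :, :]) ** 2).sum(axis=2)
    np.fill_diagonal(d2, np.inf)
    nn = np.argsort(d2, axis=1, kind="stable")[:, :k_neighbors]
    base_idx = rng.integers(0, n, size=n_synthetic)
    nbr_pick = rng.integers(0, k_neighbors, size=n_synthetic)
    u = rng.uniform(0.0, 1.0, size=n_synthetic)
    base = x[base_idx]
    neighbor = x[nn[base_idx, nbr_pick]]
    return base + u[:, None] * (neighbor - base)


def smote_balance(
    table: pd.DataFrame, labels: pd.Series, feature_names: list[str], rng_seed,
    k_neighbors: int = DEFAULT_SMOTE_K,
) -> tuple[pd.DataFrame, pd.Series]:
    """Append synthetic minority rows until both classes have equal counts."""
    counts = labels.value_counts()
    if len(counts) < 2:
        raise ValueError(
            f"cannot balance a single-class cohort (only {counts.index[0]!r} present)"
        )
    minority = counts.idxmin()
    n_syn = int(counts.max() - counts.min())
    if n_syn == 0:
        return table.copy(), labels.copy()
    minority_x = table.loc[labels == minority, feature_names].to_numpy(float)
    synthetic = smote(minority_x, n_syn, rng_seed, k_neighbors)
    syn_table = pd.DataFrame(synthetic, columns=feature_names)
    syn_table.insert(0, "lesion_id", [f"SMOTE{i:04d}" for i in range(n_syn)])
    out = pd.concat(
        [table[["lesion_id"] + feature_names], syn_table], ignore_index=True
    )
    out_labels = pd.concat(
        [labels.reset_index(drop=True), pd.Series([minority] * n_syn)],
        ignore_index=True,
    )
    return out, out_labels


# ---------------------------------------------------------------------------
# RFECV
# ---------------------------------------------------------------------------

def rfecv(
    table: pd.DataFrame,
    labels: pd.Series,
    feature_names: list[str],
    rng_seed: int,
    n_folds: int = DEFAULT_RFECV_FOLDS,
) -> tuple[list[str], np.ndarray]:
    """Stratified CV recursive feature elimination with logistic regression.

    One feature (the one with the smallest |coefficient|) is dropped per
    iteration; the retained set is the smallest one achieving the maximal
    mean cross-validated accuracy.  Returns (selected names, mean score per
    feature count, index 0 = 1 feature).
    """
    x = table[feature_names].to_numpy(float)
    y = np.asarray(labels)
    class_counts = pd.Series(y).value_counts()
    if class_counts.min() < n_folds:
        raise ValueError(
            f"smallest class has {class_counts.min()} rows < {n_folds} folds; "
            "every stratified fold must contain both classes"
        )
    if len(feature_names) == 1:
        return list(feature_names), np.array([np.nan])
    estimator = LogisticRegression(solver="lbfgs", max_iter=5000)
    cv = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=int(rng_seed))
    selector = RFECV(estimator, step=1, cv=cv, scoring="accuracy", min_features_to_select=1)
    selector.fit(x, y)
    selected = [f for f, keep in zip(feature_names, selector.support_) if keep]
    return selected, np.asarray(selector.cv_results_["mean_test_score"])


# ---------------------------------------------------------------------------
# Report + pipeline
# ---------------------------------------------------------------------------

@dataclass
class SelectionStage:
    name: str
    threshold: float | None
    removed: list
    n_remaining: int


@dataclass
class SelectionReport:
    """Ordered record of what each selection stage removed and kept."""

    stages: list[SelectionStage] = field(default_factory=list)

    def add(self, name: str, threshold, removed, n_remaining: int) -> None:
        self.stages.append(SelectionStage(name, threshold, list(removed), n_remaining))

    def to_dict(self) -> dict:
        return {
            "stages": [
                {
                    "name": s.name,
                    "threshold": s.threshold,
                    "n_removed": len(s.removed),
                    "removed": s.removed,
                    "n_remaining": s.n_remaining,
                }
                for s in self.stages
            ]
        }

    def counts_narrative(self, n_input: int) -> str:
        """'874 -> 322 -> ... -> 10'-style feature-count summary."""
        counts = [n_input] + [s.n_remaining for s in self.stages]
        return " -> ".join(str(c) for c in counts)


class SelectionPipeline:
    """Fit the scale/variance/correlation/SMOTE/RFECV cascade on training data.

    Parameters mirror the stage functions.  After ``fit``:

    ``selected_features_``
        the final RFECV-selected feature names;
    ``balanced_table_``, ``balanced_labels_``
        the SMOTE-balanced training matrix used for RFECV and available for
        classifier training;
    ``report_``
        a :class:`SelectionReport` with one entry per stage.

    ``transform`` maps any table (e.g. the external test set) through the
    frozen scaler and the selected columns; it never refits anything.
    """

    def __init__(
        self,
        variance_threshold: float = DEFAULT_VARIANCE_THRESHOLD,
        r_threshold: float = DEFAULT_CORRELATION_THRESHOLD,
        smote_k: int = DEFAULT_SMOTE_K,
        rfecv_folds: int = DEFAULT_RFECV_FOLDS,
        rng_seed: int = 0,
    ):
        self.variance_threshold = variance_threshold
        self.r_threshold = r_threshold
        self.smote_k = smote_k
        self.rfecv_folds = rfecv_folds
        self.rng_seed = rng_seed

    def fit(
        self, train_table: pd.DataFrame, labels: pd.Series, feature_names: list[str]
    ) -> "SelectionPipeline":
        report = SelectionReport()
        self.scaler_ = fit_minmax(train_table, feature_names)
        scaled = apply_minmax(train_table, self.scaler_)
        report.add("minmax_scaling", None, [], len(feature_names))

        kept_var, variances = variance_filter(
            scaled, feature_names, self.variance_threshold
        )
        removed_var = [f for f in feature_names if f not in set(kept_var)]
        report.add(
            "variance_filter",
            self.variance_threshold,
            [(f, float(variances[f])) for f in removed_var],
            len(kept_var),
        )

        kept_corr, dropped_corr = correlation_filter(scaled, kept_var, self.r_threshold)
        report.add("correlation_filter", self.r_threshold, dropped_corr, len(kept_corr))

        if "lesion_id" in scaled.columns:
            base = scaled[["lesion_id"] + kept_corr].reset_index(drop=True)
        else:
            base = scaled[kept_corr].reset_index(drop=True).copy()
            base.insert(0, "lesion_id", [f"row{i}" for i in range(len(base))])
        balanced, balanced_labels = smote_balance(
            base, labels.reset_index(drop=True), kept_corr,
            rng_seed=self.rng_seed, k_neighbors=self.smote_k,
        )
        report.add("smote", None, [], len(kept_corr))

        selected, curve = rfecv(
            balanced, balanced_labels, kept_corr,
            rng_seed=self.rng_seed, n_folds=self.rfecv_folds,
        )
        removed_rfecv = [f for f in kept_corr if f not in set(selected)]
        report.add("rfecv", None, removed_rfecv, len(selected))

        self.feature_names_ = list(feature_names)
        self.selected_features_ = selected
        self.rfecv_curve_ = curve
        self.balanced_table_ = balanced
        self.balanced_labels_ = balanced_labels
        self.report_ = report
        return self

    def transform(self, table: pd.DataFrame) -> pd.DataFrame:
        scaled = apply_minmax(table, self.scaler_)
        keep = [c for c in table.columns if c in ("lesion_id", "reader_id", "class_label")]
        return scaled[keep + self.selected_features_]

    def get_params(self, deep: bool = True) -> dict:
        return {
            "variance_threshold": self.variance_threshold,
            "r_threshold": self.r_threshold,
            "smote_k": self.smote_k,
            "rfecv_folds": self.rfecv_folds,
            "rng_seed": self.rng_seed,
        }

    def set_params(self, **params) -> "SelectionPipeline":
        for key, val in params.items():
            setattr(self, key, val)
        return self
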