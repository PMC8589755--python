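"""Random-forest lesion classifier with the study's fixed hyperparameters.

The default configuration is a fixed reference set: 400 Gini trees,
bootstrap resampling, unlimited depth, 5 candidate features per split, no
class weighting.  A seeded random-search utility over a logged space is
provided for users who want to re-tune, but the shipped defaults are the
recoverable configuration.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import ParameterSampler, StratifiedKFold

from .datatypes import BENIGN, MALIGNANT, POSITIVE_CLASS


@dataclass(frozen=True)
class RFConfig:
    """Random-forest hyperparameters (defaults = the reference configuration)."""

    n_estimators: int = 400
    criterion: str = "gini"
    max_depth: int | None = None
    max_features: int = 5
    max_leaf_nodes: int | None = None
    min_impurity_decrease: float = 0.0
    min_samples_leaf: int = 1
    min_samples_split: int = 2
    min_weight_fraction_leaf: float = 0.0
    bootstrap: bool = True
    class_weight: None = None
    rng_seed: int = 0

    def build(self, n_features: int) -> RandomForestClassifier:
        if self.n_estimators < 1:
            raise ValueError("n_estimators must be >= 1")
        return RandomForestClassifier(
            n_estimators=self.n_estimators,
            criterion=self.criterion,
            max_depth=self.max_depth,
            max_features=min(self.max_features, n_features),
            max_leaf_nodes=self.max_leaf_nodes,
            min_impurity_decrease=self.min_impurity_decrease,
            min_samples_leaf=self.min_samples_leaf,
            min_samples_split=self.min_samples_split,
            min_weight_fraction_leaf=self.min_weight_fraction_leaf,
            bootstrap=self.bootstrap,
            class_weight=self.class_weight,
            random_state=self.rng_seed,
            n_jobs=1,
        )


class LesionRandomForest:
    """Sklearn-style wrapper: fit on a feature table, predict malignancy.

    Fitted attributes: ``model_`` (the sklearn forest), ``features_`` (the
    column order the model expects).  Class calls use probability >= 0.5
    for the positive (malignant) class.
    """

    def __init__(self, config: RFConfig | None = None):
        self.config = config or RFConfig()

    def fit(self, table: pd.DataFrame, labels) -> "LesionRandomForest":
        self.features_ = [
            c for c in table.columns
            if c not in ("lesion_id", "reader_id", "class_label", "split")
        ]
        x = table[self.features_].to_numpy(float)
        y = np.asarray(labels)
        self.model_ = self.config.build(len(self.features_)).fit(x, y)
        return self

    def predict_proba(self, table: pd.DataFrame) -> np.ndarray:
        """Per-row probability of the malignant class."""
        x = table[self.features_].to_numpy(float)
        proba = self.model_.predict_proba(x)
        pos = list(self.model_.classes_).index(POSITIVE_CLASS)
        return proba[:, pos]

    def predict(self, table: pd.DataFrame, threshold: float = 0.5) -> np.ndarray:
        p = self.predict_proba(table)
        return np.where(p >= threshold, MALIGNANT, BENIGN)

    def get_params(self, deep: bool = True) -> dict:
        return {"config": self.config}

    def set_params(self, **params) -> "LesionRandomForest":
        for key, val in params.items():
            setattr(self, key, val)
        return self


def cross_validate(
    table: pd.DataFrame,
    labels,
    config: RFConfig | None = None,
    n_folds: int = 5,
) -> pd.DataFrame:
    """Stratified k-fold CV; returns per-fold accuracy/PPV/sensitivity/
    specificity/AUC plus a mean and an SD row."""
    config = config or RFConfig()
    y = pd.Series(np.asarray(labels))
    if y.value_counts().min() < n_folds:
        raise ValueError(
            f"minority class ({y.value_counts().min()} rows) smaller than "
            f"n_folds={n_folds}"
        )
    cv = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=config.rng_seed)
    rows = []
    dummy_x = np.zeros(len(y))
    for fold, (tr, te) in enumerate(cv.split(dummy_x, y)):
        clf = LesionRandomForest(config).fit(table.iloc[tr], y.iloc[tr])
        proba = clf.predict_proba(table.iloc[te])
        call = proba >= 0.5
        truth = (y.iloc[te] == POSITIVE_CLASS).to_numpy()
        tp = int((call & truth).sum())
        tn = int((~call & ~truth).sum())
        fp = int((call & ~truth).sum())
        fn = int((~call & truth).sum())
        rows.append(
            {
                "fold": fold,
                "accuracy": (tp + tn) / len(truth),
                "ppv": tp / (tp + fp) if tp + fp else np.nan,
                "sensitivity": tp / (tp + fn) if tp + fn else np.nan,
                "specificity": tn / (tn + fp) if tn + fp else np.nan,
                "auc": roc_auc_score(truth, proba),
            }
        )
    out = pd.DataFrame(rows).set_index("fold")
    out.loc["mean"] = out.mean()
    out.loc["sd"] = out.iloc[:-1].std(ddof=1)
    return out


def fit_final(table: pd.DataFrame, labels, config: RFConfig | None = None) -> LesionRandomForest:
    """Fit the final model on the whole training table (deterministic per seed)."""
    return LesionRandomForest(config or RFConfig()).fit(table, labels)


#: Search space of the optional tuning utility (logged for reproducibility).
RANDOM_SEARCH_SPACE = {
    "n_estimators": [100, 200, 400, 800],
    "max_features": [2, 3, 5, 8, "sqrt"],
    "min_samples_leaf": [1, 2, 4],
    "min_samples_split": [2, 4, 8],
    "bootstrap": [True, False],
}


def random_search(
    table: pd.DataFrame,
    labels,
    n_iter: int = 20,
    n_folds: int = 5,
    rng_seed: int = 0,
) -> pd.DataFrame:
    """Seeded random search over :data:`RANDOM_SEARCH_SPACE`; returns the
    sampled configurations with their mean CV accuracy, best first."""
    sampler = ParameterSampler(RANDOM_SEARCH_SPACE, n_iter=n_iter, random_state=rng_seed)
    results = []
    features = [
        c for c in table.columns
        if c not in ("lesion_id", "reader_id", "class_label", "split")
    ]
    for params in sampler:
        max_feat = params["max_features"]
        if isinstance(max_feat, str):
            max_feat = max(1, int(np.sqrt(len(features))))
        cfg = RFConfig(
            n_estimators=params["n_estimators"],
            max_features=max_feat,
            min_samples_leaf=params["min_samples_leaf"],
            min_samples_split=params["min_samples_split"],
            bootstrap=params["bootstrap"],
            rng_seed=rng_seed,
        )
        cv = cross_validate(table, labels, cfg, n_folds=n_folds)
        results.append({**params, "mean_cv_accuracy": cv.loc["mean", "accuracy"]})
    return (
        pd.DataFrame(results)
        .sort_values("mean_cv_accuracy", ascending=False)
        .reset_index(drop=True)
    )
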