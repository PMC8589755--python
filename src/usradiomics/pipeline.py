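"""End-to-end orchestration: config, seed management, stage runners, manifest.

A run is driven by a :class:`RunConfig` (loadable from YAML).  Each stage
reads the previous stage's artifacts from the run directory and writes its
own atomically, so stages can be re-run individually.  A single master seed
deterministically derives every stage's RNG stream; the run manifest records
the config hash, the derived seeds and the stage-by-stage feature counts, so
two runs with equal manifests produce identical outputs.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field

from . import io
from .datatypes import MALIGNANT, POSITIVE_CLASS, AnnotatedImage
from .features import ExtractionConfig, RadiomicsExtractor, feature_columns, write_manifest
from .icc import DEFAULT_ICC_THRESHOLD, ICCStabilityFilter
from .model import LesionRandomForest, RFConfig, cross_validate, fit_final
from .selection import SelectionPipeline
from .stats import (
    ConfusionTable,
    brier_score,
    calibration_table,
    confusion_metrics,
    mcnemar_from_readings,
    nir_test,
    roc_auc,
)
from .synthetic import DEFAULT_BENIGN_SPEC, DEFAULT_MALIGNANT_SPEC, generate_cohort

__version__ = "0.1.0"

_STAGE_IDS = {
    "train_cohort": 1,
    "test_cohort": 2,
    "selection": 3,
    "forest": 4,
}


def derive_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage 31-bit seed from the master seed."""
    ss = np.random.SeedSequence([int(master_seed), _STAGE_IDS[stage]])
    return int(ss.generate_state(1)[0] % (2**31))


class SyntheticBlock(BaseModel):
    n_benign_train: int = 91
    n_malignant_train: int = 44
    n_benign_test: int = 21
    n_malignant_test: int = 45
    n_readers: int = 3
    reproducibility_subset: int = 30
    reader_magnitude: float = 0.05
    image_size: int = 128


class PreprocessingBlock(BaseModel):
    bin_width: float = 3.0
    normalize_scale: float = 100.0
    normalize_shift: float = 300.0
    log_sigmas: list[float] = Field(default_factory=lambda: [1, 2, 3, 4, 5])
    wavelet: str | None = "coif1"


class SelectionBlock(BaseModel):
    icc_threshold: float = DEFAULT_ICC_THRESHOLD
    variance_threshold: float = 0.01
    r_threshold: float = 0.8
    smote_k: int = 5
    rfecv_folds: int = 10


class ModelBlock(BaseModel):
    n_estimators: int = 400
    max_features: int = 5
    min_samples_leaf: int = 1
    min_samples_split: int = 2
    bootstrap: bool = True


class EvaluationBlock(BaseModel):
    cv_folds: int = 5
    calibration_bins: int = 10


class RunConfig(BaseModel):
    """Everything a run needs; defaults mirror the study conditions."""

    out_dir: str = "run"
    master_seed: int = 0
    synthetic: SyntheticBlock = Field(default_factory=SyntheticBlock)
    preprocessing: PreprocessingBlock = Field(default_factory=PreprocessingBlock)
    selection: SelectionBlock = Field(default_factory=SelectionBlock)
    model: ModelBlock = Field(default_factory=ModelBlock)
    evaluation: EvaluationBlock = Field(default_factory=EvaluationBlock)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        with open(path, encoding="utf-8") as fh:
            payload = yaml.safe_load(fh) or {}
        return cls(**payload)

    def config_hash(self) -> str:
        canon = json.dumps(self.model_dump(), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]

    def extraction_config(self) -> ExtractionConfig:
        p = self.preprocessing
        return ExtractionConfig(
            bin_width=p.bin_width,
            normalize_scale=p.normalize_scale,
            normalize_shift=p.normalize_shift,
            log_sigmas=tuple(float(s) for s in p.log_sigmas),
            wavelet=p.wavelet,
        )

    def rf_config(self) -> RFConfig:
        m = self.model
        return RFConfig(
            n_estimators=m.n_estimators,
            max_features=m.max_features,
            min_samples_leaf=m.min_samples_leaf,
            min_samples_split=m.min_samples_split,
            bootstrap=m.bootstrap,
            rng_seed=derive_seed(self.master_seed, "forest"),
        )


class RunManifest:
    """Accumulates run metadata; written as run_manifest.json."""

    def __init__(self, config: RunConfig):
        self.payload: dict = {
            "config_hash": config.config_hash(),
            "config": config.model_dump(),
            "software_version": __version__,
            "seeds": {s: derive_seed(config.master_seed, s) for s in _STAGE_IDS},
            "feature_counts": {},
            "outputs": [],
        }

    def record_count(self, stage: str, count: int) -> None:
        self.payload["feature_counts"][stage] = count

    def record_output(self, path: Path) -> None:
        self.payload["outputs"].append(str(path))

    def write(self, out_dir: Path) -> None:
        io.write_json(out_dir / "run_manifest.json", self.payload)


def _require(path: Path, hint: str) -> Path:
    if not path.exists():
        raise FileNotFoundError(
            f"missing upstream artifact {path}; run `{hint}` first"
        )
    return path


def _build_cohorts(config: RunConfig) -> tuple[list[AnnotatedImage], pd.DataFrame,
                                               list[AnnotatedImage], pd.DataFrame]:
    from dataclasses import replace

    s = config.synthetic
    benign = replace(DEFAULT_BENIGN_SPEC, image_size=s.image_size)
    malignant = replace(DEFAULT_MALIGNANT_SPEC, image_size=s.image_size)
    train, train_truth = generate_cohort(
        s.n_benign_train, s.n_malignant_train,
        seed=derive_seed(config.master_seed, "train_cohort"),
        benign_spec=benign, malignant_spec=malignant,
        n_readers=s.n_readers, reproducibility_subset=s.reproducibility_subset,
        reader_magnitude=s.reader_magnitude, id_prefix="TR",
    )
    test, test_truth = generate_cohort(
        s.n_benign_test, s.n_malignant_test,
        seed=derive_seed(config.master_seed, "test_cohort"),
        benign_spec=benign, malignant_spec=malignant,
        n_readers=1, reproducibility_subset=0, id_prefix="TE",
    )
    return train, train_truth, test, test_truth


def cmd_simulate(config: RunConfig) -> Path:
    """Write synthetic images, masks (PNG) and the truth table (CSV)."""
    out = Path(config.out_dir)
    (out / "images").mkdir(parents=True, exist_ok=True)
    (out / "masks").mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config)
    train, train_truth, test, test_truth = _build_cohorts(config)
    truth_rows = []
    for split, cohort, truth in (("train", train, train_truth), ("test", test, test_truth)):
        for rec in cohort:
            img_path = out / "images" / f"{rec.lesion_id}.png"
            mask_path = out / "masks" / f"{rec.lesion_id}_{rec.reader_id}.png"
            if rec.reader_id == "R1":
                io.write_image_png(img_path, rec.pixels)
                manifest.record_output(img_path)
            io.write_mask_png(mask_path, rec.mask)
            manifest.record_output(mask_path)
        t = truth.copy()
        t["split"] = split
        truth_rows.append(t)
    truth_table = pd.concat(truth_rows, ignore_index=True)
    io.write_csv(out / "truth.csv", truth_table)
    manifest.record_output(out / "truth.csv")
    manifest.write(out)
    return out


def cmd_extract(config: RunConfig) -> Path:
    """Extract the full feature table for both splits and all readers."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config)
    extractor = RadiomicsExtractor(config.extraction_config())
    train, train_truth, test, test_truth = _build_cohorts(config)
    table_train = extractor.transform(train)
    table_train["split"] = "train"
    table_test = extractor.transform(test)
    table_test["split"] = "test"
    table = pd.concat([table_train, table_test], ignore_index=True)
    io.write_csv(out / "features.csv", table)
    write_manifest(out / "feature_manifest.txt", extractor.manifest_)
    manifest.record_count("extracted", len(extractor.manifest_))
    manifest.record_output(out / "features.csv")
    manifest.record_output(out / "feature_manifest.txt")
    manifest.write(out)
    return out / "features.csv"


def _load_features(out: Path) -> pd.DataFrame:
    return pd.read_csv(_require(out / "features.csv", "usradiomics extract"))


def select_features(
    table: pd.DataFrame, config: RunConfig
) -> tuple[SelectionPipeline, ICCStabilityFilter, pd.DataFrame, pd.Series, dict]:
    """The selection cascade on an in-memory feature table (both splits)."""
    train_r1 = table[(table["split"] == "train") & (table["reader_id"] == "R1")]
    multi = table[table["split"] == "train"]
    multi_lesions = multi.groupby("lesion_id")["reader_id"].nunique()
    reproducible = multi_lesions[multi_lesions > 1].index
    counts: dict[str, int] = {"extracted": len(feature_columns(table))}

    icc_filter = ICCStabilityFilter(threshold=config.selection.icc_threshold)
    icc_filter.fit(multi[multi["lesion_id"].isin(reproducible)])
    counts["icc_stable"] = len(icc_filter.retained_)

    stable_train = icc_filter.transform(train_r1)
    labels = stable_train["class_label"].reset_index(drop=True)
    pipe = SelectionPipeline(
        variance_threshold=config.selection.variance_threshold,
        r_threshold=config.selection.r_threshold,
        smote_k=config.selection.smote_k,
        rfecv_folds=config.selection.rfecv_folds,
        rng_seed=derive_seed(config.master_seed, "selection"),
    )
    pipe.fit(stable_train, labels, icc_filter.retained_)
    for stage in pipe.report_.stages:
        counts[stage.name] = stage.n_remaining
    return pipe, icc_filter, stable_train, labels, counts


def cmd_select(config: RunConfig) -> Path:
    """Run ICC -> scaling -> variance -> correlation -> SMOTE -> RFECV."""
    out = Path(config.out_dir)
    table = _load_features(out)
    pipe, icc_filter, _, _, counts = select_features(table, config)
    manifest = RunManifest(config)
    for stage, count in counts.items():
        manifest.record_count(stage, count)

    report = {
        "icc": {
            "threshold": icc_filter.threshold,
            "n_stable": len(icc_filter.retained_),
            "dropped": icc_filter.report_.dropped,
        },
        **pipe.report_.to_dict(),
        "selected_features": pipe.selected_features_,
        "counts_narrative": pipe.report_.counts_narrative(counts["icc_stable"]),
    }
    io.write_json(out / "selection_report.json", report)

    # reduced feature table: train R1 + test rows, selected columns only
    usable = table[table["reader_id"] == "R1"]
    reduced = pd.concat(
        [
            usable[["lesion_id", "reader_id", "class_label", "split"]].reset_index(drop=True),
            pipe.transform(usable)[pipe.selected_features_].reset_index(drop=True),
        ],
        axis=1,
    )
    io.write_csv(out / "features_selected.csv", reduced)
    io.write_csv(out / "features_balanced.csv",
                 pipe.balanced_table_.assign(class_label=pipe.balanced_labels_.values))
    manifest.record_output(out / "selection_report.json")
    manifest.record_output(out / "features_selected.csv")
    manifest.write(out)
    return out / "selection_report.json"


def cmd_train(config: RunConfig) -> Path:
    """5-fold stratified CV assessment and the final fit on balanced training data."""
    import joblib

    out = Path(config.out_dir)
    balanced = pd.read_csv(_require(out / "features_balanced.csv", "usradiomics select"))
    selected = json.loads(
        _require(out / "selection_report.json", "usradiomics select").read_text()
    )["selected_features"]
    labels = balanced["class_label"]
    features = balanced[["lesion_id"] + selected]
    rf_config = config.rf_config()
    cv = cross_validate(features, labels, rf_config, n_folds=config.evaluation.cv_folds)
    io.write_csv(out / "cv_report.csv", cv.reset_index())
    model = fit_final(features, labels, rf_config)
    joblib.dump({"model": model, "selected_features": selected, "config": rf_config},
                out / "model.joblib")
    manifest = RunManifest(config)
    manifest.record_output(out / "cv_report.csv")
    manifest.record_output(out / "model.joblib")
    manifest.write(out)
    return out / "model.joblib"


def cmd_evaluate(config: RunConfig) -> dict:
    """Test-set metrics: confusion metrics + CIs, NIR test, AUC, Brier, calibration."""
    import joblib

    out = Path(config.out_dir)
    bundle = joblib.load(_require(out / "model.joblib", "usradiomics train"))
    model: LesionRandomForest = bundle["model"]
    reduced = pd.read_csv(_require(out / "features_selected.csv", "usradiomics select"))
    test = reduced[reduced["split"] == "test"].reset_index(drop=True)
    proba = model.predict_proba(test)
    truth = (test["class_label"] == POSITIVE_CLASS).to_numpy()
    ct = ConfusionTable.from_calls(truth, proba >= 0.5)
    report = confusion_metrics(ct)
    nir, p_nir = nir_test(ct)
    roc = roc_auc(truth, proba)
    payload = {
        **report.to_dict(),
        "nir": nir,
        "p_vs_nir": p_nir,
        "auc": roc.auc,
        "auc_ci95": [roc.ci_low, roc.ci_high],
        "brier": brier_score(truth, proba),
    }
    io.write_json(out / "metrics.json", payload)
    io.write_csv(out / "roc.csv", roc.curve)
    io.write_csv(
        out / "calibration.csv",
        calibration_table(truth, proba, config.evaluation.calibration_bins),
    )
    predictions = test[["lesion_id", "class_label"]].copy()
    predictions["probability_malignant"] = proba
    predictions["call"] = np.where(proba >= 0.5, MALIGNANT, "benign")
    io.write_csv(out / "predictions.csv", predictions)
    return payload


def cmd_compare(config: RunConfig, readings_csv: str | Path) -> dict:
    """McNemar comparison between two paired readings of the test lesions.

    ``readings_csv`` columns: lesion_id, truth, reading_a, reading_b, with
    calls as 'benign'/'malignant'.
    """
    readings = pd.read_csv(readings_csv)
    truth = readings["truth"] == MALIGNANT
    result = mcnemar_from_readings(
        truth, readings["reading_a"] == MALIGNANT, readings["reading_b"] == MALIGNANT
    )
    payload = {
        "p_value": result.p_value,
        "b": result.b,
        "c": result.c,
        "method": result.method,
        "no_discordance": result.no_discordance,
    }
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    io.write_json(out / "mcnemar.json", payload)
    return payload
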