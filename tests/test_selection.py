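"""The selection cascade: scaling, variance/correlation pruning, SMOTE, RFECV."""

import numpy as np
import pandas as pd
import pytest

from usradiomics.selection import (
    SelectionPipeline,
    apply_minmax,
    correlation_filter,
    fit_minmax,
    rfecv,
    smote,
    smote_balance,
    variance_filter,
)


def _table(arrays: dict) -> pd.DataFrame:
    return pd.DataFrame({k: np.asarray(v, float) for k, v in arrays.items()})


class TestMinMax:
    def test_simple_mapping(self):
        params = fit_minmax(_table({"f": [2, 4, 6]}), ["f"])
        out = apply_minmax(_table({"f": [2, 4, 6]}), params)
        assert out["f"].tolist() == [0.0, 0.5, 1.0]

    def test_test_values_not_clipped(self):
        params = fit_minmax(_table({"f": [2, 4, 6]}), ["f"])
        out = apply_minmax(_table({"f": [8, 0]}), params)
        assert out["f"].tolist() == [1.5, -0.5]

    def test_constant_column_maps_to_zero(self):
        params = fit_minmax(_table({"f": [3, 3, 3]}), ["f"])
        out = apply_minmax(_table({"f": [3, 3]}), params)
        assert out["f"].tolist() == [0.0, 0.0]

    def test_params_come_from_train_only(self, rng):
        train = _table({"f": rng.uniform(0, 10, 30)})
        params = fit_minmax(train, ["f"])
        test1 = _table({"f": rng.uniform(-5, 20, 10)})
        test2 = _table({"f": rng.uniform(-5, 20, 10)})
        apply_minmax(test1, params)
        # applying to different test data leaves the params untouched
        assert np.array_equal(params.data_min, fit_minmax(train, ["f"]).data_min)
        a = apply_minmax(test2, params)
        b = apply_minmax(test2, params)
        pd.testing.assert_frame_equal(a, b)


class TestVarianceFilter:
    def test_constant_dropped_binary_kept(self):
        table = _table({"const": [5.0] * 50, "binary": [0, 1] * 25})
        kept, variances = variance_filter(table, ["const", "binary"])
        assert kept == ["binary"]
        assert variances["const"] == 0.0
        assert variances["binary"] > 0.01

    def test_boundary_is_inclusive_drop(self):
        # engineer a column with variance exactly 0.01 (values mu +/- 0.1)
        table = _table({"edge": [0.4, 0.6] * 10, "keep": np.linspace(0, 1, 20)})
        assert table["edge"].to_numpy().var() == pytest.approx(0.01)
        kept, _ = variance_filter(table, ["edge", "keep"])
        assert kept == ["keep"]


class TestCorrelationFilter:
    def test_duplicate_column_loses_one(self, rng):
        x = rng.normal(size=100)
        table = _table({"a": x, "b": x.copy(), "c": rng.normal(size=100)})
        kept, dropped = correlation_filter(table, ["a", "b", "c"])
        assert "c" in kept
        assert len([f for f in kept if f in ("a", "b")]) == 1
        assert dropped[0][1] == pytest.approx(1.0)

    def test_mutually_correlated_trio_one_survivor(self, rng):
        base = rng.normal(size=200)
        table = _table({
            "a": base + rng.normal(scale=0.1, size=200),
            "b": base + rng.normal(scale=0.1, size=200),
            "c": base + rng.normal(scale=0.1, size=200),
            "d": rng.normal(size=200),
        })
        kept, _ = correlation_filter(table, ["a", "b", "c", "d"])
        assert len([f for f in kept if f in ("a", "b", "c")]) <= 1
        assert "d" in kept

    def test_independent_columns_all_retained(self, rng):
        table = _table({f"f{i}": rng.normal(size=500) for i in range(10)})
        kept, dropped = correlation_filter(table, list(table.columns))
        assert dropped == []
        assert len(kept) == 10

    def test_deterministic(self, rng):
        base = rng.normal(size=80)
        table = _table({
            "a": base, "b": base + rng.normal(scale=0.05, size=80),
            "c": rng.normal(size=80),
        })
        first = correlation_filter(table, ["a", "b", "c"])
        second = correlation_filter(table, ["a", "b", "c"])
        assert first == second

    def test_zero_variance_column_rejected(self):
        table = _table({"const": [1.0] * 10, "x": np.arange(10)})
        with pytest.raises(ValueError, match="variance"):
            correlation_filter(table, ["const", "x"])


class TestSmote:
    def test_study_counts_44_vs_91(self, rng):
        table = _table({f"f{i}": rng.normal(size=135) for i in range(4)})
        table.insert(0, "lesion_id", [f"L{i}" for i in range(135)])
        labels = pd.Series(["malignant"] * 44 + ["benign"] * 91)
        out, out_labels = smote_balance(table, labels, [f"f{i}" for i in range(4)], 7)
        assert len(out) == 135 + 47
        assert (out_labels == "malignant").sum() == 91
        assert (out_labels == "benign").sum() == 91

    def test_synthetic_rows_lie_on_neighbor_segments(self, rng):
        x = rng.normal(size=(30, 5))
        syn = smote(x, 40, rng_seed=3, k_neighbors=5)
        d2 = ((x[:, None, :] - x[None, :, :]) ** 2).sum(axis=2)
        np.fill_diagonal(d2, np.inf)
        nn = np.argsort(d2, axis=1)[:, :5]
        for s in syn:
            found = False
            for i in range(len(x)):
                for j in nn[i]:
                    seg = x[j] - x[i]
                    denom = float(seg @ seg)
                    if denom == 0:
                        continue
                    u = float((s - x[i]) @ seg) / denom
                    if -1e-9 <= u <= 1 + 1e-9 and np.allclose(x[i] + u * seg, s, atol=1e-8):
                        found = True
                        break
                if found:
                    break
            assert found, "synthetic row off every base-neighbor segment"

    def test_interpolation_endpoint(self, rng):
        # u ~ U(0,1) can be arbitrarily close to 0: check the formula directly
        x = rng.normal(size=(10, 3))
        syn = smote(x, 200, rng_seed=1, k_neighbors=3)
        assert syn.shape == (200, 3)

    def test_deterministic_per_seed(self, rng):
        x = rng.normal(size=(20, 4))
        assert np.array_equal(smote(x, 10, 5), smote(x, 10, 5))
        assert not np.array_equal(smote(x, 10, 5), smote(x, 10, 6))

    def test_too_few_minority_rows(self, rng):
        with pytest.raises(ValueError, match="lower k"):
            smote(rng.normal(size=(5, 3)), 10, 0, k_neighbors=5)

    def test_single_class_rejected(self, rng):
        table = _table({"f": rng.normal(size=10)})
        table.insert(0, "lesion_id", [f"L{i}" for i in range(10)])
        with pytest.raises(ValueError, match="single-class"):
            smote_balance(table, pd.Series(["benign"] * 10), ["f"], 0)


class TestRfecv:
    @staticmethod
    def _informative_data(rng, n=200, n_noise=20):
        labels = pd.Series(["benign", "malignant"] * (n // 2))
        y = (labels == "malignant").to_numpy().astype(float)
        data = {f"noise{i}": rng.normal(size=n) for i in range(n_noise)}
        data["signal_a"] = y * 2 + rng.normal(scale=0.5, size=n)
        data["signal_b"] = -y * 2 + rng.normal(scale=0.5, size=n)
        return _table(data), labels

    def test_recovers_informative_features(self):
        hits = 0
        n_seeds = 10
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            table, labels = self._informative_data(rng)
            selected, _ = rfecv(table, labels, list(table.columns), rng_seed=seed)
            if {"signal_a", "signal_b"} <= set(selected):
                hits += 1
        assert hits >= int(0.95 * n_seeds)

    def test_single_feature_passthrough(self, rng):
        table = _table({"only": rng.normal(size=40)})
        selected, _ = rfecv(table, pd.Series(["a", "b"] * 20), ["only"], 0, n_folds=2)
        assert selected == ["only"]

    def test_small_minority_rejected(self, rng):
        table = _table({"f": rng.normal(size=12), "g": rng.normal(size=12)})
        labels = pd.Series(["benign"] * 9 + ["malignant"] * 3)
        with pytest.raises(ValueError, match="fold"):
            rfecv(table, labels, ["f", "g"], 0, n_folds=10)


class TestPipelineLeakageGuards:
    def _fit(self, rng, test_rows):
        n = 60
        labels = pd.Series(["benign"] * 36 + ["malignant"] * 24)
        y = (labels == "malignant").to_numpy().astype(float)
        table = _table({f"f{i}": rng.normal(size=n) for i in range(8)})
        table["f0"] = y + rng.normal(scale=0.3, size=n)
        table.insert(0, "lesion_id", [f"L{i}" for i in range(n)])
        pipe = SelectionPipeline(rfecv_folds=5, rng_seed=9)
        pipe.fit(table, labels, [f"f{i}" for i in range(8)])
        transformed = pipe.transform(test_rows)
        return pipe, transformed

    def test_test_rows_do_not_influence_fit(self, rng):
        test_a = _table({f"f{i}": np.random.default_rng(1).normal(size=10) for i in range(8)})
        test_a.insert(0, "lesion_id", [f"T{i}" for i in range(10)])
        test_b = _table({f"f{i}": np.random.default_rng(2).normal(size=10) * 100 for i in range(8)})
        test_b.insert(0, "lesion_id", [f"T{i}" for i in range(10)])
        pipe_a, _ = self._fit(np.random.default_rng(5), test_a)
        pipe_b, _ = self._fit(np.random.default_rng(5), test_b)
        assert np.array_equal(pipe_a.scaler_.data_min, pipe_b.scaler_.data_min)
        assert np.array_equal(pipe_a.scaler_.data_max, pipe_b.scaler_.data_max)
        assert pipe_a.selected_features_ == pipe_b.selected_features_
        assert [s.removed for s in pipe_a.report_.stages] == [
            s.removed for s in pipe_b.report_.stages
        ]

    def test_report_counts_non_increasing(self, rng):
        pipe, _ = self._fit(rng, _table({f"f{i}": rng.normal(size=3) for i in range(8)})
                            .assign(lesion_id=["a", "b", "c"]))
        counts = [s.n_remaining for s in pipe.report_.stages]
        assert counts == sorted(counts, reverse=True)

    def test_smote_rows_never_in_transform_output(self, rng):
        test = _table({f"f{i}": rng.normal(size=5) for i in range(8)})
        test.insert(0, "lesion_id", [f"T{i}" for i in range(5)])
        pipe, transformed = self._fit(rng, test)
        assert len(transformed) == 5
        assert not transformed.filter(like="SMOTE").size
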