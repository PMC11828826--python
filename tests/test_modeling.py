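"""Evaluation-design tests: splits, CV, sweep, ablation, explanation."""

import numpy as np
import pandas as pd
import pytest

from emovmd.errors import ConfigurationError
from emovmd.features import feature_columns
from emovmd.modeling import (
    CVSpec,
    ModelSpec,
    SplitSpec,
    ablation_table,
    best_single_cell,
    build_model,
    explain,
    split_data,
    sweep_windows,
    train_eval,
)


def _blob_features(n_per_class=30, n_features=25, seed=0, informative=True):
    """Three well-separated Gaussian blobs as a feature table."""
    rng = np.random.default_rng(seed)
    rows, labels = [], []
    centers = {"happy": 0.0, "sad": 8.0, "fear": 16.0}
    for cls, center in centers.items():
        block = rng.normal(center if informative else 0.0, 1.0, (n_per_class, n_features))
        rows.append(np.abs(block))
        labels += [cls] * n_per_class
    table = pd.DataFrame(np.vstack(rows), columns=feature_columns(5))
    table["label"] = labels
    table["segment_id"] = np.arange(len(table)) // 5
    return table


class TestSplit:
    def test_stratified_80_20_arithmetic(self):
        feats = _blob_features(30)
        train, test = split_data(feats, SplitSpec(seed=0))
        assert len(train) == 72 and len(test) == 18
        assert test["label"].value_counts().to_dict() == {"happy": 6, "sad": 6, "fear": 6}

    def test_same_seed_same_partition(self):
        feats = _blob_features(30)
        t1, _ = split_data(feats, SplitSpec(seed=3))
        t2, _ = split_data(feats, SplitSpec(seed=3))
        pd.testing.assert_frame_equal(t1, t2)

    def test_single_class_rejected(self):
        feats = _blob_features(30)
        feats["label"] = "happy"
        with pytest.raises(ConfigurationError):
            split_data(feats, SplitSpec())

    def test_by_trial_grouping_keeps_segments_together(self):
        feats = _blob_features(30)
        train, test = split_data(feats, SplitSpec(seed=1, grouping="by_trial"))
        assert set(train["segment_id"]).isdisjoint(set(test["segment_id"]))


class TestTrainEval:
    @pytest.mark.parametrize("kind", ["RF", "KNN"])
    def test_separable_blobs_perfect_test_accuracy(self, kind):
        feats = _blob_features(30)
        report = train_eval(feats, ModelSpec(kind=kind, seed=0), SplitSpec(seed=0), CVSpec(seed=0))
        assert report.test_accuracy == 1.0

    def test_confusion_matrix_conservation(self):
        feats = _blob_features(30, informative=False)
        report = train_eval(feats, ModelSpec(seed=0), SplitSpec(seed=0), CVSpec(seed=0))
        assert report.confusion.sum() == report.n_test
        assert np.trace(report.confusion) / report.n_test == pytest.approx(
            report.test_accuracy
        )
        assert 0 <= report.validation_accuracy <= 1

    def test_reports_identical_under_fixed_seeds(self):
        feats = _blob_features(30)
        r1 = train_eval(feats, ModelSpec(seed=2), SplitSpec(seed=2), CVSpec(seed=2))
        r2 = train_eval(feats, ModelSpec(seed=2), SplitSpec(seed=2), CVSpec(seed=2))
        assert r1.to_dict() == r2.to_dict()

    def test_too_many_folds_rejected(self):
        feats = _blob_features(5)
        with pytest.raises(ConfigurationError):
            train_eval(feats, ModelSpec(), SplitSpec(), CVSpec(n_folds=10))

    def test_label_permutation_gives_chance_accuracy(self, planted_dataset):
        _rec, _truth, features = planted_dataset
        rng = np.random.default_rng(123)
        accs = []
        for rep in range(20):
            shuffled = features.copy()
            shuffled["label"] = rng.permutation(shuffled["label"].to_numpy())
            report = train_eval(
                shuffled, ModelSpec(seed=rep), SplitSpec(seed=rep), CVSpec(seed=rep)
            )
            accs.append(report.test_accuracy)
        n_total = 20 * report.n_test
        half_width = 2.576 * np.sqrt((1 / 3) * (2 / 3) / n_total)
        assert abs(np.mean(accs) - 1 / 3) <= half_width


class TestSweep:
    def test_single_cell_consistent_with_train_eval(self, planted_dataset):
        from emovmd.features import WindowSpec, extract_features
        from emovmd.preprocess import bandpass_zero_phase, ica_remove_ocular, sg_detrend
        from emovmd.synth import ParadigmSpec, generate_recording

        spec = ParadigmSpec(n_phases=2)
        rec, _ = generate_recording(spec, seed=44)
        cleaned = sg_detrend(bandpass_zero_phase(rec))
        table = sweep_windows(
            cleaned,
            lengths_s=[3.0],
            models=[ModelSpec(kind="RF", seed=1)],
            split=SplitSpec(seed=1),
            cv=CVSpec(seed=1),
        )
        assert len(table) == 1
        feats = extract_features(cleaned, WindowSpec(3.0, 0.5))
        report = train_eval(feats, ModelSpec(kind="RF", seed=1), SplitSpec(seed=1), CVSpec(seed=1))
        assert table.loc[0, "validation_accuracy"] == pytest.approx(
            report.validation_accuracy
        )
        assert table.loc[0, "test_accuracy"] == pytest.approx(report.test_accuracy)

    def test_failing_cell_isolated(self):
        # 14 s single-label recording cannot host a 15 s window: that cell
        # errors, the 3 s cell is unaffected
        from emovmd.recording import Recording

        n = int(14 * 128)
        rng = np.random.default_rng(5)
        labels = np.full(n, "happy")
        labels[: n // 2] = "sad"
        rec = Recording(rng.standard_normal((2, n)), 128.0, ["Fp1", "Fp2"], labels)
        table = sweep_windows(
            rec,
            lengths_s=[3.0, 15.0],
            models=[ModelSpec(kind="DT", seed=0)],
            split=SplitSpec(seed=0),
            cv=CVSpec(n_folds=2, seed=0),
        )
        ok = table[table["window_s"] == 3.0].iloc[0]
        bad = table[table["window_s"] == 15.0].iloc[0]
        assert ok["error"] == ""
        assert bad["error"] != "" and np.isnan(bad["validation_accuracy"])


class TestAblation:
    def test_planted_cell_is_best_single_cell(self, planted_dataset, eval_specs):
        _rec, truth, features = planted_dataset
        model, split, cv = eval_specs
        table = ablation_table(features, model, split, cv)
        assert table.shape == (6, 6)
        single = table.iloc[:-1, :-1]
        planted = single.loc["IMF1", truth.discriminative_band]
        assert planted == single.to_numpy().max()
        # the deterministic reported best cell is the planted one
        assert best_single_cell(table) == ("IMF1", truth.discriminative_band)

    def test_combined_cell_at_least_best_single_minus_margin(
        self, planted_dataset, eval_specs
    ):
        _rec, truth, features = planted_dataset
        model, split, cv = eval_specs
        table = ablation_table(features, model, split, cv)
        best_single = table.iloc[:-1, :-1].to_numpy().max()
        assert table.loc["All IMFs", "Combined features"] >= best_single - 0.05

    def test_uninformative_features_stay_at_chance(self, eval_specs):
        model, split, cv = eval_specs
        feats = _blob_features(36, informative=False, seed=7)
        table = ablation_table(feats, model, split, cv)
        n_train_cv = int(len(feats) * 0.8)
        half_width = 2.576 * np.sqrt((1 / 3) * (2 / 3) / n_train_cv)
        assert ((table - 1 / 3).abs() <= 3 * half_width).all().all()


class TestExplain:
    def _fit_rf(self, features, seed=0):
        clf = build_model(ModelSpec(kind="RF", seed=seed))
        cols = [c for c in features.columns if c.startswith("IMF")]
        clf.fit(features[cols].to_numpy(), features["label"].to_numpy())
        return clf

    def test_planted_feature_ranks_first_tree_path(self, planted_dataset):
        _rec, truth, features = planted_dataset
        clf = self._fit_rf(features)
        report = explain(clf, features, method="tree_path")
        assert report.ranking[0] == truth.discriminative_column()
        assert len(report.per_class) == 25

    def test_methods_agree_on_strong_signal(self, planted_dataset):
        _rec, truth, features = planted_dataset
        clf = self._fit_rf(features)
        tree_report = explain(clf, features, method="tree_path")
        perm_report = explain(clf, features, method="permutation", seed=1, n_repeats=10)
        assert tree_report.ranking[0] == perm_report.ranking[0]

    def test_constant_features_zero_attribution(self):
        feats = _blob_features(10)
        cols = feature_columns(5)
        feats[cols] = 1.0
        clf = self._fit_rf(feats)
        report = explain(clf, feats, method="tree_path")
        assert (report.per_class.to_numpy() <= 1e-9).all()

    def test_unfitted_model_rejected(self):
        from sklearn.exceptions import NotFittedError

        feats = _blob_features(10)
        clf = build_model(ModelSpec(kind="RF"))
        with pytest.raises(NotFittedError):
            explain(clf, feats)
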