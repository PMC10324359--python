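"""Feature assembly, imputation, undersampling and nested-CV decoding."""

import numpy as np
import pandas as pd
import pytest

from gaitdecode.decode import (FEATURE_COLUMNS, band_power_table,
                               build_feature_table, feature_importance,
                               fit_spectral_model, impute_missing,
                               nested_cv_classify, undersample, welch_psd)
from gaitdecode.errors import InsufficientDataError, InvalidArgumentError
from gaitdecode.kinematics import StatusSegment
from gaitdecode.preprocess import bipolar_montage, epoch_by_status
from gaitdecode.synthetic import simulate_status_recording

from conftest import gaussian_feature_table


def _epochs(layout, duration=8.0, seed=0):
    segs = [StatusSegment("standing", 0.0, duration)]
    rec, _ = simulate_status_recording(segs, layout=layout, seed=seed,
                                       subject="s1")
    rec = bipolar_montage(rec)
    return epoch_by_status(rec, segs)


class TestFeatureTable:
    def test_complete_case_has_32_finite_features(self):
        table = build_feature_table(_epochs({
            "ECOG": ["PMC", "PMC", "M1", "M1", "SPL", "SPL"],
            "STNL": ["STN_L", "STN_L"]}))
        assert list(table.columns[4:]) == FEATURE_COLUMNS
        assert len(table) == 4
        assert np.isfinite(table[FEATURE_COLUMNS].to_numpy()).all()

    def test_missing_region_yields_missing_columns(self):
        table = build_feature_table(_epochs({
            "ECOG": ["PMC", "PMC", "M1", "M1"],
            "STNL": ["STN_L", "STN_L"]}))
        spl_cols = [c for c in FEATURE_COLUMNS if c.startswith("SPL_")]
        other = [c for c in FEATURE_COLUMNS if not c.startswith("SPL_")]
        assert table[spl_cols].isna().all().all()
        assert np.isfinite(table[other].to_numpy()).all()

    def test_region_feature_is_channel_mean(self):
        epochs = _epochs({"E1": ["SPL", "SPL", "SPL"]}, seed=5)
        table = build_feature_table(epochs)
        ep = epochs[0]
        per_channel = []
        for ch in range(ep.data.shape[0]):
            model = fit_spectral_model(welch_psd(ep.data[ch], ep.fs))
            per_channel.append(band_power_table(model)["all_beta"])
        assert table.loc[0, "SPL_all_beta"] == pytest.approx(
            np.mean(per_channel))


class TestImpute:
    def test_train_mean_fills_both_tables(self):
        train = gaussian_feature_table(n_per_class=3, seed=1)
        col = FEATURE_COLUMNS[0]
        train.loc[train.index[2], col] = np.nan
        expected = train[col].dropna().mean()
        test = train.copy()
        test[col] = np.nan
        tr, te = impute_missing(train, test)
        assert tr.loc[tr.index[2], col] == pytest.approx(expected)
        assert np.allclose(te[col], expected)

    def test_simple_mean_example(self):
        train = gaussian_feature_table(n_per_class=1, n_classes=3, seed=0)
        col = FEATURE_COLUMNS[5]
        train[col] = [1.0, 3.0, np.nan]
        tr, _ = impute_missing(train)
        assert tr[col].tolist() == [1.0, 3.0, 2.0]

    def test_no_missing_is_identity(self):
        train = gaussian_feature_table(n_per_class=4, seed=2)
        tr, te = impute_missing(train, train)
        pd.testing.assert_frame_equal(tr, train)
        pd.testing.assert_frame_equal(te, train)

    def test_all_missing_column_raises_with_name(self):
        train = gaussian_feature_table(n_per_class=3, seed=3)
        train[FEATURE_COLUMNS[7]] = np.nan
        with pytest.raises(InvalidArgumentError, match=FEATURE_COLUMNS[7]):
            impute_missing(train)


class TestUndersample:
    def test_downsampled_to_minority(self):
        parts = [gaussian_feature_table(n, 1, seed=i).assign(label=lab)
                 for i, (lab, n) in enumerate(
                     [("walking", 100), ("sitting", 60), ("freeze", 30)])]
        table = pd.concat(parts, ignore_index=True)
        out = undersample(table, seed=0)
        assert out["label"].value_counts().tolist() == [30, 30, 30]

    def test_balanced_table_unchanged(self):
        table = gaussian_feature_table(n_per_class=20, seed=4)
        out = undersample(table, seed=1)
        assert sorted(out.index) == sorted(table.index)

    def test_deterministic_under_seed(self):
        table = pd.concat([
            gaussian_feature_table(50, 1, seed=0).assign(label="walking"),
            gaussian_feature_table(20, 1, seed=1).assign(label="freeze"),
        ], ignore_index=True)
        a = undersample(table, seed=11)
        b = undersample(table, seed=11)
        assert a.index.tolist() == b.index.tolist()

    def test_empty_class_rejected(self):
        table = gaussian_feature_table(n_per_class=5, n_classes=1, seed=0)
        with pytest.raises(InvalidArgumentError):
            undersample(table)


class TestNestedCV:
    def test_separable_classes_decoded(self, feature_table_factory):
        table = feature_table_factory(n_per_class=30, separation=3.0, seed=0)
        res = nested_cv_classify(table, n_search=2, outer_k=3, inner_k=3,
                                 seed=0)
        assert res.mean_accuracy >= 90.0
        assert res.auc_macro >= 0.95

    def test_confusion_trace_matches_weighted_accuracy(self,
                                                       feature_table_factory):
        table = feature_table_factory(n_per_class=25, separation=1.0, seed=1)
        res = nested_cv_classify(table, n_search=2, outer_k=3, inner_k=3,
                                 seed=1)
        pooled = np.trace(res.confusion) / res.confusion.sum()
        weighted = np.average(res.fold_accuracies,
                              weights=res.fold_sizes) / 100.0
        assert pooled == pytest.approx(weighted, abs=1e-12)
        assert res.confusion.sum(axis=1).sum() == sum(res.fold_sizes)

    def test_reproducible_under_seed(self, feature_table_factory):
        table = feature_table_factory(n_per_class=20, separation=2.0, seed=2)
        a = nested_cv_classify(table, n_search=2, outer_k=3, inner_k=3, seed=5)
        b = nested_cv_classify(table, n_search=2, outer_k=3, inner_k=3, seed=5)
        assert a.to_dict() == b.to_dict()

    def test_rare_class_rejected(self, feature_table_factory):
        table = feature_table_factory(n_per_class=10, seed=3)
        table = table[~((table["label"] == "freeze")
                        & (table.groupby("label").cumcount() >= 3))]
        with pytest.raises(InsufficientDataError):
            nested_cv_classify(table, n_search=1, outer_k=5)

    def test_importance_sums_to_one(self, feature_table_factory):
        table = feature_table_factory(n_per_class=20, separation=2.0, seed=6)
        res = nested_cv_classify(table, n_search=1, outer_k=3, inner_k=3,
                                 seed=0)
        assert res.importances.sum() == pytest.approx(1.0)
        assert (res.importances >= 0).all()


class TestImportance:
    def test_single_informative_feature_ranks_first(self):
        table = gaussian_feature_table(n_per_class=40, n_classes=2,
                                       separation=3.0, seed=7,
                                       n_informative=1)
        res = nested_cv_classify(table, n_search=2, outer_k=3, inner_k=3,
                                 seed=0)
        ranked = feature_importance(res)
        assert ranked[0][0] == FEATURE_COLUMNS[0]
        assert ranked[0][1] > 0.5

    def test_pure_noise_importance_is_diffuse(self):
        max_shares = []
        for seed in range(8):
            table = gaussian_feature_table(n_per_class=30, separation=0.0,
                                           seed=seed)
            res = nested_cv_classify(table, n_search=1, outer_k=3, inner_k=3,
                                     seed=seed)
            max_shares.append(feature_importance(res)[0][1])
        assert max(max_shares) < 0.2

    def test_no_signal_auc_near_chance(self, feature_table_factory):
        table = feature_table_factory(n_per_class=40, separation=0.0, seed=9)
        res = nested_cv_classify(table, n_search=1, outer_k=3, inner_k=3,
                                 seed=2)
        assert res.auc_macro == pytest.approx(0.5, abs=0.08)


class TestLeakageContracts:
    def test_imputation_ignores_test_values(self):
        train = gaussian_feature_table(n_per_class=10, seed=10)
        col = FEATURE_COLUMNS[3]
        train.loc[train.index[0], col] = np.nan
        test_a = gaussian_feature_table(n_per_class=5, seed=11)
        test_b = test_a.copy()
        test_b[FEATURE_COLUMNS] += 1000.0  # extreme test values
        tr_a, _ = impute_missing(train, test_a)
        tr_b, _ = impute_missing(train, test_b)
        pd.testing.assert_frame_equal(tr_a, tr_b)

    def test_undersample_only_drops_majority_rows(self):
        table = pd.concat([
            gaussian_feature_table(40, 1, seed=0).assign(label="walking"),
            gaussian_feature_table(15, 1, seed=1).assign(label="freeze"),
        ], ignore_index=True)
        out = undersample(table, seed=3)
        minority = table[table["label"] == "freeze"]
        assert minority.index.isin(out.index).all()
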