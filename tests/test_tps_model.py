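"""Feature engineering, preprocessing filters, splitting, training."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from tpsdate.io_formats import DatingMethod, SampleRecord
from tpsdate.tps_model import (
    FEATURE_NAMES,
    engineer_features,
    predict,
    predict_with_uncertainty,
    preprocess,
    stratified_split,
    train,
)


def random_profiles(rng, n):
    q = rng.dirichlet(np.ones(8), size=n)
    return pd.DataFrame(q, index=[f"s{i}" for i in range(n)],
                        columns=[f"c{k}" for k in range(8)])


class TestEngineerFeatures:
    def test_quoted_construction_example(self):
        profile = np.array([[0.5, 0.1, 0.1, 0.2, 0.1, 0.0, 0.0, 0.0]])
        X, _ = engineer_features(profile, mode="apply", mu_c1=0.3)
        row = X.iloc[0]
        assert row["ancient_mean"] == pytest.approx(0.2)
        assert row["c1_dev"] == pytest.approx(0.2)
        assert row["c1_adj"] == pytest.approx(1.1)

    def test_fit_mode_fixed_point_when_c1_equals_mean(self, rng):
        q = random_profiles(rng, 20)
        rest = q.iloc[:, 1:].div(q.iloc[:, 1:].sum(axis=1), axis=0) * 0.75
        q = pd.concat([pd.Series(0.25, index=q.index, name="c0"), rest], axis=1)
        X, mu = engineer_features(q, mode="fit")
        assert mu == pytest.approx(q.iloc[0, 0])
        np.testing.assert_allclose(X["c1_dev"], 0.0, atol=1e-12)
        np.testing.assert_allclose(X["c1_adj"], q.iloc[:, 0], atol=1e-12)

    def test_rowwise_map_order_invariant(self, rng):
        q = random_profiles(rng, 15)
        X, mu = engineer_features(q, mode="fit")
        perm = rng.permutation(15)
        Xp, _ = engineer_features(q.iloc[perm], mode="apply", mu_c1=mu)
        pd.testing.assert_frame_equal(Xp.sort_index(), X.sort_index())

    def test_apply_without_stored_mean_rejected(self, rng):
        with pytest.raises(ValueError, match="stored"):
            engineer_features(random_profiles(rng, 3), mode="apply")

    def test_feature_count_and_order(self, rng):
        X, _ = engineer_features(random_profiles(rng, 4), mode="fit")
        assert tuple(X.columns) == FEATURE_NAMES


def _record(sid, date, sd=50.0, method=DatingMethod.RADIOCARBON_DIRECT, country="X"):
    return SampleRecord(sid, date, sd, method, country)


def toy_preprocess_table():
    """A hand-checkable cohort exercising every removal rule exactly once.

    A0 exceeds the age cap; A1 has an unusable dating method; B0 is the
    single feature outlier among the twelve rule-survivor ancients AND
    carries a wide date SD; B1 has a wide SD but ordinary features; M is
    modern. Hand application leaves 10 ancient + 1 modern.
    """
    records = [
        _record("A0", 12000.0),
        _record("A1", 9000.0, method=DatingMethod.OTHER),
        _record("B0", 8000.0, sd=900.0),
        _record("B1", 7000.0, sd=900.0),
    ]
    records += [_record(f"B{i}", 6500.0 - 400 * i) for i in range(2, 12)]
    records.append(SampleRecord("M", 10.0, 0.0, DatingMethod.MODERN))

    base = np.array([0.4, 0.2, 0.1, 0.1, 0.05, 0.05, 0.05, 0.05])
    outlier = np.array([0.05, 0.05, 0.05, 0.05, 0.4, 0.1, 0.1, 0.2])
    rows = {r.sample_id: base for r in records}
    rows["B0"] = outlier
    profiles = pd.DataFrame.from_dict(rows, orient="index",
                                      columns=[f"c{k}" for k in range(8)])
    return records, profiles


class TestPreprocess:
    def test_toy_table_matches_hand_application(self):
        records, profiles = toy_preprocess_table()
        result = preprocess(records, profiles)
        removed = dict(zip(result.ledger["sample_id"], result.ledger["rule"]))
        assert removed == {"A0": "max_age", "A1": "dating_method", "B0": "z_outlier"}
        assert set(result.retained) == {f"B{i}" for i in range(1, 12)} | {"M"}

        # independent z-score audit over the rule-i/ii ancient survivors
        survivors_12 = [f"B{i}" for i in range(12)]
        X, _ = engineer_features(profiles.loc[survivors_12], mode="fit")
        x = X.to_numpy()
        sd = x.std(axis=0)
        z = np.where(sd > 0, (x - x.mean(axis=0)) / np.where(sd > 0, sd, 1), 0)
        assert (np.abs(z[0]) >= 3).any()          # B0 is a genuine outlier
        assert not (np.abs(z[1:]) >= 3).any()

    def test_conjunction_spares_narrow_sd_outliers(self):
        records, profiles = toy_preprocess_table()
        for r in records:
            if r.sample_id == "B0":
                r.date_sd = 50.0  # outlier features, but tight date
        result = preprocess(records, profiles)
        assert "B0" in result.retained
        result_or = preprocess(records, profiles, combine="or")
        assert "B0" not in result_or.retained

    def test_identical_features_no_z_removals(self):
        records = [_record(f"S{i}", 1000.0 + i) for i in range(12)]
        profiles = pd.DataFrame(
            np.tile(np.full(8, 0.125), (12, 1)),
            index=[r.sample_id for r in records],
        )
        result = preprocess(records, profiles)
        assert len(result.ledger) == 0

    def test_disabled_filters_are_identity(self):
        records, profiles = toy_preprocess_table()
        result = preprocess(
            records, profiles, max_age=np.inf,
            allowed_methods=frozenset(DatingMethod), z_thresh=np.inf,
        )
        assert set(result.retained) == {r.sample_id for r in records}

    def test_empty_survivor_set_rejected(self):
        records = [_record("A", 12000.0)]
        profiles = pd.DataFrame([np.full(8, 0.125)], index=["A"])
        with pytest.raises(ValueError):
            preprocess(records, profiles, max_age=10000.0)


class TestStratifiedSplit:
    def test_ten_equal_strata_allocates_fifteen(self):
        records = [
            _record(f"S{b}_{i}", 250.0 + 500 * b, country="X")
            for b in range(10)
            for i in range(10)
        ]
        split = stratified_split(records, seed=0)
        assert abs(len(split.unseen) - 15) <= 1
        assert len(split.train) + len(split.validation) + len(split.unseen) == 100
        assert not (set(split.train) & set(split.unseen))

    def test_singleton_stratum_goes_to_training(self):
        records = [_record(f"S{i}", 250.0, country="X") for i in range(20)]
        records.append(_record("LONE", 9750.0, country="Far"))
        for seed in range(10):
            split = stratified_split(records, seed=seed)
            assert "LONE" in split.train

    def test_partition_is_disjoint_and_exhaustive(self, small_cohort):
        split = stratified_split(small_cohort.records, seed=3)
        parts = [set(split.train), set(split.validation), set(split.unseen)]
        assert sum(len(p) for p in parts) == len(small_cohort.records)
        assert not (parts[0] & parts[1] or parts[0] & parts[2] or parts[1] & parts[2])

    def test_same_seed_identical(self, small_cohort):
        a = stratified_split(small_cohort.records, seed=5)
        b = stratified_split(small_cohort.records, seed=5)
        assert a.as_dict() == b.as_dict()

    def test_invalid_fractions_rejected(self, small_cohort):
        with pytest.raises(ValueError):
            stratified_split(small_cohort.records, unseen_frac=0.8, val_frac=0.3)


def monotone_training_set(rng, n=200):
    dates = np.linspace(500, 9500, n)
    q = np.zeros((n, 8))
    q[:, 0] = dates / 10000.0
    q[:, 1] = 1.0 - q[:, 0]
    X, mu = engineer_features(q + rng.normal(0, 1e-4, q.shape), mode="fit")
    return X, dates, mu


class TestTrain:
    def test_recovers_monotone_signal(self, rng):
        X, dates, _ = monotone_training_set(rng)
        model = train(X, dates, seed=0)
        err = np.abs(predict(model, X) - dates)
        assert np.median(err) < 0.05 * (dates.max() - dates.min())

    def test_single_tree_memorizes(self, rng):
        X, dates, _ = monotone_training_set(rng, n=60)
        model = train(X, dates, n_trees=1, folds=5, seed=0,
                      rf_params={"bootstrap": False})
        err = np.abs(predict(model, X) - dates)
        assert np.median(err) < 1e-6

    def test_deterministic_predictions(self, rng):
        X, dates, _ = monotone_training_set(rng)
        probe = X.iloc[:10]
        a = predict(train(X, dates, seed=9), probe)
        b = predict(train(X, dates, seed=9), probe)
        np.testing.assert_array_equal(a, b)

    def test_cv_errors_recorded_and_policy(self, rng):
        X, dates, _ = monotone_training_set(rng)
        model = train(X, dates, folds=10, seed=1, final_model="best_validation")
        assert len(model.cv_errors) == 10
        assert model.replica == int(np.argmin(model.cv_errors))

    def test_too_many_folds_rejected(self, rng):
        X, dates, _ = monotone_training_set(rng, n=8)
        with pytest.raises(ValueError, match="folds"):
            train(X, dates, folds=10)


class TestPredict:
    def test_within_training_range_and_duplicates_agree(self, rng):
        X, dates, _ = monotone_training_set(rng)
        model = train(X, dates, seed=0)
        preds = predict(model, X)
        assert preds.min() >= dates.min() and preds.max() <= dates.max()
        dup = pd.concat([X.iloc[[3]], X.iloc[[3]]])
        p = predict(model, dup)
        assert p[0] == p[1]

    def test_wrong_feature_count_rejected(self, rng):
        X, dates, _ = monotone_training_set(rng)
        model = train(X, dates, seed=0)
        with pytest.raises(ValueError, match="10 features"):
            predict(model, np.zeros((2, 7)))


class TestUncertainty:
    def test_degenerate_training_dates(self, rng):
        X, _, _ = monotone_training_set(rng, n=40)
        pred = predict_with_uncertainty(X, np.full(40, 3000.0), X.iloc[0].to_numpy(),
                                        seed=0)
        assert pred.date_hat == pytest.approx(3000.0)
        assert pred.sd == 0.0
        assert pred.ci95 == (pytest.approx(3000.0), pytest.approx(3000.0))

    def test_sem_definition(self, rng):
        X, dates, _ = monotone_training_set(rng, n=80)
        pred = predict_with_uncertainty(X.iloc[1:], dates[1:], X.iloc[0].to_numpy(),
                                        repeats=10, seed=2)
        assert pred.sem == pytest.approx(pred.sd / np.sqrt(10))
        assert pred.ci95[0] <= pred.date_hat <= pred.ci95[1]

    def test_single_repeat_rejected(self, rng):
        X, dates, _ = monotone_training_set(rng, n=40)
        with pytest.raises(ValueError, match="repeats"):
            predict_with_uncertainty(X, dates, X.iloc[0].to_numpy(), repeats=1)

    def test_seed_stability(self, rng):
        X, dates, _ = monotone_training_set(rng, n=120)
        x = X.iloc[60].to_numpy()
        a = predict_with_uncertainty(X.drop(X.index[60]), np.delete(dates, 60), x, seed=1)
        b = predict_with_uncertainty(X.drop(X.index[60]), np.delete(dates, 60), x, seed=2)
        pooled = np.sqrt((a.sd**2 + b.sd**2) / 2)
        assert abs(a.date_hat - b.date_hat) < 2 * max(pooled, 1.0)


def test_no_leakage_from_held_out_samples(rng):
    """Perturbing unseen profiles leaves every training artifact unchanged."""
    q = random_profiles(rng, 120)
    train_ids, unseen_ids = q.index[:90], q.index[90:]
    dates = rng.uniform(200, 9800, size=90)

    X1, mu1 = engineer_features(q.loc[train_ids], mode="fit")
    model1 = train(X1, dates, seed=4, mu_c1=mu1)

    q_perturbed = q.copy()
    q_perturbed.loc[unseen_ids] = rng.dirichlet(np.ones(8), size=30)
    X2, mu2 = engineer_features(q_perturbed.loc[train_ids], mode="fit")
    model2 = train(X2, dates, seed=4, mu_c1=mu2)

    assert mu1 == mu2
    assert model1.fingerprint == model2.fingerprint
    probe = rng.dirichlet(np.ones(8), size=5)
    Xp1, _ = engineer_features(probe, mode="apply", mu_c1=mu1)
    Xp2, _ = engineer_features(probe, mode="apply", mu_c1=mu2)
    np.testing.assert_array_equal(predict(model1, Xp1), predict(model2, Xp2))
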