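"""Accuracy reports, family adjustment, noise, controls, MAF curves."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from tpsdate.io_formats import MISSING, DatingMethod, SampleRecord
from tpsdate.postprocess_eval import (
    PAPER_GEO_PLANS,
    GeoClusterPlan,
    accuracy,
    family_postprocess,
    inject_noise,
    leave_geo_cluster_out,
    leave_window_out,
    maf_trajectory,
    pca_projection_control,
    random_matrix_control,
)


def _record(sid, date):
    return SampleRecord(sid, date, 50.0, DatingMethod.RADIOCARBON_DIRECT)


class TestAccuracy:
    def test_perfect_predictions(self):
        records = [_record(f"s{i}", 1000.0 * i) for i in range(1, 4)]
        preds = {r.sample_id: r.date_mean for r in records}
        report = accuracy(preds, records)
        assert report.median == 0.0
        assert (report.per_sample == 0).all()

    def test_single_sample_offset(self):
        report = accuracy({"s1": 1700.0}, [_record("s1", 1000.0)])
        assert report.median == 700.0

    def test_hand_computed_median(self):
        pairs = [(100.0, 0.0), (500.0, 400.0), (2000.0, 1500.0),
                 (3000.0, 4200.0), (9000.0, 8000.0)]
        records = [_record(f"s{i}", t) for i, (_, t) in enumerate(pairs)]
        preds = {f"s{i}": p for i, (p, _) in enumerate(pairs)}
        report = accuracy(preds, records)
        # |100-0|, |500-400|, |2000-1500|, |3000-4200|, |9000-8000|
        assert report.median == float(np.median([100, 100, 500, 1200, 1000]))
        assert report.frac_over_1000 == pytest.approx(1 / 5)

    def test_missing_record_named(self):
        with pytest.raises(KeyError, match="ghost"):
            accuracy({"ghost": 1.0}, [_record("s1", 100.0)])


def one_pass_family_rule(values):
    """Direct transcription of the percentile rule, single application."""
    m = float(np.median(values))
    p30, p70 = np.percentile(values, [30, 70])
    return np.where((values < p30) | (values > p70), m, values)


class TestFamilyPostprocess:
    def test_matches_direct_rule_on_tight_family(self):
        values = np.array([100.0, 110.0, 105.0])
        fam = {f"s{i}": "f" for i in range(3)}
        preds = pd.Series(values, index=list(fam))
        out = family_postprocess(preds, fam)
        expected = one_pass_family_rule(values)  # converges in one pass here
        np.testing.assert_allclose(out.to_numpy(), one_pass_family_rule(expected))

    def test_gross_outlier_collapses_to_median(self):
        fam = {f"s{i}": "f" for i in range(4)}
        preds = pd.Series([100.0, 100.0, 100.0, 5000.0], index=list(fam))
        out = family_postprocess(preds, fam)
        assert (out == 100.0).all()

    def test_pair_untouched(self):
        fam = {"a": "f", "b": "f"}
        preds = pd.Series([100.0, 900.0], index=["a", "b"])
        out = family_postprocess(preds, fam)
        pd.testing.assert_series_equal(out, preds)

    def test_samples_without_family_pass_through(self):
        preds = pd.Series([3.0, 4.0], index=["a", "b"])
        out = family_postprocess(preds, {"a": None, "b": None})
        pd.testing.assert_series_equal(out, preds)


class TestInjectNoise:
    def test_zero_level_identity(self, rng):
        q = rng.dirichlet(np.ones(8), size=50)
        out = inject_noise(q, 0.0, 1.0, seed=1)
        np.testing.assert_array_equal(out, q)

    def test_full_noise_counts_and_clipping(self, rng):
        q = rng.dirichlet(np.ones(8), size=200)
        out = inject_noise(q, 1.0, 1.0, seed=2)
        assert out.min() >= 0.0 and out.max() <= 1.0
        lo = np.percentile(q, 5, axis=0)
        hi = np.percentile(q, 95, axis=0)
        eligible = (q >= lo) & (q <= hi)
        changed = out != q
        # every modified cell was eligible; per-sample counts exact
        assert not (changed & ~eligible).any()
        np.testing.assert_array_equal(changed.sum(axis=1), eligible.sum(axis=1))

    def test_count_audit_partial_level(self, rng):
        q = rng.dirichlet(np.ones(8), size=100)
        out = inject_noise(q, 0.5, 1.0, seed=3, clip=False)
        lo = np.percentile(q, 5, axis=0)
        hi = np.percentile(q, 95, axis=0)
        eligible = (q >= lo) & (q <= hi)
        changed = (out != q).sum(axis=1)
        expected = np.round(0.5 * eligible.sum(axis=1))
        np.testing.assert_array_equal(changed, expected)

    def test_sample_fraction_respected(self, rng):
        q = rng.dirichlet(np.ones(8), size=100)
        out = inject_noise(q, 1.0, 0.25, seed=4)
        touched = (out != q).any(axis=1)
        assert touched.sum() <= 25

    def test_invalid_fraction_rejected(self, rng):
        with pytest.raises(ValueError):
            inject_noise(np.ones((3, 8)) / 8, 1.2, 0.5)


class TestLeaveWindowOut:
    def test_weighted_mean_audited_and_gaps_skipped(self, rng):
        n = 300
        y = np.concatenate([rng.uniform(0, 3000, 150), rng.uniform(6000, 9000, 150)])
        X = np.column_stack([y / 10000.0 + rng.normal(0, 0.01, n)] * 10)
        table, weighted = leave_window_out(X, y, n_windows=20, n_trees=10, folds=5, seed=0)
        # windows in (3000, 6000) are empty and must be absent
        assert not ((table["window_start"] >= 3000) & (table["window_start"] < 6000)).any()
        recomputed = (table["n"] * table["median_accuracy"]).sum() / table["n"].sum()
        assert weighted == pytest.approx(recomputed)


class TestLeaveGeoClusterOut:
    def test_group_means_and_degenerate_cluster(self, rng):
        n = 120
        y = rng.uniform(200, 9800, n)
        X = np.column_stack([y / 10000.0 + rng.normal(0, 0.02, n)] * 10)
        coords = rng.uniform(-10, 10, size=(n, 2))
        out = leave_geo_cluster_out(X, y, coords, GeoClusterPlan(1, 4, 5), seed=0)
        # brute-force group-mean audit
        keys = [tuple(np.round(coords[i], 1)) for i in range(n)]
        df = pd.DataFrame({"k": keys, "a": out["per_sample_accuracy"]})
        med = df.groupby("k")["a"].mean().median()
        assert out["median_of_group_means"] == pytest.approx(med)

        with pytest.raises(ValueError, match="training set empty"):
            leave_geo_cluster_out(
                X, y, np.zeros((n, 2)), GeoClusterPlan(1, 1, 5), seed=0
            )

    def test_published_plan_constants(self):
        assert [p.n_clusters for p in PAPER_GEO_PLANS] == [15, 40, 20, 30, 30, 15, 10]
        assert [p.folds for p in PAPER_GEO_PLANS] == [10, 10, 10, 10, 5, 10, 10]


class TestRandomMatrixControl:
    def test_no_signal_floor_is_stable_across_seeds(self, rng):
        dates = rng.uniform(200, 9800, 400)
        a = random_matrix_control(dates, seed=1, folds=5)
        b = random_matrix_control(dates, seed=2, folds=5)
        spread = abs(dates.mean() - np.median(dates))
        assert a.median > 500.0 and b.median > 500.0
        assert abs(a.median - b.median) < 0.5 * (a.median + b.median)


class TestPcaProjectionControl:
    def test_fixed_difference_panel(self, rng):
        m = 300
        p1 = np.full(m, 0.05)
        p2 = np.full(m, 0.95)
        modern = np.vstack(
            [rng.binomial(2, np.tile(p1, (20, 1))), rng.binomial(2, np.tile(p2, (20, 1)))]
        )
        ancient = rng.binomial(2, np.tile((p1 + p2) / 2, (5, 1)))
        out = pca_projection_control(modern, ancient, n_pcs=5)
        pc1 = out["modern_features"][:, 0]
        assert np.sign(pc1[:20]).min() != np.sign(pc1[20:]).max()  # separated
        anc1 = out["ancient_features"][:, 0]
        assert (anc1 > pc1.min()).all() and (anc1 < pc1.max()).all()

    def test_self_projection_consistency(self, rng):
        modern = rng.binomial(2, 0.4, size=(15, 50)).astype(float)
        out = pca_projection_control(modern, modern.copy(), n_pcs=5)
        np.testing.assert_allclose(
            out["ancient_features"], out["modern_features"], atol=1e-8
        )
        assert (np.diff(out["explained_variance"]) <= 1e-12).all()

    def test_excess_pcs_rejected(self, rng):
        with pytest.raises(ValueError):
            pca_projection_control(np.zeros((4, 10)), np.zeros((2, 10)), n_pcs=8)

    def test_missing_genotypes_imputed_from_modern(self, rng):
        modern = rng.binomial(2, 0.5, size=(10, 30)).astype(int)
        ancient = rng.binomial(2, 0.5, size=(4, 30))
        ancient[0, :15] = MISSING
        out = pca_projection_control(modern, ancient, n_pcs=3)
        assert np.isfinite(out["ancient_features"]).all()


class TestMafTrajectory:
    def test_all_reference_calls(self):
        calls = np.zeros(30, dtype=int)
        dates = np.linspace(0, 5000, 30)
        df = maf_trajectory(calls, dates, ["radiocarbon"] * 30)
        grp = df[df["group"] == "radiocarbon"]
        assert (grp["maf"] == 0).all()
        assert (grp["se"] == 0).all()

    def test_bin_arithmetic(self):
        calls = np.array([0] * 7 + [1] * 3)  # 3 minor alleles of 20
        dates = np.full(10, 250.0)
        df = maf_trajectory(calls, dates, ["radiocarbon"] * 10)
        row = df[df["group"] == "radiocarbon"].iloc[0]
        assert row["maf"] == pytest.approx(0.15)
        assert row["se"] == pytest.approx(np.sqrt(0.15 * 0.85 / 20))

    def test_combined_is_count_weighted(self):
        calls = np.array([0] * 6 + [1] * 4 + [0] * 2 + [2] * 3 + [1] * 5)
        # group A: 10 samples, 4/20 = 0.2; group B: 10 samples, 11/20 = 0.55
        dates = np.full(20, 100.0)
        groups = ["A"] * 10 + ["B"] * 10
        df = maf_trajectory(calls, dates, groups)
        combined = df[df["group"] == "combined"].iloc[0]
        assert combined["maf"] == pytest.approx((0.2 + 0.55) / 2)

    def test_empty_bin_left_as_gap(self):
        calls = np.array([1, 1, 0, 2])
        dates = np.array([100.0, 200.0, 2100.0, 2200.0])
        df = maf_trajectory(calls, dates, ["g"] * 4)
        starts = set(df[df["group"] == "g"]["bin_start"])
        assert 500.0 not in starts and 1500.0 not in starts
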