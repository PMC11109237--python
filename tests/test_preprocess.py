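"""Accuracy filtering, composite z-scores, Wilcoxon group screening."""

import numpy as np
import pandas as pd
import pytest

from cognet.preprocess import (
    CompositeScorer,
    compare_performance,
    compute_composites,
    filter_low_accuracy,
    wilcoxon_rank_sum,
)


def make_table(accuracies, rts, task="t1", group="A"):
    n = len(accuracies)
    return pd.DataFrame(
        {
            "participant_id": [f"p{i}" for i in range(n)],
            "group": group,
            "task": task,
            "accuracy_pct": accuracies,
            "mean_rt_ms": rts,
        }
    )


class TestFilterLowAccuracy:
    def test_nothing_below_threshold(self, small_cohort):
        high = small_cohort[small_cohort["accuracy_pct"] >= 85].reset_index(drop=True)
        kept, log = filter_low_accuracy(high)
        pd.testing.assert_frame_equal(kept, high)
        assert log.empty

    def test_single_record_removed(self):
        acc = [90.0] * 19 + [49.9]
        table = make_table(acc, [500.0 + i for i in range(20)])
        kept, log = filter_low_accuracy(table)
        assert len(kept) == 19
        assert len(log) == 1
        assert log.iloc[0]["accuracy_pct"] == 49.9

    def test_boundary_threshold_empties_table(self):
        table = make_table([100.0, 90.0], [500.0, 600.0])
        kept, log = filter_low_accuracy(table, threshold_pct=101.0)
        assert kept.empty
        assert len(log) == 2

    def test_removal_is_per_record_not_per_participant(self):
        table = pd.concat(
            [make_table([40.0, 90.0], [500.0, 600.0], task="t1"),
             make_table([90.0, 90.0], [500.0, 600.0], task="t2")],
            ignore_index=True,
        )
        kept, log = filter_low_accuracy(table)
        assert ("p0", "t2") in set(zip(kept["participant_id"], kept["task"]))
        assert list(zip(log["participant_id"], log["task"])) == [("p0", "t1")]

    def test_idempotence(self, small_cohort):
        once, _ = filter_low_accuracy(small_cohort, threshold_pct=88.0)
        twice, log2 = filter_low_accuracy(once, threshold_pct=88.0)
        pd.testing.assert_frame_equal(once, twice)
        assert log2.empty


class TestComputeComposites:
    def test_z_columns_standardized(self, small_cohort):
        cm = compute_composites(small_cohort, scaling_label="all")
        for z in (cm.accuracy_z, cm.rt_z):
            np.testing.assert_allclose(z.mean(), 0.0, atol=1e-9)
            np.testing.assert_allclose(z.std(ddof=1), 1.0, atol=1e-9)

    def test_composite_is_mean_of_z_scores(self, small_cohort):
        cm = compute_composites(small_cohort, scaling_label="all")
        np.testing.assert_allclose(
            cm.composite.to_numpy(),
            (cm.accuracy_z.to_numpy() + cm.rt_z.to_numpy()) / 2.0,
        )

    def test_faster_participant_scores_higher(self):
        table = make_table([90.0, 90.0, 90.001], [600.0, 800.0, 700.0])
        cm = compute_composites(table)
        comp = cm.composite["t1"]
        assert comp["p0"] > comp["p1"]

    def test_hand_computed_composites(self):
        # accuracies (90, 95, 100), RTs (600, 500, 400), sample sd (ddof=1):
        # acc sd = 5 -> acc_z = (-1, 0, 1); -RT sd = 100 -> rt_z = (-1, 0, 1)
        # composite = (-1, 0, 1)
        table = make_table([90.0, 95.0, 100.0], [600.0, 500.0, 400.0])
        cm = compute_composites(table)
        np.testing.assert_allclose(
            cm.composite["t1"].to_numpy(), [-1.0, 0.0, 1.0], atol=1e-12
        )

    def test_zero_variance_column_raises_naming_task(self):
        table = make_table([90.0, 95.0, 100.0], [500.0, 500.0, 500.0])
        with pytest.raises(ValueError, match="t1"):
            compute_composites(table)

    def test_rt_shift_invariance(self, small_cohort):
        cm1 = compute_composites(small_cohort)
        shifted = small_cohort.copy()
        mask = shifted["task"] == "syntax"
        shifted.loc[mask, "mean_rt_ms"] += 250.0
        cm2 = compute_composites(shifted)
        pd.testing.assert_frame_equal(cm1.composite, cm2.composite)

    def test_excluded_cells_propagate_as_missing(self):
        table = pd.concat(
            [make_table([40.0, 90.0, 95.0, 97.0], [500.0, 600.0, 700.0, 800.0], task="t1"),
             make_table([90.0, 92.0, 95.0, 97.0], [500.0, 600.0, 700.0, 800.0], task="t2")],
            ignore_index=True,
        )
        cm = compute_composites(table)
        assert np.isnan(cm.composite.loc["p0", "t1"])
        assert np.isfinite(cm.composite.loc["p0", "t2"])

    def test_scaling_population_subset(self, small_cohort):
        participants = sorted(small_cohort["participant_id"].unique())
        scale_on = participants[:15]
        cm = compute_composites(small_cohort, scaling_population=scale_on)
        sub = cm.accuracy_z.loc[scale_on]
        np.testing.assert_allclose(sub.mean(), 0.0, atol=1e-9)
        full = cm.accuracy_z.mean()
        assert not np.allclose(full, 0.0, atol=1e-6)

    def test_scorer_transform_requires_fit(self, small_cohort):
        with pytest.raises(AttributeError, match="fit"):
            CompositeScorer().transform(small_cohort)

    def test_scorer_get_set_params_roundtrip(self):
        scorer = CompositeScorer().set_params(threshold_pct=60.0)
        assert scorer.get_params()["threshold_pct"] == 60.0
        with pytest.raises(ValueError):
            scorer.set_params(bogus=1)


class TestWilcoxon:
    def test_identical_samples_p_one(self):
        a = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        _, p = wilcoxon_rank_sum(a, a.copy())
        assert p == pytest.approx(1.0)

    def test_fully_separated_3v3_exact(self):
        # all group-a ranks below group-b: minimal U, exact two-sided p
        # = 2 * 1/C(6,3) = 0.1
        u, p = wilcoxon_rank_sum(np.array([1.0, 2, 3]), np.array([4.0, 5, 6]))
        assert u == 0.0
        assert p == pytest.approx(0.1)

    def test_large_samples_use_normal_approximation(self, rng):
        a = rng.normal(0, 1, 50)
        b = rng.normal(0.8, 1, 50)
        _, p = wilcoxon_rank_sum(a, b)
        assert 0 < p < 0.01


class TestComparePerformance:
    def test_identical_groups_all_p_one(self, small_cohort):
        doubled = pd.concat(
            [
                small_cohort.assign(group="A"),
                small_cohort.assign(
                    group="B",
                    participant_id=small_cohort["participant_id"] + "x",
                ),
            ],
            ignore_index=True,
        )
        out = compare_performance(doubled, "A", "B")
        np.testing.assert_allclose(out["p_raw"], 1.0)
        np.testing.assert_allclose(out["p_bonferroni"], 1.0)

    def test_bonferroni_dominance_and_cap(self, small_cohort, rng):
        table = small_cohort.copy()
        half = table["participant_id"].isin(
            sorted(table["participant_id"].unique())[:15]
        )
        table["group"] = np.where(half, "A", "B")
        out = compare_performance(table, "A", "B")
        valid = out.dropna(subset=["p_raw"])
        assert (valid["p_bonferroni"] >= valid["p_raw"] - 1e-12).all()
        assert (valid["p_bonferroni"] <= 1.0).all()
        assert out.attrs["n_comparisons"] == 30  # 10 tasks x 3 measures

    def test_missing_group_rejected(self, small_cohort):
        with pytest.raises(ValueError, match="not present"):
            compare_performance(small_cohort, "A", "Z")

    def test_shifted_group_detected(self):
        rng = np.random.default_rng(0)
        rows = []
        for g, shift in (("A", 0.0), ("B", 300.0)):
            for i in range(25):
                rows.append(
                    dict(participant_id=f"{g}{i}", group=g, task="t1",
                         accuracy_pct=90 + rng.normal(0, 2),
                         mean_rt_ms=800 + shift + rng.normal(0, 50))
                )
        out = compare_performance(pd.DataFrame(rows), "A", "B")
        rt_row = out[out["measure"] == "mean_rt_ms"].iloc[0]
        assert rt_row["p_bonferroni"] < 0.01


class TestValidation:
    def test_duplicate_record_rejected(self, tiny_table):
        dup = pd.concat([tiny_table, tiny_table.iloc[[0]]], ignore_index=True)
        with pytest.raises(ValueError, match="duplicate"):
            filter_low_accuracy(dup)

    def test_out_of_range_accuracy_rejected(self, tiny_table):
        bad = tiny_table.copy()
        bad.loc[0, "accuracy_pct"] = 103.0
        with pytest.raises(ValueError, match="row 0"):
            filter_low_accuracy(bad)

    def test_nonpositive_rt_rejected(self, tiny_table):
        bad = tiny_table.copy()
        bad.loc[2, "mean_rt_ms"] = 0.0
        with pytest.raises(ValueError, match="positive"):
            filter_low_accuracy(bad)
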