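"""Difference scores, outlier removal, within-subject ANOVA, recognition test."""

import numpy as np
import pandas as pd
import pytest

from ctlearn.datasets import reference_weighted_scores
from ctlearn.summary import (
    count_positive, difference_scores, mauchly_test, normalize_blocks,
    remove_outliers, rm_anova, score_recognition,
)


def scores_frame(rows):
    return pd.DataFrame(rows, columns=[
        "subject_id", "day", "segment_kind", "rmse", "lag_ms", "spatial_rmse"])


class TestDifferenceScores:
    def test_error_measure_sign_inverted(self):
        df = scores_frame([("s1", 7, "repeated", 1.0, -100.0, 1.0),
                           ("s1", 7, "random", 1.5, -100.0, 1.5)])
        d = difference_scores(df, day=7)
        rm = d[d["measure"] == "rmse"].iloc[0]
        assert rm["diff"] == pytest.approx(-0.5)
        assert rm["weight"] == pytest.approx(+0.5)
        sp = d[d["measure"] == "spatial"].iloc[0]
        assert sp["weight"] == pytest.approx(+0.5)

    def test_lag_sign_not_inverted(self):
        # repeated timing closer to zero lag than random -> positive weight
        df = scores_frame([("s1", 7, "repeated", 1.0, -120.0, 1.0),
                           ("s1", 7, "random", 1.0, -200.0, 1.0)])
        d = difference_scores(df, day=7)
        lag = d[d["measure"] == "lag"].iloc[0]
        assert lag["diff"] == pytest.approx(+80.0)
        assert lag["weight"] == pytest.approx(+80.0)

    def test_lag_in_seconds_option(self):
        df = scores_frame([("s1", 7, "repeated", 1.0, -120.0, 1.0),
                           ("s1", 7, "random", 1.0, -200.0, 1.0)])
        d = difference_scores(df, day=7, lag_unit="s")
        assert d[d["measure"] == "lag"]["weight"].iloc[0] == pytest.approx(0.08)

    def test_identical_means_zero_weight(self):
        df = scores_frame([("s1", 7, "repeated", 2.0, -50.0, 1.0),
                           ("s1", 7, "random", 2.0, -50.0, 1.0)])
        d = difference_scores(df, day=7)
        assert (d["weight"] == 0).all()

    def test_subject_missing_a_kind_excluded(self):
        df = scores_frame([("s1", 7, "repeated", 1.0, -50.0, 1.0),
                           ("s2", 7, "repeated", 1.0, -50.0, 1.0),
                           ("s2", 7, "random", 2.0, -60.0, 1.5)])
        d = difference_scores(df, day=7)
        assert set(d["subject_id"]) == {"s2"}
        assert d.attrs["excluded"] == ["s1"]


class TestReferenceCohortCounts:
    def test_sign_counts_3_8_1(self):
        """Positive weighted difference scores: 3 overall error, 8 lag, 1 spatial."""
        table = reference_weighted_scores()
        assert count_positive(table, "rmse") == 3
        assert count_positive(table, "lag") == 8
        assert count_positive(table, "spatial") == 1

    def test_wide_table_has_ten_participants(self):
        wide = reference_weighted_scores(long=False)
        assert len(wide) == 10


class TestRemoveOutliers:
    def test_all_equal_none_removed(self):
        df = pd.DataFrame({"value": [2.0] * 6})
        assert len(remove_outliers(df)) == 6

    def test_gross_outlier_removed(self):
        df = pd.DataFrame({"value": [0.0] * 9 + [100.0]})
        out = remove_outliers(df)
        assert len(out) == 9
        assert (out["value"] == 0).all()

    def test_exclusion_is_strictly_beyond_two_sd(self, rng):
        """Filtered rows match a z-score oracle with non-iterated mean/SD."""
        for _ in range(5):
            v = rng.normal(0, 3, 20)
            df = pd.DataFrame({"value": v})
            out = remove_outliers(df)
            z = np.abs(v - v.mean()) / v.std(ddof=1)
            np.testing.assert_array_equal(out["value"].to_numpy(), v[z <= 2.0])

    def test_too_few_rows_rejected(self):
        with pytest.raises(ValueError):
            remove_outliers(pd.DataFrame({"value": [1.0, 2.0]}))


def anova_frame(y):
    """y indexed as (subject, day, sequence)."""
    s, a, b = y.shape
    rows = []
    for i in range(s):
        for j in range(a):
            for k in range(b):
                rows.append({"subject_id": i, "day": j,
                             "sequence": ["random", "repeated"][k] if b == 2 else k,
                             "value": y[i, j, k]})
    return pd.DataFrame(rows)


class TestRmAnova:
    def test_flat_data_gives_zero_f(self):
        res = rm_anova(anova_frame(np.ones((4, 3, 2))))
        assert (res["F"] == 0).all()

    def test_pure_additive_day_effect_degenerate(self):
        y = np.zeros((4, 3, 2)) + np.arange(3)[None, :, None]
        res = rm_anova(anova_frame(y))
        day = res[res["effect"] == "day"].iloc[0]
        assert np.isinf(day["F"]) and day["flag"] == "degenerate_error_term"
        inter = res[res["effect"] == "day*sequence"].iloc[0]
        assert inter["F"] == 0

    def test_agrees_with_pingouin_on_random_toy(self, rng):
        pingouin = pytest.importorskip("pingouin")
        y = rng.normal(0, 1, (4, 3, 2)) + rng.normal(0, 1, (4, 1, 1))
        df = anova_frame(y)
        mine = rm_anova(df).set_index("effect")
        theirs = pingouin.rm_anova(data=df, dv="value", subject="subject_id",
                                   within=["day", "sequence"], detailed=True)
        for eff_mine, eff_pg in [("day", "day"), ("sequence", "sequence"),
                                 ("day*sequence", "day * sequence")]:
            row = theirs[theirs["Source"] == eff_pg].iloc[0]
            assert mine.loc[eff_mine, "F"] == pytest.approx(row["F"], rel=1e-8)
            assert mine.loc[eff_mine, "p"] == pytest.approx(row["p_unc"], rel=1e-8)

    def test_interaction_power_for_large_effect(self):
        """A sizeable day-by-sequence interaction is detected at n=10."""
        hits = 0
        n_seeds = 200
        for seed in range(n_seeds):
            r = np.random.default_rng(seed)
            y = r.normal(0, 1, (10, 5, 2))
            # repeated condition improves over days, random does not
            y[:, :, 1] -= np.linspace(0, 2.0, 5)[None, :]
            res = rm_anova(anova_frame(y)).set_index("effect")
            hits += res.loc["day*sequence", "p"] < 0.05
        assert hits >= 0.8 * n_seeds

    def test_mauchly_matches_pingouin(self, rng):
        pingouin = pytest.importorskip("pingouin")
        y = rng.normal(0, 1, (8, 4, 1))
        df = anova_frame(np.repeat(y, 2, axis=2))
        w, chi2, dof, p = mauchly_test(df, within="day")
        ref = pingouin.sphericity(df.groupby(["subject_id", "day"], as_index=False)
                                  ["value"].mean(),
                                  dv="value", subject="subject_id", within="day")
        assert w == pytest.approx(ref.W, rel=1e-6)
        assert p == pytest.approx(ref.pval, rel=1e-6)

    def test_two_level_factor_trivially_spherical(self):
        df = anova_frame(np.random.default_rng(0).normal(size=(6, 2, 2)))
        w, _, dof, p = mauchly_test(df, within="day")
        assert (w, dof, p) == (1.0, 0, 1.0)

    def test_missing_cell_rejected(self):
        df = anova_frame(np.ones((4, 2, 2))).iloc[:-1]
        with pytest.raises(ValueError, match="incomplete"):
            rm_anova(df)


class TestScoreRecognition:
    def test_all_correct_is_explicit(self):
        truth = [True] * 3 + [False] * 7
        res = score_recognition(truth, truth)
        assert res.explicit and res.percent_correct == 100.0

    def test_high_percent_without_hits_not_explicit(self):
        truth = [True] * 3 + [False] * 7
        judged = [True] + [False] * 9  # 1 hit, 7 correct rejections
        res = score_recognition(truth, judged)
        assert res.percent_correct == 80.0
        assert not res.explicit

    def test_criterion_boundary_two_hits_four_rejections(self):
        truth = [True] * 3 + [False] * 7
        judged = [True, True, False] + [True, True, True, False, False, False, False]
        res = score_recognition(truth, judged)
        assert res.hits == 2 and res.correct_rejections == 4
        assert res.explicit and res.percent_correct == 60.0

    def test_wrong_item_counts_rejected(self):
        with pytest.raises(ValueError):
            score_recognition([True] * 4 + [False] * 6, [False] * 10)


class TestNormalizeBlocks:
    def test_each_subject_scaled_by_first_block(self):
        df = pd.DataFrame({
            "subject_id": ["a"] * 2 + ["b"] * 2,
            "day": [2, 2, 2, 2], "block": [1, 2, 1, 2],
            "value": [2.0, 1.0, 4.0, 1.0]})
        out = normalize_blocks(df)
        assert out[out["subject_id"] == "a"]["value"].tolist() == [1.0, 0.5]
        assert out[out["subject_id"] == "b"]["value"].tolist() == [1.0, 0.25]
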