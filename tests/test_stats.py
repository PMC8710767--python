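"""Welch's t, Cohen's d, ICC, Pearson r, ROI aggregation, group comparisons."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from localbrainage.stats import (
    GroupSummary,
    age_matched_subset,
    bonferroni,
    cohens_d,
    compare_groups,
    icc,
    icc_map,
    pearson_r,
    roi_aggregate,
    summarize,
    welch_t,
    welch_t_from_data,
    welch_t_maps,
)
from localbrainage.volume_io import ParticipantRecord, RoiAtlas


class TestWelch:
    def test_identical_summaries_give_zero(self):
        s = GroupSummary(n=10, mean=1.0, var=2.0)
        t, df, p = welch_t(s, s)
        assert t == 0.0
        assert p == pytest.approx(1.0)

    def test_known_value(self):
        # means 1 vs 0, unit variances, n=100 each
        a = GroupSummary(n=100, mean=1.0, var=1.0)
        b = GroupSummary(n=100, mean=0.0, var=1.0)
        t, df, p = welch_t(a, b)
        assert t == pytest.approx(7.0711, abs=1e-4)
        assert df == pytest.approx(198.0, abs=1e-9)

    def test_swap_flips_sign_keeps_df(self):
        a = GroupSummary(n=12, mean=3.0, var=2.0)
        b = GroupSummary(n=40, mean=1.0, var=5.0)
        t1, df1, p1 = welch_t(a, b)
        t2, df2, p2 = welch_t(b, a)
        assert t1 == -t2 and df1 == df2 and p1 == p2

    def test_matches_scipy_on_random_pairs(self, rng):
        for _ in range(300):
            x = rng.normal(rng.uniform(-2, 2), rng.uniform(0.5, 3), size=rng.integers(5, 60))
            y = rng.normal(rng.uniform(-2, 2), rng.uniform(0.5, 3), size=rng.integers(5, 60))
            t, df, p = welch_t_from_data(x, y)
            ref = sps.ttest_ind(x, y, equal_var=False)
            assert t == pytest.approx(ref.statistic, rel=1e-10)
            assert df == pytest.approx(ref.df, rel=1e-10)
            assert p == pytest.approx(ref.pvalue, rel=1e-9)

    def test_zero_variances_error(self):
        s = GroupSummary(n=5, mean=1.0, var=0.0)
        with pytest.raises(ZeroDivisionError):
            welch_t(s, s)


class TestCohensD:
    def test_identical_groups_zero(self):
        s = GroupSummary(n=10, mean=2.0, var=1.5)
        assert cohens_d(s, s) == 0.0

    def test_unit_separation(self):
        a = GroupSummary(n=50, mean=1.0, var=1.0)
        b = GroupSummary(n=50, mean=0.0, var=1.0)
        assert cohens_d(a, b) == pytest.approx(1.0)

    def test_shift_and_scale_invariance(self, rng):
        x = rng.normal(0, 1, 40)
        y = rng.normal(1, 2, 30)
        d0 = cohens_d(summarize(x), summarize(y))
        assert cohens_d(summarize(x + 5), summarize(y + 5)) == pytest.approx(d0, rel=1e-12)
        assert cohens_d(summarize(3 * x), summarize(3 * y)) == pytest.approx(d0, rel=1e-10)

    def test_zero_pooled_sd(self):
        a = GroupSummary(n=5, mean=1.0, var=0.0)
        b = GroupSummary(n=5, mean=0.0, var=0.0)
        with pytest.raises(ZeroDivisionError):
            cohens_d(a, b)


class TestIcc:
    def test_duplicated_column_is_exactly_one(self, rng):
        x = rng.normal(size=20)
        assert icc(np.stack([x, x], 1), method="icc21") == pytest.approx(1.0, abs=1e-12)

    def test_fisher_formula_hand_evaluation(self):
        table = np.array([[1.0, 2.0], [2.0, 3.0], [3.0, 5.0]])
        # independent oracle: literal transcription with explicit sums
        n = 3
        xbar = table.sum() / (2 * n)
        s2 = (((table[:, 0] - xbar) ** 2).sum() + ((table[:, 1] - xbar) ** 2).sum()) / (2 * n)
        expected = ((table[:, 0] - xbar) * (table[:, 1] - xbar)).sum() / (n * s2)
        assert icc(table, method="fisher") == pytest.approx(expected, rel=1e-12)

    def test_icc21_matches_pingouin(self, rng):
        pg = pytest.importorskip("pingouin")
        for trial in range(20):
            n, k = int(rng.integers(5, 25)), int(rng.integers(2, 5))
            x = rng.normal(size=(n, 1)) + rng.normal(scale=0.5, size=(n, k))
            x += rng.normal(scale=0.3, size=(1, k))  # rater effects
            df = pd.DataFrame(
                {
                    "targets": np.repeat(np.arange(n), k),
                    "raters": np.tile(np.arange(k), n),
                    "ratings": x.ravel(),
                }
            )
            ref = pg.intraclass_corr(df, targets="targets", raters="raters", ratings="ratings")
            sel = ref["Type"].isin(["ICC2", "ICC(A,1)"])  # two-way random, absolute, single
            expected = float(ref.loc[sel, "ICC"].iloc[0])
            assert icc(x, method="icc21") == pytest.approx(expected, rel=1e-8, abs=1e-10)

    def test_independent_columns_near_zero(self):
        rng = np.random.default_rng(42)
        x = rng.standard_normal((10_000, 2))
        assert abs(icc(x, method="icc21")) < 0.05

    def test_noise_monotonically_degrades_agreement(self):
        rng = np.random.default_rng(7)
        base = rng.normal(size=5000)
        vals = [
            icc(np.stack([base, base + rng.normal(scale=s, size=5000)], 1), method="icc21")
            for s in (0.0, 0.5, 1.0, 2.0)
        ]
        assert vals[0] == pytest.approx(1.0)
        assert all(a > b for a, b in zip(vals, vals[1:]))

    def test_fisher_requires_two_raters(self, rng):
        with pytest.raises(ValueError, match="2 measurements"):
            icc(rng.normal(size=(5, 3)), method="fisher")

    def test_icc_map_matches_scalar_loop(self, rng):
        mask = np.zeros((4, 4, 4), dtype=bool)
        mask[1:3, 1:3, 1:3] = True
        maps = [rng.normal(size=(6, 4, 4, 4)) for _ in range(3)]  # 3 raters, 6 participants
        vec = icc_map(maps, mask)
        for v in np.argwhere(mask):
            table = np.stack([m[:, v[0], v[1], v[2]] for m in maps], axis=1)
            assert vec[tuple(v)] == pytest.approx(icc(table, method="icc21"), rel=1e-10)
        assert np.isnan(vec[~mask]).all()


class TestPearson:
    def test_perfect_correlations(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        assert pearson_r(x, x) == pytest.approx(1.0)
        assert pearson_r(x, -x) == pytest.approx(-1.0)

    def test_matches_numpy(self, rng):
        for _ in range(100):
            x = rng.normal(size=30)
            y = rng.normal(size=30)
            assert pearson_r(x, y) == pytest.approx(np.corrcoef(x, y)[0, 1], rel=1e-10)

    def test_degenerate(self):
        with pytest.raises(ValueError, match="3 pairs"):
            pearson_r([1, 2], [3, 4])
        with pytest.raises(ZeroDivisionError):
            pearson_r([1, 1, 1], [1, 2, 3])


class TestRoiAggregate:
    def _atlas(self):
        labels = np.zeros((6, 6, 6), dtype=np.int32)
        labels[:3] = 1
        labels[3:, :, :3] = 2
        labels[3:, :, 3:] = 3
        return RoiAtlas(labels=labels, names={1: "front", 2: "left", 3: "right"})

    def test_uniform_offset_map(self):
        atlas = self._atlas()
        rec = ParticipantRecord(id="p", age_years=50.0)
        df = roi_aggregate(np.full((6, 6, 6), 55.0), atlas, rec)
        assert (df["brain_pad"] == 5.0).all()
        assert set(df["roi_name"]) == {"front", "left", "right"}

    def test_volume_is_voxel_count_times_voxel_volume(self):
        atlas = self._atlas()
        rec = ParticipantRecord(id="p", age_years=50.0)
        df = roi_aggregate(np.zeros((6, 6, 6)), atlas, rec, voxel_size_mm=1.5)
        front = df[df["roi_label"] == 1].iloc[0]
        assert front["n_voxels"] == 3 * 6 * 6
        assert front["volume_mm3"] == pytest.approx(3 * 6 * 6 * 1.5**3)

    def test_single_voxel_roi(self):
        labels = np.zeros((4, 4, 4), dtype=np.int32)
        labels[2, 2, 2] = 1
        atlas = RoiAtlas(labels=labels, names={1: "dot"})
        m = np.random.default_rng(0).normal(50, 5, size=(4, 4, 4))
        rec = ParticipantRecord(id="p", age_years=40.0)
        df = roi_aggregate(m, atlas, rec)
        assert df["brain_pad"].iloc[0] == pytest.approx(m[2, 2, 2] - 40.0)

    def test_matches_brute_force_masked_mean(self, rng):
        atlas = self._atlas()
        m = rng.normal(50, 10, size=(6, 6, 6))
        m[0, 0, 0] = np.nan  # out-of-mask sentinel
        rec = ParticipantRecord(id="p", age_years=60.0)
        df = roi_aggregate(m, atlas, rec).set_index("roi_label")
        for label in (1, 2, 3):
            sel = (atlas.labels == label) & np.isfinite(m)
            assert df.loc[label, "mean_predicted_age"] == pytest.approx(m[sel].mean())

    def test_roi_outside_mask_fails(self):
        labels = np.zeros((4, 4, 4), dtype=np.int32)
        labels[0] = 1
        atlas = RoiAtlas(labels=labels, names={1: "gone"})
        m = np.full((4, 4, 4), np.nan)
        with pytest.raises(ValueError, match="outside"):
            roi_aggregate(m, atlas, ParticipantRecord(id="p", age_years=40.0))

    def test_partition_commutes_with_global_mean(self, rng):
        """Voxel-count-weighted ROI means equal the whole-mask mean."""
        atlas = self._atlas()
        m = rng.normal(50, 10, size=(6, 6, 6))
        df = roi_aggregate(m, atlas, ParticipantRecord(id="p", age_years=0.1))
        weighted = (df["mean_predicted_age"] * df["n_voxels"]).sum() / df["n_voxels"].sum()
        assert weighted == pytest.approx(m.mean(), rel=1e-12)


class TestCompareGroups:
    def test_single_comparison_adjusted_equals_raw(self, rng):
        vals = {"HC": rng.normal(size=20), "AD": rng.normal(1, 1, size=15)}
        df = compare_groups(vals)
        assert df["p_adj"].iloc[0] == pytest.approx(df["p"].iloc[0])

    def test_bonferroni_over_explicit_m(self, rng):
        vals = {"HC": rng.normal(size=20), "AD": rng.normal(size=20)}
        df = compare_groups(vals, n_comparisons=50)
        assert df["p_adj"].iloc[0] == pytest.approx(min(1.0, df["p"].iloc[0] * 50))

    def test_all_pairs_present(self, rng):
        vals = {g: rng.normal(size=10) for g in ("HC", "sMCI", "pMCI", "AD")}
        df = compare_groups(vals)
        assert len(df) == 6  # 4 choose 2
        assert (df["p_adj"] >= df["p"] - 1e-15).all()

    def test_needs_two_groups(self, rng):
        with pytest.raises(ValueError, match="2 groups"):
            compare_groups({"HC": rng.normal(size=5)})

    def test_welch_t_maps_match_per_voxel_loop(self, rng):
        mask = np.zeros((4, 4, 4), dtype=bool)
        mask[1:3] = True
        a = rng.normal(0, 1, size=(8, 4, 4, 4))
        b = rng.normal(0.5, 2, size=(6, 4, 4, 4))
        maps = welch_t_maps(a, b, mask)
        for v in np.argwhere(mask)[:10]:
            t, df, p = welch_t_from_data(a[:, v[0], v[1], v[2]], b[:, v[0], v[1], v[2]])
            assert maps["t"][tuple(v)] == pytest.approx(t, rel=1e-10)
            assert maps["df"][tuple(v)] == pytest.approx(df, rel=1e-10)
            assert maps["p"][tuple(v)] == pytest.approx(p, rel=1e-9)
        assert np.isnan(maps["t"][~mask]).all()


def test_bonferroni_caps_at_one():
    assert bonferroni(0.3, 10) == 1.0
    assert bonferroni(0.001, 10) == pytest.approx(0.01)
    with pytest.raises(ValueError):
        bonferroni(0.5, 0)


class TestAgeMatchedSubset:
    def _records(self, ages):
        return [ParticipantRecord(id=f"p{i}", age_years=a) for i, a in enumerate(ages)]

    def test_strictly_greater(self):
        subset = age_matched_subset(self._records([59.0, 60.0, 61.0]), 60.0)
        assert [r.age_years for r in subset] == [61.0]

    def test_zero_threshold_is_identity(self):
        recs = self._records([30.0, 40.0])
        assert age_matched_subset(recs, 0.0) == recs

    def test_empty_result_warns(self):
        with pytest.warns(UserWarning, match="empty"):
            out = age_matched_subset(self._records([30.0, 40.0]), 80.0)
        assert out == []
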