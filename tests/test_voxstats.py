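"""Voxel statistics: sampling, ANOVA/Tukey, relevance, thresholds, agreement."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import integrate, optimize, stats

from lungvox.dwi import ParameterMap
from lungvox.grids import Grid
from lungvox.patterns import CONSOLIDATED5, CaliperLabelMap
from lungvox.voxstats import (
    RelevanceRange,
    abnormal_percentages,
    anova_oneway,
    bland_altman,
    build_overlap_table,
    compare_groups,
    healthy_threshold,
    longitudinal_compare,
    relevance_classify,
    sample_every_k,
    tukey_hsd,
)


def _table(n, pattern="non_involved", subject="s0", timepoint="baseline", seed=0):
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        {
            "subject_id": subject,
            "voxel_index": np.arange(n),
            "pattern": pattern,
            "ADC": rng.normal(0.33, 0.1, n),
            "LmD": rng.normal(380, 90, n),
            "timepoint": timepoint,
        }
    )


class TestOverlapTable:
    grid = Grid((6, 6, 6), (1.8, 1.8, 5.0))

    def _maps_and_caliper(self, invalid=0):
        rng = np.random.default_rng(1)
        vals = rng.uniform(0.2, 0.5, self.grid.shape)
        valid = np.ones(self.grid.shape, bool)
        if invalid:
            valid.ravel()[:invalid] = False
        adc = ParameterMap("ADC", np.where(valid, vals, np.nan), valid, self.grid)
        lmd = ParameterMap("LmD", np.where(valid, vals * 1000, np.nan), valid, self.grid)
        labels = np.full(self.grid.shape, 1, dtype=np.int16)
        cal = CaliperLabelMap(labels, self.grid, "consolidated5")
        return {"ADC": adc, "LmD": lmd}, cal

    def test_full_overlap_row_count(self):
        maps, cal = self._maps_and_caliper()
        t = build_overlap_table(maps, cal, "s0")
        assert len(t) == np.prod(self.grid.shape)

    def test_fit_invalid_voxels_excluded(self):
        maps, cal = self._maps_and_caliper(invalid=3)
        t = build_overlap_table(maps, cal, "s0")
        assert len(t) == np.prod(self.grid.shape) - 3

    def test_disjoint_masks_give_empty_table(self):
        maps, cal = self._maps_and_caliper()
        cal = CaliperLabelMap(np.zeros(self.grid.shape, np.int16), self.grid, "consolidated5")
        t = build_overlap_table(maps, cal, "s0")
        assert len(t) == 0

    def test_grid_mismatch_is_error(self):
        maps, _ = self._maps_and_caliper()
        other = CaliperLabelMap(np.ones((5, 5, 5), np.int16), Grid((5, 5, 5), (1, 1, 1)),
                                "consolidated5")
        with pytest.raises(ValueError):
            build_overlap_table(maps, other, "s0")


class TestSampling:
    def test_hundred_rows_every_twentieth_keeps_five(self):
        assert len(sample_every_k(_table(100), 20)) == 5

    def test_k_one_is_identity(self):
        t = _table(37)
        assert sample_every_k(t, 1).equals(t)

    def test_nineteen_rows_keep_position_zero(self):
        t = _table(19)
        out = sample_every_k(t, 20)
        assert len(out) == 1 and out["voxel_index"].iloc[0] == 0

    def test_ceil_count_and_determinism(self):
        for n in (1, 19, 20, 21, 399, 400):
            t = _table(n)
            out1, out2 = sample_every_k(t, 20), sample_every_k(t, 20)
            assert len(out1) == int(np.ceil(n / 20))
            assert out1.equals(out2)

    def test_per_subject_offsets(self):
        t = pd.concat([_table(25, subject="a"), _table(25, subject="b")], ignore_index=True)
        out = sample_every_k(t, 20)
        assert len(out) == 4  # positions 0 and 20 within each subject

    def test_invalid_k_rejected(self):
        with pytest.raises(ValueError):
            sample_every_k(_table(10), 0)


class TestAnova:
    def test_two_groups_F_equals_t_squared(self):
        rng = np.random.default_rng(2)
        a, b = rng.normal(0, 1, 30), rng.normal(0.5, 1, 40)
        res = anova_oneway(np.r_[a, b], np.r_[["a"] * 30, ["b"] * 40])
        t = compare_groups(a, b, pooled=True)
        assert res.F == pytest.approx(t["t"] ** 2, rel=1e-9)
        assert res.df_between == 1 and res.df_within == 68

    def test_three_small_groups_match_hand_computation(self):
        values = np.array([1, 2, 3, 2, 4, 6, 5, 8, 11], dtype=float)
        groups = np.array(["a"] * 3 + ["b"] * 3 + ["c"] * 3)
        # direct sums of squares: means 2, 4, 8; grand 42/9
        grand = values.mean()
        ssb = 3 * ((2 - grand) ** 2 + (4 - grand) ** 2 + (8 - grand) ** 2)
        ssw = sum((values[:3] - 2) ** 2) + sum((values[3:6] - 4) ** 2) + sum((values[6:] - 8) ** 2)
        expected_F = (ssb / 2) / (ssw / 6)
        res = anova_oneway(values, groups)
        assert res.F == pytest.approx(expected_F, rel=1e-12)
        sp = stats.f_oneway(values[:3], values[3:6], values[6:])
        assert res.F == pytest.approx(sp.statistic, rel=1e-12)
        assert res.p == pytest.approx(sp.pvalue, rel=1e-9)

    def test_identical_group_means_give_zero_F(self):
        values = np.array([1.0, 2.0, 3.0, 1.0, 2.0, 3.0])
        res = anova_oneway(values, ["a"] * 3 + ["b"] * 3)
        assert abs(res.F) <= 1e-12

    def test_undersized_group_is_error(self):
        with pytest.raises(ValueError):
            anova_oneway([1.0, 2.0, 3.0], ["a", "a", "b"])


def _q_crit_oracle(k, df, level=0.95):
    """Studentized-range quantile by direct numerical integration."""

    def range_cdf(w):
        # P(range of k standard normals <= w)
        f = lambda z: stats.norm.pdf(z) * (
            stats.norm.cdf(z) - stats.norm.cdf(z - w)
        ) ** (k - 1)
        val, _ = integrate.quad(f, -9, 9, epsabs=1e-13, limit=200)
        return k * val

    def cdf(q):
        # integrate over the scale s ~ sqrt(chi2_df / df)
        def integrand(s):
            dens = (
                df ** (df / 2) / (2 ** (df / 2 - 1) * math.gamma(df / 2))
                * s ** (df - 1) * np.exp(-df * s**2 / 2)
            )
            return dens * range_cdf(q * s)

        val, _ = integrate.quad(integrand, 1e-9, 6, epsabs=1e-11, limit=200)
        return val

    return optimize.brentq(lambda q: cdf(q) - level, 1.0, 12.0, xtol=1e-10)


class TestTukey:
    def test_two_equal_groups_shifted_tiny_variance(self):
        rng = np.random.default_rng(3)
        base = rng.normal(0, 1e-4, 20)
        values = np.r_[base, base + 0.5]
        out = tukey_hsd(values, ["a"] * 20 + ["b"] * 20)
        row = out.iloc[0]
        assert row["mean_difference"] == pytest.approx(-0.5, abs=1e-4)
        assert row["significant"]
        assert row["ci_high"] < 0

    def test_three_group_cis_match_quantile_oracle(self):
        rng = np.random.default_rng(4)
        arrs = [rng.normal(0, 1, 4), rng.normal(1, 1, 5), rng.normal(2, 1, 6)]
        values = np.concatenate(arrs)
        groups = np.r_[["a"] * 4, ["b"] * 5, ["c"] * 6]
        out = tukey_hsd(values, groups)
        df = 15 - 3
        msw = sum(((a - a.mean()) ** 2).sum() for a in arrs) / df
        q = _q_crit_oracle(3, df)
        for _, row in out.iterrows():
            na = len(arrs["abc".index(row["group_a"])])
            nb = len(arrs["abc".index(row["group_b"])])
            half = q * np.sqrt(msw / 2 * (1 / na + 1 / nb))
            assert row["ci_high"] - row["mean_difference"] == pytest.approx(half, abs=1e-6)
            assert row["mean_difference"] - row["ci_low"] == pytest.approx(half, abs=1e-6)

    def test_ci_always_contains_point_difference(self):
        rng = np.random.default_rng(5)
        values = rng.normal(0, 1, 40)
        groups = rng.choice(list("abcd"), 40)
        out = tukey_hsd(values, groups)
        assert ((out["ci_low"] <= out["mean_difference"]) & (out["mean_difference"] <= out["ci_high"])).all()

    def test_cis_shrink_with_group_size(self):
        rng = np.random.default_rng(6)
        widths = []
        for n in (10, 40, 160):
            a = rng.standard_normal(n)
            b = rng.standard_normal(n) + 1
            c = rng.standard_normal(n) - 1
            out = tukey_hsd(np.r_[a, b, c], ["a"] * n + ["b"] * n + ["c"] * n)
            widths.append((out["ci_high"] - out["ci_low"]).mean())
        assert widths[0] > widths[1] > widths[2]

    def test_label_permutation_permutes_pairs_consistently(self):
        rng = np.random.default_rng(7)
        values = rng.normal(0, 1, 30)
        groups = np.array(["a"] * 10 + ["b"] * 10 + ["c"] * 10)
        out1 = tukey_hsd(values, groups)
        swap = {"a": "b", "b": "a", "c": "c"}
        out2 = tukey_hsd(values, np.vectorize(swap.get)(groups))
        d1 = {frozenset((r.group_a, r.group_b)): abs(r.mean_difference) for r in out1.itertuples()}
        d2 = {frozenset((swap[r.group_a], swap[r.group_b])): abs(r.mean_difference) for r in out2.itertuples()}
        assert set(d1) == set(d2)
        for key in d1:
            assert d1[key] == pytest.approx(d2[key], rel=1e-12)


# Every labelled pairwise comparison printed for the cohort: CI bounds with
# their published relevance annotation, judged against the a-priori ranges
# +/-0.041 cm^2/s (ADC) and +/-18.5 um (Lm_D).
PRINTED_FLAGS = [
    # baseline ADC, Tukey
    ("ADC", (0.053, 0.059), True),
    ("ADC", (0.059, 0.066), True),
    ("ADC", (0.109, 0.121), True),
    ("ADC", (0.256, 0.280), True),
    ("ADC", (0.002, 0.011), False),
    ("ADC", (0.053, 0.065), True),
    ("ADC", (0.200, 0.224), True),
    ("ADC", (0.045, 0.059), True),
    ("ADC", (0.193, 0.218), True),
    ("ADC", (0.140, 0.166), True),
    # baseline Lm_D, Tukey
    ("LmD", (22.0, 25.7), True),
    ("LmD", (22.4, 27.4), True),
    ("LmD", (16.0, 24.3), True),
    ("LmD", (85.6, 103.8), True),
    ("LmD", (61.7, 80.2), True),
    ("LmD", (60.4, 79.3), True),
    ("LmD", (64.6, 84.6), True),
    # longitudinal ADC
    ("ADC", (0.001, 0.003), False),
    ("ADC", (0.025, 0.033), False),
    ("ADC", (0.033, 0.043), True),
    ("ADC", (0.004, 0.006), False),
    # longitudinal Lm_D
    ("LmD", (4.4, 5.8), False),
    ("LmD", (17.2, 22.4), True),
    ("LmD", (22.0, 28.4), True),
    ("LmD", (3.2, 11.5), False),
    ("LmD", (6.8, 8.1), False),
]


class TestRelevance:
    @pytest.mark.parametrize("metric, ci, expected", PRINTED_FLAGS)
    def test_reproduces_published_annotations(self, metric, ci, expected):
        rng = RelevanceRange(metric, 0.041 if metric == "ADC" else 18.5)
        assert relevance_classify(ci, rng) is expected

    def test_invalid_ci_rejected(self):
        with pytest.raises(ValueError):
            relevance_classify((0.5, 0.1), RelevanceRange("ADC", 0.041))

    def test_nonpositive_half_width_rejected(self):
        with pytest.raises(ValueError):
            RelevanceRange("ADC", 0.0)


class TestHealthyThreshold:
    def test_interpolated_percentile_of_1_to_100(self):
        assert healthy_threshold(np.arange(1, 101)) == pytest.approx(95.05)

    def test_normal_draws_match_closed_form(self):
        rng = np.random.default_rng(10)
        v = rng.normal(300, 61, 100_000)
        assert healthy_threshold(v) == pytest.approx(300 + 1.645 * 61, abs=2.0)

    def test_constant_values(self):
        assert healthy_threshold(np.full(200, 123.0)) == 123.0

    def test_too_few_values_is_error(self):
        with pytest.raises(ValueError):
            healthy_threshold(np.arange(99))


class TestAbnormalPercentages:
    grid = Grid((5, 5, 4), (1.8, 1.8, 5.0))

    def _caliper(self, codes):
        return CaliperLabelMap(codes.astype(np.int16), self.grid, "consolidated5")

    def test_constructed_thirty_percent(self):
        lmd = np.full(self.grid.shape, 300.0)
        lmd.ravel()[:30] = 500.0
        cal = self._caliper(np.ones(self.grid.shape))
        mask = np.ones(self.grid.shape, bool)
        pct_lmd, _ = abnormal_percentages(lmd, cal, mask, 406.0)
        assert pct_lmd == pytest.approx(30.0)

    def test_all_below_threshold_is_zero(self):
        lmd = np.full(self.grid.shape, 300.0)
        cal = self._caliper(np.ones(self.grid.shape))
        pct_lmd, _ = abnormal_percentages(lmd, cal, np.ones(self.grid.shape, bool), 406.0)
        assert pct_lmd == 0.0

    def test_hyperlucent_never_counts_as_ct_abnormal(self):
        code = {v: k for k, v in CONSOLIDATED5.items()}
        labels = np.full(self.grid.shape, code["hyperlucent"])
        _, pct_cal = abnormal_percentages(
            np.zeros(self.grid.shape), self._caliper(labels),
            np.ones(self.grid.shape, bool), 406.0,
        )
        assert pct_cal == 0.0
        labels[0] = code["honeycomb"]
        _, pct_cal = abnormal_percentages(
            np.zeros(self.grid.shape), self._caliper(labels),
            np.ones(self.grid.shape, bool), 406.0,
        )
        assert pct_cal == pytest.approx(100.0 / 5)

    def test_pct_lmd_monotone_in_threshold(self):
        rng = np.random.default_rng(11)
        lmd = rng.normal(380, 90, self.grid.shape)
        cal = self._caliper(np.ones(self.grid.shape))
        mask = np.ones(self.grid.shape, bool)
        pcts = [abnormal_percentages(lmd, cal, mask, t)[0] for t in np.linspace(200, 600, 15)]
        assert np.all(np.diff(pcts) <= 0)

    def test_empty_mask_is_error(self):
        with pytest.raises(ValueError):
            abnormal_percentages(
                np.zeros(self.grid.shape), self._caliper(np.ones(self.grid.shape)),
                np.zeros(self.grid.shape, bool), 406.0,
            )


class TestBlandAltman:
    def test_constant_difference_gives_zero_width_limits(self):
        pairs = [(10.0, 25.3), (20.0, 35.3), (30.0, 45.3)]  # CT - LmD = -15.3
        res = bland_altman(pairs)
        assert res.bias == pytest.approx(-15.3)
        assert res.loa_low == pytest.approx(res.bias)
        assert res.loa_high == pytest.approx(res.bias)

    def test_hand_computed_instance(self):
        res = bland_altman([(10, 20), (30, 20)])
        assert res.bias == pytest.approx(0.0)
        assert res.sd == pytest.approx(14.142135623730951)
        assert res.loa_low == pytest.approx(-1.96 * res.sd)
        assert res.loa_high == pytest.approx(1.96 * res.sd)

    def test_limits_symmetric_about_bias(self):
        rng = np.random.default_rng(12)
        pairs = list(zip(rng.uniform(0, 50, 10), rng.uniform(0, 50, 10)))
        res = bland_altman(pairs)
        assert (res.loa_high - res.bias) == pytest.approx(res.bias - res.loa_low, abs=1e-12)

    def test_swapping_columns_negates_bias(self):
        pairs = [(10.0, 30.0), (20.0, 25.0), (5.0, 40.0)]
        res = bland_altman(pairs)
        res_swapped = bland_altman([(l, c) for c, l in pairs])
        assert res_swapped.bias == pytest.approx(-res.bias)

    def test_single_pair_is_error(self):
        with pytest.raises(ValueError):
            bland_altman([(10, 20)])


class TestCompareGroups:
    def test_identical_groups(self):
        rng = np.random.default_rng(13)
        a = rng.normal(0, 1, 50)
        res = compare_groups(a, a)
        assert res["mean_difference"] == 0.0
        assert res["ci_low"] < 0 < res["ci_high"]

    def test_welch_matches_scipy_oracle(self):
        a = np.array([5.1, 4.8, 5.6, 5.0, 4.7])
        b = np.array([4.0, 4.3, 3.9, 4.5, 4.1, 4.2, 3.8])
        res = compare_groups(a, b)
        sp = stats.ttest_ind(a, b, equal_var=False)
        assert res["t"] == pytest.approx(sp.statistic, rel=1e-9)
        assert res["p"] == pytest.approx(sp.pvalue, rel=1e-9)
        lo, hi = sp.confidence_interval()
        assert res["ci_low"] == pytest.approx(lo, rel=1e-9)
        assert res["ci_high"] == pytest.approx(hi, rel=1e-9)

    def test_degenerate_zero_variance_flagged(self):
        res = compare_groups([1.0, 1.0, 1.0], [1.0, 1.0])
        assert not res["defined"]

    def test_large_samples_recover_80_um_shift(self):
        rng = np.random.default_rng(14)
        ipf = rng.normal(380, 87, 50_000)
        healthy = rng.normal(300, 61, 20_000)
        res = compare_groups(ipf, healthy)
        assert res["mean_difference"] == pytest.approx(80.0, abs=2.0)
        assert res["p"] < 1e-10


class TestLongitudinal:
    def test_identical_tables_give_zero_differences(self):
        t = _table(200)
        out = longitudinal_compare(t, t.assign(timepoint="year1"))
        done = out[out["n_baseline"] > 0]
        assert np.allclose(done["mean_difference"].dropna(), 0.0)
        assert not out["significant"].any()

    def test_difference_column_is_year1_minus_baseline_mean(self):
        tb = pd.concat(
            [_table(100, pattern=p, seed=i) for i, p in enumerate(
                ["non_involved", "ground_glass", "reticular"])],
            ignore_index=True,
        )
        ty = tb.copy()
        ty["ADC"] = ty["ADC"] + 0.03
        ty["LmD"] = ty["LmD"] + 20.0
        out = longitudinal_compare(tb, ty)
        for _, row in out.dropna(subset=["mean_difference"]).iterrows():
            assert row["mean_difference"] == pytest.approx(
                row["year1_mean"] - row["baseline_mean"], abs=1e-12
            )

    def test_pattern_missing_at_one_timepoint_yields_na_row(self):
        tb = _table(50, pattern="honeycomb")
        ty = _table(50, pattern="ground_glass")
        out = longitudinal_compare(tb, ty)
        row = out[(out["pattern"] == "honeycomb") & (out["metric"] == "ADC")].iloc[0]
        assert np.isnan(row["mean_difference"])
        assert not row["significant"]
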