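"""Breath averaging, trajectory correction, slopes and repeated-measures tests."""

import math

import numpy as np
import pytest

import ventcost as vc
from ventcost.exceptions import (
    DegenerateTestError,
    ExtrapolationError,
    IncompleteDesignError,
    InsufficientDataError,
    ShapeError,
    UnitsError,
)
from ventcost.gas_volume import VolumeConversionParams, btps_to_stpd
from ventcost.rie import (
    RIETimeSeries,
    average_breaths,
    correct_series,
    final_slope,
    intensity_table,
    paired_slope_test,
    predict_vent_series,
    rm_anova,
)


def _series(n=20, vo2=None, ve=None, power=None, **kw):
    t = np.arange(n, dtype=float) * 3.0
    return RIETimeSeries(
        time=t,
        power=np.linspace(30, 300, n) if power is None else power,
        vo2=np.full(n, 2.0) if vo2 is None else vo2,
        ve=np.full(n, 60.0) if ve is None else ve,
        **kw,
    )


@pytest.fixture(scope="module")
def subject(table1):
    return table1.records[0]


class TestSeriesInvariants:
    def test_channel_length_mismatch(self):
        with pytest.raises(ShapeError):
            RIETimeSeries(time=[0, 1], power=[0, 1, 2], vo2=[1, 1], ve=[20, 20])

    def test_non_increasing_time(self):
        with pytest.raises(ShapeError):
            RIETimeSeries(time=[0, 2, 1], power=[0, 1, 2], vo2=[1] * 3, ve=[20] * 3)

    def test_fr_vt_consistency_bound(self):
        with pytest.raises(ShapeError, match="fr·vt"):
            RIETimeSeries(
                time=[0, 1], power=[0, 1], vo2=[1, 1], ve=[40, 40],
                fr=[20, 20], vt=[1.0, 1.0],  # fr·vt = 20, ve = 40
            )


class TestAverageBreaths:
    def test_block_count_and_trailing_drop(self):
        out = average_breaths(_series(14), 7)
        assert len(out) == 2
        assert out.averaging_width == 7

    def test_constant_channels_unchanged(self):
        out = average_breaths(_series(21), 7)
        np.testing.assert_allclose(out.vo2, 2.0)
        np.testing.assert_allclose(out.ve, 60.0)

    def test_block_time_is_mean_time(self):
        out = average_breaths(_series(14), 7)
        assert out.time[0] == pytest.approx(np.mean(np.arange(7) * 3.0))

    def test_width_one_is_identity(self):
        s = _series(9)
        out = average_breaths(s, 1)
        np.testing.assert_array_equal(out.vo2, s.vo2)

    def test_too_few_breaths(self):
        with pytest.raises(InsufficientDataError):
            average_breaths(_series(5), 7)


class TestPredictVentSeries:
    def test_constant_ve_gives_constant_peak_prediction(self, published, subject):
        s = _series(10, ve=np.full(10, subject.ve_peak))
        vent = predict_vent_series(published, s, subject)
        from ventcost.composite import predict_record

        np.testing.assert_allclose(vent, predict_record(published, subject), rtol=1e-12)

    def test_first_subject_value(self, published, subject):
        s = _series(5, ve=np.full(5, 71.66))
        vent = predict_vent_series(published, s, subject)
        assert vent[0] == pytest.approx(0.415, abs=1e-3)

    def test_monotone_ve_gives_monotone_trajectory(self, published, subject):
        s = _series(50, ve=np.linspace(55, 185, 50))
        vent = predict_vent_series(published, s, subject)
        assert np.all(np.diff(vent) >= 0)

    def test_btps_series_requires_conversion(self, published, subject):
        s = _series(5, ve_condition="BTPS")
        with pytest.raises(UnitsError):
            predict_vent_series(published, s, subject)
        params = VolumeConversionParams()
        vent = predict_vent_series(published, s, subject, conversion=params)
        s_stpd = _series(5, ve=btps_to_stpd(s.ve, params))
        np.testing.assert_allclose(vent, predict_vent_series(published, s_stpd, subject))

    def test_rest_offset_zeroes_baseline(self, published, subject):
        s = _series(20, ve=np.linspace(30, 150, 20))
        vent = predict_vent_series(published, s, subject, rest_offset=True)
        assert vent[0] == 0.0
        assert np.all(vent >= 0)


class TestCorrectSeries:
    def test_conservation_is_exact(self, published, subject):
        s = _series(40, vo2=np.linspace(1.0, 5.9, 40), ve=np.linspace(30, 170, 40))
        vent = predict_vent_series(published, s, subject)
        res = correct_series(s, vent)
        np.testing.assert_array_equal(
            res.vo2vent_series + res.vo2vcorr_series, s.vo2
        )

    def test_null_and_full_correction(self):
        s = _series(10, vo2=np.linspace(1, 4, 10))
        res = correct_series(s, np.zeros(10))
        np.testing.assert_array_equal(res.vo2vcorr_series, s.vo2)
        res2 = correct_series(s, s.vo2)
        np.testing.assert_array_equal(res2.vo2vcorr_series, np.zeros(10))

    def test_application_subject_arithmetic(self):
        # peak values of the highest-V̇O2max application cyclist
        s = _series(3, vo2=np.array([5.0, 5.5, 5.90]))
        res = correct_series(s, np.array([0.7, 0.8, 0.91]))
        assert res.vo2vcorr_series[-1] == pytest.approx(4.99, abs=1e-12)

    def test_length_mismatch(self):
        with pytest.raises(ShapeError):
            correct_series(_series(10), np.zeros(9))


class TestIntensityTable:
    def test_endpoint_fraction(self):
        s = _series(10, vo2=np.linspace(1, 4, 10))
        res = correct_series(s, np.zeros(10))
        table = intensity_table(res, fractions=(1.0,))
        assert table["vo2"].iloc[0] == 4.0

    def test_linear_channel_interpolates_exactly(self):
        power = np.linspace(50, 350, 31)
        vo2 = 0.9 + 0.01 * power  # exactly linear in power
        s = _series(31, vo2=vo2, power=power)
        res = correct_series(s, np.zeros(31))
        table = intensity_table(res, fractions=(0.35, 0.55, 0.75, 0.85, 0.95, 1.0))
        expected = 0.9 + 0.01 * np.array([0.35, 0.55, 0.75, 0.85, 0.95, 1.0]) * 350
        np.testing.assert_allclose(table["vo2"].to_numpy(), expected, rtol=1e-12)
        assert np.all(np.diff(table["vo2"]) > 0)

    def test_fraction_below_first_sample(self):
        power = np.linspace(200, 350, 10)
        s = _series(10, power=power)
        res = correct_series(s, np.zeros(10))
        with pytest.raises(ExtrapolationError):
            intensity_table(res, fractions=(0.35,))

    def test_non_monotone_power_uses_last_crossing(self):
        power = np.array([0.0, 100.0, 40.0, 100.0, 200.0])
        vo2 = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        s = RIETimeSeries(time=np.arange(5.0), power=power, vo2=vo2, ve=np.full(5, 50.0))
        res = correct_series(s, np.zeros(5))
        table = intensity_table(res, fractions=(0.5,))  # 100 W crossed at i=1 and i=3
        assert table["vo2"].iloc[0] == pytest.approx(4.0)


class TestFinalSlope:
    def test_exact_line(self):
        t = np.arange(0, 61, 3, dtype=float)
        y = 0.2866 * t / 60.0  # 0.2866 L·min⁻¹ per minute
        assert final_slope(y, t, window=30) == pytest.approx(0.2866, rel=1e-12)

    def test_constant_channel(self):
        t = np.arange(0, 61, 3, dtype=float)
        assert final_slope(np.full_like(t, 2.0), t, window=30) == 0.0

    def test_window_membership_inclusive(self):
        t = np.array([0.0, 70.0, 85.0, 100.0])
        # exactly 3 samples with t >= 100 - 30
        assert final_slope(np.array([9.9, 1.0, 2.0, 3.0]), t, window=30) > 0

    def test_too_few_samples(self):
        with pytest.raises(InsufficientDataError):
            final_slope(np.array([1.0, 2.0]), np.array([0.0, 10.0]), window=30)


class TestPairedSlopeTest:
    def test_identical_vectors(self):
        r = paired_slope_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert (r.t, r.p) == (0.0, 1.0)

    def test_hand_computed_example(self):
        a = np.array([0.30, 0.25, 0.41, 0.22])
        b = np.array([0.05, 0.10, 0.02, 0.11])
        r = paired_slope_test(a, b)
        d = a - b
        t_oracle = d.mean() / (d.std(ddof=1) / math.sqrt(4))
        assert r.t == pytest.approx(t_oracle, rel=1e-10)
        assert r.df == 3
        assert r.cohen_d == pytest.approx(d.mean() / d.std(ddof=1), rel=1e-12)

    def test_near_zero_variance_gives_huge_effect(self):
        rng = np.random.default_rng(0)
        a = np.array([1.0, 1.0, 1.0, 1.0]) + rng.normal(0, 1e-9, 4)
        r = paired_slope_test(a, np.zeros(4))
        assert r.cohen_d > 1e6

    def test_zero_variance_nonzero_diffs(self):
        with pytest.raises(DegenerateTestError):
            paired_slope_test([1.0, 1.0, 1.0], [0.0, 0.0, 0.0])


# ---------------------------------------------------------------------------
# repeated-measures ANOVA oracles


def oneway_F_oracle(X):
    """Textbook sums-of-squares decomposition, written with explicit loops."""
    n, k = len(X), len(X[0])
    grand = sum(sum(row) for row in X) / (n * k)
    col_means = [sum(X[i][j] for i in range(n)) / n for j in range(k)]
    row_means = [sum(X[i][j] for j in range(k)) / k for i in range(n)]
    ss_cond = n * sum((m - grand) ** 2 for m in col_means)
    ss_subj = k * sum((m - grand) ** 2 for m in row_means)
    ss_tot = sum((X[i][j] - grand) ** 2 for i in range(n) for j in range(k))
    ss_err = ss_tot - ss_cond - ss_subj
    if ss_cond <= 1e-300:
        return 0.0
    if ss_err <= 1e-12 * max(ss_tot, 1.0):
        return math.inf
    return (ss_cond / (k - 1)) / (ss_err / ((n - 1) * (k - 1)))


class TestRmAnova:
    def test_identical_conditions_give_zero_F(self):
        X = np.tile(np.array([[1.0], [2.0], [3.0]]), (1, 4))
        res = rm_anova(X)
        assert res.effects.loc["condition", "F"] == 0.0

    def test_two_conditions_have_unit_epsilon(self):
        rng = np.random.default_rng(1)
        res = rm_anova(rng.normal(size=(6, 2)))
        assert res.effects.loc["condition", "eps"] == 1.0

    def test_four_by_three_matches_oracle(self):
        X = np.array(
            [[3.0, 4.0, 6.0], [2.0, 4.0, 5.0], [1.0, 3.0, 3.0], [4.0, 6.0, 9.0]]
        )
        res = rm_anova(X)
        assert res.effects.loc["condition", "F"] == pytest.approx(
            oneway_F_oracle(X.tolist()), abs=1e-8
        )

    def test_small_integer_instances_match_oracle(self):
        """Sampled 3×3 designs with entries in {0,1,2} agree with the loop oracle."""
        rng = np.random.default_rng(5)
        for _ in range(200):
            X = rng.integers(0, 3, size=(3, 3)).astype(float)
            expected = oneway_F_oracle(X.tolist())
            got = rm_anova(X).effects.loc["condition", "F"]
            if math.isinf(expected):
                assert math.isinf(got)
            else:
                assert got == pytest.approx(expected, abs=1e-8)

    def test_oneway_matches_pingouin(self):
        """Independent cross-check of F, epsilon and GG p-value against pingouin."""
        pg = pytest.importorskip("pingouin")
        import pandas as pd

        rng = np.random.default_rng(5)
        X = rng.normal(size=(8, 4)) + np.array([0.0, 0.3, 0.5, 1.0])
        res = rm_anova(X)
        df = pd.DataFrame(X, columns=[f"c{j}" for j in range(4)])
        df["subj"] = range(8)
        long = df.melt(id_vars="subj", var_name="cond", value_name="y")
        ref = pg.rm_anova(
            data=long, dv="y", within="cond", subject="subj", correction=True
        )
        row = res.effects.loc["condition"]
        assert row["F"] == pytest.approx(float(ref["F"].iloc[0]), rel=1e-9)
        assert row["eps"] == pytest.approx(float(ref["eps"].iloc[0]), rel=1e-9)
        assert row["p_gg"] == pytest.approx(float(ref["p_GG_corr"].iloc[0]), rel=1e-6)

    def test_twoway_matches_pingouin(self):
        pg = pytest.importorskip("pingouin")
        import pandas as pd

        rng = np.random.default_rng(6)
        n, a, b = 9, 4, 2
        Y = (
            rng.normal(size=(n, a, b))
            + np.arange(a)[None, :, None] * 0.5
            + np.arange(b)[None, None, :] * 0.8
        )
        res = rm_anova(Y)
        rows = [
            {"subj": i, "A": f"a{j}", "B": f"b{l}", "y": Y[i, j, l]}
            for i in range(n) for j in range(a) for l in range(b)
        ]
        ref = pg.rm_anova(
            data=pd.DataFrame(rows), dv="y", within=["A", "B"], subject="subj",
            correction=True,
        )
        for effect, source in (("factor_a", "A"), ("factor_b", "B"), ("interaction", "A * B")):
            r = ref[ref["Source"] == source].iloc[0]
            assert res.effects.loc[effect, "F"] == pytest.approx(float(r["F"]), rel=1e-9)
            assert res.effects.loc[effect, "eps"] == pytest.approx(float(r["eps"]), rel=1e-9)
            assert res.effects.loc[effect, "p_gg"] == pytest.approx(
                float(r["p_GG_corr"]), rel=1e-6
            )

    def test_second_factor_entry_point(self):
        rng = np.random.default_rng(7)
        A = rng.normal(size=(6, 4)) + 2.0
        B = A - 0.5
        res = rm_anova(A, second_factor=B)
        assert set(res.effects.index) == {"factor_a", "factor_b", "interaction"}
        assert res.effects.loc["factor_b", "df1"] == 1.0
        assert not res.pairwise.empty
        assert (res.pairwise["p_bonferroni"] >= res.pairwise["p_uncorrected"] - 1e-15).all()

    def test_missing_cells_rejected(self):
        X = np.ones((4, 3))
        X[1, 2] = np.nan
        with pytest.raises(IncompleteDesignError):
            rm_anova(X)


def test_percent_vent_at_max_matches_ratio(published, subject):
    s = _series(30, vo2=np.linspace(1.0, 4.5, 30), ve=np.linspace(40, 160, 30))
    res = vc.apply_correction(published, s, subject)
    expected = vc.percent_of_max(res.vo2vent_series[-1], res.vo2[-1])
    assert res.percent_vent_at_max == expected
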