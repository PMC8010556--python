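"""Agreement statistics: hand-computed oracles, reference implementations,
and algebraic invariants."""

import math

import numpy as np
import pandas as pd
import pingouin as pg
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import qibrepeat as q
from qibrepeat.agreement import LOA_FACTOR
from qibrepeat.exceptions import (
    CompletenessError,
    ConfigurationError,
    DegenerateDataError,
    SampleSizeError,
)

from conftest import uniform_config


def toy_table(small_pairs, metric="ADC-Mean"):
    """Minimal complete table with given (rep1, rep2) reader-1 values for the
    small class; reader 2 and the large class are filled with constants."""
    rows = []
    for i, (x1, x2) in enumerate(small_pairs):
        sid = f"S{i + 1:03d}"
        for map_type in ("ADC", "FF"):
            for cls in ("small", "large"):
                for reader, rep in ((1, 1), (1, 2), (2, 1)):
                    if cls == "small" and map_type == "ADC":
                        value = {(1, 1): x1, (1, 2): x2, (2, 1): x1}[(reader, rep)]
                    else:
                        value = 10.0
                    rows.append(
                        {
                            "subject_id": sid,
                            "lesion_class": cls,
                            "lesion_diameter_mm": 7.0 if cls == "small" else 15.0,
                            "map": map_type,
                            "reader": reader,
                            "replicate": rep,
                            "roi_mean": value,
                            "roi_sd": 1.0,
                            "roi_area_mm2": 50.0,
                        }
                    )
    return pd.DataFrame(rows)


class TestBuildDifferences:
    def test_intra_direct_construction(self):
        table = toy_table([(5, 3), (4, 4), (7, 6)])
        d = q.build_differences(table, "ADC-Mean", "intra", "small")
        np.testing.assert_array_equal(d.differences, [2, 0, 1])
        assert d.subject_ids == ["S001", "S002", "S003"]
        np.testing.assert_array_equal(d.pair_means, [4, 4, 6.5])

    def test_equal_estimates_give_zero_differences(self):
        table = toy_table([(5, 5), (4, 4)])
        d = q.build_differences(table, "ADC-Mean", "intra", "small")
        assert (d.differences == 0).all()
        assert d.mean_difference == 0.0

    def test_missing_reader_raises_completeness_error_naming_subject(self):
        table = toy_table([(5, 3), (4, 4)])
        table = table[~((table["subject_id"] == "S002") & (table["reader"] == 2))]
        with pytest.raises(CompletenessError, match="S002"):
            q.build_differences(table, "ADC-Mean", "inter", "small")


class TestWithinSubjectSd:
    @pytest.mark.parametrize(
        "d, expected",
        [
            ([0.0, 0.0, 0.0], 0.0),
            ([1.0, -1.0], math.sqrt(2.0 / 4.0)),
            ([2.0, 4.0, 6.0], math.sqrt(8.0 / 6.0)),
        ],
    )
    def test_printed_formula_hand_values(self, d, expected):
        assert q.within_subject_sd(d) == pytest.approx(expected, abs=1e-12)

    def test_too_few_differences(self):
        with pytest.raises(SampleSizeError):
            q.within_subject_sd([1.0])

    @given(
        st.lists(st.floats(-1e3, 1e3), min_size=2, max_size=40),
        st.floats(-100, 100),
        st.floats(0.1, 10),
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_formula_identity_and_location_scale(self, x2, shift, scale):
        """s_w = sd(d) * sqrt((N-1)/(2N)); shifting both measurements of every
        subject leaves s_w unchanged, scaling all measurements scales it."""
        x2 = np.asarray(x2)
        x1 = x2 + np.linspace(-1, 1, x2.size)  # arbitrary paired partner
        d = x1 - x2
        n = d.size
        sw = q.within_subject_sd(d)
        assert sw == pytest.approx(
            np.std(d, ddof=1) * math.sqrt((n - 1) / (2 * n)), abs=1e-9, rel=1e-9
        )
        shifted = (x1 + shift) - (x2 + shift)
        assert q.within_subject_sd(shifted) == pytest.approx(sw, rel=1e-9, abs=1e-9)
        assert q.within_subject_sd(scale * x1 - scale * x2) == pytest.approx(
            scale * sw, rel=1e-6, abs=1e-9
        )

    def test_anova_equivalence_when_mean_difference_is_zero(self, rng):
        """With dbar = 0 exactly, s_w^2 equals the within-subject mean square
        of the paired one-way ANOVA."""
        half = rng.normal(size=10)
        d = np.concatenate([half, -half])  # dbar exactly 0
        x1 = rng.normal(100, 10, size=20)
        pairs = np.column_stack([x1, x1 - d])
        msw = np.sum((pairs - pairs.mean(axis=1, keepdims=True)) ** 2) / pairs.shape[0]
        assert q.within_subject_sd(d) ** 2 == pytest.approx(msw, rel=1e-12)


class TestCovAndLoa:
    def test_cov_hand_values(self):
        assert q.cov_percent(5.0, 50.0) == 10.0
        assert q.cov_percent(28.4, 791.0) == pytest.approx(3.59, abs=0.005)
        assert q.cov_percent(0.0, 7.0) == 0.0
        with pytest.raises(DegenerateDataError):
            q.cov_percent(1.0, 0.0)

    def test_loa_closed_form(self):
        assert q.limits_of_agreement(0.0) == 0.0
        assert q.limits_of_agreement(1.0) == pytest.approx(2.77186, abs=1e-5)
        assert q.limits_of_agreement(28.4) == pytest.approx(78.72, abs=0.01)
        assert LOA_FACTOR == pytest.approx(1.96 * math.sqrt(2))
        with pytest.raises(ConfigurationError):
            q.limits_of_agreement(-1.0)

    def test_cov_scale_invariance(self, rng):
        d = rng.normal(size=22)
        x = rng.normal(100, 10, size=22)
        sw = q.within_subject_sd(d)
        cov = q.cov_percent(sw, x.mean())
        c = 3.7
        assert q.cov_percent(
            q.within_subject_sd(c * d), c * x.mean()
        ) == pytest.approx(cov, rel=1e-12)


class TestMeanDifferenceCi:
    def test_t_quantile_hand_value(self):
        dbar, lo, hi = q.mean_difference_ci([2.0, 4.0, 6.0], alpha=0.05)
        assert dbar == 4.0
        assert lo == pytest.approx(-0.968, abs=0.01)
        assert hi == pytest.approx(8.968, abs=0.01)

    def test_degenerate_and_limit_cases(self):
        assert q.mean_difference_ci([0.0, 0.0, 0.0]) == (0.0, 0.0, 0.0)
        dbar, lo, hi = q.mean_difference_ci([2.0, 4.0, 6.0], alpha=1.0)
        assert (dbar, lo, hi) == (4.0, 4.0, 4.0)
        with pytest.raises(SampleSizeError):
            q.mean_difference_ci([1.0])

    def test_ci_contains_estimate(self, rng):
        d = rng.normal(size=22)
        dbar, lo, hi = q.mean_difference_ci(d)
        assert lo <= dbar <= hi


class TestIcc:
    def test_perfect_agreement(self):
        r = q.icc_oneway(np.array([[0.0, 0.0], [1.0, 1.0], [2.0, 2.0]]))
        assert r.icc == 1.0
        assert r.band == "excellent"
        assert r.ci == (1.0, 1.0)

    def test_negative_icc_when_within_exceeds_between(self):
        r = q.icc_oneway(np.array([[0.0, 1.0], [1.0, 0.0], [0.5, 0.5]]))
        assert r.icc < 0
        assert r.band == "poor"

    def test_matches_pingouin_icc1_on_seeded_instance(self, rng):
        truth = rng.normal(10, 3, 22)
        pairs = np.column_stack(
            [truth + rng.normal(0, 1, 22), truth + rng.normal(0, 1, 22)]
        )
        mine = q.icc_oneway(pairs)
        df = pd.DataFrame(
            {
                "targets": np.repeat(np.arange(22), 2),
                "raters": np.tile([0, 1], 22),
                "score": pairs.ravel(),
            }
        )
        row = pg.intraclass_corr(
            df, targets="targets", raters="raters", ratings="score"
        ).set_index("Type").loc["ICC(1,1)"]
        assert mine.icc == pytest.approx(float(row["ICC"]), abs=1e-10)
        # pingouin rounds its CI to 2 decimals
        assert mine.ci[0] == pytest.approx(float(row["CI95"][0]), abs=5e-3)
        assert mine.ci[1] == pytest.approx(float(row["CI95"][1]), abs=5e-3)

    def test_icc_approaches_one_as_noise_vanishes(self, rng):
        truth = rng.normal(0, 5, size=30)
        last = -np.inf
        for noise in (1.0, 0.3, 0.01):
            pairs = np.column_stack(
                [truth + rng.normal(0, noise, 30), truth + rng.normal(0, noise, 30)]
            )
            icc = q.icc_oneway(pairs).icc
            assert icc <= 1.0
            assert icc > last
            last = icc
        assert last > 0.99

    def test_banding_boundaries(self):
        assert q.icc_band(0.49) == "poor"
        assert q.icc_band(0.5) == "moderate"
        assert q.icc_band(0.75) == "good"
        assert q.icc_band(0.9) == "excellent"

    def test_degenerate_and_small_n(self):
        with pytest.raises(DegenerateDataError):
            q.icc_oneway(np.full((5, 2), 3.0))
        with pytest.raises(SampleSizeError):
            q.icc_oneway(np.array([[0.0, 1.0], [1.0, 0.0]]))


class TestLevene:
    def test_identical_groups_give_w_zero(self):
        r = q.levene_equal_variance([-1, 0, 1], [-1, 0, 1])
        assert r.statistic == 0.0
        assert r.p_value == 1.0

    def test_hand_computed_w(self):
        r = q.levene_equal_variance([-2, 0, 2], [-1, 0, 1], center="mean")
        assert r.statistic == pytest.approx(0.8, abs=1e-12)
        assert r.df == (1, 4)

    def test_matches_scipy_to_1e10(self, rng):
        a = rng.normal(size=22)
        b = rng.normal(scale=2, size=22)
        for center in ("mean", "median"):
            mine = q.levene_equal_variance(a, b, center=center)
            ref = stats.levene(a, b, center=center)
            assert mine.statistic == pytest.approx(ref.statistic, abs=1e-10)
            assert mine.p_value == pytest.approx(ref.pvalue, abs=1e-10)

    def test_degenerate_identical_constants(self):
        with pytest.raises(DegenerateDataError):
            q.levene_equal_variance([1.0, 1.0], [1.0, 1.0])


class TestGroupMeans:
    def test_identical_groups_report_p1_with_flag(self):
        table = toy_table([(5, 5), (4, 4), (6, 6)])
        res = q.group_mean_comparison(table, "FF-Mean")  # constant 10 everywhere
        assert res.mean_small == res.mean_large == 10.0
        assert res.p_value == 1.0
        assert res.zero_variance

    def test_constant_shift_triggers_zero_variance_flag(self):
        table = toy_table([(5, 5), (4, 4), (6, 6)])
        # small = large + 1 for every subject on FF-Mean
        idx = (table["map"] == "FF") & (table["lesion_class"] == "small")
        table.loc[idx, "roi_mean"] = 11.0
        res = q.group_mean_comparison(table, "FF-Mean")
        assert (res.mean_small, res.mean_large) == (11.0, 10.0)
        assert res.zero_variance

    def test_matches_scipy_paired_t(self, reference_table):
        res = q.group_mean_comparison(reference_table, "ADC-Mean")
        per = q.agreement.lesion_values(reference_table, "ADC-Mean")
        wide = per.pivot(index="subject_id", columns="lesion_class", values="value")
        ref = stats.ttest_rel(wide["small"], wide["large"])
        assert res.p_value == pytest.approx(float(ref.pvalue), abs=1e-10)
        assert not res.zero_variance


class TestSdRatioByThreshold:
    def test_hand_computed_ratio(self):
        out = q.sd_ratio_by_threshold(
            diameters_mm=[4, 6, 12, 20],
            estimates_reader1=[4, -4, 1, -1],
            estimates_reader2=[0, 0, 0, 0],
            thresholds_mm=[10.0],
        )
        row = out.iloc[0]
        assert row["evaluable"]
        assert row["ratio"] == pytest.approx(4.0)

    def test_equal_differences_give_unit_ratio(self):
        out = q.sd_ratio_by_threshold(
            [4, 6, 12, 20], [1, -1, 1, -1], [0, 0, 0, 0], thresholds_mm=[10.0]
        )
        assert out.iloc[0]["ratio"] == pytest.approx(1.0)

    def test_unevaluable_threshold_marked(self):
        out = q.sd_ratio_by_threshold(
            [4, 6, 12, 20], [4, -4, 1, -1], [0, 0, 0, 0], thresholds_mm=[1.0]
        )
        assert not out.iloc[0]["evaluable"]
        assert math.isnan(out.iloc[0]["ratio"])

    def test_empty_lesion_list_rejected(self):
        with pytest.raises(ConfigurationError):
            q.sd_ratio_by_threshold([], [], [], [10.0])


class TestAnalyzeStudy:
    def test_noise_free_study_is_all_zero_sw_and_unit_icc(self):
        cfg = uniform_config(n_subjects=5, mean=100.0, between=10.0)
        table = q.generate_measurement_table(cfg)
        report = q.analyze_study(table)
        for key, s in report.summaries.items():
            assert s.sw == 0.0
            assert s.cov_percent == 0.0
            assert s.loa_halfwidth == 0.0
            assert s.icc == 1.0  # between-subject spread > 0, no noise

    def test_report_covers_full_grid(self, reference_table):
        report = q.analyze_study(reference_table)
        assert len(report.summaries) == 6 * 2 * 2
        assert len(report.levene) == 6 * 2
        assert len(report.group_means) == 6
        table = report.to_table()
        assert len(table) == 12
        assert {"sw_small", "cov_small", "sw_large", "cov_large", "levene_p",
                "mean_small", "mean_large", "ttest_p"} <= set(table.columns)

    def test_cell_values_match_direct_computation(self, reference_table):
        report = q.analyze_study(reference_table)
        d = q.build_differences(reference_table, "FF-Mean", "intra", "small")
        s = report.summaries[("FF-Mean", "intra", "small")]
        assert s.sw == pytest.approx(q.within_subject_sd(d), rel=1e-12)
        assert s.loa_halfwidth == pytest.approx(LOA_FACTOR * s.sw, rel=1e-12)
        lev = report.levene[("FF-Mean", "intra")]
        d_large = q.build_differences(reference_table, "FF-Mean", "intra", "large")
        ref = q.levene_equal_variance(d.differences, d_large.differences)
        assert lev.p_value == pytest.approx(ref.p_value, rel=1e-12)

    def test_report_json_round_trip(self, tmp_path, reference_table):
        report = q.analyze_study(reference_table)
        path = tmp_path / "report.json"
        report.to_json(path)
        loaded = q.StudyReport.from_json(path)
        assert loaded.to_json_dict() == report.to_json_dict()

    def test_bland_altman_points_are_mean_vs_difference(self, reference_table):
        report = q.analyze_study(reference_table)
        ba = report.bland_altman[("ADC-Mean", "inter")]
        d = q.build_differences(reference_table, "ADC-Mean", "inter", "small")
        sub = ba[ba["lesion_class"] == "small"]
        np.testing.assert_allclose(sub["difference"].to_numpy(), d.differences)
        np.testing.assert_allclose(sub["mean"].to_numpy(), d.pair_means)
        assert (sub["loa_center"] == 0.0).all()
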