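"""Calibration regression, census aggregation, and error propagation."""

import numpy as np
import pytest

import pengcensus as pc
from pengcensus.census import SiteCount, RegionalBaseline
from pengcensus.field_counts import N1, N2


class TestCalibration:
    def test_identity_line(self):
        m = pc.fit_calibration([(10, 10), (20, 20), (30, 30)], "s")
        assert m.slope == pytest.approx(1.0)
        assert m.intercept == pytest.approx(0.0)
        assert m.residual_scale == 0.0

    def test_exact_two_point_line(self):
        m = pc.fit_calibration([(10, 21), (20, 41)], "s")
        assert m.slope == pytest.approx(2.0)
        assert m.intercept == pytest.approx(1.0)
        assert m.residual_scale == 0.0

    def test_parameter_recovery_under_noise(self, rng):
        x = rng.uniform(50, 400, size=20)
        y = 1.05 * x - 3 + rng.normal(0, 2, size=20)
        m = pc.fit_calibration(np.column_stack([x, y]), "s")
        sxx = np.sum((x - x.mean()) ** 2)
        se_slope = m.residual_scale / np.sqrt(sxx)
        assert abs(m.slope - 1.05) <= 3 * se_slope

    def test_degenerate_design_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            pc.fit_calibration([(10, 11), (10, 12), (10, 13)], "s")

    @pytest.mark.parametrize("detected,expected", [
        (500, 500), (0, 0),
    ])
    def test_apply_identity_model(self, detected, expected):
        m = pc.fit_calibration([(10, 10), (20, 20), (30, 30)], "s")
        est, rel = pc.apply_calibration(m, detected)
        assert est == expected and rel == 0.0

    def test_apply_two_point_model(self):
        m = pc.fit_calibration([(10, 21), (20, 41)], "s")
        est, _ = pc.apply_calibration(m, 10)
        assert est == 21

    def test_negative_estimate_forced_to_zero_with_warning(self):
        m = pc.fit_calibration([(100, 10), (200, 5), (300, 0)], "s")
        with pytest.warns(UserWarning, match="forcing 0"):
            est, _ = pc.apply_calibration(m, 1000)
        assert est == 0


class TestAggregation:
    def test_census_table_sums(self):
        sites = pc.load_table1()
        assert pc.sum_census(sites, "adeliae") == 751_527
        assert pc.sum_census(sites, "antarctica") == 27
        assert pc.sum_census([], "adeliae") == 0

    def test_duplicate_island_records_rejected(self):
        sites = [SiteCount("a", "adeliae", 10, N1),
                 SiteCount("a", "adeliae", 12, N1)]
        with pytest.raises(ValueError, match="duplicate"):
            pc.sum_census(sites, "adeliae")

    @pytest.mark.parametrize("total,expected", [
        (751_527, 55), (0, 0), (606_526, 50),
    ])
    def test_regional_share(self, total, expected):
        assert round(pc.regional_share(total)) == expected

    def test_regional_share_unrounded_value(self):
        assert pc.regional_share(751_527) == pytest.approx(55.34, abs=0.01)


class TestPropagation:
    def test_zero_half_width_collapses_ci_to_point(self):
        sites = [SiteCount("a", "adeliae", 100, N1),
                 SiteCount("b", "adeliae", 200, N1)]
        est = pc.propagate_error(sites, "normal95", 2000, seed=0,
                                 half_width_override={"N1": 0.0})
        assert est.ci_low == est.total == est.ci_high == 300

    def test_two_site_half_width_matches_closed_form(self):
        sites = [SiteCount("a", "adeliae", 100, N2),
                 SiteCount("b", "adeliae", 100, N2)]
        est = pc.propagate_error(sites, "normal95", 100_000, seed=3)
        half = (est.ci_high - est.ci_low) / 2
        expected = 1.96 * np.sqrt(2) * (10 / 1.96)
        assert abs(half - expected) <= 0.05 * expected

    def test_uniform_interpretation_is_narrower(self):
        sites = [SiteCount("a", "adeliae", 1000, N2)]
        n = pc.propagate_error(sites, "normal95", 50_000, seed=1)
        u = pc.propagate_error(sites, "uniform", 50_000, seed=1)
        assert (u.ci_high - u.ci_low) < (n.ci_high - n.ci_low)
        assert u.ci_low >= 900 - 1 and u.ci_high <= 1100 + 1

    def test_ci_half_width_converges_when_replicates_double(self):
        sites = pc.load_table1()

        def mean_half_width(n_reps, seeds):
            halves = [
                (e.ci_high - e.ci_low) / 2
                for e in (pc.propagate_error(sites, "normal95", n_reps, s)
                          for s in seeds)
            ]
            return np.mean(halves)

        a = mean_half_width(50_000, (7, 8, 9))
        b = mean_half_width(100_000, (17, 18, 19))
        assert abs(a - b) / b < 0.01

    def test_unknown_interpretation_rejected(self):
        with pytest.raises(ValueError, match="interpretation"):
            pc.propagate_error(pc.load_table1(), "triangular", 2000, 0)

    def test_baseline_fixture_values(self):
        b = RegionalBaseline()
        assert b.pairs == 606_526 and b.ci == (322_477, 990_402)
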