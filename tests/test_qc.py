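"""Calibration linearity, precision, stability, IS quantification, QC gate."""

import numpy as np
import pytest

from mrmkit.errors import InputError
from mrmkit.qc import (
    QcConfig,
    assess_precision,
    assess_stability,
    fit_linearity,
    qc_gate,
    quantify_with_is,
)
from mrmkit.synthetic import generate_calibration_series


def _line_points(slope=2.0, intercept=1.0, n=6):
    conc = 2.0 ** np.arange(n)
    return list(zip(conc, slope * conc + intercept))


class TestLinearity:
    def test_exact_line(self):
        res = fit_linearity(_line_points())
        assert res.r_squared == pytest.approx(1.0, abs=1e-12)
        assert res.slope == pytest.approx(2.0)
        assert res.intercept == pytest.approx(1.0)
        assert np.allclose(res.per_point_accuracy, 100.0)
        assert res.accuracy_pass

    def test_one_outlier_still_passes(self):
        # a +30% outlier at the lowest point leaves the other five
        # back-calculated accuracies within +/-20%: 5 of 6 rule passes
        pts = _line_points(intercept=0.0)
        conc, resp = pts[0]
        pts[0] = (conc, resp * 1.3)
        res = fit_linearity(pts)
        assert res.accuracy_pass

    def test_two_outliers_fail(self):
        pts = _line_points(intercept=0.0)
        for i in (2, 4):
            conc, resp = pts[i]
            pts[i] = (conc, resp * 1.3)
        assert not fit_linearity(pts).accuracy_pass

    def test_too_few_points(self):
        with pytest.raises(InputError):
            fit_linearity(_line_points(n=5))

    def test_zero_conc_variance(self):
        with pytest.raises(InputError):
            fit_linearity([(1.0, 2.0)] * 6)

    def test_r2_decreases_with_noise(self):
        def mean_r2(cv):
            vals = []
            for seed in range(100):
                table = generate_calibration_series(
                    6, slope=2.0, intercept=0.0, error_cv=cv, seed=seed
                )
                vals.append(fit_linearity(table).r_squared)
            return np.mean(vals)

        assert mean_r2(0.0) == pytest.approx(1.0, abs=1e-12)
        assert mean_r2(0.02) > mean_r2(0.1) > mean_r2(0.3)

    def test_weighted_option_exact_line(self):
        res = fit_linearity(_line_points(), cfg=QcConfig(weighted_1_over_x=True))
        assert res.slope == pytest.approx(2.0) and res.r_squared == pytest.approx(1.0)


class TestPrecision:
    def test_identical_replicates(self):
        res = assess_precision({0: [100] * 5, 1: [100] * 5})
        assert res.intra_day_cv == 0.0 and res.inter_day_cv == 0.0 and res.passed

    def test_hand_computed_cv(self):
        res = assess_precision({0: [90, 95, 100, 105, 110]})
        assert res.intra_day_cv == pytest.approx(7.9057, abs=1e-3)

    def test_worst_day_governs(self):
        good = [100, 101, 99, 100, 100]
        bad = [60, 140, 100, 130, 70]  # CV ~ 35%
        res = assess_precision({0: good, 1: bad})
        assert not res.passed and res.intra_day_cv > 20

    def test_interday_cv_of_daily_means(self):
        res = assess_precision({0: [100] * 5, 1: [120] * 5})
        means = np.array([100.0, 120.0])
        expected = means.std(ddof=1) / means.mean() * 100
        assert res.inter_day_cv == pytest.approx(expected)

    def test_nonpositive_mean_fails(self):
        res = assess_precision({0: [0.0, 0.0, 0.0]})
        assert not res.passed


class TestStability:
    @pytest.mark.parametrize(
        "day7,expected",
        [(100.0, True), (70.0, False), (115.0, True), (125.0, False)],
    )
    def test_recovery_rule(self, day7, expected):
        res = assess_stability(100.0, day7)
        assert res.passed is expected
        assert res.recovery_pct == pytest.approx(day7)

    def test_nonpositive_day0(self):
        res = assess_stability(0.0, 50.0)
        assert not res.passed and "nonpositive_day0" in res.reasons

    def test_unknown_condition(self):
        with pytest.raises(InputError):
            assess_stability(100, 100, condition="room_temp")


class TestIsQuantification:
    @pytest.mark.parametrize(
        "analyte,is_area,is_amount,expected",
        [(2000, 1000, 5.0, 10.0), (0, 1000, 5.0, 0.0), (1500, 3000, 10.0, 5.0)],
    )
    def test_arithmetic(self, analyte, is_area, is_amount, expected):
        assert quantify_with_is(analyte, is_area, is_amount) == pytest.approx(expected)

    def test_zero_is_area(self):
        with pytest.raises(InputError):
            quantify_with_is(100, 0, 5)

    def test_linearity_and_common_scaling(self, rng):
        a, i, amt = 1234.0, 567.0, 2.5
        base = quantify_with_is(a, i, amt)
        assert quantify_with_is(3 * a, i, amt) == pytest.approx(3 * base)
        assert quantify_with_is(a, i, 3 * amt) == pytest.approx(3 * base)
        assert quantify_with_is(7 * a, 7 * i, amt) == pytest.approx(base)


class TestGate:
    def _components(self, pid, cal_ok=True, prec_ok=True, stab_ok=True):
        pts = _line_points()
        if not cal_ok:
            for i in (1, 3):
                c, r = pts[i]
                pts[i] = (c, r * 1.4)
        cal = fit_linearity(pts, pid)
        prec = assess_precision(
            {0: [100] * 5, 1: ([100] * 5 if prec_ok else [50, 150, 100, 40, 160])},
            100.0, pid,
        )
        stab = [
            assess_stability(100.0, 100.0 if stab_ok else 60.0, c, pid)
            for c in ("deep_freeze", "fridge_4C")
        ]
        return cal, prec, stab

    def test_all_pass_validates(self):
        cal, prec, stab = self._components("m1")
        gate = qc_gate(["m1"], {"m1": cal}, {"m1": prec}, {"m1": stab})
        assert gate[0].validated and not gate[0].failed_tests

    def test_stability_failure_names_the_test(self):
        cal, prec, stab = self._components("m1", stab_ok=False)
        gate = qc_gate(["m1"], {"m1": cal}, {"m1": prec}, {"m1": stab})
        assert not gate[0].validated and gate[0].failed_tests == ["stability"]

    def test_missing_component_is_incomplete(self):
        cal, prec, stab = self._components("m1")
        gate = qc_gate(["m1"], {}, {"m1": prec}, {"m1": stab})
        assert not gate[0].validated and "incomplete_qc" in gate[0].failed_tests

    def test_sixteen_candidates_nine_engineered_passes(self):
        # funnel fixture: 16 candidates, exactly 9 built to pass all gates
        ids = [f"m{i:02d}" for i in range(16)]
        cal, prec, stab = {}, {}, {}
        fail_plan = {
            "m09": dict(cal_ok=False), "m10": dict(prec_ok=False),
            "m11": dict(stab_ok=False), "m12": dict(cal_ok=False, stab_ok=False),
            "m13": dict(prec_ok=False), "m14": dict(stab_ok=False),
            "m15": dict(cal_ok=False),
        }
        for pid in ids:
            c, p, s = self._components(pid, **fail_plan.get(pid, {}))
            cal[pid], prec[pid], stab[pid] = c, p, s
        gate = qc_gate(ids, cal, prec, stab)
        validated = [g.peptide_id for g in gate if g.validated]
        assert validated == [f"m{i:02d}" for i in range(9)]

    def test_relaxing_tolerance_is_monotone(self):
        cal, prec, stab = self._components("m1", stab_ok=False)
        strict = qc_gate(["m1"], {"m1": cal}, {"m1": prec}, {"m1": stab})
        loose_stab = [
            assess_stability(100.0, 60.0, c, "m1",
                             QcConfig(stability_tolerance_pct=50.0))
            for c in ("deep_freeze", "fridge_4C")
        ]
        loose = qc_gate(["m1"], {"m1": cal}, {"m1": prec}, {"m1": loose_stab})
        assert loose[0].validated and not strict[0].validated
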