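"""Unit and property tests for the repolarization model core."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fetalqt import core_model as cm
from fetalqt.errors import (
    ConfigurationError,
    DegenerateGridError,
    ImplausibleBeatError,
    InvalidArgumentError,
    NoEstimateError,
)


from _oracles import brute_force_t_end


class TestRepolarizationCurve:
    def test_starts_at_v0_and_follows_formula(self):
        c = cm.repolarization_curve(425.0)
        assert c.values[0] == 100.0
        assert c.t_ms[0] == 0.0
        np.testing.assert_allclose(
            c.values, 100.0 * np.exp(-2 * np.pi * c.t_ms / 425.0), rtol=1e-12
        )
        # the continuous curve decays to 100*e^(-2*pi) ~ 0.187 at t -> RR
        assert 100.0 * math.exp(-2 * math.pi * c.t_ms[-1] / 425.0) == pytest.approx(
            c.values[-1]
        )
        assert c.values[-1] < 0.2

    @settings(deadline=None, max_examples=60)
    @given(rr=st.floats(min_value=250.0, max_value=700.0))
    def test_strictly_decreasing_and_bounded(self, rr):
        c = cm.repolarization_curve(rr)
        assert np.all(np.diff(c.values) < 0)
        assert np.all(c.values > 0) and np.all(c.values <= 100.0)
        assert np.all((c.t_ms >= 0) & (c.t_ms < rr))

    @pytest.mark.parametrize("alpha", [0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9])
    @pytest.mark.parametrize("rr", [300.0, 425.0, 557.0])
    def test_scale_covariance(self, alpha, rr):
        """The value at t = alpha*RR is 100*e^(-2*pi*alpha), whatever RR is."""
        c = cm.repolarization_curve(rr, dt_ms=alpha * rr)
        assert c.values[1] == pytest.approx(100.0 * math.exp(-2 * math.pi * alpha), rel=1e-12)

    @pytest.mark.parametrize("rr", [300.0, 334.0, 425.0, 557.0, 1000.0])
    def test_mean_close_to_analytic_limit(self, rr):
        c = cm.repolarization_curve(rr, dt_ms=1.0)
        assert c.mean() == pytest.approx(cm.CURVE_MEAN_LIMIT, rel=5e-3)

    def test_invalid_arguments(self):
        with pytest.raises(InvalidArgumentError):
            cm.repolarization_curve(-5.0)
        with pytest.raises(InvalidArgumentError):
            cm.repolarization_curve(400.0, dt_ms=0.0)
        with pytest.raises(DegenerateGridError):
            cm.repolarization_curve(100.0, dt_ms=200.0)


class TestBandConstant:
    def test_quotient_reading_value(self):
        # arithmetic evaluation of the printed formula with the closed-form
        # curve mean ~15.886: |15.886/2.3529 - 6*pi*2.3529^2| ~ 97.61
        c = cm.repolarization_curve(425.0)
        band = cm.compute_k(c, "quotient")
        x = 1000.0 / 425.0
        assert band.k == pytest.approx(abs(c.mean() / x - 6 * math.pi * x**2), rel=1e-12)
        assert band.k == pytest.approx(97.61, abs=0.01)
        assert band.x_hz == pytest.approx(x)

    def test_product_reading_value(self):
        # same oracle, alternate reading: |15.886*2.3529 - 6*pi*2.3529^2| ~ 66.98
        c = cm.repolarization_curve(425.0)
        band = cm.compute_k(c, "product")
        x = 1000.0 / 425.0
        assert band.k == pytest.approx(abs(c.mean() * x - 6 * math.pi * x**2), rel=1e-12)
        assert band.k == pytest.approx(66.98, abs=0.01)

    @settings(deadline=None, max_examples=40)
    @given(rr=st.floats(min_value=250.0, max_value=700.0),
           interp=st.sampled_from(["quotient", "product"]))
    def test_k_is_nonnegative(self, rr, interp):
        assert cm.compute_k(cm.repolarization_curve(rr), interp).k >= 0

    def test_unknown_interpretation(self):
        c = cm.repolarization_curve(425.0)
        with pytest.raises(ConfigurationError):
            cm.compute_k(c, "nonsense")

    def test_register_interpretation(self):
        cm.register_interpretation("_test_linear", lambda mean, x: mean - x)
        try:
            c = cm.repolarization_curve(425.0)
            band = cm.compute_k(c, "_test_linear")
            assert band.k == pytest.approx(abs(c.mean() - c.x_hz))
        finally:
            del cm.BAND_INTERPRETATIONS["_test_linear"]


class TestTEndFromCurve:
    def test_median_of_three_consecutive_grid_points(self):
        # k = 33.8 puts exactly the samples t = 72, 73, 74 ms inside the open
        # band for RR = 425 ms (checked against the curve values on the grid)
        c = cm.repolarization_curve(425.0)
        est = cm.t_end_from_curve(c, 33.8)
        assert est.n_in_band == 3
        assert est.t_end_ms == 73.0

    def test_matches_exhaustive_scan(self):
        c = cm.repolarization_curve(425.0)
        k = 97.61
        selected = [t for t, v in zip(c.t_ms, c.values) if k - 0.5 < v < k + 1.0]
        est = cm.t_end_from_curve(c, k)
        assert est.t_end_ms == float(np.median(selected))
        assert est.n_in_band == len(selected)

    def test_empty_band_raises(self):
        c = cm.repolarization_curve(425.0)
        with pytest.raises(NoEstimateError):
            cm.t_end_from_curve(c, 300.0)  # band entirely above the curve range

    def test_band_at_r_peak_raises(self):
        # k just under 100: band covers only t = 0, violating 0 < t_end
        c = cm.repolarization_curve(425.0)
        with pytest.raises(NoEstimateError):
            cm.t_end_from_curve(c, 99.8)

    @settings(deadline=None, max_examples=80)
    @given(rr=st.floats(min_value=300.0, max_value=700.0),
           k=st.floats(min_value=1.0, max_value=99.0))
    def test_median_band_properties(self, rr, k):
        """Returned time is a grid point (or midpoint of two), lies inside the
        beat, and splits the band samples evenly."""
        c = cm.repolarization_curve(rr)
        try:
            est = cm.t_end_from_curve(c, k)
        except NoEstimateError:
            return
        assert 0 < est.t_end_ms < rr
        mask = (c.values > est.band_low) & (c.values < est.band_high)
        times = c.t_ms[mask]
        n_before = int(np.sum(times < est.t_end_ms))
        n_after = int(np.sum(times > est.t_end_ms))
        assert abs(n_before - n_after) <= 1
        assert est.band_high - est.band_low == pytest.approx(1.5)

    def test_plausibility_flag(self):
        c = cm.repolarization_curve(500.0)
        early = cm.t_end_from_curve(c, cm.compute_k(c, "quotient"))
        assert not early.plausible  # quotient reading lands ~30 ms after R
        in_window = cm.t_end_from_curve(c, 10.0)  # R(t)~10 around t=183 ms
        assert in_window.plausible


class TestQtc:
    # printed group means (QT, RR) -> printed QTc, model-based and reference
    # columns of the clinical comparison tables; recomputation matches the
    # printed value within 1 ms after rounding (inputs are themselves rounded)
    TABLE = [
        (244.0, 425.0, 325),
        (245.0, 425.0, 326),
        (324.0, 557.0, 394),
        (196.0, 334.0, 283),
        (254.0, 432.0, 336),
        (233.0, 406.0, 315),
        (231.0, 408.0, 311),
        (237.0, 411.0, 318),
    ]

    @pytest.mark.parametrize("qt,rr,expected", TABLE)
    def test_fridericia_on_printed_group_means(self, qt, rr, expected):
        assert abs(round(cm.qtc(qt, rr, "fridericia")) - expected) <= 1

    @pytest.mark.parametrize("formula", sorted(cm.QTC_FORMULAS))
    def test_all_formulas_identity_at_rr_1000(self, formula):
        assert cm.qtc(300.0, 1000.0, formula) == pytest.approx(300.0)

    def test_formula_definitions(self):
        assert cm.qtc(300.0, 640.0, "bazett") == pytest.approx(300.0 / 0.8)
        assert cm.qtc(300.0, 500.0, "framingham") == pytest.approx(300.0 + 154.0 * 0.5)
        assert cm.qtc(300.0, 500.0, "hodges") == pytest.approx(300.0 + 1.75 * 60.0)

    def test_invalid_inputs(self):
        with pytest.raises(InvalidArgumentError):
            cm.qtc(-1.0, 400.0)
        with pytest.raises(InvalidArgumentError):
            cm.qtc(300.0, 0.0)
        with pytest.raises(ConfigurationError):
            cm.qtc(300.0, 400.0, "unknown")


class TestEstimateBeat:
    def test_zero_q_offset_makes_qt_equal_t_end(self):
        m = cm.estimate_beat(0.0, 500.0, 0.0)
        assert m.qt_ms == m.t_end_offset_ms
        assert m.hr_bpm * m.rr_ms == pytest.approx(60000.0)

    def test_estimator_depends_only_on_rr(self):
        ms = [cm.estimate_beat(i * 500.0, 500.0, 35.0) for i in range(200)]
        offsets = {m.t_end_offset_ms for m in ms}
        assert len(offsets) == 1

    def test_qt_is_sum_of_q_offset_and_t_end(self):
        m = cm.estimate_beat(0.0, 500.0, 35.0)
        assert m.qt_ms == m.q_offset_ms + m.t_end_offset_ms
        assert m.qt_ms < m.rr_ms

    @pytest.mark.parametrize("interp", ["quotient", "product"])
    @pytest.mark.parametrize("rr", [334.0, 405.0, 425.0, 432.0, 557.0])
    def test_batch_matches_brute_force(self, interp, rr):
        cfg = cm.ModelConfig(interpretation=interp)
        try:
            expected = brute_force_t_end(rr, interp)
        except ValueError:
            with pytest.raises(NoEstimateError):
                cm.estimate_beat(0.0, rr, 0.0, cfg)
            return
        m = cm.estimate_beat(0.0, rr, 0.0, cfg)
        assert m.t_end_offset_ms == expected

    def test_degenerate_rr_excluded(self):
        with pytest.raises(ImplausibleBeatError):
            cm.estimate_beat(0.0, 150.0, 10.0)
        with pytest.raises(ImplausibleBeatError):
            cm.estimate_beat(0.0, 1500.0, 10.0)

    def test_invalid_q_offset(self):
        with pytest.raises(InvalidArgumentError):
            cm.estimate_beat(0.0, 400.0, -5.0)
        with pytest.raises(InvalidArgumentError):
            cm.estimate_beat(0.0, 400.0, 400.0)

    def test_batch_collects_rejections(self):
        import pandas as pd

        beats = pd.DataFrame(
            {
                "beat_index": [0, 1, 2],
                "r_time_ms": [0.0, 500.0, 1000.0],
                "rr_ms": [500.0, 150.0, 500.0],
                "q_offset_ms": [35.0, 35.0, 35.0],
            }
        )
        measures, excluded = cm.estimate_beats(beats)
        assert list(measures["beat_index"]) == [0, 2]
        assert list(excluded["beat_index"]) == [1]
        assert "bounds" in excluded["reason"].iloc[0]


class TestCalibration:
    def test_sweep_covers_all_interpretations(self):
        df = cm.calibrate_interpretations(np.arange(400.0, 451.0, 10.0))
        assert set(df["interpretation"]) == set(cm.BAND_INTERPRETATIONS)
        assert len(df) == 2 * 6

    def test_sweep_is_deterministic(self):
        a = cm.calibrate_interpretations(np.arange(330.0, 601.0, 30.0))
        b = cm.calibrate_interpretations(np.arange(330.0, 601.0, 30.0))
        assert a.equals(b)
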