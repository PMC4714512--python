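"""Thermal-stability and FRAP normalization formulas."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import tssenrich as te
from tssenrich.assay_curves import HalfTemperature


def melt_curve(temps, fluor):
    return te.MeltCurve(np.asarray(temps, float), np.asarray(fluor, float))


def linear_curve(a, b):
    temps = np.arange(26.0, 96.0)
    return melt_curve(temps, a + b * temps)


class TestNormalizeMeltCurve:
    def test_midpoint_value(self):
        curve = melt_curve([26, 60, 95], [100, 200, 300])
        norm = te.normalize_melt_curve(curve)
        assert norm["normalized_fluorescence"].tolist() == [0.0, 0.5, 1.0]

    def test_anchors_are_exactly_zero_and_one(self):
        curve = linear_curve(37.0, 2.5)
        norm = te.normalize_melt_curve(curve).set_index("temperature")
        assert norm.loc[26.0, "normalized_fluorescence"] == 0.0
        assert norm.loc[95.0, "normalized_fluorescence"] == 1.0

    def test_linear_raw_curve_normalizes_to_linear_ramp(self):
        norm = te.normalize_melt_curve(linear_curve(10.0, 3.0))
        expected = (norm["temperature"] - 26.0) / (95.0 - 26.0)
        np.testing.assert_allclose(norm["normalized_fluorescence"], expected)

    @given(st.floats(-1e3, 1e3, allow_nan=False),
           st.floats(0.1, 100, allow_nan=False))
    def test_invariant_to_affine_gain_and_offset(self, offset, gain):
        base = melt_curve([26, 50, 70, 95], [5.0, 40.0, 90.0, 120.0])
        transformed = melt_curve(base.temperature,
                                 gain * base.fluorescence + offset)
        np.testing.assert_allclose(
            te.normalize_melt_curve(transformed)["normalized_fluorescence"],
            te.normalize_melt_curve(base)["normalized_fluorescence"],
            rtol=1e-9, atol=1e-12)

    def test_missing_anchor_and_degenerate_curve_rejected(self):
        with pytest.raises(ValueError, match="26"):
            te.normalize_melt_curve(melt_curve([30, 95], [1.0, 2.0]))
        with pytest.raises(ValueError, match="degenerate"):
            te.normalize_melt_curve(melt_curve([26, 95], [2.0, 2.0]))


class TestMeltHalfTemperature:
    @staticmethod
    def norm_frame(temps, values):
        import pandas as pd
        return pd.DataFrame({"temperature": temps,
                             "normalized_fluorescence": values})

    def test_linear_interpolation_between_bracketing_points(self):
        half = te.melt_half_temperature(self.norm_frame([50, 52], [0.4, 0.6]))
        assert half == HalfTemperature(51.0, False)

    def test_exact_half_sample_returned_as_is(self):
        half = te.melt_half_temperature(
            self.norm_frame([50, 51, 52], [0.2, 0.5, 0.9]))
        assert half.temperature_c == 51.0

    def test_logistic_midpoint_recovered_within_half_degree(self):
        temps = np.arange(26.0, 96.0)  # 1 degree sampling
        raw = 1 / (1 + np.exp(-(temps - 70.0) / 4.0))
        norm = te.normalize_melt_curve(melt_curve(temps, raw))
        half = te.melt_half_temperature(norm)
        assert half.temperature_c == pytest.approx(70.0, abs=0.5)
        assert not half.multiple_crossings

    def test_multiple_crossings_flagged_first_returned(self):
        half = te.melt_half_temperature(
            self.norm_frame([40, 42, 44, 46], [0.3, 0.7, 0.3, 0.8]))
        assert half.multiple_crossings
        assert half.temperature_c == 41.0

    def test_no_crossing_rejected(self):
        with pytest.raises(ValueError, match="0.5"):
            te.melt_half_temperature(self.norm_frame([40, 50], [0.1, 0.2]))


def test_replicate_averaging_pointwise_mean_and_sd():
    temps = [26, 60, 95]
    a = melt_curve(temps, [0.0, 40.0, 100.0])
    b = melt_curve(temps, [10.0, 70.0, 110.0])  # normalized mid = 0.6
    avg = te.average_melt_replicates([a, b])
    np.testing.assert_allclose(avg["mean"], [0.0, 0.5, 1.0])
    np.testing.assert_allclose(avg["sd"][1],
                               np.std([0.4, 0.6], ddof=1))


class TestFrapRelativeIntensity:
    @staticmethod
    def series(time, bleached, unbleached, background, n_pre=1):
        return te.FrapSeries(np.asarray(time, float),
                             np.asarray(bleached, float),
                             np.asarray(unbleached, float),
                             np.asarray(background, float), n_pre)

    def test_equal_channels_give_constant_one(self):
        s = self.series([0, 1, 2], [50, 60, 70], [50, 60, 70], [10, 10, 10])
        out = te.frap_relative_intensity(s)
        np.testing.assert_allclose(out["relative_intensity"], 1.0)

    def test_prebleach_anchor_is_exactly_one(self):
        s = self.series([-1, 0, 1], [110, 60, 70], [110, 110, 110],
                        [10, 10, 10])
        out = te.frap_relative_intensity(s)
        assert out["relative_intensity"].iloc[0] == 1.0

    def test_half_recovery_arithmetic(self):
        s = self.series([-1, 1], [110, 60], [110, 110], [10, 10])
        out = te.frap_relative_intensity(s)
        assert out["relative_intensity"].iloc[1] == pytest.approx(0.5)

    def test_full_recovery_returns_to_one(self):
        s = self.series([-1, 1, 60], [110, 60, 110], [110, 110, 110],
                        [10, 10, 10])
        out = te.frap_relative_intensity(s)
        assert out["relative_intensity"].iloc[-1] == pytest.approx(1.0)

    @given(st.floats(0.1, 50, allow_nan=False),
           st.floats(-20, 20, allow_nan=False))
    def test_invariant_to_channel_scale_and_shift(self, gain, shift):
        base = self.series([-1, 1, 5], [110, 60, 90], [110, 108, 109],
                           [10, 10, 10])
        scaled = self.series(
            base.time_min, gain * base.bleached + shift,
            gain * base.unbleached + shift, gain * base.background + shift)
        np.testing.assert_allclose(
            te.frap_relative_intensity(scaled)["relative_intensity"],
            te.frap_relative_intensity(base)["relative_intensity"],
            rtol=1e-9)

    def test_nonpositive_corrected_unbleached_rejected(self):
        with pytest.raises(ValueError, match="unbleached"):
            self.series([0, 1], [5, 5], [10, 10], [10, 10])
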