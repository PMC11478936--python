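"""Calibration chain: H3+ factor, delta notation, normalization, drift,
methanol correction and error propagation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from isofame.calibrate import (
    drift_check,
    estimate_h3_factor,
    fit_two_point,
    h3_correct,
    methanol_correct,
    normalize_delta,
    propagate_uncertainty,
    raw_delta,
)
from isofame.simulate import simulate_dilution_series


class TestH3Correction:
    def test_zero_factor_leaves_series_unchanged(self):
        i2 = np.array([1.0, 5.0, 2.0])
        i3 = np.array([0.0005, 0.0026, 0.001])
        assert np.array_equal(h3_correct(i2, i3, 0.0), i3)

    def test_constant_series_recovers_true_ratio(self):
        # i2 = 5 V, true ratio 500 ppm, K = 3 ppm/V: i3 = 2500 + 75 uV
        i2 = np.full(10, 5.0)
        i3 = 500e-6 * i2 + 3e-6 * i2**2
        assert np.allclose(i3, 2575e-6)
        corrected = h3_correct(i2, i3, 3.0)
        assert np.allclose(corrected / i2, 500e-6)

    def test_correction_vanishes_with_signal(self):
        i2 = np.array([1e-9])
        i3 = np.array([5e-13])
        assert h3_correct(i2, i3, 3.0)[0] == pytest.approx(i3[0], rel=1e-6)

    def test_negative_factor_rejected(self):
        with pytest.raises(ValueError):
            h3_correct(np.ones(3), np.ones(3), -1.0)


class TestH3Estimation:
    def test_noiseless_recovery_of_injected_factor(self):
        for k in (0.0, 3.0):
            traces = simulate_dilution_series(k, [1, 2, 3, 4, 6, 8], seed=0)
            k_hat, u_k = estimate_h3_factor(traces)
            assert k_hat == pytest.approx(k, abs=1e-9)

    def test_two_pulses_rejected(self):
        traces = simulate_dilution_series(3.0, [1.0, 4.0], seed=0)
        with pytest.raises(ValueError, match="3 pulses"):
            estimate_h3_factor(traces)

    def test_narrow_amplitude_range_rejected(self):
        traces = simulate_dilution_series(3.0, [4.0, 4.5, 5.0], seed=0)
        with pytest.raises(ValueError, match="degenerate"):
            estimate_h3_factor(traces)


class TestRawDelta:
    def test_sample_equal_to_reference(self):
        assert raw_delta(3e-4, 3e-4, 0.0) == pytest.approx(0.0, abs=1e-12)

    def test_zero_deuterium_limit(self):
        assert raw_delta(0.0, 3e-4, -100.0) == pytest.approx(-1000.0)

    def test_worked_example(self):
        # ratio 1.1 vs reference assigned -100: (1.1 * 0.9 - 1) * 1000 = -10
        assert raw_delta(1.1, 1.0, -100.0) == pytest.approx(-10.0, abs=1e-9)

    def test_invalid_reference_rejected(self):
        with pytest.raises(ValueError):
            raw_delta(1.0, 0.0, 0.0)


class TestTwoPointNormalization:
    def test_identity_when_measured_equals_assigned(self):
        m, c = fit_two_point((-183.9, -4.9))
        assert m == pytest.approx(1.0) and c == pytest.approx(0.0, abs=1e-12)

    def test_worked_line(self):
        m, c = fit_two_point((-190.0, -10.0))
        assert m == pytest.approx(0.994444, abs=1e-6)
        assert c == pytest.approx(5.0444, abs=1e-4)
        assert normalize_delta(-100.0, m, c) == pytest.approx(-94.40, abs=1e-9)

    def test_order_invariance(self):
        m1, c1 = fit_two_point((-190.0, -10.0), (-183.9, -4.9))
        m2, c2 = fit_two_point((-10.0, -190.0), (-4.9, -183.9))
        assert (m1, c1) == pytest.approx((m2, c2))

    def test_equal_measured_values_rejected(self):
        with pytest.raises(ValueError, match="equal"):
            fit_two_point((-50.0, -50.0))

    @settings(derandomize=True, max_examples=100, deadline=None)
    @given(scale=st.floats(0.8, 1.2), offset=st.floats(-20.0, 20.0))
    def test_anchors_mapped_exactly_for_any_affine_distortion(self, scale, offset):
        assigned = (-183.9, -4.9)
        measured = tuple(scale * a + offset for a in assigned)
        m, c = fit_two_point(measured, assigned)
        for meas, ass in zip(measured, assigned):
            assert normalize_delta(meas, m, c) == pytest.approx(ass, abs=1e-9)


class TestDrift:
    def test_constant_anchors_not_flagged(self):
        df = pd.DataFrame(
            {"anchor": "USGS70", "run_index": range(5), "measured": [-183.9] * 5}
        )
        [res] = drift_check(df)
        assert res.slope == pytest.approx(0.0, abs=1e-12)
        assert not res.flagged

    def test_injected_drift_flagged(self):
        # 1 per-mil/run over 10 runs with 2.7 per-mil scatter: span 10 > 2.7
        rng = np.random.default_rng(4)
        x = np.arange(11)
        df = pd.DataFrame(
            {"anchor": "USGS70", "run_index": x, "measured": -183.9 + 1.0 * x + rng.normal(0, 2.7, 11)}
        )
        [res] = drift_check(df)
        assert res.flagged

    def test_noise_only_rarely_flagged(self):
        """Monte-Carlo calibration: noise-only sequences flag in < 5 % of cases."""
        rng = np.random.default_rng(42)
        flagged = 0
        n_seq = 1000
        x = np.arange(11)
        for _ in range(n_seq):
            df = pd.DataFrame(
                {"anchor": "a", "run_index": x, "measured": -100.0 + rng.normal(0, 2.0, len(x))}
            )
            flagged += drift_check(df)[0].flagged
        assert flagged / n_seq <= 0.05

    def test_single_position_rejected(self):
        df = pd.DataFrame({"anchor": "a", "run_index": [3, 3, 3], "measured": [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError, match="positions"):
            drift_check(df)


class TestMethanolCorrection:
    def test_identity_case(self):
        assert methanol_correct(-100.0, 32, -100.0) == pytest.approx(-100.0, abs=1e-12)

    def test_worked_c16(self):
        # (34*(-200) - 3*(-146.8)) / 31 = -205.1 per mil
        assert methanol_correct(-200.0, 32, -146.8) == pytest.approx(-205.148, abs=5e-4)

    def test_worked_c20(self):
        assert methanol_correct(-183.9, 40, -146.8) == pytest.approx(-186.754, abs=5e-4)

    def test_low_h_count_rejected(self):
        with pytest.raises(ValueError):
            methanol_correct(-200.0, 3, -146.8)


class TestUncertainty:
    @pytest.mark.parametrize(
        "components,expected",
        [((2.7, 1.4, 1.0, 0.3), 3.2), ((1.3, 1.4, 1.0, 0.3), 2.2), ((0, 0, 0, 0), 0.0)],
    )
    def test_quadrature_examples(self, components, expected):
        assert round(propagate_uncertainty(*components), 1) == expected

    def test_negative_component_rejected(self):
        with pytest.raises(ValueError):
            propagate_uncertainty(-1.0, 1.4, 1.0, 0.3)

    @settings(derandomize=True, max_examples=100, deadline=None)
    @given(
        base=st.tuples(*[st.floats(0.0, 10.0)] * 4),
        bump=st.floats(0.0, 5.0),
        which=st.integers(0, 3),
    )
    def test_monotone_in_every_component(self, base, bump, which):
        bigger = list(base)
        bigger[which] += bump
        u0 = propagate_uncertainty(*base)
        u1 = propagate_uncertainty(*bigger)
        assert u1 >= u0 - 1e-12
        assert u0 >= max(base) - 1e-12  # never below the largest component
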