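"""Peak detection, integration, QC gates and coelution merging."""

import numpy as np
import pytest

from conftest import flat_background, gaussian, make_trace
from isofame.peaks import Peak, detect_peaks, integrate_peak, integrate_peaks, merge_coeluting, qc_filter
from isofame.simulate import R_MACHINE


def brute_force_boundaries(amplitude, mu, sigma, start_slope=1.0, end_slope=0.5):
    """Dense-grid scan of the analytic Gaussian derivative with the same
    start/end rules as the detector."""
    tt = np.arange(mu - 8 * sigma, mu + 8 * sigma, 0.001)
    d = -amplitude * (tt - mu) / sigma**2 * np.exp(-(((tt - mu) / sigma) ** 2) / 2)
    start = tt[np.argmax(d >= start_slope)]
    after_apex = tt > mu
    descended = after_apex & (d < -end_slope)
    t_desc = tt[np.argmax(descended)]
    recover = (tt > t_desc) & (d >= -end_slope)
    end = tt[np.argmax(recover)]
    return float(start), float(end)


class TestDetection:
    def test_constant_trace_yields_no_peaks(self, time_axis):
        trace = make_trace(time_axis, np.full(len(time_axis), 30.0))
        assert detect_peaks(trace, flat_background(len(time_axis), 30.0)) == []

    def test_single_gaussian_matches_brute_force_scan(self, time_axis):
        amplitude, mu, sigma = 2000.0, 300.0, 5.0
        trace = make_trace(time_axis, gaussian(time_axis, amplitude, mu, sigma))
        [peak] = detect_peaks(trace, flat_background(len(time_axis)))
        assert abs(peak.t_apex - mu) <= 0.25  # within one sample of the true centre
        start, end = brute_force_boundaries(amplitude, mu, sigma)
        # boundaries match the analytic scan up to the derivative-smoothing
        # window (21 samples at 4 Hz -> sub-second lag on the tail)
        assert peak.t_start == pytest.approx(start, abs=0.75)
        assert peak.t_end == pytest.approx(end, abs=1.0)

    def test_well_separated_pair_yields_two_clean_peaks(self, time_axis):
        y = gaussian(time_axis, 2000.0, 280.0, 5.0) + gaussian(time_axis, 2000.0, 320.0, 5.0)
        trace = make_trace(time_axis, y)
        peaks = detect_peaks(trace, flat_background(len(time_axis)))
        assert len(peaks) == 2
        assert all("merged" not in p.flags for p in peaks)

    def test_partially_resolved_pair_split_and_flagged_merged(self, time_axis):
        # 3 sigma apart: split at a valley that stays far above baseline
        y = gaussian(time_axis, 2000.0, 280.0, 5.0) + gaussian(time_axis, 2000.0, 295.0, 5.0)
        trace = make_trace(time_axis, y)
        peaks = detect_peaks(trace, flat_background(len(time_axis)))
        assert len(peaks) == 2
        assert all("merged" in p.flags for p in peaks)

    def test_unresolvable_pair_is_one_region(self, time_axis):
        # 1 sigma apart: the sum is unimodal; a single region is detected
        # (the simulator's GroundTruth carries the overlap warning instead)
        y = gaussian(time_axis, 2000.0, 280.0, 5.0) + gaussian(time_axis, 2000.0, 285.0, 5.0)
        trace = make_trace(time_axis, y)
        peaks = detect_peaks(trace, flat_background(len(time_axis)))
        assert len(peaks) == 1

    def test_detection_invariant_to_constant_background_offset(self, time_axis):
        y = gaussian(time_axis, 2000.0, 300.0, 5.0)
        n = len(time_axis)
        p0 = detect_peaks(make_trace(time_axis, y), flat_background(n))
        p1 = detect_peaks(make_trace(time_axis, y + 100.0), flat_background(n, 100.0))
        assert [(p.t_start, p.t_apex, p.t_end) for p in p0] == [
            (p.t_start, p.t_apex, p.t_end) for p in p1
        ]


class TestIntegration:
    def test_zero_signal_zero_areas(self, time_axis):
        trace = make_trace(time_axis, np.zeros(len(time_axis)))
        assert integrate_peak(trace, flat_background(len(time_axis)), (100.0, 150.0)) == (
            0.0,
            0.0,
            0.0,
        )

    def test_gaussian_closed_form_area(self, time_axis):
        # 1 V amplitude, sigma 5 s -> area = A*sigma*sqrt(2*pi) = 12.533 V*s
        trace = make_trace(time_axis, gaussian(time_axis, 1000.0, 300.0, 5.0))
        _, area2, _ = integrate_peak(trace, flat_background(len(time_axis)), (250.0, 350.0))
        assert area2 == pytest.approx(5.0 * np.sqrt(2 * np.pi), rel=1e-3)

    def test_constant_background_subtracted_exactly(self, time_axis):
        y = gaussian(time_axis, 1000.0, 300.0, 5.0)
        n = len(time_axis)
        _, a_clean, _ = integrate_peak(make_trace(time_axis, y), flat_background(n), (250, 350))
        _, a_offset, _ = integrate_peak(
            make_trace(time_axis, y + 100.0), flat_background(n, 100.0), (250, 350)
        )
        assert a_offset == pytest.approx(a_clean, abs=1e-12)

    def test_additive_over_window_split(self, time_axis):
        trace = make_trace(time_axis, gaussian(time_axis, 1500.0, 300.0, 8.0))
        bg = flat_background(len(time_axis))
        _, whole, _ = integrate_peak(trace, bg, (250.0, 350.0))
        _, left, _ = integrate_peak(trace, bg, (250.0, 300.0))
        _, right, _ = integrate_peak(trace, bg, (300.0, 350.0))
        assert left + right == pytest.approx(whole, abs=1e-12)

    def test_short_window_rejected(self, time_axis):
        trace = make_trace(time_axis, np.zeros(len(time_axis)))
        with pytest.raises(ValueError, match="3 samples"):
            integrate_peak(trace, flat_background(len(time_axis)), (100.0, 100.3))


def make_peak(t0, amplitude, area2, area3=None, flags=()):
    return Peak(
        t_start=t0,
        t_apex=t0 + 5.0,
        t_end=t0 + 10.0,
        amplitude=amplitude,
        area2=area2,
        area3=area3 if area3 is not None else area2 * 3e-4,
        flags=set(flags),
    )


class TestQC:
    def test_boundary_cases_exactly_one_accepted(self):
        peaks = [
            make_peak(0.0, 500.0, 5.0),    # passes both gates
            make_peak(20.0, 400.0, 10.0),  # amplitude too low
            make_peak(40.0, 451.0, 4.0),   # area not strictly greater
        ]
        flagged = qc_filter(peaks)
        assert [p.accepted for p in flagged] == [True, False, False]
        assert "below_min_amplitude" in flagged[1].flags
        assert "below_min_area" in flagged[2].flags

    def test_rejected_peaks_retained_with_data(self):
        flagged = qc_filter([make_peak(0.0, 100.0, 1.0)])
        assert len(flagged) == 1
        assert flagged[0].area2 == 1.0


class TestMerging:
    def test_merge_single_peak_is_identity(self):
        p = make_peak(0.0, 600.0, 5.0)
        assert merge_coeluting([p], [0]) is p

    def test_area_weighted_delta_of_merged_isomers(self):
        # areas 2:1 with true deltas -100 / -130 -> combined -110
        r1 = R_MACHINE * (1 - 100 / 1000)
        r2 = R_MACHINE * (1 - 130 / 1000)
        peaks = [make_peak(0.0, 800.0, 2.0, 2.0 * r1), make_peak(10.0, 500.0, 1.0, 1.0 * r2)]
        merged = merge_coeluting(peaks, [0, 1])
        delta = (merged.ratio / R_MACHINE - 1.0) * 1000.0
        assert delta == pytest.approx(-110.0, abs=1e-9)
        assert "merged" in merged.flags
        assert merged.amplitude == 800.0

    def test_merged_area_can_pass_qc_where_members_fail(self):
        peaks = [make_peak(0.0, 700.0, 2.5), make_peak(10.0, 650.0, 2.5)]
        assert all(not p.accepted for p in qc_filter(peaks))
        merged = merge_coeluting(peaks, [0, 1])
        [flagged] = qc_filter([merged])
        assert flagged.accepted

    def test_non_contiguous_group_rejected(self):
        peaks = [make_peak(0.0, 600.0, 5.0), make_peak(20.0, 600.0, 5.0), make_peak(40.0, 600.0, 5.0)]
        with pytest.raises(ValueError, match="contiguous"):
            merge_coeluting(peaks, [0, 2])


class TestSimulatedEnsembleIntegration:
    def test_simulated_amount_recovered_through_detection(self):
        """detect + integrate on a simulated noiseless peak recovers the amount."""
        from isofame.background import estimate_dynamic
        from isofame.simulate import BackgroundModel, CompoundSpec, SimulationSpec, simulate_chromatogram

        spec = SimulationSpec(
            compounds=[CompoundSpec("x", 32, 340.0, 5.0, delta_fa_true=-200.0)],
            background=BackgroundModel(mode="constant", level=30.0),
            noise_sd=0.0, noise_sd3=0.0, run_jitter_sd=0.0,
            duration=600.0, seed=0,
        )
        trace, _ = simulate_chromatogram(spec)
        bg = estimate_dynamic(trace, 150.0)
        peaks = integrate_peaks(trace, bg, detect_peaks(trace, bg))
        assert len(peaks) == 1
        assert peaks[0].area2 == pytest.approx(5.0, rel=2e-3)  # tails beyond slope bounds
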