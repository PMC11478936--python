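"""End-to-end processing: traces in, normalized fatty-acid delta-2H out.

The chain per injection: H3+ correction of the mass-3 trace -> background
estimation in the configured mode -> peak detection on the
background-subtracted mass-2 trace -> integration -> per-peak area ratio ->
raw delta against the within-run reference-gas pulses.  Across a sequence:
anchor injections (USGS70/USGS71) give the two-point normalization line,
samples are normalized, identified against the RT library, coelution rules
applied, and the methanol correction converts FAME values to free
fatty-acid values.

In ``individual`` background mode, detection runs on an internal dynamic
estimate (slope thresholds on a derivative are invariant to a constant
offset, so the choice cannot move boundaries materially), while amplitudes
and integrals use the per-peak history-minimum constants the mode defines.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import background as bg
from . import calibrate as cal
from . import peaks as pk
from .identify import apply_merge_rules, assign_compounds
from .trace_io import CompoundLibrary, IsotopeTrace, RunConfig

__all__ = ["TraceMeasurement", "measure_trace", "process_sequence"]

_DETECTION_STEP = 150.0  # s, internal dynamic step used for detection in individual mode


@dataclass
class TraceMeasurement:
    """Per-injection measurement: integrated peaks and the reference ratio."""

    trace: IsotopeTrace
    peaks: list[pk.Peak]
    r_ref: float                    # measured reference-gas area ratio
    background: bg.BackgroundEstimate
    flags: set = field(default_factory=set)

    def raw_deltas(self, delta_ref: float) -> list[float]:
        return [cal.raw_delta(p.ratio, self.r_ref, delta_ref) for p in self.peaks]


def _resolve_robust(trace: IsotopeTrace, config: RunConfig) -> bool:
    """Step statistic choice: explicit setting wins, else the trace's
    declared noise level decides (strict minimum only on noiseless data)."""
    if config.background.robust is not None:
        return config.background.robust
    return float(trace.meta.get("noise_sd", 0.0) or 0.0) > 0.0


def _full_background(
    trace: IsotopeTrace, config: RunConfig, robust: bool
) -> bg.BackgroundEstimate:
    s = config.background
    if s.mode == "dynamic":
        return bg.estimate_dynamic(trace, step_width=s.step_width, robust=robust)
    if s.mode == "basefit":
        return bg.estimate_basefit(
            trace, step_width=s.step_width, smoothing=s.smoothing, robust=robust
        )
    # individual mode: detection-only estimate; integration overrides per peak
    return bg.estimate_dynamic(trace, step_width=_DETECTION_STEP, robust=robust)


def _constant_estimate(trace: IsotopeTrace, b2: float, b3: float) -> bg.BackgroundEstimate:
    n = len(trace)
    return bg.BackgroundEstimate(
        mode="individual", b2=np.full(n, b2), b3=np.full(n, b3), params={}
    )


def _window_overlaps(window: tuple[float, float], other: tuple[float, float]) -> bool:
    return window[0] < other[1] and other[0] < window[1]


def measure_trace(
    trace: IsotopeTrace, config: RunConfig, k: float
) -> TraceMeasurement:
    """H3-correct, subtract background, detect and integrate one injection.

    Detected regions overlapping a declared reference-pulse window are
    treated as reference pulses (they set the within-run ratio anchor) and
    excluded from the compound peak list.
    """
    corrected = cal.h3_correct_trace(trace, k)
    robust = _resolve_robust(trace, config)
    estimate = _full_background(corrected, config, robust)
    ps = config.peaks
    detected = pk.detect_peaks(
        corrected,
        estimate,
        start_slope=ps.start_slope,
        end_slope=ps.end_slope,
        sg_window=ps.sg_window,
        sg_poly=ps.sg_poly,
    )
    ref_windows = [tuple(w) for w in trace.meta.get("ref_windows", [])]
    detected = [
        p
        for p in detected
        if not any(_window_overlaps((p.t_start, p.t_end), w) for w in ref_windows)
    ]

    individual = config.background.mode == "individual"
    flags: set = set(estimate.flags)
    integrated: list[pk.Peak] = []
    for p in detected:
        est = estimate
        if individual:
            b2c, b3c = bg.estimate_individual(
                corrected,
                (p.t_start, p.t_end),
                history_time=config.background.history_time,
                robust=robust,
            )
            est = _constant_estimate(corrected, b2c, b3c)
        integrated.extend(pk.integrate_peaks(corrected, est, [p]))
    integrated = pk.qc_filter(integrated, ps.min_amplitude, ps.min_area)

    # within-run reference ratio: mean area ratio of the pulses
    ratios = []
    for w in ref_windows:
        est = estimate
        if individual:
            b2c, b3c = bg.estimate_individual(
                corrected, w, history_time=config.background.history_time,
                robust=robust,
            )
            est = _constant_estimate(corrected, b2c, b3c)
        _, a2, a3 = pk.integrate_peak(corrected, est, w)
        ratios.append(a3 / a2)
    if not ratios:
        raise ValueError(
            "trace declares no reference-pulse windows; cannot anchor the ratio scale"
        )
    return TraceMeasurement(
        trace=trace, peaks=integrated, r_ref=float(np.mean(ratios)),
        background=estimate, flags=flags,
    )


def _anchor_raw_delta(
    measurement: TraceMeasurement, delta_ref: float
) -> float:
    """Raw delta of an anchor injection: its largest acceptable peak."""
    candidates = [p for p in measurement.peaks if p.accepted] or measurement.peaks
    if not candidates:
        raise ValueError("anchor injection contains no detectable peak")
    best = max(candidates, key=lambda p: p.area2)
    return cal.raw_delta(best.ratio, measurement.r_ref, delta_ref)


def process_sequence(
    anchor_traces: dict[str, list[IsotopeTrace]],
    sample_traces: list[IsotopeTrace],
    config: RunConfig,
    library: CompoundLibrary | None = None,
    dilution_traces: list[IsotopeTrace] | None = None,
    include_rejected: bool = False,
) -> tuple[pd.DataFrame, cal.CalibrationModel]:
    """Process a full measurement sequence.

    ``anchor_traces`` maps each configured anchor name (e.g. USGS70) to its
    replicate injections.  The H3+ factor comes from the configuration or,
    if unset there, from ``dilution_traces``.  Returns the results table
    (one row per sample peak; rejected peaks are retained with flags and an
    ``accepted`` column — set ``include_rejected`` to also report their
    delta values) and the fitted :class:`~isofame.calibrate.CalibrationModel`.
    """
    cset = config.calibrate
    if cset.h3_factor is not None:
        k, u_k = float(cset.h3_factor), 0.0
    elif dilution_traces:
        k, u_k = cal.estimate_h3_factor(dilution_traces)
    else:
        raise ValueError("no H3 factor configured and no dilution series provided")

    anchors_cfg = {a["name"]: a for a in cset.anchors}
    missing = set(anchors_cfg) - set(anchor_traces)
    if missing:
        raise ValueError(f"missing anchor injections for {sorted(missing)}")

    anchor_rows = []
    for name in anchors_cfg:
        for run_idx, trace in enumerate(anchor_traces[name]):
            m = measure_trace(trace, config, k)
            anchor_rows.append(
                {
                    "anchor": name,
                    "run_index": trace.meta.get("run_index", run_idx),
                    "measured": _anchor_raw_delta(m, cset.ref_delta),
                }
            )
    anchor_results = pd.DataFrame(anchor_rows)
    means = anchor_results.groupby("anchor")["measured"].mean()
    names = list(anchors_cfg)
    m_slope, c_inter = cal.fit_two_point(
        (means[names[0]], means[names[1]]),
        (anchors_cfg[names[0]]["assigned_delta"], anchors_cfg[names[1]]["assigned_delta"]),
    )
    model = cal.CalibrationModel(
        k=k,
        u_k=u_k,
        r_ref=float("nan"),
        delta_ref=cset.ref_delta,
        m=m_slope,
        c=c_inter,
        anchor_results=anchor_results,
        u70=anchors_cfg[names[0]]["u"],
        u71=anchors_cfg[names[1]]["u"],
        u_vsmow=cset.u_vsmow,
    )

    u_me = cset.methanol_u if cset.include_methanol_u else 0.0
    u_total = model.uncertainty(cset.replicate_sd, u_me)

    rows = []
    for trace in sample_traces:
        m = measure_trace(trace, config, k)
        peaks = m.peaks
        if library is not None:
            assignments = assign_compounds(peaks, library, config.identify.tolerance)
            assignments, peaks = apply_merge_rules(
                assignments, peaks, config.identify.merge, library
            )
        else:
            assignments = [None] * len(peaks)
        for peak, assignment in zip(peaks, assignments):
            compound = assignment.compound if assignment is not None else None
            report = peak.accepted or include_rejected
            delta_raw = cal.raw_delta(peak.ratio, m.r_ref, cset.ref_delta) if report else np.nan
            delta_fame = model.normalize(delta_raw) if report else np.nan
            delta_fa = np.nan
            h_n = None
            if library is not None and compound is not None and compound in library.names:
                h_n = library.get(compound).h_n
            if report and h_n is not None:
                delta_fa = cal.methanol_correct(delta_fame, h_n, cset.methanol_delta)
            rows.append(
                {
                    "sample": trace.meta.get("sample_id", ""),
                    "compound": compound,
                    "rt": peak.t_apex,
                    "amplitude_mV": peak.amplitude,
                    "area2_Vs": peak.area2,
                    "area3_Vs": peak.area3,
                    "delta_fame": delta_fame,
                    "delta_fa": delta_fa,
                    "u_total": u_total if report else np.nan,
                    "accepted": peak.accepted,
                    "flags": ";".join(sorted(peak.flags)),
                }
            )
    results = pd.DataFrame(
        rows,
        columns=[
            "sample", "compound", "rt", "amplitude_mV", "area2_Vs", "area3_Vs",
            "delta_fame", "delta_fa", "u_total", "accepted", "flags",
        ],
    )
    return results, model
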