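"""Peak detection, delimitation, integration and QC on the mass-2 trace.

Detection follows the slope-threshold convention of IRMS chromatography
software: a peak starts where the first derivative of the
background-subtracted mass-2 signal sustains at least ``start_slope``
(default 1 mV/s) over one smoothing window, and ends where, after the apex,
the descending derivative's magnitude falls back below ``end_slope``
(default 0.5 mV/s).  The derivative is a Savitzky-Golay local-polynomial
slope: raw finite differences at 4 Hz are noise-dominated well above the
450 mV QC amplitude.

QC uses strict inequalities (amplitude > 450 mV AND area > 4 V s);
rejected peaks are retained with flags, never silently dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.signal import find_peaks, savgol_filter

from .background import BackgroundEstimate
from .trace_io import IsotopeTrace

__all__ = ["Peak", "detect_peaks", "integrate_peak", "qc_filter", "merge_coeluting"]

#: valley height (fraction of the smaller apex) above which adjacent peaks
#: split at a valley are considered coeluting rather than baseline-separated
COELUTION_VALLEY_FRACTION = 0.25


@dataclass
class Peak:
    """One detected chromatographic peak on the mass-2 trace."""

    t_start: float
    t_apex: float
    t_end: float
    amplitude: float                 # background-subtracted mass-2 maximum, mV
    area2: float | None = None       # background-subtracted mass-2 integral, V*s
    area3: float | None = None       # H3-corrected, background-subtracted mass-3 integral, V*s
    flags: set = field(default_factory=set)

    def __post_init__(self) -> None:
        if not (self.t_start < self.t_apex < self.t_end):
            raise ValueError("peak must satisfy t_start < t_apex < t_end")

    @property
    def ratio(self) -> float:
        """Mass-3 / mass-2 area ratio (dimensionless)."""
        if self.area2 is None or self.area3 is None:
            raise ValueError("peak has not been integrated")
        return self.area3 / self.area2

    @property
    def accepted(self) -> bool:
        return not ({"below_min_amplitude", "below_min_area"} & self.flags)


def _sustained_run_start(mask: np.ndarray, length: int, from_idx: int) -> int | None:
    """First index >= from_idx opening a run of ``length`` consecutive True."""
    if from_idx >= len(mask):
        return None
    m = mask[from_idx:]
    if length <= 1:
        hits = np.flatnonzero(m)
        return from_idx + int(hits[0]) if len(hits) else None
    window = np.lib.stride_tricks.sliding_window_view(m, min(length, len(m)))
    if window.shape[1] < length:
        return None
    hits = np.flatnonzero(window.all(axis=1))
    return from_idx + int(hits[0]) if len(hits) else None


def detect_peaks(
    trace: IsotopeTrace,
    background: BackgroundEstimate,
    start_slope: float = 1.0,
    end_slope: float = 0.5,
    sg_window: int = 21,
    sg_poly: int = 2,
) -> list[Peak]:
    """Detect peaks on the background-subtracted mass-2 trace.

    Returns peaks with windows, apex and background-subtracted amplitude;
    areas are filled in by :func:`integrate_peak`.  Adjacent peaks split at
    a valley that does not return near baseline, and regions containing
    more than one prominent maximum, are flagged ``merged``.
    """
    y = trace.i2 - background.b2
    n = len(y)
    if n < sg_window:
        return []
    dt = trace.dt
    d = savgol_filter(y, sg_window, sg_poly, deriv=1, delta=dt)

    regions: list[tuple[int, int, int]] = []
    rising = d >= start_slope
    i = 0
    while True:
        s = _sustained_run_start(rising, sg_window, i)
        if s is None:
            break
        # apex crossing: derivative returns to <= 0
        after = np.flatnonzero(d[s:] <= 0.0)
        if len(after) == 0:
            break
        a0 = s + int(after[0])
        # end: descending derivative magnitude falls back below end_slope
        e = None
        descended = False
        for k in range(a0, n):
            if d[k] < -end_slope:
                descended = True
            elif descended:  # d[k] >= -end_slope after a steep descent
                e = k
                break
        if e is None and descended:
            e = n - 1
        if e is None:
            # gentle peak that never descends steeply: end where the signal
            # returns to its start level or starts rising again
            for k in range(a0 + 1, n):
                if y[k] <= y[s] or d[k] >= start_slope:
                    e = k
                    break
            if e is None:
                e = n - 1
        if e - s >= 2:
            apex = s + int(np.argmax(y[s : e + 1]))  # plateau ties: earliest sample
            apex = min(max(apex, s + 1), e - 1)
            regions.append((s, apex, e))
        if e <= i:  # no forward progress; avoid an infinite scan
            i = a0 + 1
        else:
            i = e
    peaks: list[Peak] = []
    for s, apex, e in regions:
        flags: set = set()
        seg = y[s : e + 1]
        prom = 0.25 * float(np.max(seg))
        if prom > 0:
            maxima, _ = find_peaks(seg, prominence=prom)
            if len(maxima) >= 2:
                flags.add("merged")
        peaks.append(
            Peak(
                t_start=float(trace.time[s]),
                t_apex=float(trace.time[apex]),
                t_end=float(trace.time[e]),
                amplitude=float(np.max(seg)),
                flags=flags,
            )
        )
    # coelution: consecutive peaks sharing a boundary with a high valley
    for p, q in zip(peaks, peaks[1:]):
        if q.t_start - p.t_end <= dt + 1e-9:
            j = int(np.searchsorted(trace.time, p.t_end))
            valley = y[j]
            if valley > COELUTION_VALLEY_FRACTION * min(p.amplitude, q.amplitude):
                p.flags.add("merged")
                q.flags.add("merged")
    return peaks


def integrate_peak(
    trace: IsotopeTrace,
    background: BackgroundEstimate,
    window: tuple[float, float],
) -> tuple[float, float, float]:
    """Trapezoidal integration of a peak window.

    Returns ``(amplitude mV, area2 V*s, area3 V*s)`` of the
    background-subtracted signals.  The trace's mass-3 series is expected to
    be H3+-corrected already (see :func:`isofame.calibrate.h3_correct_trace`).
    """
    sl = trace.window_slice(*window)
    if sl.stop - sl.start < 3:
        raise ValueError("integration window must contain at least 3 samples")
    t = trace.time[sl]
    y2 = trace.i2[sl] - background.b2[sl]
    y3 = trace.i3[sl] - background.b3[sl]
    amplitude = float(np.max(y2))
    area2 = float(np.trapezoid(y2, t)) / 1000.0  # mV*s -> V*s
    area3 = float(np.trapezoid(y3, t)) / 1000.0
    return amplitude, area2, area3


def integrate_peaks(
    trace: IsotopeTrace, background: BackgroundEstimate, peaks: list[Peak]
) -> list[Peak]:
    """Fill areas (and refresh amplitude) of detected peaks."""
    out = []
    for p in peaks:
        amplitude, area2, area3 = integrate_peak(trace, background, (p.t_start, p.t_end))
        out.append(replace(p, amplitude=amplitude, area2=area2, area3=area3, flags=set(p.flags)))
    return out


def qc_filter(
    peaks: list[Peak], min_amplitude: float = 450.0, min_area: float = 4.0
) -> list[Peak]:
    """Apply the acceptance gates (strict inequalities) as flags.

    A peak is acceptable only if amplitude > ``min_amplitude`` (mV) AND
    area2 > ``min_area`` (V*s); boundary values are rejected.  Rejected
    peaks keep their data and gain a flag.
    """
    out = []
    for p in peaks:
        if p.area2 is None:
            raise ValueError("peaks must be integrated before QC filtering")
        flags = set(p.flags)
        if not p.amplitude > min_amplitude:
            flags.add("below_min_amplitude")
        if not p.area2 > min_area:
            flags.add("below_min_area")
        out.append(replace(p, flags=flags))
    return out


def merge_coeluting(peaks: list[Peak], group: list[int]) -> Peak:
    """Combine coeluting peaks (by index into ``peaks``) into one peak.

    Areas sum (so the downstream delta is the mass-2-area-weighted mean),
    the amplitude is the maximum, and the window spans the group.  The
    group must be contiguous in elution order.
    """
    if not group:
        raise ValueError("empty merge group")
    order = sorted(range(len(peaks)), key=lambda i: peaks[i].t_start)
    positions = sorted(order.index(i) for i in group)
    if positions != list(range(positions[0], positions[0] + len(positions))):
        raise ValueError("merge group is not contiguous in time")
    members = [peaks[i] for i in sorted(group, key=lambda i: peaks[i].t_start)]
    if len(members) == 1:
        return members[0]
    for m in members:
        if m.area2 is None:
            raise ValueError("peaks must be integrated before merging")
    tallest = max(members, key=lambda m: m.amplitude)
    flags = set().union(*(m.flags for m in members)) | {"merged"}
    return Peak(
        t_start=members[0].t_start,
        t_apex=tallest.t_apex,
        t_end=members[-1].t_end,
        amplitude=tallest.amplitude,
        area2=sum(m.area2 for m in members),
        area3=sum(m.area3 for m in members),
        flags=flags,
    )
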