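"""Background (baseline) estimation under IRMS chromatograms.

Three modes, mirroring common vendor practice:

``individual``
    one constant pair (b2, b3) per peak, the lowest intensities found in a
    look-back ("history") window just before the peak start.  Cheap but
    fragile: a preceding peak tail or a rising baseline inflates or offsets
    the constant.

``dynamic``
    the trace is partitioned into fixed-width steps; in each step the
    minimum (or, on declared-noisy data, the 2nd percentile) intensity and
    the time at which it occurs form a node; the background is the linear
    interpolation through the nodes, extended flat at both ends.  Placing a
    node at the argmin time (not the step midpoint) makes the estimate exact
    on linear ramps.

``basefit``
    a whole-chromatogram penalized smoothing spline through the same step
    nodes, iteratively refit while discarding nodes sitting more than one
    robust scale above the current fit (nodes on peak flanks).  The
    ``smoothing`` parameter is the spline stiffness: large values approach a
    straight-line fit.  The vendor algorithm of the same name is
    unpublished; this robust-spline definition is this package's concrete
    realization of the behaviours attributed to it (whole-trace fit, tunable
    smoothing, robustness to injection-volume changes).

Mass-2 and mass-3 are estimated independently — the two channels sit on
different amplifiers and have different noise floors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import make_smoothing_spline

from .trace_io import IsotopeTrace

__all__ = [
    "BackgroundEstimate",
    "estimate_individual",
    "estimate_dynamic",
    "estimate_basefit",
]

#: order statistic used for step nodes on declared-noisy traces
ROBUST_PERCENTILE = 2.0
_MIN_SPLINE_NODES = 5
_MAX_BASEFIT_ITER = 20


@dataclass
class BackgroundEstimate:
    """Background series aligned to a trace, for both channels."""

    mode: str
    b2: np.ndarray
    b3: np.ndarray
    params: dict = field(default_factory=dict)
    flags: set = field(default_factory=set)


def _node_index(values: np.ndarray, robust: bool) -> int:
    """Index of the step's background node sample (min or 2nd percentile)."""
    order = np.argsort(values, kind="stable")
    if not robust:
        return int(order[0])
    k = int(np.floor(ROBUST_PERCENTILE / 100.0 * (len(values) - 1)))
    return int(order[k])


def estimate_individual(
    trace: IsotopeTrace,
    peak_window: tuple[float, float],
    history_time: float,
    robust: bool = False,
) -> tuple[float, float]:
    """Constant background pair from the history window before a peak.

    Returns the lowest (b2, b3) intensities, in mV, found in
    ``[t_start - history_time, t_start)``.
    """
    if history_time <= 0:
        raise ValueError("history_time must be positive")
    t_start = peak_window[0]
    h0 = t_start - history_time
    if h0 < trace.time[0] - 1e-9:
        raise ValueError(
            f"history window [{h0:.1f}, {t_start:.1f}) lies outside the trace"
        )
    i0 = int(np.searchsorted(trace.time, h0, side="left"))
    i1 = int(np.searchsorted(trace.time, t_start, side="left"))
    if i1 <= i0:
        raise ValueError("history window contains no samples")
    seg2 = trace.i2[i0:i1]
    seg3 = trace.i3[i0:i1]
    return (
        float(seg2[_node_index(seg2, robust)]),
        float(seg3[_node_index(seg3, robust)]),
    )


def _step_nodes(
    trace: IsotopeTrace, step_width: float, robust: bool
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(node times, node i2, node i3) — one node per step at the argmin time."""
    t = trace.time
    if step_width <= trace.dt:
        raise ValueError("step_width must exceed the sampling interval")
    span = t[-1] + trace.dt - t[0]
    if span <= 2 * step_width:
        raise ValueError("trace must be longer than 2 background steps")
    n_steps = int(np.ceil(span / step_width))
    edges = t[0] + step_width * np.arange(n_steps + 1)
    edges[-1] = t[-1] + trace.dt  # trailing partial step keeps its own node
    xs, y2, y3 = [], [], []
    for lo, hi in zip(edges[:-1], edges[1:]):
        i0 = int(np.searchsorted(t, lo, side="left"))
        i1 = int(np.searchsorted(t, hi, side="left"))
        if i1 - i0 < 1:
            continue
        j2 = i0 + _node_index(trace.i2[i0:i1], robust)
        j3 = i0 + _node_index(trace.i3[i0:i1], robust)
        # both channels keyed on a single node time axis: use each channel's
        # own argmin value but the mass-2 node time for x (channels are
        # interpolated separately below, so keep per-channel x too)
        xs.append((t[j2], t[j3]))
        y2.append(trace.i2[j2])
        y3.append(trace.i3[j3])
    x = np.asarray(xs)
    return x, np.asarray(y2), np.asarray(y3)


def _interp_flat(t: np.ndarray, x: np.ndarray, y: np.ndarray) -> np.ndarray:
    return np.interp(t, x, y)  # np.interp extends flat beyond the end nodes


def estimate_dynamic(
    trace: IsotopeTrace, step_width: float = 150.0, robust: bool = False
) -> BackgroundEstimate:
    """Piecewise-linear background through per-step minimum nodes."""
    x, y2, y3 = _step_nodes(trace, step_width, robust)
    b2 = _interp_flat(trace.time, x[:, 0], y2)
    b3 = _interp_flat(trace.time, x[:, 1], y3)
    return BackgroundEstimate(
        mode="dynamic", b2=b2, b3=b3,
        params={"step_width": step_width, "robust": robust},
    )


def _noise_side_scale(residuals: np.ndarray) -> float:
    """Robust scale from the non-positive residuals only.

    Outlier nodes (peak flanks) lie strictly above the background, so the
    negative residual side estimates the noise scale without being inflated
    or deflated by the outliers; this keeps the rejection loop from
    cascading on plain noisy traces.
    """
    low = residuals[residuals <= 0]
    if len(low) == 0:
        return 0.0
    return 1.4826 * float(np.median(np.abs(low)))


def _loo_residuals(x: np.ndarray, y: np.ndarray, keep: np.ndarray, smoothing: float) -> np.ndarray:
    """Leave-one-out residuals of kept nodes against the smoothing spline.

    A flexible spline interpolates its own nodes (outliers included), so
    ordinary residuals cannot expose contaminated nodes; the leave-one-out
    residual measures each node against a fit through its neighbours.
    """
    resid = np.zeros(len(x))
    for i in np.flatnonzero(keep):
        mask = keep.copy()
        mask[i] = False
        spline = make_smoothing_spline(x[mask], y[mask], lam=smoothing)
        resid[i] = y[i] - float(spline(x[i]))
    return resid


def _basefit_channel(
    t: np.ndarray,
    x: np.ndarray,
    y: np.ndarray,
    smoothing: float,
    flags: set,
    channel: str,
) -> np.ndarray | None:
    """Iteratively refit a smoothing spline, discarding high outlier nodes.

    Returns the background series, or None to request the dynamic fallback.
    """
    keep = np.ones(len(x), dtype=bool)
    tol = 1e-8 * max(1.0, float(np.max(np.abs(y))))  # float-noise floor
    for _ in range(_MAX_BASEFIT_ITER):
        if keep.sum() < _MIN_SPLINE_NODES:
            flags.add(f"basefit_fallback_{channel}")
            return None
        if keep.sum() == _MIN_SPLINE_NODES:
            break  # cannot leave one out below the spline minimum
        resid = _loo_residuals(x, y, keep, smoothing)
        scale = _noise_side_scale(resid[keep])
        bad = keep & (resid > max(scale, tol))
        if not bad.any():
            break
        if (keep.sum() - bad.sum()) < _MIN_SPLINE_NODES:
            # drop only the worst offenders down to the minimum node count
            n_drop = keep.sum() - _MIN_SPLINE_NODES
            order = np.argsort(resid)[::-1]
            bad = np.zeros_like(keep)
            bad[order[:n_drop]] = True
            bad &= keep
        keep = keep & ~bad
    else:
        flags.add(f"basefit_fallback_{channel}")
        return None
    spline = make_smoothing_spline(x[keep], y[keep], lam=smoothing)
    b = spline(t)
    # flat extension outside the node range (cubic extrapolation is unsafe)
    x_kept = x[keep]
    b[t < x_kept[0]] = float(spline(x_kept[0]))
    b[t > x_kept[-1]] = float(spline(x_kept[-1]))
    # diagnostic (not a clip): the final fit should track the kept minima
    final_resid = spline(x[keep]) - y[keep]
    scale = _noise_side_scale(y[keep] - spline(x[keep]))
    if np.any(final_resid > max(scale, tol)):
        flags.add(f"basefit_above_nodes_{channel}")
    return b


def estimate_basefit(
    trace: IsotopeTrace,
    step_width: float = 200.0,
    smoothing: float = 1.0,
    robust: bool = False,
) -> BackgroundEstimate:
    """Robust whole-chromatogram smoothing-spline background.

    Falls back to the dynamic estimate (with a warning flag) when the
    outlier-rejection loop fails to stabilize within the iteration cap.
    """
    if smoothing <= 0:
        raise ValueError("smoothing must be positive")
    x, y2, y3 = _step_nodes(trace, step_width, robust)
    flags: set = set()
    b2 = _basefit_channel(trace.time, x[:, 0], y2, smoothing, flags, "i2")
    b3 = _basefit_channel(trace.time, x[:, 1], y3, smoothing, flags, "i3")
    if b2 is None or b3 is None:
        dyn = estimate_dynamic(trace, step_width=step_width, robust=robust)
        flags.add("basefit_fallback")
        return BackgroundEstimate(
            mode="basefit",
            b2=dyn.b2 if b2 is None else b2,
            b3=dyn.b3 if b3 is None else b3,
            params={"step_width": step_width, "smoothing": smoothing, "robust": robust},
            flags=flags,
        )
    return BackgroundEstimate(
        mode="basefit", b2=b2, b3=b3,
        params={"step_width": step_width, "smoothing": smoothing, "robust": robust},
        flags=flags,
    )
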