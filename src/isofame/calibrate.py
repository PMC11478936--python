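"""Conversion of peak areas to normalized, methanol-corrected delta-2H.

Processing order (fixed contract): H3+ correction (pointwise,
pre-integration) -> integration -> raw delta vs the reference gas ->
two-point normalization onto the VSMOW-SLAP scale through the USGS70/USGS71
FAME anchors -> methanol correction (samples only; the anchors' assigned
values are whole-molecule FAME values) -> quadrature error propagation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import linregress

from .trace_io import IsotopeTrace

__all__ = [
    "h3_correct",
    "h3_correct_trace",
    "estimate_h3_factor",
    "raw_delta",
    "fit_two_point",
    "normalize_delta",
    "drift_check",
    "DriftResult",
    "methanol_correct",
    "propagate_uncertainty",
    "CalibrationModel",
    "DeltaResult",
]


def h3_correct(i2_v: np.ndarray, i3_v: np.ndarray, k: float) -> np.ndarray:
    """Pointwise H3+ correction on series in volts.

    ``i3_corr = i3 - k * 1e-6 * i2**2`` with ``k`` in ppm/V; applied before
    any integration.
    """
    if k < 0:
        raise ValueError("H3 factor must be non-negative")
    i2_v = np.asarray(i2_v, dtype=float)
    i3_v = np.asarray(i3_v, dtype=float)
    if i2_v.shape != i3_v.shape:
        raise ValueError("i2 and i3 series must be aligned")
    return i3_v - k * 1e-6 * i2_v ** 2


def h3_correct_trace(trace: IsotopeTrace, k: float) -> IsotopeTrace:
    """H3+ correction for traces stored in mV (same model, unit-converted)."""
    i3_corr_v = h3_correct(trace.i2 / 1000.0, trace.i3 / 1000.0, k)
    return trace.with_i3(i3_corr_v * 1000.0)


def _pulse_measurement(trace: IsotopeTrace, window: tuple[float, float]) -> tuple[float, float]:
    """(amplitude V, apparent ratio) of one reference pulse on a clean baseline."""
    sl = trace.window_slice(*window)
    t = trace.time[sl]
    i2 = trace.i2[sl]
    i3 = trace.i3[sl]
    if len(t) < 3:
        raise ValueError("pulse window contains fewer than 3 samples")
    plateau = i2 > 0.5 * np.max(i2)
    amplitude_v = float(np.mean(i2[plateau])) / 1000.0
    ratio = float(np.trapezoid(i3, t) / np.trapezoid(i2, t))
    return amplitude_v, ratio


def estimate_h3_factor(dilution_traces: list[IsotopeTrace]) -> tuple[float, float]:
    """H3+ factor from a reference-gas dilution series.

    Least-squares slope of apparent mass-3/mass-2 ratio (ppm) against pulse
    amplitude (V); returns ``(K ppm/V, standard error)``.  Requires at
    least 3 pulses spanning at least a 2-fold amplitude range.
    """
    points = []
    for trace in dilution_traces:
        window = trace.meta.get("pulse_window")
        if window is None:
            raise ValueError("dilution trace lacks a 'pulse_window' meta entry")
        amp, ratio = _pulse_measurement(trace, tuple(window))
        points.append((amp, ratio * 1e6))  # ratio in ppm
    if len(points) < 3:
        raise ValueError("H3 determination needs at least 3 pulses")
    amps = np.array([p[0] for p in points])
    ratios = np.array([p[1] for p in points])
    if len(np.unique(np.round(amps, 9))) < 2 or np.max(amps) < 2.0 * np.min(amps):
        raise ValueError(
            "degenerate dilution design: amplitudes must span at least a 2-fold range"
        )
    fit = linregress(amps, ratios)
    return float(fit.slope), float(fit.stderr)


def raw_delta(r_sample: float, r_ref: float, delta_ref: float) -> float:
    """Delta-2H (per mil vs VSMOW) from the sample and reference-gas ratios.

    ``delta = ((1 + delta_ref/1000) * r_sample/r_ref - 1) * 1000``
    """
    if r_ref <= 0:
        raise ValueError("reference ratio must be positive")
    if r_sample < 0:
        raise ValueError("sample ratio must be non-negative")
    return ((1.0 + delta_ref / 1000.0) * r_sample / r_ref - 1.0) * 1000.0


def fit_two_point(
    measured: tuple[float, float],
    assigned: tuple[float, float] = (-183.9, -4.9),
) -> tuple[float, float]:
    """Two-point normalization line mapping measured anchor means onto
    assigned values.

    Returns ``(m, c)`` with ``normalized = m * measured + c``; applying the
    line to the measured anchors reproduces the assigned values exactly.
    """
    (m1, m2), (a1, a2) = measured, assigned
    if m1 == m2:
        raise ValueError("measured anchor values are equal; normalization line undefined")
    m = (a1 - a2) / (m1 - m2)
    c = a2 - m * m2
    return float(m), float(c)


def normalize_delta(delta: float, m: float, c: float) -> float:
    return m * delta + c


@dataclass(frozen=True)
class DriftResult:
    anchor: str
    slope: float          # per mil per run
    p_value: float
    residual_sd: float    # per mil, replicate SD around the trend
    span: float           # run-index span of the sequence
    flagged: bool


def drift_check(anchor_results: pd.DataFrame, alpha: float = 0.01) -> list[DriftResult]:
    """Instrumental drift monitoring over a measurement sequence.

    ``anchor_results`` needs columns ``anchor``, ``run_index``, ``measured``
    (per mil).  Per anchor, the measured values are regressed on run index;
    drift is flagged when the slope is statistically significant (p < alpha)
    AND its accumulated effect over the sequence span exceeds the replicate
    SD — a drift smaller than the scatter is not actionable.  The default
    alpha is deliberately strict: a drift monitor that cries wolf on a few
    percent of clean sequences would be ignored in routine use.
    """
    out = []
    for anchor, grp in anchor_results.groupby("anchor"):
        x = grp["run_index"].to_numpy(dtype=float)
        y = grp["measured"].to_numpy(dtype=float)
        if len(np.unique(x)) < 2:
            raise ValueError(f"{anchor}: anchors measured at fewer than 2 sequence positions")
        fit = linregress(x, y)
        resid = y - (fit.intercept + fit.slope * x)
        dof = max(len(y) - 2, 1)
        resid_sd = float(np.sqrt(np.sum(resid ** 2) / dof))
        span = float(x.max() - x.min())
        magnitude = abs(fit.slope) * span
        flagged = bool(fit.pvalue < alpha and magnitude > resid_sd)
        out.append(
            DriftResult(
                anchor=str(anchor),
                slope=float(fit.slope),
                p_value=float(fit.pvalue),
                residual_sd=resid_sd,
                span=span,
                flagged=flagged,
            )
        )
    return out


def methanol_correct(delta_fame: float, h_n: int, delta_me: float) -> float:
    """Remove the methyl-group contribution from a measured FAME delta-2H.

    Inverse of the derivatization mass balance::

        delta_fa = ((h_n + 2) * delta_fame - 3 * delta_me) / (h_n - 1)

    ``h_n`` is the H count of the free fatty acid (>= 4); all deltas in per
    mil vs VSMOW.
    """
    h_n = int(h_n)
    if h_n < 4:
        raise ValueError(f"h_n={h_n}: a fatty acid has at least 4 H atoms")
    return ((h_n + 2) * delta_fame - 3.0 * delta_me) / (h_n - 1)


def propagate_uncertainty(
    sd_replicates: float,
    u70: float = 1.4,
    u71: float = 1.0,
    u_vsmow: float = 0.3,
    u_methanol: float = 0.0,
) -> float:
    """Quadrature sum of the uncertainty components, per mil.

    Components: replicate SD of control samples, the USGS70/USGS71
    assignment uncertainties, the VSMOW2 assignment uncertainty, and
    (optionally) the methanol determination uncertainty.  Report to 0.1
    per mil.
    """
    parts = (sd_replicates, u70, u71, u_vsmow, u_methanol)
    if any(p < 0 for p in parts):
        raise ValueError("uncertainty components must be non-negative")
    return math.sqrt(sum(p * p for p in parts))


@dataclass
class CalibrationModel:
    """Everything needed to map peak area ratios onto the VSMOW scale."""

    k: float                       # H3+ factor, ppm/V
    u_k: float                     # ppm/V
    r_ref: float                   # measured reference-gas area ratio
    delta_ref: float               # assigned reference-gas delta, per mil
    m: float                       # normalization slope
    c: float                       # normalization intercept, per mil
    anchor_results: pd.DataFrame = field(default_factory=pd.DataFrame)
    u70: float = 1.4
    u71: float = 1.0
    u_vsmow: float = 0.3

    def __post_init__(self) -> None:
        if self.k < 0:
            raise ValueError("H3 factor must be non-negative")
        if self.m <= 0:
            raise ValueError("normalization slope must be positive")

    def normalize(self, delta: float) -> float:
        return normalize_delta(delta, self.m, self.c)

    def uncertainty(self, sd_replicates: float, u_methanol: float = 0.0) -> float:
        return propagate_uncertainty(sd_replicates, self.u70, self.u71, self.u_vsmow, u_methanol)


@dataclass(frozen=True)
class DeltaResult:
    """Final per-compound result."""

    compound: str
    delta_fame: float    # per mil vs VSMOW (normalized FAME value)
    delta_fa: float      # per mil vs VSMOW (methanol-corrected fatty acid)
    u_total: float       # per mil
    flags: frozenset = frozenset()

    def __post_init__(self) -> None:
        if self.delta_fame <= -1000.0 or self.delta_fa <= -1000.0:
            raise ValueError("delta values cannot be at or below -1000 per mil")
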