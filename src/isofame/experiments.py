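"""Performance-evaluation experiments on synthetic chromatograms.

These functions reproduce, on simulated data with known ground truth, the
standard method-validation experiments for a GC/pyrolysis-IRMS setup:

* exact end-to-end recovery of fatty-acid delta-2H on noiseless traces,
  for each background mode;
* H3+-factor recovery from dilution series, noiseless and under noise;
* the amplitude-dependence of delta-2H precision, processed under all
  three background modes.

They are used by the test suite and by ``scripts/acceptance.py``; the
chromatogram layouts here (peak positions, pulse windows, background ramp)
are fixed experimental designs, with peak spacing and history windows
chosen so every estimator's preconditions hold.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import calibrate as cal
from .pipeline import measure_trace, process_sequence
from .simulate import (
    BackgroundModel,
    CompoundSpec,
    PeakShape,
    RefPulse,
    SimulationSpec,
    simulate_chromatogram,
    simulate_dilution_series,
)
from .trace_io import CompoundLibrary, LibraryEntry, load_config

__all__ = [
    "amount_for_amplitude",
    "end_to_end_recovery",
    "h3_recovery_noiseless",
    "h3_noise_coverage",
    "amplitude_precision",
]

_SHAPE = PeakShape(width=3.0, tailing=2.0)
_PULSES = [RefPulse(80.0, 110.0, 4.0), RefPulse(140.0, 170.0, 4.0)]

MODE_CONFIGS = {
    "dynamic": "background: {mode: dynamic}",
    "basefit": "background: {mode: basefit, smoothing: 1000.0}",
    "individual": "background: {mode: individual, history_time: 60.0}",
}


def amount_for_amplitude(amplitude_mv: float, shape: PeakShape = _SHAPE) -> float:
    """Peak area (V*s) that yields a given apex amplitude (mV) for a shape."""
    peak_height = float(shape.pdf(np.array([0.0]), 0.0)[0])  # 1/s at unit area
    return amplitude_mv / 1000.0 / peak_height


def _mode_config(mode: str, robust: bool = False):
    config = load_config(text=MODE_CONFIGS[mode])
    config.background.robust = robust
    return config


def end_to_end_recovery(mode: str, seed: int = 1) -> float:
    """Max |recovered - true| delta-2H_FA (per mil) on a noiseless sequence.

    The sequence uses a linear-ramp background, an H3+ factor of 3 ppm/V
    estimated from its own dilution series, and an instrumental distortion
    (scale 0.98, offset +6 per mil) that the USGS70/USGS71 normalization
    must undo.  Anchors are prepared at sample-like amount and shape, as in
    routine practice.
    """
    background = BackgroundModel(mode="ramp", level=20.0, slope=0.008, delta_bg=-80.0)

    def make_spec(compounds, sample_id, run_seed):
        return SimulationSpec(
            compounds=compounds,
            ref_pulses=_PULSES,
            ref_delta=-120.0,
            h3_factor=3.0,
            background=background,
            noise_sd=0.0,
            noise_sd3=0.0,
            run_jitter_sd=0.0,
            cal_scale=0.98,
            cal_offset=6.0,
            sample_rate=4.0,
            duration=1500.0,
            seed=run_seed,
            sample_id=sample_id,
        )

    compounds = [
        CompoundSpec("C16:0", 32, 340.0, 10.0, delta_fa_true=-204.0, shape=_SHAPE),
        CompoundSpec("C18:0", 36, 640.0, 10.0, delta_fa_true=-180.0, shape=_SHAPE),
        CompoundSpec("C18:1", 34, 940.0, 10.0, delta_fa_true=-260.0, shape=_SHAPE),
        CompoundSpec("C20:0", 40, 1240.0, 10.0, delta_fa_true=-150.0, shape=_SHAPE),
    ]
    anchors = {
        "USGS70": [CompoundSpec("USGS70", 40, 640.0, 10.0, delta_fame_true=-183.9, shape=_SHAPE)],
        "USGS71": [CompoundSpec("USGS71", 40, 640.0, 10.0, delta_fame_true=-4.9, shape=_SHAPE)],
    }
    library = CompoundLibrary(
        [LibraryEntry(c.name, c.h_n, c.rt) for c in compounds]
    )
    sample_trace, truth = simulate_chromatogram(make_spec(compounds, "sample", seed))
    anchor_traces = {
        name: [simulate_chromatogram(make_spec(specs, name, seed + 10 + i))[0]]
        for i, (name, specs) in enumerate(anchors.items())
    }
    dilution = simulate_dilution_series(3.0, [1, 2, 3, 4, 6, 8], seed=seed + 20)
    config = _mode_config(mode)
    results, _ = process_sequence(anchor_traces, [sample_trace], config, library,
                                  dilution_traces=dilution)
    by_name = results.set_index("compound")["delta_fa"]
    errors = [
        abs(float(by_name[row["name"]]) - row["delta_fa"])
        for _, row in truth.compounds.iterrows()
    ]
    return max(errors)


def h3_recovery_noiseless(k_values=(0.0, 1.0, 3.0, 6.0), seed: int = 0) -> dict[float, float]:
    """Recovered H3+ factor per injected value, noiseless dilution series."""
    out = {}
    for k in k_values:
        traces = simulate_dilution_series(k, [1, 2, 3, 4, 6, 8], seed=seed)
        k_hat, _ = cal.estimate_h3_factor(traces)
        out[k] = k_hat
    return out


def h3_noise_coverage(
    seed: int = 0, n_reps: int = 200, k_true: float = 3.0, noise_sd: float = 1.0
) -> tuple[float, float, float]:
    """Fraction of noisy replicates with |K_hat - K| <= 3 standard errors.

    Returns ``(coverage, mean K_hat, mean SE)``.
    """
    hits = 0
    k_hats, ses = [], []
    for rep in range(n_reps):
        traces = simulate_dilution_series(
            k_true, [1, 2, 3, 4, 6, 8], seed=seed + rep, noise_sd=noise_sd
        )
        k_hat, se = cal.estimate_h3_factor(traces)
        k_hats.append(k_hat)
        ses.append(se)
        if abs(k_hat - k_true) <= 3.0 * se:
            hits += 1
    return hits / n_reps, float(np.mean(k_hats)), float(np.mean(ses))


#: amplitude bins of the precision experiment (target apex amplitudes, mV)
PRECISION_AMPLITUDES = {
    ">2500": 4000.0,
    "500-2500": 1200.0,
    "200-500": 330.0,
    "100-200": 140.0,
    "<100": 60.0,
}


def amplitude_precision(
    seed: int = 0,
    n_reps: int = 200,
    amplitudes: dict[str, float] | None = None,
    modes: tuple[str, ...] = ("individual", "dynamic", "basefit"),
    delta_fa_true: float = -200.0,
) -> pd.DataFrame:
    """Precision of recovered delta-2H vs peak amplitude, per background mode.

    Each replicate simulates one injection (single compound at rt 500 s on
    a slowly rising background, default channel noise and run jitter) and
    processes it under every requested background mode; the same trace is
    shared across modes so mode differences are paired.  Returns a table
    with columns ``bin``, ``amplitude_mv``, ``mode``, ``n``, ``mean_delta``,
    ``sd_delta``, ``mean_error`` (mean of recovered minus true FAME delta).
    """
    if amplitudes is None:
        amplitudes = PRECISION_AMPLITUDES
    h_n = 34
    configs = {mode: _mode_config(mode, robust=True) for mode in modes}
    background = BackgroundModel(mode="ramp", level=20.0, slope=0.005, delta_bg=-80.0)
    rows = []
    for b, (bin_name, amp) in enumerate(amplitudes.items()):
        amount = amount_for_amplitude(amp)
        deltas: dict[str, list[float]] = {mode: [] for mode in modes}
        true_fame = None
        for rep in range(n_reps):
            spec = SimulationSpec(
                compounds=[
                    CompoundSpec("FAME", h_n, 500.0, amount,
                                 delta_fa_true=delta_fa_true, shape=_SHAPE)
                ],
                ref_pulses=[RefPulse(80.0, 110.0, 3.0), RefPulse(140.0, 170.0, 3.0)],
                ref_delta=-120.0,
                h3_factor=3.0,
                background=background,
                sample_rate=4.0,
                duration=1200.0,
                seed=seed + 1000 * b + rep,
                sample_id=f"{bin_name}_{rep}",
            )
            trace, truth = simulate_chromatogram(spec)
            true_fame = float(truth.compounds["delta_fame"].iloc[0])
            for mode in modes:
                m = measure_trace(trace, configs[mode], 3.0)
                near = [p for p in m.peaks if abs(p.t_apex - 500.0) < 20.0]
                if not near:
                    continue
                peak = max(near, key=lambda p: p.area2)
                deltas[mode].append(cal.raw_delta(peak.ratio, m.r_ref, -120.0))
        for mode in modes:
            vals = np.asarray(deltas[mode])
            rows.append(
                {
                    "bin": bin_name,
                    "amplitude_mv": amp,
                    "mode": mode,
                    "n": len(vals),
                    "mean_delta": float(np.mean(vals)) if len(vals) else np.nan,
                    "sd_delta": float(np.std(vals, ddof=1)) if len(vals) > 1 else np.nan,
                    "mean_error": float(np.mean(vals) - true_fame) if len(vals) else np.nan,
                }
            )
    return pd.DataFrame(rows)
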