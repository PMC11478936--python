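"""Synthetic pyrolysis-IRMS chromatograms with fully known ground truth.

The generator emulates the measurement chain of a GC / high-temperature
conversion / IRMS instrument at the signal level: a mass-2 (H2+) ion-current
trace built from a background model, exponentially-modified-Gaussian (EMG)
compound peaks and rectangular reference-gas pulses, and a mass-3 (HD+ plus
H3+) trace whose isotope-ratio encoding carries each compound's delta-2H
value.  The H3+ interference enters as the standard quadratic term
K * 1e-6 * i2^2 (i2 in volts, K in ppm/V).

Within a compound's contribution the mass-3/mass-2 ratio is
``R_machine * (1 + delta_enc/1000)`` where ``R_machine = 2 * 155.76 ppm``
(the HD/H2 equivalent of the VSMOW 2H/1H ratio) and ``delta_enc`` is the
compound's FAME delta-2H after an optional instrumental scale/offset
distortion (``cal_scale``, ``cal_offset``) that the downstream two-point
normalization is expected to undo.  Reference-gas pulses encode their
assigned delta undistorted: they are the within-run anchor everything else
is measured against.

Two stochastic components are modelled: white Gaussian channel noise
(independent per channel) and a per-run isotopic jitter that shifts all
compound ratios of one injection coherently, emulating run-to-run
conversion/flow variability.  The jitter is what keeps the precision of
large peaks finite, as observed on real instruments; channel noise controls
the amplitude-dependent part.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import exponnorm, norm

from .trace_io import IsotopeTrace

__all__ = [
    "R_VSMOW_2H",
    "R_MACHINE",
    "PeakShape",
    "CompoundSpec",
    "BackgroundModel",
    "RefPulse",
    "SimulationSpec",
    "GroundTruth",
    "fame_delta_from_fa",
    "simulate_chromatogram",
    "simulate_dilution_series",
]

#: 2H/1H of VSMOW (fixed literature constant; the delta scale's zero point)
R_VSMOW_2H = 155.76e-6
#: mass-3/mass-2 ion-current ratio equivalent ([HD]/[H2] = 2 * 2H/1H)
R_MACHINE = 2.0 * R_VSMOW_2H

#: default mass-3 channel noise per 1 mV of mass-2 noise.  The mass-3 cup
#: sits behind a much higher-gain amplifier; expressed on the common scale
#: used here (i3 ~ 300 ppm of i2) its noise floor is correspondingly small.
DEFAULT_NOISE3_PER_NOISE2 = 1e-4


def fame_delta_from_fa(delta_fa: float, h_n: int, delta_me: float) -> float:
    """Forward mass balance: delta-2H of the FAME from the free fatty acid.

    The methyl ester carries ``h_n - 1`` H atoms from the acid (the acidic H
    is lost) plus 3 from methanol::

        delta_FAME = ((h_n - 1) * delta_fa + 3 * delta_me) / (h_n + 2)

    Parameters are in per mil vs VSMOW; ``h_n`` is the H count of the free
    fatty acid (>= 4).
    """
    h_n = int(h_n)
    if h_n < 4:
        raise ValueError(f"h_n={h_n}: a fatty acid has at least 4 H atoms")
    return ((h_n - 1) * delta_fa + 3.0 * delta_me) / (h_n + 2)


@dataclass(frozen=True)
class PeakShape:
    """EMG peak shape: Gaussian width plus exponential tailing, both in s.

    ``tailing -> 0`` degenerates to a pure Gaussian.
    """

    width: float = 3.0
    tailing: float = 2.0

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError("peak width must be positive")
        if self.tailing < 0:
            raise ValueError("tailing must be non-negative")

    def apex_offset(self) -> float:
        """Mode of the unit EMG relative to its Gaussian centre, s."""
        if self.tailing < 1e-9 * self.width:
            return 0.0
        grid = np.linspace(-self.width, self.width + 5 * self.tailing, 4001)
        pdf = exponnorm.pdf(grid, self.tailing / self.width, loc=0.0, scale=self.width)
        return float(grid[np.argmax(pdf)])

    def pdf(self, t: np.ndarray, apex: float) -> np.ndarray:
        """Unit-area shape positioned so its maximum sits at ``apex``."""
        mu = apex - self.apex_offset()
        if self.tailing < 1e-9 * self.width:
            return norm.pdf(t, loc=mu, scale=self.width)
        return exponnorm.pdf(t, self.tailing / self.width, loc=mu, scale=self.width)


@dataclass(frozen=True)
class CompoundSpec:
    """One simulated FAME peak and its isotopic ground truth.

    Either ``delta_fa_true`` (free fatty acid, converted through the methanol
    mass balance) or ``delta_fame_true`` (whole-molecule value, used for FAME
    reference materials such as the USGS C20 standards) must be given.
    """

    name: str
    h_n: int
    rt: float                      # apex retention time, s
    amount: float                  # mass-2 peak area, V*s
    delta_fa_true: float | None = None
    delta_fame_true: float | None = None
    shape: PeakShape = field(default_factory=PeakShape)

    def __post_init__(self) -> None:
        if self.h_n < 4:
            raise ValueError(f"{self.name}: h_n must be >= 4")
        if self.amount <= 0:
            raise ValueError(f"{self.name}: amount must be positive")
        if (self.delta_fa_true is None) == (self.delta_fame_true is None):
            raise ValueError(
                f"{self.name}: give exactly one of delta_fa_true / delta_fame_true"
            )

    def delta_fame(self, delta_me: float) -> float:
        if self.delta_fame_true is not None:
            return float(self.delta_fame_true)
        return fame_delta_from_fa(self.delta_fa_true, self.h_n, delta_me)


@dataclass(frozen=True)
class BackgroundModel:
    """True background: constant, linear ramp, or ramp + exponential rise.

    The exponential term emulates the late-run rise driven by the GC
    temperature program (column bleed).  ``delta_bg`` is the isotopic value
    carried by the background H2.
    """

    mode: str = "constant"       # constant | ramp | ramp_exp
    level: float = 20.0          # mV at t = 0
    slope: float = 0.0           # mV/s (ramp component)
    exp_amplitude: float = 0.0   # mV reached asymptotically by the exp term
    exp_onset: float = 0.0       # s, start of the exponential rise
    exp_tau: float = 400.0       # s, time constant of the rise
    delta_bg: float = -80.0      # per mil vs VSMOW

    def __post_init__(self) -> None:
        if self.mode not in ("constant", "ramp", "ramp_exp"):
            raise ValueError(f"unknown background mode {self.mode!r}")
        if self.exp_tau <= 0:
            raise ValueError("exp_tau must be positive")

    def evaluate(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        b = np.full_like(t, self.level)
        if self.mode in ("ramp", "ramp_exp"):
            b = b + self.slope * t
        if self.mode == "ramp_exp":
            rise = np.where(
                t >= self.exp_onset,
                1.0 - np.exp(-(t - self.exp_onset) / self.exp_tau),
                0.0,
            )
            b = b + self.exp_amplitude * rise
        return b


@dataclass(frozen=True)
class RefPulse:
    """Rectangular reference-gas pulse: [t_on, t_off) at ``amplitude`` volts."""

    t_on: float
    t_off: float
    amplitude: float  # V

    def __post_init__(self) -> None:
        if self.t_off <= self.t_on:
            raise ValueError("pulse must have t_off > t_on")
        if self.amplitude <= 0:
            raise ValueError("pulse amplitude must be positive")


@dataclass
class SimulationSpec:
    """Full description of one simulated injection.

    Defaults reproduce the measurement conditions of the study setup: a
    52-min run sampled at 4 Hz, an H3+ factor of 3.0 ppm/V, methanol at
    -146.8 per mil, ~1 mV mass-2 channel noise and ~2 per-mil run-to-run
    isotopic jitter (which together give a high-amplitude delta-2H
    repeatability of about 2 per mil).
    """

    compounds: list[CompoundSpec] = field(default_factory=list)
    ref_pulses: list[RefPulse] = field(default_factory=list)
    ref_delta: float = -120.0        # per mil, assigned value of the reference gas
    delta_methanol: float = -146.8   # per mil
    h3_factor: float = 3.0           # ppm/V
    background: BackgroundModel = field(default_factory=BackgroundModel)
    noise_sd: float = 1.0            # mV, mass-2 white noise
    noise_sd3: float | None = None   # mV, mass-3 white noise (default scaled from noise_sd)
    run_jitter_sd: float = 2.0       # per mil, coherent per-run isotopic jitter
    cal_scale: float = 1.0           # instrumental scale distortion on measured deltas
    cal_offset: float = 0.0          # per mil, instrumental offset distortion
    sample_rate: float = 4.0         # Hz
    duration: float = 3120.0         # s (52-min run)
    seed: int = 0
    sample_id: str = "sim"

    def __post_init__(self) -> None:
        if self.noise_sd < 0 or (self.noise_sd3 is not None and self.noise_sd3 < 0):
            raise ValueError("noise standard deviations must be non-negative")
        if self.run_jitter_sd < 0:
            raise ValueError("run_jitter_sd must be non-negative")
        if self.h3_factor < 0:
            raise ValueError("h3_factor must be non-negative")
        if self.sample_rate <= 0 or self.duration <= 0:
            raise ValueError("sample_rate and duration must be positive")
        for c in self.compounds:
            if not (0.0 < c.rt < self.duration):
                raise ValueError(f"{c.name}: rt {c.rt} outside trace span")
        for p in self.ref_pulses:
            for c in self.compounds:
                half = 4 * (c.shape.width + c.shape.tailing)
                if p.t_on < c.rt + half and c.rt - half < p.t_off:
                    raise ValueError(
                        f"reference pulse [{p.t_on}, {p.t_off}) overlaps compound {c.name}"
                    )

    @property
    def mass3_noise_sd(self) -> float:
        if self.noise_sd3 is not None:
            return self.noise_sd3
        return self.noise_sd * DEFAULT_NOISE3_PER_NOISE2

    @classmethod
    def from_dict(cls, data: dict) -> "SimulationSpec":
        data = dict(data)
        data["compounds"] = [
            CompoundSpec(
                **{**c, "shape": PeakShape(**c["shape"])} if "shape" in c else c
            )
            for c in data.get("compounds", [])
        ]
        data["ref_pulses"] = [RefPulse(**p) for p in data.get("ref_pulses", [])]
        if "background" in data:
            data["background"] = BackgroundModel(**data["background"])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown simulation key(s): {sorted(unknown)}")
        return cls(**data)


@dataclass
class GroundTruth:
    """Exact per-compound truth and trace-level truth for one simulation."""

    compounds: pd.DataFrame          # name, h_n, rt, amount, delta_fa, delta_fame, delta_encoded
    background2: np.ndarray          # true mass-2 background series, mV
    background3: np.ndarray          # true mass-3 background series, mV
    h3_factor: float                 # ppm/V
    ref_delta: float
    delta_methanol: float
    run_jitter: float                # per mil, realized per-run isotopic jitter
    overlap_warnings: list[tuple[str, str]] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return self.compounds.copy()


def _ratio_for_delta(delta: float) -> float:
    return R_MACHINE * (1.0 + delta / 1000.0)


def simulate_chromatogram(spec: SimulationSpec) -> tuple[IsotopeTrace, GroundTruth]:
    """Simulate one injection; identical spec + seed gives bit-identical output."""
    rng = np.random.default_rng(spec.seed)
    n = int(round(spec.duration * spec.sample_rate))
    t = np.arange(n) / spec.sample_rate

    b2 = spec.background.evaluate(t)
    delta_bg_enc = spec.cal_scale * spec.background.delta_bg + spec.cal_offset
    i2 = b2.copy()
    i3 = _ratio_for_delta(delta_bg_enc) * b2

    # coherent per-run isotopic jitter (conversion / flow variability)
    jitter = float(rng.normal(0.0, spec.run_jitter_sd)) if spec.run_jitter_sd > 0 else 0.0

    rows = []
    for comp in spec.compounds:
        peak_mv = comp.amount * 1000.0 * comp.shape.pdf(t, comp.rt)
        d_fame = comp.delta_fame(spec.delta_methanol)
        d_enc = spec.cal_scale * d_fame + spec.cal_offset + jitter
        i2 += peak_mv
        i3 += _ratio_for_delta(d_enc) * peak_mv
        rows.append(
            {
                "name": comp.name,
                "h_n": comp.h_n,
                "rt": comp.rt,
                "amount": comp.amount,
                "delta_fa": comp.delta_fa_true,
                "delta_fame": d_fame,
                "delta_encoded": d_enc,
            }
        )

    for pulse in spec.ref_pulses:
        rect = ((t >= pulse.t_on) & (t < pulse.t_off)) * (pulse.amplitude * 1000.0)
        i2 += rect
        i3 += _ratio_for_delta(spec.ref_delta) * rect

    # H3+ interference forms from the true H2 pressure (pre-noise signal):
    # K [ppm/V] * (i2 [V])^2 expressed in mV.
    i3 += spec.h3_factor * 1e-9 * i2 ** 2

    if spec.noise_sd > 0:
        i2 = i2 + rng.normal(0.0, spec.noise_sd, size=n)
    if spec.mass3_noise_sd > 0:
        i3 = i3 + rng.normal(0.0, spec.mass3_noise_sd, size=n)

    warnings: list[tuple[str, str]] = []
    ordered = sorted(spec.compounds, key=lambda c: c.rt)
    for a, b in zip(ordered, ordered[1:]):
        resolvable = 2.0 * (a.shape.width + a.shape.tailing + b.shape.width + b.shape.tailing)
        if b.rt - a.rt < resolvable:
            warnings.append((a.name, b.name))

    meta = {
        "sample_id": spec.sample_id,
        "seed": spec.seed,
        "noise_sd": spec.noise_sd,
        "ref_delta": spec.ref_delta,
        "ref_windows": [[p.t_on, p.t_off] for p in spec.ref_pulses],
    }
    trace = IsotopeTrace(t, i2, i3, meta)
    truth = GroundTruth(
        compounds=pd.DataFrame(
            rows,
            columns=["name", "h_n", "rt", "amount", "delta_fa", "delta_fame", "delta_encoded"],
        ),
        background2=b2,
        background3=_ratio_for_delta(delta_bg_enc) * b2,
        h3_factor=spec.h3_factor,
        ref_delta=spec.ref_delta,
        delta_methanol=spec.delta_methanol,
        run_jitter=jitter,
        overlap_warnings=warnings,
    )
    return trace, truth


def simulate_dilution_series(
    k: float,
    amplitudes: list[float],
    seed: int = 0,
    *,
    true_ratio_ppm: float = 500.0,
    noise_sd: float = 0.0,
    noise_sd3: float | None = None,
    pulse_length: float = 30.0,
    pad: float = 30.0,
    sample_rate: float = 4.0,
) -> list[IsotopeTrace]:
    """Reference-gas dilution series for H3+-factor determination.

    One trace per pulse amplitude (volts); every pulse carries the same true
    mass-3/mass-2 ratio (``true_ratio_ppm``) so that the apparent ratio grows
    linearly with amplitude at slope ``k`` ppm/V.
    """
    if k < 0:
        raise ValueError("H3 factor must be non-negative")
    amplitudes = [float(a) for a in amplitudes]
    if len(set(amplitudes)) < 2:
        raise ValueError(
            "a dilution series needs at least 2 distinct amplitudes; "
            "the H3 factor is unidentifiable otherwise"
        )
    rng = np.random.default_rng(seed)
    sd3 = noise_sd3 if noise_sd3 is not None else noise_sd * DEFAULT_NOISE3_PER_NOISE2
    ratio = true_ratio_ppm * 1e-6
    traces = []
    duration = pulse_length + 2 * pad
    n = int(round(duration * sample_rate))
    t = np.arange(n) / sample_rate
    for idx, amp in enumerate(amplitudes):
        rect = ((t >= pad) & (t < pad + pulse_length)) * (amp * 1000.0)  # mV
        i2 = rect.copy()
        i3 = ratio * rect + k * 1e-9 * rect ** 2
        if noise_sd > 0:
            i2 = i2 + rng.normal(0.0, noise_sd, size=n)
        if sd3 > 0:
            i3 = i3 + rng.normal(0.0, sd3, size=n)
        traces.append(
            IsotopeTrace(
                t,
                i2,
                i3,
                {
                    "sample_id": f"dilution_{idx}",
                    "pulse_window": [pad, pad + pulse_length],
                    "pulse_amplitude_v": amp,
                },
            )
        )
    return traces
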