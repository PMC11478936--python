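# Methods

This note documents the models, algorithms and numerical choices behind
`isofame`, and what the synthetic-data experiments do and do not establish
about real instrument data.

## Signal model of the simulator

One injection is modelled as two time series sampled at `sample_rate`
(default 4 Hz) over `duration` (default 3120 s, a 52-minute GC run):

* **mass 2** (H₂⁺, mV): `i2(t) = b(t) + Σ_p a_p·g_p(t) + Σ_r pulse_r(t) + ε₂(t)`
  where `b` is the background model, `g_p` a unit-area exponentially
  modified Gaussian (EMG) positioned so its **mode** sits at the compound's
  retention time, `a_p` the compound amount in V·s, and the reference-gas
  pulses are hard-edged rectangles.  The EMG width/tailing defaults
  (σ = 3 s, τ = 2 s) give realistic 25–30 s peak widths; τ → 0 degenerates
  to a pure Gaussian.
* **mass 3** (HD⁺ + H₃⁺, mV): every component of `i2` contributes with its
  own isotope-ratio factor `R = R_m·(1 + δ_enc/1000)`, where
  `R_m = 2 × 155.76 ppm` is the HD/H₂ equivalent of the VSMOW ²H/¹H ratio
  (a fixed literature constant — VSMOW enters only as the scale anchor),
  plus the H₃⁺ interference `K·10⁻⁶·i2²` (i2 in V, K in ppm/V, default
  3.0) computed from the pre-noise signal, plus independent white noise
  ε₃(t).

`δ_enc` is the compound's FAME δ²H after an optional instrumental affine
distortion (`cal_scale`, `cal_offset`) standing in for ion-source
scale-compression effects; reference-gas pulses are encoded undistorted
because they are the within-run anchor everything is measured against.
Two-point normalization through the USGS70/USGS71 anchors is what undoes
the distortion downstream, exactly mirroring its role on a real instrument.

### Stochastic components and their defaults

* `noise_sd = 1.0 mV`: white mass-2 channel noise.
* `noise_sd3 = 1e-4 × noise_sd` (as mV on the common scale): the mass-3 cup
  sits behind a much higher-gain amplifier, so expressed on the scale where
  `i3 ≈ 300 ppm × i2` its noise floor is small.  This ratio makes the
  relative mass-3 noise per sample ~10⁻⁴ for a 1 V peak, consistent with a
  high-gain measurement chain.
* `run_jitter_sd = 2.0 ‰`: a per-injection shift applied coherently to all
  compound ratios of one run, emulating pyrolysis-conversion and flow
  variability.  This is what bounds the precision of *large* peaks: with
  channel noise alone, V-scale peaks would be implausibly precise.  The two
  defaults together give a high-amplitude δ²H repeatability near 2 ‰,
  matching the repeatability a well-tuned setup reports, while channel
  noise and background statistics drive the blow-up of scatter and bias
  below a few hundred mV.

Determinism: all randomness flows from an explicit integer seed through one
`numpy` generator per simulation; identical spec + seed is bit-identical.

The simulator emulates: amplitude-dependent precision, background-mode
sensitivity, H₃⁺ contamination, coelution, detector-side QC, normalization
distortion.  It does **not** emulate: retention-time drift or prediction,
pyrolysis chemistry (incomplete conversion, memory effects between
injections), column overload peak-shape changes, or correlated (1/f)
detector noise.  Passing tests therefore validate the *processing
arithmetic* under controlled conditions, not chromatographic practice on
any particular instrument.

## Background estimation

All three modes estimate mass 2 and mass 3 independently (different
amplifiers, different noise floors).

* **individual** — constant per peak: the lowest intensities within
  `history_time` before the peak start.  No default history time is
  offered; it is instrument-specific and must be configured.  The mode's
  documented failure modes (tail contamination of the history window,
  bias on sloped backgrounds) are reproduced by the tests.
* **dynamic** — the trace is cut into `step_width` slices (default 150 s);
  each contributes a node at the **time of its minimum** (not the step
  midpoint — argmin placement makes the estimate exact on linear ramps,
  which midpoint placement is not); the background is the piecewise-linear
  interpolation through the nodes, extended flat at the ends.  A trailing
  partial step keeps its own node so late-eluting peaks are not left beyond
  the last node.
* **basefit** — a penalized cubic smoothing spline (`scipy`'s
  `make_smoothing_spline`; the `smoothing` parameter is the roughness
  penalty λ, approaching a straight-line fit as λ → ∞) through the same
  step nodes, made robust by iteratively discarding nodes lying more than
  one robust scale *above* the fit.  Two numerical points matter:
  residuals are computed **leave-one-out** (a flexible spline interpolates
  its own nodes, outliers included, so ordinary residuals cannot expose a
  contaminated node), and the robust scale is estimated from the
  non-positive residual side only (outliers are one-sided, and a two-sided
  scale makes the rejection loop cascade on noisy traces).  The loop is
  capped at 20 iterations and at a minimum of 5 nodes; on failure the
  estimator falls back to the dynamic estimate with a warning flag.  The
  spline is evaluated flat outside the kept-node range (cubic
  extrapolation is unsafe).  A diagnostic flag (never a clip) marks fits
  that ride above their own nodes by more than the robust scale.
  Commercial software ships an algorithm of this name with unpublished
  internals; this definition is this package's concrete realization of the
  behaviours attributed to it (whole-chromatogram fit, tunable smoothing,
  robustness to injection-volume changes).

Step nodes use the strict minimum on noiseless data and the 2nd percentile
when the trace declares channel noise (`noise_sd` metadata), avoiding the
negative bias of an extreme order statistic; an explicit `robust:
true/false` in the configuration overrides the automatic choice.

## Peak detection, integration, QC

The derivative is a Savitzky–Golay local-polynomial slope (default window
21 samples ≈ 5 s, order 2): raw finite differences at 4 Hz have mV/s-scale
noise for mV-scale channel noise, swamping the 1 mV/s start threshold.  A
peak starts where the derivative sustains ≥ `start_slope` over one
smoothing window, and ends where, after the apex, the descending
derivative's magnitude returns below `end_slope`; gentle peaks that never
descend steeply end where the signal returns to its start level.  Plateau
apex ties resolve to the earliest sample.

Adjacent peaks split at a valley exceeding 25 % of the smaller apex are
flagged `merged` (not baseline-separated), as are single regions containing
two prominence-filtered maxima.  A mixture of two equal peaks less than ~2 σ
apart is strictly unimodal — no detector working from the trace alone can
flag it; the simulator's ground truth carries an `overlap_warnings` list
for apex spacings below `2·(σ₁+τ₁+σ₂+τ₂)` so such fixtures are at least
known to be unresolvable.

Integration is trapezoidal over the detected window, in V·s, of the
background-subtracted mass-2 and the H₃⁺-corrected, background-subtracted
mass-3 signal.  The per-peak ratio is the **ratio of areas** ∫i3corr/∫i2
(not the mean of pointwise ratios): the area ratio is what area-weighted
coelution merging assumes, and it makes tail truncation cancel between the
channels.  QC applies strict inequalities (amplitude > 450 mV, area
> 4 V·s, both on background-subtracted quantities); boundary values are
rejected, and rejected peaks are retained with flags rather than dropped.
The amplitude is measured after background subtraction — the publication
behind these thresholds does not say which side of subtraction it means,
and the subtracted amplitude is the one that tracks actual peak size on a
sloped background.

## Calibration chain

Fixed order: H₃⁺ correction → integration → raw δ against the within-run
reference-gas pulses → two-point normalization → methanol correction →
quadrature uncertainty.  The anchors (USGS70/71) are C20 FAMEs measured
like samples, and their assigned values are whole-molecule FAME values, so
the methanol correction applies to samples only, after normalization — the
order is forced by what the anchor certificates certify.

* H₃⁺ factor: least-squares slope of apparent ratio (ppm) vs. pulse
  amplitude (V) over a dilution series; requires ≥ 3 pulses spanning ≥ 2×
  amplitude; the standard error of the slope is the factor's uncertainty.
* Two-point normalization maps the mean measured anchor values exactly onto
  the assigned values; it inverts any affine instrumental distortion.
* Drift monitoring regresses each anchor's measured δ on run index and
  flags when the slope is significant (p < α, default α = 0.01) **and**
  its accumulated effect over the sequence span exceeds the replicate SD.
  The magnitude condition alone fires on 20–30 % of clean sequences (its
  implied t-threshold is ~1); the significance gate brings the false-alarm
  rate to the percent level, which is what makes a drift monitor usable,
  while a genuine 1 ‰/run drift over ten runs remains far above both
  conditions.
* Uncertainty: √(sd² + u₇₀² + u₇₁² + u_VSMOW²), with the methanol
  determination uncertainty (±2.6 ‰) available as an optional fifth
  component, off by default — the methanol term enters the mass balance
  with weight 3/(H_n−1) ≈ 0.1, so budgeting its full uncertainty would
  overstate it; deltas are reported to 0.1 ‰.

With the `individual` background mode the pipeline detects peaks on an
internal dynamic estimate (slope thresholds on a derivative are invariant
to constant offsets, so this cannot move boundaries materially) and then
integrates with the per-peak history constants the mode defines — the
constants cannot exist before the peaks do.

## Identification and merging

Greedy nearest-RT matching within a tolerance (default 10 s — no published
value exists; 10 s is tight enough to separate adjacent FAME peaks at
these widths and loose enough for run-to-run RT scatter), each library
entry used at most once, exact ties flagged ambiguous.  Greedy matching is
transparent to audit and coincides with exhaustive minimum-total-offset
matching whenever library spacing exceeds the tolerance, which the test
suite verifies against a brute-force oracle.  Coelution rules (e.g. the
C18:1n-7/n-9 pair a high-capacity column cannot separate) merge contiguous
member peaks by summing areas, which makes the merged δ the
mass-2-area-weighted mean.

## Ecology layer

Class pooling weights each compound's δ²H by its mass-2 peak area within
SFA/MUFA, n-6 PUFA and n-3 PUFA classes per sample; empty classes are
omitted, never reported as zero.  Diet–consumer fits are ordinary least
squares of individual consumer records on diet values averaged per
site × compound, with a tissue filter defaulting to muscle and a minimum
of 3 pairs.  OLS (not reduced-major-axis) is used because the reported
slopes it should be compared to are plain regressions; the records table
is exportable for any external treatment.

## Experiment problem sizes

The bundled performance experiments (`isofame.experiments`) use 1200–1500 s
traces at 4 Hz, 200 replicates per amplitude bin for the precision
experiment and 200 replicates for the noisy H₃⁺-recovery coverage check —
ensembles large enough that the monotone SD ordering across amplitude bins
and the ≤ 1 ‰ inter-mode agreement at > 2500 mV are stable properties, not
sampling accidents.  Peak positions in these layouts are chosen mid-step
relative to both background grids and pulse windows are placed after the
individual-mode history window; these are preconditions of the estimators,
not tuning.

## Known limitations

* No deconvolution of overlapped peaks beyond explicit merging; no
  Fourier/wavelet baselines; no Kovats RT calibration or spectral
  identification; no memory-effect correction between injections.
* The simulator's affine calibration distortion cannot represent
  non-linear scale effects; with real non-linearity, two-point
  normalization leaves a residual the simulator will not show.
* `individual`-mode exactness on sloped backgrounds relies on anchors
  measured at sample-like amount and shape (equal affine bias cancels in
  normalization); with heterogeneous peak sizes the mode is biased, which
  is precisely the behaviour the mode comparison demonstrates.
* Bayesian mixing models, isoscapes and migration inference are out of
  scope.
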