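# isofame

Compound-specific stable hydrogen isotope (δ²H) processing for
GC/pyrolysis-IRMS chromatograms of fatty-acid methyl esters (FAMEs) — from
raw mass-2/mass-3 ion-current traces to methanol-corrected, VSMOW-normalized
fatty-acid δ²H values with propagated uncertainty, plus the downstream
food-web pooling and diet–consumer regression analysis used in stable-isotope
trophic ecology.

δ²H values of individual fatty acids separate dietary sources (terrestrial
leaves vs. aquatic algae, diet vs. consumer) far more sharply than bulk
tissue isotopes, but the measurement is hard: natural ²H abundance is tiny,
the mass-3 (HD⁺) ion current is contaminated by H₃⁺ ions, the chromatographic
background rises with the GC temperature program, and derivatization adds
three methanol-derived hydrogens to every molecule.  `isofame` implements the
complete data-processing chain that turns these raw signals into comparable
fatty-acid δ²H values, together with a chromatogram **simulator** with fully
known ground truth, so every processing step is testable without instrument
data.

## The method

For each injection, on traces `i2(t)` (mass 2, mV) and `i3(t)` (mass 3):

1. **H₃⁺ correction** (pointwise, before any integration), with the H₃⁺
   factor *K* in ppm/V determined from a reference-gas dilution series
   (apparent ratio vs. pulse amplitude is linear with slope *K*):

       i3_corr(t) = i3(t) − K·10⁻⁶·i2(t)²          (i2 in volts)

2. **Background subtraction** in one of three modes: `individual` (constant
   per peak: lowest intensities in a history window before the peak),
   `dynamic` (linear interpolation through per-step minima, default step
   150 s), or `basefit` (robust smoothing spline through the step minima,
   default step 200 s, explicit smoothing factor).

3. **Peak detection and integration** on the background-subtracted mass-2
   trace: start where the smoothed derivative sustains ≥ 1 mV/s, end where
   it falls back below 0.5 mV/s; trapezoidal areas; QC gate amplitude
   > 450 mV **and** area > 4 V·s (strict; rejected peaks are kept, flagged).
   Unresolved C18:1 isomers are merged into one area, giving their
   area-weighted δ²H.

4. **δ notation and normalization**: each peak's area ratio
   R = ∫i3_corr/∫i2 is referenced to the within-run H₂ reference-gas pulses,

       δ²H = ((1 + δ_ref/1000)·R_sample/R_ref − 1)·1000   (‰ vs VSMOW)

   then mapped onto the VSMOW-SLAP scale by two-point normalization through
   the FAME reference materials USGS70 (−183.9 ± 1.4 ‰) and USGS71
   (−4.9 ± 1.0 ‰).

5. **Methanol correction** removes the three derivatization hydrogens by
   mass balance (H_n = H atoms of the free fatty acid, δ²H_Me the measured
   methanol value, −146.8 ± 2.6 ‰ by default):

       (H_n + 2)·δ²H_FAME = (H_n − 1)·δ²H_FA + 3·δ²H_Me

6. **Uncertainty** is the quadrature sum of the replicate SD and the
   VSMOW2 (±0.3 ‰) and USGS70/71 assignment uncertainties — e.g.
   √(2.7² + 1.4² + 1.0² + 0.3²) = 3.2 ‰.

The ecology layer pools compounds into fatty-acid classes by peak-area
weighting and fits site-specific ordinary least-squares regressions of
consumer δ²H on potential-diet δ²H (diet averaged per site × compound).

## Worked example

Simulate a small sequence (three compounds on a rising background, H₃⁺
factor 3 ppm/V, an instrumental distortion of scale 0.98 / offset +6 ‰ that
the normalization must undo, triplicate anchor injections, default noise),
then process it end to end:

```python
from isofame import (
    BackgroundModel, CompoundSpec, RefPulse, SimulationSpec,
    simulate_chromatogram, simulate_dilution_series,
    CompoundLibrary, LibraryEntry, load_config, process_sequence,
)

run_kw = dict(h3_factor=3.0, ref_delta=-120.0,
              ref_pulses=[RefPulse(80, 110, 4.0), RefPulse(140, 170, 4.0)],
              background=BackgroundModel(mode="ramp", level=20.0,
                                         slope=0.008, delta_bg=-80.0),
              duration=1500.0, cal_scale=0.98, cal_offset=6.0)

sample, truth = simulate_chromatogram(SimulationSpec(
    compounds=[
        CompoundSpec("C16:0", 32, 340.0, 10.0, delta_fa_true=-244.3),
        CompoundSpec("C18:0", 36, 640.0, 10.0, delta_fa_true=-142.2),
        CompoundSpec("ALA",   28, 940.0, 10.0, delta_fa_true=-209.2),
    ],
    seed=11, sample_id="leaf_litter", **run_kw))

anchors = {
    name: [simulate_chromatogram(SimulationSpec(
        compounds=[CompoundSpec(name, 40, 640.0, 10.0, delta_fame_true=d)],
        seed=s0 + i, sample_id=name, **run_kw))[0] for i in range(3)]
    for name, d, s0 in [("USGS70", -183.9, 20), ("USGS71", -4.9, 30)]
}
library = CompoundLibrary([
    LibraryEntry("C16:0", 32, 340.0, "SFA"),
    LibraryEntry("C18:0", 36, 640.0, "SFA"),
    LibraryEntry("ALA",   28, 940.0, "n-3"),
])
dilution = simulate_dilution_series(3.0, [1, 2, 3, 4, 6, 8], seed=40, noise_sd=1.0)

config = load_config(text="calibrate: {replicate_sd: 2.7}")
results, model = process_sequence(anchors, [sample], config, library,
                                  dilution_traces=dilution)
print(f"H3+ factor: {model.k:.3f} +/- {model.u_k:.3f} ppm/V")
print(f"normalization: delta = {model.m:.4f} * delta_measured + {model.c:.2f}")
```

This prints:

```
H3+ factor: 3.009 +/- 0.009 ppm/V
normalization: delta = 1.0075 * delta_measured + -4.85
compound     rt  amplitude_mV  area2_Vs  delta_fame  delta_fa  u_total
   C16:0 340.25        1155.0     10.04      -233.3    -241.6      3.2
   C18:0 640.00        1157.0     10.05      -142.6    -142.3      3.2
     ALA 940.00        1154.0     10.06      -202.2    -208.3      3.2
```

The H₃⁺ factor is recovered from the dilution series (3.009 vs. 3.0
injected); `delta_fame` is the normalized FAME value and `delta_fa` the
methanol-corrected fatty-acid value — within the 3.2 ‰ propagated
uncertainty of the true values (−244.3, −142.2, −209.2 ‰).  On a noiseless
simulation the same chain is exact to < 0.01 ‰ in every background mode.

The same pipeline is available from the shell:

```sh
isofame simulate --config sim.yaml --seed 11 --out runs/
isofame process --trace runs/leaf_litter.trace.csv \
    --anchor-trace runs/USGS70.csv --anchor-trace runs/USGS71.csv \
    --library lib.csv --config run.yaml --background dynamic --out out/
```

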