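# biozkit

Cardiorespiratory analysis of multi-site **bioimpedance** signals, with a
ground-truthed synthetic signal generator.

Wearable bioimpedance sensors inject a small 10 kHz AC current and measure
the complex tissue impedance, which varies with pulsatile blood flow at
arterial sites (wrist radial/ulnar, ankle tibial, neck carotid) and with
lung motion at thoracic sites (side-rib cage, thoracolumbar fascia).
`biozkit` is for researchers who want to extract beat-by-beat and
breath-by-breath timing from such recordings — and to validate every stage
of that extraction against exact ground truth, which human recordings
cannot provide.

## What it computes

Given a demodulated complex bioimpedance channel sampled at rate *f_s*, the
pipeline is:

1. **Band decomposition** — zero-phase 6th-order Butterworth band-passes
   into a cardiac band HF (0.5–6 Hz), a respiratory band LF (0.045–0.5 Hz),
   and a baseline-baseband BB (0.05–0.5 Hz).
2. **Beat detection** — arterial pulses appear as negative-going troughs
   (blood arrival lowers impedance); the detector finds the *arrival*
   trough of each cycle with a MAD-adaptive depth threshold, a 0.3 s
   refractory period and sub-sample parabolic refinement, and records the
   maximum-negative-slope point per cycle. Inter-beat intervals are
   IBI*ᵢ* = *tᵢ₊₁* − *tᵢ*.
3. **Ensemble morphology** — HF segments aligned on reference (finger-PPG)
   beats are stacked into a mean cycle ± SD, yielding per-site features:
   peak-to-peak amplitude, the two trough times/depths (arrival and
   reflection; at the carotid the reflection trough is the deeper one), and
   the maximum-slope time.
4. **Respiration extraction** — directly from thoracic LF, or indirectly
   from three modulations that cardiopulmonary coupling imprints on
   arterial pulses: baseline wander (**BB**), per-cycle amplitude
   modulation (**AM**, the HF envelope), and per-cycle frequency modulation
   (**FM**, respiratory sinus arrhythmia from max-slope timing). Breath
   peaks give inter-breath intervals IBrI and the per-trial breathing rate
   BR = 60 / mean(IBrI).
5. **Agreement statistics** — tolerance-matched event pairing, then
   ME, RMSE, MAE, Bland–Altman bias with 95 % limits of agreement
   (bias ± 1.96·SD) and Pearson's *r* between matched interval series.

The synthetic generator (`biozkit.simulate`) renders all of this with known
ground truth: site-specific double-trough pulse trains (100/60/250 mΩ
real-part peak-to-peak at radial–ulnar/tibial/carotid sites), HRV with
white jitter plus respiration-coupled RSA, BB/AM/FM driven by a single
respiration phase, thoracic channels with no cardiac content, a delayed
finger-PPG reference, an effort-belt reference, and a carrier-level
10 kHz quadrature-demodulation model.

## Worked example

```python
import biozkit as bz

cfg = bz.SimulationConfig(duration=300.0, seed=42,
                          respiratory=bz.RespiratoryParams(rate_brpm=15))
rec = bz.synthesize_record(cfg)

hf = bz.bandpass(rec.bioz_real, rec.fs, bz.HF_SPEC)
beats = bz.detect_bioz_beats(hf, rec.fs)
ibi, flags = bz.compute_ibi(beats)

m = bz.match_events(beats, rec.truth_beats, tolerance=0.25)
rep = bz.agreement(m)
resp = bz.analyze_respiration(rec, "BB")
```

printing, for this seed:

```
beats detected: 329
mean IBI: 0.8986 s  (configured 0.9000 s)
IBI vs truth:  ME -0.00000 s  RMSE 0.00048 s  MAE 0.00038 s  r 0.9999
Bland-Altman LoA: [-0.00095, 0.00094] s
breathing rate (BB modulation): 15.00 BrPM  (configured 15.00)
```

i.e. on a five-minute simulated radial recording at moderate noise, beat
timing from the HF troughs recovers the true inter-beat intervals with
sub-millisecond mean absolute error, and the baseline-wander modulation
recovers the configured breathing rate exactly to two decimals.

The same pipeline is available from the shell:

```bash
biozkit generate --site radial --duration 300 --seed 42 --out rec1
biozkit analyze cardiac --in rec1.csv --out cardiac.json
biozkit analyze respiration --in rec1.csv --mode bb --out resp.json
biozkit evaluate --in rec1.csv --out eval.json
```

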