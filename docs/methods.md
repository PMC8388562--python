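# Methods

This note documents the signal model behind `biozkit.simulate`, the
analysis procedures in `preprocessing`, `cardiac`, `respiration` and
`agreement`, the numerical choices that make them robust, and the known
limitations. It is the package's own scientific account; the API reference
lives in the docstrings.

## 1. Signal model

### 1.1 Measurement chain

A wearable bioimpedance front end injects a sub-sensation AC current at a
carrier frequency f_c = 10 kHz and measures the complex tissue impedance
Z(t) = R(t) + jX(t). `modulate_carrier` renders the raw voltage
`R·cos(2πf_c t) − X·sin(2πf_c t)`; `quadrature_demodulate` recovers R and X
by mixing with `2cos` / `−2sin` and low-pass filtering at f_c/4 (4th-order
Butterworth, zero-phase). The round-trip error is below 2 % RMS away from
edges (verified in the test suite). All other modules operate on the
demodulated baseband, in milliohms.

### 1.2 Cardiac component (arterial sites)

Blood is a better conductor than the surrounding tissue, so each arriving
pulse-pressure wave *decreases* impedance: arterial pulses are
negative-going. Each cycle is rendered as two negative Gaussian lobes — an
arrival trough at 0.22·IBI into the cycle and a reflection trough
`reflection_delay` later — whose relative depths, spacing and width are
site parameters:

| site          | pp real (mΩ) | pp imag (mΩ) | trough fracs (1st, 2nd) | reflection delay (s) | lobe σ (s) |
|---------------|-------------:|-------------:|-------------------------|---------------------:|-----------:|
| radial, ulnar | 100          | 20           | 1.0, 0.6                | 0.18                 | 0.05       |
| tibial        | 60           | 15           | 1.0, 0.35               | 0.22                 | 0.05       |
| carotid       | 250          | 40           | 0.6, 1.0                | 0.15                 | 0.04       |

At limb arteries the arrival trough is the deeper of the two; at the
carotid the *reflection* trough is deeper (late systolic flow), and a
narrower lobe width plus shorter delay keep the two troughs resolvable
after band-pass filtering. The imaginary channel uses the same waveform
scaled to `pp_imag`.

**Amplitude convention.** `pp_real` is defined as the peak-to-peak
excursion of the cardiac-band (HF) ensemble, not of the raw template.
Band-pass filtering attenuates the template by ≈ 4–5 %, so the generator
measures its own template's HF-band gain (on a tiled 9-cycle rendering,
centre cycle) and pre-scales by its inverse. PPG-referenced ensembles then
recover the configured amplitudes within 1 %.

### 1.3 Heart rhythm

Beat times are generated by accumulating per-beat intervals

IBI_i = mean_ibi + rsa_depth·sin(2π f_resp t_i) + ε_i,  ε_i ~ N(0, jitter²)

with redraws enforcing IBI ≥ 0.3 s. The RSA term is the FM respiratory
modulation; because jitter is drawn per interval, successive-difference SD
of the IBI series is jitter·√2.

### 1.4 Respiratory coupling

One respiration phase φ(t) = 2π f_resp t drives all routes:

- **BB** — additive baseline `bb_amplitude·sin φ` on both bioimpedance
  channels (default 30 mΩ at arterial sites; 200 mΩ at thoracic sites,
  where it is the dominant signal).
- **AM** — per-cycle pulse scaling `1 + am_depth·sin φ` (default depth
  0.10).
- **FM** — the RSA term above (default depth 0.05 s).

Thoracic sites (`ribcage`, `fascia`) carry no cardiac HF content: only the
respiratory baseline plus noise. Ground-truth breath times are the maxima
of sin φ, at t = (k + 0.25)/f_resp.

### 1.5 References and noise

A finger PPG is rendered per beat as an asymmetric raised cosine (rise
fraction 0.35, fall shaped `cos(π·u^(0.65/0.35))` so the valley curvature
is symmetric), delayed by `ppg_delay` = 50 ms; its foot marks the
reference beat. An effort belt reproduces sin φ in arbitrary units.
Measurement noise is additive white Gaussian, SD `noise_sd` (default
2 mΩ = 2 % of the radial pulse) on both bioimpedance channels.

Every `SignalRecord` carries its `truth_beats` (with per-beat slope times)
and `truth_breaths`, so estimators can be scored exactly.

## 2. Analysis procedures

### 2.1 Band decomposition

Three 6th-order Butterworth band-passes, applied zero-phase with
`sosfiltfilt`:

| band | pass-band (Hz) | content |
|------|----------------|---------|
| HF   | 0.5 – 6        | cardiac pulses |
| LF   | 0.045 – 0.5    | respiration (direct) |
| BB   | 0.05 – 0.5     | respiratory baseline wander |

Padding uses *even* reflection (`padtype="even"`, padlen ⌈f_s/f_low⌉).
Odd reflection — the scipy default — doubles any level offset at the
record edge and rings for tens of seconds at a 0.05 Hz corner; even
reflection reduced start-of-record BB leakage by more than an order of
magnitude. A 2 s edge guard is still applied to all event detections.

### 2.2 Beat detection

On the HF band, candidate minima below k·σ (k = 2, σ = 1.4826·MAD, a
median-based scale immune to the pulses themselves) are scanned left to
right with a 0.3 s refractory period, which keeps the *first* — arrival —
trough of each cycle and discards the reflection trough. The 2 s edge
guard is applied *after* the refractory chain: removing edge candidates
first can promote a reflection trough into the accepted set and produce a
single large interval error. Accepted troughs are refined to sub-sample
precision with a 3-point parabolic fit (shift clipped to ±½ sample). A
pulsatility gate requires the median accepted depth to be ≥ 3.0·σ;
otherwise the channel is judged non-pulsatile (e.g. a thoracic channel or
pure noise, whose ratio is ≈ 2.3 versus 4–10 for arterial sites) and the
detector raises instead of returning spurious beats. Each beat also
records the maximum-negative-slope time in the 0.25 s preceding its
trough, used by FM extraction. IBIs outside [0.3, 2.0] s are flagged.

PPG beats are detected analogously: 10 Hz zero-phase smoothing, systolic
peaks by prominence, foot = parabolic-refined minimum between peaks.

### 2.3 Ensemble averaging

HF segments in a (−0.2, +0.8) s window around each reference (PPG) beat
are stacked (≥ 10 beats required; overlapping windows flagged). The mean
cycle ± SD yields the morphology features: peak-to-peak amplitude, the two
most prominent trough times and depths, and the maximum-slope time. The
residual noise of the mean scales as 1/√n, verified at n = 25/100/400.

### 2.4 Respiration extraction

All four modalities produce a uniformly sampled modulation series on a
4 Hz grid (ample for < 0.5 Hz content, cheap to filter):

- **direct** (thoracic) — the LF band itself, interpolated to the grid;
- **BB** — the BB band, interpolated;
- **AM** — per-cycle HF max−min between consecutive beats, placed at cycle
  midpoints, interpolated, then BB-filtered at the grid rate;
- **FM** — successive differences of per-beat slope times (the
  instantaneous IBI), same placement and filtering.

Breath peaks are found with a 2 s minimum separation and prominence
0.3·(MAD-scaled amplitude), refined parabolically. IBrI are the
successive differences; the per-trial breathing rate is 60/mean(IBrI).

### 2.5 Agreement statistics

Estimated and reference events are matched greedily by nearest neighbour
within a tolerance (0.25 s for beats, 1.0 s for breaths), smallest
absolute difference first, ties to the earlier reference, each event used
at most once. Interval pairs are formed only where *consecutive* events
matched on both sides, so a missed event drops its two adjacent intervals
rather than corrupting them. On the paired intervals the report gives ME,
RMSE, MAE, the Bland–Altman bias with 95 % limits of agreement
(bias ± 1.96·SD, SD with ddof = 1) and Pearson's r (None, with a warning,
if either series has zero variance). At least 3 pairs are required.

## 3. Parameter defaults and rationale

| parameter | default | unit | rationale |
|-----------|---------|------|-----------|
| fs | 250 | Hz | typical wearable rate; > 40× the HF upper corner |
| duration | 300 | s | ≥ 300 cardiac cycles for stable ensembles |
| mean_ibi | 0.9 | s | resting adult heart rate ≈ 67 bpm |
| ibi_jitter_sd | 0.02 | s | resting short-term HRV scale |
| rsa_depth | 0.05 | s | resting RSA; detectable but subordinate to jitter default |
| ppg_delay | 0.05 | s | finger transit delay relative to wrist arrival |
| rate_brpm | 14 | BrPM | mid typical adult range 12–16 |
| bb_amplitude | 30 / 200 | mΩ | arterial wander small vs pulse; thoracic respiration dominant |
| am_depth | 0.10 | – | visible envelope without clipping pulses |
| noise_sd | 2.0 | mΩ | 2 % of radial pulse, moderate-quality contact |
| MAD threshold k | 2 | – | admits shallow troughs; refractory chain rejects duplicates |
| refractory | 0.3 | s | equals MIN_IBI_S; max plausible 200 bpm |
| pulsatility gate | 3.0·σ | – | separates arterial (4–10·σ) from noise (≈2.3·σ) depth ratios |
| breath min separation | 2.0 | s | max plausible 30 BrPM |
| edge guard | 2.0 | s | covers HF filter transient at 0.5 Hz corner |
| resample grid | 4 | Hz | ≥ 8× the highest respiratory frequency |

## 4. What the generator does and does not emulate

Modelled: site-specific double-trough morphology, real/imaginary amplitude
ratios, respiratory BB/AM/FM coupling through a single phase driver, white
HRV, sensor noise, PPG transit delay, carrier-level demodulation.

Not modelled: motion artefacts, electrode contact drift and impedance
steps, ectopic beats and arrhythmia, non-stationary breathing rate or
amplitude, inspiratory/expiratory asymmetry beyond the optional
raised-cosine waveform, pulse-shape change with posture or temperature,
and physiological coupling beyond first order (e.g. amplitude–rate
covariation). Error levels obtained on these simulations are therefore
best-case bounds for clean, stationary recordings.

## 5. Benchmark protocols

`biozkit.protocols` defines the standard evaluation conditions so scripts
and tests run identical procedures:

- **IBI recovery** — 10-minute radial records at 250 Hz, 20 ms jitter,
  30 ms RSA, 2 mΩ noise; HF-trough beats matched to truth within 0.25 s.
  MAE over five seeds ≈ 0.4 ms.
- **IBrI recovery** — 10-minute rib-cage records at 15 BrPM with noise at
  10 % of the respiratory swing; direct-mode breaths matched within 1 s.
  MAE over five seeds ≈ 6 ms.
- **Breathing-rate recovery** — 5-minute trials at 12/14/16 BrPM, three
  seeds each; per-trial rate error per modality. Worst modality (FM)
  MAE ≈ 0.04 BrPM.

`scripts/acceptance.py` runs all three and emits the results as JSON; all
trial seeds derive from a single `--seed` and stay below 2³¹.

## 6. Design decisions on open points

- **Arrival versus reflection trough**: beat timing is defined at the
  arrival trough, since the reflection delay varies by site and would bias
  inter-site comparisons.
- **Interval pairing**: interval-level statistics are restricted to
  consecutively matched events (Section 2.5) rather than interpolating
  across gaps, trading a little data for unbiased errors.
- **Rate definition**: the per-trial breathing rate is 60/mean(IBrI), not
  a spectral peak; it degrades gracefully at low breath counts and matches
  the event-level ground truth definition.
- **Direct mode on arterial sites** warns ("off-design"): the arterial LF
  band mixes baseline wander with residual pulse energy, so BB/AM/FM are
  the supported arterial modalities.
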