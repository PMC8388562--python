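"""Beat detection, inter-beat intervals, and PPG-referenced ensembles.

The HF bioimpedance pulse is a negative-going excursion: blood arrival drops
the impedance at the sensing site.  Each cardiac cycle shows an arrival
trough and, for arterial sites with a distal reflection path, a second
reflection trough.  Beat timing is taken at the *arrival* (first) trough;
the maximum-negative-slope point preceding it is recorded per cycle for
frequency-modulation (respiratory sinus arrhythmia) analysis.

Detection thresholds adapt to the signal via the median absolute deviation,
because per-site pulse amplitudes span roughly 60–250 mΩ.  Trough and slope
times are refined below the sample period with a three-point parabola.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .preprocessing import EDGE_GUARD_S
from .simulate import EventSeries

#: minimum interval between successive beat detections, seconds
REFRACTORY_S = 0.3
#: physiological IBI gate, seconds
IBI_GATE = (0.3, 2.0)
#: default MAD multiplier for the trough-depth threshold
K_MAD = 2.0

_MAD_TO_SD = 1.4826


def _mad_sigma(x: np.ndarray) -> float:
    return _MAD_TO_SD * float(np.median(np.abs(x - np.median(x))))


def _parabolic_refine(y: np.ndarray, i: int) -> float:
    """Sub-sample offset of the extremum of a 3-point parabola around i."""
    if i <= 0 or i >= y.size - 1:
        return 0.0
    a, b, c = y[i - 1], y[i], y[i + 1]
    denom = a - 2 * b + c
    if denom == 0:
        return 0.0
    delta = 0.5 * (a - c) / denom
    return float(np.clip(delta, -0.5, 0.5))


@dataclass(frozen=True)
class EnsembleResult:
    """PPG-aligned ensemble of HF cycles with morphology features."""

    cycle_matrix: np.ndarray   # (n_cycles, n_samples), mΩ
    mean_cycle: np.ndarray     # mΩ
    deviation: np.ndarray      # per-sample SD, mΩ
    window: tuple[float, float]
    fs: float
    features: dict

    @property
    def n_cycles(self) -> int:
        return int(self.cycle_matrix.shape[0])

    @property
    def time(self) -> np.ndarray:
        """Sample times relative to the alignment (reference beat) point."""
        n = self.mean_cycle.size
        return self.window[0] + np.arange(n) / self.fs


def detect_ppg_beats(ppg: np.ndarray, fs: float) -> EventSeries:
    """Locate PPG beats at the pulse foot.

    Systolic peaks establish the cycles; the foot of each cycle is the
    minimum between consecutive peaks (the valley preceding the upstroke),
    refined to sub-sample precision.  Detections closer than the 0.3 s
    refractory period to the previous one are suppressed.
    """
    ppg = np.asarray(ppg, dtype=float)
    # light zero-phase low-pass: the pulse waveform lives below ~10 Hz and
    # smoothing stabilises the foot (valley) location under sensor noise
    if ppg.size > 50 and fs > 24:
        sos = sps.butter(4, 10.0, btype="low", fs=fs, output="sos")
        ppg = sps.sosfiltfilt(sos, ppg)
    sigma = _mad_sigma(ppg)
    if sigma == 0:
        warnings.warn("flat PPG signal; no beats detected", stacklevel=2)
        return EventSeries(times=np.empty(0), kind="beat", source="ppg")
    peaks, _ = sps.find_peaks(ppg, distance=max(1, int(REFRACTORY_S * fs)),
                              prominence=1.0 * sigma)
    if peaks.size < 2:
        warnings.warn("fewer than two PPG pulses found", stacklevel=2)
        return EventSeries(times=np.empty(0), kind="beat", source="ppg")
    guard = int(round(EDGE_GUARD_S * fs))
    times = []
    for p0, p1 in zip(peaks[:-1], peaks[1:]):
        seg = ppg[p0:p1 + 1]
        i = p0 + int(np.argmin(seg))
        t = (i + _parabolic_refine(ppg, i)) / fs
        if i < guard or i >= ppg.size - guard:
            continue
        if times and t - times[-1] < REFRACTORY_S:
            continue
        times.append(t)
    return EventSeries(times=np.asarray(times), kind="beat", source="ppg")


def detect_bioz_beats(hf: np.ndarray, fs: float, k_mad: float = K_MAD,
                      refractory_s: float = REFRACTORY_S) -> EventSeries:
    """Detect beats at the arrival trough of the HF bioimpedance signal.

    Candidate minima deeper than ``k_mad`` MAD-scaled sigmas below zero are
    scanned left to right; within each refractory window only the first
    candidate — the arrival trough — is kept, which suppresses the
    reflection trough even at the carotid, where the reflection is the
    deeper of the two.  Each accepted beat also records the time of maximum
    negative slope on the preceding downstroke.
    """
    hf = np.asarray(hf, dtype=float)
    sigma = _mad_sigma(hf)
    thresh = k_mad * sigma
    minima, _ = sps.find_peaks(-hf, height=thresh)

    times: list[float] = []
    slope_times: list[float] = []
    dhf = np.gradient(hf) * fs
    last = -np.inf
    for i in minima:
        t = (i + _parabolic_refine(hf, i)) / fs
        if t - last < refractory_s:
            continue
        last = t
        times.append(t)
        # maximum negative slope on the downstroke into the arrival trough
        w0 = max(0, i - int(round(0.25 * fs)))
        if w0 < i:
            j = w0 + int(np.argmin(dhf[w0:i + 1]))
            slope_times.append((j + _parabolic_refine(dhf, j)) / fs)
        else:
            slope_times.append(t)
    # the refractory chain runs over the whole record so that a guarded-out
    # arrival trough still suppresses its reflection; the edge guard is
    # applied to the accepted events afterwards
    times_a = np.asarray(times)
    slope_a = np.asarray(slope_times)
    lo, hi = EDGE_GUARD_S, hf.size / fs - EDGE_GUARD_S
    keep = (times_a >= lo) & (times_a <= hi)
    times_a, slope_a = times_a[keep], slope_a[keep]
    if times_a.size < 2:
        raise ValueError("insufficient pulsatility: fewer than two beats "
                         "detected in HF bioimpedance")
    # pulsatility gate: genuine arterial troughs stand far outside the bulk
    # of the signal, while extremes of unstructured noise hug the threshold
    depths = -np.interp(times_a * fs, np.arange(hf.size), hf)
    if sigma > 0 and np.median(depths) < 3.0 * sigma:
        raise ValueError("insufficient pulsatility: trough depths are not "
                         "separated from the noise floor")
    return EventSeries(times=times_a, kind="beat", source="bioz",
                       slope_times=slope_a)


def compute_ibi(events: EventSeries,
                gate: tuple[float, float] = IBI_GATE) -> tuple[np.ndarray, np.ndarray]:
    """Inter-beat intervals with a physiological plausibility flag.

    Returns ``(intervals, flags)`` where ``flags`` marks intervals outside
    the [0.3, 2.0] s physiological gate.  Flagged intervals are not dropped:
    callers decide how to treat them.
    """
    if len(events) < 2:
        raise ValueError("need at least two events to form intervals")
    ibi = events.intervals
    flags = (ibi < gate[0]) | (ibi > gate[1])
    return ibi, flags


def ensemble_average(hf: np.ndarray, fs: float, reference_beats: EventSeries,
                     window: tuple[float, float] = (-0.2, 0.8)) -> EnsembleResult:
    """Stack HF segments around reference (PPG) beats and average them.

    Segments run from ``beat + window[0]`` to ``beat + window[1]``; beats
    whose window is not fully covered by the signal are skipped.  The mean
    cycle and the per-sample standard deviation quantify the site's average
    pulse morphology and its variability.  Overlapping segments (window
    longer than the local IBI) are allowed but flagged in the features.
    """
    hf = np.asarray(hf, dtype=float)
    w0, w1 = window
    if w1 <= w0:
        raise ValueError("window must have positive span")
    n_seg = int(round((w1 - w0) * fs))
    segs = []
    used_beats = []
    for tb in reference_beats.times:
        i0 = int(round((tb + w0) * fs))
        if i0 < 0 or i0 + n_seg > hf.size:
            continue
        segs.append(hf[i0:i0 + n_seg])
        used_beats.append(tb)
    if len(segs) < 10:
        raise ValueError("need at least 10 fully covered reference beats")
    mat = np.vstack(segs)
    mean_cycle = mat.mean(axis=0)
    deviation = mat.std(axis=0, ddof=0)
    overlap = bool(len(used_beats) > 1
                   and (w1 - w0) > np.min(np.diff(used_beats)))
    features = _morphology_features(mean_cycle, fs, w0)
    features["overlapping_segments"] = overlap
    return EnsembleResult(cycle_matrix=mat, mean_cycle=mean_cycle,
                          deviation=deviation, window=window, fs=fs,
                          features=features)


def _morphology_features(mean_cycle: np.ndarray, fs: float,
                         w0: float) -> dict:
    """Peak-to-peak amplitude, the two trough times, and max-slope time."""
    pp = float(mean_cycle.max() - mean_cycle.min())
    minima, props = sps.find_peaks(-mean_cycle, prominence=0.05 * pp)
    order = np.argsort(props["prominences"])[::-1]
    troughs = np.sort(minima[order[:2]])
    t_of = lambda i: w0 + (i + _parabolic_refine(mean_cycle, int(i))) / fs
    trough1_time = t_of(troughs[0]) if troughs.size >= 1 else None
    trough2_time = t_of(troughs[1]) if troughs.size >= 2 else None
    trough1_depth = float(mean_cycle[troughs[0]]) if troughs.size >= 1 else None
    trough2_depth = float(mean_cycle[troughs[1]]) if troughs.size >= 2 else None
    d = np.gradient(mean_cycle) * fs
    j = int(np.argmin(d))
    return {"pp_amplitude": pp,
            "trough1_time": trough1_time, "trough2_time": trough2_time,
            "trough1_depth": trough1_depth, "trough2_depth": trough2_depth,
            "max_slope_time": w0 + (j + _parabolic_refine(d, j)) / fs}
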