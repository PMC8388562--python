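"""Respiration waveform extraction, breath detection, IBrI and rate.

Respiration reaches the bioimpedance signal by two routes:

* **directly** at thoracic sites, where lung motion dominates the
  low-frequency (LF) band of both impedance components; and
* **indirectly** at arterial sites through cardiopulmonary coupling, which
  imprints three modulations on the pulse signal — a baseline shift (BB), a
  per-cycle amplitude change (AM), and a per-cycle timing change (FM,
  respiratory sinus arrhythmia).

Each route yields a respiration waveform on a uniform low-rate grid; breath
events are its local maxima (end-inspiration, matching the effort-belt
convention), inter-breath intervals (IBrI) are consecutive peak spacings,
and the per-trial breathing rate is ``60 / mean(IBrI)``.

Beat-indexed series (AM, FM) are linearly interpolated to a 4 Hz grid —
eight-fold oversampling of the 0.5 Hz respiratory band edge — and band-pass
filtered to the BB band before peak detection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .cardiac import _mad_sigma, _parabolic_refine
from .preprocessing import BB_SPEC, LF_SPEC, BandSpec, bandpass
from .simulate import ARTERIAL_SITES, EventSeries, SignalRecord

#: uniform grid rate for modulation series, Hz
RESAMPLE_HZ = 4.0
#: minimum separation between breath peaks, seconds (0.5 Hz band edge)
MIN_BREATH_SEP_S = 2.0
#: prominence threshold as a fraction of the MAD-scaled series amplitude
PROMINENCE_FRAC = 0.3

MODALITIES = ("direct", "BB", "AM", "FM")


@dataclass(frozen=True)
class ModulationSeries:
    """A respiration waveform extracted by one modality, on a uniform grid."""

    kind: str                 # {"BB", "AM", "FM", "direct"}
    t: np.ndarray             # s
    value: np.ndarray         # mΩ for BB/AM/direct, s for FM
    resample_hz: float

    def __post_init__(self):
        if self.kind not in MODALITIES and self.kind not in ("BB", "AM", "FM"):
            raise ValueError(f"unknown modulation kind {self.kind!r}")
        if self.resample_hz < 2.0:
            raise ValueError("resample_hz must be >= 2 Hz (4x the 0.5 Hz "
                             "respiratory band edge)")
        if not np.all(np.isfinite(self.value)):
            raise ValueError("modulation series contains non-finite values")


@dataclass(frozen=True)
class BreathReport:
    """Breath events, IBrI series and average rate for one modality."""

    events: EventSeries
    ibri: np.ndarray          # s
    rate_brpm: float
    modality: str             # {"direct", "BB", "AM", "FM"}
    component: str = "real"   # {"real", "imaginary"}


def _resample_uniform(t_irregular: np.ndarray, v: np.ndarray,
                      duration: float, resample_hz: float) -> ModulationSeries:
    grid = np.arange(0.0, duration, 1.0 / resample_hz)
    out = np.interp(grid, t_irregular, v)
    return grid, out


def _bb_filter_lowrate(v: np.ndarray, fs: float) -> np.ndarray:
    """BB band-pass for low-rate series; falls back to mean removal when the
    series is too short for the filter startup."""
    try:
        return bandpass(v, fs, BB_SPEC)
    except ValueError:
        return v - np.mean(v)


def extract_bb(channel: np.ndarray, fs: float,
               resample_hz: float = RESAMPLE_HZ,
               spec: BandSpec = BB_SPEC) -> ModulationSeries:
    """Baseline-wander respiration: BB band-pass, then downsample.

    The band-pass (0.05–0.5 Hz) is itself the anti-aliasing step for any
    resample rate above 1 Hz, so plain linear interpolation onto the uniform
    low-rate grid follows it.
    """
    channel = np.asarray(channel, dtype=float)
    filtered = bandpass(channel, fs, spec)
    t_in = np.arange(channel.size) / fs
    grid, out = _resample_uniform(t_in, filtered, t_in[-1], resample_hz)
    return ModulationSeries(kind="BB", t=grid, value=out,
                            resample_hz=resample_hz)


def extract_am(hf: np.ndarray, fs: float, beats: EventSeries,
               resample_hz: float = RESAMPLE_HZ) -> ModulationSeries:
    """Amplitude-modulation respiration from the HF envelope.

    The envelope is measured as the per-cycle peak-to-peak excursion of the
    HF signal between consecutive beats, attached to the cycle midpoint,
    interpolated to the uniform grid, and BB band-passed.
    """
    if len(beats) < 3:
        raise ValueError("need at least 3 beats for AM extraction")
    hf = np.asarray(hf, dtype=float)
    times = beats.times
    mids, amps = [], []
    for t0, t1 in zip(times[:-1], times[1:]):
        i0, i1 = int(round(t0 * fs)), int(round(t1 * fs))
        i0, i1 = max(i0, 0), min(i1, hf.size)
        if i1 - i0 < 2:
            continue
        seg = hf[i0:i1]
        mids.append(0.5 * (t0 + t1))
        amps.append(float(seg.max() - seg.min()))
    duration = hf.size / fs
    grid, out = _resample_uniform(np.asarray(mids), np.asarray(amps),
                                  duration, resample_hz)
    out = _bb_filter_lowrate(out, resample_hz)
    return ModulationSeries(kind="AM", t=grid, value=out,
                            resample_hz=resample_hz)


def extract_fm(beats: EventSeries,
               resample_hz: float = RESAMPLE_HZ,
               duration: float | None = None) -> ModulationSeries:
    """Frequency-modulation respiration (respiratory sinus arrhythmia).

    Instantaneous inter-beat intervals are measured between successive
    maximum-negative-slope points (falling back to the trough times when
    slope times are absent), attached to cycle midpoints, interpolated to
    the uniform grid, and BB band-passed.  Units are seconds of IBI
    deviation.
    """
    if len(beats) < 3:
        raise ValueError("need at least 3 cycles for FM extraction")
    marks = beats.slope_times if beats.slope_times is not None else beats.times
    marks = np.asarray(marks, dtype=float)
    ibi = np.diff(marks)
    mids = 0.5 * (marks[:-1] + marks[1:])
    if duration is None:
        duration = float(marks[-1])
    grid, out = _resample_uniform(mids, ibi, duration, resample_hz)
    out = _bb_filter_lowrate(out, resample_hz)
    return ModulationSeries(kind="FM", t=grid, value=out,
                            resample_hz=resample_hz)


def extract_direct(record: SignalRecord, component: str = "real",
                   resample_hz: float = RESAMPLE_HZ,
                   spec: BandSpec = LF_SPEC) -> ModulationSeries:
    """Direct thoracic respiration: the LF band of one impedance component."""
    import warnings
    if record.site in ARTERIAL_SITES:
        warnings.warn(
            f"direct respiration extraction on arterial site {record.site!r} "
            "is off-design; the LF content there is modulation, not lung "
            "motion", stacklevel=2)
    channel = {"real": "bioz_real", "imaginary": "bioz_imag",
               "imag": "bioz_imag"}[component]
    x = record.channel(channel)
    filtered = bandpass(x, record.fs, spec)
    grid, out = _resample_uniform(record.t, filtered, record.duration,
                                  resample_hz)
    return ModulationSeries(kind="direct", t=grid, value=out,
                            resample_hz=resample_hz)


def detect_breaths(mod: ModulationSeries,
                   min_sep_s: float = MIN_BREATH_SEP_S,
                   prominence_frac: float = PROMINENCE_FRAC) -> EventSeries:
    """Breath events at the local maxima of a respiration waveform.

    Peaks must be at least 2 s apart (the 0.5 Hz band edge) and at least
    ``prominence_frac`` of the MAD-scaled series amplitude prominent, which
    rejects sub-threshold ripples.  Peak times are refined with a
    three-point parabola.
    """
    v = mod.value
    fs = mod.resample_hz
    scale = _mad_sigma(v)
    if scale == 0:
        raise ValueError("flat respiration series; no breaths detectable")
    peaks, _ = sps.find_peaks(v, distance=max(1, int(round(min_sep_s * fs))),
                              prominence=prominence_frac * scale)
    if peaks.size == 0:
        raise ValueError("no breath peaks found")
    times = mod.t[0] + (peaks + np.array(
        [_parabolic_refine(v, int(p)) for p in peaks])) / fs
    return EventSeries(times=times, kind="breath", source=mod.kind)


def compute_ibri(events: EventSeries) -> np.ndarray:
    """Inter-breath intervals from consecutive breath peaks, in seconds."""
    if len(events) < 2:
        raise ValueError("need at least two breaths to form intervals")
    return events.intervals


def breathing_rate(events: EventSeries,
                   trial_duration: float | None = None) -> float:
    """Per-trial average breathing rate: 60 / mean(IBrI), in BrPM."""
    ibri = compute_ibri(events)
    return 60.0 / float(np.mean(ibri))


def analyze_respiration(record: SignalRecord, modality: str,
                        component: str = "real",
                        beats: EventSeries | None = None,
                        resample_hz: float = RESAMPLE_HZ) -> BreathReport:
    """Run one extraction modality end to end on a record.

    ``direct`` uses the LF band of a thoracic channel; ``BB``/``AM``/``FM``
    use the arterial modulations (AM and FM require a beat series — one is
    detected from the HF band if not supplied).
    """
    modality_u = "direct" if modality.lower() == "direct" else modality.upper()
    channel = "bioz_real" if component == "real" else "bioz_imag"
    if modality_u == "direct":
        mod = extract_direct(record, component, resample_hz)
    elif modality_u == "BB":
        mod = extract_bb(record.channel(channel), record.fs, resample_hz)
    elif modality_u in ("AM", "FM"):
        from .cardiac import detect_bioz_beats
        from .preprocessing import HF_SPEC
        hf = bandpass(record.channel(channel), record.fs, HF_SPEC)
        if beats is None:
            beats = detect_bioz_beats(hf, record.fs)
        if modality_u == "AM":
            mod = extract_am(hf, record.fs, beats, resample_hz)
        else:
            mod = extract_fm(beats, resample_hz, duration=record.duration)
    else:
        raise ValueError(f"unknown modality {modality!r}")
    events = detect_breaths(mod)
    ibri = compute_ibri(events)
    return BreathReport(events=events, ibri=ibri,
                        rate_brpm=60.0 / float(np.mean(ibri)),
                        modality=modality_u, component=component)
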