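"""Synthetic multi-site bioimpedance generator with ground truth.

Emulates the signal structure a wearable bioimpedance front end produces
after quadrature demodulation of a 10 kHz carrier: site-specific
quasi-periodic arterial pulse trains riding on a respiratory baseline,
respiration-dominated thoracic channels, a finger-PPG beat reference and a
respiration-effort belt reference.  Every record carries the event times it
was rendered from, so downstream beat/breath estimators can be scored
against exact ground truth.

Conventions
-----------
* Blood arrival *decreases* impedance, so arterial pulses are negative-going
  troughs on a zero baseline; detectors downstream target minima.
* One respiration phase signal drives baseline wander (BB), pulse-amplitude
  modulation (AM) and respiratory sinus arrhythmia (FM) — cardiopulmonary
  coupling is modelled as a single driver.
* All stochastic draws are fixed by ``SimulationConfig.seed``.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

ARTERIAL_SITES = ("radial", "ulnar", "tibial", "carotid")
THORACIC_SITES = ("ribcage", "fascia")

#: Minimum physiologically admissible inter-beat interval (seconds).
MIN_IBI_S = 0.3


@dataclass(frozen=True)
class EventSeries:
    """Ordered event times (beats or breaths) with derived intervals."""

    times: np.ndarray
    kind: str = "beat"  # {"beat", "breath"}
    source: str = ""
    #: optional per-cycle maximum-negative-slope times (beats only)
    slope_times: np.ndarray | None = None

    def __post_init__(self):
        times = np.asarray(self.times, dtype=float)
        object.__setattr__(self, "times", times)
        if times.ndim != 1:
            raise ValueError("event times must be a 1-D array")
        if times.size > 1 and not np.all(np.diff(times) > 0):
            raise ValueError("event times must be strictly increasing")
        if self.kind not in ("beat", "breath"):
            raise ValueError(f"unknown event kind {self.kind!r}")

    @property
    def intervals(self) -> np.ndarray:
        """Successive differences of the event times, in seconds."""
        return np.diff(self.times)

    def __len__(self) -> int:
        return int(self.times.size)


@dataclass(frozen=True)
class CardiacParams:
    """Heart-rhythm parameters: mean rate, white HRV, and RSA coupling."""

    mean_ibi: float = 0.9          # s
    ibi_jitter_sd: float = 0.02    # s, white HRV component
    rsa_depth: float = 0.05        # s, peak IBI deviation at respiration phase
    ppg_delay: float = 0.05        # s, PPG transit delay vs bioimpedance pulse

    def __post_init__(self):
        if not np.isfinite([self.mean_ibi, self.ibi_jitter_sd,
                            self.rsa_depth, self.ppg_delay]).all():
            raise ValueError("cardiac parameters must be finite")
        if self.mean_ibi <= 0:
            raise ValueError("mean_ibi must be positive")
        if self.ibi_jitter_sd < 0:
            raise ValueError("ibi_jitter_sd must be non-negative")
        if self.rsa_depth >= self.mean_ibi / 2:
            raise ValueError("rsa_depth must be below mean_ibi/2")


@dataclass(frozen=True)
class RespiratoryParams:
    """Breathing rate and the strength of its three modulation routes."""

    rate_brpm: float = 14.0        # breaths per minute
    bb_amplitude: float = 30.0     # mΩ baseline-wander depth (half peak-to-peak)
    am_depth: float = 0.10         # fraction of pulse amplitude
    waveform: str = "sinusoid"     # {"sinusoid", "raised-cosine"}

    def __post_init__(self):
        f = self.rate_brpm / 60.0
        if not (0.045 < f < 0.5):
            raise ValueError(
                "rate_brpm/60 must lie in (0.045, 0.5) Hz so respiration "
                "falls inside the LF/BB analysis bands")
        if not (0 <= self.am_depth < 1):
            raise ValueError("am_depth must be in [0, 1)")
        if self.bb_amplitude < 0:
            raise ValueError("bb_amplitude must be non-negative")
        if self.waveform not in ("sinusoid", "raised-cosine"):
            raise ValueError(f"unknown respiration waveform {self.waveform!r}")

    @property
    def freq_hz(self) -> float:
        return self.rate_brpm / 60.0


@dataclass(frozen=True)
class SiteMorphology:
    """Per-site pulse morphology: double-trough depths, delay, amplitudes."""

    site: str
    pp_real: float                 # mΩ peak-to-peak, real part
    pp_imag: float                 # mΩ peak-to-peak, imaginary part
    trough1_frac: float = 1.0      # relative depth of arrival trough
    trough2_frac: float = 0.6      # relative depth of reflection trough
    reflection_delay: float = 0.18  # s between arrival and reflection troughs
    trough_width: float = 0.05     # s, Gaussian lobe sigma of each trough
    has_cardiac_hf: bool = True

    def __post_init__(self):
        known = ARTERIAL_SITES + THORACIC_SITES
        if self.site not in known:
            raise ValueError(f"unknown site {self.site!r}; expected one of {known}")
        if self.site in THORACIC_SITES and self.has_cardiac_hf:
            raise ValueError("thoracic sites carry no cardiac HF content")
        if self.has_cardiac_hf:
            if not (self.pp_real > self.pp_imag > 0):
                raise ValueError("arterial sites require pp_real > pp_imag > 0")
            if self.site == "carotid":
                if not self.trough2_frac > self.trough1_frac:
                    raise ValueError(
                        "carotid morphology has the second trough deeper")
            elif not self.trough1_frac >= self.trough2_frac:
                raise ValueError(
                    "limb-artery morphology has the first trough deepest")

    @property
    def is_thoracic(self) -> bool:
        return self.site in THORACIC_SITES


def site_morphology(site: str) -> SiteMorphology:
    """Default morphology for a named sensing site.

    Arterial peak-to-peak amplitudes follow the per-site ensemble
    measurements (radial/ulnar 100/20, tibial 60/15, carotid 250/40 mΩ for
    real/imaginary); the carotid reflection trough is the deeper one due to
    late systolic carotid flow.  Thoracic amplitudes parameterise the
    respiration-dominated LF excursion instead of a pulse.
    """
    defaults = {
        "radial": SiteMorphology("radial", 100.0, 20.0, 1.0, 0.6, 0.18),
        "ulnar": SiteMorphology("ulnar", 100.0, 20.0, 1.0, 0.6, 0.18),
        "tibial": SiteMorphology("tibial", 60.0, 15.0, 1.0, 0.35, 0.22),
        "carotid": SiteMorphology("carotid", 250.0, 40.0, 0.6, 1.0, 0.15,
                                  trough_width=0.04),
        "ribcage": SiteMorphology("ribcage", 200.0, 50.0,
                                  has_cardiac_hf=False),
        "fascia": SiteMorphology("fascia", 200.0, 50.0,
                                 has_cardiac_hf=False),
    }
    try:
        return defaults[site]
    except KeyError:
        raise ValueError(f"unknown site {site!r}") from None


@dataclass(frozen=True)
class SimulationConfig:
    """Full description of one synthetic recording."""

    duration: float = 300.0        # s
    fs: float = 250.0              # Hz, demodulated sampling rate
    noise_sd: float = 2.0          # mΩ additive Gaussian noise
    seed: int = 0
    cardiac: CardiacParams = field(default_factory=CardiacParams)
    respiratory: RespiratoryParams = field(default_factory=RespiratoryParams)
    morphology: SiteMorphology = field(
        default_factory=lambda: site_morphology("radial"))

    def __post_init__(self):
        if self.fs <= 12:
            raise ValueError("fs must exceed 12 Hz (Nyquist above the 6 Hz "
                             "cardiac band edge)")
        min_dur = 3.0 / self.respiratory.freq_hz
        if self.duration < min_dur:
            raise ValueError(
                f"duration must cover >= 3 respiration periods ({min_dur:.1f} s)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


@dataclass(frozen=True)
class SignalRecord:
    """A multi-channel demodulated recording plus optional ground truth."""

    t: np.ndarray                  # s, uniform grid
    bioz_real: np.ndarray          # mΩ
    bioz_imag: np.ndarray          # mΩ
    ppg: np.ndarray | None        # a.u.
    belt: np.ndarray | None       # a.u.
    fs: float
    site: str
    truth_beats: EventSeries | None = None
    truth_breaths: EventSeries | None = None
    config: SimulationConfig | None = None

    def __post_init__(self):
        n = self.t.size
        for name in ("bioz_real", "bioz_imag", "ppg", "belt"):
            ch = getattr(self, name)
            if ch is not None and ch.size != n:
                raise ValueError(f"channel {name} length {ch.size} != {n}")
        dt = np.diff(self.t)
        if n > 1 and not np.allclose(dt, 1.0 / self.fs, atol=1e-6):
            raise ValueError("time grid is not uniform at 1/fs")
        for ev in (self.truth_beats, self.truth_breaths):
            if ev is not None and len(ev) and (
                    ev.times[0] < self.t[0] - 1e-9
                    or ev.times[-1] > self.t[-1] + 1e-9):
                raise ValueError("truth event times fall outside the record")

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0]) if self.t.size else 0.0

    def channel(self, name: str) -> np.ndarray:
        """Return a channel array by label (bioz_real, bioz_imag, ppg, belt)."""
        try:
            ch = getattr(self, name)
        except AttributeError:
            raise KeyError(f"no channel {name!r}") from None
        if ch is None:
            raise KeyError(f"channel {name!r} absent from record")
        return ch


# ---------------------------------------------------------------------------
# respiration phase


def _respiration_waveform(phase: np.ndarray, kind: str) -> np.ndarray:
    """Unit-amplitude respiration waveform as a function of phase (radians).

    Both variants peak (end-inspiration) at phase = pi/2 + 2*pi*k so that
    breath ground truth is waveform-independent.
    """
    if kind == "sinusoid":
        return np.sin(phase)
    # raised-cosine: sharper inspiratory peak, same peak locations,
    # zero mean, unit peak
    return 2.0 * ((0.5 - 0.5 * np.cos(phase - np.pi / 2)) ** 2) - 0.5


def breath_truth_times(resp: RespiratoryParams, duration: float) -> EventSeries:
    """Exact end-inspiration (waveform-peak) times within [0, duration]."""
    f = resp.freq_hz
    first = 0.25 / f
    times = np.arange(first, duration, 1.0 / f)
    return EventSeries(times=times, kind="breath", source="truth")


# ---------------------------------------------------------------------------
# beat times


def generate_beat_times(cardiac: CardiacParams, respiratory: RespiratoryParams,
                        duration: float, seed: int) -> EventSeries:
    """Draw heartbeat times with white HRV and respiration-coupled RSA.

    Successive intervals follow ``mean_ibi + rsa_depth * sin(respiration
    phase at the beat) + N(0, ibi_jitter_sd)``.  Jitter draws that would push
    an interval to or below 0.3 s are redrawn (not clipped) to keep the IBI
    distribution smooth.  Deterministic for a given seed.
    """
    if duration <= cardiac.mean_ibi:
        raise ValueError("duration must exceed one mean IBI")
    det_min = cardiac.mean_ibi - cardiac.rsa_depth
    if det_min <= 0:
        raise ValueError("deterministic IBI component can reach zero; "
                         "reduce rsa_depth or raise mean_ibi")
    rng = np.random.default_rng(seed)
    f_resp = respiratory.freq_hz
    times = [0.0]
    t = 0.0
    while True:
        base = cardiac.mean_ibi + cardiac.rsa_depth * math.sin(
            2.0 * math.pi * f_resp * t)
        ibi = base
        if cardiac.ibi_jitter_sd > 0:
            for _ in range(1000):
                ibi = base + rng.normal(0.0, cardiac.ibi_jitter_sd)
                if ibi > MIN_IBI_S:
                    break
            else:  # pragma: no cover - pathological parameter sets
                raise RuntimeError("could not draw an admissible IBI")
        elif ibi <= MIN_IBI_S:
            raise ValueError("deterministic IBI falls below 0.3 s")
        t += ibi
        if t >= duration:
            break
        times.append(t)
    return EventSeries(times=np.asarray(times), kind="beat", source="truth")


# ---------------------------------------------------------------------------
# pulse template


def pulse_template(morph: SiteMorphology, ibi: float, fs: float) -> np.ndarray:
    """One-cycle arterial pulse: two negative Gaussian troughs on baseline 0.

    The first lobe is the arrival (systolic inflow) trough; the second, at
    ``reflection_delay`` after it, is the distal reflection.  The waveform is
    scaled so its peak-to-peak excursion equals ``pp_real`` (within 1%),
    starts and ends at baseline, and is smooth everywhere — which keeps
    max-negative-slope ground truth well defined.
    """
    if morph.is_thoracic:
        raise ValueError(f"site {morph.site!r} has no arterial pulse template")
    if ibi <= 0:
        raise ValueError("ibi must be positive")
    n = int(round(ibi * fs))
    t = np.arange(n) / fs
    shape = _pulse_shape(morph, t, ibi)
    pp = shape.max() - shape.min()
    if pp <= 0:
        return np.zeros(n)
    return shape * (morph.pp_real / pp)


def _pulse_shape(morph: SiteMorphology, t: np.ndarray,
                 ibi: float) -> np.ndarray:
    """Unit-scale double-Gaussian trough shape evaluated at times ``t``."""
    width = morph.trough_width
    t1 = 0.22 * ibi
    t2 = t1 + morph.reflection_delay
    shape = -morph.trough1_frac * np.exp(-0.5 * ((t - t1) / width) ** 2)
    if morph.trough2_frac > 0:
        shape = shape - morph.trough2_frac * np.exp(
            -0.5 * ((t - t2) / width) ** 2)
    return shape


def pulse_trough_offsets(morph: SiteMorphology, ibi: float) -> tuple[float, float]:
    """Times of the arrival and reflection troughs relative to cycle start."""
    t1 = 0.22 * ibi
    return t1, t1 + morph.reflection_delay


# ---------------------------------------------------------------------------
# full record synthesis


def _render_pulse_train(t: np.ndarray, beats: EventSeries,
                        morph: SiteMorphology, fs: float,
                        am_depth: float, resp_freq: float,
                        pp_scale: float) -> np.ndarray:
    """Place one pulse per truth beat, AM-scaled by the respiration phase.

    Each pulse is positioned so its *arrival trough* sits exactly at the
    truth beat time (evaluated on the continuous shape, so sub-sample beat
    times render faithfully).
    """
    out = np.zeros_like(t)
    times = beats.times
    n_beats = len(times)
    # Gaussian support on each side of a trough
    pulse_halfspan = 4.0 * morph.trough_width
    for k, tb in enumerate(times):
        ibi = (times[k + 1] - tb) if k + 1 < n_beats else (
            times[k] - times[k - 1] if n_beats > 1 else 0.9)
        t1, t2 = pulse_trough_offsets(morph, ibi)
        start = tb - t1
        stop = start + max(ibi, t2 + pulse_halfspan)
        i0 = max(0, int(np.ceil((start - pulse_halfspan) * fs)))
        i1 = min(t.size, int(np.floor(stop * fs)) + 1)
        if i0 >= i1:
            continue
        local = t[i0:i1] - start
        shape = _pulse_shape(morph, local, ibi)
        ref = _pulse_shape(morph, np.linspace(0, max(ibi, t2 + pulse_halfspan),
                                              512), ibi)
        pp = ref.max() - ref.min()
        scale = pp_scale / pp if pp > 0 else 0.0
        am = 1.0 + am_depth * math.sin(2.0 * math.pi * resp_freq * tb)
        out[i0:i1] += shape * scale * am
    return out


def _render_ppg(t: np.ndarray, beats: EventSeries, delay: float,
                mean_ibi: float) -> np.ndarray:
    """Positive raised-cosine pulse train whose feet sit at beat + delay.

    Each cycle spans foot-to-foot, so the waveform is continuous with a
    smooth minimum (the pulse foot) exactly at every delayed beat time.
    """
    feet = beats.times + delay
    out = np.zeros_like(t)
    for k in range(len(feet)):
        t0 = feet[k]
        t1 = feet[k + 1] if k + 1 < len(feet) else t0 + mean_ibi
        span = t1 - t0
        sel = (t >= t0) & (t < t1)
        tau = (t[sel] - t0) / span
        # asymmetric raised cosine: fast systolic upstroke peaking at 35%
        # of the cycle, slower diastolic decay.  The decay exponent makes
        # the valley curvature equal on both sides of the foot, so the
        # minimum is smooth, symmetric and exactly at the foot.
        rise = tau < 0.35
        u = np.clip((tau - 0.35) / 0.65, 0.0, 1.0)
        out[sel] = np.where(
            rise,
            0.5 * (1.0 - np.cos(np.pi * tau / 0.35)),
            0.5 * (1.0 + np.cos(np.pi * u ** (0.65 / 0.35))))
    return out


def _hf_band_gain(morph: SiteMorphology, mean_ibi: float, fs: float) -> float:
    """Peak-to-peak gain of the cardiac analysis band on this pulse shape.

    The printed per-site amplitudes describe the *HF-band* ensemble
    excursion, so the generator calibrates the rendered pulse scale against
    the attenuation its own template suffers in the 0.5–6 Hz band (measured
    on a periodic tiling, zero-phase 6th-order Butterworth, centre cycle).
    """
    tmpl = pulse_template(morph, mean_ibi, fs)
    tiled = np.tile(tmpl, 9)
    sos = sps.butter(6, [0.5, 6.0], btype="bandpass", fs=fs, output="sos")
    filt = sps.sosfiltfilt(sos, tiled)
    mid = filt[4 * tmpl.size:5 * tmpl.size]
    pp_f = mid.max() - mid.min()
    pp_0 = tmpl.max() - tmpl.min()
    return pp_f / pp_0 if pp_0 > 0 else 1.0


def synthesize_record(cfg: SimulationConfig) -> SignalRecord:
    """Render a full synthetic recording from a configuration.

    Arterial sites: ``bioz = respiration baseline + AM-scaled pulse train +
    Gaussian noise``; the imaginary channel repeats the construction scaled
    to ``pp_imag`` with independent noise.  Thoracic sites carry the
    respiration waveform only.  The PPG is a positive pulse train delayed by
    ``ppg_delay``; the belt is the noiseless respiration waveform.  Ground
    truth beat and breath series are attached.
    """
    morph = cfg.morphology
    resp = cfg.respiratory
    card = cfg.cardiac
    n = int(round(cfg.duration * cfg.fs))
    t = np.arange(n) / cfg.fs
    rng = np.random.default_rng(cfg.seed)

    phase = 2.0 * np.pi * resp.freq_hz * t
    resp_wave = _respiration_waveform(phase, resp.waveform)
    truth_breaths = breath_truth_times(resp, t[-1] if n else 0.0)
    truth_beats = generate_beat_times(card, resp, cfg.duration,
                                      seed=cfg.seed + 1)
    # keep only beats inside the rendered grid
    truth_beats = EventSeries(
        times=truth_beats.times[truth_beats.times <= t[-1]],
        kind="beat", source="truth")

    if morph.is_thoracic:
        real = morph.pp_real * resp_wave
        imag = morph.pp_imag * resp_wave
    else:
        baseline = resp.bb_amplitude * resp_wave
        # configured site amplitudes describe the HF-band ensemble
        # excursion; pre-compensate the band attenuation of this pulse shape
        gain = _hf_band_gain(morph, card.mean_ibi, cfg.fs)
        train = _render_pulse_train(t, truth_beats, morph, cfg.fs,
                                    resp.am_depth, resp.freq_hz,
                                    pp_scale=morph.pp_real / gain)
        imag_train = train * (morph.pp_imag / morph.pp_real)
        real = baseline + train
        imag = baseline * (morph.pp_imag / morph.pp_real) + imag_train
    if cfg.noise_sd > 0:
        real = real + rng.normal(0.0, cfg.noise_sd, n)
        imag = imag + rng.normal(0.0, cfg.noise_sd, n)

    ppg = _render_ppg(t, truth_beats, card.ppg_delay, card.mean_ibi)
    if cfg.noise_sd > 0:
        ppg = ppg + rng.normal(0.0, 0.01, n)  # PPG is a.u.; light sensor noise
    belt = resp_wave.copy()

    return SignalRecord(t=t, bioz_real=real, bioz_imag=imag, ppg=ppg,
                        belt=belt, fs=cfg.fs, site=morph.site,
                        truth_beats=truth_beats, truth_breaths=truth_breaths,
                        config=cfg)


# ---------------------------------------------------------------------------
# carrier model


def modulate_carrier(real: np.ndarray, imag: np.ndarray, carrier_freq: float,
                     fs_raw: float) -> np.ndarray:
    """Impress a complex baseband impedance onto an AC carrier.

    Models the sensed voltage under a 10 kHz current stimulation:
    ``v(t) = Re(t)·cos(2π f_c t) − Im(t)·sin(2π f_c t)``.
    """
    n = real.size
    t = np.arange(n) / fs_raw
    w = 2.0 * np.pi * carrier_freq * t
    return real * np.cos(w) - imag * np.sin(w)


def quadrature_demodulate(raw: np.ndarray, carrier_freq: float,
                          fs_raw: float) -> np.ndarray:
    """Recover the complex baseband impedance from a carrier-level voltage.

    Mixes with in-phase (cos) and quadrature (−sin) references, low-pass
    filters below half the carrier frequency, and applies the ×2 mixer gain
    correction, so a tone ``A·cos(2π f_c t)`` demodulates to ``A + 0j`` and
    ``A·sin(2π f_c t)`` to ``0 − Aj``.
    """
    if fs_raw <= 2.0 * carrier_freq:
        raise ValueError("fs_raw must exceed twice the carrier frequency "
                         "(aliasing)")
    n = raw.size
    t = np.arange(n) / fs_raw
    w = 2.0 * np.pi * carrier_freq * t
    i_mix = raw * (2.0 * np.cos(w))
    q_mix = raw * (-2.0 * np.sin(w))
    cutoff = carrier_freq / 4.0
    sos = sps.butter(4, cutoff, btype="low", fs=fs_raw, output="sos")
    i_bb = sps.sosfiltfilt(sos, i_mix)
    q_bb = sps.sosfiltfilt(sos, q_mix)
    return i_bb + 1j * q_bb


def config_to_dict(cfg: SimulationConfig) -> dict:
    """Serialise a configuration to plain JSON-compatible types."""
    d = dataclasses.asdict(cfg)
    return d


def config_from_dict(d: dict) -> SimulationConfig:
    """Rebuild a SimulationConfig from :func:`config_to_dict` output."""
    d = dict(d)
    card = CardiacParams(**d.pop("cardiac"))
    resp = RespiratoryParams(**d.pop("respiratory"))
    morph = SiteMorphology(**d.pop("morphology"))
    return SimulationConfig(cardiac=card, respiratory=resp, morphology=morph,
                            **d)
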