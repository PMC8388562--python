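"""Band decomposition of demodulated bioimpedance channels.

Three fixed analysis bands separate cardiac from respiratory content:

* **HF** (0.5–6 Hz): the cardiac pulse band,
* **LF** (0.045–0.5 Hz): the respiratory band used for direct thoracic
  respiration,
* **BB** (0.05–0.5 Hz): the baseline-baseband respiratory-modulation band.

LF and BB differ only in the low edge (0.045 vs 0.05 Hz) and are kept as two
distinct specs rather than unified.  All filters are 6th-order Butterworth
band-passes applied forward-backward (zero phase) as second-order sections;
zero-phase application preserves event timing, which the beat-interval
estimators depend on, and second-order sections keep the design stable at
the very low 0.045 Hz edge.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import signal as sps

from .simulate import SignalRecord

#: seconds at each end of a filtered series considered unreliable
EDGE_GUARD_S = 2.0


@dataclass(frozen=True)
class BandSpec:
    """A named band-pass: corner frequencies in Hz and Butterworth order."""

    name: str            # {"HF", "LF", "BB"}
    low_hz: float
    high_hz: float
    order: int = 6

    def __post_init__(self):
        if not (0 < self.low_hz < self.high_hz):
            raise ValueError("need 0 < low_hz < high_hz")
        if self.order < 1:
            raise ValueError("order must be positive")

    def sos(self, fs: float) -> np.ndarray:
        if self.high_hz >= fs / 2:
            raise ValueError(
                f"{self.name} high edge {self.high_hz} Hz >= Nyquist ({fs/2})")
        return sps.butter(self.order, [self.low_hz, self.high_hz],
                          btype="bandpass", fs=fs, output="sos")

    def response_at(self, freq_hz: float, fs: float,
                    zero_phase: bool = True) -> float:
        """Magnitude response at one frequency (squared if zero-phase)."""
        w, h = sps.sosfreqz(self.sos(fs), worN=[freq_hz], fs=fs)
        mag = float(np.abs(h[0]))
        return mag ** 2 if zero_phase else mag


HF_SPEC = BandSpec("HF", 0.5, 6.0)
LF_SPEC = BandSpec("LF", 0.045, 0.5)
BB_SPEC = BandSpec("BB", 0.05, 0.5)


@dataclass(frozen=True)
class BandSignals:
    """The HF/LF/BB decompositions of one channel."""

    source: str
    hf: np.ndarray
    lf: np.ndarray
    bb: np.ndarray
    fs: float
    specs: tuple[BandSpec, BandSpec, BandSpec] = (HF_SPEC, LF_SPEC, BB_SPEC)


def bandpass(x: np.ndarray, fs: float, spec: BandSpec,
             zero_phase: bool = True) -> np.ndarray:
    """Apply a Butterworth band-pass; forward-backward by default.

    Reflect-padding of one filter startup length handles the edges; the
    output has the same length as the input.  With ``zero_phase=False`` a
    causal single pass is used instead (available for comparison; event
    timing then carries the filter's group delay).
    """
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("input contains non-finite samples")
    sos = spec.sos(fs)
    # startup length: impulse-response scale of the slowest pole
    padlen = min(x.size - 1, max(3 * (2 * sos.shape[0] + 1),
                                 int(np.ceil(fs / spec.low_hz))))
    if x.size <= 3 * (2 * sos.shape[0] + 1):
        raise ValueError("input too short for the filter startup length")
    if zero_phase:
        # even reflection keeps the signal level at the edges; odd
        # reflection doubles edge excursions and rings for tens of seconds
        # at the 0.045-0.05 Hz low edges
        return sps.sosfiltfilt(sos, x, padlen=padlen, padtype="even")
    zi = sps.sosfilt_zi(sos) * x[0]
    y, _ = sps.sosfilt(sos, x, zi=zi)
    return y


def decompose(record: SignalRecord, channel: str = "bioz_real",
              hf: BandSpec = HF_SPEC, lf: BandSpec = LF_SPEC,
              bb: BandSpec = BB_SPEC) -> BandSignals:
    """Split one channel of a record into its HF, LF and BB bands."""
    x = record.channel(channel)
    return BandSignals(source=channel,
                       hf=bandpass(x, record.fs, hf),
                       lf=bandpass(x, record.fs, lf),
                       bb=bandpass(x, record.fs, bb),
                       fs=record.fs, specs=(hf, lf, bb))


def edge_mask(n: int, fs: float, guard_s: float = EDGE_GUARD_S) -> np.ndarray:
    """Boolean mask that is False within ``guard_s`` of either end."""
    m = np.ones(n, dtype=bool)
    g = int(round(guard_s * fs))
    if g > 0:
        m[:g] = False
        m[-g:] = False
    return m
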