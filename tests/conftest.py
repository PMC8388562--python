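import numpy as np
import pytest

import biozkit as bz


@pytest.fixture(scope="session")
def radial_record():
    """Four minutes of radial bioimpedance at default (moderate) noise."""
    cfg = bz.SimulationConfig(duration=240.0, seed=11,
                              respiratory=bz.RespiratoryParams(rate_brpm=15))
    return bz.synthesize_record(cfg)


@pytest.fixture(scope="session")
def noiseless_radial_record():
    cfg = bz.SimulationConfig(duration=120.0, seed=13, noise_sd=0.0)
    return bz.synthesize_record(cfg)


@pytest.fixture(scope="session")
def carotid_record():
    cfg = bz.SimulationConfig(duration=240.0, seed=12,
                              morphology=bz.site_morphology("carotid"))
    return bz.synthesize_record(cfg)


@pytest.fixture(scope="session")
def thoracic_record():
    """Four minutes of side-rib-cage record, noise at 10% of the LF swing."""
    cfg = bz.SimulationConfig(
        duration=240.0, seed=14, noise_sd=20.0,
        morphology=bz.site_morphology("ribcage"),
        respiratory=bz.RespiratoryParams(rate_brpm=15, bb_amplitude=200.0))
    return bz.synthesize_record(cfg)


@pytest.fixture(scope="session")
def radial_hf(radial_record):
    return bz.bandpass(radial_record.bioz_real, radial_record.fs, bz.HF_SPEC)


@pytest.fixture(scope="session")
def radial_beats(radial_record, radial_hf):
    return bz.detect_bioz_beats(radial_hf, radial_record.fs)


def dominant_frequency(x, fs):
    """FFT-peak frequency of a (mean-removed, Hann-windowed) series."""
    x = np.asarray(x, dtype=float)
    x = (x - x.mean()) * np.hanning(x.size)
    spec = np.abs(np.fft.rfft(x))
    freqs = np.fft.rfftfreq(x.size, 1.0 / fs)
    return freqs[np.argmax(spec[1:]) + 1]
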