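"""Reading and writing recordings: CSV channel data + JSON sidecar.

A recording is stored as ``<name>.csv`` with the fixed header
``time_s,bioz_real_mohm,bioz_imag_mohm,ppg_au,belt_au`` (optional trailing
channels may be absent, but the order is fixed) and a ``<name>.json``
sidecar holding the sampling rate, site label, the full simulation
configuration when the record is synthetic, and any ground-truth beat and
breath time arrays.  Values are written at 9 significant digits, so a
write→read round trip is lossless at that precision.  The time column is
stored explicitly rather than implied by ``fs`` to make truncated or
concatenated files detectable.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import simulate
from .simulate import EventSeries, SignalRecord, SimulationConfig

CSV_COLUMNS = ("time_s", "bioz_real_mohm", "bioz_imag_mohm", "ppg_au",
               "belt_au")
#: tolerated deviation from a uniform time grid, seconds
GRID_TOL_S = 1e-6


def write_record(record: SignalRecord, stem: str | Path) -> tuple[Path, Path]:
    """Write ``<stem>.csv`` and ``<stem>.json``; returns both paths."""
    stem = Path(stem)
    csv_path = stem.with_suffix(".csv")
    json_path = stem.with_suffix(".json")

    cols = {"time_s": record.t,
            "bioz_real_mohm": record.bioz_real,
            "bioz_imag_mohm": record.bioz_imag}
    if record.ppg is not None:
        cols["ppg_au"] = record.ppg
    if record.belt is not None:
        cols["belt_au"] = record.belt
    pd.DataFrame(cols).to_csv(csv_path, index=False, float_format="%.9g")

    sidecar = {"fs": record.fs, "site": record.site,
               "n_samples": int(record.t.size)}
    if record.config is not None:
        sidecar["config"] = simulate.config_to_dict(record.config)
    if record.truth_beats is not None:
        sidecar["truth_beats"] = record.truth_beats.times.tolist()
    if record.truth_breaths is not None:
        sidecar["truth_breaths"] = record.truth_breaths.times.tolist()
    json_path.write_text(json.dumps(sidecar, indent=1))
    return csv_path, json_path


def read_record(path: str | Path) -> SignalRecord:
    """Reconstruct a :class:`SignalRecord` from a CSV + JSON sidecar pair.

    ``path`` may point at either file or the common stem.  Raises
    descriptive errors on a malformed header, a non-uniform time grid, or a
    sampling-rate mismatch between the sidecar and the time column.
    """
    stem = Path(path)
    if stem.suffix in (".csv", ".json"):
        stem = stem.with_suffix("")
    csv_path, json_path = stem.with_suffix(".csv"), stem.with_suffix(".json")
    if not csv_path.exists() or not json_path.exists():
        raise FileNotFoundError(
            f"need both {csv_path.name} and {json_path.name}")

    sidecar = json.loads(json_path.read_text())
    df = pd.read_csv(csv_path)
    expected = [c for c in CSV_COLUMNS]
    got = list(df.columns)
    if got != expected[:len(got)]:
        raise ValueError(
            f"malformed CSV header {got}; expected a prefix of {expected}")
    if "time_s" not in df or len(df) < 2:
        raise ValueError("CSV must contain a time_s column with >= 2 rows")

    t = df["time_s"].to_numpy(dtype=float)
    dt = np.diff(t)
    if np.any(np.abs(dt - dt[0]) > GRID_TOL_S):
        raise ValueError("non-uniform time grid (tolerance 1e-6 s)")
    fs = float(sidecar["fs"])
    if abs(dt[0] - 1.0 / fs) > GRID_TOL_S:
        raise ValueError(
            f"sampling-rate mismatch: sidecar fs={fs} but time step {dt[0]}")
    if "n_samples" in sidecar and int(sidecar["n_samples"]) != len(df):
        raise ValueError("sidecar n_samples disagrees with CSV length")

    def _arr(name):
        return df[name].to_numpy(dtype=float) if name in df else None

    cfg = None
    if "config" in sidecar:
        cfg = simulate.config_from_dict(sidecar["config"])

    def _events(key, kind):
        if key not in sidecar:
            return None
        return EventSeries(times=np.asarray(sidecar[key], dtype=float),
                           kind=kind, source="truth")

    return SignalRecord(
        t=t, bioz_real=_arr("bioz_real_mohm"), bioz_imag=_arr("bioz_imag_mohm"),
        ppg=_arr("ppg_au"), belt=_arr("belt_au"), fs=fs,
        site=sidecar.get("site", "radial"),
        truth_beats=_events("truth_beats", "beat"),
        truth_breaths=_events("truth_breaths", "breath"),
        config=cfg)
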