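"""Event matching and agreement statistics (ME, RMSE, MAE, Bland–Altman, r).

Estimated beat or breath series are first paired with reference events by
greedy nearest-neighbour matching within a tolerance; interval pairs are
then formed only where *both* sides of the interval were matched, so a
missed or spurious event never contaminates its neighbours' intervals.
Agreement between the paired interval series is summarised with the mean
error, RMSE, MAE, Bland–Altman bias with 95% limits of agreement
(bias ± 1.96·SD of the differences, n−1 denominator), and Pearson's r.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .simulate import EventSeries, SignalRecord

#: default matching tolerances: half the minimum physiological interval
BEAT_TOLERANCE_S = 0.25
BREATH_TOLERANCE_S = 1.0


@dataclass(frozen=True)
class MatchedIntervals:
    """Paired estimated/reference intervals from tolerance-matched events."""

    est: np.ndarray            # s
    ref: np.ndarray            # s
    n_matched: int             # matched event pairs
    n_unmatched_est: int
    n_unmatched_ref: int
    tolerance: float
    #: paired event times (est, ref) the intervals were derived from
    event_pairs: np.ndarray = field(default=None, repr=False)

    def __post_init__(self):
        if self.est.size != self.ref.size:
            raise ValueError("est/ref interval arrays must be paired")


@dataclass(frozen=True)
class AgreementReport:
    """The agreement summary for one matched interval series."""

    me: float                  # mean error, s
    rmse: float
    mae: float
    ba_bias: float
    ba_loa_low: float
    ba_loa_high: float
    pearson_r: float | None
    n: int

    def to_dict(self) -> dict:
        return {"me": self.me, "rmse": self.rmse, "mae": self.mae,
                "ba_bias": self.ba_bias, "ba_loa_low": self.ba_loa_low,
                "ba_loa_high": self.ba_loa_high,
                "pearson_r": self.pearson_r, "n": self.n}


def match_events(est: EventSeries, ref: EventSeries,
                 tolerance: float) -> MatchedIntervals:
    """Pair estimated with reference events and derive interval pairs.

    Greedy nearest-neighbour: candidate pairs within the tolerance are
    accepted in order of increasing time difference (ties broken toward the
    earlier reference event), each event used at most once.  Interval pairs
    are formed only between *consecutively matched* events on both sides.
    """
    te, tr = est.times, ref.times
    if te.size == 0 or tr.size == 0:
        raise ValueError("cannot match empty event series")
    pairs = []
    for i, t in enumerate(te):
        j0 = int(np.searchsorted(tr, t))
        for j in (j0 - 1, j0):
            if 0 <= j < tr.size and abs(t - tr[j]) <= tolerance:
                pairs.append((abs(t - tr[j]), tr[j], i, j))
    pairs.sort(key=lambda p: (p[0], p[1]))
    used_e, used_r = set(), set()
    matched = []
    for _, _, i, j in pairs:
        if i in used_e or j in used_r:
            continue
        used_e.add(i)
        used_r.add(j)
        matched.append((i, j))
    if not matched:
        raise ValueError("zero matches within tolerance")
    matched.sort()
    idx_e = np.array([m[0] for m in matched])
    idx_r = np.array([m[1] for m in matched])
    consec = (np.diff(idx_e) == 1) & (np.diff(idx_r) == 1)
    est_iv = np.diff(te[idx_e])[consec]
    ref_iv = np.diff(tr[idx_r])[consec]
    return MatchedIntervals(
        est=est_iv, ref=ref_iv, n_matched=len(matched),
        n_unmatched_est=te.size - len(matched),
        n_unmatched_ref=tr.size - len(matched),
        tolerance=tolerance,
        event_pairs=np.column_stack([te[idx_e], tr[idx_r]]))


def agreement(matched: MatchedIntervals) -> AgreementReport:
    """Compute ME/RMSE/MAE, Bland–Altman bias and LoA, and Pearson's r."""
    est, ref = matched.est, matched.ref
    if est.size < 3:
        raise ValueError("need at least 3 matched interval pairs")
    diff = est - ref
    me = float(np.mean(diff))
    rmse = float(np.sqrt(np.mean(diff ** 2)))
    mae = float(np.mean(np.abs(diff)))
    sd = float(np.std(diff, ddof=1))
    if np.std(est) == 0 or np.std(ref) == 0:
        warnings.warn("zero variance in an interval series; Pearson's r "
                      "undefined", stacklevel=2)
        r = None
    else:
        r = float(stats.pearsonr(est, ref).statistic)
    return AgreementReport(me=me, rmse=rmse, mae=mae, ba_bias=me,
                           ba_loa_low=me - 1.96 * sd,
                           ba_loa_high=me + 1.96 * sd,
                           pearson_r=r, n=int(est.size))


def evaluate_pipeline(record: SignalRecord,
                      beat_tolerance: float = BEAT_TOLERANCE_S,
                      breath_tolerance: float = BREATH_TOLERANCE_S) -> dict:
    """Run the full cardiac + respiration pipelines against the references.

    Arterial records are scored on IBI (HF-trough beats vs the record's
    ground-truth or PPG-derived beats) and on the three indirect respiration
    modalities vs belt-derived breaths; thoracic records are scored on
    direct-mode IBrI.  Returns one structured summary with an
    :class:`AgreementReport` per modality plus per-trial breathing-rate
    errors.
    """
    from .cardiac import detect_bioz_beats, detect_ppg_beats
    from .preprocessing import HF_SPEC, bandpass
    from .respiration import analyze_respiration, detect_breaths
    from .respiration import ModulationSeries

    if record.truth_beats is None and record.ppg is None:
        raise ValueError("no reference: record carries neither ground-truth "
                         "events nor a PPG channel")
    summary: dict = {"site": record.site, "cardiac": None, "respiration": {}}

    thoracic = record.site not in ("radial", "ulnar", "tibial", "carotid")

    # --- reference breath series
    ref_breaths = record.truth_breaths
    if ref_breaths is None and record.belt is not None:
        belt_mod = ModulationSeries(
            kind="direct", t=record.t, value=record.belt,
            resample_hz=record.fs)
        ref_breaths = detect_breaths(belt_mod)

    if not thoracic:
        ref_beats = record.truth_beats
        if ref_beats is None:
            ref_beats = detect_ppg_beats(record.ppg, record.fs)
        hf = bandpass(record.bioz_real, record.fs, HF_SPEC)
        beats = detect_bioz_beats(hf, record.fs)
        summary["cardiac"] = agreement(
            match_events(beats, ref_beats, beat_tolerance)).to_dict()
        modalities = ("BB", "AM", "FM")
    else:
        beats = None
        modalities = ("direct",)

    if ref_breaths is not None:
        true_rate = (record.config.respiratory.rate_brpm
                     if record.config is not None else None)
        for mode in modalities:
            rep = analyze_respiration(record, mode, beats=beats)
            entry = agreement(match_events(
                rep.events, ref_breaths, breath_tolerance)).to_dict()
            entry["rate_brpm"] = rep.rate_brpm
            if true_rate is not None:
                entry["rate_error_brpm"] = rep.rate_brpm - true_rate
            summary["respiration"][mode] = entry
    else:
        warnings.warn("record has no belt channel or breath truth; "
                      "respiration evaluation disabled", stacklevel=2)
    return summary
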