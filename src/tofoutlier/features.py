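"""Envelope combination, twitch detection and the 15 TOF features.

The raw 6-channel kinetic recording is collapsed to a single non-negative
envelope by root-mean-square combination of the (baseline-corrected)
acceleration and angular-velocity channels.  Four twitches are detected on
the envelope, and two feature families are computed per measurement:

basic (7)       T1..T4 twitch amplitudes, TOFR = T4/T1, and the mean and
                standard deviation of the whole-measurement envelope
                (AMG_Mean, AMG_StdDev);
engineered (8)  inter-twitch elapsed times deltaT2_T1, deltaT3_T2,
                deltaT4_T3, deltaT4_T1 and the twitch-to-mean ratios
                ratioT1..ratioT4 (Ti / AMG_Mean).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .errors import DegenerateInputError, ValidationError
from .synth import RawRecording

logger = logging.getLogger(__name__)

BASIC_FEATURES = ["T1", "T2", "T3", "T4", "TOFR", "AMG_StdDev", "AMG_Mean"]
ENGINEERED_FEATURES = [
    "deltaT2_T1",
    "deltaT3_T2",
    "deltaT4_T3",
    "deltaT4_T1",
    "ratioT1",
    "ratioT2",
    "ratioT3",
    "ratioT4",
]
ALL_FEATURES = BASIC_FEATURES + ENGINEERED_FEATURES
#: fixed column order of a written feature table
TABLE_COLUMNS = ALL_FEATURES + ["label", "measurement_id", "patient_id"]


@dataclass
class FeatureParams:
    """Tunable extraction parameters (times in samples)."""

    gyro_weight: float = 1.0
    min_separation: float = 5.0
    threshold_k: float = 1.0
    window_halfwidth: int = 3
    tofr_convention: str = "t4_over_t1"  # or "t1_over_t4"
    aggregate: str = "mean"  # or "sum": twitch amplitude aggregation

    def __post_init__(self) -> None:
        if self.tofr_convention not in ("t4_over_t1", "t1_over_t4"):
            raise ValidationError("tofr_convention must be t4_over_t1 or t1_over_t4")
        if self.aggregate not in ("mean", "sum"):
            raise ValidationError("aggregate must be mean or sum")
        if self.min_separation <= 0 or self.window_halfwidth <= 0:
            raise ValidationError("min_separation and window_halfwidth must be > 0")


@dataclass
class EnvelopeSignal:
    """Combined acceleration/angulation magnitude series."""

    t: np.ndarray
    v: np.ndarray
    measurement_id: str = ""

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.v = np.asarray(self.v, dtype=float)
        if len(self.t) != len(self.v):
            raise ValidationError("t and v must have equal length")


@dataclass
class Twitch:
    peak_time: float
    peak_index: int
    amplitude: float
    window: Tuple[int, int]  # half-open [start, end) sample indices


@dataclass
class TwitchSet:
    peaks: List[Twitch]  # exactly 4, ordered by time
    n_raw_peaks_detected: int
    detection_quality: str  # "complete" | "padded"


def combine_axes(rec: RawRecording, gyro_weight: float = 1.0) -> EnvelopeSignal:
    """RMS-combine the six channels into one envelope.

    Each channel is first baseline-corrected by subtracting its median
    (removing gravity and sensor offsets), then

        v[k] = sqrt((ax^2 + ay^2 + az^2 + w^2 (gx^2 + gy^2 + gz^2))[k] / 6).
    """
    if len(rec.t) == 0:
        raise ValidationError("empty recording")
    accel = rec.accel - np.median(rec.accel, axis=0)
    gyro = rec.gyro - np.median(rec.gyro, axis=0)
    ss = np.sum(accel**2, axis=1) + gyro_weight**2 * np.sum(gyro**2, axis=1)
    return EnvelopeSignal(
        t=rec.t, v=np.sqrt(ss / 6.0), measurement_id=rec.measurement_id
    )


def _window_for(
    peak: int, halfwidth: int, n: int, neighbors: Sequence[int]
) -> Tuple[int, int]:
    start = max(0, peak - halfwidth)
    end = min(n, peak + halfwidth)
    # trim at midpoints so windows of nearby twitches never overlap
    for other in neighbors:
        if other == peak:
            continue
        mid = (peak + other) // 2
        if other < peak:
            start = max(start, mid + 1)
        else:
            end = min(end, mid + 1)
    if end <= peak:
        end = peak + 1
    if start > peak:
        start = peak
    return start, end


def detect_twitches(
    env: EnvelopeSignal,
    min_separation: float = 5.0,
    threshold_k: float = 1.0,
    window_halfwidth: int = 3,
) -> TwitchSet:
    """Locate the four twitches on the envelope.

    Local maxima above mean(v) + threshold_k * SD(v), separated by at least
    ``min_separation`` samples, are candidate peaks; the four largest are
    kept and re-ordered by time.  If fewer than four qualify the threshold
    is relaxed stepwise to zero and, failing that, the set is padded with
    the largest remaining non-adjacent samples (``detection_quality`` is
    then ``"padded"``).
    """
    v = env.v
    n = len(v)
    if n < 4 * min_separation:
        raise DegenerateInputError(
            f"envelope of {n} samples is shorter than 4*min_separation"
        )
    mu, sd = float(np.mean(v)), float(np.std(v))
    distance = max(1, int(round(min_separation)))
    idx = np.array([], dtype=int)
    n_raw = 0
    # relax the threshold multiplier stepwise to zero (floor: the envelope
    # mean, which stays above the sensor-noise floor)
    for k in (threshold_k, threshold_k / 2.0, threshold_k / 4.0, 0.0):
        idx, _ = find_peaks(v, height=mu + k * sd, distance=distance)
        if k == threshold_k:
            n_raw = len(idx)
        if len(idx) >= 4:
            break
    quality = "complete"
    if len(idx) < 4:
        # padding: fill from the largest remaining non-adjacent samples that
        # are themselves local maxima (>= min_separation from every selected
        # peak); on a flat/noisy envelope these are the tallest noise bumps
        quality = "padded"
        chosen = list(idx)
        sub, _ = find_peaks(v, distance=distance)
        for cand in sub[np.argsort(-v[sub], kind="stable")]:
            if len(chosen) >= 4:
                break
            if all(abs(int(cand) - c) >= distance for c in chosen):
                chosen.append(int(cand))
        # last resort (e.g. noiseless two-burst signals): plain samples
        if len(chosen) < 4:
            for cand in np.argsort(-v, kind="stable"):
                if len(chosen) >= 4:
                    break
                if all(abs(int(cand) - c) > 1 for c in chosen):
                    chosen.append(int(cand))
        idx = np.array(sorted(chosen), dtype=int)
    if len(idx) < 4:  # pragma: no cover - requires pathological input
        raise DegenerateInputError("could not locate 4 distinct twitch candidates")

    top4 = idx[np.argsort(-v[idx], kind="stable")[:4]]
    top4 = np.sort(top4)
    peaks = []
    for p in top4:
        start, end = _window_for(int(p), window_halfwidth, n, top4)
        peaks.append(
            Twitch(
                peak_time=float(env.t[p]),
                peak_index=int(p),
                amplitude=float(v[p]),
                window=(start, end),
            )
        )
    return TwitchSet(peaks=peaks, n_raw_peaks_detected=n_raw, detection_quality=quality)


def twitch_amplitude(
    env: EnvelopeSignal, window: Tuple[int, int], aggregate: str = "mean"
) -> float:
    """Aggregate the envelope over a twitch window ([start, end), samples).

    The default is the arithmetic mean of the envelope points in the
    vicinity of the peak, making amplitudes comparable across window sizes;
    ``aggregate="sum"`` gives the raw summation instead.
    """
    start, end = window
    if end <= start:
        raise ValidationError("empty twitch window")
    if start < 0 or end > len(env.v):
        raise ValidationError("window outside signal bounds")
    seg = env.v[start:end]
    return float(np.sum(seg) if aggregate == "sum" else np.mean(seg))


def extract_features(
    rec: RawRecording, params: Optional[FeatureParams] = None
) -> dict:
    """Compute the 15 named features (plus bookkeeping) for one recording."""
    params = params or FeatureParams()
    env = combine_axes(rec, gyro_weight=params.gyro_weight)
    try:
        twitches = detect_twitches(
            env,
            min_separation=params.min_separation,
            threshold_k=params.threshold_k,
            window_halfwidth=params.window_halfwidth,
        )
    except DegenerateInputError as exc:
        raise DegenerateInputError(
            f"measurement {rec.measurement_id}: {exc}"
        ) from exc

    amps = [
        twitch_amplitude(env, tw.window, aggregate=params.aggregate)
        for tw in twitches.peaks
    ]
    times = [tw.peak_time for tw in twitches.peaks]
    t1, t2, t3, t4 = amps
    if params.tofr_convention == "t4_over_t1":
        num, den = t4, t1
    else:
        num, den = t1, t4
    if den == 0:
        logger.warning(
            "measurement %s: zero-amplitude TOFR denominator; TOFR set to 0",
            rec.measurement_id,
        )
        tofr = 0.0
    else:
        tofr = num / den
    amg_mean = float(np.mean(env.v))
    amg_sd = float(np.std(env.v))
    d21 = times[1] - times[0]
    d32 = times[2] - times[1]
    d43 = times[3] - times[2]
    feats = {
        "T1": t1,
        "T2": t2,
        "T3": t3,
        "T4": t4,
        "TOFR": tofr,
        "AMG_StdDev": amg_sd,
        "AMG_Mean": amg_mean,
        "deltaT2_T1": d21,
        "deltaT3_T2": d32,
        "deltaT4_T3": d43,
        "deltaT4_T1": d21 + d32 + d43,
        "ratioT1": t1 / amg_mean,
        "ratioT2": t2 / amg_mean,
        "ratioT3": t3 / amg_mean,
        "ratioT4": t4 / amg_mean,
        "label": rec.label,
        "measurement_id": rec.measurement_id,
        "patient_id": rec.patient_id,
        "detection_quality": twitches.detection_quality,
    }
    return feats


def build_feature_table(
    recordings: Sequence[RawRecording], params: Optional[FeatureParams] = None
) -> pd.DataFrame:
    """One row of features per measurement, in the documented column order."""
    if len(recordings) == 0:
        raise ValidationError("no recordings given")
    ids = [r.measurement_id for r in recordings]
    if len(set(ids)) != len(ids):
        raise ValidationError("duplicate measurement_id in recording set")
    rows = [extract_features(r, params) for r in recordings]
    df = pd.DataFrame(rows)
    return df[TABLE_COLUMNS + ["detection_quality"]]


def basic_features(table: pd.DataFrame) -> pd.DataFrame:
    """The 7 raw-signal features."""
    return table[BASIC_FEATURES]


def engineered_features(table: pd.DataFrame) -> pd.DataFrame:
    """The 8 TOF-pattern features."""
    return table[ENGINEERED_FEATURES]
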