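"""Synthetic acceleromyographic train-of-four (TOF) recordings.

A TOF measurement evokes four thumb twitches (T1..T4) whose amplitudes fade
under non-depolarizing neuromuscular block.  The generator emulates a cohort
of such measurements recorded by a combined accelerometer/gyroscope sensor:
each recording is a 6-channel kinetic time series (triaxial acceleration in
m/s^2 and triaxial angular velocity in rad/s) containing four raised-cosine
twitch bursts plus sensor noise.  A small fraction of recordings realize one
of seven anomaly morphologies seen in clinical practice (rebound bursts,
non-monotonic fade, equidistant oscillations, crescendo patterns, gross
oscillatory decrescendo, missing peaks, wide inter-twitch gaps).

Time is measured in samples, one sample per centisecond.  Amplitudes are
expressed on the combined-envelope scale (the root-mean-square combination
of all six channels), so generator amplitudes line up directly with the
extracted twitch features.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from .errors import ValidationError

ANOMALY_TYPES = (
    "REBOUND_BURST",
    "NON_MONOTONIC_T3",
    "EQUIDISTANT_OSCILLATION",
    "CRESCENDO",
    "DECRESCENDO_GROSS_OSC",
    "MISSING_PEAKS",
    "WIDE_GAP",
)

#: Published marginal statistics (mean, SD) of the 15 features on the
#: clinical cohort the generator emulates; used by :func:`calibration_report`.
REFERENCE_FEATURE_STATS = {
    "T1": (1.89, 1.13),
    "T2": (1.82, 1.20),
    "T3": (1.65, 1.25),
    "T4": (1.60, 1.25),
    "TOFR": (0.84, 0.40),
    "AMG_StdDev": (0.44, 0.32),
    "AMG_Mean": (0.27, 0.23),
    "deltaT2_T1": (13.99, 6.55),
    "deltaT3_T2": (14.44, 7.23),
    "deltaT4_T3": (16.30, 18.95),
    "deltaT4_T1": (44.73, 25.36),
    "ratioT1": (8.55, 3.73),
    "ratioT2": (7.57, 2.83),
    "ratioT3": (6.52, 2.76),
    "ratioT4": (6.36, 2.90),
}


def _uniform_mix() -> dict:
    p = 1.0 / len(ANOMALY_TYPES)
    return {t: p for t in ANOMALY_TYPES}


@dataclass
class GeneratorConfig:
    """Study-design and signal-level parameters of the synthetic cohort.

    Defaults emulate the clinical data set the package targets: 533
    measurements from 35 patients with 30 anomalous recordings concentrated
    in 18 patients, and feature marginals calibrated to the published
    descriptive statistics (T1 mean 1.89, TOFR mean 0.84, inter-twitch
    spacing ~14 samples, AMG_Mean ~0.27).
    """

    n_patients: int = 35
    n_measurements: int = 533
    n_outliers: int = 30
    n_outlier_patients: int = 18
    sampling_rate: float = 1.0  # samples per centisecond
    n_samples: int = 185  # nominal recording length (samples)
    inter_twitch_interval_mean: float = 14.0
    inter_twitch_interval_sd: float = 2.0
    min_interval: float = 7.0
    first_peak_range: tuple = (8.0, 14.0)
    twitch_amplitude_scale: float = 2.54  # mean envelope-peak amplitude
    twitch_amplitude_cv: float = 0.85
    # fraction of measurements with weak transducer coupling, where the
    # evoked response sits just above the sensor noise floor (the clinical
    # cohort spans twitch amplitudes down to ~0.06 envelope units)
    low_gain_fraction: float = 0.0
    low_gain_range: tuple = (0.3, 0.9)
    twitch_width: float = 5.0  # nominal raised-cosine half-width (samples)
    twitch_width_range: tuple = (4.0, 6.0)  # per-measurement draw
    # twitch-to-twitch amplitude variability (lognormal sd), on top of the
    # geometric fade
    twitch_jitter_sd: float = 0.28
    # fade factor f: T_{i+1} = f * T_i; truncated normal (mu, sd, lo, hi)
    # for the recovering bulk, plus a deep-block component with strong fade
    # (the clinical cohort's lower TOFR quartile reaches 0.05)
    fade_distribution_params: tuple = (0.95, 0.18, 0.45, 1.15)
    deep_block_fraction: float = 0.15
    deep_block_fade_range: tuple = (0.27, 0.5)
    gyro_scale: float = 1.0
    noise_sd: float = 0.01
    # slow background hand activity (tremor/drift): envelope mass drawn
    # uniformly up to this fraction of the twitch mass
    baseline_mass_range: tuple = (0.0, 0.8)
    baseline_period_range: tuple = (30.0, 70.0)
    anomaly_mix: dict = field(default_factory=_uniform_mix)
    amplitude_matched_anomalies: bool = True
    seed: int = 42

    def __post_init__(self) -> None:
        if self.n_outliers > self.n_measurements:
            raise ValidationError("n_outliers cannot exceed n_measurements")
        if self.n_outlier_patients > self.n_patients:
            raise ValidationError("n_outlier_patients cannot exceed n_patients")
        if self.n_outliers < self.n_outlier_patients:
            raise ValidationError(
                "infeasible allocation: n_outliers < n_outlier_patients"
            )
        unknown = set(self.anomaly_mix) - set(ANOMALY_TYPES)
        if unknown:
            raise ValidationError(f"unknown anomaly types in mix: {sorted(unknown)}")
        total = sum(self.anomaly_mix.values())
        if self.anomaly_mix and abs(total - 1.0) > 1e-9:
            raise ValidationError("anomaly_mix proportions must sum to 1")
        for name in (
            "sampling_rate",
            "inter_twitch_interval_mean",
            "twitch_amplitude_scale",
            "twitch_width",
            "noise_sd",
        ):
            if getattr(self, name) < 0 or (
                name != "noise_sd" and getattr(self, name) == 0
            ):
                raise ValidationError(f"{name} must be strictly positive")

    def replace(self, **kw) -> "GeneratorConfig":
        return dataclasses.replace(self, **kw)


@dataclass
class RawRecording:
    """One TOF measurement: 6-channel kinetic samples plus label metadata."""

    measurement_id: str
    patient_id: str
    t: np.ndarray  # (n,) sample times, uniform spacing
    accel: np.ndarray  # (n, 3) m/s^2
    gyro: np.ndarray  # (n, 3) rad/s
    label: str  # "normal" | "outlier"
    anomaly_type: Optional[str] = None

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.accel = np.asarray(self.accel, dtype=float)
        self.gyro = np.asarray(self.gyro, dtype=float)
        if self.label not in ("normal", "outlier"):
            raise ValidationError(f"label must be normal/outlier, got {self.label!r}")
        if (self.label == "outlier") != (self.anomaly_type is not None):
            raise ValidationError("label == outlier iff anomaly_type is present")
        n = len(self.t)
        if self.accel.shape != (n, 3) or self.gyro.shape != (n, 3):
            raise ValidationError("accel/gyro must be (n, 3) arrays matching t")
        if n > 1 and not np.all(np.diff(self.t) > 0):
            raise ValidationError("t must be strictly increasing")


def _unit_vector(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    norm = np.linalg.norm(v)
    while norm < 1e-12:  # pragma: no cover - essentially impossible
        v = rng.normal(size=3)
        norm = np.linalg.norm(v)
    return v / norm


def raised_cosine(t: np.ndarray, peak_time: float, width: float) -> np.ndarray:
    """Unit-peak raised-cosine burst with support (peak-width, peak+width).

    Its integral over the support is exactly ``width`` (kernel constant 1).
    """
    x = (np.asarray(t, dtype=float) - peak_time) / width
    out = np.zeros_like(x)
    inside = np.abs(x) < 1.0
    out[inside] = 0.5 * (1.0 + np.cos(np.pi * x[inside]))
    return out


def simulate_twitch(
    peak_time: float,
    amplitude: float,
    width: float,
    orientation: Sequence[float],
    rng: np.random.Generator,
    gyro_scale: float = 1.0,
    t: Optional[np.ndarray] = None,
):
    """Render one twitch burst as a 6-channel segment.

    ``amplitude`` is the peak of the *combined* envelope, i.e. of
    sqrt((|accel|^2 + |gyro|^2) / 6); the acceleration channels are scaled
    so the combined magnitude peaks at ``amplitude`` at ``peak_time``.
    Returns ``(t, accel, gyro)`` with accel/gyro of shape (n, 3).
    """
    orientation = np.asarray(orientation, dtype=float)
    if abs(np.linalg.norm(orientation) - 1.0) > 1e-6:
        raise ValidationError("orientation must be a unit 3-vector")
    if amplitude < 0:
        raise ValidationError("amplitude must be non-negative")
    if width <= 0:
        raise ValidationError("width must be positive")
    if t is None:
        t = np.arange(np.floor(peak_time - width), np.ceil(peak_time + width) + 1)
    s = raised_cosine(t, peak_time, width)
    chan_scale = amplitude * np.sqrt(6.0 / (1.0 + gyro_scale**2))
    gyro_orientation = _unit_vector(rng)
    accel = np.outer(s, orientation) * chan_scale
    gyro = np.outer(s, gyro_orientation) * chan_scale * gyro_scale
    return t, accel, gyro


def _draw_fade(
    config: GeneratorConfig, rng: np.random.Generator, allow_deep: bool = True
) -> float:
    if (
        allow_deep
        and config.deep_block_fraction > 0
        and rng.random() < config.deep_block_fraction
    ):
        return float(rng.uniform(*config.deep_block_fade_range))
    mu, sd, lo, hi = config.fade_distribution_params
    if sd <= 0:
        return float(np.clip(mu, lo, hi))
    a, b = (lo - mu) / sd, (hi - mu) / sd
    return float(truncnorm.rvs(a, b, loc=mu, scale=sd, random_state=rng))


def _draw_amplitude_scale(config: GeneratorConfig, rng: np.random.Generator) -> float:
    cv = config.twitch_amplitude_cv
    if cv <= 0:
        return config.twitch_amplitude_scale
    p = config.low_gain_fraction
    if p > 0 and rng.random() < p:
        return float(rng.uniform(*config.low_gain_range))
    # main component mean adjusted so the overall mean stays on target
    low_mean = 0.5 * sum(config.low_gain_range)
    main_mean = (config.twitch_amplitude_scale - p * low_mean) / (1.0 - p)
    # heavy-tailed gain spread, as seen across patients and hand positions
    sigma = np.sqrt(np.log1p(cv**2))
    return float(rng.lognormal(np.log(main_mean) - sigma**2 / 2.0, sigma))


def _draw_intervals(config: GeneratorConfig, rng: np.random.Generator, n: int = 3):
    raw = rng.normal(
        config.inter_twitch_interval_mean, config.inter_twitch_interval_sd, size=n
    )
    return np.clip(raw, config.min_interval, None)


def _normal_pattern(
    config: GeneratorConfig, rng: np.random.Generator, allow_deep: bool = True
):
    """Peak times and amplitudes of a normal 4-twitch fade pattern."""
    a = _draw_amplitude_scale(config, rng)
    f = _draw_fade(config, rng, allow_deep=allow_deep)
    # a measurement is only recorded when all four twitches are resolvable:
    # floor the fade so the smallest twitch stays above the noise floor
    min_resolvable = 5.0 * config.noise_sd
    if a > 0 and min_resolvable > 0:
        f = max(f, (min(1.0, min_resolvable / a)) ** (1.0 / 3.0))
    intervals = _draw_intervals(config, rng)
    t0 = rng.uniform(*config.first_peak_range)
    times = t0 + np.concatenate([[0.0], np.cumsum(intervals)])
    amps = a * f ** np.arange(4)
    if config.twitch_jitter_sd > 0:
        amps = amps * np.exp(rng.normal(0.0, config.twitch_jitter_sd, size=4))
    return times, amps


def _render_recording(
    config: GeneratorConfig,
    peak_times: np.ndarray,
    amplitudes: np.ndarray,
    rng: np.random.Generator,
    oscillation: Optional[tuple] = None,
    envelope_scale: float = 1.0,
    width: Optional[float] = None,
):
    """Project an envelope built from twitch bursts onto 6 noisy channels."""
    if width is None:
        width = config.twitch_width
    last = float(np.max(peak_times)) if len(peak_times) else 0.0
    n = max(config.n_samples, int(np.ceil(last + width + 10)))
    t = np.arange(n, dtype=float) / config.sampling_rate
    env = np.zeros(n)
    for tp, a in zip(peak_times, amplitudes):
        env += a * raised_cosine(t, tp, width)
    if oscillation is not None:
        amp, period, lo, hi = oscillation
        mask = (t >= lo) & (t <= hi)
        env[mask] += amp * 0.5 * (1.0 - np.cos(2.0 * np.pi * (t[mask] - lo) / period))
    env *= envelope_scale
    lo_m, hi_m = config.baseline_mass_range
    if hi_m > 0:
        twitch_mass = float(np.sum(np.abs(amplitudes))) * width * envelope_scale
        base_mass = rng.uniform(lo_m, hi_m) * twitch_mass
        period_b = rng.uniform(*config.baseline_period_range)
        phase = rng.uniform(0.0, period_b)
        b_amp = 2.0 * base_mass / n
        # background activity stays below the smallest evoked twitch, so it
        # never masquerades as one
        pos = np.abs(amplitudes[np.abs(amplitudes) > 0])
        if len(pos):
            b_amp = min(b_amp, 0.6 * float(pos.min()) * envelope_scale)
        env += b_amp * 0.5 * (1.0 - np.cos(2.0 * np.pi * (t - phase) / period_b))
    gs = config.gyro_scale
    chan_scale = np.sqrt(6.0 / (1.0 + gs**2))
    orient_a = _unit_vector(rng)
    orient_g = _unit_vector(rng)
    accel = np.outer(env * chan_scale, orient_a)
    gyro = np.outer(env * chan_scale * gs, orient_g)
    if config.noise_sd > 0:
        accel += rng.normal(0.0, config.noise_sd, size=accel.shape)
        gyro += rng.normal(0.0, config.noise_sd, size=gyro.shape)
    return t, accel, gyro


def simulate_measurement(
    config: GeneratorConfig,
    patient_id: str,
    label: str,
    anomaly_type: Optional[str] = None,
    rng: Optional[np.random.Generator] = None,
    measurement_id: str = "M0",
) -> RawRecording:
    """Simulate one labeled TOF recording.

    Normal recordings contain four twitches with amplitudes T1*f^(i-1) for a
    per-measurement fade factor f; anomalous recordings realize the given
    anomaly morphology.  When ``config.amplitude_matched_anomalies`` is set,
    anomaly amplitudes (and, for morphologies that change the total envelope
    mass, the envelope integral) are drawn from the normal class's marginal
    distribution so amplitude-only features carry minimal signal.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if (label == "outlier") != (anomaly_type is not None):
        raise ValidationError("anomaly_type must be given iff label == outlier")
    if anomaly_type is not None and anomaly_type not in ANOMALY_TYPES:
        raise ValidationError(f"unknown anomaly_type {anomaly_type!r}")

    # anomalies arise during ordinary monitoring, not deep block: their
    # amplitude pattern is drawn from the recovering bulk of the cohort
    times, amps = _normal_pattern(config, rng, allow_deep=(anomaly_type is None))
    lo_w, hi_w = config.twitch_width_range
    width = float(rng.uniform(lo_w, hi_w)) if hi_w > lo_w else config.twitch_width
    oscillation = None
    envelope_scale = 1.0
    cfg = config

    if anomaly_type is None:
        pass
    elif anomaly_type == "REBOUND_BURST":
        # single-movement rebound: a broad burst carrying a TOF-like ripple
        # with >=3-fold compressed inter-twitch distances, right at the
        # start of the recording
        intervals = np.diff(times) / rng.uniform(3.0, 4.0)
        times = times[0] + np.concatenate([[0.0], np.cumsum(intervals)])
        burst_width = float(rng.uniform(6.0, 9.0))
        if config.amplitude_matched_anomalies:
            # the merged burst reads as a single twitch; carry roughly the
            # envelope mass of one normal twitch so the whole-recording
            # statistics stay in the normal range
            amps = amps * 0.3 * (width / burst_width)
        width = burst_width
    elif anomaly_type == "NON_MONOTONIC_T3":
        amps = amps.copy()
        amps[2] = rng.uniform(0.15, 0.4) * min(amps[1], amps[3])
    elif anomaly_type == "EQUIDISTANT_OSCILLATION":
        # a long train of near-equal oscillations at roughly the nominal
        # stimulation cadence, in place of the 4-twitch fade pattern
        n_pk = 7
        spacing = config.inter_twitch_interval_mean
        jitter = rng.normal(0.0, 0.03 * spacing, size=n_pk - 1)
        intervals = np.clip(spacing + jitter, 2.0, None)
        t0 = rng.uniform(*config.first_peak_range)
        osc_times = t0 + np.concatenate([[0.0], np.cumsum(intervals)])
        # near-equal peaks carrying the envelope mass of the pattern they
        # replace, with the cohort's twitch-to-twitch variability
        osc_amps = rng.uniform(0.9, 1.1, size=n_pk) * np.exp(
            rng.normal(0.0, config.twitch_jitter_sd, size=n_pk)
        )
        osc_amps *= amps.sum() / osc_amps.sum()
        times, amps = osc_times, osc_amps
    elif anomaly_type == "CRESCENDO":
        # reversed fade: strictly increasing amplitudes with bounded steps
        steps = np.cumprod(rng.uniform(1.2, 1.45, size=4))
        if config.amplitude_matched_anomalies:
            amps = steps / steps.sum() * amps.sum()
        else:
            amps = amps[0] * steps / steps[0]
    elif anomaly_type == "DECRESCENDO_GROSS_OSC":
        # fade preserved, but interpeak spacing perturbed >=50% and a gross
        # oscillation superimposed across the stimulation window
        factors = np.array([1.0, rng.uniform(1.8, 2.6), rng.uniform(1.8, 2.6)])
        intervals = np.diff(times) * factors
        times = times[0] + np.concatenate([[0.0], np.cumsum(intervals)])
        osc_amp = 0.1 * amps[0]
        period = rng.uniform(4.0, 7.0)
        oscillation = (osc_amp, period, times[0] - 5.0, times[-1] + 5.0)
    elif anomaly_type == "MISSING_PEAKS":
        amps = amps.copy()
        amps[[2, 3]] = 0.0  # the last twitches vanish below the noise floor
    elif anomaly_type == "WIDE_GAP":
        intervals = np.diff(times)
        j = int(rng.integers(1, 3))  # gap after the second or third twitch
        intervals[j] *= rng.uniform(3.0, 4.0)
        times = times[0] + np.concatenate([[0.0], np.cumsum(intervals)])

    t, accel, gyro = _render_recording(
        cfg,
        times,
        amps,
        rng,
        oscillation=oscillation,
        envelope_scale=envelope_scale,
        width=width,
    )
    return RawRecording(
        measurement_id=measurement_id,
        patient_id=patient_id,
        t=t,
        accel=accel,
        gyro=gyro,
        label=label,
        anomaly_type=anomaly_type,
    )


def _allocate(counts: np.ndarray, total: int) -> np.ndarray:
    """Distribute ``total`` items over bins proportionally (largest remainder)."""
    quota = counts / counts.sum() * total
    base = np.floor(quota).astype(int)
    rem = total - base.sum()
    order = np.argsort(-(quota - base), kind="stable")
    base[order[:rem]] += 1
    return base


def simulate_dataset(config: GeneratorConfig) -> list:
    """Simulate the full labeled cohort described by ``config``.

    Exactly ``n_measurements`` recordings over ``n_patients`` patients, with
    exactly ``n_outliers`` anomalies spread over exactly
    ``n_outlier_patients`` distinct patients.  Fully deterministic given
    ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    n_pat, n_meas = config.n_patients, config.n_measurements

    # per-patient measurement counts: near-even split, remainder at random
    per_patient = np.full(n_pat, n_meas // n_pat)
    extra = rng.choice(n_pat, size=n_meas % n_pat, replace=False)
    per_patient[extra] += 1

    patients = [f"P{i + 1:02d}" for i in range(n_pat)]

    # outlier allocation: each chosen patient gets >=1 anomaly
    outlier_counts = np.zeros(n_pat, dtype=int)
    if config.n_outliers > 0:
        chosen = rng.choice(n_pat, size=config.n_outlier_patients, replace=False)
        outlier_counts[chosen] = 1
        spare = config.n_outliers - config.n_outlier_patients
        for _ in range(spare):
            room = chosen[outlier_counts[chosen] < per_patient[chosen]]
            pick = int(rng.choice(room))
            outlier_counts[pick] += 1
    if np.any(outlier_counts > per_patient):  # pragma: no cover - guarded above
        raise ValidationError("cannot place more outliers than measurements")

    # anomaly types per the configured mix
    if config.n_outliers > 0:
        mix_types = sorted(config.anomaly_mix)
        mix_p = np.array([config.anomaly_mix[t] for t in mix_types])
        type_counts = _allocate(mix_p, config.n_outliers)
        type_pool = [t for t, c in zip(mix_types, type_counts) for _ in range(c)]
        rng.shuffle(type_pool)
    else:
        type_pool = []

    recordings = []
    m = 0
    for p_idx, pid in enumerate(patients):
        k_out = outlier_counts[p_idx]
        labels = ["outlier"] * k_out + ["normal"] * (per_patient[p_idx] - k_out)
        rng.shuffle(labels)
        for lab in labels:
            atype = type_pool.pop() if lab == "outlier" else None
            m += 1
            recordings.append(
                simulate_measurement(
                    config,
                    patient_id=pid,
                    label=lab,
                    anomaly_type=atype,
                    rng=rng,
                    measurement_id=f"M{m:04d}",
                )
            )
    return recordings


def calibration_report(feature_table: pd.DataFrame) -> pd.DataFrame:
    """Observed feature means/SDs next to the published reference statistics.

    Returns one row per feature with observed mean/SD, reference mean/SD and
    the relative deviation of the mean.
    """
    if feature_table is None or len(feature_table) == 0:
        raise ValidationError("feature table is empty")
    rows = []
    for name, (ref_mean, ref_sd) in REFERENCE_FEATURE_STATS.items():
        if name not in feature_table.columns:
            raise ValidationError(f"feature table lacks column {name!r}")
        obs = feature_table[name].to_numpy(dtype=float)
        rows.append(
            {
                "feature": name,
                "mean": float(np.mean(obs)),
                "sd": float(np.std(obs, ddof=1)),
                "ref_mean": ref_mean,
                "ref_sd": ref_sd,
                "rel_dev_mean": float((np.mean(obs) - ref_mean) / ref_mean),
            }
        )
    return pd.DataFrame(rows).set_index("feature")
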