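"""Synthetic IMU sessions, recovery cohorts, flexion data and PROMs responses.

Real recordings from monitored arthroplasty patients are not publicly
deposited, so this module generates sessions with *known ground truth*
that reproduce the statistical structure the analysis assumes:

* Walking gait as a train of foot-strike transients on a 1 g gravity
  baseline. Each step is a half-sine spike on the axial acceleration
  channel whose resultant peak equals the drawn per-step peak. Peaks
  are log-normal (median 3 g, sigma 0.4 on the log scale) with a 2.5 g
  floor: soft, sub-threshold foot contacts are not modeled, every
  simulated impact is a real loading event at level >= 1 g.
* Between-limb load asymmetry as a multiplicative scaling of the
  operative limb's peaks. Both limbs share the same base peak draws, so
  with zero noise the ratio of mean true peaks is the configured factor
  exactly.
* Week-over-week recovery as per-week peak-scale multipliers and
  asymmetry factors across a cohort of patients.
* Knee-flexion training data: a smooth periodic flexion waveform drives
  thigh and shank segment angles, and the 24 IMU channels of the four
  sensors (thigh + ankle per leg) are deterministic functions of those
  angles (gyro = angular velocity, accelerometer = gravity projection),
  so a surrogate regressor can in principle invert them.
* PROMs questionnaire responses whose expected weekly scores follow a
  configured trajectory.

All randomness flows from an explicit integer seed through a single
``numpy.random.Generator`` per call; identical parameters and seed give
bit-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .session import CHANNEL_NAMES, ImuSession, Limb, SensorLocation, WeekLabel

__all__ = [
    "GaitParams",
    "GroundTruth",
    "PromsWeekParams",
    "RecoveryTrajectoryParams",
    "FlexionSimParams",
    "generate_gait_session",
    "generate_recovery_cohort",
    "generate_flexion_dataset",
    "generate_proms_responses",
    "default_recovery_params",
]

SPIKE_WIDTH_S = 0.05  # half-sine foot-strike transient width
GYRO_NOISE_SCALE = 50.0  # deg/s of gyro noise per g of accel noise


@dataclass(frozen=True)
class GaitParams:
    """Conditions for one simulated walking session.

    cadence : steps/min *per limb* (a typical adult walks ~50-60).
    peak_dist_mu, peak_dist_sigma : log-scale parameters of the
        log-normal per-step peak distribution (defaults ln(3 g), 0.4).
    min_peak : g, lower truncation of drawn peaks (default 2.5).
    asymmetry_factor : multiplicative scaling of operative-limb peaks;
        1.0 = symmetric. Must leave the smallest operative spike above
        the 1 g gravity baseline.
    peak_scale : overall multiplicative scaling of both limbs' peaks
        (used by the recovery-cohort generator).
    noise_sd : g, additive white sensor noise on the accelerometer
        channels (default 0.02 g; gyro channels get 50x in deg/s).
    """

    cadence: float = 55.0
    duration: float = 60.0
    peak_dist_mu: float = math.log(3.0)
    peak_dist_sigma: float = 0.4
    min_peak: float = 2.5
    asymmetry_factor: float = 1.0
    peak_scale: float = 1.0
    noise_sd: float = 0.02
    sample_rate: float = 1149.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cadence <= 0:
            raise ValueError(f"cadence must be > 0, got {self.cadence}")
        if self.duration <= 0:
            raise ValueError(f"duration must be > 0, got {self.duration}")
        if self.asymmetry_factor <= 0:
            raise ValueError(f"asymmetry_factor must be > 0, got {self.asymmetry_factor}")
        if self.sample_rate <= 0:
            raise ValueError(f"sample_rate must be > 0, got {self.sample_rate}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.min_peak <= 1.0:
            raise ValueError("min_peak must exceed the 1 g gravity baseline")
        floor = self.min_peak * self.peak_scale * min(self.asymmetry_factor, 1.0)
        if floor <= 1.05:
            raise ValueError(
                f"smallest possible peak {floor:.3g} g is not distinguishable from "
                "the 1 g baseline; raise min_peak, peak_scale or asymmetry_factor"
            )


@dataclass(frozen=True)
class GroundTruth:
    """Per-limb true step times (s) and peak magnitudes (g)."""

    steps: dict[Limb, list[tuple[float, float]]]

    def __post_init__(self) -> None:
        for limb, pairs in self.steps.items():
            times = [t for t, _ in pairs]
            if any(b <= a for a, b in zip(times, times[1:])):
                raise ValueError(f"{limb}: step times must be strictly increasing")
            if any(p <= 0 for _, p in pairs):
                raise ValueError(f"{limb}: peaks must be > 0")

    def times(self, limb: Limb) -> np.ndarray:
        return np.array([t for t, _ in self.steps[limb]])

    def peaks(self, limb: Limb) -> np.ndarray:
        return np.array([p for _, p in self.steps[limb]])


def _truncated_lognormal(rng: np.random.Generator, mu: float, sigma: float,
                         floor: float, n: int) -> np.ndarray:
    """Draw n log-normal variates conditioned on exceeding ``floor``."""
    out = np.empty(n)
    filled = 0
    while filled < n:
        draw = rng.lognormal(mu, sigma, size=2 * (n - filled))
        draw = draw[draw >= floor]
        take = min(len(draw), n - filled)
        out[filled : filled + take] = draw[:take]
        filled += take
    return out


def _spike_train(times: np.ndarray, amplitudes: np.ndarray, n_samples: int,
                 fs: float) -> np.ndarray:
    """Superimpose half-sine transients (width SPIKE_WIDTH_S) on zeros."""
    sig = np.zeros(n_samples)
    half = SPIKE_WIDTH_S / 2.0
    width_n = max(int(round(SPIKE_WIDTH_S * fs)), 3)
    for t, a in zip(times, amplitudes):
        i0 = int(round((t - half) * fs))
        idx = np.arange(width_n)
        lobe = a * np.sin(np.pi * (idx + 0.5) / width_n)
        lo, hi = max(i0, 0), min(i0 + width_n, n_samples)
        if hi > lo:
            sig[lo:hi] += lobe[lo - i0 : hi - i0]
    return sig


def generate_gait_session(
    params: GaitParams,
) -> tuple[ImuSession, ImuSession, GroundTruth]:
    """Simulate one bilateral walking session.

    Returns the operative-limb session, the non-operative-limb session
    and the ground truth. Step count per limb is exactly
    ``round(cadence * duration / 60)``; the two limbs alternate half a
    stride apart. Peaks are paired across limbs (same base draw), with
    the operative limb's scaled by ``asymmetry_factor``.
    """
    rng = np.random.default_rng(params.seed)
    fs = params.sample_rate
    n_samples = int(round(params.duration * fs))
    n_steps = int(round(params.cadence * params.duration / 60.0))
    period = 60.0 / params.cadence

    # place steps so every transient (and its jitter) fits inside the session
    period_eff = (params.duration - 2 * SPIKE_WIDTH_S) / max(n_steps, 1)
    jitter_bound = 0.2 * min(period, period_eff)

    base_peaks = params.peak_scale * _truncated_lognormal(
        rng, params.peak_dist_mu, params.peak_dist_sigma, params.min_peak, n_steps
    )
    jitter = {
        limb: np.clip(rng.normal(0.0, 0.01, size=n_steps), -jitter_bound, jitter_bound)
        for limb in Limb
    }
    phase = {Limb.OPERATIVE: 0.25, Limb.NON_OPERATIVE: 0.75}

    sessions: dict[Limb, ImuSession] = {}
    truth: dict[Limb, list[tuple[float, float]]] = {}
    for limb in Limb:
        times = SPIKE_WIDTH_S + (np.arange(n_steps) + phase[limb]) * period_eff + jitter[limb]
        peaks = base_peaks.copy()
        if limb is Limb.OPERATIVE:
            peaks *= params.asymmetry_factor
        az = 1.0 + _spike_train(times, peaks - 1.0, n_samples, fs)
        channels = {
            "ax": np.zeros(n_samples),
            "ay": np.zeros(n_samples),
            "az": az,
            "gx": np.zeros(n_samples),
            "gy": np.zeros(n_samples),
            "gz": np.zeros(n_samples),
        }
        if params.noise_sd > 0:
            for c in ("ax", "ay", "az"):
                channels[c] = channels[c] + rng.normal(0, params.noise_sd, n_samples)
            for c in ("gx", "gy", "gz"):
                channels[c] = channels[c] + rng.normal(
                    0, GYRO_NOISE_SCALE * params.noise_sd, n_samples
                )
        sessions[limb] = ImuSession(
            channels=channels,
            sample_rate=fs,
            limb=limb,
            location=SensorLocation.ANKLE,
        )
        truth[limb] = list(zip(times.tolist(), peaks.tolist()))

    return sessions[Limb.OPERATIVE], sessions[Limb.NON_OPERATIVE], GroundTruth(steps=truth)


# ---------------------------------------------------------------------------
# Recovery cohorts


@dataclass(frozen=True)
class PromsWeekParams:
    """Expected PROMs response levels for one week.

    oks_item_mean : expected per-item response level, in [0, 4]; the
        expected total score is 12x this.
    eq5d_level_probs : probabilities of levels (1, 2, 3) shared across
        the five dimensions.
    eqvas_mean, eqvas_sd : self-rated health on the 0-100 visual scale.
    """

    oks_item_mean: float
    eq5d_level_probs: tuple[float, float, float]
    eqvas_mean: float
    eqvas_sd: float = 8.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.oks_item_mean <= 4.0):
            raise ValueError("oks_item_mean must be in [0, 4]")
        if not math.isclose(sum(self.eq5d_level_probs), 1.0, abs_tol=1e-9):
            raise ValueError("eq5d_level_probs must sum to 1")


@dataclass(frozen=True)
class RecoveryTrajectoryParams:
    """Week-over-week cohort conditions.

    One peak-scale ``load_multiplier`` and one ``asymmetry_factor`` per
    week drive the IMU sessions; ``proms`` drives the questionnaires.
    """

    weeks: tuple[WeekLabel, ...]
    load_multiplier: dict[WeekLabel, float]
    asymmetry_factor: dict[WeekLabel, float]
    proms: dict[WeekLabel, PromsWeekParams] = field(default_factory=dict)
    n_patients: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.weeks) == 0:
            raise ValueError("weeks list must not be empty")
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        for table, name in (
            (self.load_multiplier, "load_multiplier"),
            (self.asymmetry_factor, "asymmetry_factor"),
        ):
            missing = [w.value for w in self.weeks if w not in table]
            if missing:
                raise ValueError(f"{name} missing entries for weeks {missing}")


def default_recovery_params(n_patients: int = 5, seed: int = 0) -> RecoveryTrajectoryParams:
    """Cohort conditions emulating a typical post-operative recovery.

    Asymmetry factors run from 0.70 at Week 2 (operative limb carrying
    ~30% less per step, asymmetry index ~ -17.6%) to 0.81 by Week 6
    (index ~ -10.5%); per-step load scale grows monotonically as
    patients load the limb more confidently. Expected PROMs climb from
    a pre-operative OKS around 26 and a moderate-problem EQ-5D profile
    to near-ceiling levels by Week 12.
    """
    weeks = (WeekLabel.W2, WeekLabel.W3, WeekLabel.W4, WeekLabel.W5, WeekLabel.W6)
    proms_weeks = (WeekLabel.PREOP,) + weeks + (WeekLabel.W12,)
    oks_item = {  # expected score = 12 * item mean
        WeekLabel.PREOP: 2.13, WeekLabel.W2: 2.3, WeekLabel.W3: 2.54,
        WeekLabel.W4: 2.7, WeekLabel.W5: 2.9, WeekLabel.W6: 3.04,
        WeekLabel.W12: 3.24,
    }
    eq5d_probs = {
        WeekLabel.PREOP: (0.30, 0.55, 0.15), WeekLabel.W2: (0.35, 0.55, 0.10),
        WeekLabel.W3: (0.45, 0.48, 0.07), WeekLabel.W4: (0.55, 0.41, 0.04),
        WeekLabel.W5: (0.62, 0.35, 0.03), WeekLabel.W6: (0.70, 0.28, 0.02),
        WeekLabel.W12: (0.78, 0.21, 0.01),
    }
    eqvas = {
        WeekLabel.PREOP: 75.0, WeekLabel.W2: 72.0, WeekLabel.W3: 76.0,
        WeekLabel.W4: 79.0, WeekLabel.W5: 82.0, WeekLabel.W6: 84.0,
        WeekLabel.W12: 87.0,
    }
    return RecoveryTrajectoryParams(
        weeks=weeks,
        load_multiplier={
            WeekLabel.W2: 1.0, WeekLabel.W3: 1.2, WeekLabel.W4: 1.4,
            WeekLabel.W5: 1.6, WeekLabel.W6: 1.8,
        },
        asymmetry_factor={
            WeekLabel.W2: 0.70, WeekLabel.W3: 0.72, WeekLabel.W4: 0.75,
            WeekLabel.W5: 0.78, WeekLabel.W6: 0.81,
        },
        proms={
            w: PromsWeekParams(
                oks_item_mean=oks_item[w],
                eq5d_level_probs=eq5d_probs[w],
                eqvas_mean=eqvas[w],
            )
            for w in proms_weeks
        },
        n_patients=n_patients,
        seed=seed,
    )


@dataclass(frozen=True)
class CohortSession:
    """One patient-week bilateral recording with its ground truth."""

    patient_id: str
    week: WeekLabel
    operative: ImuSession
    non_operative: ImuSession
    truth: GroundTruth


def generate_recovery_cohort(
    params: RecoveryTrajectoryParams, gait: GaitParams | None = None
) -> list[CohortSession]:
    """One bilateral session per patient per week.

    Each week's sessions use the week's ``load_multiplier`` as an
    overall peak scale and the week's ``asymmetry_factor``; everything
    else follows ``gait``. Per patient-week seeds are spawned
    deterministically from ``params.seed``.
    """
    gait = gait or GaitParams()
    ss = np.random.SeedSequence(params.seed)
    seeds = ss.generate_state(params.n_patients * len(params.weeks)) % (2**31)
    out: list[CohortSession] = []
    k = 0
    for p in range(params.n_patients):
        pid = f"SYN{p + 1:03d}"
        for week in params.weeks:
            wk_params = GaitParams(
                cadence=gait.cadence,
                duration=gait.duration,
                peak_dist_mu=gait.peak_dist_mu,
                peak_dist_sigma=gait.peak_dist_sigma,
                min_peak=gait.min_peak,
                asymmetry_factor=params.asymmetry_factor[week],
                peak_scale=gait.peak_scale * params.load_multiplier[week],
                noise_sd=gait.noise_sd,
                sample_rate=gait.sample_rate,
                seed=int(seeds[k]),
            )
            k += 1
            op, nonop, truth = generate_gait_session(wk_params)
            out.append(
                CohortSession(
                    patient_id=pid,
                    week=week,
                    operative=op.with_metadata(patient_id=pid, week_label=week),
                    non_operative=nonop.with_metadata(patient_id=pid, week_label=week),
                    truth=truth,
                )
            )
    return out


# ---------------------------------------------------------------------------
# Flexion training data


@dataclass(frozen=True)
class FlexionSimParams:
    """Conditions for a paired IMU / knee-flexion-angle dataset.

    The knee flexion angle follows
    ``offset + amplitude * sin(2 pi f t)`` so its true maximum is
    ``offset + amplitude``. Defaults model slow rehabilitation walking:
    stride frequency 0.8 Hz, flexion swinging 30 +/- 30 deg.
    """

    cycle_hz: float = 0.8
    amplitude_deg: float = 30.0
    offset_deg: float = 30.0
    duration: float = 60.0
    noise_sd: float = 0.02
    sample_rate: float = 1149.0
    target_rate: float = 100.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.amplitude_deg < 0:
            raise ValueError(f"amplitude must be >= 0, got {self.amplitude_deg}")
        if self.cycle_hz <= 0 or self.duration <= 0:
            raise ValueError("cycle_hz and duration must be > 0")
        if self.sample_rate <= 0 or self.target_rate <= 0:
            raise ValueError("rates must be > 0")


# sagittal segment-angle shares of the knee angle: thigh minus shank = knee
THIGH_SHARE = 0.4
SHANK_SHARE = -0.6


def _flexion_angle(t: np.ndarray, p: FlexionSimParams) -> np.ndarray:
    return p.offset_deg + p.amplitude_deg * np.sin(2 * np.pi * p.cycle_hz * t)


def generate_flexion_dataset(
    params: FlexionSimParams,
) -> tuple[dict[tuple[Limb, SensorLocation], ImuSession], pd.DataFrame]:
    """Four-sensor IMU set plus a ground-truth flexion trace.

    The sagittal gyro channel of each sensor is the segment's angular
    velocity (deg/s); the accelerometer channels are the unit-gravity
    projection onto the tilted segment axes. The right (non-operative)
    leg runs half a cycle out of phase. The ground-truth trace is the
    operative knee's flexion angle sampled at ``target_rate``, returned
    as a DataFrame with columns ``time`` and ``flexion_deg``.
    """
    rng = np.random.default_rng(params.seed)
    fs = params.sample_rate
    n = int(round(params.duration * fs))
    t = np.arange(n) / fs

    sessions: dict[tuple[Limb, SensorLocation], ImuSession] = {}
    for limb in Limb:
        shift = 0.0 if limb is Limb.OPERATIVE else 0.5 / params.cycle_hz
        theta = _flexion_angle(t + shift, params)
        dtheta = (
            params.amplitude_deg
            * 2 * np.pi * params.cycle_hz
            * np.cos(2 * np.pi * params.cycle_hz * (t + shift))
        )
        for location, share in (
            (SensorLocation.THIGH, THIGH_SHARE),
            (SensorLocation.ANKLE, SHANK_SHARE),
        ):
            seg = np.deg2rad(share * theta)
            channels = {
                "ax": np.sin(seg),
                "ay": np.zeros(n),
                "az": np.cos(seg),
                "gx": np.zeros(n),
                "gy": share * dtheta,
                "gz": np.zeros(n),
            }
            if params.noise_sd > 0:
                for c in ("ax", "ay", "az"):
                    channels[c] = channels[c] + rng.normal(0, params.noise_sd, n)
                for c in ("gx", "gy", "gz"):
                    channels[c] = channels[c] + rng.normal(
                        0, GYRO_NOISE_SCALE * params.noise_sd, n
                    )
            sessions[(limb, location)] = ImuSession(
                channels=channels, sample_rate=fs, limb=limb, location=location
            )

    t_target = np.arange(int(round(params.duration * params.target_rate))) / params.target_rate
    trace = pd.DataFrame(
        {"time": t_target, "flexion_deg": _flexion_angle(t_target, params)}
    )
    return sessions, trace


# ---------------------------------------------------------------------------
# PROMs responses


def generate_proms_responses(params: RecoveryTrajectoryParams) -> pd.DataFrame:
    """Per-patient per-week questionnaire responses.

    OKS items are Binomial(4, item_mean/4) per item (expectation =
    configured item mean; degenerate at the 0 and 4 anchors). EQ-5D
    dimension levels are i.i.d. categorical over (1, 2, 3); the visual
    analogue scale is normal, clipped to [0, 100] and rounded. Returns
    a tidy DataFrame: patient_id, week, oks_1..oks_12, eq5d_state,
    eq_vas.
    """
    if not params.proms:
        raise ValueError("params.proms is empty: no questionnaire trajectory configured")
    rng = np.random.default_rng(params.seed)
    rows = []
    weeks = sorted(params.proms, key=lambda w: w.order)
    for p in range(params.n_patients):
        pid = f"SYN{p + 1:03d}"
        for week in weeks:
            wp = params.proms[week]
            items = rng.binomial(4, wp.oks_item_mean / 4.0, size=12)
            levels = rng.choice([1, 2, 3], size=5, p=wp.eq5d_level_probs)
            vas = int(round(float(np.clip(rng.normal(wp.eqvas_mean, wp.eqvas_sd), 0, 100))))
            row = {"patient_id": pid, "week": week.value}
            row.update({f"oks_{i + 1}": int(items[i]) for i in range(12)})
            row["eq5d_state"] = "".join(str(l) for l in levels)
            row["eq_vas"] = vas
            rows.append(row)
    return pd.DataFrame(rows)
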