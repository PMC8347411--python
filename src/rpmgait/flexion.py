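"""Surrogate estimation of knee flexion angle from thigh + ankle IMU windows.

The pipeline mirrors how patient-specific flexion estimators are built
against motion-capture kinematics:

1. window the 24 IMU channels (4 sensors x 6 channels) one second
   backwards from each target timestamp;
2. extract a fixed bank of per-channel time-series features;
3. keep features significantly associated with the target (per-feature
   Spearman rank test with Benjamini-Yekutieli FDR control);
4. fit a random-forest regressor, rank features by model-based
   importance, keep the top-k (default 200) and refit;
5. slide the model over a session to produce a flexion-angle trace,
   from which the maximum flexion during an activity is read.

The feature bank is deliberately compact (26 features per channel) and
config-extensible; its size changes the feature count, not the shape of
the pipeline.
"""

from __future__ import annotations

import hashlib
import pickle
import warnings
from functools import partial
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd
from scipy import stats
from scipy.signal import find_peaks
from sklearn.ensemble import RandomForestRegressor
from statsmodels.stats.multitest import multipletests

from .session import ImuSession, Limb, SensorLocation, window_backwards

__all__ = [
    "Feature",
    "FeatureBankConfig",
    "default_feature_bank",
    "TrainingSet",
    "SurrogateModel",
    "FlexionTrace",
    "extract_features",
    "build_training_set",
    "select_significant_features",
    "train_surrogate",
    "predict_flexion",
    "max_flexion",
    "save_model",
    "load_model",
]

MODEL_FORMAT_VERSION = 1

SensorSet = dict[tuple[Limb, SensorLocation], ImuSession]


# ---------------------------------------------------------------------------
# Feature bank


@dataclass(frozen=True)
class Feature:
    """A named deterministic map from (window samples, sample rate) to one number."""

    name: str
    fn: Callable[[np.ndarray, float], float]


def _safe(v: float) -> float:
    return float(v) if np.isfinite(v) else 0.0


def _autocorr(x: np.ndarray, lag: int) -> float:
    if len(x) <= lag:
        return 0.0
    s = np.std(x)
    if s == 0:
        return 0.0
    x0 = x - np.mean(x)
    return _safe(np.dot(x0[:-lag], x0[lag:]) / ((len(x) - lag) * s**2))

def _dominant_freq(x: np.ndarray, fs: float) -> float:
    if np.ptp(x) == 0 or len(x) < 4:
        return 0.0
    spec = np.abs(np.fft.rfft(x - np.mean(x)))
    freqs = np.fft.rfftfreq(len(x), d=1.0 / fs)
    return _safe(freqs[int(np.argmax(spec))])

def _band_energy(x: np.ndarray, fs: float, lo: float, hi: float) -> float:
    if len(x) < 4:
        return 0.0
    spec = np.abs(np.fft.rfft(x - np.mean(x))) ** 2
    freqs = np.fft.rfftfreq(len(x), d=1.0 / fs)
    return _safe(spec[(freqs >= lo) & (freqs < hi)].sum() / len(x))

def _linfit(x: np.ndarray, fs: float) -> tuple[float, float]:
    t = np.arange(len(x)) / fs
    slope, intercept = np.polyfit(t, x, 1)
    return _safe(slope), _safe(intercept)

def _n_peaks(x: np.ndarray) -> float:
    if np.ptp(x) == 0:
        return 0.0
    idx, _ = find_peaks(x, height=np.mean(x) + np.std(x))
    return float(len(idx))


def _f_mean(x, fs):
    return _safe(np.mean(x))

def _f_sd(x, fs):
    return _safe(np.std(x))

def _f_min(x, fs):
    return _safe(np.min(x))

def _f_max(x, fs):
    return _safe(np.max(x))

def _f_range(x, fs):
    return _safe(np.ptp(x))

def _f_rms(x, fs):
    return _safe(np.sqrt(np.mean(x**2)))

def _f_skewness(x, fs):
    return _safe(stats.skew(x)) if np.ptp(x) else 0.0

def _f_kurtosis(x, fs):
    return _safe(stats.kurtosis(x)) if np.ptp(x) else 0.0

def _f_mean_abs_change(x, fs):
    return _safe(np.mean(np.abs(np.diff(x))))

def _f_n_peaks(x, fs):
    return _n_peaks(x)

def _f_autocorr(x, fs, lag):
    return _autocorr(x, lag)

def _f_band_energy(x, fs, lo, hi):
    return _band_energy(x, fs, lo, hi)

def _f_trend_slope(x, fs):
    return _linfit(x, fs)[0]

def _f_trend_intercept(x, fs):
    return _linfit(x, fs)[1]

def _f_quantile(x, fs, q):
    return _safe(np.quantile(x, q))

def _f_abs_energy(x, fs):
    return _safe(np.sum(x**2))

def _f_first(x, fs):
    return _safe(x[0])

def _f_last(x, fs):
    return _safe(x[-1])


def default_feature_bank() -> "FeatureBankConfig":
    """The default 26-feature per-channel bank (all maps picklable)."""
    feats = [
        Feature("mean", _f_mean),
        Feature("sd", _f_sd),
        Feature("min", _f_min),
        Feature("max", _f_max),
        Feature("range", _f_range),
        Feature("rms", _f_rms),
        Feature("skewness", _f_skewness),
        Feature("kurtosis", _f_kurtosis),
        Feature("mean_abs_change", _f_mean_abs_change),
        Feature("n_peaks", _f_n_peaks),
        Feature("autocorr_lag1", partial(_f_autocorr, lag=1)),
        Feature("autocorr_lag10", partial(_f_autocorr, lag=10)),
        Feature("autocorr_lag100", partial(_f_autocorr, lag=100)),
        Feature("dominant_freq", _dominant_freq),
        Feature("band_energy_0_5", partial(_f_band_energy, lo=0.0, hi=5.0)),
        Feature("band_energy_5_20", partial(_f_band_energy, lo=5.0, hi=20.0)),
        Feature("band_energy_20_75", partial(_f_band_energy, lo=20.0, hi=75.0)),
        Feature("trend_slope", _f_trend_slope),
        Feature("trend_intercept", _f_trend_intercept),
        Feature("q10", partial(_f_quantile, q=0.10)),
        Feature("q25", partial(_f_quantile, q=0.25)),
        Feature("q75", partial(_f_quantile, q=0.75)),
        Feature("q90", partial(_f_quantile, q=0.90)),
        Feature("abs_energy", _f_abs_energy),
        Feature("first", _f_first),
        Feature("last", _f_last),
    ]
    return FeatureBankConfig(features=tuple(feats))


@dataclass(frozen=True)
class FeatureBankConfig:
    """Ordered, uniquely named per-channel feature definitions."""

    features: tuple[Feature, ...]

    def __post_init__(self) -> None:
        names = [f.name for f in self.features]
        if len(set(names)) != len(names):
            raise ValueError("feature names must be unique")

    @property
    def names(self) -> list[str]:
        return [f.name for f in self.features]

    def config_hash(self) -> str:
        return hashlib.sha256(",".join(self.names).encode()).hexdigest()[:12]


def extract_features(
    channel_windows: dict[str, np.ndarray],
    sample_rate: float,
    config: FeatureBankConfig | None = None,
) -> pd.Series:
    """Feature vector for one multichannel window.

    ``channel_windows`` maps channel keys (e.g. ``operative_thigh_gy``)
    to equal-span sample arrays. The output ordering is fixed: sorted
    channel keys x bank order, names ``<channel>__<feature>``.
    """
    config = config or default_feature_bank()
    vals: dict[str, float] = {}
    for key in sorted(channel_windows):
        x = np.asarray(channel_windows[key], dtype=float)
        if len(x) < 2:
            raise ValueError(f"channel {key}: window must hold at least 2 samples")
        for f in config.features:
            vals[f"{key}__{f.name}"] = f.fn(x, sample_rate)
    return pd.Series(vals)


# ---------------------------------------------------------------------------
# Training data assembly


def _channel_key(limb: Limb, loc: SensorLocation, channel: str) -> str:
    return f"{limb.value}_{loc.value}_{channel}"


def _windows_at(sensors: SensorSet, t: float, width: float) -> dict[str, np.ndarray]:
    out = {}
    for (limb, loc), sess in sensors.items():
        w = window_backwards(sess, t, width)
        for c, arr in w.channels.items():
            out[_channel_key(limb, loc, c)] = arr
    return out


@dataclass(frozen=True)
class TrainingSet:
    """Windowed multichannel IMU data paired with target flexion angles."""

    windows: list[dict[str, np.ndarray]] = field(repr=False)
    targets: np.ndarray
    sample_rate: float
    window_width: float = 1.0

    def __post_init__(self) -> None:
        if len(self.windows) != len(self.targets):
            raise ValueError("one target per window required")
        if not np.all(np.isfinite(self.targets)):
            raise ValueError("targets must be finite")

    def __len__(self) -> int:
        return len(self.windows)

    def split(self, holdout_frac: float = 0.25) -> tuple["TrainingSet", "TrainingSet"]:
        """Contiguous-block split: last fraction held out (no temporal leakage)."""
        k = int(round(len(self) * (1 - holdout_frac)))
        k = max(1, min(k, len(self) - 1))
        return (
            TrainingSet(self.windows[:k], self.targets[:k], self.sample_rate, self.window_width),
            TrainingSet(self.windows[k:], self.targets[k:], self.sample_rate, self.window_width),
        )


def build_training_set(
    sensors: SensorSet,
    trace: pd.DataFrame,
    window_width: float = 1.0,
    hop: float = 0.25,
) -> TrainingSet:
    """Pair backward windows with target angles at subsampled trace times.

    Targets come from a (typically 100 Hz) flexion trace; windows are
    anchored at target timestamps at least ``window_width`` into the
    recording, thinned to one per ``hop`` seconds. The IMU data are not
    resampled.
    """
    any_sess = next(iter(sensors.values()))
    fs = any_sess.sample_rate
    t0 = any_sess.start_time
    windows, targets = [], []
    next_t = t0 + window_width
    for t, angle in zip(trace["time"].to_numpy(), trace["flexion_deg"].to_numpy()):
        if t < next_t - 1e-9:
            continue
        windows.append(_windows_at(sensors, t, window_width))
        targets.append(angle)
        next_t = t + hop
    return TrainingSet(windows, np.asarray(targets, dtype=float), fs, window_width)


def _feature_matrix(ts: TrainingSet, config: FeatureBankConfig) -> pd.DataFrame:
    rows = [extract_features(w, ts.sample_rate, config) for w in ts.windows]
    return pd.DataFrame(rows).reset_index(drop=True)


# ---------------------------------------------------------------------------
# Feature selection


def select_significant_features(
    features: pd.DataFrame, targets: np.ndarray, fdr_alpha: float = 0.05
) -> list[str]:
    """Names of features significantly rank-associated with the target.

    Each feature gets a Spearman correlation test against the target;
    p-values are corrected with the Benjamini-Yekutieli procedure
    (valid under arbitrary dependence) at ``fdr_alpha``. Constant
    features are never selected. Returns names in the input column
    order; warns when nothing survives.
    """
    if len(features) < 10:
        raise ValueError(f"need >= 10 rows to test significance, got {len(features)}")
    targets = np.asarray(targets, dtype=float)
    names, pvals = [], []
    for col in features.columns:
        x = features[col].to_numpy(dtype=float)
        if np.ptp(x) == 0 or np.ptp(targets) == 0:
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rho, p = stats.spearmanr(x, targets)
        if np.isfinite(p):
            names.append(col)
            pvals.append(p)
    if not names:
        warnings.warn("no testable (non-constant) features; empty selection", stacklevel=2)
        return []
    reject, *_ = multipletests(pvals, alpha=fdr_alpha, method="fdr_by")
    selected = [n for n, r in zip(names, reject) if r]
    if not selected:
        warnings.warn("no features passed FDR control; empty selection", stacklevel=2)
    return selected


# ---------------------------------------------------------------------------
# Model


@dataclass
class SurrogateModel:
    """A trained patient-specific flexion estimator."""

    feature_names: list[str]
    estimator: RandomForestRegressor = field(repr=False)
    target_range: tuple[float, float]
    bank: FeatureBankConfig = field(repr=False)
    window_width: float
    seed: int
    patient_id: str = ""
    config_hash: str = ""

    @property
    def required_sensors(self) -> set[tuple[Limb, SensorLocation]]:
        out = set()
        for limb in Limb:
            for loc in SensorLocation:
                prefix = _channel_key(limb, loc, "")
                if any(name.startswith(prefix) for name in self.feature_names):
                    out.add((limb, loc))
        return out


def train_surrogate(
    training: TrainingSet,
    config: FeatureBankConfig | None = None,
    top_k: int = 200,
    seed: int = 0,
    n_trees: int = 200,
    fdr_alpha: float = 0.05,
    patient_id: str = "",
) -> SurrogateModel:
    """Fit the full pipeline: extract, select, fit, rank, reduce, refit.

    The forest uses ``n_trees`` bootstrap trees, unlimited depth and
    sqrt-p feature subsampling, all seeded; feature-importance ranking
    keeps at most ``top_k`` of the significant features before the
    final refit. Fully deterministic given the data and seed.
    """
    if top_k < 1:
        raise ValueError("top_k must be >= 1")
    if len(training) < 10:
        raise ValueError(f"need at least 10 training windows, got {len(training)}")
    config = config or default_feature_bank()
    X = _feature_matrix(training, config)
    y = training.targets

    selected = select_significant_features(X, y, fdr_alpha=fdr_alpha)
    if not selected:
        # fall back to all non-constant features so a model always exists
        selected = [c for c in X.columns if np.ptp(X[c].to_numpy()) > 0]
        if not selected:
            raise ValueError("all features constant; cannot train")

    def _fit(cols: list[str]) -> RandomForestRegressor:
        rf = RandomForestRegressor(
            n_estimators=n_trees,
            max_depth=None,
            max_features="sqrt",
            bootstrap=True,
            random_state=seed,
            n_jobs=1,
        )
        rf.fit(X[cols].to_numpy(), y)
        return rf

    rf_full = _fit(selected)
    if len(selected) > top_k:
        order = np.argsort(rf_full.feature_importances_)[::-1]
        kept = [selected[i] for i in sorted(order[:top_k])]  # keep stable order
        rf = _fit(kept)
    else:
        kept, rf = selected, rf_full

    return SurrogateModel(
        feature_names=kept,
        estimator=rf,
        target_range=(float(np.min(y)), float(np.max(y))),
        bank=config,
        window_width=training.window_width,
        seed=seed,
        patient_id=patient_id,
        config_hash=config.config_hash(),
    )


def _predict_matrix(model: SurrogateModel, ts: TrainingSet) -> np.ndarray:
    X = _feature_matrix(ts, model.bank)
    return model.estimator.predict(X[model.feature_names].to_numpy())


def predict_training(model: SurrogateModel, ts: TrainingSet) -> np.ndarray:
    """Predict flexion angles for an assembled window set (e.g. a held-out block)."""
    return _predict_matrix(model, ts)


# ---------------------------------------------------------------------------
# Prediction over sessions


class FlexionTrace(pd.DataFrame):
    """Estimated flexion-angle trace: columns time, angle_deg, activity."""

    @property
    def _constructor(self):
        return FlexionTrace


def predict_flexion(
    model: SurrogateModel,
    sensors: SensorSet,
    hop: float = 0.1,
    activity: str = "walk",
) -> FlexionTrace:
    """Slide the model over a session set at a fixed window hop.

    Raises when a sensor the model's features require is absent (e.g. a
    missing thigh sensor). Tree ensembles average training targets, so
    estimates always lie within the model's training target range.
    """
    missing = model.required_sensors - set(sensors)
    if missing:
        pretty = sorted(f"{l.value}/{s.value}" for l, s in missing)
        raise ValueError(f"session set lacks required sensors: {pretty}")
    any_sess = next(iter(sensors.values()))
    t0, dur = any_sess.start_time, any_sess.duration
    t_ends = np.arange(t0 + model.window_width, t0 + dur + 1e-9, hop)
    windows = [_windows_at(sensors, t, model.window_width) for t in t_ends]
    ts = TrainingSet(windows, np.zeros(len(windows)), any_sess.sample_rate, model.window_width)
    angles = _predict_matrix(model, ts)
    return FlexionTrace(
        {"time": t_ends, "angle_deg": angles, "activity": activity}
    )


def max_flexion(trace: pd.DataFrame, activity: str | None = None) -> float:
    """Maximum estimated flexion angle (deg), optionally for one activity."""
    df = trace
    if activity is not None:
        df = df[df["activity"] == activity]
    if len(df) == 0:
        raise ValueError(
            f"no trace samples{f' for activity {activity!r}' if activity else ''}"
        )
    col = "angle_deg" if "angle_deg" in df.columns else "flexion_deg"
    return float(df[col].max())


# ---------------------------------------------------------------------------
# Serialization


def save_model(model: SurrogateModel, path: str | Path) -> None:
    """Write a versioned model archive (pickle; includes trees, features, seeds)."""
    payload = {"format_version": MODEL_FORMAT_VERSION, "model": model}
    Path(path).write_bytes(pickle.dumps(payload))


def load_model(path: str | Path) -> SurrogateModel:
    payload = pickle.loads(Path(path).read_bytes())
    if payload.get("format_version") != MODEL_FORMAT_VERSION:
        raise ValueError(f"unsupported model format: {payload.get('format_version')}")
    return payload["model"]
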