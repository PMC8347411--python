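"""Data model and I/O for multichannel IMU recordings.

A recording session is six uniformly sampled channels from one sensor:
tri-axial acceleration in g and tri-axial angular velocity in deg/s,
nominally at 1149 Hz, with metadata identifying the patient, the week of
the recovery schedule, the limb (operative / non-operative) and the body
location of the sensor (ankle or thigh).
"""

from __future__ import annotations

import enum
import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "WeekLabel",
    "Limb",
    "SensorLocation",
    "ImuSession",
    "Window",
    "SessionParseError",
    "read_session_csv",
    "write_session_csv",
    "resultant_acceleration",
    "window_backwards",
]

CSV_HEADER = "time,ax,ay,az,gx,gy,gz"
CHANNEL_NAMES = ("ax", "ay", "az", "gx", "gy", "gz")

#: Relative jitter in the sample spacing tolerated before warning.
RATE_JITTER_TOL = 0.01


class WeekLabel(enum.Enum):
    """Time points of the monitoring schedule, in chronological order."""

    PREOP = "preop"
    W2 = "W2"
    W3 = "W3"
    W4 = "W4"
    W5 = "W5"
    W6 = "W6"
    W12 = "W12"

    @property
    def order(self) -> int:
        return list(WeekLabel).index(self)

    @classmethod
    def from_string(cls, s: str) -> "WeekLabel":
        for w in cls:
            if w.value.lower() == s.lower():
                return w
        raise ValueError(f"unknown week label: {s!r}")


class Limb(enum.Enum):
    OPERATIVE = "operative"
    NON_OPERATIVE = "non_operative"


class SensorLocation(enum.Enum):
    ANKLE = "ankle"
    THIGH = "thigh"


class SessionParseError(ValueError):
    """Raised when a session CSV cannot be parsed into a valid session."""


@dataclass(frozen=True)
class ImuSession:
    """One sensor's recording: six equal-length uniform-rate channels.

    Attributes
    ----------
    channels : dict
        Maps ``ax, ay, az`` (g) and ``gx, gy, gz`` (deg/s) to 1-d float
        arrays of equal length.
    sample_rate : float
        Samples per second, > 0.
    start_time : float
        Time of the first sample, in seconds.
    """

    channels: dict[str, np.ndarray]
    sample_rate: float
    patient_id: str = ""
    week_label: WeekLabel | None = None
    limb: Limb | None = None
    location: SensorLocation | None = None
    start_time: float = 0.0

    def __post_init__(self) -> None:
        if self.sample_rate <= 0:
            raise ValueError(f"sample_rate must be > 0, got {self.sample_rate}")
        missing = set(CHANNEL_NAMES) - set(self.channels)
        if missing:
            raise ValueError(f"missing channels: {sorted(missing)}")
        lengths = {len(self.channels[c]) for c in CHANNEL_NAMES}
        if len(lengths) != 1:
            raise ValueError(f"channels have unequal lengths: {sorted(lengths)}")
        if lengths.pop() < 1:
            raise ValueError("channels must contain at least one sample")
        object.__setattr__(
            self,
            "channels",
            {c: np.asarray(self.channels[c], dtype=float) for c in CHANNEL_NAMES},
        )

    @property
    def n_samples(self) -> int:
        return len(self.channels["ax"])

    @property
    def duration(self) -> float:
        return self.n_samples / self.sample_rate

    @property
    def times(self) -> np.ndarray:
        return self.start_time + np.arange(self.n_samples) / self.sample_rate

    def with_metadata(self, **kwargs) -> "ImuSession":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class Window:
    """A backward-looking slice of a session: samples in ``(end_time - width, end_time]``."""

    end_time: float
    width: float
    channels: dict[str, np.ndarray] = field(repr=False)
    sample_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError("window width must be > 0")

    @property
    def n_samples(self) -> int:
        return len(next(iter(self.channels.values())))


def resultant_acceleration(session: ImuSession) -> np.ndarray:
    """Per-sample Euclidean norm of the three acceleration channels, in g."""
    return np.sqrt(
        session.channels["ax"] ** 2
        + session.channels["ay"] ** 2
        + session.channels["az"] ** 2
    )


def window_backwards(session: ImuSession, t: float, width: float = 1.0) -> Window:
    """Slice all channels over the half-open interval ``(t - width, t]``.

    Consecutive windows at ``t`` and ``t + width`` partition the series
    without sample duplication. At 1149 Hz and width 1 s a window holds
    1149 samples.
    """
    if width <= 0:
        raise ValueError("width must be > 0")
    if t - width < session.start_time - 0.5 / session.sample_rate:
        raise ValueError(
            f"window ({t - width:.6g}, {t:.6g}] starts before the session "
            f"(start_time {session.start_time:.6g})"
        )
    # Sample i has time start + i/rate; keep i with t-width < time <= t.
    # Work on indices to avoid float-accumulation artifacts at the edges.
    lo = int(np.floor((t - width - session.start_time) * session.sample_rate + 1e-9)) + 1
    hi = int(np.floor((t - session.start_time) * session.sample_rate + 1e-9)) + 1
    lo = max(lo, 0)
    hi = min(hi, session.n_samples)
    if hi <= lo:
        raise ValueError(f"window ({t - width:.6g}, {t:.6g}] contains no samples")
    return Window(
        end_time=t,
        width=width,
        channels={c: session.channels[c][lo:hi] for c in CHANNEL_NAMES},
        sample_rate=session.sample_rate,
    )


def write_session_csv(session: ImuSession, path: str | Path) -> None:
    """Write the session in the project CSV dialect (full double precision)."""
    path = Path(path)
    df = pd.DataFrame({"time": session.times})
    for c in CHANNEL_NAMES:
        df[c] = session.channels[c]
    df.to_csv(path, index=False, float_format="%.17g")
    meta = {
        "patient_id": session.patient_id,
        "week_label": session.week_label.value if session.week_label else None,
        "limb": session.limb.value if session.limb else None,
        "location": session.location.value if session.location else None,
        "sample_rate": session.sample_rate,
        "start_time": session.start_time,
    }
    path.with_suffix(path.suffix + ".meta.json").write_text(json.dumps(meta, indent=1))


def read_session_csv(path: str | Path, metadata: dict | None = None) -> ImuSession:
    """Read a session CSV (header ``time,ax,ay,az,gx,gy,gz``).

    The sample rate is inferred from the median time step; jitter above
    1% of the median step triggers a warning. ``metadata`` overrides any
    sidecar ``.meta.json`` next to the file.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.EmptyDataError as exc:
        raise SessionParseError(f"{path}: empty file") from exc
    except pd.errors.ParserError as exc:
        raise SessionParseError(f"{path}: {exc}") from exc

    expected = CSV_HEADER.split(",")
    if list(df.columns) != expected:
        raise SessionParseError(
            f"{path}: expected header {CSV_HEADER!r}, got {','.join(map(str, df.columns))!r}"
        )
    if len(df) < 1:
        raise SessionParseError(f"{path}: no data rows")
    for col in expected:
        bad = df[col].isna()
        if bad.any():
            row = int(bad.idxmax()) + 2  # 1-based, counting the header line
            raise SessionParseError(f"{path}: missing/unparsable value in column {col}, row {row}")
    t = df["time"].to_numpy(dtype=float)
    dt = np.diff(t)
    if len(dt) and (dt <= 0).any():
        row = int(np.argmax(dt <= 0)) + 3
        raise SessionParseError(f"{path}: non-monotonic time at row {row}")

    if len(dt):
        med = float(np.median(dt))
        rate = 1.0 / med
        if np.abs(dt - med).max() > RATE_JITTER_TOL * med:
            warnings.warn(
                f"{path}: sample-time jitter exceeds {RATE_JITTER_TOL:.0%} of the "
                "median step; inferred rate may be unreliable",
                stacklevel=2,
            )
    else:
        rate = 1.0

    meta = {}
    sidecar = path.with_suffix(path.suffix + ".meta.json")
    if sidecar.exists():
        meta.update({k: v for k, v in json.loads(sidecar.read_text()).items() if v is not None})
    if metadata:
        meta.update(metadata)

    kwargs: dict = {}
    if "patient_id" in meta:
        kwargs["patient_id"] = meta["patient_id"]
    if meta.get("week_label"):
        wl = meta["week_label"]
        kwargs["week_label"] = wl if isinstance(wl, WeekLabel) else WeekLabel.from_string(wl)
    if meta.get("limb"):
        lb = meta["limb"]
        kwargs["limb"] = lb if isinstance(lb, Limb) else Limb(lb)
    if meta.get("location"):
        loc = meta["location"]
        kwargs["location"] = loc if isinstance(loc, SensorLocation) else SensorLocation(loc)

    return ImuSession(
        channels={c: df[c].to_numpy(dtype=float) for c in CHANNEL_NAMES},
        sample_rate=meta.get("sample_rate", rate),
        start_time=float(t[0]),
        **kwargs,
    )
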