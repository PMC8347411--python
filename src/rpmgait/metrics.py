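"""Cumulative-load metrics per limb-session and weekly cohort aggregates.

Three metrics summarise a limb's loading over a recording session:

* **Impact load** — the g-weighted step count ``sum_x x * n_x`` over
  integer impact levels x = 1..200 g, where ``n_x`` is the number of
  steps whose peak resultant acceleration fell in level x.
* **Bone Stimulus** — ``(sum_j n_j * sigma_j**m) ** (1 / (2m))``, a
  daily-stress-style stimulus in which sigma_j is the peak tibial
  acceleration of impact group j and n_j its cycle count. The exponent
  m (default 4) encodes that bone adapts far more to load magnitude
  than to cycle count.
* **Impact-load asymmetry** — the normalised between-limb difference of
  mean load per step, in percent: negative when the non-operative limb
  carries more load per step than the operative one.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .impacts import ImpactEvent, ImpactHistogram, bin_impacts
from .session import WeekLabel

__all__ = [
    "BoneStimulusConfig",
    "ExponentForm",
    "SessionMetrics",
    "AsymmetryResult",
    "WeeklySummary",
    "impact_load",
    "bone_stimulus",
    "impact_load_asymmetry",
    "session_metrics",
    "weekly_trajectory",
]


class ExponentForm(enum.Enum):
    """Root applied to the cumulative stimulus sum: 1/(2m) or 1/m."""

    INVERSE_2M = "inverse_2m"
    INVERSE_M = "inverse_m"


@dataclass(frozen=True)
class BoneStimulusConfig:
    """Bone-response exponent m (> 0, default 4) and the root convention."""

    m: float = 4.0
    exponent_form: ExponentForm = ExponentForm.INVERSE_2M

    def __post_init__(self) -> None:
        if self.m <= 0:
            raise ValueError(f"bone-response exponent m must be > 0, got {self.m}")

    @property
    def root(self) -> float:
        return 1.0 / (2.0 * self.m) if self.exponent_form is ExponentForm.INVERSE_2M else 1.0 / self.m


@dataclass(frozen=True)
class SessionMetrics:
    """Load metrics for one limb over one recording session."""

    impact_load: float
    bone_stimulus: float
    step_count: int
    mean_load_per_step: float

    def __post_init__(self) -> None:
        if self.impact_load < 0 or self.bone_stimulus < 0 or self.step_count < 0:
            raise ValueError("metrics must be non-negative")
        if self.step_count > 0:
            expected = self.impact_load / self.step_count
            if not np.isclose(self.mean_load_per_step, expected):
                raise ValueError(
                    "mean_load_per_step must equal impact_load / step_count"
                )


@dataclass(frozen=True)
class AsymmetryResult:
    """Between-limb impact-load asymmetry, percent in [-100, 100]."""

    il_operative_mean: float
    il_nonoperative_mean: float
    asymmetry_pct: float


def impact_load(hist: ImpactHistogram) -> float:
    """Weighted step count ``sum_{x=1..200} x * n_x`` in g-weighted steps."""
    return float(sum(x * n for x, n in hist.counts.items()))


def bone_stimulus(
    events: list[ImpactEvent] | ImpactHistogram,
    config: BoneStimulusConfig | None = None,
) -> float:
    """Cumulative bone stimulus ``(sum_j n_j sigma_j^m) ** root``.

    Accepts either raw events (each an independent unit cycle, exact
    peaks) or a histogram (peaks grouped at integer-g resolution,
    sigma_j = level, n_j = count). Returns 0 for no events.
    """
    config = config or BoneStimulusConfig()
    if isinstance(events, ImpactHistogram):
        pairs = [(float(x), n) for x, n in events.counts.items()]
    else:
        pairs = [(ev.peak, 1) for ev in events]
    total = sum(n * sigma**config.m for sigma, n in pairs)
    if total == 0:
        return 0.0
    return float(total**config.root)


def impact_load_asymmetry(op: SessionMetrics, nonop: SessionMetrics) -> AsymmetryResult:
    """Normalised between-limb difference of mean load per step, x100.

    ``(IL_op - IL_nonop) / (IL_op + IL_nonop) * 100`` on the per-step
    means; negative when the non-operative limb carries more per-step
    load. Undefined (raises) when either limb has no steps — zero would
    wrongly read as perfect symmetry.
    """
    if op.step_count == 0 or nonop.step_count == 0:
        raise ValueError(
            "asymmetry is undefined when a limb has no detected steps "
            f"(operative: {op.step_count}, non-operative: {nonop.step_count})"
        )
    a, b = op.mean_load_per_step, nonop.mean_load_per_step
    pct = (a - b) / (a + b) * 100.0 if (a + b) > 0 else 0.0
    return AsymmetryResult(
        il_operative_mean=a, il_nonoperative_mean=b, asymmetry_pct=float(pct)
    )


def session_metrics(
    events: list[ImpactEvent],
    config: BoneStimulusConfig | None = None,
    use_raw_events: bool = False,
) -> SessionMetrics:
    """Bundle impact load, Bone Stimulus and step statistics for one limb-session.

    ``use_raw_events=True`` computes Bone Stimulus from exact peaks
    instead of the integer-g histogram grouping.
    """
    hist = bin_impacts(events)
    il = impact_load(hist)
    bs = bone_stimulus(
        [ev for ev in events if ev.peak >= 1.0] if use_raw_events else hist, config
    )
    n = hist.total_steps
    return SessionMetrics(
        impact_load=il,
        bone_stimulus=bs,
        step_count=n,
        mean_load_per_step=il / n if n else 0.0,
    )


@dataclass(frozen=True)
class WeeklySummary:
    """Per-week cohort mean +/- SD (n-1 denominator) for one metric."""

    week_label: WeekLabel
    metric: str
    mean: float
    sd: float
    n: int


def weekly_trajectory(
    cohort: pd.DataFrame, metrics: list[str] | None = None
) -> list[WeeklySummary]:
    """Aggregate per-patient per-week metric values into weekly mean +/- SD.

    ``cohort`` is tidy: one row per (patient_id, week, metric value),
    with columns ``patient_id``, ``week`` (WeekLabel or its string
    value) and one column per metric. A patient missing a week is
    simply absent from that week's n. Sample SD uses the n-1
    denominator; a single-patient week reports SD 0 with a warning.
    """
    if len(cohort) == 0:
        raise ValueError("empty cohort")
    df = cohort.copy()
    df["week"] = df["week"].map(
        lambda w: w if isinstance(w, WeekLabel) else WeekLabel.from_string(str(w))
    )
    if metrics is None:
        metrics = [c for c in df.columns if c not in ("patient_id", "week")]
    out: list[WeeklySummary] = []
    degenerate: list[str] = []
    for week in sorted(df["week"].unique(), key=lambda w: w.order):
        sub = df[df["week"] == week]
        for metric in metrics:
            vals = sub[metric].dropna().to_numpy(dtype=float)
            if len(vals) == 0:
                continue
            if len(vals) == 1:
                degenerate.append(f"{week.value}/{metric}")
                sd = 0.0
            else:
                sd = float(np.std(vals, ddof=1))
            out.append(
                WeeklySummary(
                    week_label=week,
                    metric=metric,
                    mean=float(np.mean(vals)),
                    sd=sd,
                    n=len(vals),
                )
            )
    if degenerate:
        warnings.warn(
            f"single-patient week/metric cells report SD 0: {', '.join(degenerate)}",
            stacklevel=2,
        )
    return out
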