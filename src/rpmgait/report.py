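"""Recovery-trajectory reporting: patient timelines and cohort tables.

Weekly PROMs scores and IMU load metrics are merged into per-patient
timelines and summarised cohort-wide as per-week mean +/- SD with
change-from-baseline columns. Two change conventions are emitted side
by side, explicitly labeled, because both appear in clinical reporting:

* ``pct_change``  = (value - baseline) / baseline * 100  (difference)
* ``ratio_pct``   = value / baseline * 100               (ratio)

They differ by exactly 100 points. PROMs are referenced to the
pre-operative baseline; IMU metrics, which have no pre-operative
recording, to post-operative Week 2.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .metrics import WeeklySummary, weekly_trajectory
from .proms import Eq5dTariff, score_eq5d_index, score_oks
from .session import WeekLabel

__all__ = [
    "percent_change",
    "ratio_percent",
    "PatientTimeline",
    "build_timeline",
    "cohort_report",
    "write_report",
    "study_weekly_means",
    "PROM_METRICS",
    "IMU_METRICS",
]

PROM_METRICS = ("oks", "eq5d_index", "eq_vas")
IMU_METRICS = ("impact_load", "bone_stimulus", "step_count", "asymmetry_pct")

OKS_ITEM_COLS = [f"oks_{i}" for i in range(1, 13)]


def percent_change(baseline: float, value: float) -> float:
    """Difference-based change: ``(value - baseline) / baseline * 100``."""
    if baseline == 0:
        raise ZeroDivisionError("percent change undefined for a zero baseline")
    return (value - baseline) / baseline * 100.0


def ratio_percent(baseline: float, value: float) -> float:
    """Ratio-based change: ``value / baseline * 100``; equals percent_change + 100."""
    if baseline == 0:
        raise ZeroDivisionError("ratio percent undefined for a zero baseline")
    return value / baseline * 100.0


def study_weekly_means() -> pd.DataFrame:
    """Published weekly cohort means +/- SD from the 14-patient pilot study.

    Columns metric, week, mean, sd. These are reference *inputs* for
    report arithmetic and formatting; the underlying raw recordings are
    not public, so they cannot be recomputed here.
    """
    with resources.as_file(
        resources.files("rpmgait.data").joinpath("study_weekly_means.csv")
    ) as p:
        return pd.read_csv(p)


@dataclass(frozen=True)
class PatientTimeline:
    """Week-ordered merged record for one patient.

    ``data`` is indexed by week label string in schedule order, one
    column per metric; weeks inside the observed span with no record
    appear as all-NaN rows (explicit gaps, never imputed).
    """

    patient_id: str
    data: pd.DataFrame = field(repr=False)

    @property
    def missing_weeks(self) -> list[str]:
        return [str(w) for w in self.data.index[self.data.isna().all(axis=1)]]


def _normalise_week(w) -> WeekLabel:
    return w if isinstance(w, WeekLabel) else WeekLabel.from_string(str(w))


def _score_proms_frame(proms: pd.DataFrame, tariff: Eq5dTariff | None) -> pd.DataFrame:
    """Reduce raw questionnaire columns to oks / eq5d_index / eq_vas scores."""
    out = pd.DataFrame({"patient_id": proms["patient_id"].astype(str)})
    out["week"] = proms["week"].map(_normalise_week)
    if set(OKS_ITEM_COLS) <= set(proms.columns):
        out["oks"] = [
            score_oks([int(v) for v in row]) for row in proms[OKS_ITEM_COLS].to_numpy()
        ]
    elif "oks" in proms.columns:
        out["oks"] = proms["oks"].astype(float).to_numpy()
    if "eq5d_state" in proms.columns:
        out["eq5d_index"] = [
            score_eq5d_index(str(s), tariff) for s in proms["eq5d_state"]
        ]
    elif "eq5d_index" in proms.columns:
        out["eq5d_index"] = proms["eq5d_index"].astype(float).to_numpy()
    if "eq_vas" in proms.columns:
        out["eq_vas"] = proms["eq_vas"].astype(float).to_numpy()
    return out


def build_timeline(
    proms_records: pd.DataFrame | None,
    metrics_records: pd.DataFrame | None,
    patient_id: str | None = None,
    tariff: Eq5dTariff | None = None,
) -> PatientTimeline:
    """Merge PROMs and IMU-metric records into one week-ordered timeline.

    ``proms_records`` may carry raw item columns (``oks_1..oks_12``,
    ``eq5d_state``, ``eq_vas``) or pre-scored columns; ``metrics_records``
    is tidy with ``patient_id``, ``week`` and metric columns. Records
    must agree on the patient; duplicate week entries that conflict
    raise. The merge result does not depend on input row order.
    """
    frames = []
    if proms_records is not None and len(proms_records):
        frames.append(_score_proms_frame(proms_records, tariff))
    if metrics_records is not None and len(metrics_records):
        m = metrics_records.copy()
        m["patient_id"] = m["patient_id"].astype(str)
        m["week"] = m["week"].map(_normalise_week)
        frames.append(m)
    if not frames:
        raise ValueError("no records supplied")

    pids = set().union(*(set(f["patient_id"]) for f in frames))
    if patient_id is not None:
        frames = [f[f["patient_id"] == str(patient_id)] for f in frames]
        pids = {str(patient_id)}
    if len(pids) != 1:
        raise ValueError(f"records span multiple patients: {sorted(pids)}; pass patient_id")
    pid = pids.pop()

    merged: dict[WeekLabel, dict[str, float]] = {}
    for f in frames:
        for _, row in f.iterrows():
            week = row["week"]
            entry = merged.setdefault(week, {})
            for col, val in row.items():
                if col in ("patient_id", "week") or pd.isna(val):
                    continue
                if col in entry and not np.isclose(entry[col], float(val)):
                    raise ValueError(
                        f"conflicting duplicate entries for patient {pid}, "
                        f"week {week.value}, metric {col}: {entry[col]} vs {val}"
                    )
                entry[col] = float(val)

    observed = sorted(merged, key=lambda w: w.order)
    span = [w for w in WeekLabel if observed[0].order <= w.order <= observed[-1].order]
    cols = sorted({c for e in merged.values() for c in e})
    data = pd.DataFrame(
        [[merged.get(w, {}).get(c, np.nan) for c in cols] for w in span],
        index=pd.Index([w.value for w in span], name="week"),
        columns=cols,
    )
    return PatientTimeline(patient_id=pid, data=data)


def _summaries_frame(summaries: list[WeeklySummary]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "week": s.week_label.value,
                "metric": s.metric,
                "mean": s.mean,
                "sd": s.sd,
                "n": s.n,
            }
            for s in summaries
        ]
    )


def cohort_report(
    timelines: list[PatientTimeline],
    prom_metrics: tuple[str, ...] = PROM_METRICS,
    imu_metrics: tuple[str, ...] = IMU_METRICS,
) -> dict[str, pd.DataFrame]:
    """Cohort tables: weekly mean +/- SD and change-from-baseline columns.

    Returns ``{"summary": ..., "changes": ...}``. Changes are computed
    on weekly cohort means — PROMs against the pre-operative week, IMU
    metrics against Week 2 — in both labeled conventions, with
    display-rounded percent columns (nearest integer, matching how such
    figures are customarily quoted). Weeks with no baseline available
    yield no change rows. Pure: identical inputs give identical tables.
    """
    if not timelines:
        raise ValueError("empty cohort")
    rows = []
    for tl in timelines:
        for week, row in tl.data.iterrows():
            r = {"patient_id": tl.patient_id, "week": week}
            r.update(row.to_dict())
            rows.append(r)
    tidy = pd.DataFrame(rows)
    value_cols = [c for c in tidy.columns if c not in ("patient_id", "week")]
    summary = _summaries_frame(weekly_trajectory(tidy, metrics=value_cols))

    baselines = {m: WeekLabel.PREOP.value for m in prom_metrics}
    baselines.update({m: WeekLabel.W2.value for m in imu_metrics})

    change_rows = []
    for metric in value_cols:
        base_week = baselines.get(metric)
        if base_week is None:
            continue
        sub = summary[summary["metric"] == metric].set_index("week")
        if base_week not in sub.index:
            continue
        base = float(sub.loc[base_week, "mean"])
        for week, row in sub.iterrows():
            if week == base_week or base == 0:
                continue
            pc = percent_change(base, float(row["mean"]))
            rp = ratio_percent(base, float(row["mean"]))
            change_rows.append(
                {
                    "metric": metric,
                    "baseline_week": base_week,
                    "week": week,
                    "baseline_mean": base,
                    "mean": float(row["mean"]),
                    "abs_change": float(row["mean"]) - base,
                    "pct_change": pc,
                    "ratio_pct": rp,
                    "pct_change_display": int(round(pc)),
                    "ratio_pct_display": int(round(rp)),
                }
            )
    changes = pd.DataFrame(change_rows)
    return {"summary": summary, "changes": changes}


def write_report(report: dict[str, pd.DataFrame], outdir: str | Path) -> list[Path]:
    """Write each report table as CSV and JSON (byte-deterministic)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    for name, df in report.items():
        csv_path = outdir / f"{name}.csv"
        df.to_csv(csv_path, index=False, float_format="%.10g")
        json_path = outdir / f"{name}.json"
        json_path.write_text(
            json.dumps(df.to_dict(orient="records"), indent=1, default=float)
        )
        written += [csv_path, json_path]
    return written
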