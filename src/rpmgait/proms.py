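"""Patient-reported outcome scoring: OKS, EQ-5D-3L index and EQ-VAS.

The Oxford Knee Score (OKS) is a 12-item knee-specific instrument, each
item scored 0-4 (4 = best) and summed to 0-48. The EQ-5D-3L describes
health on five dimensions (mobility, self-care, usual activities,
pain/discomfort, anxiety/depression) at three levels each — 243
states — and a country-specific tariff maps each state to a utility
index anchored at 1.0 for full health (state 11111). The shipped
default is the UK time-trade-off value set; other additive tariffs can
be loaded from the same TSV format. The EQ visual analogue scale
(EQ-VAS) is the patient's 0-100 self-rating and needs no scoring.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "OksResponse",
    "Eq5dState",
    "Eq5dTariff",
    "load_uk_tariff",
    "load_tariff",
    "score_oks",
    "score_eq5d_index",
]

EQ5D_DIMENSIONS = ("MO", "SC", "UA", "PD", "AD")


@dataclass(frozen=True)
class OksResponse:
    """Twelve item responses, each an integer 0-4 (4 = best)."""

    items: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.items) != 12:
            raise ValueError(f"OKS has exactly 12 items, got {len(self.items)}")
        for i, v in enumerate(self.items, start=1):
            if not (isinstance(v, (int, np.integer)) and 0 <= v <= 4):
                raise ValueError(f"OKS item {i} must be an integer in 0..4, got {v!r}")


@dataclass(frozen=True)
class Eq5dState:
    """A 5-digit health state, each digit in {1, 2, 3}."""

    digits: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.digits) != 5:
            raise ValueError(f"EQ-5D state has 5 digits, got {len(self.digits)}")
        for dim, d in zip(EQ5D_DIMENSIONS, self.digits):
            if d not in (1, 2, 3):
                raise ValueError(f"dimension {dim}: level must be 1, 2 or 3, got {d!r}")

    @classmethod
    def from_string(cls, s: str) -> "Eq5dState":
        s = str(s).strip()
        if len(s) != 5 or not s.isdigit():
            raise ValueError(f"EQ-5D state must be 5 digits, got {s!r}")
        return cls(tuple(int(c) for c in s))

    def __str__(self) -> str:
        return "".join(map(str, self.digits))


@dataclass(frozen=True)
class Eq5dTariff:
    """Additive decrement tariff for the 3-level descriptive system.

    index = 1.0
            - constant            (once, if any dimension > level 1)
            - sum of per-dimension per-level decrements
            - any_level3          (once, if any dimension = level 3)
    """

    name: str
    constant: float
    decrements: dict[str, float]  # keys like "MO2", "PD3"
    any_level3: float

    def __post_init__(self) -> None:
        for dim in EQ5D_DIMENSIONS:
            for level in (2, 3):
                if f"{dim}{level}" not in self.decrements:
                    raise ValueError(f"tariff {self.name}: missing decrement {dim}{level}")


def load_tariff(path: str | Path, name: str | None = None) -> Eq5dTariff:
    """Load a tariff from a two-column TSV (term, decrement; '#' comments)."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", comment="#")
    if list(df.columns) != ["term", "decrement"]:
        raise ValueError(f"{path}: expected columns term, decrement")
    table = dict(zip(df["term"], df["decrement"].astype(float)))
    try:
        constant = table.pop("constant")
        any3 = table.pop("N3")
    except KeyError as exc:
        raise ValueError(f"{path}: tariff must define 'constant' and 'N3'") from exc
    return Eq5dTariff(
        name=name or path.stem, constant=constant, decrements=table, any_level3=any3
    )


def load_uk_tariff() -> Eq5dTariff:
    """The shipped UK time-trade-off value set."""
    with resources.as_file(
        resources.files("rpmgait.data").joinpath("eq5d_uk_tariff.tsv")
    ) as p:
        return load_tariff(p, name="UK-TTO")


def score_oks(resp: OksResponse | list[int] | tuple[int, ...]) -> int:
    """Sum the 12 items: 0 (worst) to 48 (best)."""
    if not isinstance(resp, OksResponse):
        resp = OksResponse(tuple(resp))
    return int(sum(resp.items))


def score_eq5d_index(
    state: Eq5dState | str, tariff: Eq5dTariff | None = None
) -> float:
    """Map a health state to its tariff utility index.

    1.0 for 11111; monotone non-increasing as any dimension worsens.
    The UK tariff's floor (33333) is -0.594: states valued worse than
    dead are legal.
    """
    if not isinstance(state, Eq5dState):
        state = Eq5dState.from_string(state)
    tariff = tariff or load_uk_tariff()
    if all(d == 1 for d in state.digits):
        return 1.0
    value = 1.0 - tariff.constant
    for dim, d in zip(EQ5D_DIMENSIONS, state.digits):
        if d > 1:
            value -= tariff.decrements[f"{dim}{d}"]
    if any(d == 3 for d in state.digits):
        value -= tariff.any_level3
    return float(value)
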