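"""Premature-death outcome from a sex x age period life table.

A participant's actuarial life expectancy (ALE) at baseline is read off a
period life table by sex and *completed* age (floor of the exact age, the
convention period life tables are indexed by).  A death is premature when the
participant died at least a buffer period (default nine months) before their
ALE, i.e. ``excess = ALE - years_survived >= buffer``; a death inside the
buffer is not counted, which guards against classifying minor discrepancies
as premature mortality.  Alive-at-censor participants are never premature but
stay in the data matrix (they contribute to the not-psi side).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import LifeTableLookupError, ValidationError

__all__ = [
    "BufferSpec",
    "LifeTable",
    "OutcomeRecord",
    "lookup_ale",
    "classify_premature",
    "compute_outcomes",
    "buffer_sensitivity",
    "DIED",
    "ALIVE",
]

DIED = "died"
ALIVE = "alive_at_censor"
_SEXES = ("male", "female")


@dataclass(frozen=True)
class BufferSpec:
    """Tolerance before ALE below which a death is not premature."""

    months: int = 9

    def __post_init__(self) -> None:
        if int(self.months) != self.months or not 1 <= self.months <= 120:
            raise ValidationError(
                f"buffer must be an integer number of months in 1..120, got {self.months}"
            )

    @property
    def years(self) -> float:
        return self.months / 12.0


class LifeTable:
    """Remaining life expectancy (years) keyed by (sex, completed age)."""

    def __init__(self, entries: Mapping[tuple[str, int], float]):
        self._entries: dict[tuple[str, int], float] = {}
        for (sex, age), ale in entries.items():
            if sex not in _SEXES:
                raise ValidationError(f"sex must be one of {_SEXES}, got {sex!r}")
            if ale < 0:
                raise ValidationError(
                    f"life expectancy must be nonnegative, got {ale} for ({sex}, {age})"
                )
            self._entries[(sex, int(age))] = float(ale)
        if not self._entries:
            raise ValidationError("life table has no entries")

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "LifeTable":
        required = {"sex", "age", "ex"}
        if not required.issubset(df.columns):
            raise ValidationError(
                f"life-table frame needs columns {sorted(required)}, got {list(df.columns)}"
            )
        return cls(
            {
                (str(row.sex), int(row.age)): float(row.ex)
                for row in df.itertuples(index=False)
            }
        )

    @classmethod
    def from_csv(cls, path) -> "LifeTable":
        return cls.from_frame(pd.read_csv(path))

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"sex": sex, "age": age, "ex": ale}
            for (sex, age), ale in sorted(self._entries.items())
        ]
        return pd.DataFrame(rows, columns=["sex", "age", "ex"])

    def lookup(self, sex: str, age_at_baseline: float) -> float:
        """ALE for the participant's sex and completed age (floor of age)."""
        key = (sex, math.floor(age_at_baseline))
        try:
            return self._entries[key]
        except KeyError:
            raise LifeTableLookupError(
                f"no life-table entry for sex={sex!r}, completed age={key[1]}"
            ) from None


def lookup_ale(life_table: LifeTable, sex: str, age_at_baseline: float) -> float:
    """Functional alias for :meth:`LifeTable.lookup`."""
    return life_table.lookup(sex, age_at_baseline)


@dataclass(frozen=True)
class OutcomeRecord:
    participant_id: str
    sex: str
    age_at_baseline: float
    vital_status: str
    years_survived: float
    ale: float
    excess: float | None  # ALE minus years survived; defined for the died
    premature: bool


def classify_premature(
    participant_id,
    sex: str,
    age_at_baseline: float,
    vital_status: str,
    years_survived: float,
    ale: float,
    buffer: BufferSpec = BufferSpec(),
) -> OutcomeRecord:
    """Classify one participant.

    Premature iff died and ``ale - years_survived >= buffer.years`` — a death
    exactly at the buffer IS premature (the buffer excludes deaths *less*
    than the buffer before ALE).
    """
    if years_survived < 0:
        raise ValidationError(
            f"years_survived must be nonnegative, got {years_survived} "
            f"for participant {participant_id!r}"
        )
    if vital_status not in (DIED, ALIVE):
        raise ValidationError(
            f"vital_status must be {DIED!r} or {ALIVE!r}, got {vital_status!r}"
        )
    if vital_status == DIED:
        excess = ale - years_survived
        premature = excess >= buffer.years
    else:
        excess = None
        premature = False
    return OutcomeRecord(
        participant_id=str(participant_id),
        sex=sex,
        age_at_baseline=float(age_at_baseline),
        vital_status=vital_status,
        years_survived=float(years_survived),
        ale=float(ale),
        excess=excess,
        premature=premature,
    )


def compute_outcomes(
    cohort: pd.DataFrame,
    life_table: LifeTable,
    buffer: BufferSpec = BufferSpec(),
) -> pd.DataFrame:
    """Outcome table (id, ale, years_survived, excess, premature) for a cohort.

    The cohort frame needs columns id, sex, age, vital_status, years_survived.
    Row order is preserved; the classification is a pure function of each row.
    """
    required = {"id", "sex", "age", "vital_status", "years_survived"}
    if not required.issubset(cohort.columns):
        raise ValidationError(
            f"cohort frame needs columns {sorted(required)}, got {list(cohort.columns)}"
        )
    records = [
        classify_premature(
            row.id, row.sex, row.age, row.vital_status, row.years_survived,
            life_table.lookup(row.sex, row.age), buffer,
        )
        for row in cohort.itertuples(index=False)
    ]
    return pd.DataFrame(
        {
            "id": [r.participant_id for r in records],
            "sex": [r.sex for r in records],
            "age": [r.age_at_baseline for r in records],
            "vital_status": [r.vital_status for r in records],
            "years_survived": [r.years_survived for r in records],
            "ale": [r.ale for r in records],
            "excess": [r.excess for r in records],
            "premature": [r.premature for r in records],
        }
    )


def buffer_sensitivity(
    outcomes: pd.DataFrame,
    buffers: Sequence[BufferSpec] | Iterable[int],
) -> dict:
    """Premature counts/shares per buffer plus adjacent-pair differences.

    ``outcomes`` is the frame from :func:`compute_outcomes` (only
    vital_status and excess are used).  Buffers may be given as BufferSpecs
    or month integers; the report is ordered by increasing buffer.  Because
    the premature sets are nested, counts are non-increasing in the buffer.
    """
    specs = [b if isinstance(b, BufferSpec) else BufferSpec(int(b)) for b in buffers]
    if not specs:
        raise ValidationError("at least one buffer is required")
    specs = sorted(specs, key=lambda b: b.months)
    died = outcomes[outcomes["vital_status"] == DIED]
    n_deaths = len(died)
    per_buffer = []
    for spec in specs:
        count = int((died["excess"] >= spec.years).sum())
        share = count / n_deaths if n_deaths else 0.0
        per_buffer.append(
            {"months": spec.months, "premature_count": count, "share_of_deaths": share}
        )
    diffs = [
        {
            "pair_months": [lo["months"], hi["months"]],
            "diff_pp": abs(lo["share_of_deaths"] - hi["share_of_deaths"]) * 100.0,
        }
        for lo, hi in zip(per_buffer, per_buffer[1:])
    ]
    return {
        "n_deaths": n_deaths,
        "buffers": per_buffer,
        "adjacent_differences": diffs,
    }


def write_sensitivity_report(report: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
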