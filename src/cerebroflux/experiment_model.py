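"""Domain model for the six-phase haemorrhagic-shock / aortic-occlusion experiment.

The experiment timeline is encoded in minutes relative to T0, the moment of
aortic balloon inflation.  Negative times are legal: the default protocol runs
from T-90 (start of stabilisation) through bleeding (T-30..0), two hours of
occlusion (0..120) and 15 minutes of reperfusion (120..135), sampled manually
every five minutes, which gives 46 gridded timepoints.

Monitoring traces are exchanged as a long-format CSV with header

    animal_id,group,weight_kg,time_min,pmap_mmHg,icp_mmHg[,cvp_mmHg,hr_bpm]

where an empty cell is an explicit missing value (never silently zero).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CerebrofluxError",
    "ValidationError",
    "CohortFormatError",
    "ConfigurationError",
    "Group",
    "PhaseSchedule",
    "HemodynamicSample",
    "AnimalRecord",
    "CohortTable",
    "phase_of",
    "read_cohort_csv",
    "write_cohort_csv",
    "validate_record",
]


class CerebrofluxError(Exception):
    """Base class for all package errors."""


class ValidationError(CerebrofluxError, ValueError):
    """Input violates a domain invariant."""


class CohortFormatError(CerebrofluxError, ValueError):
    """A cohort CSV file does not follow the long-format contract."""


class ConfigurationError(CerebrofluxError, ValueError):
    """Inconsistent configuration (e.g. grid step vs index interval)."""


class Group(str, Enum):
    """Study arm: normal vs elevated (epidural-mass-induced) intracranial pressure."""

    NICPG = "NICPG"
    EICPG = "EICPG"

    @classmethod
    def parse(cls, label: "str | Group") -> "Group":
        if isinstance(label, cls):
            return label
        try:
            return cls[str(label).strip().upper()]
        except KeyError:
            raise ValidationError(
                f"unknown group label {label!r}; expected NICPG or EICPG"
            ) from None


PHASES = ("stabilisation", "bleeding", "occlusion", "reperfusion")


@dataclass(frozen=True)
class PhaseSchedule:
    """Boundaries of the experimental phases, in minutes relative to occlusion.

    Phase intervals are half-open ``[start, next_start)``; the terminal sample
    at ``end`` belongs to reperfusion.  All boundaries must sit on the sampling
    grid (integer multiples of ``step``).
    """

    stabilisation_start: float = -90.0
    bleeding_start: float = -30.0
    occlusion_start: float = 0.0
    reperfusion_start: float = 120.0
    end: float = 135.0
    step: float = 5.0

    def __post_init__(self) -> None:
        bounds = (
            self.stabilisation_start,
            self.bleeding_start,
            self.occlusion_start,
            self.reperfusion_start,
            self.end,
        )
        if not all(b < c for b, c in zip(bounds, bounds[1:])):
            raise ValidationError(f"phase boundaries must be strictly increasing, got {bounds}")
        if self.step <= 0:
            raise ValidationError(f"step must be positive, got {self.step}")
        for b in bounds:
            if not math.isclose(b / self.step, round(b / self.step), abs_tol=1e-9):
                raise ValidationError(
                    f"boundary {b} is not an integer multiple of step {self.step}"
                )

    def grid(self) -> np.ndarray:
        """The full sampling grid, ``stabilisation_start..end`` inclusive."""
        n = round((self.end - self.stabilisation_start) / self.step) + 1
        return self.stabilisation_start + self.step * np.arange(n)

    def on_grid(self, time: float) -> bool:
        q = (time - self.stabilisation_start) / self.step
        return bool(
            math.isclose(q, round(q), abs_tol=1e-9)
            and self.stabilisation_start - 1e-9 <= time <= self.end + 1e-9
        )

    def contains(self, time: float) -> bool:
        return self.stabilisation_start - 1e-9 <= time <= self.end + 1e-9


def phase_of(schedule: PhaseSchedule, time: float) -> str:
    """Label the phase a timepoint belongs to.

    Intervals are half-open at the right boundary; the final sample at
    ``schedule.end`` is assigned to reperfusion.
    """
    if not schedule.contains(time):
        raise ValidationError(
            f"time {time} min is outside the schedule "
            f"[{schedule.stabilisation_start}, {schedule.end}]"
        )
    if time < schedule.bleeding_start:
        return "stabilisation"
    if time < schedule.occlusion_start:
        return "bleeding"
    if time < schedule.reperfusion_start:
        return "occlusion"
    return "reperfusion"


def _finite_or_none(value: Optional[float], name: str) -> None:
    if value is not None and not math.isfinite(value):
        raise ValidationError(f"{name} must be finite or None (missing), got {value}")


@dataclass
class HemodynamicSample:
    """One timestamped observation: proximal MAP and ICP in mmHg.

    ``None`` marks an explicitly missing measurement; optional central venous
    pressure and heart rate are carried as pass-through fields.
    """

    time: float
    pmap: Optional[float]
    icp: Optional[float]
    cvp: Optional[float] = None
    hr: Optional[float] = None

    def __post_init__(self) -> None:
        if not math.isfinite(self.time):
            raise ValidationError(f"sample time must be finite, got {self.time}")
        _finite_or_none(self.pmap, "pmap")
        _finite_or_none(self.icp, "icp")
        _finite_or_none(self.cvp, "cvp")
        _finite_or_none(self.hr, "hr")


@dataclass
class AnimalRecord:
    """One animal: identity, study arm, weight, and its ordered sample series."""

    animal_id: str
    group: Group
    weight_kg: float
    samples: list[HemodynamicSample] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.group = Group.parse(self.group) if not isinstance(self.group, Group) else self.group
        if self.weight_kg <= 0:
            raise ValidationError(
                f"animal {self.animal_id}: weight must be positive, got {self.weight_kg}"
            )
        times = [s.time for s in self.samples]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValidationError(f"animal {self.animal_id}: sample times must strictly increase")

    def times(self) -> np.ndarray:
        return np.array([s.time for s in self.samples], dtype=float)

    def channel(self, name: str) -> np.ndarray:
        """A channel as a float array with NaN for missing values."""
        if name not in ("pmap", "icp", "cvp", "hr"):
            raise ValidationError(f"unknown channel {name!r}")
        return np.array(
            [math.nan if getattr(s, name) is None else getattr(s, name) for s in self.samples],
            dtype=float,
        )


@dataclass
class CohortTable:
    """All animals of one experiment plus the schedule they were sampled on."""

    animals: list[AnimalRecord]
    schedule: PhaseSchedule = field(default_factory=PhaseSchedule)

    def __post_init__(self) -> None:
        ids = [a.animal_id for a in self.animals]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate animal_ids: {dupes}")

    def by_group(self, group: Group) -> list[AnimalRecord]:
        group = Group.parse(group) if not isinstance(group, Group) else group
        return [a for a in self.animals if a.group is group]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CohortTable):
            return NotImplemented
        return self.animals == other.animals and self.schedule == other.schedule


def validate_record(record: AnimalRecord, schedule: PhaseSchedule) -> list[str]:
    """Collect invariant violations (empty list means the record is clean).

    Violations are returned, not raised, so a whole cohort can be screened in
    one pass.
    """
    violations: list[str] = []
    if record.weight_kg <= 0:
        violations.append(f"{record.animal_id}: weight {record.weight_kg} kg is not positive")
    times = [s.time for s in record.samples]
    for a, b in zip(times, times[1:]):
        if b <= a:
            violations.append(f"{record.animal_id}: times not strictly increasing at {b}")
    for t in times:
        if not schedule.contains(t):
            violations.append(
                f"{record.animal_id}: time {t} outside schedule "
                f"[{schedule.stabilisation_start}, {schedule.end}]"
            )
        elif not schedule.on_grid(t):
            violations.append(
                f"{record.animal_id}: time {t} is off the {schedule.step}-min grid"
            )
    return violations


_REQUIRED_COLUMNS = ["animal_id", "group", "weight_kg", "time_min", "pmap_mmHg", "icp_mmHg"]
_OPTIONAL_COLUMNS = ["cvp_mmHg", "hr_bpm"]


def _parse_cell(raw: str, column: str, row: int) -> Optional[float]:
    raw = raw.strip()
    if raw == "":
        return None
    try:
        return float(raw)
    except ValueError:
        raise CohortFormatError(
            f"row {row}: non-numeric value {raw!r} in column {column}"
        ) from None


def read_cohort_csv(path: str | Path, schedule: Optional[PhaseSchedule] = None) -> CohortTable:
    """Read a long-format monitoring CSV into a :class:`CohortTable`.

    Empty pressure cells become explicit missing values.  Rows are sorted by
    (animal_id, time).  Unknown group labels, duplicated (animal_id, time)
    pairs and non-numeric pressures raise :class:`CohortFormatError` naming
    the offending row (1-based, counting the header as row 1).
    """
    schedule = schedule or PhaseSchedule()
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing_cols = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing_cols:
        raise CohortFormatError(f"missing required columns: {missing_cols}")
    has_cvp = "cvp_mmHg" in df.columns
    has_hr = "hr_bpm" in df.columns

    rows: dict[str, list[tuple[int, HemodynamicSample]]] = {}
    meta: dict[str, tuple[Group, float]] = {}
    seen: set[tuple[str, float]] = set()
    for i, row in enumerate(df.itertuples(index=False)):
        rownum = i + 2  # header is row 1
        animal_id = str(row.animal_id).strip()
        group = Group.parse(getattr(row, "group"))
        weight = _parse_cell(str(row.weight_kg), "weight_kg", rownum)
        time = _parse_cell(str(row.time_min), "time_min", rownum)
        if weight is None or time is None:
            raise CohortFormatError(f"row {rownum}: weight_kg and time_min may not be empty")
        key = (animal_id, time)
        if key in seen:
            raise CohortFormatError(f"row {rownum}: duplicate (animal_id, time) = {key}")
        seen.add(key)
        sample = HemodynamicSample(
            time=time,
            pmap=_parse_cell(str(row.pmap_mmHg), "pmap_mmHg", rownum),
            icp=_parse_cell(str(row.icp_mmHg), "icp_mmHg", rownum),
            cvp=_parse_cell(str(row.cvp_mmHg), "cvp_mmHg", rownum) if has_cvp else None,
            hr=_parse_cell(str(row.hr_bpm), "hr_bpm", rownum) if has_hr else None,
        )
        if animal_id in meta and meta[animal_id] != (group, weight):
            raise CohortFormatError(
                f"row {rownum}: inconsistent group/weight for animal {animal_id}"
            )
        meta[animal_id] = (group, weight)
        rows.setdefault(animal_id, []).append((rownum, sample))

    animals = []
    for animal_id in sorted(rows):
        group, weight = meta[animal_id]
        samples = [s for _, s in sorted(rows[animal_id], key=lambda p: p[1].time)]
        animals.append(AnimalRecord(animal_id, group, weight, samples))
    return CohortTable(animals=animals, schedule=schedule)


def write_cohort_csv(cohort: CohortTable, path: str | Path) -> None:
    """Write a cohort as the long-format CSV dialect.

    Optional columns are emitted only when at least one sample carries them;
    floats are written at full precision so a read-back round trip is exact.
    """
    any_cvp = any(s.cvp is not None for a in cohort.animals for s in a.samples)
    any_hr = any(s.hr is not None for a in cohort.animals for s in a.samples)
    columns = list(_REQUIRED_COLUMNS)
    if any_cvp:
        columns.append("cvp_mmHg")
    if any_hr:
        columns.append("hr_bpm")

    def fmt(v: Optional[float]) -> str:
        return "" if v is None else repr(float(v))

    records = []
    for animal in cohort.animals:
        for s in animal.samples:
            rec = {
                "animal_id": animal.animal_id,
                "group": animal.group.value,
                "weight_kg": fmt(animal.weight_kg),
                "time_min": fmt(s.time),
                "pmap_mmHg": fmt(s.pmap),
                "icp_mmHg": fmt(s.icp),
            }
            if any_cvp:
                rec["cvp_mmHg"] = fmt(s.cvp)
            if any_hr:
                rec["hr_bpm"] = fmt(s.hr)
            records.append(rec)
    pd.DataFrame.from_records(records, columns=columns).to_csv(path, index=False)


def cohort_to_frame(cohort: CohortTable) -> pd.DataFrame:
    """Flatten a cohort into a tidy DataFrame (NaN marks missing values)."""
    rows = []
    for animal in cohort.animals:
        for s in animal.samples:
            rows.append(
                {
                    "animal_id": animal.animal_id,
                    "group": animal.group.value,
                    "weight_kg": animal.weight_kg,
                    "time_min": s.time,
                    "pmap_mmHg": math.nan if s.pmap is None else s.pmap,
                    "icp_mmHg": math.nan if s.icp is None else s.icp,
                    "phase": phase_of(cohort.schedule, s.time),
                }
            )
    return pd.DataFrame(rows)
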