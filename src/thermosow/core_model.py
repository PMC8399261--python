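"""Domain types and CSV readers/writers shared by all pipeline stages.

Two plain-text exchange formats are used throughout:

* germination CSV — ``species,day_temp,night_temp,replicate,day,cumulative_pct``
  with one row per (condition, replicate, day);
* climate CSV — ``date,tmax,tmin,precip`` with ISO-8601 dates and an
  optional (possibly empty) precipitation column in mm.

Temperatures are °C, germination is on the 0–100 percentage scale.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from datetime import date as Date
from typing import NamedTuple, Optional, Sequence

import numpy as np
import pandas as pd

GERMINATION_COLUMNS = ["species", "day_temp", "night_temp", "replicate", "day", "cumulative_pct"]
CLIMATE_COLUMNS = ["date", "tmax", "tmin", "precip"]


class ValidationError(ValueError):
    """Input violates a domain invariant (e.g. non-monotone germination)."""


class FormatError(ValueError):
    """Input file does not follow the expected CSV layout."""


@dataclass(frozen=True, order=True)
class TemperatureCondition:
    """A day/night temperature pair of a controlled germination trial.

    The daily mean temperature (DMT) and daily temperature range (DTR) are
    derived quantities: DMT = (day + night)/2, DTR = day − night.
    """

    day_temp: float
    night_temp: float
    photoperiod_light_h: float = 12.0

    def __post_init__(self) -> None:
        if not (math.isfinite(self.day_temp) and math.isfinite(self.night_temp)):
            raise ValidationError("temperatures must be finite")
        if self.day_temp < self.night_temp:
            raise ValidationError(
                f"day_temp {self.day_temp} < night_temp {self.night_temp}"
            )
        if not 0 < self.photoperiod_light_h <= 24:
            raise ValidationError("photoperiod must be in (0, 24] h")

    def dmt(self) -> float:
        return (self.day_temp + self.night_temp) / 2.0

    def dtr(self) -> float:
        return self.day_temp - self.night_temp

    def label(self) -> str:
        return f"{self.day_temp:g}/{self.night_temp:g}"


@dataclass
class GerminationTimecourse:
    """Daily cumulative germination percentages of one replicate dish."""

    condition: TemperatureCondition
    replicate_id: int
    cumulative_pct: np.ndarray  # indexed by day 1..D
    n_seeds: Optional[int] = None

    def __post_init__(self) -> None:
        self.cumulative_pct = np.asarray(self.cumulative_pct, dtype=float)
        if self.cumulative_pct.ndim != 1 or self.cumulative_pct.size < 1:
            raise ValidationError("cumulative_pct must be a non-empty 1-D sequence")
        if np.any(~np.isfinite(self.cumulative_pct)):
            raise ValidationError("cumulative_pct contains non-finite values")
        if np.any(self.cumulative_pct < 0) or np.any(self.cumulative_pct > 100):
            raise ValidationError("cumulative_pct outside [0, 100]")
        if np.any(np.diff(self.cumulative_pct) < 0):
            day = int(np.argmax(np.diff(self.cumulative_pct) < 0)) + 2
            raise ValidationError(
                f"cumulative_pct decreases at day {day} "
                f"(condition {self.condition.label()}, replicate {self.replicate_id})"
            )

    @property
    def n_days(self) -> int:
        return int(self.cumulative_pct.size)


@dataclass
class GerminationDataset:
    """All timecourses of one species' factorial germination trial."""

    species_label: str
    timecourses: list[GerminationTimecourse] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.timecourses:
            raise ValidationError("dataset must contain at least one timecourse")
        counts = {c: 0 for c in self.conditions()}
        for tc in self.timecourses:
            counts[tc.condition] += 1
        if len(set(counts.values())) != 1:
            raise ValidationError(
                f"unequal replicate counts per condition: {counts}"
            )

    def conditions(self) -> list[TemperatureCondition]:
        """Distinct conditions sorted by (dmt, dtr)."""
        seen = {tc.condition for tc in self.timecourses}
        return sorted(seen, key=lambda c: (c.dmt(), c.dtr()))

    def replicates(self, condition: TemperatureCondition) -> list[GerminationTimecourse]:
        return [tc for tc in self.timecourses if tc.condition == condition]

    @property
    def n_replicates(self) -> int:
        return len(self.replicates(self.conditions()[0]))

    def mean_cumulative_pct(self, condition: TemperatureCondition) -> np.ndarray:
        """Replicate-mean cumulative germination, indexed by day 1..D."""
        reps = self.replicates(condition)
        return np.mean([tc.cumulative_pct for tc in reps], axis=0)


@dataclass(frozen=True)
class ClimateDay:
    """One day of a site's climate record."""

    date: Date
    tmax: float
    tmin: float
    precip: Optional[float] = None

    def __post_init__(self) -> None:
        if self.tmax < self.tmin:
            raise ValidationError(f"{self.date}: tmax {self.tmax} < tmin {self.tmin}")
        if self.precip is not None and self.precip < 0:
            raise ValidationError(f"{self.date}: negative precipitation")

    def dmt(self) -> float:
        return (self.tmax + self.tmin) / 2.0

    def dtr(self) -> float:
        return self.tmax - self.tmin


@dataclass
class ClimateSeries:
    """Date-ordered daily climate record of one site."""

    site_label: str
    days: list[ClimateDay]

    def __post_init__(self) -> None:
        if not self.days:
            raise ValidationError("climate series is empty")
        self.days = sorted(self.days, key=lambda d: d.date)
        dates = [d.date for d in self.days]
        if len(set(dates)) != len(dates):
            dup = next(d for i, d in enumerate(dates) if d in dates[:i])
            raise ValidationError(f"duplicate date {dup}")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "date": [d.date for d in self.days],
                "tmax": [d.tmax for d in self.days],
                "tmin": [d.tmin for d in self.days],
                "precip": [d.precip for d in self.days],
                "dmt": [d.dmt() for d in self.days],
                "dtr": [d.dtr() for d in self.days],
            }
        )

    def years(self) -> list[int]:
        return sorted({d.date.year for d in self.days})


# ---------------------------------------------------------------------------
# CSV I/O


def read_germination_csv(path) -> GerminationDataset:
    """Read a germination trial CSV into a validated :class:`GerminationDataset`.

    Rows are grouped into one timecourse per (condition, replicate) and
    sorted by day; gaps in day numbering are rejected.
    """
    df = pd.read_csv(path)
    required = [c for c in GERMINATION_COLUMNS if c != "species"] + ["species"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"germination CSV missing columns: {missing}")
    species = df["species"].unique()
    if len(species) != 1:
        raise FormatError(f"expected a single species per file, found {list(species)}")

    timecourses = []
    for (day_t, night_t, rep), grp in df.groupby(
        ["day_temp", "night_temp", "replicate"], sort=True
    ):
        grp = grp.sort_values("day")
        days = grp["day"].to_numpy()
        if not np.array_equal(days, np.arange(1, len(days) + 1)):
            raise FormatError(
                f"condition {day_t}/{night_t} replicate {rep}: days must be 1..D "
                f"without gaps, got {days.tolist()}"
            )
        n_seeds = None
        if "n_seeds" in grp.columns and grp["n_seeds"].notna().all():
            n_seeds = int(grp["n_seeds"].iloc[0])
        timecourses.append(
            GerminationTimecourse(
                condition=TemperatureCondition(float(day_t), float(night_t)),
                replicate_id=int(rep),
                cumulative_pct=grp["cumulative_pct"].to_numpy(dtype=float),
                n_seeds=n_seeds,
            )
        )
    return GerminationDataset(species_label=str(species[0]), timecourses=timecourses)


def write_germination_csv(ds: GerminationDataset, path) -> None:
    """Write a dataset in the germination CSV dialect (0.1 precision)."""
    rows = []
    for tc in ds.timecourses:
        for day, pct in enumerate(tc.cumulative_pct, start=1):
            row = {
                "species": ds.species_label,
                "day_temp": round(tc.condition.day_temp, 1),
                "night_temp": round(tc.condition.night_temp, 1),
                "replicate": tc.replicate_id,
                "day": day,
                "cumulative_pct": round(float(pct), 1),
            }
            if tc.n_seeds is not None:
                row["n_seeds"] = tc.n_seeds
            rows.append(row)
    df = pd.DataFrame(rows).sort_values(  # canonical row order for round-trips
        ["day_temp", "night_temp", "replicate", "day"]
    )
    df.to_csv(path, index=False)


def read_climate_csv(path, site_label: str = "site") -> ClimateSeries:
    """Read a daily climate CSV (``date,tmax,tmin,precip``) into a series."""
    df = pd.read_csv(path)
    missing = [c for c in ("date", "tmax", "tmin") if c not in df.columns]
    if missing:
        raise FormatError(f"climate CSV missing columns: {missing}")
    try:
        dates = pd.to_datetime(df["date"], format="ISO8601").dt.date
    except (ValueError, TypeError) as exc:
        raise FormatError(f"unparseable date in climate CSV: {exc}") from exc
    days = []
    for i, d in enumerate(dates):
        precip = None
        if "precip" in df.columns and pd.notna(df["precip"].iloc[i]):
            precip = float(df["precip"].iloc[i])
        days.append(
            ClimateDay(
                date=d,
                tmax=float(df["tmax"].iloc[i]),
                tmin=float(df["tmin"].iloc[i]),
                precip=precip,
            )
        )
    return ClimateSeries(site_label=site_label, days=days)


def write_climate_csv(series: ClimateSeries, path) -> None:
    """Write a climate series in the climate CSV dialect (0.1 precision)."""
    df = pd.DataFrame(
        {
            "date": [d.date.isoformat() for d in series.days],
            "tmax": [round(d.tmax, 1) for d in series.days],
            "tmin": [round(d.tmin, 1) for d in series.days],
            "precip": [
                "" if d.precip is None else round(d.precip, 2) for d in series.days
            ],
        }
    )
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Final germination


class FinalGermination(NamedTuple):
    value: float
    day: int  # 1-based day on which the final value was first reached
    stabilized: bool


def final_germination(
    tc: GerminationTimecourse, stability_days: int = 5
) -> FinalGermination:
    """Final germination percentage of a timecourse.

    Returns the cumulative percentage on the first day after which the value
    remains unchanged for more than ``stability_days`` further observed days
    (and through the end of the record). If the course never stabilizes, the
    final-day value is returned with ``stabilized=False`` and a warning.
    """
    pct = tc.cumulative_pct
    n = pct.size
    if n <= stability_days:
        raise ValidationError(
            f"timecourse of length {n} too short for stability_days={stability_days}"
        )
    # first index of the constant tail
    i = n - 1
    while i > 0 and pct[i - 1] == pct[n - 1]:
        i -= 1
    tail_days_after = n - 1 - i
    if tail_days_after > stability_days:
        return FinalGermination(value=float(pct[i]), day=i + 1, stabilized=True)
    warnings.warn(
        f"germination did not stabilize within the {n}-day window "
        f"(condition {tc.condition.label()}, replicate {tc.replicate_id}); "
        "returning the final-day value",
        stacklevel=2,
    )
    return FinalGermination(value=float(pct[-1]), day=n, stabilized=False)


def dataset_to_frame(ds: GerminationDataset) -> pd.DataFrame:
    """Long-format view of a dataset with derived dmt/dtr columns."""
    rows = []
    for tc in ds.timecourses:
        for day, pct in enumerate(tc.cumulative_pct, start=1):
            rows.append(
                {
                    "species": ds.species_label,
                    "day_temp": tc.condition.day_temp,
                    "night_temp": tc.condition.night_temp,
                    "dmt": tc.condition.dmt(),
                    "dtr": tc.condition.dtr(),
                    "replicate": tc.replicate_id,
                    "day": day,
                    "cumulative_pct": float(pct),
                }
            )
    return pd.DataFrame(rows)
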