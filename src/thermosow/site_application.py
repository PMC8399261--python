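"""Apply a fitted temperature-score model to a daily climate series.

The site stage turns a multi-year climate record into sowing guidance:

* daily TS for every climate day (:func:`score_series`);
* the *accumulation period* — the longest run of favourable (TS > 0) days
  in each year, intersected across years (:func:`accumulation_period`);
* the mean first date at which an early sowing accumulates the species'
  cumulative-TS requirement, and the mean last date from which the rest of
  the season can still supply it;
* climate and precipitation summaries, monsoon (rainy-season) detection
  from monthly totals, and the final sowing window — from the accumulation
  start to one calendar month before the rainy month begins.

Negative daily TS are floored at zero during accumulation by default:
unfavourable days cannot undo germination that has already happened. Day-of
-year arithmetic uses a non-leap reference calendar (Feb 29 shares day 60
with Mar 1) so years can be averaged; this carries a ±1-day ambiguity in
leap years.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from datetime import date as Date, timedelta
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .core_model import ClimateSeries, ValidationError
from .ts_model import SpeciesTSModel, daily_ts

logger = logging.getLogger(__name__)

_REF_YEAR = 2001  # any non-leap year


def ref_doy(d: Date) -> int:
    """Day-of-year on a non-leap reference calendar (Feb 29 → 60)."""
    if d.month == 2 and d.day == 29:
        return 60
    return Date(_REF_YEAR, d.month, d.day).timetuple().tm_yday


def doy_to_date(doy: int, year: int) -> Date:
    """Invert :func:`ref_doy` into the given calendar year."""
    ref = Date(_REF_YEAR, 1, 1) + timedelta(days=int(doy) - 1)
    return Date(year, ref.month, ref.day)


_doy_to_date = doy_to_date


@dataclass
class DailyScoreSeries:
    """Per-day temperature scores of one species at one site."""

    species_label: str
    frame: pd.DataFrame  # columns: date, year, doy, dmt, dtr, ts

    def years(self) -> list[int]:
        return sorted(self.frame["year"].unique().tolist())


@dataclass
class AccumulationPeriod:
    start_doy: int
    end_doy: int
    by_year: dict[int, tuple[int, int]]


@dataclass
class RequirementDates:
    mean_doy: int
    by_year: dict[int, Optional[int]]
    missed_years: list[int] = field(default_factory=list)


@dataclass
class ClimateSummary:
    max_tmax: float
    min_tmin: float
    max_dmt: float
    min_dmt: float
    mean_dmt: float
    max_dtr: float
    min_dtr: float
    mean_dtr: float


@dataclass
class RainySeason:
    month: int  # 1..12
    is_rainy: bool
    ratio_to_previous: float


@dataclass
class SowingReport:
    species_label: str
    accumulation_start_doy: int
    accumulation_end_doy: int
    initial_requirement_doy: int
    last_requirement_doy: int
    rainy_month: int
    window_start: Date
    window_end: Date
    per_year: pd.DataFrame

    def to_text(self) -> str:
        lines = [
            f"Sowing report — {self.species_label}",
            f"  TS accumulation period: "
            f"{_doy_to_date(self.accumulation_start_doy, _REF_YEAR):%d %b} – "
            f"{_doy_to_date(self.accumulation_end_doy, _REF_YEAR):%d %b} "
            f"(doy {self.accumulation_start_doy}–{self.accumulation_end_doy})",
            f"  Initial requirement date (mean): "
            f"{_doy_to_date(self.initial_requirement_doy, _REF_YEAR):%d %b}",
            f"  Last requirement date (mean): "
            f"{_doy_to_date(self.last_requirement_doy, _REF_YEAR):%d %b}",
            f"  Rainy month: {self.rainy_month}",
            f"  Recommended sowing window: {self.window_start:%d %b} – "
            f"{self.window_end:%d %b}",
        ]
        return "\n".join(lines)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "species": self.species_label,
                    "accum_start": self.accumulation_start_doy,
                    "accum_end": self.accumulation_end_doy,
                    "initial_req_doy": self.initial_requirement_doy,
                    "last_req_doy": self.last_requirement_doy,
                    "rainy_month": self.rainy_month,
                    "window_start": self.window_start.isoformat(),
                    "window_end": self.window_end.isoformat(),
                }
            ]
        )


# ---------------------------------------------------------------------------


def score_series(model: SpeciesTSModel, climate: ClimateSeries) -> DailyScoreSeries:
    """Daily TS for every climate day, via the model's weight curves."""
    rows = []
    for day in climate.days:
        rows.append(
            {
                "date": day.date,
                "year": day.date.year,
                "doy": ref_doy(day.date),
                "dmt": day.dmt(),
                "dtr": day.dtr(),
                "ts": daily_ts(model, day.dmt(), day.dtr()),
            }
        )
    return DailyScoreSeries(species_label=model.species_label, frame=pd.DataFrame(rows))


def _longest_run(mask: np.ndarray) -> Optional[tuple[int, int]]:
    """(start, end) indices (inclusive) of the longest True run, or None."""
    best, cur_start, best_len = None, None, 0
    for i, v in enumerate(mask):
        if v and cur_start is None:
            cur_start = i
        elif not v and cur_start is not None:
            if i - cur_start > best_len:
                best, best_len = (cur_start, i - 1), i - cur_start
            cur_start = None
    if cur_start is not None and len(mask) - cur_start > best_len:
        best = (cur_start, len(mask) - 1)
    return best


def _yearly_runs(scores: DailyScoreSeries, min_ts: float) -> dict[int, tuple[int, int]]:
    runs = {}
    for year, grp in scores.frame.groupby("year"):
        grp = grp.sort_values("date")
        run = _longest_run((grp["ts"] > min_ts).to_numpy())
        if run is None:
            raise ValidationError(f"year {year}: no day with ts > {min_ts}")
        doys = grp["doy"].to_numpy()
        runs[int(year)] = (int(doys[run[0]]), int(doys[run[1]]))
    return runs


def accumulation_period(
    scores: DailyScoreSeries, min_ts: float = 0.0
) -> AccumulationPeriod:
    """Longest favourable run per year, intersected across years.

    The common period starts at the latest per-year run start and ends at
    the earliest per-year run end (day-of-year on the non-leap reference).
    """
    runs = _yearly_runs(scores, min_ts)
    start = max(s for s, _ in runs.values())
    end = min(e for _, e in runs.values())
    if start > end:
        raise ValidationError("no common favorable period across years")
    return AccumulationPeriod(start_doy=start, end_doy=end, by_year=runs)


def initial_requirement_date(
    scores: DailyScoreSeries,
    requirement_ts: float,
    sowing_doy: int,
    min_ts: float = 0.0,
    floor_negative: bool = True,
) -> RequirementDates:
    """Mean first date on which an early sowing meets the TS requirement.

    Per year, non-negative daily TS is accumulated from the later of the
    sowing date and the year's favourable-run start; the first date where
    the running sum reaches ``requirement_ts`` is recorded. Years that
    never reach it are excluded from the mean with a warning.
    """
    runs = _yearly_runs(scores, min_ts)
    by_year: dict[int, Optional[int]] = {}
    missed = []
    for year, grp in scores.frame.groupby("year"):
        grp = grp.sort_values("date")
        start = max(int(sowing_doy), runs[int(year)][0])
        sel = grp[grp["doy"] >= start]
        ts = sel["ts"].to_numpy()
        cum = np.cumsum(np.maximum(0.0, ts) if floor_negative else ts)
        hit = np.searchsorted(cum, requirement_ts)
        if requirement_ts <= 0:
            by_year[int(year)] = start
        elif hit < cum.size:
            by_year[int(year)] = int(sel["doy"].to_numpy()[hit])
        else:
            by_year[int(year)] = None
            missed.append(int(year))
    reached = [d for d in by_year.values() if d is not None]
    if not reached:
        raise ValidationError("requirement never reached in any year")
    if missed:
        logger.warning(
            "requirement %s not reached in years %s; excluded from the mean",
            requirement_ts,
            missed,
        )
    return RequirementDates(
        mean_doy=int(np.floor(np.mean(reached) + 0.5)),
        by_year=by_year,
        missed_years=missed,
    )


def last_requirement_date(
    scores: DailyScoreSeries,
    requirement_ts: float,
    min_ts: float = 0.0,
    floor_negative: bool = True,
) -> RequirementDates:
    """Mean latest date from which the rest of the season meets the requirement.

    Per year, the latest date d such that the sum of non-negative TS from d
    through the favourable-run end is still ≥ ``requirement_ts``.
    """
    runs = _yearly_runs(scores, min_ts)
    by_year: dict[int, Optional[int]] = {}
    for year, grp in scores.frame.groupby("year"):
        grp = grp.sort_values("date")
        end = runs[int(year)][1]
        sel = grp[grp["doy"] <= end]
        ts = sel["ts"].to_numpy()
        if floor_negative:
            ts = np.maximum(0.0, ts)
        tail = np.cumsum(ts[::-1])[::-1]  # tail[i] = sum from day i to end
        ok = np.nonzero(tail >= requirement_ts)[0]
        if ok.size == 0:
            raise ValidationError(
                f"year {year}: seasonal total TS {tail[0] if tail.size else 0:.1f} "
                f"below requirement {requirement_ts}"
            )
        by_year[int(year)] = int(sel["doy"].to_numpy()[ok[-1]])
    vals = [v for v in by_year.values() if v is not None]
    return RequirementDates(
        mean_doy=int(np.floor(np.mean(vals) + 0.5)), by_year=by_year
    )


def climate_summary(climate: ClimateSeries) -> ClimateSummary:
    """Site temperature extremes and means, each rounded to 0.1 °C."""
    df = climate.to_frame()
    return ClimateSummary(
        max_tmax=round(float(df["tmax"].max()), 1),
        min_tmin=round(float(df["tmin"].min()), 1),
        max_dmt=round(float(df["dmt"].max()), 1),
        min_dmt=round(float(df["dmt"].min()), 1),
        mean_dmt=round(float(df["dmt"].mean()), 1),
        max_dtr=round(float(df["dtr"].max()), 1),
        min_dtr=round(float(df["dtr"].min()), 1),
        mean_dtr=round(float(df["dtr"].mean()), 1),
    )


def monthly_precipitation(climate: ClimateSeries) -> np.ndarray:
    """Mean monthly accumulated precipitation (mm), Jan..Dec.

    Monthly totals are computed per (year, month) and averaged across the
    years present; days with missing precipitation count as 0 mm (their
    number is logged).
    """
    df = climate.to_frame()
    n_missing = int(df["precip"].isna().sum())
    if n_missing == len(df):
        raise ValidationError("climate series has no precipitation data")
    if n_missing:
        logger.warning("%d days with missing precipitation treated as 0 mm", n_missing)
    df = df.assign(
        precip=df["precip"].fillna(0.0),
        year=[d.year for d in df["date"]],
        month=[d.month for d in df["date"]],
    )
    totals = df.groupby(["year", "month"])["precip"].sum().reset_index()
    means = totals.groupby("month")["precip"].mean()
    out = np.zeros(12)
    for month, value in means.items():
        out[month - 1] = value
    return out


def detect_rainy_season(
    monthly: Sequence[float], ratio_threshold: float = 3.0
) -> RainySeason:
    """Peak-precipitation month, flagged rainy if ≥ threshold × previous month.

    The monsoon signature is a month whose accumulated precipitation is at
    least ``ratio_threshold`` times the preceding month's.
    """
    m = np.asarray(monthly, dtype=float)
    if m.size != 12:
        raise ValidationError("need 12 monthly values")
    if np.all(m == 0):
        raise ValidationError("all-zero monthly precipitation")
    month = int(np.argmax(m)) + 1
    prev = m[(month - 2) % 12]
    ratio = float(m[month - 1] / prev) if prev > 0 else float("inf")
    return RainySeason(
        month=month, is_rainy=bool(ratio >= ratio_threshold), ratio_to_previous=ratio
    )


def sowing_window(
    accum_start_doy: int, rainy_month: int, year: int = _REF_YEAR
) -> tuple[Date, Date]:
    """Sowing window from accumulation start to one month before the rains.

    The cutoff is the first day of the month preceding the rainy month
    ("at least one month before the beginning of the rainy season"); the
    window ends the day before the cutoff. Rainy month July ⇒ cutoff
    June 1 ⇒ window end May 31.
    """
    if not 1 <= rainy_month <= 12:
        raise ValidationError("rainy_month must be 1..12")
    start = _doy_to_date(int(accum_start_doy), year)
    cutoff_month = rainy_month - 1
    cutoff_year = year
    if cutoff_month == 0:
        cutoff_month, cutoff_year = 12, year - 1
    end = Date(cutoff_year, cutoff_month, 1) - timedelta(days=1)
    if start > end:
        raise ValidationError(
            f"no valid sowing window: accumulation starts {start}, cutoff {end}"
        )
    return start, end


def build_sowing_report(
    model: SpeciesTSModel,
    climate: ClimateSeries,
    sowing_doy: int = 91,  # early-April sowing by default
    min_ts: float = 0.0,
    ratio_threshold: float = 3.0,
    floor_negative: bool = True,
    report_year: int = _REF_YEAR,
) -> SowingReport:
    """Full site application of one species' model to one climate record."""
    scores = score_series(model, climate)
    period = accumulation_period(scores, min_ts)
    initial = initial_requirement_date(
        scores, model.requirement_ts, sowing_doy, min_ts, floor_negative
    )
    last = last_requirement_date(scores, model.requirement_ts, min_ts, floor_negative)
    rainy = detect_rainy_season(monthly_precipitation(climate), ratio_threshold)
    window = sowing_window(period.start_doy, rainy.month, report_year)
    per_year = pd.DataFrame(
        [
            {
                "year": y,
                "run_start_doy": period.by_year[y][0],
                "run_end_doy": period.by_year[y][1],
                "initial_req_doy": initial.by_year.get(y),
                "last_req_doy": last.by_year.get(y),
            }
            for y in scores.years()
        ]
    )
    return SowingReport(
        species_label=model.species_label,
        accumulation_start_doy=period.start_doy,
        accumulation_end_doy=period.end_doy,
        initial_requirement_doy=initial.mean_doy,
        last_requirement_doy=last.mean_doy,
        rainy_month=rainy.month,
        window_start=window[0],
        window_end=window[1],
        per_year=per_year,
    )
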