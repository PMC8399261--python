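"""Synthetic germination trials and mountain-site climate series.

The generator plays the role of the wet-lab experiment and the weather
station: it produces (a) a factorial day/night germination trial with a
*known* ground-truth temperature response, so parameter recovery by the
fitting pipeline can be checked, and (b) a multi-year daily climate series
shaped like a Korean temperate mountain site (cold winters, ~8 °C annual
mean, a July monsoon precipitation spike).

Generative model for germination: each condition has a constant true daily
temperature score

    TS_true = a·w_dmt(DMT) + b·w_dtr(DTR) + c,

and the expected cumulative germination after d days is a saturating
exponential in the accumulated (non-negative) score,

    E[G_d] = max_germ · (1 − exp(−rate · max(0, d·TS_true))).

Each seed draws one uniform variate and counts as germinated by day d iff
it falls below E[G_d]/100, which gives monotone cumulative counts with
Binomial(n_seeds, E[G_d]/100) margins.
"""

from __future__ import annotations

import calendar
from dataclasses import dataclass, field
from datetime import date as Date, timedelta
from typing import Callable, Optional, Sequence

import numpy as np

from .core_model import (
    ClimateDay,
    ClimateSeries,
    GerminationDataset,
    GerminationTimecourse,
    TemperatureCondition,
    ValidationError,
)

#: DMT and DTR levels realized by the factorial trial (°C).
DMT_LEVELS = (15.0, 17.5, 20.0, 22.5, 25.0)
DTR_LEVELS = (0.0, 5.0, 10.0, 15.0, 20.0)


@dataclass
class TrueResponse:
    """Ground-truth temperature response used to generate trials."""

    dmt_weight_fn: Callable[[float], float]
    dtr_weight_fn: Callable[[float], float]
    combine_a: float
    combine_b: float
    combine_c: float
    germ_rate_scale: float
    max_germ: float = 95.0

    def __post_init__(self) -> None:
        if not 0 < self.max_germ <= 100:
            raise ValidationError("max_germ must be in (0, 100]")
        if self.germ_rate_scale <= 0:
            raise ValidationError("germ_rate_scale must be positive")

    def daily_ts(self, condition: TemperatureCondition) -> float:
        w1 = self.dmt_weight_fn(condition.dmt())
        w2 = self.dtr_weight_fn(condition.dtr())
        if not (np.isfinite(w1) and np.isfinite(w2)):
            raise ValidationError(
                f"truth weight function non-finite at {condition.label()}"
            )
        return self.combine_a * w1 + self.combine_b * w2 + self.combine_c


def _quadratic_bump(peak: float, half_width: float) -> Callable[[float], float]:
    """Concave parabola equal to 1 at *peak* and 0 at peak ± half_width."""

    def fn(t: float) -> float:
        return 1.0 - ((t - peak) / half_width) ** 2

    return fn


def rugosa_like_response() -> TrueResponse:
    """A species profile preferring warm days and large diurnal swings.

    The DMT optimum sits at 25 °C and the DTR optimum at 20 °C (the warm
    extreme of the tested grid), with germination suppressed at constant
    temperature — the Korean-mint-like pattern.
    """
    return TrueResponse(
        dmt_weight_fn=_quadratic_bump(25.0, 15.0),
        dtr_weight_fn=_quadratic_bump(20.0, 18.0),
        combine_a=3.0,
        combine_b=4.0,
        combine_c=2.0,
        germ_rate_scale=0.02,
        max_germ=95.0,
    )


def rubra_like_response() -> TrueResponse:
    """A species profile preferring cool days; DMT optimum 17.5 °C, DTR 15 °C."""
    return TrueResponse(
        dmt_weight_fn=_quadratic_bump(17.5, 12.0),
        dtr_weight_fn=_quadratic_bump(15.0, 14.0),
        combine_a=3.5,
        combine_b=1.7,
        combine_c=2.5,
        germ_rate_scale=0.018,
        max_germ=92.0,
    )


# ---------------------------------------------------------------------------
# Condition grids


def make_condition_grid(
    day_levels: Sequence[float],
    night_levels: Sequence[float],
    dmt_filter: Optional[Sequence[float]] = None,
    dtr_filter: Optional[Sequence[float]] = None,
) -> list[TemperatureCondition]:
    """All day ≥ night pairs of the given levels, sorted by (dmt, dtr).

    Optional filters restrict the grid to pairs whose derived DMT and DTR
    fall (within 1e-9) in the given level sets, reproducing the level
    structure of a thermal-gradient-plate trial.
    """
    if not day_levels or not night_levels:
        raise ValidationError("temperature level lists must be non-empty")
    conds = {
        TemperatureCondition(float(d), float(n))
        for d in day_levels
        for n in night_levels
        if d >= n
    }

    def in_set(x: float, levels: Sequence[float]) -> bool:
        return any(abs(x - lv) < 1e-9 for lv in levels)

    out = [
        c
        for c in conds
        if (dmt_filter is None or in_set(c.dmt(), dmt_filter))
        and (dtr_filter is None or in_set(c.dtr(), dtr_filter))
    ]
    if not out:
        raise ValidationError("no conditions remain after filtering")
    return sorted(out, key=lambda c: (c.dmt(), c.dtr()))


#: Balanced default trial: each DMT level and each DTR level occurs exactly
#: twice among 10 day/night pairs, including the 25/15 °C optimum.
_DEFAULT_PAIRS = (
    (20.0, 10.0),
    (25.0, 5.0),
    (20.0, 15.0),
    (25.0, 10.0),
    (20.0, 20.0),
    (25.0, 15.0),
    (25.0, 20.0),
    (30.0, 15.0),
    (25.0, 25.0),
    (35.0, 15.0),
)


def default_experiment_conditions() -> list[TemperatureCondition]:
    """The 10-condition factorial trial used by the default pipeline."""
    conds = [TemperatureCondition(d, n) for d, n in _DEFAULT_PAIRS]
    return sorted(conds, key=lambda c: (c.dmt(), c.dtr()))


# ---------------------------------------------------------------------------
# Germination simulation


def expected_cumulative_pct(
    truth: TrueResponse, condition: TemperatureCondition, n_days: int
) -> np.ndarray:
    """Noise-free expected cumulative germination for days 1..n_days."""
    ts = truth.daily_ts(condition)
    cum_ts = np.maximum(0.0, ts * np.arange(1, n_days + 1))
    return truth.max_germ * (1.0 - np.exp(-truth.germ_rate_scale * cum_ts))


def simulate_germination(
    truth: TrueResponse,
    conditions: Sequence[TemperatureCondition],
    n_reps: int = 4,
    n_seeds: int = 25,
    n_days: int = 16,
    rng_seed: int = 0,
    species_label: str = "synthetic",
) -> GerminationDataset:
    """Simulate a replicated factorial germination trial.

    Sampling is seed-level: replicate r draws ``n_seeds`` uniforms and the
    cumulative count on day d is the number below the expected fraction, so
    every replicate's course is monotone by construction and identical for a
    fixed ``rng_seed``.
    """
    if n_seeds < 1:
        raise ValidationError("n_seeds must be >= 1")
    if n_days < 6:
        raise ValidationError("n_days must be >= 6 (final-germination window)")
    rng = np.random.default_rng(rng_seed)
    timecourses = []
    for cond in conditions:
        expected = expected_cumulative_pct(truth, cond, n_days) / 100.0
        for rep in range(1, n_reps + 1):
            u = rng.random(n_seeds)
            counts = (u[:, None] < expected[None, :]).sum(axis=0)
            pct = 100.0 * counts / n_seeds
            timecourses.append(
                GerminationTimecourse(
                    condition=cond,
                    replicate_id=rep,
                    cumulative_pct=pct,
                    n_seeds=n_seeds,
                )
            )
    return GerminationDataset(species_label=species_label, timecourses=timecourses)


def expected_dataset(
    truth: TrueResponse,
    conditions: Sequence[TemperatureCondition],
    n_days: int = 16,
    species_label: str = "synthetic-expected",
) -> GerminationDataset:
    """The n_seeds → ∞ limit of :func:`simulate_germination` (one replicate
    per condition holding the exact expected percentages)."""
    timecourses = [
        GerminationTimecourse(
            condition=cond,
            replicate_id=1,
            cumulative_pct=expected_cumulative_pct(truth, cond, n_days),
        )
        for cond in conditions
    ]
    return GerminationDataset(species_label=species_label, timecourses=timecourses)


# ---------------------------------------------------------------------------
# Climate simulation


@dataclass
class ClimateParams:
    """Parameters of the sinusoidal-seasonality climate generator."""

    annual_mean_dmt: float = 7.9
    annual_amplitude: float = 14.0
    dmt_noise_sd: float = 2.5
    dtr_mean: float = 8.6
    dtr_sd: float = 3.2
    monthly_precip_means: Sequence[float] = field(
        default_factory=lambda: (0.0,) * 12
    )
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.dtr_mean <= 0:
            raise ValidationError("dtr_mean must be positive")
        if len(self.monthly_precip_means) != 12:
            raise ValidationError("monthly_precip_means must have 12 entries")
        if any(m < 0 for m in self.monthly_precip_means):
            raise ValidationError("monthly precipitation means must be non-negative")


#: Average monthly accumulated precipitation (mm, Jan..Dec) of the target
#: mountain site; July carries the monsoon spike.
GARIWANG_MONTHLY_PRECIP = (
    15.63, 32.38, 54.38, 120.25, 94.25, 101.75,
    348.13, 156.00, 92.25, 85.00, 85.88, 40.63,
)


def gariwang_like_params(rng_seed: int = 0) -> ClimateParams:
    """Climate parameters emulating the Mt.-Gariwang record (2015–2018):
    annual mean DMT ≈ 7.9 °C, mean DTR ≈ 8.6 °C, July monsoon peak."""
    return ClimateParams(
        annual_mean_dmt=7.9,
        annual_amplitude=14.0,
        dmt_noise_sd=2.5,
        dtr_mean=8.6,
        dtr_sd=3.2,
        monthly_precip_means=GARIWANG_MONTHLY_PRECIP,
        rng_seed=rng_seed,
    )


def simulate_climate(
    params: ClimateParams,
    start_year: int = 2015,
    n_years: int = 4,
    site_label: str = "synthetic-site",
) -> ClimateSeries:
    """Simulate a daily climate series with sinusoidal seasonality.

    Daily mean temperature follows
    ``mean − amplitude·cos(2π(doy − 15)/365.25) + N(0, noise_sd)`` (coldest
    mid-January, warmest mid-July); the diurnal range is a positively
    truncated normal and tmax/tmin are reconstructed as dmt ± dtr/2. Daily
    precipitation is exponential with a monthly scale chosen so expected
    monthly totals equal ``monthly_precip_means``.
    """
    if n_years < 1:
        raise ValidationError("n_years must be >= 1")
    rng = np.random.default_rng(params.rng_seed)
    days = []
    d = Date(start_year, 1, 1)
    end = Date(start_year + n_years - 1, 12, 31)
    while d <= end:
        doy = d.timetuple().tm_yday
        seasonal = -params.annual_amplitude * np.cos(2 * np.pi * (doy - 15) / 365.25)
        dmt = params.annual_mean_dmt + seasonal + rng.normal(0.0, params.dmt_noise_sd)
        dtr = -1.0
        while dtr <= 0:  # truncate the diurnal range at zero
            dtr = rng.normal(params.dtr_mean, params.dtr_sd)
        monthly_mean = params.monthly_precip_means[d.month - 1]
        n_in_month = calendar.monthrange(d.year, d.month)[1]
        precip = (
            float(rng.exponential(monthly_mean / n_in_month))
            if monthly_mean > 0
            else 0.0
        )
        days.append(
            ClimateDay(
                date=d,
                tmax=float(dmt + dtr / 2.0),
                tmin=float(dmt - dtr / 2.0),
                precip=precip,
            )
        )
        d += timedelta(days=1)
    return ClimateSeries(site_label=site_label, days=days)
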