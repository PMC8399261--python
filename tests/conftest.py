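from datetime import date, timedelta

import numpy as np
import pandas as pd
import pytest

from thermosow.core_model import (
    GerminationDataset,
    GerminationTimecourse,
    TemperatureCondition,
)
from thermosow.site_application import DailyScoreSeries
from thermosow.synthetic_data import (
    default_experiment_conditions,
    rugosa_like_response,
    simulate_germination,
)


@pytest.fixture(scope="session")
def conditions():
    return default_experiment_conditions()


@pytest.fixture(scope="session")
def truth():
    return rugosa_like_response()


@pytest.fixture(scope="session")
def small_dataset(truth, conditions):
    """10 conditions x 4 reps x 16 days at modest seed count."""
    return simulate_germination(
        truth, conditions, n_reps=4, n_seeds=25, n_days=16, rng_seed=12
    )


@pytest.fixture(scope="session")
def deep_dataset(truth, conditions):
    """The 400-seed trial used for parameter-recovery checks."""
    return simulate_germination(
        truth, conditions, n_reps=4, n_seeds=400, n_days=16, rng_seed=0
    )


def make_timecourse(pct, day=25.0, night=15.0, rep=1):
    return GerminationTimecourse(
        condition=TemperatureCondition(day, night),
        replicate_id=rep,
        cumulative_pct=np.asarray(pct, dtype=float),
    )


def make_dataset(pct_by_condition, species="toy"):
    """Dataset with one replicate per condition from {(day, night): pct list}."""
    tcs = [
        make_timecourse(pct, day=d, night=n)
        for (d, n), pct in pct_by_condition.items()
    ]
    return GerminationDataset(species_label=species, timecourses=tcs)


def make_score_series(ts_by_year, species="toy"):
    """DailyScoreSeries from {year: daily ts array starting Jan 1}."""
    rows = []
    for year, ts in ts_by_year.items():
        d0 = date(year, 1, 1)
        for i, t in enumerate(ts):
            d = d0 + timedelta(days=i)
            rows.append(
                {
                    "date": d,
                    "year": d.year,
                    "doy": i + 1,
                    "dmt": 15.0,
                    "dtr": 10.0,
                    "ts": float(t),
                }
            )
    return DailyScoreSeries(species_label=species, frame=pd.DataFrame(rows))
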