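"""Daily Temperature Score equation and the 85% cumulative-TS requirement.

Given fitted weight curves w_DMT(T) and w_DTR(T), a second multiple
regression of cumulative germination on the two *cumulative impact
weights* (d·w_DMT, d·w_DTR after d days) yields a single combined daily
score

    TS(day) = a·w_DMT(DMT) + b·w_DTR(DTR) + c,

so the accumulated TS plays the role of thermal time. Inverting the linear
germination-vs-cumulative-TS relationship at the 85% seed-vitality
threshold (the Royal Botanic Gardens, Kew standard) gives the species'
cumulative-TS requirement.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import yaml

from .core_model import GerminationDataset, ValidationError
from .vigor_regression import (
    Convention,
    build_cumulative_design,
    fit_impact_weights,
)
from typing import Literal

from .weight_curves import (
    WeightCurve,
    curve_from_dict,
    curve_to_dict,
    fit_weight_curve,
)

#: How daily scoring treats temperatures outside the fitted curve domains.
#: ``base_cutoff`` (default) is the thermal-time convention: days at or
#: below a base temperature contribute no score, the score ramps linearly
#: up to its full clamped value between the base and the coldest tested
#: mean temperature, and warmer-than-tested days clamp to the boundary
#: weight. ``clamp``/``zero``/``extrapolate`` apply the corresponding
#: curve policy to both weights.
ModelOOBPolicy = Literal["base_cutoff", "clamp", "zero", "extrapolate"]


@dataclass
class TSEquationFit:
    """Coefficients of the combined TS equation with fit diagnostics."""

    a: float  # coefficient on the DMT impact weight
    b: float  # coefficient on the DTR impact weight
    c: float  # intercept
    r_squared: float
    standardized_a: float
    standardized_b: float
    n: int


@dataclass
class RequirementFit:
    """Cumulative-TS requirement from the germination-vs-score line."""

    requirement_ts: int
    requirement_ts_raw: float
    slope: float
    intercept: float
    r_squared: float
    threshold_pct: float


@dataclass
class SpeciesTSModel:
    """A species' complete fitted temperature-score model."""

    species_label: str
    dmt_curve: WeightCurve
    dtr_curve: WeightCurve
    a: float
    b: float
    c: float
    r_squared: float
    requirement_ts: int
    requirement_ts_raw: Optional[float] = None
    oob_policy: ModelOOBPolicy = "base_cutoff"
    base_temp_c: float = 5.0  # germination base temperature for site scoring
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, v in (("a", self.a), ("b", self.b), ("c", self.c)):
            if not np.isfinite(v):
                raise ValidationError(f"coefficient {name} is not finite")
        if self.requirement_ts <= 0:
            raise ValidationError("requirement_ts must be positive")


def fit_ts_equation(
    cum_germ: Sequence[float],
    cum_w_dmt: Sequence[float],
    cum_w_dtr: Sequence[float],
) -> TSEquationFit:
    """OLS of cumulative germination on the two cumulative impact weights."""
    y = np.asarray(cum_germ, dtype=float)
    x1 = np.asarray(cum_w_dmt, dtype=float)
    x2 = np.asarray(cum_w_dtr, dtype=float)
    if not (y.size == x1.size == x2.size):
        raise ValidationError("input vectors must have equal length")
    if y.size <= 3:
        raise ValidationError("need more than 3 rows")
    X = np.column_stack([np.ones_like(x1), x1, x2])
    if np.linalg.matrix_rank(X) < 3:
        raise ValidationError("collinear cumulative-weight predictors")
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    yhat = X @ beta
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    sd_y = np.std(y, ddof=1)
    return TSEquationFit(
        a=float(beta[1]),
        b=float(beta[2]),
        c=float(beta[0]),
        r_squared=r2,
        standardized_a=float(beta[1] * np.std(x1, ddof=1) / sd_y),
        standardized_b=float(beta[2] * np.std(x2, ddof=1) / sd_y),
        n=int(y.size),
    )


def daily_ts(
    model: SpeciesTSModel,
    dmt: float,
    dtr: float,
    oob: Optional[ModelOOBPolicy] = None,
) -> float:
    """Daily Temperature Score a·w_DMT(dmt) + b·w_DTR(dtr) + c.

    Out-of-domain temperatures follow the model's configured policy. The
    default ``base_cutoff`` scores a day at or below the base temperature
    as 0 (no germination progress), ramps the score linearly between the
    base and the coldest tested mean temperature, and clamps weights for
    warmer-than-tested days and diurnal ranges.
    """
    policy = oob if oob is not None else model.oob_policy
    if policy == "base_cutoff":
        lo = model.dmt_curve.domain[0]
        base = min(model.base_temp_c, lo)
        if dmt <= base:
            return 0.0
        w1 = model.dmt_curve(dmt, oob="clamp")
        w2 = model.dtr_curve(dtr, oob="clamp")
        ts = model.a * w1 + model.b * w2 + model.c
        if base < dmt < lo:  # partial credit below the tested range
            ts *= (dmt - base) / (lo - base)
        return float(ts)
    w1 = model.dmt_curve(dmt, oob=policy)
    w2 = model.dtr_curve(dtr, oob=policy)
    return float(model.a * w1 + model.b * w2 + model.c)


def fit_requirement(
    germ_pct: Sequence[float],
    cum_ts: Sequence[float],
    threshold: float = 85.0,
) -> RequirementFit:
    """Cumulative TS at which the germ = m·cumTS + k line reaches threshold.

    The slope must be positive — germination that does not increase with
    accumulated score has no defined requirement.
    """
    g = np.asarray(germ_pct, dtype=float)
    s = np.asarray(cum_ts, dtype=float)
    if g.size != s.size or g.size < 2:
        raise ValidationError("need >= 2 paired observations")
    m, k = np.polyfit(s, g, 1)
    if m <= 0:
        raise ValidationError("non-increasing germination vs score; requirement undefined")
    raw = (threshold - k) / m
    ghat = m * s + k
    ss_tot = float(np.sum((g - g.mean()) ** 2))
    r2 = 1.0 - float(np.sum((g - ghat) ** 2)) / ss_tot if ss_tot > 0 else 1.0
    return RequirementFit(
        requirement_ts=int(round(raw)),
        requirement_ts_raw=float(raw),
        slope=float(m),
        intercept=float(k),
        r_squared=r2,
        threshold_pct=float(threshold),
    )


def fit_species_model(
    ds: GerminationDataset,
    dmt_levels: Sequence[float],
    dtr_levels: Sequence[float],
    convention: Convention = "signed_ratio",
    r2_threshold: float = 0.98,
    germination_threshold: float = 85.0,
    oob_policy: ModelOOBPolicy = "base_cutoff",
) -> SpeciesTSModel:
    """End-to-end fit: weights → curves → TS equation → requirement.

    Deterministic for a fixed dataset and configuration. The cumulative
    impact weight of a condition after d days is d times the curve value at
    the condition's DMT (resp. DTR); the requirement comes from regressing
    the same cumulative germination rows on their accumulated daily TS.
    """
    dmt_table, dtr_table, dmt_fit, dtr_fit = fit_impact_weights(
        ds, dmt_levels, dtr_levels, convention
    )
    dmt_curve = fit_weight_curve(
        dmt_table.levels, dmt_table.weights, r2_threshold, variable="DMT"
    )
    dtr_curve = fit_weight_curve(
        dtr_table.levels, dtr_table.weights, r2_threshold, variable="DTR"
    )

    rows = build_cumulative_design(ds, dmt_levels, dtr_levels)
    cum_germ = np.array([r.cumulative_germ_pct for r in rows])
    w_dmt = np.array([float(dmt_curve(r.condition.dmt())) for r in rows])
    w_dtr = np.array([float(dtr_curve(r.condition.dtr())) for r in rows])
    days = np.array([r.day for r in rows], dtype=float)
    eq = fit_ts_equation(cum_germ, days * w_dmt, days * w_dtr)

    ts_daily = eq.a * w_dmt + eq.b * w_dtr + eq.c
    cum_ts = days * ts_daily
    req = fit_requirement(cum_germ, cum_ts, germination_threshold)

    return SpeciesTSModel(
        species_label=ds.species_label,
        dmt_curve=dmt_curve,
        dtr_curve=dtr_curve,
        a=eq.a,
        b=eq.b,
        c=eq.c,
        r_squared=eq.r_squared,
        requirement_ts=req.requirement_ts,
        requirement_ts_raw=req.requirement_ts_raw,
        oob_policy=oob_policy,
        diagnostics={
            "dmt_weights": {
                "levels": dmt_table.levels,
                "coefficients": dmt_table.coefficients.tolist(),
                "weights": dmt_table.weights.tolist(),
                "r_squared": dmt_fit.r_squared,
                "f_pvalue": dmt_fit.f_pvalue,
            },
            "dtr_weights": {
                "levels": dtr_table.levels,
                "coefficients": dtr_table.coefficients.tolist(),
                "weights": dtr_table.weights.tolist(),
                "r_squared": dtr_fit.r_squared,
                "f_pvalue": dtr_fit.f_pvalue,
            },
            "ts_equation": {
                "standardized_a": eq.standardized_a,
                "standardized_b": eq.standardized_b,
                "n": eq.n,
            },
            "requirement": {
                "slope": req.slope,
                "intercept": req.intercept,
                "r_squared": req.r_squared,
                "threshold_pct": req.threshold_pct,
            },
        },
    )


# ---------------------------------------------------------------------------
# Serialization


def model_to_dict(model: SpeciesTSModel) -> dict:
    return {
        "species_label": model.species_label,
        "dmt_curve": curve_to_dict(model.dmt_curve),
        "dtr_curve": curve_to_dict(model.dtr_curve),
        "a": float(model.a),
        "b": float(model.b),
        "c": float(model.c),
        "r_squared": float(model.r_squared),
        "requirement_ts": int(model.requirement_ts),
        "requirement_ts_raw": (
            None if model.requirement_ts_raw is None else float(model.requirement_ts_raw)
        ),
        "oob_policy": model.oob_policy,
        "base_temp_c": float(model.base_temp_c),
        "diagnostics": model.diagnostics,
    }


def model_from_dict(d: dict) -> SpeciesTSModel:
    return SpeciesTSModel(
        species_label=d["species_label"],
        dmt_curve=curve_from_dict(d["dmt_curve"]),
        dtr_curve=curve_from_dict(d["dtr_curve"]),
        a=float(d["a"]),
        b=float(d["b"]),
        c=float(d["c"]),
        r_squared=float(d["r_squared"]),
        requirement_ts=int(d["requirement_ts"]),
        requirement_ts_raw=d.get("requirement_ts_raw"),
        oob_policy=d.get("oob_policy", "base_cutoff"),
        base_temp_c=float(d.get("base_temp_c", 5.0)),
        diagnostics=d.get("diagnostics", {}),
    )


def save_model(model: SpeciesTSModel, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(model_to_dict(model), fh, sort_keys=True)


def load_model(path) -> SpeciesTSModel:
    with open(path) as fh:
        return model_from_dict(yaml.safe_load(fh))
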