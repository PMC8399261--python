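"""Cumulative design matrices, standardized regression and impact weights.

The first modelling stage treats each tested DMT level and each tested DTR
level as its own predictor: for a condition whose DMT matches level L, the
cumulative exposure on day d is L·d (°C·day) and every other DMT-level
column is zero, and likewise for DTR. Cumulative germination (replicate
mean, %) on day d is the response. Standardized regression coefficients of
a per-variable fit are rescaled by the largest absolute coefficient to give
dimensionless *impact weights* in [−1, 1].

A zero level (a constant-temperature condition has DTR = 0) would produce
an identically zero column under the level×day encoding; such levels are
encoded as 1×day instead. Standardized coefficients are invariant to any
positive per-column rescaling, so this choice only makes the zero-level
coefficient estimable — it changes nothing else.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .core_model import GerminationDataset, TemperatureCondition, ValidationError

Variable = Literal["DMT", "DTR"]
Convention = Literal["signed_ratio", "magnitude_at_reference"]


@dataclass
class CumulativeDesignRow:
    """One (condition, day) row of the cumulative design."""

    condition: TemperatureCondition
    day: int
    cumulative_germ_pct: float
    cum_exposure_by_dmt_level: dict[float, float]
    cum_exposure_by_dtr_level: dict[float, float]


@dataclass
class RegressionFit:
    """OLS fit with standardized coefficients and test statistics."""

    predictor_names: list[str]
    coefficients: np.ndarray  # raw, excluding intercept
    intercept: float
    standardized_coefficients: np.ndarray
    p_values: np.ndarray  # per-coefficient t-test
    f_pvalue: float
    r_squared: float
    n: int


@dataclass
class ImpactWeightTable:
    """Per-level impact weights of one variable (DMT or DTR)."""

    variable: Variable
    levels: list[float]
    coefficients: np.ndarray  # standardized regression coefficients
    weights: np.ndarray
    p_values: Optional[np.ndarray] = None
    convention: Convention = "signed_ratio"

    def to_frame(self, species: str = "") -> pd.DataFrame:
        return pd.DataFrame(
            {
                "species": species,
                "variable": self.variable,
                "level": self.levels,
                "coefficient": self.coefficients,
                "p_value": self.p_values if self.p_values is not None else np.nan,
                "weight": self.weights,
                "convention": self.convention,
            }
        )


def _exposure_scale(level: float) -> float:
    # zero levels are encoded as indicator×day; see module docstring
    return level if level != 0 else 1.0


def _match_level(value: float, levels: Sequence[float], what: str) -> float:
    for lv in levels:
        if abs(value - lv) <= 0.01:
            return lv
    raise ValidationError(f"{what} {value} matches no listed level {list(levels)}")


def build_cumulative_design(
    ds: GerminationDataset,
    dmt_levels: Sequence[float],
    dtr_levels: Sequence[float],
) -> list[CumulativeDesignRow]:
    """One row per (condition, day) with replicate-mean germination.

    Every condition's derived DMT and DTR must match one of the listed
    levels to within 0.01 °C; the matching level's cumulative exposure on
    day d is level×d and all other levels carry zero.
    """
    rows = []
    for cond in ds.conditions():
        dmt_lv = _match_level(cond.dmt(), dmt_levels, f"condition {cond.label()} dmt")
        dtr_lv = _match_level(cond.dtr(), dtr_levels, f"condition {cond.label()} dtr")
        mean_pct = ds.mean_cumulative_pct(cond)
        for day, pct in enumerate(mean_pct, start=1):
            rows.append(
                CumulativeDesignRow(
                    condition=cond,
                    day=day,
                    cumulative_germ_pct=float(pct),
                    cum_exposure_by_dmt_level={
                        lv: (_exposure_scale(lv) * day if lv == dmt_lv else 0.0)
                        for lv in dmt_levels
                    },
                    cum_exposure_by_dtr_level={
                        lv: (_exposure_scale(lv) * day if lv == dtr_lv else 0.0)
                        for lv in dtr_levels
                    },
                )
            )
    return rows


def design_matrix(
    rows: Sequence[CumulativeDesignRow], variable: Variable
) -> tuple[np.ndarray, np.ndarray, list[float]]:
    """Response vector, predictor matrix and level list for one variable."""
    if not rows:
        raise ValidationError("empty design")
    key = (
        "cum_exposure_by_dmt_level" if variable == "DMT" else "cum_exposure_by_dtr_level"
    )
    levels = sorted(getattr(rows[0], key).keys())
    y = np.array([r.cumulative_germ_pct for r in rows])
    X = np.array([[getattr(r, key)[lv] for lv in levels] for r in rows])
    return y, X, levels


def standardized_regression(
    y: np.ndarray,
    X: np.ndarray,
    predictor_names: Optional[Sequence[str]] = None,
) -> RegressionFit:
    """OLS with intercept; reports standardized coefficients and tests.

    Standardized coefficient_j = raw coefficient_j × sd(x_j)/sd(y), the
    coefficient the fit would have after z-scoring response and predictors.
    Rank-deficient designs are rejected with the offending columns listed.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n, k = X.shape
    if predictor_names is None:
        predictor_names = [f"x{j + 1}" for j in range(k)]
    if n <= k + 1:
        raise ValidationError(f"need more than {k + 1} rows for {k} predictors, got {n}")
    zero_cols = [predictor_names[j] for j in range(k) if np.all(X[:, j] == 0)]
    if zero_cols:
        raise ValidationError(f"constant-zero predictor columns: {zero_cols}")
    Xc = sm.add_constant(X, has_constant="add")
    if np.linalg.matrix_rank(Xc) < k + 1:
        # flag columns whose removal restores full rank
        collinear = [
            predictor_names[j]
            for j in range(k)
            if np.linalg.matrix_rank(np.delete(Xc, j + 1, axis=1))
            == np.linalg.matrix_rank(Xc)
        ]
        raise ValidationError(f"rank-deficient design; collinear columns: {collinear}")
    res = sm.OLS(y, Xc).fit()
    coefs = res.params[1:]
    sd_y = np.std(y, ddof=1)
    sd_x = np.std(X, axis=0, ddof=1)
    return RegressionFit(
        predictor_names=list(predictor_names),
        coefficients=np.asarray(coefs),
        intercept=float(res.params[0]),
        standardized_coefficients=np.asarray(coefs * sd_x / sd_y),
        p_values=np.asarray(res.pvalues[1:]),
        f_pvalue=float(res.f_pvalue),
        r_squared=float(res.rsquared),
        n=n,
    )


def impact_weights_from_coefficients(
    coefficients: Sequence[float],
    convention: Convention = "signed_ratio",
) -> np.ndarray:
    """Rescale coefficients so the largest-magnitude one maps to 1.

    ``signed_ratio`` (default, self-consistent): w_i = c_i / max_j |c_j|;
    each weight keeps its coefficient's sign and the extremal weight is ±1.
    ``magnitude_at_reference``: w_i = |c_i| / max_j |c_j|, all weights
    non-negative with the reference (largest-|c|) level exactly 1 — the
    convention some published tables apply when the reference coefficient
    is negative.
    """
    c = np.asarray(coefficients, dtype=float)
    if np.all(c == 0):
        raise ValidationError("all coefficients are zero; weights undefined")
    # tie toward the lower level (first index) via argmax on |c|
    ref = int(np.argmax(np.abs(c)))
    scale = abs(c[ref])
    if convention == "signed_ratio":
        return c / scale
    if convention == "magnitude_at_reference":
        w = np.abs(c) / scale
        w[ref] = 1.0
        return w
    raise ValueError(f"unknown convention {convention!r}")


def to_impact_weights(
    fit: RegressionFit,
    variable: Variable,
    levels: Sequence[float],
    convention: Convention = "signed_ratio",
) -> ImpactWeightTable:
    """Impact-weight table from a per-variable standardized fit."""
    if len(levels) != len(fit.standardized_coefficients):
        raise ValidationError(
            f"{len(levels)} levels but {len(fit.standardized_coefficients)} coefficients"
        )
    return ImpactWeightTable(
        variable=variable,
        levels=list(levels),
        coefficients=np.asarray(fit.standardized_coefficients),
        weights=impact_weights_from_coefficients(
            fit.standardized_coefficients, convention
        ),
        p_values=np.asarray(fit.p_values),
        convention=convention,
    )


def fit_impact_weights(
    ds: GerminationDataset,
    dmt_levels: Sequence[float],
    dtr_levels: Sequence[float],
    convention: Convention = "signed_ratio",
) -> tuple[ImpactWeightTable, ImpactWeightTable, RegressionFit, RegressionFit]:
    """Design build → per-variable standardized regressions → weight tables.

    The DMT-level and DTR-level blocks are fitted separately: each condition
    activates exactly one level of each block, so a joint fit of both blocks
    is structurally rank-deficient (the unit-scaled sum of either block
    reproduces the day column).
    """
    rows = build_cumulative_design(ds, dmt_levels, dtr_levels)
    out = []
    for variable in ("DMT", "DTR"):
        y, X, levels = design_matrix(rows, variable)
        names = [f"{variable}_{lv:g}" for lv in levels]
        fit = standardized_regression(y, X, names)
        out.append((fit, to_impact_weights(fit, variable, levels, convention)))
    (dmt_fit, dmt_table), (dtr_fit, dtr_table) = out
    return dmt_table, dtr_table, dmt_fit, dtr_fit
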