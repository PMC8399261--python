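"""Continuous impact-weight curves over temperature.

Impact weights are observed only at the tested temperature levels; a
polynomial least-squares fit interpolates between them so that any daily
site temperature can be scored. The fitting rule mirrors common practice
for response-surface smoothing: the lowest-degree polynomial (degree ≥ 2)
whose R² exceeds a threshold (default 0.98) is kept; if no degree below
n−1 qualifies, the exact degree-(n−1) interpolant is used.

Peaks (local maxima) and sign changes of a fitted curve are located from
the real roots of the derivative / of the polynomial itself, so statements
like "the weight is negative below 13.5 °C" can be computed rather than
assumed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from numpy.polynomial import polynomial as P

from .core_model import ValidationError

OOBPolicy = Literal["raise", "clamp", "zero", "extrapolate"]


@dataclass
class WeightCurve:
    """A polynomial weight curve w(T) on a temperature domain.

    ``coefficients`` are in ascending-degree order: w(T) = Σ c_k T^k.
    Direct evaluation outside the domain raises; callers that must score
    out-of-range temperatures choose an explicit out-of-domain policy.
    """

    variable: str  # "DMT" or "DTR"
    coefficients: np.ndarray
    domain: tuple[float, float]
    r_squared: float
    degree: int = field(init=False)

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if self.coefficients.ndim != 1 or self.coefficients.size == 0:
            raise ValidationError("coefficients must be a non-empty 1-D array")
        if self.domain[0] >= self.domain[1]:
            raise ValidationError(f"degenerate domain {self.domain}")
        self.degree = int(self.coefficients.size - 1)

    def __call__(self, t, oob: OOBPolicy = "raise"):
        t = np.asarray(t, dtype=float)
        lo, hi = self.domain
        below, above = t < lo, t > hi
        if oob == "raise":
            if np.any(below | above):
                raise ValidationError(
                    f"temperature outside curve domain [{lo}, {hi}]"
                )
            te = t
        elif oob == "clamp":
            te = np.clip(t, lo, hi)
        elif oob in ("zero", "extrapolate"):
            te = t
        else:
            raise ValueError(f"unknown out-of-domain policy {oob!r}")
        w = P.polyval(te, self.coefficients)
        if oob == "zero":
            w = np.where(below | above, 0.0, w)
        return float(w) if w.ndim == 0 else w

    def derivative_coefficients(self) -> np.ndarray:
        return P.polyder(self.coefficients)


def _r_squared(y: np.ndarray, yhat: np.ndarray) -> float:
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - np.mean(y)) ** 2))
    if ss_tot == 0:
        return 1.0 if ss_res == 0 else 0.0
    return 1.0 - ss_res / ss_tot


def fit_weight_curve(
    levels: Sequence[float],
    weights: Sequence[float],
    r2_threshold: float = 0.98,
    variable: str = "DMT",
    domain_margin: float = 0.0,
    min_degree: int = 2,
) -> WeightCurve:
    """Lowest-degree polynomial with R² above the threshold.

    Degrees ``min_degree`` .. n−2 are tried in order; if none qualifies the
    degree-(n−1) interpolant (R² = 1 by construction) is returned. The
    curve's domain is [min level, max level] widened by ``domain_margin``.
    """
    levels = np.asarray(levels, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if levels.size != weights.size:
        raise ValidationError("levels and weights must have equal length")
    if np.unique(levels).size < 3:
        raise ValidationError("need at least 3 distinct levels")
    if np.unique(levels).size != levels.size:
        for lv in np.unique(levels):
            ws = weights[levels == lv]
            if np.unique(ws).size > 1:
                raise ValidationError(
                    f"duplicate level {lv} with conflicting weights {ws.tolist()}"
                )
    n = int(np.unique(levels).size)
    order = np.argsort(levels)
    levels, weights = levels[order], weights[order]
    domain = (float(levels.min()) - domain_margin, float(levels.max()) + domain_margin)

    chosen = None
    for degree in range(min_degree, n - 1):
        coefs = P.polyfit(levels, weights, degree)
        if _r_squared(weights, P.polyval(levels, coefs)) > r2_threshold:
            chosen = coefs
            break
    if chosen is None:
        # exact interpolation fallback: Vandermonde solve, R² = 1
        uniq_idx = np.unique(levels, return_index=True)[1]
        lv, wt = levels[uniq_idx], weights[uniq_idx]
        chosen = np.linalg.solve(np.vander(lv, n, increasing=True), wt)
    r2 = _r_squared(weights, P.polyval(levels, chosen))
    return WeightCurve(
        variable=variable, coefficients=np.asarray(chosen), domain=domain, r_squared=r2
    )


def evaluate_curve(
    curve: WeightCurve, step: float = 0.1
) -> list[tuple[float, float]]:
    """Sample the curve from domain low to high inclusive at ``step`` °C."""
    if step <= 0:
        raise ValidationError("step must be positive")
    lo, hi = curve.domain
    n = int(np.floor((hi - lo) / step + 1e-9)) + 1
    grid = lo + step * np.arange(n)
    if grid[-1] < hi - 1e-9:
        grid = np.append(grid, hi)
    return [(float(t), float(curve(t))) for t in grid]


def _interior_real_roots(coefs: np.ndarray, domain: tuple[float, float]) -> np.ndarray:
    """Real roots of a polynomial strictly inside the domain, deduplicated."""
    coefs = np.trim_zeros(np.asarray(coefs, dtype=float), "b")
    if coefs.size <= 1:
        return np.array([])
    roots = P.polyroots(coefs)
    real = np.sort(roots[np.abs(roots.imag) < 1e-8].real)
    lo, hi = domain
    real = real[(real > lo + 1e-12) & (real < hi - 1e-12)]
    if real.size > 1:  # merge near-coincident roots
        keep = np.concatenate(([True], np.diff(real) > 1e-9))
        real = real[keep]
    return real


def find_peaks(curve: WeightCurve) -> list[tuple[float, float]]:
    """Local maxima strictly inside the domain.

    Peaks are real roots of w′ with w″ < 0, reported to 0.01 °C with the
    curve value at the (unrounded) peak, sorted by temperature.
    """
    if curve.degree < 2:
        raise ValidationError("peak finding requires degree >= 2")
    d1 = curve.derivative_coefficients()
    d2 = P.polyder(d1)
    peaks = []
    for r in _interior_real_roots(d1, curve.domain):
        if P.polyval(r, d2) < 0:
            peaks.append((round(float(r), 2), float(P.polyval(r, curve.coefficients))))
    return sorted(peaks)


def find_sign_changes(curve: WeightCurve) -> list[tuple[float, str]]:
    """Zero crossings of the curve inside its domain.

    Each crossing is reported to 0.01 °C with a direction tag:
    ``"negative_below"`` if the curve is negative on the left of the root,
    ``"negative_above"`` otherwise. Touch points (no sign change) are
    skipped.
    """
    crossings = []
    eps = 1e-6 * max(1.0, curve.domain[1] - curve.domain[0])
    for r in _interior_real_roots(curve.coefficients, curve.domain):
        left = float(curve(max(r - eps, curve.domain[0])))
        right = float(curve(min(r + eps, curve.domain[1])))
        if left < 0 < right:
            crossings.append((round(float(r), 2), "negative_below"))
        elif left > 0 > right:
            crossings.append((round(float(r), 2), "negative_above"))
    return sorted(crossings)


def curve_to_dict(curve: WeightCurve) -> dict:
    """Config-file block for one curve."""
    return {
        "variable": curve.variable,
        "degree": curve.degree,
        "coefficients": [float(c) for c in curve.coefficients],
        "domain": [float(curve.domain[0]), float(curve.domain[1])],
        "r_squared": float(curve.r_squared),
    }


def curve_from_dict(d: dict) -> WeightCurve:
    return WeightCurve(
        variable=d["variable"],
        coefficients=np.asarray(d["coefficients"], dtype=float),
        domain=(float(d["domain"][0]), float(d["domain"][1])),
        r_squared=float(d["r_squared"]),
    )
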