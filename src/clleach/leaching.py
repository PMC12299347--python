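"""Rainfall-response fitting, leaching efficiency and critical rainfall.

Layer Cl⁻ content declines with cumulative rainfall roughly quadratically
over a growing season, so per-layer responses are summarised as
``content = a·rain² + b·rain + c`` together with the (linear) Pearson
correlation between rain and content.  Leaching efficiency — the fraction
of the applied dose leached below the profiled layers, i.e. the budget's
leaching factor — rises with rainfall; the cumulative rainfall at which a
target efficiency is first reached ("critical rainfall") is read off a
straight-line fit of efficiency against rain.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .accounting import ClBudget
from .errors import DomainError, InsufficientDataError, NoLeachingTrendError


@dataclass(frozen=True)
class QuadraticFit:
    """Quadratic rainfall response of one layer/treatment."""

    a: float  # mg/kg per mm^2
    b: float  # mg/kg per mm
    c: float  # mg/kg
    pearson_r: float  # linear rain-content correlation, not the fit R
    rain_min: float = 0.0  # fitted domain, mm
    rain_max: float = 0.0

    def predict(self, rain):
        return self.a * np.asarray(rain, float) ** 2 + self.b * np.asarray(rain, float) + self.c

    @property
    def vertex(self) -> float:
        """Stationary rainfall of the parabola (mm); inf when a == 0."""
        if self.a == 0:
            return np.inf
        return -self.b / (2.0 * self.a)


def fit_quadratic_response(rain, conc) -> QuadraticFit:
    """Least-squares quadratic of layer content against cumulative rain.

    Also reports the Pearson correlation of rain vs content — the summary
    statistic conventionally printed beside such fits (negative for a
    declining response even though the parabola opens upward).
    """
    x = np.asarray(rain, dtype=float)
    y = np.asarray(conc, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise DomainError("rain and conc must be 1-d and equal length")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise DomainError("rain and conc must be finite")
    if np.unique(x).size < 4:
        raise InsufficientDataError(
            f"need >= 4 distinct rainfall values, got {np.unique(x).size}"
        )
    a, b, c = np.polyfit(x, y, 2)
    r = float(stats.pearsonr(x, y).statistic) if np.ptp(y) > 0 else 0.0
    return QuadraticFit(
        a=float(a), b=float(b), c=float(c), pearson_r=r,
        rain_min=float(x.min()), rain_max=float(x.max()),
    )


@dataclass(frozen=True)
class EfficiencyPoint:
    """Leaching efficiency at one sampling date."""

    cum_rain: float  # mm
    efficiency: float  # fraction, nominally in [0, 1]
    out_of_range: bool = False  # noisy stocks can push it outside [0, 1]


def efficiency_series(budgets: list[ClBudget]) -> list[EfficiencyPoint]:
    """Leaching efficiency over time from per-date Cl budgets.

    All budgets must carry ``cum_rain`` and share one applied dose;
    cumulative rain must be strictly increasing.  Efficiency values outside
    [0, 1] are retained but flagged.
    """
    if not budgets:
        raise InsufficientDataError("no budgets supplied")
    if any(b.cum_rain is None for b in budgets):
        raise DomainError("every budget needs cum_rain to build a series")
    doses = {b.cl_applied for b in budgets}
    if len(doses) != 1:
        raise DomainError(f"budgets mix applied doses: {sorted(doses)}")
    rains = [b.cum_rain for b in budgets]
    if any(r2 <= r1 for r1, r2 in zip(rains, rains[1:])):
        raise DomainError("cum_rain must be strictly increasing")
    return [
        EfficiencyPoint(
            cum_rain=b.cum_rain,
            efficiency=b.leaching_factor,
            out_of_range=not 0.0 <= b.leaching_factor <= 1.0,
        )
        for b in budgets
    ]


@dataclass(frozen=True)
class CriticalRainfall:
    """Linear-fit solution for the rain reaching a target efficiency."""

    rainfall: float  # mm
    target: float  # fraction
    slope: float  # efficiency per mm
    intercept: float
    extrapolated: bool  # beyond 1.25x the observed rain range


def critical_rainfall(
    points: list[EfficiencyPoint],
    target: float,
    include_out_of_range: bool = False,
    fit_max_efficiency: float | None = None,
) -> CriticalRainfall:
    """Cumulative rainfall (mm) at which efficiency first reaches ``target``.

    Fits ``efficiency = α + β·rain`` by least squares over the usable points
    and returns ``(target − α)/β``.  Flagged points are excluded unless
    ``include_out_of_range``.  Efficiency series are concave in rain, so for
    low targets a line fitted over a whole season overshoots at the origin;
    ``fit_max_efficiency`` restricts the fit to points at or below that
    efficiency (a local linearization; at least 3 points are always kept).
    A non-positive fitted slope raises
    :class:`~clleach.errors.NoLeachingTrendError`; solutions beyond 1.25×
    the observed maximum rain are flagged as extrapolation.
    """
    if not 0.0 < target < 1.0:
        raise DomainError(f"target efficiency must lie in (0, 1), got {target}")
    used = [p for p in points if include_out_of_range or not p.out_of_range]
    if len(used) < 3:
        raise InsufficientDataError(
            f"need >= 3 usable efficiency points, got {len(used)}"
        )
    if fit_max_efficiency is not None:
        windowed = [p for p in used if p.efficiency <= fit_max_efficiency]
        used = windowed if len(windowed) >= 3 else used[:3]
    x = np.array([p.cum_rain for p in used], dtype=float)
    y = np.array([p.efficiency for p in used], dtype=float)
    beta, alpha = np.polyfit(x, y, 1)
    if beta <= 0:
        raise NoLeachingTrendError(
            f"fitted efficiency slope {beta:.3e} per mm is not positive"
        )
    rain = (target - alpha) / beta
    rain = max(rain, 0.0)
    return CriticalRainfall(
        rainfall=float(rain),
        target=float(target),
        slope=float(beta),
        intercept=float(alpha),
        extrapolated=bool(rain > 1.25 * float(x.max())),
    )


@dataclass(frozen=True)
class LayerDistribution:
    """Normalized share of Cl stock per sampled layer at one rain milestone."""

    fractions: tuple[float, ...]
    milestone_rain: float  # mm

    def __post_init__(self):
        if abs(sum(self.fractions) - 1.0) > 1e-9:
            raise DomainError("fractions must sum to 1")


def layer_distribution(stocks, milestone_rain: float) -> LayerDistribution:
    """Normalize per-layer stocks (kg/ha) into profile fractions."""
    s = np.asarray(stocks, dtype=float)
    if s.ndim != 1 or s.size == 0:
        raise DomainError("stocks must be a non-empty 1-d sequence")
    if not np.all(np.isfinite(s)) or np.any(s < 0):
        raise DomainError("stocks must be finite and >= 0")
    total = float(s.sum())
    if total == 0:
        raise DomainError("all-zero stocks: layer distribution undefined")
    return LayerDistribution(
        fractions=tuple(float(v) for v in s / total),
        milestone_rain=float(milestone_rain),
    )
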