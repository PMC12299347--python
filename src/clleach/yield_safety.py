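"""Relative yield, dose–response fitting and the safe KCl window.

Tuber yield under chloride fertilization first rises (potassium response)
then falls (chloride toxicity) with the Cl dose, so relative yield —
treated yield as a percentage of the unfertilized control — is modelled as
a concave quadratic RY(d) = p₀ + p₁·d + p₂·d².  The safe window is bounded
by the descending-limb doses where RY returns to 100% and drops to 95%;
dividing by the 45% Cl content of KCl converts Cl doses to fertilizer
rates.  Relative yields are also binned into agronomic toxicity classes
(95–100% safe, 80–90% mild, <50% severe, with flagged gap-filling classes
in between).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd

from .accounting import KCL_CL_FRACTION
from .errors import DomainError, InsufficientDataError

#: Relative yield (%) bounds of the safe dose window.
SAFE_RY_UPPER = 100.0
SAFE_RY_LOWER = 95.0


def relative_yield(treated: float, control: float) -> float:
    """Treated-plot yield as % of the control plot yield."""
    if not math.isfinite(control) or control <= 0:
        raise DomainError(f"control yield must be > 0, got {control!r}")
    if not math.isfinite(treated) or treated < 0:
        raise DomainError(f"treated yield must be >= 0, got {treated!r}")
    return 100.0 * treated / control


class ToxicityClass(str, Enum):
    """Relative-yield toxicity classes; two are interpolated gap fillers."""

    NO_SUPPRESSION = "no_suppression"  # > 100 %
    SAFE = "safe"  # [95, 100] %
    MARGINAL = "marginal"  # [90, 95) %, gap-filling
    MILD = "mild"  # [80, 90) %
    MODERATE = "moderate"  # [50, 80) %, gap-filling
    SEVERE = "severe"  # < 50 %

    @property
    def gap_fill(self) -> bool:
        """True for classes interpolated between the published bands."""
        return self in (ToxicityClass.MARGINAL, ToxicityClass.MODERATE)


def classify_toxicity(relative_yield_percent: float) -> ToxicityClass:
    """Bin a relative yield (%) into its toxicity class."""
    ry = float(relative_yield_percent)
    if not math.isfinite(ry) or ry < 0:
        raise DomainError(f"relative yield must be finite and >= 0, got {ry!r}")
    if ry > 100:
        return ToxicityClass.NO_SUPPRESSION
    if ry >= 95:
        return ToxicityClass.SAFE
    if ry >= 90:
        return ToxicityClass.MARGINAL
    if ry >= 80:
        return ToxicityClass.MILD
    if ry >= 50:
        return ToxicityClass.MODERATE
    return ToxicityClass.SEVERE


@dataclass(frozen=True)
class SafeRange:
    """Descending-limb dose bounds of the safe window."""

    dose_ry100: float | None  # kg Cl/ha where RY returns to 100%
    dose_ry95: float  # kg Cl/ha where RY drops to 95%
    kcl_ry100: float | None  # kg KCl/ha
    kcl_ry95: float  # kg KCl/ha
    flag: str | None = None


@dataclass(frozen=True)
class DoseResponseResults:
    """Fitted quadratic relative-yield curve RY(d) = p0 + p1 d + p2 d²."""

    p2: float  # % per (kg/ha)^2
    p1: float  # % per kg/ha
    p0: float  # %
    n: int
    dose_min: float
    dose_max: float

    def predict(self, dose):
        d = np.asarray(dose, dtype=float)
        return self.p0 + self.p1 * d + self.p2 * d**2

    #: curvature below this magnitude is numerically indistinguishable from
    #: a straight line (constant-yield fits give |p2| ~ 1e-18)
    _CURVATURE_EPS = 1e-12

    @property
    def concave(self) -> bool:
        return self.p2 < -self._CURVATURE_EPS

    @property
    def optimum_dose(self) -> float | None:
        """Vertex dose (kg/ha); None when the curve has no maximum."""
        if not self.concave:
            return None
        return -self.p1 / (2.0 * self.p2)

    @property
    def ry_at_optimum(self) -> float | None:
        d = self.optimum_dose
        return None if d is None else float(self.predict(d))

    def _descending_root(self, target: float) -> float | None:
        """Root of RY(d) = target above the vertex, or None."""
        disc = self.p1**2 - 4.0 * self.p2 * (self.p0 - target)
        if disc < 0:
            return None
        root = (-self.p1 - math.sqrt(disc)) / (2.0 * self.p2)  # larger root, p2<0
        opt = self.optimum_dose
        if root < opt or root < 0:
            return None
        return float(root)

    def safe_range(self, cl_fraction: float = KCL_CL_FRACTION) -> SafeRange:
        """Solve the 100%- and 95%-RY doses on the descending limb.

        KCl equivalents divide the Cl doses by the fertilizer Cl grade.
        Raises :class:`~clleach.errors.DomainError` for a non-concave curve;
        when RY never returns to 100% for d > 0, only the 95% bound is
        returned, flagged.
        """
        if not self.concave:
            raise DomainError("no descending limb: p2 >= 0, safe range undefined")
        d95 = self._descending_root(SAFE_RY_LOWER)
        if d95 is None:
            raise DomainError("fitted curve never drops to 95% relative yield")
        d100 = self._descending_root(SAFE_RY_UPPER)
        flag = None if d100 is not None else "ry_never_reaches_100"
        return SafeRange(
            dose_ry100=d100,
            dose_ry95=d95,
            kcl_ry100=None if d100 is None else d100 / cl_fraction,
            kcl_ry95=d95 / cl_fraction,
            flag=flag,
        )

    def summary(self) -> str:
        opt = self.optimum_dose
        lines = [
            "Quadratic dose-response (relative yield, %)",
            f"  RY(d) = {self.p0:.4f} {self.p1:+.5f} d {self.p2:+.7f} d^2",
            f"  n = {self.n}, dose range [{self.dose_min:g}, {self.dose_max:g}] kg Cl/ha",
        ]
        if opt is not None:
            lines.append(
                f"  optimum {opt:.1f} kg Cl/ha, RY {self.ry_at_optimum:.1f}%"
            )
        else:
            lines.append("  no interior optimum (curve not concave)")
        return "\n".join(lines)

    def plot(self, ax=None, doses=None, ry=None):
        """Diagnostic plot of the fitted curve (and data, if given)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        grid = np.linspace(0, max(self.dose_max * 1.1, 1.0), 200)
        ax.plot(grid, self.predict(grid), label="fitted RY(d)")
        if doses is not None and ry is not None:
            ax.scatter(doses, ry, color="k", zorder=3, label="data")
        ax.axhline(SAFE_RY_UPPER, ls=":", c="grey")
        ax.axhline(SAFE_RY_LOWER, ls=":", c="grey")
        ax.set_xlabel("Cl dose (kg/ha)")
        ax.set_ylabel("relative yield (%)")
        ax.legend()
        return ax


class DoseResponseModel:
    """Least-squares quadratic model of relative yield against Cl dose.

    Accepts per-observation (dose, relative yield %) pairs; replicate and
    multi-year records should be averaged per dose first (see
    :meth:`from_yields`).
    """

    def __init__(self, doses, relative_yields):
        self.doses = np.asarray(doses, dtype=float)
        self.ry = np.asarray(relative_yields, dtype=float)
        if self.doses.shape != self.ry.shape or self.doses.ndim != 1:
            raise DomainError("doses and relative yields must match in length")
        if not (np.all(np.isfinite(self.doses)) and np.all(np.isfinite(self.ry))):
            raise DomainError("doses and relative yields must be finite")
        if np.unique(self.doses).size < 4:
            raise InsufficientDataError(
                f"need >= 4 distinct doses, got {np.unique(self.doses).size}"
            )
        if 0.0 not in np.unique(self.doses):
            raise InsufficientDataError("a zero-dose (control) level is required")

    @classmethod
    def from_yields(cls, df: pd.DataFrame, dose: str = "dose",
                    yield_col: str = "yield_t_ha") -> "DoseResponseModel":
        """Build from raw yield records (replicates/years averaged per dose).

        Relative yield is computed against the mean zero-dose yield.
        """
        means = df.groupby(dose)[yield_col].mean()
        if 0.0 not in means.index:
            raise InsufficientDataError("a zero-dose (control) level is required")
        control = float(means.loc[0.0])
        ry = [relative_yield(v, control) for v in means.to_numpy()]
        return cls(means.index.to_numpy(), ry)

    def fit(self) -> DoseResponseResults:
        p2, p1, p0 = np.polyfit(self.doses, self.ry, 2)
        return DoseResponseResults(
            p2=float(p2), p1=float(p1), p0=float(p0), n=int(self.doses.size),
            dose_min=float(self.doses.min()), dose_max=float(self.doses.max()),
        )


def fit_dose_response(records) -> DoseResponseResults:
    """Fit from ``[(dose, relative_yield_percent), ...]`` pairs."""
    doses, ry = zip(*records)
    return DoseResponseModel(doses, ry).fit()


def safe_dose_range(
    fit: DoseResponseResults, cl_fraction: float = KCL_CL_FRACTION
) -> SafeRange:
    """Functional form of :meth:`DoseResponseResults.safe_range`."""
    return fit.safe_range(cl_fraction)
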