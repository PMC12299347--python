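"""Chloride stock accounting and fertilizer-scheme arithmetic.

All chloride budgeting works on area-based stocks (kg Cl ha⁻¹).  A
water-soluble Cl⁻ concentration ``C`` (mg kg⁻¹ dry soil) in a layer of
depth ``D`` (cm) with bulk density ``BD`` (g cm⁻³) corresponds to

    ClA = C × BD × D × 0.1   [kg ha⁻¹]

The factor 0.1 converts (mg kg⁻¹)·(g cm⁻³)·cm to kg ha⁻¹ (one hectare of
soil 1 cm deep at 1 g cm⁻³ weighs 10⁵ kg).

From the stocks of a treated plot and an unfertilized control the leaching
factor of an applied dose ``Cl_r`` is

    ClLF = (Cl_r − (ClA_T − ClA_CK)) / Cl_r

and the residual ratio closes the budget with the plant uptake fraction
``ClP``:

    ClRR = 1 − ClLF − ClP

Fractions are used internally everywhere; percentages appear only at I/O
boundaries.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

from .errors import DomainError, OutOfRangeWarning, SchemeInfeasibleError

#: (mg/kg) x (g/cm3) x cm -> kg/ha
STOCK_FACTOR = 0.1
#: Mass fraction of Cl in commercial KCl fertilizer.
KCL_CL_FRACTION = 0.45
#: K2O grade of commercial KCl fertilizer.
KCL_K2O_FRACTION = 0.60
#: Basal K2O target shared by all treatments (kg/ha).
DEFAULT_BASAL_K2O = 150.0

#: Default sampling layers, cm below the ridge surface, [top, bottom).
DEFAULT_LAYERS = ((0.0, 15.0), (15.0, 30.0), (30.0, 45.0))


def _require_finite_nonneg(name: str, value: float) -> float:
    value = float(value)
    if not math.isfinite(value) or value < 0:
        raise DomainError(f"{name} must be finite and >= 0, got {value!r}")
    return value


@dataclass(frozen=True)
class LayerObservation:
    """One water-soluble Cl⁻ (and optional SO₄²⁻) measurement.

    A single site/treatment/date/layer cell of a long-format trial table.
    """

    site_id: str
    texture: str  # "loam" | "sandy_loam"
    treatment: str  # "CK" | "L" | "M" | "H"
    das: int  # days after sowing
    cum_rain: float  # cumulative rainfall since basal application, mm
    layer_top: float  # cm
    layer_bottom: float  # cm
    cl_conc: float  # mg/kg
    so4_conc: float | None = None  # mg/kg, optional inert covariate
    replicate: int = 1

    def __post_init__(self):
        if self.texture not in ("loam", "sandy_loam"):
            raise DomainError(f"unknown texture {self.texture!r}")
        if self.treatment not in ("CK", "L", "M", "H"):
            raise DomainError(f"unknown treatment {self.treatment!r}")
        if self.layer_bottom <= self.layer_top:
            raise DomainError(
                f"layer_bottom ({self.layer_bottom}) must exceed "
                f"layer_top ({self.layer_top})"
            )
        _require_finite_nonneg("cum_rain", self.cum_rain)
        _require_finite_nonneg("cl_conc", self.cl_conc)
        if self.so4_conc is not None:
            _require_finite_nonneg("so4_conc", self.so4_conc)

    @property
    def depth(self) -> float:
        """Layer thickness in cm."""
        return self.layer_bottom - self.layer_top


@dataclass(frozen=True)
class SoilProfile:
    """Site-level soil physical properties."""

    bulk_density: float  # g/cm3
    clay: float  # %
    silt: float | None = None  # %
    sand: float | None = None  # %
    layer_depth: float = 15.0  # cm

    def __post_init__(self):
        if not 0.8 < self.bulk_density < 2.0:
            raise DomainError(
                f"bulk_density {self.bulk_density} g/cm3 outside (0.8, 2.0)"
            )
        if not 0 <= self.clay <= 100:
            raise DomainError(f"clay {self.clay}% outside [0, 100]")
        if self.silt is not None and self.sand is not None:
            total = self.clay + self.silt + self.sand
            if abs(total - 100.0) > 1.0:
                raise DomainError(
                    f"clay+silt+sand = {total}% departs from 100% by more than 1"
                )


def cl_stock(conc: float, bulk_density: float, depth: float) -> float:
    """Area-based Cl stock (kg/ha) of one layer.

    Parameters
    ----------
    conc : water-soluble Cl⁻ concentration, mg/kg dry soil.
    bulk_density : g/cm³.
    depth : layer thickness, cm.
    """
    conc = _require_finite_nonneg("conc", conc)
    bulk_density = _require_finite_nonneg("bulk_density", bulk_density)
    depth = _require_finite_nonneg("depth", depth)
    return conc * bulk_density * depth * STOCK_FACTOR


def stock_to_conc(stock: float, bulk_density: float, depth: float) -> float:
    """Inverse of :func:`cl_stock`: kg/ha back to mg/kg."""
    stock = _require_finite_nonneg("stock", stock)
    bulk_density = _require_finite_nonneg("bulk_density", bulk_density)
    depth = _require_finite_nonneg("depth", depth)
    if bulk_density == 0 or depth == 0:
        raise DomainError("bulk_density and depth must be positive to invert")
    return stock / (bulk_density * depth * STOCK_FACTOR)


def leaching_factor(
    cl_applied: float, stock_treated: float, stock_control: float
) -> float:
    """Fraction of the applied dose no longer held in the profiled layers.

    ``(Cl_r − (ClA_T − ClA_CK)) / Cl_r``.  Values outside [0, 1] (possible
    with measurement noise) are returned unchanged with an
    :class:`~clleach.errors.OutOfRangeWarning` so budgets stay conservative.
    """
    cl_applied = float(cl_applied)
    if not math.isfinite(cl_applied) or cl_applied <= 0:
        raise DomainError(f"cl_applied must be > 0, got {cl_applied!r}")
    stock_treated = _require_finite_nonneg("stock_treated", stock_treated)
    stock_control = _require_finite_nonneg("stock_control", stock_control)
    lf = (cl_applied - (stock_treated - stock_control)) / cl_applied
    if not 0.0 <= lf <= 1.0:
        warnings.warn(
            f"leaching factor {lf:.4f} outside [0, 1]; kept unclamped",
            OutOfRangeWarning,
            stacklevel=2,
        )
    return lf


def residual_ratio(leach_frac: float, plant_uptake: float) -> float:
    """Close the Cl budget: residual = 1 − leaching − plant uptake."""
    for name, v in (("leach_frac", leach_frac), ("plant_uptake", plant_uptake)):
        if not math.isfinite(v) or not 0.0 <= v <= 1.0:
            raise DomainError(f"{name} must lie in [0, 1], got {v!r}")
    rr = 1.0 - leach_frac - plant_uptake
    if rr < 0:
        warnings.warn(
            f"residual ratio {rr:.4f} < 0 (leaching + uptake exceed 1)",
            OutOfRangeWarning,
            stacklevel=2,
        )
    return rr


@dataclass(frozen=True)
class ClBudget:
    """Budget of one applied dose at one sampling date."""

    cl_applied: float  # kg/ha, Cl_r
    stock_treated: float  # kg/ha over the profiled layers
    stock_control: float  # kg/ha
    plant_uptake_fraction: float = 0.0  # ClP
    cum_rain: float | None = None  # mm, for efficiency series
    leaching_factor: float = field(init=False)
    residual_ratio: float = field(init=False)

    def __post_init__(self):
        lf = leaching_factor(self.cl_applied, self.stock_treated, self.stock_control)
        clp = self.plant_uptake_fraction
        if not 0.0 <= clp <= 1.0:
            raise DomainError(f"plant_uptake_fraction {clp!r} outside [0, 1]")
        rr = 1.0 - lf - clp
        object.__setattr__(self, "leaching_factor", lf)
        object.__setattr__(self, "residual_ratio", rr)

    @property
    def flags(self) -> tuple[str, ...]:
        out = []
        if not 0.0 <= self.leaching_factor <= 1.0:
            out.append("leaching_factor_out_of_range")
        if self.residual_ratio < 0:
            out.append("negative_residual_ratio")
        return tuple(out)


@dataclass(frozen=True)
class FertilizerScheme:
    """Basal nutrient plan for one Cl treatment level."""

    cl_rate: float  # kg Cl/ha
    kcl_mass: float  # kg KCl/ha (full precision)
    kcl_k2o: float  # kg K2O/ha supplied by KCl
    k2so4_k2o: float  # kg K2O/ha supplied by K2SO4
    n_rate: float = 100.0  # basal N, kg/ha
    p2o5_rate: float = 90.0  # basal P2O5, kg/ha
    kcl_cl_fraction: float = KCL_CL_FRACTION
    kcl_k2o_fraction: float = KCL_K2O_FRACTION

    @property
    def kcl_mass_rounded(self) -> int:
        """KCl mass rounded to whole kg for reporting."""
        return round(self.kcl_mass)


def build_scheme(
    cl_rate: float,
    basal_k2o_target: float = DEFAULT_BASAL_K2O,
    cl_fraction: float = KCL_CL_FRACTION,
    k2o_fraction: float = KCL_K2O_FRACTION,
) -> FertilizerScheme:
    """Derive the KCl / K₂SO₄ split that delivers ``cl_rate`` kg Cl/ha.

    KCl supplies the chloride; the remaining basal K₂O requirement is topped
    up with K₂SO₄.  Raises :class:`SchemeInfeasibleError` (naming the largest
    feasible dose) when the KCl-derived K₂O would exceed the basal target.
    """
    cl_rate = _require_finite_nonneg("cl_rate", cl_rate)
    if not 0 < cl_fraction <= 1 or not 0 < k2o_fraction <= 1:
        raise DomainError("fertilizer grades must lie in (0, 1]")
    basal_k2o_target = _require_finite_nonneg("basal_k2o_target", basal_k2o_target)
    kcl_mass = cl_rate / cl_fraction
    kcl_k2o = kcl_mass * k2o_fraction
    if kcl_k2o > basal_k2o_target + 1e-9:
        max_cl = basal_k2o_target / k2o_fraction * cl_fraction
        raise SchemeInfeasibleError(
            f"dose {cl_rate} kg Cl/ha needs {kcl_k2o:.1f} kg K2O from KCl, "
            f"exceeding the basal target {basal_k2o_target}; the maximum "
            f"feasible Cl rate is {max_cl:.1f} kg/ha",
            max_feasible_cl_rate=max_cl,
        )
    return FertilizerScheme(
        cl_rate=cl_rate,
        kcl_mass=kcl_mass,
        kcl_k2o=kcl_k2o,
        k2so4_k2o=basal_k2o_target - kcl_k2o,
        kcl_cl_fraction=cl_fraction,
        kcl_k2o_fraction=k2o_fraction,
    )


def plot_area(
    n_ridges: int = 6, ridge_length_m: float = 12.0, ridge_width_m: float = 0.8
) -> float:
    """Field-plot area in m² from the ridge layout (default 6 × 12 m × 0.8 m)."""
    if n_ridges <= 0 or ridge_length_m <= 0 or ridge_width_m <= 0:
        raise DomainError("plot dimensions must be positive")
    return n_ridges * ridge_length_m * ridge_width_m
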