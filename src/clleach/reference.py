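"""Reference coefficients for the two Northeast-China field sites.

Defaults throughout the package come from a two-year rain-fed potato trial
on a loam (Suihua, black soil) and a sandy loam (Mudanjiang, dark brown
soil): site soil properties, the quadratic rainfall-response coefficients
fitted per treatment and sampling layer, the residual-estimation model
coefficients, and the goodness-of-fit rubric used to judge model validation.
"""

from __future__ import annotations

from dataclasses import dataclass

#: Cl doses of the low/medium/high treatments, kg Cl/ha.
CL_DOSES = {"CK": 0.0, "L": 37.5, "M": 75.0, "H": 112.5}

#: Nominal concentration increment of each dose in the 0-15 cm layer, mg/kg.
DOSE_NOMINAL_MGKG = {"CK": 0.0, "L": 20.0, "M": 40.0, "H": 60.0}


@dataclass(frozen=True)
class SiteSoil:
    texture: str
    bulk_density: float  # g/cm3
    clay: float  # %
    silt: float  # %
    sand: float  # %
    background_cl: tuple[float, float, float]  # mg/kg per layer, pre-sowing
    so4: float  # mg/kg


#: Pre-season soil characterisation, keyed by (site, year).
SITE_SOILS = {
    ("suihua", 2022): SiteSoil("loam", 1.32, 12.9, 37.9, 49.2, (12.5, 11.5, 10.9), 78.3),
    ("mudanjiang", 2022): SiteSoil("sandy_loam", 1.36, 9.8, 34.1, 56.1, (8.6, 9.3, 7.9), 81.9),
    ("suihua", 2023): SiteSoil("loam", 1.31, 12.7, 36.4, 50.9, (10.8, 9.2, 11.0), 55.2),
    ("mudanjiang", 2023): SiteSoil("sandy_loam", 1.38, 10.8, 31.4, 57.8, (10.6, 8.7, 9.7), 65.2),
}

DEFAULT_SOILS = {
    "loam": SITE_SOILS[("suihua", 2022)],
    "sandy_loam": SITE_SOILS[("mudanjiang", 2022)],
}

#: Clay contents spanned by the trials, % — the model calibration envelope.
CLAY_ENVELOPE = (9.8, 12.9)

#: Residual-estimation model: Y = b0 + b1*rain + b2*dose + b3*clay (mg/kg).
RESIDUAL_MODEL_COEFFS = (38.518, -0.219, 0.143, 0.557)

#: Published quadratic rainfall-response rows, keyed by
#: (texture, treatment, layer index 0/1/2): (a, b, c, pearson_r) for
#: content = a*rain**2 + b*rain + c.  The Pearson r column is the linear
#: rain-content correlation, not the fit's own R.
LAYER_RESPONSE_ROWS: dict[tuple[str, str, int], tuple[float, float, float, float]] = {
    ("loam", "L", 0): (4.55e-4, -0.27, 41.93, -0.823),
    ("loam", "L", 1): (8.31e-4, -0.39, 50.70, -0.704),
    ("loam", "L", 2): (-7.68e-4, 0.16, 15.55, -0.318),
    ("loam", "M", 0): (1.51e-3, -0.61, 66.42, -0.800),
    ("loam", "M", 1): (-1.28e-3, 0.32, 8.55, -0.650),
    ("loam", "M", 2): (-1.37e-3, 0.35, 11.42, -0.342),
    ("loam", "H", 0): (1.08e-3, -0.49, 64.34, -0.727),
    ("loam", "H", 1): (-1.93e-3, 0.31, 47.98, -0.644),
    ("loam", "H", 2): (-2.04e-3, 0.52, 11.19, -0.131),
    ("sandy_loam", "L", 0): (6.55e-4, -0.32, 44.09, -0.785),
    ("sandy_loam", "L", 1): (2.04e-4, -0.19, 44.10, -0.755),
    ("sandy_loam", "L", 2): (-7.25e-5, -0.02, 20.03, -0.650),
    ("sandy_loam", "M", 0): (8.49e-4, -0.44, 61.21, -0.829),
    ("sandy_loam", "M", 1): (6.68e-5, -0.16, 48.25, -0.750),
    ("sandy_loam", "M", 2): (-3.47e-4, 0.05, 26.95, -0.636),
    ("sandy_loam", "H", 0): (1.01e-3, -0.53, 74.73, -0.836),
    ("sandy_loam", "H", 1): (2.94e-5, -0.19, 61.06, -0.793),
    ("sandy_loam", "H", 2): (-6.03e-4, 0.13, 27.72, -0.674),
}

#: Reported validation metrics per texture (r, R2, NRMSE, PBIAS interval %).
REPORTED_VALIDATION = {
    "loam": {"r": 0.976, "r2": 0.927, "nrmse": 0.054, "pbias": (-9.1, 19.3)},
    "sandy_loam": {"r": 0.969, "r2": 0.933, "nrmse": 0.063, "pbias": (-27.0, 19.0)},
}

#: Safe Cl dose windows (kg Cl/ha) at relative yields 100% and 95%.
REPORTED_SAFE_CL_RANGE = {
    "loam": (51.6, 73.8),
    "sandy_loam": (96.3, 106.8),
}
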