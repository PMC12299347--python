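"""Model-validation metrics and the goodness-of-fit rubric.

Agreement between measured values ``m`` and model-calculated values ``p``
is scored with five statistics:

    r      Pearson correlation
    R²     1 − Σ(p−m)² / Σ(m−m̄)²           (can be negative)
    RMSE   √(Σ(m−p)²/n)                      (mg/kg)
    NRMSE  RMSE / (max(m) − min(m))          (range-normalized)
    PBIAS  Σ(m−p) / Σm × 100                 (%; positive = under-prediction)

Each metric is then labelled medium / high / very_high against the rubric
used in agro-hydrological model evaluation (Moriasi-style bands): |r| > 0.8,
R² > 0.75, NRMSE < 0.5 and |PBIAS| ≤ 25% are "very high".  Printed band
edges overlap, so boundary values are assigned to the better class.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DomainError, InsufficientDataError


class GFI(str, Enum):
    """Goodness-of-fit index classes."""

    MEDIUM = "medium"
    HIGH = "high"
    VERY_HIGH = "very_high"


@dataclass(frozen=True)
class ValidationReport:
    """Metric values plus their rubric labels for one measured/modeled pairing."""

    r: float
    r2: float
    rmse: float  # mg/kg
    nrmse: float
    pbias: float  # %
    n: int
    gfi_labels: dict[str, GFI] = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {
            "r": self.r,
            "r2": self.r2,
            "rmse": self.rmse,
            "nrmse": self.nrmse,
            "pbias_percent": self.pbias,
            "n": self.n,
        }
        d["gfi"] = {k: v.value for k, v in self.gfi_labels.items()}
        return d


def classify_gfi(
    r: float, r2: float, nrmse: float, pbias: float
) -> dict[str, GFI]:
    """Label each metric per the evaluation rubric.

    Boundary values go to the better band (e.g. R² = 0.75 → very_high).
    """
    for name, v in (("r", r), ("r2", r2), ("nrmse", nrmse), ("pbias", pbias)):
        if not np.isfinite(v):
            raise DomainError(f"{name} must be finite to classify, got {v!r}")
    labels: dict[str, GFI] = {}
    a = abs(r)
    labels["r"] = GFI.VERY_HIGH if a > 0.8 else GFI.HIGH if a > 0.6 else GFI.MEDIUM
    labels["r2"] = (
        GFI.VERY_HIGH if r2 >= 0.75 else GFI.HIGH if r2 >= 0.65 else GFI.MEDIUM
    )
    labels["nrmse"] = (
        GFI.VERY_HIGH if nrmse <= 0.5 else GFI.HIGH if nrmse <= 0.7 else GFI.MEDIUM
    )
    p = abs(pbias)
    labels["pbias"] = GFI.VERY_HIGH if p <= 25 else GFI.HIGH if p <= 50 else GFI.MEDIUM
    return labels


def compute_metrics(measured, modeled) -> ValidationReport:
    """Score a measured/modeled series pair and attach rubric labels.

    Requires n ≥ 3, finite values, and a non-constant measured series
    (NRMSE normalizes by the observed range).
    """
    m = np.asarray(measured, dtype=float)
    p = np.asarray(modeled, dtype=float)
    if m.shape != p.shape or m.ndim != 1:
        raise DomainError("measured and modeled must be 1-d and equal length")
    if m.size < 3:
        raise InsufficientDataError(f"need at least 3 pairs, got {m.size}")
    if not (np.all(np.isfinite(m)) and np.all(np.isfinite(p))):
        raise DomainError("series must be finite")
    rng = float(m.max() - m.min())
    if rng == 0:
        raise DomainError("measured series is constant; NRMSE undefined")
    resid = m - p
    sse = float(resid @ resid)
    sst = float(((m - m.mean()) ** 2).sum())
    rmse = float(np.sqrt(sse / m.size))
    r = float(stats.pearsonr(m, p).statistic) if np.ptp(p) > 0 else np.nan
    if not np.isfinite(r):
        # constant modeled series: correlation undefined, report 0
        r = 0.0
    r2 = 1.0 - sse / sst
    nrmse = rmse / rng
    pbias = float(resid.sum() / m.sum() * 100.0) if m.sum() != 0 else np.inf
    labels = (
        classify_gfi(r, r2, nrmse, pbias)
        if np.isfinite(pbias)
        else classify_gfi(r, r2, nrmse, 1e9)
    )
    return ValidationReport(
        r=r, r2=r2, rmse=rmse, nrmse=nrmse, pbias=pbias, n=int(m.size),
        gfi_labels=labels,
    )


def grouped_pbias(
    df: pd.DataFrame,
    by,
    measured: str = "measured",
    modeled: str = "modeled",
) -> tuple[pd.Series, tuple[float, float]]:
    """PBIAS per group plus its (min, max) interval across groups.

    Field validations often report percentage bias as an interval over
    treatments or dates rather than a single pooled number.
    """
    def _pb(g: pd.DataFrame) -> float:
        s = g[measured].sum()
        if s == 0:
            return np.inf
        return float((g[measured] - g[modeled]).sum() / s * 100.0)

    per_group = df.groupby(by).apply(_pb, include_groups=False)
    return per_group, (float(per_group.min()), float(per_group.max()))
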