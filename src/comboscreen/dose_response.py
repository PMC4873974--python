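"""Median-effect dose-response fitting.

The median-effect equation (Chou) unifies sigmoidal dose-effect data:

    fa / fu = (D / Dm)^m,      fu = 1 - fa

where ``fa`` is the fraction affected at dose ``D``, ``Dm`` the dose
producing the half-maximal effect (the operational IC50) and ``m`` the
sigmoidicity slope.  Taking base-10 logs linearises the model,

    log10(fa / (1 - fa)) = m * log10(D) - m * log10(Dm),

so (m, Dm) are obtained by ordinary least squares of the logit of ``fa``
on log-dose.  This is the CalcuSyn convention used throughout the
combination-index machinery in :mod:`comboscreen.combination`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "DoseResponseDataset",
    "MedianEffectModel",
    "MedianEffectResults",
    "fit_median_effect",
    "ic50",
]

#: fa values outside this open band are excluded before the logit transform
DEFAULT_CLIP_BAND = (0.005, 0.995)


@dataclass(frozen=True)
class DoseResponseDataset:
    """One dose-response series: doses (μM) and fractions affected.

    ``fa`` is 1 minus the mean normalised viability at each dose.  Doses
    must be strictly positive; they are sorted ascending on construction.
    """

    series_id: str
    doses: np.ndarray
    fa: np.ndarray
    n_replicates: int = 1

    def __post_init__(self) -> None:
        doses = np.asarray(self.doses, dtype=float)
        fa = np.asarray(self.fa, dtype=float)
        if doses.ndim != 1 or fa.ndim != 1 or len(doses) != len(fa):
            raise ValueError("doses and fa must be 1-D and equal length")
        if np.any(doses <= 0):
            raise ValueError(f"{self.series_id}: doses must be strictly positive")
        order = np.argsort(doses)
        object.__setattr__(self, "doses", doses[order])
        object.__setattr__(self, "fa", fa[order])

    @staticmethod
    def from_viability(series_id: str, doses: Sequence[float],
                       viability: Sequence[float],
                       replicate: Sequence[int] | None = None) -> "DoseResponseDataset":
        """Build a dataset from per-well viability, averaging replicates per dose."""
        df = np.asarray(doses, dtype=float)
        vi = np.asarray(viability, dtype=float)
        if np.any(np.isnan(vi)):
            raise ValueError(f"{series_id}: NaN viability")
        uniq = np.unique(df)
        fa = np.array([1.0 - vi[df == d].mean() for d in uniq])
        n_rep = int(round(len(df) / len(uniq))) if len(uniq) else 0
        return DoseResponseDataset(series_id, uniq, fa, n_replicates=max(n_rep, 1))


@dataclass
class MedianEffectResults:
    """Fitted median-effect parameters for one series.

    Attributes
    ----------
    m : float
        Sigmoidicity slope (unitless); > 0 for a well-behaved fit.
    dm : float
        Median-effect dose in μM; the operational IC50.
    r_squared : float
        Coefficient of determination of the logit-log regression.
    n_points_used : int
        Dose points retained after clipping fa to the open band.
    status : str
        "ok", "fit_failed" (fewer than 2 usable points) or
        "nonpositive_slope".
    """

    series_id: str
    m: float = np.nan
    dm: float = np.nan
    r_squared: float = np.nan
    n_points_used: int = 0
    status: str = "ok"
    model: "MedianEffectModel | None" = field(default=None, repr=False)

    @property
    def ok(self) -> bool:
        return self.status == "ok"

    def predict_fa(self, dose):
        """Fraction affected predicted at ``dose`` (μM)."""
        dose = np.asarray(dose, dtype=float)
        ratio = (dose / self.dm) ** self.m
        return ratio / (1.0 + ratio)

    def dx_at_effect(self, fa):
        """Dose Dx producing effect level ``fa``: Dx = Dm (fa/(1-fa))^(1/m)."""
        fa = np.asarray(fa, dtype=float)
        if np.any(fa <= 0) or np.any(fa >= 1):
            raise ValueError("fa must lie strictly inside (0, 1)")
        if not self.ok:
            raise ValueError(f"{self.series_id}: cannot invert a failed fit ({self.status})")
        out = self.dm * (fa / (1.0 - fa)) ** (1.0 / self.m)
        return float(out) if out.ndim == 0 else out

    @property
    def ic50(self) -> float:
        """Alias for ``dm`` (dose of half-maximal effect)."""
        return self.dm

    def summary(self) -> str:
        lines = [
            "Median-effect fit",
            "=" * 40,
            f"series:        {self.series_id}",
            f"status:        {self.status}",
            f"m (slope):     {self.m:.6g}",
            f"Dm = IC50 (uM):{self.dm:.6g}",
            f"R-squared:     {self.r_squared:.6g}",
            f"points used:   {self.n_points_used}",
        ]
        return "\n".join(lines)


class MedianEffectModel:
    """Least-squares fit of the linearised median-effect equation.

    Parameters
    ----------
    data : DoseResponseDataset
        Dose points with fractions affected (replicates already averaged).
    clip_band : (float, float)
        Open fa interval retained for the logit transform; points at or
        outside the band are excluded (the logit diverges at 0 and 1 and
        plate readers saturate there).
    """

    def __init__(self, data: DoseResponseDataset,
                 clip_band: tuple[float, float] = DEFAULT_CLIP_BAND):
        lo, hi = clip_band
        if not (0.0 <= lo < hi <= 1.0):
            raise ValueError("clip band must satisfy 0 <= lo < hi <= 1")
        self.data = data
        self.clip_band = (float(lo), float(hi))

    def fit(self) -> MedianEffectResults:
        lo, hi = self.clip_band
        fa = self.data.fa
        usable = (fa > lo) & (fa < hi)
        n_used = int(usable.sum())
        res = MedianEffectResults(self.data.series_id, n_points_used=n_used, model=self)
        if n_used < 2:
            res.status = "fit_failed"
            return res
        x = np.log10(self.data.doses[usable])
        y = np.log10(fa[usable] / (1.0 - fa[usable]))
        slope, intercept = np.polyfit(x, y, 1)
        yhat = slope * x + intercept
        ss_res = float(np.sum((y - yhat) ** 2))
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        res.r_squared = 1.0 if ss_tot == 0 else max(0.0, 1.0 - ss_res / ss_tot)
        if slope <= 0:
            res.status = "nonpositive_slope"
            res.m = float(slope)
            return res
        res.m = float(slope)
        res.dm = float(10.0 ** (-intercept / slope))
        return res


def fit_median_effect(data: DoseResponseDataset,
                      clip_band: tuple[float, float] = DEFAULT_CLIP_BAND) -> MedianEffectResults:
    """Convenience wrapper: ``MedianEffectModel(data, clip_band).fit()``."""
    return MedianEffectModel(data, clip_band).fit()


def ic50(data: DoseResponseDataset) -> float:
    """IC50 of a series, defined as the fitted median-effect dose Dm."""
    res = fit_median_effect(data)
    if not res.ok:
        raise ValueError(f"{data.series_id}: IC50 undefined, fit status {res.status}")
    return res.dm
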