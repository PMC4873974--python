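"""Chou-Talalay combination-index analysis for fixed-ratio drug pairs.

A pair of drugs is mixed at the equipotent ratio (the ratio of their
IC50s) and the mixture is serially diluted; the combined series is itself
fitted by the median-effect model on total dose.  The combination index
at effect level ``fa`` uses the mutually-exclusive two-term form

    CI(fa) = D1 / Dx1(fa) + D2 / Dx2(fa)

where D_i = rho_i * Dtotal(fa) is the amount of drug i in the mixture
producing ``fa`` (from the combination fit) and Dx_i(fa) is the dose of
drug i alone producing the same effect (from the single-agent fits).
CI < 1 indicates Loewe synergy, CI = 1 additivity, CI > 1 antagonism.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dose_response import DoseResponseDataset, MedianEffectModel, MedianEffectResults

__all__ = [
    "ComboDesign",
    "CombinationIndexModel",
    "CombinationIndexResults",
    "build_design",
    "combination_index",
    "classify_ci",
    "DEFAULT_CI_BINS",
    "DEFAULT_DILUTION_FACTORS",
    "CATEGORIES",
]

DEFAULT_DILUTION_FACTORS = (1, 2, 4, 8)

#: upper CI bound of each category, scanned in order; the last bin is open
DEFAULT_CI_BINS = {
    "synergism": 0.7,
    "moderate_synergism": 0.9,
    "nearly_additive": 1.1,
    "antagonism": np.inf,
}

CATEGORIES = tuple(DEFAULT_CI_BINS)


@dataclass(frozen=True)
class ComboDesign:
    """Fixed-ratio mixture design for one drug pair.

    rho1/rho2 are the dose fractions each drug contributes to the total
    mixture dose; at the equipotent ratio rho1 = IC50_1/(IC50_1+IC50_2).
    The undiluted ("1:1") mixture delivers each drug at its IC50; level j
    divides the top total dose by ``dilution_factors[j]``.
    """

    pair_id: str
    rho1: float
    rho2: float
    top_doses: tuple[float, float]
    dilution_factors: tuple[int, ...] = DEFAULT_DILUTION_FACTORS

    def __post_init__(self) -> None:
        if not (0 < self.rho1 < 1 and 0 < self.rho2 < 1):
            raise ValueError("dose fractions must lie in (0, 1)")
        if abs(self.rho1 + self.rho2 - 1.0) > 1e-9:
            raise ValueError("rho1 + rho2 must equal 1")
        if any(f <= 0 for f in self.dilution_factors):
            raise ValueError("dilution factors must be positive")

    @property
    def top_total_dose(self) -> float:
        return self.top_doses[0] + self.top_doses[1]

    @property
    def total_doses(self) -> np.ndarray:
        """Total mixture dose at each dilution level, descending."""
        return self.top_total_dose / np.asarray(self.dilution_factors, dtype=float)


def build_design(fit_a: MedianEffectResults, fit_b: MedianEffectResults,
                 dilution_factors=DEFAULT_DILUTION_FACTORS,
                 pair_id: str | None = None) -> ComboDesign:
    """Equipotent-ratio design from two single-agent fits.

    Raises ``ValueError`` if either fit failed: a pair without both IC50s
    cannot be designed and is flagged upstream.
    """
    for f in (fit_a, fit_b):
        if not f.ok:
            raise ValueError(f"cannot build design: fit for {f.series_id} "
                             f"has status {f.status}")
    rho1 = fit_a.dm / (fit_a.dm + fit_b.dm)
    return ComboDesign(
        pair_id=pair_id or f"{fit_a.series_id}+{fit_b.series_id}",
        rho1=rho1,
        rho2=1.0 - rho1,
        top_doses=(fit_a.dm, fit_b.dm),
        dilution_factors=tuple(int(f) for f in dilution_factors),
    )


def classify_ci(ci: float, bins=None) -> str:
    """Map a combination index to its synergy category.

    Default bins: CI < 0.7 synergism; [0.7, 0.9) moderate synergism;
    [0.9, 1.1] nearly additive; > 1.1 antagonism.  CI < 1 always lands in
    a synergy class or the lower half of nearly-additive.
    """
    if not np.isfinite(ci) or ci <= 0:
        raise ValueError(f"combination index must be positive and finite, got {ci}")
    bins = DEFAULT_CI_BINS if bins is None else bins
    for category, upper in bins.items():
        if ci < upper:
            return category
    return list(bins)[-1]  # ci == inf bound edge; cannot happen with default bins


@dataclass
class CombinationIndexResults:
    """Fa-CI profile and synergy call for one drug pair.

    ``ci_at_ed50`` is CI evaluated at the median effective dose
    (fa = 0.5) from the fitted combination curve; ``ci_at_points`` is CI
    at each measured (total dose, observed fa) pair, computed without the
    combination fit.  ``fa_at_top`` is the fitted fraction affected at
    the undiluted IC50-mixture, the x-coordinate of the screen's Fa-CI
    ranking plot.
    """

    pair_id: str
    design: ComboDesign
    combo_fit: MedianEffectResults
    fa_grid: np.ndarray = field(default_factory=lambda: np.array([]))
    ci_values: np.ndarray = field(default_factory=lambda: np.array([]))
    ci_at_ed50: float = np.nan
    ci_at_points: np.ndarray = field(default_factory=lambda: np.array([]))
    fa_at_top: float = np.nan
    category: str | None = None
    status: str = "ok"

    @property
    def ok(self) -> bool:
        return self.status == "ok"

    def summary(self) -> str:
        lines = [
            "Combination-index analysis",
            "=" * 44,
            f"pair:            {self.pair_id}",
            f"status:          {self.status}",
            f"mixture ratio:   {self.design.rho1:.4f} : {self.design.rho2:.4f}",
            f"combo m, Dm:     {self.combo_fit.m:.4g}, {self.combo_fit.dm:.4g} uM",
            f"CI at ED50:      {self.ci_at_ed50:.4g}",
            f"category:        {self.category}",
            f"Fa at IC50 mix:  {self.fa_at_top:.4g}",
        ]
        return "\n".join(lines)


class CombinationIndexModel:
    """Fit a fixed-ratio combination series and derive its Fa-CI profile.

    Parameters
    ----------
    fit_a, fit_b : MedianEffectResults
        Single-agent median-effect fits (must be successful).
    combo_data : DoseResponseDataset
        Total mixture dose versus fraction affected for the combination.
    design : ComboDesign
        Mixture composition (dose fractions, top doses, dilutions).
    fa_grid : array-like, optional
        Effect levels for the CI profile; default 0.01 ... 0.99 in steps
        of 0.01.
    bins : mapping, optional
        Category bins passed to :func:`classify_ci`.
    """

    def __init__(self, fit_a: MedianEffectResults, fit_b: MedianEffectResults,
                 combo_data: DoseResponseDataset, design: ComboDesign,
                 fa_grid=None, bins=None):
        for f in (fit_a, fit_b):
            if not f.ok:
                raise ValueError(f"single-agent fit {f.series_id} failed "
                                 f"({f.status})")
        self.fit_a = fit_a
        self.fit_b = fit_b
        self.combo_data = combo_data
        self.design = design
        self.fa_grid = (np.round(np.arange(0.01, 1.0, 0.01), 10)
                        if fa_grid is None else np.asarray(fa_grid, dtype=float))
        if np.any(self.fa_grid <= 0) or np.any(self.fa_grid >= 1):
            raise ValueError("fa grid must lie strictly inside (0, 1)")
        self.bins = bins

    def _ci_at(self, total_dose, fa):
        """Two-term CI at observed (total dose, fa), single-agent fits only."""
        d1 = self.design.rho1 * np.asarray(total_dose, dtype=float)
        d2 = self.design.rho2 * np.asarray(total_dose, dtype=float)
        return d1 / self.fit_a.dx_at_effect(fa) + d2 / self.fit_b.dx_at_effect(fa)

    def fit(self) -> CombinationIndexResults:
        combo_fit = MedianEffectModel(self.combo_data).fit()
        res = CombinationIndexResults(self.design.pair_id, self.design, combo_fit)
        if not combo_fit.ok:
            res.status = f"combo_{combo_fit.status}"
            return res
        # CI(fa) with Dtotal(fa) from the combination fit
        d_total = combo_fit.dx_at_effect(self.fa_grid)
        res.fa_grid = self.fa_grid
        res.ci_values = self._ci_at(d_total, self.fa_grid)
        res.ci_at_ed50 = float(self._ci_at(combo_fit.dm, 0.5))
        # CI at the measured points: observed fa, no combination fit involved
        lo, hi = 1e-4, 1 - 1e-4
        fa_obs = np.clip(self.combo_data.fa, lo, hi)
        res.ci_at_points = self._ci_at(self.combo_data.doses, fa_obs)
        res.fa_at_top = float(combo_fit.predict_fa(self.design.top_total_dose))
        res.category = classify_ci(res.ci_at_ed50, self.bins)
        return res


def combination_index(fit_a: MedianEffectResults, fit_b: MedianEffectResults,
                      combo_data: DoseResponseDataset, design: ComboDesign,
                      fa_grid=None, bins=None) -> CombinationIndexResults:
    """Convenience wrapper around :class:`CombinationIndexModel`."""
    return CombinationIndexModel(fit_a, fit_b, combo_data, design,
                                 fa_grid=fa_grid, bins=bins).fit()
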