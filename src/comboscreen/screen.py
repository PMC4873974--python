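"""Screen-level aggregation of combination-index results.

Enumerates the all-pairs design, tallies synergy categories across the
screen, ranks pairs by their Fa-CI coordinates at the IC50 mixture, and
attributes synergies (CI < 1) to drugs targeting synthetic-lethal genes.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import pandas as pd

from .combination import CATEGORIES, CombinationIndexResults

__all__ = ["DrugRecord", "ScreenSummary", "enumerate_pairs", "tally_screen",
           "rank_fa_ci"]


@dataclass(frozen=True)
class DrugRecord:
    """Panel annotation for one drug."""

    drug_id: str
    name: str = ""
    target_gene: str = ""
    target_class: str = "other"
    ic50: float | None = None


def enumerate_pairs(panel: list[DrugRecord]) -> list[tuple[str, str]]:
    """All n(n-1)/2 unordered drug pairs of a panel; ids must be unique."""
    ids = [d.drug_id for d in panel]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate drug ids in panel")
    if len(ids) < 2:
        raise ValueError("need at least 2 drugs to form pairs")
    return list(itertools.combinations(ids, 2))


@dataclass
class ScreenSummary:
    """Category tallies and synthetic-lethal attribution for one screen.

    ``sl_synergy_fraction`` is the fraction of synergy pairs
    (CI at ED50 < 1) containing at least one drug whose target class is
    synthetic_lethal; ``None`` when no pair is synergistic.
    """

    n_pairs: int = 0
    n_classified: int = 0
    n_failed: int = 0
    counts: dict = field(default_factory=dict)
    percentages: dict = field(default_factory=dict)
    synergy_pairs: list = field(default_factory=list)
    sl_synergy_fraction: float | None = None
    ranked: pd.DataFrame = field(default_factory=pd.DataFrame)
    failed_pairs: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "n_pairs": self.n_pairs,
            "n_classified": self.n_classified,
            "n_failed": self.n_failed,
            "counts": dict(self.counts),
            "percentages": dict(self.percentages),
            "synergy_pairs": list(self.synergy_pairs),
            "sl_synergy_fraction": self.sl_synergy_fraction,
            "failed_pairs": list(self.failed_pairs),
        }

    def summary(self) -> str:
        lines = ["Screen summary", "=" * 40,
                 f"pairs analysed:   {self.n_pairs}",
                 f"classified:       {self.n_classified}",
                 f"failed fits:      {self.n_failed}"]
        for cat in CATEGORIES:
            lines.append(f"  {cat:<20s} {self.counts.get(cat, 0):4d}  "
                         f"({self.percentages.get(cat, 0.0):5.1f}%)")
        frac = ("n/a" if self.sl_synergy_fraction is None
                else f"{100 * self.sl_synergy_fraction:.1f}%")
        lines.append(f"synergies (CI<1) with an SL-targeting drug: {frac}")
        return "\n".join(lines)


def rank_fa_ci(results: list[CombinationIndexResults]) -> pd.DataFrame:
    """Rank pairs ascending by CI at ED50.

    Ties break by descending Fa at the IC50 mixture, then by pair id;
    the leading rank is the most synergistic pair with the best effect.
    Failed profiles are excluded.
    """
    rows = [{"pair_id": r.pair_id, "ci_at_ed50": r.ci_at_ed50,
             "fa_at_top": r.fa_at_top, "category": r.category}
            for r in results if r.ok]
    table = pd.DataFrame(rows, columns=["pair_id", "ci_at_ed50", "fa_at_top",
                                        "category"])
    table = table.sort_values(
        ["ci_at_ed50", "fa_at_top", "pair_id"],
        ascending=[True, False, True]).reset_index(drop=True)
    table.index = table.index + 1
    table.index.name = "rank"
    return table


def tally_screen(results: list[CombinationIndexResults],
                 panel: list[DrugRecord]) -> ScreenSummary:
    """Aggregate per-pair CI results into the screen-level summary.

    Percentages are computed over classified pairs only; failures are
    counted and listed separately, never coerced into a category.  A pair
    counts toward synthetic-lethal attribution when at least one of its
    drugs targets a synthetic-lethal gene.
    """
    class_by_drug = {d.drug_id: d.target_class for d in panel}
    summary = ScreenSummary(n_pairs=len(results))
    counts = {cat: 0 for cat in CATEGORIES}
    pair_drugs: dict[str, tuple[str, str]] = {}
    for r in results:
        if not r.ok or r.category is None:
            summary.n_failed += 1
            summary.failed_pairs.append({"pair_id": r.pair_id, "status": r.status})
            continue
        counts[r.category] = counts.get(r.category, 0) + 1
        summary.n_classified += 1
        if r.ci_at_ed50 < 1.0:
            summary.synergy_pairs.append(r.pair_id)
            pair_drugs[r.pair_id] = (r.design.pair_id.split("+") + ["", ""])[:2]
    summary.counts = counts
    if summary.n_classified:
        summary.percentages = {cat: 100.0 * n / summary.n_classified
                               for cat, n in counts.items()}
    else:
        summary.percentages = {cat: 0.0 for cat in counts}
    if summary.synergy_pairs:
        n_sl = 0
        for pid in summary.synergy_pairs:
            d1, d2 = pair_drugs[pid]
            if (class_by_drug.get(d1) == "synthetic_lethal"
                    or class_by_drug.get(d2) == "synthetic_lethal"):
                n_sl += 1
        summary.sl_synergy_fraction = n_sl / len(summary.synergy_pairs)
    summary.ranked = rank_fa_ci(results)
    return summary
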