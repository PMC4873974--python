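"""High-level pipeline stages tying the models together.

Each function consumes/produces the plain-text formats in
:mod:`comboscreen.io`, so the CLI subcommands stay one call deep and the
same entry points are usable from Python.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from . import io as csio
from .combination import (ComboDesign, CombinationIndexModel,
                          CombinationIndexResults)
from .dose_response import DoseResponseDataset, MedianEffectModel
from .enrichment import TFBSPermutationTest, count_sites, ora_table, promoter_windows
from .expression import ExpressionMatrix, ModeratedTTest, zscore_by_gene
from .screen import DrugRecord, ScreenSummary, tally_screen
from .simulate import (ExpressionTruth, RegulatoryTruth, gen_expression,
                       gen_gene_annotation, gen_regulatory, gen_screen)

__all__ = [
    "simulate_inputs", "fit_single_agents", "run_combination_indices",
    "summarise_screen", "run_differential_expression", "run_tfbs_enrichment",
]


def simulate_inputs(out_dir, config: csio.PipelineConfig,
                    n_deg: int = 50, p_genes: int = 2000,
                    log2fc: float = 2.0, sigma: float = 0.25,
                    n_tfs: int = 5, n_enriched_tfs: int = 1) -> dict:
    """Generate the full synthetic study into ``out_dir``.

    Writes the screen tables (panel, single-agent and combination
    viability, truth), the expression matrix and sample sheet, the gene
    annotation, the TFBS BED and a truth JSON.  Returns the file map.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)

    screen = gen_screen(n_drugs=config.n_drugs, seed=int(rng.integers(2 ** 31)),
                        noise_sd=config.noise_sd, replicates=config.replicates,
                        dilution_factors=config.dilution_factors)
    csio.write_drug_panel(screen.panel, out / "drug_panel.tsv")
    csio.write_viability(screen.single_agent, out / "viability_single.csv")
    csio.write_combination_viability(screen.combinations, out / "viability_combo.csv")
    csio.write_table(screen.pair_truth, out / "pair_truth.tsv")

    deg_ids = [f"DEG{i:04d}" for i in range(n_deg)]
    signs = np.where(rng.random(n_deg) < 0.5, 1.0, -1.0)
    expr_truth = ExpressionTruth(
        deg_genes=tuple(deg_ids),
        log2fc_planted={g: float(s * log2fc) for g, s in zip(deg_ids, signs)},
        sigma=sigma, n_per_group=config.replicates)
    matrix, sheet = gen_expression(expr_truth, p_genes=p_genes,
                                   seed=int(rng.integers(2 ** 31)))
    csio.write_expression(matrix, out / "expression.tsv")
    csio.write_sample_sheet(sheet, out / "samples.tsv")

    annotation = gen_gene_annotation(matrix.index, seed=int(rng.integers(2 ** 31)))
    csio.write_gene_annotation(annotation, out / "genes.tsv")
    tfs = tuple(f"TF{i + 1}" for i in range(n_tfs))
    reg_truth = RegulatoryTruth(tfs=tfs, enriched_tfs=tfs[:n_enriched_tfs])
    bed = gen_regulatory(reg_truth, annotation, deg_genes=deg_ids,
                         seed=int(rng.integers(2 ** 31)),
                         upstream=config.upstream, downstream=config.downstream)
    csio.write_bed(bed, out / "tfbs.bed")

    truth = {
        "deg_genes": deg_ids,
        "log2fc": log2fc,
        "sigma": sigma,
        "enriched_tfs": list(reg_truth.enriched_tfs),
        "rate_background": reg_truth.rate_background,
        "rate_enriched": reg_truth.rate_enriched,
        "alpha_true": {p.pair_id: p.alpha_true for p in screen.pairs.values()},
    }
    csio.write_json(truth, out / "truth.json")
    return {name: str(out / name) for name in (
        "drug_panel.tsv", "viability_single.csv", "viability_combo.csv",
        "pair_truth.tsv", "expression.tsv", "samples.tsv", "genes.tsv",
        "tfbs.bed", "truth.json")}


def fit_single_agents(viability: pd.DataFrame,
                      config: csio.PipelineConfig | None = None) -> pd.DataFrame:
    """Median-effect fit per drug; one row per series."""
    config = config or csio.PipelineConfig()
    rows = []
    for drug_id, sub in viability.groupby("drug_id", sort=True):
        ds = DoseResponseDataset.from_viability(
            str(drug_id), sub["dose_uM"], sub["viability"])
        fit = MedianEffectModel(ds, (config.clip_lo, config.clip_hi)).fit()
        rows.append({"series_id": fit.series_id, "m": fit.m, "dm": fit.dm,
                     "r2": fit.r_squared, "n_points_used": fit.n_points_used,
                     "status": fit.status})
    return pd.DataFrame(rows)


def run_combination_indices(combo_viability: pd.DataFrame, fits: pd.DataFrame,
                            config: csio.PipelineConfig | None = None
                            ) -> tuple[list[CombinationIndexResults], pd.DataFrame]:
    """CI analysis for every pair in the combination table.

    ``fits`` is the single-agent fit table from :func:`fit_single_agents`.
    Returns the per-pair results plus a flat summary frame.
    """
    config = config or csio.PipelineConfig()
    from .dose_response import MedianEffectResults
    fit_by_id = {}
    for row in fits.itertuples(index=False):
        fit_by_id[row.series_id] = MedianEffectResults(
            series_id=row.series_id, m=row.m, dm=row.dm, r_squared=row.r2,
            n_points_used=int(row.n_points_used), status=row.status)
    results = []
    for pair_id, sub in combo_viability.groupby("pair_id", sort=True):
        d1, d2 = sub["drug1"].iloc[0], sub["drug2"].iloc[0]
        fit_a, fit_b = fit_by_id.get(d1), fit_by_id.get(d2)
        total = sub["dose1_uM"] + sub["dose2_uM"]
        if fit_a is None or fit_b is None or not (fit_a.ok and fit_b.ok):
            results.append(CombinationIndexResults(
                pair_id=str(pair_id),
                design=ComboDesign(str(pair_id), 0.5, 0.5, (1.0, 1.0)),
                combo_fit=MedianEffectResults(str(pair_id), status="fit_failed"),
                status="single_agent_fit_failed"))
            continue
        rho1 = float((sub["dose1_uM"] / total).iloc[0])
        design = ComboDesign(str(pair_id), rho1, 1.0 - rho1,
                             (fit_a.dm, fit_b.dm), config.dilution_factors)
        ds = DoseResponseDataset.from_viability(str(pair_id), total,
                                                sub["viability"])
        results.append(CombinationIndexModel(
            fit_a, fit_b, ds, design, bins=config.ci_bins_numeric()).fit())
    summary = pd.DataFrame([{
        "pair_id": r.pair_id, "m_c": r.combo_fit.m, "dm_c": r.combo_fit.dm,
        "ci_at_ed50": r.ci_at_ed50, "fa_at_top": r.fa_at_top,
        "category": r.category, "status": r.status} for r in results])
    return results, summary


def summarise_screen(results: list[CombinationIndexResults],
                     panel: pd.DataFrame) -> ScreenSummary:
    records = [DrugRecord(drug_id=row.drug_id, name=getattr(row, "name", ""),
                          target_gene=row.target_gene,
                          target_class=row.target_class)
               for row in panel.itertuples(index=False)]
    return tally_screen(results, records)


def run_differential_expression(matrix: pd.DataFrame, sheet: pd.DataFrame,
                                config: csio.PipelineConfig | None = None):
    config = config or csio.PipelineConfig()
    data = ExpressionMatrix.from_frames(matrix, sheet)
    res = ModeratedTTest(data, fdr_threshold=config.fdr_threshold,
                         fc_threshold=config.fc_threshold).fit()
    zmat, _flagged = zscore_by_gene(matrix)
    return res, zmat


def run_tfbs_enrichment(annotation: pd.DataFrame, bed: pd.DataFrame,
                        expressed, degs,
                        config: csio.PipelineConfig | None = None):
    config = config or csio.PipelineConfig()
    windows = promoter_windows(annotation, upstream=config.upstream,
                               downstream=config.downstream)
    counts = count_sites(windows, bed)
    return TFBSPermutationTest(counts, expressed, degs, n_perm=config.n_perm,
                               seed=config.seed).fit()
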