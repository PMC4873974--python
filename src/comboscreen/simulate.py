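"""Synthetic-data generators with recorded ground truth.

Every input the pipeline consumes can be generated here: single-agent and
fixed-ratio combination viability tables obeying the median-effect
equation, a two-group log2 expression matrix with planted differentially
expressed genes, and promoter TFBS tracks with planted enrichment.  The
generators define the study conditions for all downstream tests; the
truth objects they take record exactly what was planted so estimators can
be scored against it.

Combination data are generated under a constant combination-index model:
for a mixture delivering dose fractions (rho1, rho2) of two drugs at
total dose D, the true fraction affected fa* solves

    rho1 * D / Dx1(fa) + rho2 * D / Dx2(fa) = alpha_true

(the left side is strictly decreasing in fa, so fa* is unique in (0, 1)).
By construction the true CI at every effect level equals ``alpha_true``:
alpha < 1 plants synergy, alpha = 1 Loewe additivity, alpha > 1
antagonism, and alpha is the exact recoverable ground truth of the CI
estimator.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .combination import ComboDesign, DEFAULT_DILUTION_FACTORS

__all__ = [
    "DrugTruth",
    "PairTruth",
    "ExpressionTruth",
    "RegulatoryTruth",
    "AlphaSampler",
    "ScreenDataset",
    "gen_dose_response",
    "gen_combination",
    "gen_screen",
    "gen_expression",
    "gen_gene_annotation",
    "gen_regulatory",
    "default_dose_ladder",
]

VIABILITY_CLIP = (1e-4, 1.0 - 1e-4)


@dataclass(frozen=True)
class DrugTruth:
    """True median-effect parameters and annotation of one drug."""

    drug_id: str
    m_true: float
    dm_true: float  # μM
    target_gene: str = ""
    target_class: str = "other"  # {"synthetic_lethal", "other"}

    def __post_init__(self) -> None:
        if self.m_true <= 0 or self.dm_true <= 0:
            raise ValueError("m_true and dm_true must be positive")
        if self.target_class not in ("synthetic_lethal", "other"):
            raise ValueError(f"unknown target_class {self.target_class!r}")

    def fa(self, dose):
        """Noiseless fraction affected at ``dose`` (μM)."""
        dose = np.asarray(dose, dtype=float)
        r = (dose / self.dm_true) ** self.m_true
        return r / (1.0 + r)

    def dx(self, fa):
        """Dose producing effect ``fa``."""
        fa = np.asarray(fa, dtype=float)
        return self.dm_true * (fa / (1.0 - fa)) ** (1.0 / self.m_true)


@dataclass(frozen=True)
class PairTruth:
    """True interaction level of an unordered drug pair.

    alpha_true is the constant combination index planted by the
    generator: 1 = Loewe additive, < 1 synergistic, > 1 antagonistic.
    """

    drug1_id: str
    drug2_id: str
    alpha_true: float

    def __post_init__(self) -> None:
        if self.alpha_true <= 0:
            raise ValueError("alpha_true must be positive")
        if self.drug1_id == self.drug2_id:
            raise ValueError("pair members must differ (use sham helpers for self-pairs)")

    @property
    def pair_id(self) -> str:
        return f"{self.drug1_id}+{self.drug2_id}"


@dataclass(frozen=True)
class ExpressionTruth:
    """Planted differential-expression design for a two-group experiment."""

    deg_genes: tuple[str, ...]
    log2fc_planted: dict = field(default_factory=dict)  # gene -> signed log2 FC
    sigma: float = 0.25
    n_per_group: int = 3

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.n_per_group < 2:
            raise ValueError("need at least 2 samples per group (variance undefined below)")
        missing = set(self.deg_genes) - set(self.log2fc_planted)
        if missing:
            raise ValueError(f"planted log2fc missing for DEGs: {sorted(missing)[:5]}")


@dataclass(frozen=True)
class RegulatoryTruth:
    """Planted promoter TFBS densities.

    Non-enriched TFs place sites at ``rate_background`` per promoter
    everywhere; enriched TFs use ``rate_enriched`` in DEG promoters and
    the background rate elsewhere.
    """

    tfs: tuple[str, ...]
    enriched_tfs: tuple[str, ...] = ()
    rate_background: float = 0.5
    rate_enriched: float = 2.5
    site_length: int = 10

    def __post_init__(self) -> None:
        if self.rate_background < 0:
            raise ValueError("rate_background must be >= 0")
        if self.rate_enriched < self.rate_background:
            raise ValueError("rate_enriched must be >= rate_background")
        if set(self.enriched_tfs) - set(self.tfs):
            raise ValueError("enriched_tfs must be a subset of tfs")


def default_dose_ladder(truth: DrugTruth, n_points: int = 5, factor: float = 2.0) -> np.ndarray:
    """Serial-dilution ladder centred on the drug's true Dm.

    5 points, 2-fold spacing by default: Dm/4, Dm/2, Dm, 2 Dm, 4 Dm — the
    ladder a screening lab would pick around a pilot IC50.
    """
    half = (n_points - 1) / 2.0
    exponents = np.arange(n_points) - half
    return truth.dm_true * factor ** exponents


def _noisy_viability(fa_true: np.ndarray, replicates: int, noise_sd: float,
                     rng: np.random.Generator) -> np.ndarray:
    """Additive Gaussian noise on the viability scale, clipped to (0, 1)."""
    viability = 1.0 - np.repeat(fa_true, replicates)
    if noise_sd > 0:
        viability = viability + rng.normal(0.0, noise_sd, size=viability.size)
    return np.clip(viability, *VIABILITY_CLIP)


def gen_dose_response(truth: DrugTruth, doses, replicates: int = 3,
                      noise_sd: float = 0.03, seed: int = 0) -> pd.DataFrame:
    """Single-agent viability table under the median-effect model.

    Returns a long-format frame with columns drug_id, dose_uM, replicate,
    viability.  Reproducible: identical arguments and seed give identical
    tables.
    """
    doses = np.asarray(doses, dtype=float)
    if np.any(doses <= 0):
        raise ValueError("doses must be strictly positive")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    fa = truth.fa(doses)
    viability = _noisy_viability(fa, replicates, noise_sd, rng)
    return pd.DataFrame({
        "drug_id": truth.drug_id,
        "dose_uM": np.repeat(doses, replicates),
        "replicate": np.tile(np.arange(1, replicates + 1), len(doses)),
        "viability": viability,
    })


def combination_fa_true(truth_a: DrugTruth, truth_b: DrugTruth,
                        alpha: float, rho1: float, total_dose: float) -> float:
    """Solve the constant-CI model for the true fraction affected.

    Root of rho1*D/Dx1(fa) + rho2*D/Dx2(fa) - alpha in fa; the left term
    decreases monotonically from +inf to 0 on (0, 1) so the root exists
    and is unique.  Bisection (Brent) to 1e-12 on fa.
    """
    rho2 = 1.0 - rho1

    def excess(fa: float) -> float:
        return (rho1 * total_dose / truth_a.dx(fa)
                + rho2 * total_dose / truth_b.dx(fa) - alpha)

    lo, hi = 1e-12, 1.0 - 1e-12
    try:
        return brentq(excess, lo, hi, xtol=1e-12, rtol=8.9e-16)
    except ValueError:
        # numerically out of bracket: dose so extreme fa saturates
        return 1e-6 if excess(lo) < 0 else 1.0 - 1e-6


def gen_combination(truth_a: DrugTruth, truth_b: DrugTruth, pair: PairTruth | None,
                    design: ComboDesign, noise_sd: float = 0.03,
                    seed: int = 0, replicates: int = 3,
                    alpha: float | None = None) -> pd.DataFrame:
    """Fixed-ratio combination viability table under the constant-CI model.

    ``pair`` carries alpha_true for a real pair; pass ``alpha`` directly
    for sham self-combinations.  Columns: pair_id, drug1, drug2,
    dose1_uM, dose2_uM, dilution_level, replicate, viability.
    """
    if alpha is None:
        if pair is None:
            raise ValueError("either pair truth or alpha must be given")
        alpha = pair.alpha_true
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    rng = np.random.default_rng(seed)
    totals = design.total_doses
    if np.any(totals <= 0):
        raise ValueError("design doses must be positive")
    fa_true = np.array([
        combination_fa_true(truth_a, truth_b, alpha, design.rho1, d) for d in totals
    ])
    viability = _noisy_viability(fa_true, replicates, noise_sd, rng)
    n_lv = len(totals)
    return pd.DataFrame({
        "pair_id": design.pair_id,
        "drug1": truth_a.drug_id,
        "drug2": truth_b.drug_id,
        "dose1_uM": np.repeat(design.rho1 * totals, replicates),
        "dose2_uM": np.repeat(design.rho2 * totals, replicates),
        "dilution_level": np.repeat(np.asarray(design.dilution_factors[:n_lv]), replicates),
        "replicate": np.tile(np.arange(1, replicates + 1), n_lv),
        "viability": viability,
    })


@dataclass(frozen=True)
class AlphaSampler:
    """Log-normal interaction-level sampler for screen generation.

    Pairs containing at least one synthetic-lethal-class drug draw from a
    log-normal with median ``median_sl``; all other pairs use
    ``median_other``.  Defaults plant mostly additive-to-antagonistic
    interactions with synergy concentrated in SL-containing pairs, the
    qualitative structure of a synthetic-lethal combination screen.
    """

    median_sl: float = 0.75
    median_other: float = 1.15
    sigma_log: float = 0.35

    def draw(self, contains_sl: bool, rng: np.random.Generator) -> float:
        median = self.median_sl if contains_sl else self.median_other
        return float(np.exp(np.log(median) + self.sigma_log * rng.standard_normal()))


@dataclass
class ScreenDataset:
    """A full synthetic screen: panel truth, viability tables, pair truth."""

    drugs: dict  # drug_id -> DrugTruth
    pairs: dict  # pair_id -> PairTruth
    designs: dict  # pair_id -> ComboDesign
    single_agent: pd.DataFrame
    combinations: pd.DataFrame

    @property
    def panel(self) -> pd.DataFrame:
        return pd.DataFrame([
            {"drug_id": d.drug_id, "name": d.drug_id, "target_gene": d.target_gene,
             "target_class": d.target_class, "m_true": d.m_true, "dm_true": d.dm_true}
            for d in self.drugs.values()
        ])

    @property
    def pair_truth(self) -> pd.DataFrame:
        return pd.DataFrame([
            {"pair_id": p.pair_id, "drug1": p.drug1_id, "drug2": p.drug2_id,
             "alpha_true": p.alpha_true}
            for p in self.pairs.values()
        ])


def gen_screen(n_drugs: int = 20, alpha_sampler: AlphaSampler | None = None,
               sl_fraction: float = 0.5, seed: int = 0,
               noise_sd: float = 0.03, replicates: int = 3,
               dilution_factors=DEFAULT_DILUTION_FACTORS,
               n_single_doses: int = 5) -> ScreenDataset:
    """Generate an all-pairs combination screen with recorded truth.

    ``n_drugs`` drugs (a fraction ``sl_fraction`` of them annotated as
    targeting synthetic-lethal genes) are each assayed alone on a 2-fold
    ladder around their true Dm, and every unordered pair is assayed as an
    equipotent-ratio mixture at the designed serial dilutions.  Drug
    potencies are drawn once per seed: slope m ~ Uniform(0.8, 2.0), Dm
    log-uniform over 0.05-10 μM.
    """
    if n_drugs < 2:
        raise ValueError("need at least 2 drugs")
    rng = np.random.default_rng(seed)
    sampler = alpha_sampler or AlphaSampler()
    n_sl = int(round(sl_fraction * n_drugs))
    drugs: dict[str, DrugTruth] = {}
    for i in range(n_drugs):
        drug_id = f"D{i + 1:02d}"
        drugs[drug_id] = DrugTruth(
            drug_id=drug_id,
            m_true=float(rng.uniform(0.8, 2.0)),
            dm_true=float(np.exp(rng.uniform(np.log(0.05), np.log(10.0)))),
            target_gene=f"GENE{i + 1:02d}",
            target_class="synthetic_lethal" if i < n_sl else "other",
        )

    single_tables = []
    for drug_id, truth in drugs.items():
        doses = default_dose_ladder(truth, n_points=n_single_doses)
        single_tables.append(gen_dose_response(
            truth, doses, replicates=replicates, noise_sd=noise_sd,
            seed=int(rng.integers(2 ** 31))))

    pairs: dict[str, PairTruth] = {}
    designs: dict[str, ComboDesign] = {}
    combo_tables = []
    for a_id, b_id in itertools.combinations(drugs, 2):
        ta, tb = drugs[a_id], drugs[b_id]
        contains_sl = "synthetic_lethal" in (ta.target_class, tb.target_class)
        pair = PairTruth(a_id, b_id, sampler.draw(contains_sl, rng))
        rho1 = ta.dm_true / (ta.dm_true + tb.dm_true)
        design = ComboDesign(pair.pair_id, rho1, 1.0 - rho1,
                             (ta.dm_true, tb.dm_true),
                             tuple(int(f) for f in dilution_factors))
        pairs[pair.pair_id] = pair
        designs[pair.pair_id] = design
        combo_tables.append(gen_combination(
            ta, tb, pair, design, noise_sd=noise_sd,
            seed=int(rng.integers(2 ** 31)), replicates=replicates))

    return ScreenDataset(
        drugs=drugs, pairs=pairs, designs=designs,
        single_agent=pd.concat(single_tables, ignore_index=True),
        combinations=pd.concat(combo_tables, ignore_index=True),
    )


def gen_expression(truth: ExpressionTruth, p_genes: int = 2000,
                   seed: int = 0, baseline_mean: float = 8.0,
                   baseline_sd: float = 1.5) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Two-group log2 expression matrix with planted DEGs.

    Returns (matrix, sample_sheet).  The matrix is genes x samples;
    control samples draw Normal(baseline_g, sigma), treated samples are
    shifted by the planted log2 fold change for DEGs only.  Baselines
    emulate typical normalised array intensities (log2 scale, mean 8).
    """
    if p_genes < len(truth.deg_genes):
        raise ValueError("p_genes must cover all planted DEGs")
    rng = np.random.default_rng(seed)
    n = truth.n_per_group
    deg_set = set(truth.deg_genes)
    genes = list(truth.deg_genes) + [f"G{i:05d}" for i in range(p_genes - len(deg_set))]
    genes = genes[:p_genes]
    baseline = rng.normal(baseline_mean, baseline_sd, size=p_genes)
    shift = np.array([truth.log2fc_planted.get(g, 0.0) for g in genes])
    control = rng.normal(0.0, truth.sigma, size=(p_genes, n)) + baseline[:, None]
    treated = (rng.normal(0.0, truth.sigma, size=(p_genes, n))
               + baseline[:, None] + shift[:, None])
    samples = [f"ctrl_{j + 1}" for j in range(n)] + [f"trt_{j + 1}" for j in range(n)]
    matrix = pd.DataFrame(np.hstack([control, treated]), index=genes, columns=samples)
    matrix.index.name = "gene"
    sheet = pd.DataFrame({
        "sample": samples,
        "group": ["control"] * n + ["treated"] * n,
    })
    return matrix, sheet


def gen_gene_annotation(genes, seed: int = 0, n_chroms: int = 5,
                        chrom_span: int = 50_000_000) -> pd.DataFrame:
    """Random TSS annotation: gene, chrom, tss (0-based), strand."""
    rng = np.random.default_rng(seed)
    genes = list(genes)
    return pd.DataFrame({
        "gene": genes,
        "chrom": [f"chr{int(c) + 1}" for c in rng.integers(n_chroms, size=len(genes))],
        "tss": rng.integers(10_000, chrom_span, size=len(genes)),
        "strand": np.where(rng.random(len(genes)) < 0.5, "+", "-"),
    })


def gen_regulatory(truth: RegulatoryTruth, gene_annotation: pd.DataFrame,
                   deg_genes, seed: int = 0, upstream: int = 5000,
                   downstream: int = 1000) -> pd.DataFrame:
    """TFBS interval set (BED4 records) with planted promoter enrichment.

    Per-promoter site counts are Poisson with the background rate
    everywhere except enriched TFs in DEG promoters, which use the
    enriched rate.  Site starts are uniform within the promoter window
    (−upstream to +downstream of the TSS, transcription-oriented,
    clipped at 0); sites have fixed length ``truth.site_length``.
    Returns a frame with columns chrom, start, end, tf (0-based
    half-open), sorted by chrom then start.
    """
    rng = np.random.default_rng(seed)
    deg_set = set(deg_genes)
    records = []
    for row in gene_annotation.itertuples(index=False):
        if row.strand == "+":
            start = max(0, row.tss - upstream)
            end = row.tss + downstream
        else:
            start = max(0, row.tss - downstream)
            end = row.tss + upstream
        width = max(end - start - truth.site_length, 1)
        is_deg = row.gene in deg_set
        for tf in truth.tfs:
            rate = (truth.rate_enriched
                    if is_deg and tf in truth.enriched_tfs
                    else truth.rate_background)
            k = rng.poisson(rate)
            if k == 0:
                continue
            starts = start + rng.integers(0, width, size=k)
            for s in starts:
                records.append((row.chrom, int(s), int(s) + truth.site_length, tf))
    bed = pd.DataFrame(records, columns=["chrom", "start", "end", "tf"])
    return bed.sort_values(["chrom", "start", "end", "tf"]).reset_index(drop=True)
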