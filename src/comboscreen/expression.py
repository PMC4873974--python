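"""Differential expression by empirical-Bayes moderated t-statistics.

Two-group comparison of a normalised log2 expression matrix.  Per-gene
sample variances s_g^2 (pooled across the two groups, d_g = n1 + n2 - 2
degrees of freedom) are shrunk toward a prior variance s0^2 with prior
degrees of freedom d0:

    s~_g^2 = (d0 * s0^2 + d_g * s_g^2) / (d0 + d_g)

    t_mod  = log2fc_g / (s~_g * sqrt(1/n1 + 1/n2)),   df = d0 + d_g

The prior (d0, s0^2) is estimated by moment-matching the log sample
variances against their theoretical scaled log-F distribution: with
z_g = log s_g^2 and e_g = z_g - digamma(d_g/2) + log(d_g/2),

    Var(e_g) - trigamma(d_g/2) = trigamma(d0/2)
    E(e_g)                     = log s0^2 + digamma(d0/2) - log(d0/2)

and the trigamma equation is inverted by Newton iteration.  When the
excess variance of e_g is non-positive the prior is degenerate
(d0 = infinity) and all gene variances pool to s0^2.  Raw p-values are
two-sided from the t distribution with d0 + d_g df and are corrected by
the Benjamini-Hochberg step-up procedure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ExpressionMatrix",
    "ModeratedTTest",
    "DifferentialExpressionResults",
    "bh_adjust",
    "call_degs",
    "zscore_by_gene",
    "trigamma_inverse",
]


@dataclass(frozen=True)
class ExpressionMatrix:
    """Log2 expression values with a two-group sample assignment.

    ``values`` is genes x samples; ``groups`` maps each sample id to
    "control" or "treated".  Missing values are refused — imputation is
    out of scope and silently dropping wells would bias the variance
    estimates.
    """

    values: pd.DataFrame
    groups: dict

    def __post_init__(self) -> None:
        if self.values.isna().any().any():
            raise ValueError("expression matrix contains missing values")
        unknown = set(self.groups.values()) - {"control", "treated"}
        if unknown:
            raise ValueError(f"unknown group labels: {sorted(unknown)}")
        missing = [s for s in self.values.columns if s not in self.groups]
        if missing:
            raise ValueError(f"samples without group assignment: {missing[:5]}")
        for g in ("control", "treated"):
            if len(self.sample_ids(g)) < 2:
                raise ValueError(f"need at least 2 samples in group {g!r}")

    def sample_ids(self, group: str) -> list:
        return [s for s in self.values.columns if self.groups[s] == group]

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @staticmethod
    def from_frames(matrix: pd.DataFrame, sample_sheet: pd.DataFrame) -> "ExpressionMatrix":
        groups = dict(zip(sample_sheet["sample"], sample_sheet["group"]))
        return ExpressionMatrix(matrix, groups)


def trigamma_inverse(y: float, tol: float = 1e-8, max_iter: int = 50) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration.

    trigamma is strictly decreasing and convex on (0, inf); the iteration
    below (on the inverse scale) converges monotonically from the
    asymptotic starting value x ~ 1/y.  Returns inf for y <= 0.
    """
    if y <= 0:
        return np.inf
    if y > 1e7:  # trigamma(x) ~ 1/x^2 + ... for tiny x
        return 1.0 / np.sqrt(y)
    x = 0.5 + 1.0 / y
    for _ in range(max_iter):
        tri = special.polygamma(1, x)
        # Newton step on the 1/trigamma scale, which is nearly linear in x
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x = x + dif
        if abs(dif / x) < tol:
            return float(x)
    return float(x)  # best effort; caller may apply a fallback


def _fit_variance_prior(s2: np.ndarray, d_g: float,
                        fallback_d0: float = 4.0) -> tuple[float, float]:
    """Moment-match (d0, s0^2) from pooled per-gene variances.

    Genes with exactly zero sample variance carry no information about
    the prior spread and are excluded from the moment fit (log 0).
    """
    s2 = s2[s2 > 0]
    if s2.size < 2:
        return np.inf, float(s2.mean()) if s2.size else 0.0
    z = np.log(s2)
    e = z - special.digamma(d_g / 2.0) + np.log(d_g / 2.0)
    emean = float(e.mean())
    evar = float(e.var(ddof=1)) - float(special.polygamma(1, d_g / 2.0))
    if evar <= 0:
        # no excess spread beyond chi-square sampling noise: degenerate prior
        s0_sq = float(np.exp(emean))
        return np.inf, s0_sq
    half_d0 = trigamma_inverse(evar)
    if not np.isfinite(half_d0) or half_d0 <= 0:
        d0 = fallback_d0
    else:
        d0 = 2.0 * half_d0
    s0_sq = float(np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return d0, s0_sq


@dataclass
class DifferentialExpressionResults:
    """Per-gene moderated-t results and DEG calls.

    ``table`` has one row per gene: log2fc, t_mod, p, fdr, is_deg,
    direction.  ``d0`` and ``s0_sq`` are the empirical-Bayes prior
    degrees of freedom and variance.
    """

    table: pd.DataFrame
    d0: float
    s0_sq: float
    fdr_threshold: float
    fc_threshold: float
    n_per_group: tuple[int, int]
    flags: list = field(default_factory=list)

    @property
    def degs(self) -> pd.Index:
        return self.table.index[self.table["is_deg"]]

    @property
    def up_genes(self) -> pd.Index:
        mask = self.table["is_deg"] & (self.table["direction"] == "up")
        return self.table.index[mask]

    @property
    def down_genes(self) -> pd.Index:
        mask = self.table["is_deg"] & (self.table["direction"] == "down")
        return self.table.index[mask]

    def summary(self) -> str:
        n = len(self.table)
        lines = [
            "Moderated-t differential expression",
            "=" * 44,
            f"genes tested:        {n}",
            f"samples (ctrl, trt): {self.n_per_group}",
            f"prior d0:            {self.d0:.4g}",
            f"prior s0^2:          {self.s0_sq:.4g}",
            f"DEG rule:            FDR <= {self.fdr_threshold}, "
            f"|log2FC| >= {np.log2(self.fc_threshold):.3g}",
            f"DEGs:                {int(self.table['is_deg'].sum())} "
            f"({len(self.up_genes)} up, {len(self.down_genes)} down)",
        ]
        if self.flags:
            lines.append(f"flags:               {'; '.join(self.flags)}")
        return "\n".join(lines)


class ModeratedTTest:
    """Empirical-Bayes moderated two-sample t-test, treated vs control.

    Parameters
    ----------
    data : ExpressionMatrix
    fdr_threshold, fc_threshold : float
        DEG rule: BH-adjusted p <= fdr_threshold and linear fold change
        >= fc_threshold (|log2fc| >= log2 fc_threshold).
    moderation : bool
        ``False`` forces d0 = 0, reproducing the ordinary pooled
        two-sample t (used as a cross-check limit).
    """

    MIN_GENES_FOR_PRIOR = 10

    def __init__(self, data: ExpressionMatrix, fdr_threshold: float = 0.05,
                 fc_threshold: float = 2.0, moderation: bool = True):
        if not (0 < fdr_threshold <= 1):
            raise ValueError("fdr_threshold must lie in (0, 1]")
        if fc_threshold < 1:
            raise ValueError("fc_threshold is a linear fold change >= 1")
        self.data = data
        self.fdr_threshold = fdr_threshold
        self.fc_threshold = fc_threshold
        self.moderation = moderation

    def fit(self) -> DifferentialExpressionResults:
        flags = []
        ctrl = self.data.values[self.data.sample_ids("control")].to_numpy(dtype=float)
        trt = self.data.values[self.data.sample_ids("treated")].to_numpy(dtype=float)
        n1, n2 = ctrl.shape[1], trt.shape[1]
        d_g = n1 + n2 - 2
        log2fc = trt.mean(axis=1) - ctrl.mean(axis=1)
        # pooled two-group variance per gene
        ss = ctrl.var(axis=1, ddof=1) * (n1 - 1) + trt.var(axis=1, ddof=1) * (n2 - 1)
        s2 = ss / d_g

        if not self.moderation:
            d0, s0_sq = 0.0, 0.0
            flags.append("moderation disabled: ordinary pooled t (d0=0)")
        elif len(log2fc) < self.MIN_GENES_FOR_PRIOR:
            d0, s0_sq = 0.0, 0.0
            flags.append(f"fewer than {self.MIN_GENES_FOR_PRIOR} genes: "
                         "fell back to ordinary t")
        else:
            d0, s0_sq = _fit_variance_prior(s2, d_g)

        if np.isinf(d0):
            s2_post = np.full_like(s2, s0_sq)
            df = np.inf
        else:
            s2_post = (d0 * s0_sq + d_g * s2) / (d0 + d_g)
            df = d0 + d_g

        se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
        with np.errstate(divide="ignore", invalid="ignore"):
            t_mod = np.where(se > 0, log2fc / np.where(se > 0, se, 1.0), 0.0)
        # zero variance and zero difference: no evidence either way
        t_mod = np.where((se == 0) & (log2fc == 0), 0.0, t_mod)
        if np.any((se == 0) & (log2fc != 0)):
            # only possible when d0*s0^2 == 0 (unmoderated, constant groups)
            t_mod = np.where((se == 0) & (log2fc != 0),
                             np.sign(log2fc) * np.inf, t_mod)
            flags.append("zero-variance genes with nonzero difference: t=+/-inf")
        p = 2.0 * stats.t.sf(np.abs(t_mod), df)
        table = pd.DataFrame({
            "log2fc": log2fc,
            "t_mod": t_mod,
            "p": p,
        }, index=self.data.genes)
        table = call_degs(table, fdr_threshold=self.fdr_threshold,
                          fc_threshold=self.fc_threshold)
        return DifferentialExpressionResults(
            table=table, d0=d0, s0_sq=s0_sq,
            fdr_threshold=self.fdr_threshold, fc_threshold=self.fc_threshold,
            n_per_group=(n1, n2), flags=flags)


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def call_degs(table: pd.DataFrame, fdr_threshold: float = 0.05,
              fc_threshold: float = 2.0) -> pd.DataFrame:
    """Append fdr, is_deg and direction columns to a (log2fc, p) table.

    A gene is a DEG when its BH-adjusted p is at most ``fdr_threshold``
    and its linear fold change at least ``fc_threshold`` in either
    direction.
    """
    out = table.copy()
    out["fdr"] = bh_adjust(out["p"].to_numpy())
    lfc_cut = np.log2(fc_threshold)
    out["is_deg"] = (out["fdr"] <= fdr_threshold) & (out["log2fc"].abs() >= lfc_cut)
    out["direction"] = np.where(out["log2fc"] >= 0, "up", "down")
    return out


def zscore_by_gene(matrix: pd.DataFrame) -> tuple[pd.DataFrame, list]:
    """Standardise each gene row to mean 0, SD 1 (sample SD, ddof=1).

    Constant rows cannot be standardised; they are emitted as all-zero
    rows and their gene ids returned as flags.
    """
    values = matrix.to_numpy(dtype=float)
    mean = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, ddof=1, keepdims=True)
    flat = (sd == 0).ravel()
    sd_safe = np.where(sd == 0, 1.0, sd)
    z = (values - mean) / sd_safe
    z[flat.nonzero()[0], :] = 0.0
    flagged = matrix.index[flat].tolist()
    return pd.DataFrame(z, index=matrix.index, columns=matrix.columns), flagged
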