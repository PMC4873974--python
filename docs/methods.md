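# Methods

## Dose–response model and fitting

Every viability series — single agent or fixed-ratio mixture — is
modelled by the median-effect equation `fa/fu = (D/Dm)^m` (base-10 logs,
the convention of the median-effect literature). Replicate wells are
averaged to one fraction affected per dose before fitting (the CalcuSyn
convention); `fa = 1 − mean viability`. Points with fa outside the open
band (0.005, 0.995) are excluded before the logit transform, since the
logit is undefined at 0/1 and plate readers saturate; the band is
configurable. Fewer than two usable points gives a flagged `fit_failed`
result and a non-positive slope a flagged `nonpositive_slope` result —
neither is ever silently coerced. Noiseless model data are recovered
exactly (the logit is exactly linear), which the tests assert to 1e−9
relative error.

## Combination index

Mixtures are designed at the equipotent ratio: drug 1 contributes dose
fraction `rho1 = IC50_1/(IC50_1 + IC50_2)` so the undiluted mixture
delivers each drug at its IC50; serial dilution factors default to
(1, 2, 4, 8), i.e. four combination dose points. The CI uses the
mutually-exclusive two-term form; the non-exclusive third term is not
implemented. "CI at ED50" is CI evaluated at fa = 0.5 from the fitted
combination curve, which reduces to
`rho1·Dm_c/Dm_1 + rho2·Dm_c/Dm_2`. CI is also reported at each measured
(total dose, observed fa) point without using the combination fit, as a
fit-free diagnostic. Category bins (configurable): CI < 0.7 synergism,
[0.7, 0.9) moderate synergism, [0.9, 1.1] nearly additive, > 1.1
antagonism — the published CI bands collapsed to four screen-reporting
categories. The Fa–CI profile grid defaults to fa = 0.01 … 0.99.

## Synthetic data: what it emulates and what it does not

The generators define the study conditions for every test.

* **Single agents.** Viability follows the median-effect model with
  additive Gaussian noise on the viability scale (sd 0.03 by default,
  matching how plate readers err), clipped to (0, 1). Dose ladders
  default to 5 points, 2-fold serial, centred on the true Dm — standard
  screening practice.
* **Combinations.** Truth is a *constant-CI* model: the true fraction
  affected at total dose D solves
  `rho1·D/Dx1(fa) + rho2·D/Dx2(fa) = alpha`, found by Brent bisection
  (tolerance 1e−12 on fa; the left side is strictly decreasing, so the
  root is unique). This makes alpha the exact recoverable ground truth
  of the CI estimator at every effect level, and makes the Loewe sham
  identity (a drug combined with itself at alpha = 1 reproduces its own
  single-agent curve) hold exactly. When the two slopes differ the
  combination curve is not exactly median-effect, so the estimator is
  genuinely approximate there — noiseless recovery is still within
  ±0.01 at ED50 on the default 4-point design.
* **Screens.** 20 drugs by default (190 pairs); slopes m ~ U(0.8, 2.0),
  potencies Dm log-uniform over 0.05–10 µM; half the panel annotated as
  targeting synthetic-lethal genes. Interaction levels alpha are drawn
  log-normally (sigma_log 0.35) with median 0.75 for pairs containing a
  synthetic-lethal-targeting drug and 1.15 otherwise, so the generated
  screen shows the qualitative structure of a synthetic-lethal screen —
  a broad mix of interactions with synergy concentrated in SL-containing
  pairs. These are package choices; no published per-pair truth exists
  to calibrate against.
* **Expression.** Two groups of n = 3 replicates by default; control
  values Normal(baseline_g, sigma) with baselines ~ N(8, 1.5) on the
  log2 scale, treated values shifted by the planted log2 fold change for
  DEGs only; one shared sigma (0.25 default). This emulates a normalised
  array matrix, not probe effects, batch structure or variance
  heterogeneity — with a shared sigma the variance prior is degenerate
  (d0 → ∞), so the moderation machinery is additionally exercised on
  heteroscedastic fixtures and against limma.
* **Regulatory tracks.** Promoter site counts are Poisson per promoter
  (background 0.5; enriched TFs 2.5 in DEG promoters), site positions
  uniform in the window, fixed 10 bp length. No sequence content, motif
  structure or conservation weighting is emulated; passing tests show
  the counting and resampling machinery is correct, not that real
  UCSC-track densities behave like Poisson draws.

## Moderated t and FDR

The prior is moment-matched exactly as described in the module docstring:
`e_g = log s_g² − digamma(d_g/2) + log(d_g/2)`; the excess of
`Var(e_g)` over `trigamma(d_g/2)` is inverted through the trigamma
function by Newton iteration (relative tolerance 1e−8, 50 iterations,
fallback d0 = 4 on divergence; non-positive excess ⇒ d0 = ∞ and full
pooling). With fewer than 10 genes the prior is not estimable and the
test falls back to the ordinary pooled t, flagged. The d0 = 0 limit
reproduces the ordinary t exactly and the implementation agrees with
Bioconductor limma on a heteroscedastic fixture (t, p, d0, s0² all
checked in the suite). BH adjustment is the standard step-up procedure
(via statsmodels). The DEG rule is FDR ≤ 0.05 and linear fold change
≥ 2 (|log2FC| ≥ 1); both thresholds configurable. Only the two-group
contrast is implemented; multi-arm designs are handled as independent
pairwise contrasts.

## TFBS permutation test

Promoter windows are −5000/+1000 bp around the TSS,
transcription-oriented (mirrored on the − strand; a flag disables
strand awareness), clipped at 0, 0-based half-open. A site counts for a
gene when it overlaps the window by ≥ 1 bp (configurable rule noted in
the code); a site spanning two windows counts in both. The null draws
k-subsets uniformly without replacement — implemented as the k smallest
entries of rows of uniform variates, chunked so memory stays bounded —
and the *same* draws are reused for every TF, making per-TF p-values
comparable and the cost independent of TF count. The empirical p uses
the add-one estimator `(1 + hits)/(n + 1)`, which cannot return zero and
is conservative; a `plus_one=False` switch gives raw `hits/n` for
sensitivity analysis. n defaults to 10⁵. Degenerate input k = p returns
p = 1 for all TFs, flagged. Because site totals are integers, ties make
the p-value distribution slightly super-uniform under the null; the
calibration test allows for this.

## Over-representation

Gene-set ORA is the one-sided hypergeometric upper tail of the overlap
(scipy), scored as −log10 p and reported top-10; the caller chooses the
DEG subset (up-regulated by default, matching how activated pathways are
usually screened).

## Numerical and interface choices

* Determinism: every generator and the permutation stream take an
  explicit seed; `run-all` with a fixed seed produces byte-identical
  result files.
* All genomic coordinates are 0-based half-open; doses µM; viability a
  fraction in [0, 1] (percent-scale input is rejected, not guessed).
* Failed fits propagate as status flags and are excluded from screen
  percentages rather than coerced.
* Screen aggregation: synthetic-lethal attribution counts a synergy pair
  (CI at ED50 < 1) if at least one member targets a synthetic-lethal
  gene; with no synergy pairs the fraction is reported as not
  applicable. Fa–CI ranking sorts ascending by CI, ties broken by
  descending Fa at the IC50 mixture, then pair id.

## Problem sizes used in the checks

The test suite and acceptance script use a 20-drug screen (190 pairs),
200-seed noise replicates for recovery statistics, 2000-gene expression
matrices (500 genes × 200 simulations for the FDR sweep), and 10⁵
permutations on a 2000-gene × 50-DEG enrichment fixture — sizes chosen
so each statistical bound is tight while a full run stays interactive.

## Known limitations

* The constant-CI generative model is the estimator's own inverse by
  design; it validates the estimator's algebra and noise behaviour, not
  the adequacy of the median-effect model for arbitrary real mixtures.
* Dose-matrix (checkerboard) designs, Bliss/HSA/ZIP scores and
  non-exclusive CI are out of scope.
* The moderated t assumes exchangeable per-gene variances around a
  single prior; no trend or robust variants.
* ORA and the permutation test treat gene sets as unweighted id sets;
  no motif scanning or conservation weighting.
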