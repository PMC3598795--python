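# Methods

This note documents the statistical procedures the package implements, the
defaults it chooses where the field leaves room, and what the synthetic
data generator does and does not emulate.

## Scoring model

Responses are 5-point problem-frequency ratings (0 = never … 4 = almost
always a problem). The transform `score = 25·(4 − raw)` reverse-scores and
linearly maps them onto 0–100 so that higher scores mean better
functioning. Scale scores are means of answered transformed items, with
the *more-than-half* rule: a score is withheld only when strictly more than
50% of the scale's items are missing, so a 2-item subscale with one answer
is still scored. The Total Score is the item-weighted mean over all
analyzed items (67 by default), **not** the mean of subscale scores — with
unequal subscale lengths the two differ, and the item-weighted definition
is the one the scoring rules imply. The sensitive Sexual Functioning
subscale is excluded from the Total and from all psychometric analyses by
default (it attracts block "not applicable" skips); the exclusion set is
configurable per instrument.

Feasibility denominators count every cell of every respondent present in
the table, including fully blank respondents; no exclusion rule is applied.
Because the headline "overall missing" figure can defensibly be computed
over analyzed subscales only or over all subscales, the report exposes both
(`overall_pct`, `overall_pct_all`) rather than guessing.

Printed reports round percentages to 1 decimal and scores to 2; exported
CSVs keep full precision (`%.10g`), which is what the byte-level
determinism guarantees refer to.

## Reliability

Cronbach's α uses sample variances (denominator n−1) with complete-case
(listwise) handling within each scale — the default of the era's standard
statistics packages; a pairwise-covariance option exists behind a flag.
Which convention the original analyses used is not documented anywhere we
could check, so listwise is an explicit assumption. α is computed on the
transformed 0–100 scores; since the transform is one joint affine map, the
raw-scale α is identical and the choice is purely cosmetic. Negative α is
reported as computed, with a warning, never truncated. α-if-item-deleted
physically removes the column and recomputes, and is exactly equal to α of
the reduced matrix by construction (a test asserts this equivalence).

`calibrate_loadings` inverts the standardized-α identity
α = k·r̄/(1 + (k−1)·r̄) with r̄ = λ², giving the equal loading that hits a
target α on the continuous scale; discretizing into 5 ordinal categories
attenuates the realized α slightly (the recovery test allows ±0.05). Note
the identity implies every target α < 1 is reachable for k ≥ 2 (r̄ ≤ 1
always); the error branch exists only for targets outside (0, 1).

## Multitrait scaling

The item–scale matrix correlates every analyzed item with every analyzed
subscale score, pairwise-complete per cell. The own-scale correlation is
corrected for overlap by recomputing the subscale score without the item
(equivalently: the plain correlation with the (k−1)-item reduced score —
tested as an exact equivalence). The source analyses describe the
correction as removing the item "from the Total Score"; standard multitrait
practice, and the structure of the published summary table, point to
own-subscale correction, which is the default here. Item discrimination
passes at own-r ≥ 0.40 (inclusive).

The scaling-success rule — own-scale correlation higher than a competitor's
by at least two standard errors — is stated in the literature as an
approximation without a formula. The default operationalisation is the
Fisher-z difference z(r_own) − z(r_other) ≥ 2·√(2/(n−3)), treating the two
correlations as independent (conservative; the shared item makes them
positively dependent, which would shrink the true SE). A raw-difference
variant (r_own − r_other ≥ 2/√(n−3)) is provided; the method is recorded in
every output, and neither variant is claimed to replicate any published
success count, since those depend on undeposited raw data. The n for a
test is the smaller of the two cells' pairwise ns — the most conservative
defensible choice under pairwise deletion. Undefined cells (zero variance)
are excluded and shrink the denominator with a warning.

## Exploratory factor analysis

Extraction is principal-axis factoring with iterated communalities:
initialise at squared multiple correlations (falling back to max |r| per
row if the correlation matrix is singular), eigen-decompose the reduced
matrix, rebuild communalities from the top-k loadings, repeat to 1e-6.
Negative eigenvalues of the reduced matrix are truncated at zero;
communalities above 1 (Heywood) are clipped and flagged. The extraction
method and factor count of the original analyses are not stated; PAF with
one factor per analyzed subscale (15) is the default, with the input
matrix's eigenvalues returned for Kaiser/scree diagnostics. Pairwise
correlation matrices can be slightly indefinite; eigenvalues above −0.05
are lifted to a nearby PSD matrix, anything worse is an error.

Varimax is the SVD-based iteration on Kaiser-normalized loadings;
communalities are preserved to 1e-10 (tested). Promax powers the varimax
pattern elementwise to |λ|^κ·sign(λ) with κ = 4 (the conventional default),
solves the least-squares transform to that target, and rescales so factors
have unit variance, returning pattern loadings and the factor correlation
matrix (unit diagonal, PSD up to −1e-8).

Salience is judged on absolute **pattern** loadings at 0.30 (inclusive):
exactly one salient loading = simple structure. Deletion candidates must
fail the salience screen *and* improve their subscale's α when deleted;
ranking is by α gain, and nothing is deleted automatically — item deletion
is an analyst decision. A warning fires when the respondent-to-item ratio
is below 5:1, where factor solutions are imprecise.

## Known groups

Five self-report health levels collapse into three groups
(excellent/very good · good · fair/poor). Each scale gets a fixed-effects
one-way ANOVA (listwise per scale, which is why per-row ns drift), with p
from F(g−1, N−g). The effect size is the correlation ratio
η = √(SS_between/SS_total): the published comparison table never names its
effect-size formula, but recomposing each unfootnoted row's ANOVA from its
printed (n, mean, SD) triplets reproduces the printed effect sizes to
2 d.p. under this definition — that recomputation is run in the test suite
and is the evidence for the choice. Cohen's f is available as a property.
`anova_from_summary` is algebraically exact: grand = Σnᵢmᵢ/Σnᵢ,
SSb = Σnᵢ(mᵢ−grand)², SSw = Σ(nᵢ−1)sdᵢ², and equals the raw-data
decomposition whenever the summaries are exact (tested to 1e-9).
Respondents without a health rating are excluded from this stage only. A
scale whose missingness empties one of the groups present in the data is
flagged and skipped, not silently reduced to fewer groups.

## Synthetic data generator

One latent problem-burden trait per subscale, drawn from a multivariate
normal with a configurable inter-factor correlation matrix; the health
group adds an ordered mean shift to every factor (per-factor shift vectors
are configurable to mimic heterogeneous effect sizes). Item latents are
λ·trait + √(1−λ²)·noise, cut at 4 ordered thresholds into raw 0–4
responses, oriented so more burden → higher raw value → lower transformed
score. Missingness is applied afterwards: MCAR cells, then all-or-none
block skips on sensitive subscales.

Reference-scenario defaults: n = 134 respondents split 47/46/41 across
health groups, shifts −0.8/0/+0.8 SD, MCAR rate 0.048, block-skip rate
0.30, thresholds (−1.5, −0.5, 0.5, 1.5). Where the scenario left a value
open, the defaults are λ = 0.8 for every item and an equicorrelation of
0.5 between factors: HRQOL domains in chronic-condition instruments
correlate moderately to strongly (a high Total-score α requires substantial
inter-domain correlation), and λ = 0.8 puts subscale α in the realistic
0.7–0.96 range across the 2–12-item subscale lengths. Symmetric thresholds
give roughly uniform category use; skewed cuts (which real instruments
show on low-burden domains) can be supplied per item.

Each generator stage draws from its own child stream of the seed
(`SeedSequence.spawn`), so adding a stage never perturbs earlier draws and
identical (config, seed) gives bit-identical output.

What the generator does **not** emulate: informative (MNAR) missingness
beyond the block mechanism, differential item functioning, per-item
discrimination heterogeneity within a subscale (unless configured),
response styles (acquiescence, extreme responding), or longitudinal
structure. Tests passing on this model therefore demonstrate the
*estimators* behave correctly under a clean graded-response world; they do
not certify behaviour under real-world response artifacts.

## Problem sizes and numerical choices

Simulation-based tests use n between 500 and 5000 depending on how tight
the asserted bound is (e.g. α recovery ±0.05 at n = 1000; null η < 0.15 at
n = 600; independence limits at n = 5000); these sizes make the stochastic
assertions comfortably stable under their fixed seeds while keeping the
suite fast. Exact identities (overlap correction, summary-vs-raw ANOVA,
deleted-α) are asserted at 1e-9 to 1e-12; iterative procedures (PAF,
varimax) converge at 1e-6/1e-10 with capped iterations and explicit
convergence flags.

## Known limitations

- Published success counts and α values from the original field test are
  not reproducible without the undeposited raw data; the package verifies
  everything that is arithmetically derivable from printed numbers and
  validates the rest by parameter recovery on synthetic data.
- The Fisher-z independence assumption in the scaling test is conservative
  (see above); success rates on correlated scales are slightly
  underestimated relative to a dependence-corrected SE.
- Listwise α on the 67-item Total under diffuse MCAR missingness can rest
  on few complete cases; the pairwise flag is the practical alternative.
- No McDonald's ω, α confidence intervals, CFA/fit indices, post-hoc
  pairwise comparisons, Welch correction or multiplicity adjustment — none
  of these is part of the field-test analysis plan this package implements.
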