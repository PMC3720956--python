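# Methods

## The modelling problem

A stenotopic heathland beetle is surveyed in two locations (A and B) at
fine spatial resolution.  Adults are trapped at 120 stratified sampling
points per location; sedentary larvae are mapped at three nested scales
around each point — the 1×1 m quadrat, its central 50×50 cm quadrat,
and the sixteen 25×25 cm cells of a 4×4 grid.  The combination of life
stage, scale and location yields eight data sets (odd ids location A,
even ids B): adults at the trap (1–2), larvae at 1×1 m (3–4), at
50×50 cm (5–6) and per 25×25 cm cell (7–8).  The questions the pipeline
answers are (i) how well abiotic versus biotic predictors explain each
stage's occurrence and abundance at each scale, (ii) how well models
transfer between stages and locations, and (iii) whether the biotic
contribution is separable from the abiotic one.

## Error families and links

Presence/absence responses are modelled with a logit link under a
binomial family.  A quasibinomial family (dispersion estimated from the
Pearson statistic) is substituted when grouped PA data show Pearson
dispersion above 1.5; strictly binary 0/1 data cannot exhibit estimable
overdispersion, so for them the binomial family is always kept.
Abundance responses use a log link under a negative binomial family
with clumping parameter *k* (variance = μ + μ²/k), estimated by profile
maximum likelihood on log *k* (bounded bracket, tolerance 1e-8).  When
*k̂* exceeds 10 — near-equidispersion, little aggregation — the Poisson
family is used instead; the switch threshold is configurable and the
trigger values are logged.  Quasibinomial models are compared by QAIC
(−2ℓ/ĉ + 2p, with ĉ taken from the largest model in scope) and their
Nagelkerke *R²* is computed from the underlying binomial deviances;
every quasi-model report carries a flag.

Perfect separation of a PA response is detected (coefficients beyond 25
on the logit scale, or solver failure) and replaced by a weakly
ridge-penalized fit with the `separation` flag set; standard errors are
not reported for such fits.

## Screening chain

1. **Univariate screen** — each candidate's single-term GLM is tested
   against the intercept-only model by a likelihood-ratio χ² (1 df);
   candidates with *p* < 0.1 are kept and ranked by explained deviance
   (ties broken lexicographically).  Non-convergent or constant
   candidates are excluded with a logged reason, never fatally.
2. **Correlation filter** — a greedy pass in rank order drops any
   candidate with |Spearman ρ| ≥ 0.7 against an already-retained
   variable.  Scale competition is applied inside this pass: among the
   25 cm / 50 cm / 1 m versions of the same cover variable (or the
   3 m / 6 m versions of a structure variable) only the best-ranked
   scale survives, correlated or not.  Whether scale competition
   precedes or follows the correlation filter is genuinely open; doing
   it within the filter keeps a single rank order authoritative, and
   the choice is recorded in every screening report.
3. **VIF cascade** — VIF_j = 1/(1 − R²_j) from the OLS regression of
   predictor j on the other retained predictors; the largest VIF ≥ 10
   is dropped and the step repeated.  Exact collinearity yields an
   infinite VIF and is removed first.  VIFs are computed on the plain
   predictor design, not the GLM-weighted one, which is the standard
   diagnostic practice.

The judgement-based part of variable selection ("expected relevance in
the literature") is not automatable; it is exposed as an optional
allowlist/blocklist in the screening call.

## Model selection and fit statistics

Minimal adequate models are selected by bidirectional stepwise AIC run
from two starts — the full screened scope (backward-led) and the
intercept-only model (forward-led).  At each step all single-term
additions and deletions are evaluated; the move with the largest AIC
decrease is taken; ties go to fewer parameters and then to the
lexicographically smaller predictor set; stepping stops when no move
strictly decreases AIC, and the lower-AIC endpoint wins.  The FULL
model is selected by the same procedure over the union of the ABIOT and
BIOT MAMs' retained predictors (the combination rule; whether to
re-select or simply pool is open — re-selection is used and recorded).

Goodness of fit is Nagelkerke's *R²* computed from deviances:
[1 − exp(−(D₀−D₁)/n)] / [1 − exp(−D₀/n)].  Values within numerical
dust of 0 (a null MAM refitted to its own null deviance) are clamped to
exactly 0.  The explanatory weight of each abiotic category is the rise
in residual deviance when that category's retained predictors are
removed from the MAM, as a percentage of the null deviance; categories
absent from the MAM contribute 0.

## Evaluation, transferability, partitioning

Internal evaluation repeats a random unstratified 50/50 split 100
times; the MAM's predictor set is refitted on each half and scored on
the pooled held-out predictions of both folds (one metric value per
iteration, averaged).  Pooling avoids the single-class-fold failures
that per-fold scoring invites; splits whose training half cannot
support a fit are redrawn and counted.  Refits keep the MAM's family
fixed, including its profile-estimated *k* — the selected model is
evaluated as calibrated rather than re-specified per split.  External
evaluation calibrates on one location's data set and scores
predictions of the paired data set in the other location.  AUC uses
the Mann–Whitney midrank formulation (P(score⁺ > score⁻) + ½P(tie));
abundance agreement is Spearman's ρ.  Qualitative bands are
left-closed on their boundaries (AUC 0.80 is "good", ρ 0.20 is
"poor") since strict published inequalities leave boundary points
unassigned.

Cross-stage transferability applies a stage's fitted abiotic linear
predictor to the shared abiotic covariates of the other stage's table
and scores it against that stage's responses; transfer fails below AUC
0.70 or ρ 0.40 (boundary passes).  Asymmetric transferability is
AT = (mean T stronger − mean T weaker)/mean T stronger × 100; the
algebraic form is a reconstruction from the published semantics (the
original presents it only graphically) and every transfer report says
so.  Positive AT means the forward direction (A→B for locations,
larva→adult for stages) transfers worse.

Partitioning is exact arithmetic on the (ABIOT, BIOT, FULL) *R²*
triplet: pure-abiotic = FULL − BIOT, pure-biotic = FULL − ABIOT,
joint = ABIOT + BIOT − FULL, which sum to FULL identically.  Components
are never clipped; a component below −0.01 (possible with 2-dp rounded
published inputs or when AIC-selected FULL models shed terms) is
flagged.  Grouped summaries report the arithmetic mean and sample
(n−1) SD, which reproduces the published ± values at two decimals.

## Residual spatial autocorrelation

Moran's *I* is computed on deviance residuals (the default; Pearson or
response residuals can be supplied instead) with row-standardized
inverse-distance weights — the standard choice for irregular point
surveys; k-nearest-neighbour and user-supplied matrices (e.g. rook
contiguity) are supported.  Significance is a permutation test
(default 1000 permutations, p = (1+#extreme)/(n_perm+1)), two-sided on
|I| by default with a one-sided "greater" option for pure clumping.
Holm's step-down correction is applied across all models of one
pipeline run (32 models in the default design: 8 data sets × 2
responses × ABIOT/BIOT).

## Synthetic survey generator

The generator is the package's stand-in for the unavailable field data
and defines the study conditions for every simulation-based test.

**Design defaults** (fixed to the study design): 2 locations × 120
points, minimum 5.5 m spacing by rejection sampling inside per-location
rectangles (300×300 m and 300×500 m, matching the 9 and 15 ha extents),
five habitat types per location with proportional stratified
allocation, a 4×4 cell grid per point, minimum-larvae thresholds 5 (A)
and 3 (B), and fine-scale caps of 10 and 11 points, giving 160 and 176
cell rows.  Location B's allocation leans toward closed heath and
recently burned ground, making it the poorer location.

**Covariates.** Percentage covers are logit-normal with
habitat-specific means (bare ground concentrated in the bare-mosaic
habitats, heather in the heath types, herbs in grassland) rescaled to
[0, 100].  The three scale versions of each cover variable share a
latent value; the cross-scale parameter is a target Spearman
correlation (default 0.8), mapped to the latent Pearson correlation by
2·sin(πρ/6) with the habitat-mean variance accounted for, so the
emitted rank correlation lands on the parameter.  Resistance, soil and
structure variables are generated from habitat density scores with
plausible distributions (Dirichlet particle-size fractions, Poisson
patch counts, log-normal distances); they are deliberately simple —
the analysis only needs them to exist, correlate modestly and
occasionally matter.

**Responses.** Larval totals per point are negative binomial
(log link, default k = 0.8) driven by bare-soil, herb and heather
cover; the total is allocated multinomially over the 16 cells with
weights from a cell-level log-linear model times gamma noise
(`cell_aggregation`, default 1), which induces within-point clumping
while keeping count conservation across scales exact: the 1×1 m
abundance is the cell sum and the 50×50 cm abundance the central-2×2
sum, by construction.  Instars split each point's larvae
multinomially (0.3/0.4/0.3).  Adult presence is Bernoulli on a logit
model over the same abiotic gradient plus larval presence; abundance
is negative binomial (k = 1.5) reconciled with presence (an occupied
trap has ≥ 1 capture); sexes split binomially.  The congeneric species
runs through the same machinery with its own coefficients and no
interspecific dynamics.  Default intercepts and coefficients were
calibrated once so that adults occupy roughly a third of the traps,
larvae just under half of the points, and location A is richer than B
— the occupancy pattern of the original survey — and are not tuned
thereafter.

**What the generator does not emulate:** temporal dynamics (instar
progression, burrow closure, capture histories), observation error in
the covariates, interspecific interaction mechanisms, and real spatial
autocorrelation fields beyond habitat patchiness.  Passing tests
therefore demonstrate that the pipeline recovers known structure under
the assumed model families, not that those families describe any
particular field system.

## Numerical choices

* Negative-binomial *k*: profile ML over log k in [log 1e-4, log 1e6],
  `xatol` 1e-8; under-dispersed samples fall back to Poisson with a
  warning.
* Linear predictors in the generator are clipped to ±30 before
  exponentiation, with clipping logged.
* Stepwise, correlation-filter and fine-scale-selection ties all break
  deterministically (lexicographic names; ascending point id), so
  every run is bit-reproducible under a fixed seed.
* Coincident points in the inverse-distance weights receive a 1e-9
  distance floor, logged.
* The permutation p-value is never 0 (add-one formulation).

## Problem sizes used in the shipped analyses

The numbered analysis scripts and the acceptance script run the
pipeline at the study's own sizes: 120 points per location, 100
cross-validation iterations, 1000 permutations.  Simulation-based test
checks use the sample sizes stated with each property (up to n = 5000
for moment checks, 100–500 replicates for coverage and calibration),
chosen as the smallest sizes at which the Monte-Carlo error is
comfortably inside the asserted tolerance.

## Known limitations

* The asymmetric-transferability algebra is a reconstruction (see
  above); only its two published worked values anchor it.
* Quasibinomial QAIC stepping uses a single ĉ from the largest model
  in scope; mixing quasi and likelihood families in one comparison
  table is flagged but not prevented.
* The catalog's tall-shrub counts are named SHRUBTALL_3/6 to keep the
  multiscale competition families unambiguous against the SHRUB cover
  family.
* The generator's habitat allocation and covariate distributions are
  plausible inventions; analyses of real surveys should enter through
  `read_observation_table` with catalog-conformant columns.
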