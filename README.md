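# stageniche

Fine-scale ecological niche modelling for species with complex life
cycles, where co-occurring life stages (here: the adults and larvae of
a heathland tiger beetle) may occupy different niches and respond to
the environment at different spatial scales.

The package implements, as a tested and reusable pipeline, the complete
analysis chain of a two-location, fine-resolution survey design:

* **Responses** — presence/absence (PA) and abundance (AB) of each life
  stage, surveyed at nested scales: one pitfall trap per sampling point
  for adults, and larval burrow maps in the 1×1 m quadrat, its central
  50×50 cm quadrat, and the sixteen 25×25 cm cells of a 4×4 grid.
* **Models** — GLMs with a logit link (binomial, or quasibinomial under
  overdispersion) for PA and a log link (negative binomial with
  clumping parameter *k*, or Poisson when *k* is large) for AB, each
  calibrated three ways: abiotic predictors only (ABIOT), biotic
  predictors only (BIOT), and the combination of both selected sets
  (FULL).
* **Screening** — univariate GLM filter (*p* < 0.1, ranked by explained
  deviance), pairwise Spearman correlation filter (|ρ| < 0.7) with
  one-scale-per-variable competition, and a sequential variance
  inflation factor cascade (VIF < 10).
* **Selection** — minimal adequate models (MAMs) by bidirectional
  stepwise AIC; goodness of fit by Nagelkerke's *R²*; per-category
  explained deviance for the abiotic categories (COVER, RESISTANCE,
  SOIL, STRUCTURE).
* **Evaluation** — internal evaluation (100 iterated random 2-fold
  cross-validations) and external evaluation (calibrate in one
  location, predict the other), scored by AUC (PA) or Spearman's ρ
  (AB) with the conventional excellent/good/fair/poor/fail bands.
* **Transferability** — cross-life-stage transferability *T* of the
  abiotic MAMs (fail below AUC 0.70 / ρ 0.40) and asymmetric
  transferability *AT* between locations and stages as a percentage
  decrease in mean *T*.
* **Partitioning** — hierarchical partitioning of the FULL model's
  *R²* into pure-abiotic (*R²_FULL − R²_BIOT*), pure-biotic
  (*R²_FULL − R²_ABIOT*) and joint (*R²_ABIOT + R²_BIOT − R²_FULL*)
  contributions.
* **Spatial autocorrelation** — Moran's *I* on model residuals with a
  1000-permutation test and Holm correction across the model family.

Because no field data are deposited with the original study, a seeded
synthetic survey generator (`stageniche.synthetic`) reproduces the
study design — 120 stratified points per location, minimum 5.5 m
spacing, nested quadrats with exact count conservation across scales,
neighbour-larvae crowding counts, a congeneric species — with
GLM-structured responses whose generating coefficients are known, so
parameter recovery and evaluation calibration can be verified.  The
published 16-row model-performance table (Nagelkerke *R²* of the
ABIOT/BIOT/FULL models per data set and response) ships as a fixture
for the partitioning analyses that depend only on printed values.

## Worked example

```python
import stageniche as sn

# partition the published performance table
r2 = sn.load_published_r2()
triples = sn.partition_table(r2)
print(sn.summarize_partitions(triples, "all").round(2).to_string(index=False))
```

```
group  n  pure_abiotic_mean  pure_abiotic_sd  pure_biotic_mean  pure_biotic_sd  joint_mean  joint_sd
  all 16               0.37             0.22              0.02            0.02        0.34      0.24
```

Across the 16 models, the biotic predictors alone contribute 0.02 ±
0.02 of explanatory power — negligible — while the abiotic-only share
(0.37 ± 0.22) and the joint abiotic–biotic share (0.34 ± 0.24) carry
the fit: most of the biotic signal is contained in the abiotic
signature.

The full synthetic analysis is driven by the numbered scripts:

```sh
python analysis/01_simulate_survey.py      # writes results/data/
python analysis/02_fit_evaluate_models.py  # writes results/analysis/
python analysis/03_partition_published_r2.py
```

`02_fit_evaluate_models.py` prints the fitted *R²* table and, for the
default generating models, finds the same qualitative pattern the
survey design is meant to expose: abiotic fit degrades from the coarse
scales (mean ABIOT *R²* ≈ 0.57) to the 25 cm cell scale (≈ 0.30),
cross-stage transferability passes for most models (mean AUC ≈ 0.75),
the pure-biotic contribution is near zero, and no model shows
Holm-significant residual autocorrelation (0/32).

A `stageniche` command-line interface wraps the same stages
(`simulate`, `screen`, `fit`, `evaluate`, `transfer`, `partition`,
`autocorr`, `run`); see `stageniche --help`.

## Layout

```
src/stageniche/     library: synthetic, screening, glm, evaluation,
                    transfer, partitioning, spatial, pipeline, cli
analysis/           numbered narrative drivers over the library
scripts/            acceptance script
tests/              pytest suite (unit, property and acceptance tests)
docs/methods.md     models, assumptions, parameter defaults, limitations
```
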