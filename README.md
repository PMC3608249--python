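# famewas

Family-based analysis of CpG methylation: heritability and
phenotype-association scans for methylation panels measured in extended
pedigrees, together with an in-silico model of the EpiTYPER/MassARRAY
assay and a synthetic-cohort generator so the whole pipeline can be
exercised, calibrated, and validated without any external data.

## What it does

Quantitative methylation at a candidate region (here a promoter/first-exon
CpG panel, 17 CpG "units" plus their regional average) is measured by
bisulfite mass spectrometry in members of extended families. Two
questions follow:

1. **Is methylation heritable?** Family resemblance is modeled with the
   polygenic variance-component model: the trait vector is multivariate
   normal with covariance `2 Φ σ²a + I σ²e`, where `Φ` is the kinship
   matrix computed recursively from the pedigree. Heritability
   `h² = σ²a / (σ²a + σ²e)` is estimated by maximum likelihood and tested
   with a likelihood-ratio test against the boundary-mixture null
   (½ χ²₁ + ½ point mass at zero).
2. **Is methylation associated with metabolic traits?** Each trait is
   rank-normalized and regressed on each (rank-normalized) methylation
   unit under the same polygenic model, with age, age², sex, and their
   interactions as fixed covariates; a 1-df likelihood-ratio test gives
   the p-value, and per-test significance thresholds account for the 18
   correlated tests per trait (Bonferroni 0.05/18 = 0.0028 "significant",
   0.10/18 = 0.0056 "suggestive"; a Li–Ji effective-number-of-tests
   estimator is also provided).

Supporting layers make this testable end to end:

* **`famewas.epityper`** — in-silico EpiTYPER: bisulfite conversion,
  T-cleavage of the reverse-complement transcript, average fragment
  masses (one methylated CpG shifts a fragment by **16 Da**), detection of
  CpG units that share a fragment or collide in mass, and quantification
  from peak-intensity ladders.
* **`famewas.qc`** — replicate aggregation (cells with replicate SD > 0.1
  excluded), subject calling-rate filtering (< 95% of units called →
  subject rejected), collision-unit merging, and the regional average as
  an 18th analysis variable.
* **`famewas.simulate`** — generator for three-generation family cohorts
  (default 40 families, n ≈ 517) with kinship-structured methylation,
  age/sex effects, planted trait associations, and a replicate-level
  measurement layer (triplicates, noisy cells, failed subjects).
* **`famewas.pipeline` / `famewas` CLI** — end-to-end scans with
  complete-case handling, cached model rotations, multiple-testing
  flags, a Manhattan-style plot, and run manifests.

## Worked example

Simulate a cohort, run QC, and scan (seed 7; your numbers will match
exactly — everything is deterministic given the seed):

```bash
famewas simulate --seed 7 --out demo/cohort
# cohort of 501 individuals written to demo/cohort
famewas qc --methylation demo/cohort/methylation_long.csv --out demo/qc
# QC: 12 subjects rejected, 0.049 of cells excluded
famewas h2scan --pedigree demo/cohort/pedigree.ped \
    --matrix demo/qc/methylation_matrix.csv \
    --phenotypes demo/cohort/phenotypes.csv --out demo/h2
famewas assoc --pedigree demo/cohort/pedigree.ped \
    --matrix demo/qc/methylation_matrix.csv \
    --phenotypes demo/cohort/phenotypes.csv --traits TC,dBP --out demo/assoc
famewas thresholds
# {"alpha=0.05": 0.002777..., "alpha=0.1": 0.005555...}
```

Selected rows of `demo/h2/heritability_scan.csv` (the generative
heritability of unit FABP3_9 is 0.48, with a positive age slope):

```text
    unit       h2    h2_se        p_h2  beta_age    p_age   n
 FABP3_9 0.438415 0.088057 1.73e-08    0.000481 0.001031 465
FABP3_13 0.413541 0.082994 1.44e-09    0.000006 0.971682 464
 FABP3_1 0.034899 0.060419 2.72e-01   -0.000004 0.940234 460
```

Top of `demo/assoc/association_scan.csv` sorted by p — the planted
dBP ← FABP3_13 effect (generative standardized β = −0.16) is flagged
significant at the 0.0028 threshold:

```text
trait      unit      beta       se        p  significant  suggestive   n
  dBP  FABP3_13 -0.211791 0.045315 0.000004        True        True  464
   TC  FABP3_20  0.122403 0.046888 0.009299       False       False  467
   TC FABP3_AVG  0.084203 0.044409 0.058905       False       False  489
```

Note the planted TC ← FABP3_AVG effect (generative 0.17) is attenuated
here (0.084) because this scan runs on the *measured* methylation,
which carries replicate noise and QC losses; see docs/methods.md on
measurement attenuation.

## Layout

```
src/famewas/
  pedigree.py          PED parsing, validation, recursive kinship
  epityper.py          in-silico bisulfite/cleavage/mass model
  qc.py                replicate aggregation, filters, analysis matrix
  varcomp.py           polygenic model, LRTs, rank-normalization
  multiple_testing.py  Li-Ji Meff, Bonferroni/Sidak thresholds, BH-FDR
  simulate.py          synthetic family cohorts and measurement layer
  pipeline.py          heritability/association/expression scans
  cli.py               `famewas` command-line interface
docs/methods.md        model, assumptions, parameter rationale
scripts/acceptance.py  headline checks as JSON
tests/                 unit, property, oracle, and acceptance tests
```
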