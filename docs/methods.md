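# Methods

This document records the statistical models, the numerical choices,
and the rationale for every default parameter in `famewas`. Problem
sizes quoted here (40 families, n ≈ 517, 17 CpG units + regional
average, 18 tests per trait) are the package's reference configuration;
every routine accepts other sizes.

## 1. Pedigrees and kinship

Pedigrees are read from whitespace- or comma-delimited PED-like files
(`family individual father mother sex`, missing parent `0` or empty,
sex coded `1/M/male`, `2/F/female`). Validation enforces: both parents
present or both absent, parents in the same family, no duplicate IDs,
and acyclicity (cycles are reported with the offending path).

The kinship coefficient φ(i, j) is the probability that randomly drawn
alleles from i and j are identical by descent. It is computed by the
standard tabular recursion over a topological order of the pedigree —
for a non-founder i with parents f and m,

    φ(i, j) = ½ (φ(f, j) + φ(m, j))   for j earlier than i,
    φ(i, i) = ½ (1 + φ(f, m)),

with founders φ = ½ on the diagonal and 0 to earlier individuals.
Rows are filled with vectorized NumPy operations, so the cost is
O(n²) with small constants; a 517-member cohort takes milliseconds.
The matrix stored is φ itself; the additive-genetic covariance kernel
`2Φ` is formed where the model needs it. Correctness is checked against
a gene-dropping Monte-Carlo oracle in the test suite.

## 2. Polygenic variance-component model

For a quantitative trait y with fixed-effect design X,

    y ~ N(Xβ, Ω),   Ω = 2Φ σ²a + I σ²e,
    h² = σ²a / (σ²a + σ²e).

Fitting (`famewas.varcomp.PolygenicModel`):

* `2Φ` is eigendecomposed once per subject subset (`U Λ Uᵀ`); rotating
  y and X by `Uᵀ` diagonalizes Ω for every (σ²a, σ²e), so each
  likelihood evaluation is a weighted least-squares solve, O(n·p).
* For fixed h², β and the total variance profile out analytically;
  the ML fit is a bounded 1-D search over h² ∈ [0, 1) by golden-section
  /parabolic minimization (`scipy.optimize.minimize_scalar`,
  `xatol = 1e-8`). Estimates within `xatol` of 0 snap to the boundary.
* The standard error of ĥ² is computed from the numerical curvature of
  the profile log-likelihood at the optimum (central differences).
* Maximum likelihood (not REML) is used throughout so that
  likelihood-ratio tests between fixed-effect-nested models are valid.

### Hypothesis tests

* **Heritability**: LRT of h² = 0 versus h² > 0. Because the null value
  lies on the boundary of the parameter space, the null distribution is
  the ½:½ mixture of χ²₁ and a point mass at zero: p = 1 if T = 0, else
  ½ P(χ²₁ > T).
* **Association**: the focal variable enters X; the LRT dropping it is
  1-df χ². The reported β and SE are the GLS estimates at the ML
  variance components.

**Calibration.** At the reference cohort size both tests hold nominal
α = 0.05 within the binomial 95% CI over 1000 null replicates (observed
0.037 for the heritability LRT — the boundary test is mildly
conservative — and 0.053 for the association LRT). On much smaller
cohorts (n ≈ 130) the ML-based association LRT is visibly liberal
(≈ 0.065 at nominal 0.05), the usual finite-sample behavior of ML
variance estimation; inference on small pedigrees should use
permutation or REML-based alternatives.

### Transformations and covariates

* Traits and focal methylation values are rank-normalized before
  association testing: z = Φ⁻¹((r − c)/(n − 2c + 1)) with Blom-type
  offset c = 0.5 and average ranks for ties. This makes the Gaussian
  working model tenable for skewed metabolic traits; monotone
  invariance is property-tested.
* The standard covariate design is intercept, sex, age, age², sex×age,
  sex×age² with age centered (reduces collinearity between age and
  age²).
* Reported methylation effects are back-transformed to raw units:
  `raw change per 1% methylation = β_z · sd(trait_raw) · 0.01 / sd(meth_raw)`.

## 3. In-silico EpiTYPER model

The assay model follows the EpiTYPER measurement principle:

1. **Bisulfite conversion**: every cytosine converts to T except a
   methylated CpG cytosine.
2. **Transcription and cleavage**: the reverse-complement transcript of
   the converted amplicon is cleaved 3′ of every U (T-cleavage). The
   cleavage pattern is methylation-invariant because transcript Us come
   from template As, which bisulfite never touches — so fragment spans
   and per-fragment CpG counts are computed once per amplicon.
3. **Masses**: average residue masses A 329.21, C 305.18, G 345.21,
   U 306.17 Da plus 18.02 Da terminal water. Each methylated CpG
   retains C (instead of converting to U→A-pairing changes), shifting
   the fragment by **16.00 Da** (G − A on the transcript strand).
4. **CpG units**: CpGs on one fragment form a multi-site unit (e.g.
   "1/2"). Units whose full mass ladders coincide at the 1.0 Da
   instrument resolution are flagged `mass_collision`; fragments whose
   methylated masses collide with CpG-free background fragments are
   `unresolvable`. The QC layer averages collision groups into merged
   units (e.g. "3a/3b" → "3").
5. **Quantification**: with K CpGs on a fragment and intensity ladder
   I₀…I_K, the methylation fraction is Σ k·I_k / (K·Σ I_k); an all-zero
   ladder yields a missing value. Measurement replicates are modeled as
   clamped Gaussian noise around the true fraction.

## 4. Quality control

Defaults (all configurable in `QCConfig`):

* **Subject calling rate** — subjects with < 95% of panel units called
  in the raw data are rejected entirely. This is applied first, on raw
  calledness, so a subject's rejection does not depend on downstream
  replicate-consistency decisions.
* **Replicate consistency** — among retained subjects, a subject×unit
  cell is excluded when the sample SD of its replicates exceeds 0.1;
  otherwise the cell value is the replicate mean.
* **Regional average** — the mean of a subject's retained unit values,
  appended as an 18th analysis variable (`FABP3_AVG` in the default
  panel).
* **Control calibration** — a helper regresses observed control-panel
  fractions (0/25/50/75/100%) on expected and flags slope/intercept
  deviations.

## 5. Multiple testing

Per-trait thresholds treat the 18 unit tests as a family:
Bonferroni α/M (default; 0.05/18 = 0.0028, 0.10/18 = 0.0056) or Šidák
1 − (1 − α)^{1/M}. Because CpG units are correlated, the Li–Ji
effective number of tests is available:
Meff = Σᵢ [ 1{λᵢ ≥ 1} + (λᵢ − ⌊λᵢ⌋) ] over eigenvalues λ of the unit
correlation matrix; it agrees with a min-p permutation calibration
within 15% in the test suite. Benjamini–Hochberg step-up FDR is
provided for discovery-style screens (expression analysis uses it for
detection filtering).

## 6. Synthetic cohort generator

`famewas.simulate` builds cohorts whose structure matches what the
analysis assumes, so recovery and calibration are meaningful.

**Pedigrees.** Each family: two grandparents; 3 + Poisson(1.2) children;
each child marries an unrelated spouse with probability 0.5 and then has
1 + Poisson(1.2) children. With 40 families the expected cohort size is
≈ 517 (across seeds the per-seed size varies by roughly ±15%).

**Covariates.** Generation age means 68/49/26 years (SD 5, floor 18);
female with probability 0.589 for married-in and third-generation
members (founder couples are one male + one female).

**Methylation.** Each unit u has mean, SD, heritability h²_u, and raw
age/sex coefficients. On the latent scale
`z = β̃_age·age + β̃_sex·female + g + e` with `g ~ N(0, 2Φ h²_u v_resid)`;
values map to the fraction scale by mean + SD·z and clamp to [0, 1].
To keep clamping negligible, the effective SD is capped at
min(mean, 1 − mean)/3.5 with raw coefficients rescaled proportionally
(preserving variance fractions); the realized clamping fraction is
reported and warned about above 5%. The default panel sets unit
FABP3_9 to mean 0.115, SD 0.0321, h² 0.48, age slope 2.9×10⁻⁴/yr.

**Phenotypes.** On the z scale each trait is
`Σ_u β_u · ranknorm(meth_u) + g + e`, with residual variance 1 − Σβ²
split by the trait's residual heritability, then mapped to raw units by
sex-specific means/SDs (e.g. total cholesterol 193.08 ± 45.75 male,
189.06 ± 40.03 female mg/dl). Default planted effects include
TC ← FABP3_AVG β = 0.17 and dBP ← FABP3_13 β = −0.16.

**Measurement layer.** Triplicate measurements with Gaussian noise
SD 0.02; 4.8% of cells are made discordant (spread ±0.25, so the
replicate-SD filter excludes them); 2.5% of subjects fail (2–3 units
uncalled, so the 95% calling-rate filter rejects them). These rates are
recovered by the QC report within binomial error in the tests.

**Expression (optional).** Log-normal probe intensities with a set of
near-background undetectable probes and one kinship-structured focal
probe, for exercising the detection-filter + association path.

**Measurement attenuation.** Replicate noise and QC losses attenuate
both ĥ² and β̂ when scans run on measured data (classical errors-in-
variables). The acceptance recovery loops therefore fit the noise-free
methylation: they verify the *estimator* is unbiased at the generative
values (mean ĥ² over 200 replicates 0.477 ± 0.005 at truth 0.48; mean
β̂ 0.168 ± 0.003 at truth 0.17), while the pipeline tests separately
verify the measured-data path end to end.

## 7. Numerical and reproducibility choices

* All randomness flows through `numpy.random.Generator`; every public
  stochastic routine takes a seed or Generator. Replicate seeds in
  scripts are derived as `(seed·100003 + k) mod 2³¹`.
* Eigendecomposition (`numpy.linalg.eigh`) rather than Cholesky for the
  kernel, because `2Φ` can be singular (e.g. monozygotic-like
  duplicates) and the rotation is reused across likelihood evaluations;
  simulation uses Cholesky with an eigendecomposition fallback for
  semidefinite kernels.
* Complete-case analysis per trait-unit pair; the kinship matrix is
  subset to the complete cases and model rotations are cached per
  subject subset (the dominant cost at 18 units × several traits).
* Ranking uses mergesort (stable) so tie handling is deterministic.
* `statsmodels` is not a runtime dependency; it appears only in tests
  as an independent oracle for the h² = 0 (OLS) likelihood.
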