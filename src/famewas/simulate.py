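"""Synthetic family cohort generator.

Emulates the study conditions the analysis modules assume: ~40 extended
nuclear families totalling ~517 individuals across three generations, a
panel of 17 CpG methylation units with unit-specific heritabilities
(0.03-0.48) and small age/sex effects, metabolic-syndrome traits with
sex-specific raw scales and standardized methylation effects ~0.15-0.17,
triplicate measurements with Gaussian noise, ~4.8% high-scatter cell
exclusions and ~2.5% subject-level assay failures.

Default unit parameters follow the reported per-unit heritability and
age/sex coefficient magnitudes; each unit's raw standard deviation is
derived from its age coefficient and age-variance-explained
(sd = |beta_age| * sd_age / sqrt(ve_age) at a cohort age sd of 16 y),
falling back to the analogous sex-based expression or 0.03 where those
are too small to be informative.  Unit means follow the reported pattern
of low promoter methylation (<8%) rising steeply within the first exon.

All randomness flows through one seeded generator, so regeneration from
the same configuration and seed is bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .epityper import simulate_measurement
from .pedigree import Individual, Pedigree, KinshipMatrix, kinship_matrix
from .varcomp import rank_normalize

__all__ = [
    "UnitSpec",
    "TraitSpec",
    "MeasurementSpec",
    "SimulationConfig",
    "SyntheticCohort",
    "default_config",
    "gen_pedigrees",
    "simulate_trait_with_h2",
    "simulate_methylation_panel",
    "simulate_phenotypes",
    "apply_measurement_layer",
    "simulate_expression",
    "generate_cohort",
    "write_cohort",
    "read_phenotypes",
    "read_methylation_records",
]


@dataclass
class UnitSpec:
    """Generative parameters of one methylation unit (fraction scale)."""

    label: str
    mean: float
    sd: float
    h2: float
    beta_age: float = 0.0  # fraction per year of age
    beta_sex: float = 0.0  # fraction, female minus male

    def __post_init__(self) -> None:
        if not 0 <= self.h2 <= 1:
            raise ValueError(f"unit {self.label}: h2 must be in [0, 1]")
        if self.sd <= 0:
            raise ValueError(f"unit {self.label}: sd must be positive")


@dataclass
class TraitSpec:
    """Generative parameters of one quantitative trait.

    ``assoc`` maps methylation unit labels (or the regional-average
    label) to standardized effects of that unit's z-scale methylation on
    the trait's z-scale value.
    """

    name: str
    mean_male: float
    sd_male: float
    mean_female: float
    sd_female: float
    h2: float
    assoc: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0 <= self.h2 <= 1:
            raise ValueError(f"trait {self.name}: h2 must be in [0, 1]")
        if self.sd_male <= 0 or self.sd_female <= 0:
            raise ValueError(f"trait {self.name}: sds must be positive")
        b2 = sum(b**2 for b in self.assoc.values())
        if b2 >= 1:
            raise ValueError(f"trait {self.name}: association effects exceed unit variance")


@dataclass
class MeasurementSpec:
    """Triplicate measurement layer and its failure processes."""

    replicates: int = 3
    noise_sd: float = 0.02
    cell_exclusion_rate: float = 0.048
    subject_failure_rate: float = 0.025
    # half-spread of the injected replicate scatter for excluded cells;
    # 0.25 guarantees a sample sd above the 0.1 QC cutoff even after
    # clamping at the [0, 1] boundaries
    exclusion_spread: float = 0.25


@dataclass
class SimulationConfig:
    """Cohort structure, panel, traits, and measurement parameters."""

    n_families: int = 40
    base_sibship: int = 3
    sibship_extra_mean: float = 1.2
    spouse_prob: float = 0.5
    base_grandchildren: int = 1
    grandchildren_extra_mean: float = 1.2
    age_means: tuple[float, float, float] = (68.0, 49.0, 26.0)  # by generation
    age_sd: float = 5.0
    min_age: float = 18.0
    female_fraction: float = 0.589
    units: list[UnitSpec] = field(default_factory=list)
    traits: list[TraitSpec] = field(default_factory=list)
    measurement: MeasurementSpec = field(default_factory=MeasurementSpec)
    regional_average_label: str = "FABP3_AVG"

    def unit(self, label: str) -> UnitSpec:
        for u in self.units:
            if u.label == label:
                return u
        raise KeyError(label)


# Default 17-unit panel: (label, mean, sd, h2, beta_age, beta_sex).
# Heritabilities and coefficient magnitudes follow the reported per-unit
# values; sds derive from beta_age and its variance explained at age sd
# 16 y.  Means follow the low-promoter/high-exon gradient but are kept at
# least 3.5 sd inside [0, 1] (clamped-Gaussian scale): default_config
# shrinks any sd violating that margin and rescales the raw coefficients
# proportionally so the variance fractions (and hence power) of the age
# and sex effects are preserved.
_DEFAULT_UNITS = [
    ("FABP3_1",        0.020, 0.0497, 0.21,  1.7e-4,  1.9e-3),
    ("FABP3_2",        0.020, 0.0252, 0.05,  1.6e-4, -7.3e-4),
    ("FABP3_3",        0.025, 0.0202, 0.09,  1.5e-4,  4.6e-3),
    ("FABP3_4",        0.030, 0.0180, 0.18,  4.0e-5,  2.7e-3),
    ("FABP3_5",        0.035, 0.0148, 0.15,  1.1e-4,  5.4e-4),
    ("FABP3_6/7",      0.045, 0.0156, 0.17,  1.2e-4,  2.5e-4),
    ("FABP3_8",        0.055, 0.0182, 0.17, -2.0e-5,  6.2e-3),
    ("FABP3_9",        0.115, 0.0321, 0.48,  2.9e-4, -7.6e-4),
    ("FABP3_10/11/12", 0.120, 0.0313, 0.19,  2.8e-4,  6.0e-3),
    ("FABP3_13",       0.300, 0.0384, 0.46,  2.2e-4,  3.9e-3),
    ("FABP3_14",       0.400, 0.0517, 0.48,  2.8e-4,  1.3e-2),
    ("FABP3_15",       0.500, 0.0695, 0.15, -2.8e-4,  4.5e-3),
    ("FABP3_16",       0.600, 0.0361, 0.32,  2.3e-4,  6.3e-3),
    ("FABP3_17/18",    0.700, 0.0685, 0.03,  1.3e-4,  7.6e-3),
    ("FABP3_19",       0.750, 0.0715, 0.26, -3.3e-4,  1.3e-2),
    ("FABP3_20",       0.800, 0.0313, 0.41,  1.0e-5,  8.1e-3),
    ("FABP3_21/22",    0.830, 0.0475, 0.14, -7.0e-5, -5.5e-3),
]

_CLAMP_MARGIN_SIGMA = 3.5

# Default traits: (name, mean_m, sd_m, mean_f, sd_f, h2, {unit: beta_z})
_DEFAULT_TRAITS = [
    ("TC",    193.08, 45.75, 189.06, 40.03, 0.29, {"FABP3_AVG": 0.17}),
    ("LDL_c", 131.44, 40.55, 126.95, 36.61, 0.33, {}),
    ("HDL_c",  38.24, 12.05,  43.65, 18.63, 0.69, {}),
    ("TG",    135.40, 208.06, 106.45, 64.89, 0.52, {}),
    ("dBP",    78.97, 12.18,  75.68, 10.74, 0.22, {"FABP3_13": -0.16}),
    ("SI",      3.32,  2.94,   2.86,  2.79, 0.20, {"FABP3_21/22": -0.16}),
    ("BMED",   27.67,  1.09,  28.07,  1.28, 0.42, {"FABP3_17/18": -0.15}),
]


def default_config(**overrides) -> SimulationConfig:
    """The default study-scale configuration (40 families, 17-unit panel)."""
    units = []
    for label, mean, sd, h2, b_age, b_sex in _DEFAULT_UNITS:
        sd_eff = min(sd, mean / _CLAMP_MARGIN_SIGMA, (1.0 - mean) / _CLAMP_MARGIN_SIGMA)
        scale = sd_eff / sd
        units.append(UnitSpec(label, mean, sd_eff, h2, b_age * scale, b_sex * scale))
    cfg = SimulationConfig(
        units=units,
        traits=[TraitSpec(*row) for row in _DEFAULT_TRAITS],
        **overrides,
    )
    return cfg


@dataclass
class SyntheticCohort:
    """Generated cohort with full ground truth for parameter-recovery tests."""

    pedigree: Pedigree
    kinship: KinshipMatrix
    covariates: pd.DataFrame  # id-indexed: age, female, family, generation
    meth_true: pd.DataFrame  # id x unit true fractions (+ regional average)
    phenotypes: pd.DataFrame  # id x trait raw values
    records: pd.DataFrame  # long replicate-level measurements
    config: SimulationConfig
    seed: int
    clamp_fraction: float = 0.0
    expression: pd.DataFrame | None = None


def gen_pedigrees(config: SimulationConfig, seed: int | np.random.Generator) -> Pedigree:
    """Sample extended three-generation nuclear families.

    Each family has two founding grandparents, a sibship, and for some
    sibs a married-in spouse with grandchildren; expected family size
    ~13, so the default 40 families land near the target cohort size of
    ~517.
    """
    if config.n_families < 1:
        raise ValueError("n_families must be >= 1")
    if config.base_sibship < 1 or config.sibship_extra_mean < 0:
        raise ValueError("impossible sibship parameters")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    individuals: list[Individual] = []
    for f in range(1, config.n_families + 1):
        fam = f"F{f:03d}"
        counter = 0

        def new_id() -> str:
            nonlocal counter
            counter += 1
            return f"{fam}_{counter:03d}"

        gpa, gma = new_id(), new_id()
        individuals.append(Individual(gpa, fam, None, None, "male"))
        individuals.append(Individual(gma, fam, None, None, "female"))
        n_sibs = config.base_sibship + rng.poisson(config.sibship_extra_mean)
        for _ in range(n_sibs):
            child = new_id()
            child_sex = "female" if rng.random() < config.female_fraction else "male"
            individuals.append(Individual(child, fam, gpa, gma, child_sex))
            if config.spouse_prob > 0 and rng.random() < config.spouse_prob:
                spouse = new_id()
                spouse_sex = "male" if child_sex == "female" else "female"
                individuals.append(Individual(spouse, fam, None, None, spouse_sex))
                father, mother = (
                    (child, spouse) if child_sex == "male" else (spouse, child)
                )
                n_gc = config.base_grandchildren + rng.poisson(
                    config.grandchildren_extra_mean
                )
                for _ in range(n_gc):
                    gc_sex = "female" if rng.random() < config.female_fraction else "male"
                    individuals.append(Individual(new_id(), fam, father, mother, gc_sex))
    return Pedigree(individuals)


def _generation_of(ped: Pedigree) -> dict[str, int]:
    gen: dict[str, int] = {}
    for iid in ped.topological_order():
        ind = ped[iid]
        if ind.is_founder:
            gen[iid] = 0
        else:
            gen[iid] = max(gen[ind.father_id], gen[ind.mother_id]) + 1
    # married-in founders sit in their spouse's generation: anyone with
    # children inherits max(child generation - 1)
    children: dict[str, list[str]] = {}
    for ind in ped:
        for pid in (ind.father_id, ind.mother_id):
            if pid is not None:
                children.setdefault(pid, []).append(ind.individual_id)
    for iid, kids in children.items():
        gen[iid] = max(gen[iid], max(gen[k] for k in kids) - 1)
    return gen


def sample_covariates(
    ped: Pedigree, config: SimulationConfig, rng: np.random.Generator
) -> pd.DataFrame:
    """Ages by generation and sexes from the pedigree."""
    gens = _generation_of(ped)
    rows = []
    for ind in ped:
        g = min(gens[ind.individual_id], len(config.age_means) - 1)
        age = max(rng.normal(config.age_means[g], config.age_sd), config.min_age)
        rows.append(
            {
                "id": ind.individual_id,
                "family": ind.family_id,
                "generation": g,
                "age": age,
                "female": ind.sex == "female",
            }
        )
    return pd.DataFrame(rows).set_index("id")


def _chol_2phi(phi: np.ndarray) -> np.ndarray:
    A = 2.0 * phi
    try:
        return np.linalg.cholesky(A)
    except np.linalg.LinAlgError:
        lam, U = np.linalg.eigh(A)
        if lam.min() < -1e-8:
            raise ValueError("2*Phi is not positive semidefinite")
        return U @ np.diag(np.sqrt(np.clip(lam, 0.0, None)))


def simulate_trait_with_h2(
    phi: np.ndarray | KinshipMatrix,
    h2: float,
    fixed: np.ndarray | float,
    total_var: float,
    seed: int | np.random.Generator,
) -> np.ndarray:
    """Additive-genetic plus residual draw around a fixed part.

    g ~ MVN(0, 2*Phi * h2 * total_var) via a factorization of 2*Phi and
    e ~ N(0, (1 - h2) * total_var) i.i.d.; the value is fixed + g + e.
    """
    if not 0 <= h2 <= 1:
        raise ValueError("h2 must be in [0, 1]")
    if total_var < 0:
        raise ValueError("total_var must be non-negative")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    P = phi.phi if isinstance(phi, KinshipMatrix) else np.asarray(phi, float)
    n = P.shape[0]
    L = _chol_2phi(P)
    g = L @ rng.standard_normal(n) * np.sqrt(h2 * total_var)
    e = rng.standard_normal(n) * np.sqrt((1.0 - h2) * total_var)
    return np.asarray(fixed) + g + e


def simulate_methylation_panel(
    config: SimulationConfig,
    phi: np.ndarray | KinshipMatrix,
    ages: Sequence[float],
    female: Sequence[bool],
    seed: int | np.random.Generator,
) -> tuple[pd.DataFrame, float]:
    """True per-unit methylation fractions plus the clamping fraction.

    Per unit: mean + beta_age*(age - mean age) + beta_sex*1{female}
    + genetic + residual noise at the unit's h2 and sd, clamped to
    [0, 1].  A derived regional-average column is appended.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    ages = np.asarray(ages, dtype=float)
    fem = np.asarray(female, dtype=float)
    # one shared factorization across units
    P = phi.phi if isinstance(phi, KinshipMatrix) else np.asarray(phi, float)
    L = _chol_2phi(P)
    n = P.shape[0]
    cols = {}
    clamped = 0
    for u in config.units:
        fixed = u.mean + u.beta_age * (ages - ages.mean()) + u.beta_sex * fem
        g = L @ rng.standard_normal(n) * np.sqrt(u.h2) * u.sd
        e = rng.standard_normal(n) * np.sqrt(1.0 - u.h2) * u.sd
        raw = fixed + g + e
        clamped += int(np.sum((raw < 0) | (raw > 1)))
        cols[u.label] = np.clip(raw, 0.0, 1.0)
    df = pd.DataFrame(cols)
    df[config.regional_average_label] = df.mean(axis=1)
    clamp_fraction = clamped / (n * len(config.units))
    return df, clamp_fraction


def simulate_phenotypes(
    config: SimulationConfig,
    phi: np.ndarray | KinshipMatrix,
    meth_true: pd.DataFrame,
    female: Sequence[bool],
    seed: int | np.random.Generator,
) -> pd.DataFrame:
    """Raw trait values with planted standardized methylation effects.

    On the z scale each trait is sum_u beta_u * z(meth_u) + genetic +
    residual, scaled to unit total variance with the trait's residual
    heritability, then mapped to the raw scale by sex-specific mean and
    sd.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    fem = np.asarray(female, dtype=bool)
    P = phi.phi if isinstance(phi, KinshipMatrix) else np.asarray(phi, float)
    L = _chol_2phi(P)
    n = P.shape[0]
    out = {}
    for t in config.traits:
        driver = np.zeros(n)
        b2 = 0.0
        for label, beta in t.assoc.items():
            if label not in meth_true.columns:
                raise KeyError(f"trait {t.name}: unknown methylation column {label!r}")
            driver += beta * rank_normalize(meth_true[label].to_numpy())
            b2 += beta**2
        if b2 >= 1:
            raise ValueError(f"trait {t.name}: planted effects exceed unit variance")
        resid_var = 1.0 - b2
        g = L @ rng.standard_normal(n) * np.sqrt(t.h2 * resid_var)
        e = rng.standard_normal(n) * np.sqrt((1.0 - t.h2) * resid_var)
        z = driver + g + e
        raw = np.where(
            fem, t.mean_female + t.sd_female * z, t.mean_male + t.sd_male * z
        )
        out[t.name] = raw
    return pd.DataFrame(out, index=meth_true.index)


def apply_measurement_layer(
    meth_true: pd.DataFrame,
    config: SimulationConfig,
    seed: int | np.random.Generator,
) -> pd.DataFrame:
    """Replicate-level measurement records with injected QC failures.

    Every unit of every subject is measured in triplicate with Gaussian
    noise.  A configured fraction of subjects suffers an assay failure
    (several units entirely uncalled, driving the calling rate below the
    QC threshold); independently, a configured fraction of remaining
    cells receives inflated replicate scatter so that the downstream
    sd > 0.1 rule excludes them.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    m = config.measurement
    unit_labels = [u.label for u in config.units]
    n_units = len(unit_labels)
    rows = []
    for sid in meth_true.index:
        failed = rng.random() < m.subject_failure_rate
        missing_units: set[str] = set()
        if failed:
            # enough uncalled units to force the calling rate below 95%
            k = int(rng.integers(2, max(3, n_units // 4)))
            missing_units = set(rng.choice(unit_labels, size=k, replace=False))
        for label in unit_labels:
            truth = float(meth_true.loc[sid, label])
            if label in missing_units:
                reps = [np.nan] * m.replicates
            elif not failed and rng.random() < m.cell_exclusion_rate:
                # scattered triplet: sd well above the 0.1 exclusion cutoff
                offsets = np.linspace(-m.exclusion_spread, m.exclusion_spread, m.replicates)
                reps = list(np.clip(truth + offsets, 0.0, 1.0))
            else:
                reps = list(simulate_measurement(truth, m.noise_sd, m.replicates, rng))
            for r, v in enumerate(reps, start=1):
                rows.append(
                    {"subject": sid, "unit": label, "replicate": r, "fraction": v}
                )
    return pd.DataFrame(rows)


def simulate_expression(
    cohort_ids: Sequence[str],
    seed: int | np.random.Generator,
    n_probes: int = 30,
    n_undetected: int = 5,
    focal_probe: str = "FABP3_probe",
    focal_driver: np.ndarray | None = None,
    focal_beta: float = 0.0,
) -> pd.DataFrame:
    """Simple log-normal probe intensity matrix (subjects x probes).

    ``n_undetected`` probes get near-background intensities so a
    detection filter can remove them; the focal probe's log2 level can
    be driven by a standardized covariate with effect ``focal_beta``.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = len(cohort_ids)
    probes = [focal_probe] + [f"probe_{k:03d}" for k in range(1, n_probes)]
    log2_means = np.concatenate(
        [[9.0], rng.uniform(7.0, 12.0, size=n_probes - 1 - n_undetected),
         rng.uniform(0.1, 0.5, size=n_undetected)]
    )
    log2 = log2_means[None, :] + rng.normal(0.0, 0.8, size=(n, n_probes))
    if focal_driver is not None and focal_beta != 0.0:
        z = (focal_driver - np.mean(focal_driver)) / np.std(focal_driver)
        log2[:, 0] += focal_beta * z
    return pd.DataFrame(2.0**log2, index=list(cohort_ids), columns=probes)


def generate_cohort(
    config: SimulationConfig | None = None,
    seed: int = 0,
    with_expression: bool = False,
) -> SyntheticCohort:
    """Full generation pass: pedigree, covariates, methylation, phenotypes,
    replicate-level measurements (and optionally expression)."""
    config = config if config is not None else default_config()
    rng = np.random.default_rng(seed)
    ped = gen_pedigrees(config, rng)
    kin = kinship_matrix(ped)
    cov = sample_covariates(ped, config, rng)
    meth_true, clamp_fraction = simulate_methylation_panel(
        config, kin.phi, cov["age"].to_numpy(), cov["female"].to_numpy(), rng
    )
    meth_true.index = pd.Index(ped.ids, name="id")
    phen = simulate_phenotypes(config, kin.phi, meth_true, cov["female"].to_numpy(), rng)
    records = apply_measurement_layer(meth_true.drop(columns=[config.regional_average_label]), config, rng)
    expression = None
    if with_expression:
        expression = simulate_expression(ped.ids, rng)
    return SyntheticCohort(
        pedigree=ped,
        kinship=kin,
        covariates=cov,
        meth_true=meth_true,
        phenotypes=phen,
        records=records,
        config=config,
        seed=seed,
        clamp_fraction=clamp_fraction,
        expression=expression,
    )


def write_cohort(cohort: SyntheticCohort, directory) -> dict[str, Path]:
    """Write the cohort as plain-text files that round-trip the readers.

    Emits a PED-like pedigree file, a phenotype CSV (with age/sex
    covariates), a long-format replicate methylation CSV, a true
    methylation CSV, and a YAML file with every generative parameter and
    the seed.
    """
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    paths = {
        "pedigree": d / "pedigree.ped",
        "phenotypes": d / "phenotypes.csv",
        "methylation": d / "methylation_long.csv",
        "meth_true": d / "methylation_true.csv",
        "truth": d / "truth.yaml",
    }
    cohort.pedigree.write(paths["pedigree"])
    phen = cohort.phenotypes.copy()
    phen.insert(0, "age", cohort.covariates["age"])
    phen.insert(1, "sex", np.where(cohort.covariates["female"], "female", "male"))
    phen.to_csv(paths["phenotypes"], index_label="id")
    cohort.records.to_csv(paths["methylation"], index=False)
    cohort.meth_true.to_csv(paths["meth_true"], index_label="id")
    truth = {
        "seed": cohort.seed,
        "clamp_fraction": cohort.clamp_fraction,
        "config": _config_to_dict(cohort.config),
    }
    with open(paths["truth"], "w") as fh:
        yaml.safe_dump(truth, fh, sort_keys=False)
    if cohort.expression is not None:
        paths["expression"] = d / "expression.csv"
        cohort.expression.to_csv(paths["expression"], index_label="id")
    return paths


def _config_to_dict(config: SimulationConfig) -> dict:
    d = asdict(config)
    d["age_means"] = list(config.age_means)
    return d


def config_from_dict(d: dict) -> SimulationConfig:
    d = dict(d)
    d["units"] = [UnitSpec(**u) for u in d.get("units", [])]
    d["traits"] = [TraitSpec(**t) for t in d.get("traits", [])]
    d["measurement"] = MeasurementSpec(**d.get("measurement", {}))
    if "age_means" in d:
        d["age_means"] = tuple(d["age_means"])
    return SimulationConfig(**d)


def read_phenotypes(path) -> pd.DataFrame:
    """Read a phenotype CSV (id-indexed, with age and sex columns)."""
    df = pd.read_csv(path, index_col="id")
    if "sex" in df.columns:
        df["female"] = df["sex"].astype(str).str.lower().isin({"female", "f", "2"})
    return df


def read_methylation_records(path) -> pd.DataFrame:
    """Read a long-format replicate methylation CSV."""
    df = pd.read_csv(path)
    required = {"subject", "unit", "replicate", "fraction"}
    if not required <= set(df.columns):
        raise ValueError(f"methylation records need columns {sorted(required)}")
    return df
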