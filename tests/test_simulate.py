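import numpy as np
import pandas as pd
import pytest
import yaml

from famewas.pedigree import kinship_matrix, read_pedigree
from famewas.qc import REGIONAL_AVERAGE_LABEL, build_methylation_matrix
from famewas.simulate import (
    SimulationConfig,
    TraitSpec,
    UnitSpec,
    apply_measurement_layer,
    config_from_dict,
    default_config,
    gen_pedigrees,
    generate_cohort,
    read_methylation_records,
    read_phenotypes,
    simulate_methylation_panel,
    simulate_phenotypes,
    simulate_trait_with_h2,
    write_cohort,
)


class TestGenPedigrees:
    def test_single_minimal_family(self):
        cfg = default_config(
            n_families=1, base_sibship=2, sibship_extra_mean=0.0, spouse_prob=0.0
        )
        ped = gen_pedigrees(cfg, seed=0)
        assert len(ped) == 4
        assert len(ped.founders) == 2

    def test_cohort_size_targets_517(self):
        sizes = [len(gen_pedigrees(default_config(), seed=s)) for s in range(50)]
        assert abs(np.mean(sizes) - 517) / 517 <= 0.10

    def test_determinism(self):
        a = gen_pedigrees(default_config(), seed=9)
        b = gen_pedigrees(default_config(), seed=9)
        assert a.ids == b.ids
        assert [i.father_id for i in a] == [i.father_id for i in b]

    def test_invalid_shape(self):
        with pytest.raises(ValueError):
            gen_pedigrees(default_config(n_families=0), seed=0)


class TestSimulateTraitWithH2:
    def test_h2_zero_no_sib_correlation(self, nuclear_family, rng):
        K = kinship_matrix(nuclear_family)
        pairs = []
        for _ in range(800):
            y = simulate_trait_with_h2(K, 0.0, 0.0, 1.0, rng)
            pairs.append((y[2], y[3]))
        r = np.corrcoef(np.array(pairs).T)[0, 1]
        assert abs(r) < 0.1

    def test_h2_one_parent_offspring_correlation_half(self, nuclear_family, rng):
        K = kinship_matrix(nuclear_family)
        pairs = []
        for _ in range(800):
            y = simulate_trait_with_h2(K, 1.0, 0.0, 1.0, rng)
            pairs.append((y[0], y[2]))
        r = np.corrcoef(np.array(pairs).T)[0, 1]
        assert r == pytest.approx(0.5, abs=0.1)

    def test_covariance_recovery(self, rng):
        """Empirical genetic covariance matches 2*Phi*h2*var elementwise."""
        from famewas.pedigree import Individual, Pedigree

        ped = Pedigree(
            [
                Individual("f", "x", None, None, "male"),
                Individual("m", "x", None, None, "female"),
                Individual("c1", "x", "f", "m", "male"),
                Individual("c2", "x", "f", "m", "female"),
                Individual("s", "x", None, None, "male"),
                Individual("g", "x", "s", "c2", "female"),
            ]
        )
        K = kinship_matrix(ped)
        h2, var = 0.8, 2.0
        draws = np.array(
            [simulate_trait_with_h2(K, h2, 0.0, var, rng) for _ in range(2500)]
        )
        emp = np.cov(draws.T)
        expected = 2 * K.phi * h2 * var + np.eye(6) * (1 - h2) * var
        mc_se = np.sqrt((np.outer(np.diag(expected), np.diag(expected)) + expected**2) / 2500)
        assert np.all(np.abs(emp - expected) <= 4 * mc_se)

    def test_invalid_h2(self, nuclear_family):
        K = kinship_matrix(nuclear_family)
        with pytest.raises(ValueError):
            simulate_trait_with_h2(K, 1.5, 0.0, 1.0, 0)


class TestMethylationPanel:
    def test_zero_effects_iid_clamped_normal(self, rng):
        cfg = SimulationConfig(units=[UnitSpec("u", 0.5, 0.05, 0.0)])
        n = 300
        phi = np.eye(n) * 0.5
        df, clamp = simulate_methylation_panel(cfg, phi, np.full(n, 40.0), np.zeros(n, bool), rng)
        assert clamp == 0.0
        assert df["u"].mean() == pytest.approx(0.5, abs=0.02)
        assert df["u"].std() == pytest.approx(0.05, abs=0.01)

    def test_no_clamping_at_ten_sigma(self, rng):
        cfg = SimulationConfig(units=[UnitSpec("u", 0.5, 0.05, 0.0)])
        n = 10_000
        phi = np.eye(n) * 0.5
        _, clamp = simulate_methylation_panel(cfg, phi, np.full(n, 40.0), np.zeros(n, bool), rng)
        assert clamp == 0.0

    def test_age_slope_recovered(self):
        """Positive generative age slope recovers a positive fit in most reps."""
        from famewas.pipeline import heritability_scan

        signs = []
        for seed in range(6):
            c = generate_cohort(default_config(), seed=seed)
            scan = heritability_scan(
                c.meth_true[["FABP3_9"]], c.covariates, c.kinship
            )
            signs.append(scan.loc[0, "beta_age"] > 0)
        assert sum(signs) >= 5

    def test_regional_average_column(self, rng):
        cfg = default_config()
        n = 50
        phi = np.eye(n) * 0.5
        df, _ = simulate_methylation_panel(cfg, phi, np.full(n, 40.0), np.zeros(n, bool), rng)
        units = [u.label for u in cfg.units]
        assert np.allclose(df[REGIONAL_AVERAGE_LABEL], df[units].mean(axis=1))


class TestPhenotypes:
    def test_raw_scale_by_sex(self, rng):
        cfg = default_config()
        n = 4000
        phi = np.eye(n) * 0.5
        fem = np.arange(n) % 2 == 0
        meth, _ = simulate_methylation_panel(cfg, phi, np.full(n, 40.0), fem, rng)
        phen = simulate_phenotypes(cfg, phi, meth, fem, rng)
        tc = phen["TC"]
        tol_f = 4 * 40.03 / np.sqrt(fem.sum())
        tol_m = 4 * 45.75 / np.sqrt((~fem).sum())
        assert tc[fem].mean() == pytest.approx(189.06, abs=tol_f)
        assert tc[~fem].mean() == pytest.approx(193.08, abs=tol_m)
        assert tc[~fem].std() == pytest.approx(45.75, rel=0.1)

    def test_variance_misconfiguration_rejected(self):
        with pytest.raises(ValueError):
            TraitSpec("t", 0, 1, 0, 1, 0.5, assoc={"u": 1.1})


class TestMeasurementLayer:
    def test_lossless_when_clean(self, rng):
        cfg = default_config()
        cfg.measurement.noise_sd = 0.0
        cfg.measurement.cell_exclusion_rate = 0.0
        cfg.measurement.subject_failure_rate = 0.0
        truths = pd.DataFrame(
            {u.label: np.clip(rng.normal(u.mean, u.sd, 40), 0, 1) for u in cfg.units},
            index=[f"s{i}" for i in range(40)],
        )
        records = apply_measurement_layer(truths, cfg, rng)
        matrix, report = build_methylation_matrix(records)
        assert report["n_rejected_subjects"] == 0
        units = [u.label for u in cfg.units]
        assert np.allclose(matrix.loc[truths.index, units].to_numpy(), truths[units].to_numpy())

    def test_failure_rates_recovered(self):
        c = generate_cohort(default_config(), seed=21)
        matrix, report = build_methylation_matrix(c.records)
        n = len(c.pedigree)
        # subject failures ~ Binomial(n, 0.025)
        k = report["n_rejected_subjects"]
        p = 0.025
        assert abs(k - n * p) <= 3 * np.sqrt(n * p * (1 - p)) + 1
        # cell exclusions ~ 4.8% of measured cells
        f = report["cell_exclusion_fraction"]
        n_cells = (n - k) * 17
        assert abs(f - 0.048) <= 3 * np.sqrt(0.048 * 0.952 / n_cells)


class TestCohortIO:
    def test_roundtrip_and_determinism(self, tmp_path):
        c1 = generate_cohort(default_config(), seed=5)
        c2 = generate_cohort(default_config(), seed=5)
        pd.testing.assert_frame_equal(c1.records, c2.records)
        pd.testing.assert_frame_equal(c1.phenotypes, c2.phenotypes)

        paths = write_cohort(c1, tmp_path / "cohort")
        ped = read_pedigree(paths["pedigree"])
        assert ped.ids == c1.pedigree.ids
        recs = read_methylation_records(paths["methylation"])
        assert len(recs) == len(c1.records)
        phen = read_phenotypes(paths["phenotypes"])
        assert np.allclose(phen["TC"], c1.phenotypes["TC"])
        assert phen["female"].equals(c1.covariates["female"].rename("female"))

    def test_truth_yaml_complete(self, tmp_path):
        c = generate_cohort(default_config(), seed=6)
        paths = write_cohort(c, tmp_path / "cohort")
        with open(paths["truth"]) as fh:
            truth = yaml.safe_load(fh)
        assert truth["seed"] == 6
        cfg = config_from_dict(truth["config"])
        assert len(cfg.units) == 17
        assert cfg.unit("FABP3_9").h2 == pytest.approx(0.48)
        assert {t.name for t in cfg.traits} >= {"TC", "dBP", "SI", "BMED"}

    def test_different_seeds_different_data_same_schema(self, tmp_path):
        a = generate_cohort(default_config(), seed=1)
        b = generate_cohort(default_config(), seed=2)
        assert list(a.records.columns) == list(b.records.columns)
        assert not a.phenotypes["TC"].head(20).equals(b.phenotypes["TC"].head(20))
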