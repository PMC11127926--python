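import numpy as np
import pytest

from prscohort.qc import apply_variant_filters, genotype_counts, hwe_exact_pvalue
from prscohort.scoring import compute_prs, normalize_scores, orient_dosages
from prscohort.simulate import (
    SimulationConfig,
    plant_qc_failures,
    simulate_cohort_genotypes,
    simulate_prs_model,
    simulate_study,
    simulate_survival,
    write_study_directory,
)
from prscohort.stats import sample_skewness


def _scores(study):
    model = study["model"]
    case_o, _ = orient_dosages(study["case_genotypes"], model)
    ctrl_o, _ = orient_dosages(study["control_genotypes"], model)
    # generator tests use complete data (missing_rate=0), no imputation step
    case_raw = compute_prs(case_o).raw_score
    ctrl_raw = compute_prs(ctrl_o).raw_score
    return normalize_scores(case_raw, ctrl_raw)


class TestModelSimulation:
    def test_default_model_has_66_weighted_variants(self):
        model, freqs = simulate_prs_model(SimulationConfig(seed=0))
        assert len(model) == 66
        assert freqs.shape == (66,)
        assert np.all((freqs > 0) & (freqs < 1))

    def test_same_seed_reproduces_model(self):
        cfg = SimulationConfig(seed=5)
        m1, f1 = simulate_prs_model(cfg)
        m2, f2 = simulate_prs_model(cfg)
        assert m1.variants == m2.variants
        np.testing.assert_array_equal(f1, f2)

    def test_zero_weight_sd_gives_all_zero_weights(self):
        model, _ = simulate_prs_model(SimulationConfig(seed=1, weight_sd=0.0))
        assert np.all(model.weights == 0.0)


class TestGenotypeSimulation:
    def test_seeded_determinism_end_to_end(self):
        cfg = SimulationConfig(seed=9, n_case=20, n_control=50, n_variants=12,
                               pool_size=600)
        s1, s2 = simulate_study(cfg), simulate_study(cfg)
        np.testing.assert_array_equal(
            s1["case_genotypes"].dosage, s2["case_genotypes"].dosage
        )
        assert s1["cohort"].df.equals(s2["cohort"].df)

    def test_control_genotypes_respect_hardy_weinberg(self):
        cfg = SimulationConfig(seed=2, n_case=51, n_control=414,
                               missing_rate=0.0)
        model, freqs = simulate_prs_model(cfg)
        _, ctrl, _ = simulate_cohort_genotypes(model, freqs, cfg)
        # oriented to the stored ALT allele; HWE is allele-label symmetric
        ps = [
            hwe_exact_pvalue(*genotype_counts(ctrl.dosage[:, j]))
            for j in range(ctrl.n_variants)
        ]
        assert np.mean(np.array(ps) > 0.001) >= 0.95

    def test_null_link_gives_similar_cohort_means(self):
        cfg = SimulationConfig(seed=3, n_case=500, n_control=500, true_beta=0.0,
                               missing_rate=0.0, pool_size=6000)
        study = simulate_study(cfg)
        case_n, ctrl_n = _scores(study)
        assert abs(case_n.mean() - ctrl_n.mean()) < 0.25

    def test_positive_link_separates_cohort_means(self):
        cfg = SimulationConfig(seed=4, n_case=200, n_control=400,
                               missing_rate=0.0, pool_size=6000)
        study = simulate_study(cfg)
        case_n, ctrl_n = _scores(study)
        assert case_n.mean() > ctrl_n.mean() + 0.4

    def test_skew_mixture_produces_left_skewed_cases(self):
        # 30% baseline / 70% shifted +2 SD: mixture third central moment
        # q(1-q)(1-2q) d^3 < 0 for q = 0.7, so case skewness is negative
        cfg = SimulationConfig(seed=6, n_case=400, n_control=400,
                               skew_mixture=(0.3, 2.0), missing_rate=0.0,
                               pool_size=6000)
        study = simulate_study(cfg)
        case_n, _ = _scores(study)
        assert sample_skewness(case_n) < 0

    def test_unattainable_case_count_raises(self):
        cfg = SimulationConfig(seed=0, n_case=300, n_control=300, pool_size=400)
        model, freqs = simulate_prs_model(cfg)
        with pytest.raises(ValueError):
            simulate_cohort_genotypes(model, freqs, cfg)


class TestSurvivalSimulation:
    def test_zero_censor_rate_gives_all_events(self):
        cfg = SimulationConfig(seed=1, n_case=30, n_control=60, pool_size=900,
                               censor_rates={"case": 0.0, "control": 0.0})
        study = simulate_study(cfg)
        assert set(study["cohort"].df["vital_status"]) == {"deceased"}

    def test_rate_ratio_reflected_in_group_medians(self):
        cfg = SimulationConfig(
            seed=2, n_case=2000, n_control=2000, pool_size=20000,
            n_variants=5,
            event_rates={"case": 0.1, "control": 0.5},
            censor_rates={"case": 0.0, "control": 0.0},
        )
        model, freqs = simulate_prs_model(cfg)
        _, _, cohort = simulate_cohort_genotypes(model, freqs, cfg)
        cohort = simulate_survival(cohort, cfg)
        med = cohort.df.groupby("cohort")["survival_years"].median()
        assert med["case"] / med["control"] == pytest.approx(5.0, rel=0.2)

    def test_nonpositive_rate_raises(self):
        cfg = SimulationConfig(seed=0, event_rates={"case": 0.0, "control": 1.0})
        study_cohort = simulate_study(
            SimulationConfig(seed=0, n_case=10, n_control=10, pool_size=300,
                             n_variants=4)
        )["cohort"]
        with pytest.raises(ValueError):
            simulate_survival(study_cohort, cfg)


class TestPlantedFailures:
    def test_planted_r2_failures_are_dropped_at_read(self, tmp_path):
        from prscohort.io import read_genotypes_vcf

        cfg = SimulationConfig(seed=7, n_case=10, n_control=20, n_variants=10,
                               pool_size=300, r2_fail_count=2)
        write_study_directory(tmp_path, cfg)
        gm = read_genotypes_vcf(tmp_path / "control.vcf")
        assert gm.n_variants == 8
        assert gm.log.n_dropped_r2 == 2

    def test_planted_high_missingness_variant_fails_callrate(self):
        cfg = SimulationConfig(seed=8, n_case=50, n_control=50, n_variants=8,
                               pool_size=1000, missing_rate=0.0,
                               highmiss_variant_indices=(3,))
        study = simulate_study(cfg)
        _, report = apply_variant_filters(study["control_genotypes"])
        assert report.failed_callrate == [study["control_genotypes"].variant_keys[3]]

    def test_planted_all_het_variant_fails_hwe(self):
        cfg = SimulationConfig(seed=9, n_case=50, n_control=50, n_variants=8,
                               pool_size=1000, missing_rate=0.0,
                               plant_hwe_violation=True)
        study = simulate_study(cfg)
        gm = study["control_genotypes"]
        _, report = apply_variant_filters(gm)
        assert gm.variant_keys[-1] in report.failed_hwe

    def test_overplanting_raises(self):
        cfg = SimulationConfig(seed=0, n_variants=3, r2_fail_count=5)
        study = simulate_study(
            SimulationConfig(seed=0, n_case=5, n_control=5, n_variants=3,
                             pool_size=200)
        )
        with pytest.raises(ValueError):
            plant_qc_failures(study["case_genotypes"], cfg)


class TestStudyDirectory:
    def test_written_study_round_trips_through_readers(self, tmp_path):
        from prscohort.io import (
            read_cohort_table,
            read_genotypes_vcf,
            read_prs_model,
        )

        cfg = SimulationConfig(seed=10, n_case=15, n_control=30, n_variants=10,
                               pool_size=500, missing_rate=0.05)
        study = write_study_directory(tmp_path, cfg)
        model = read_prs_model(tmp_path / "model.tsv")
        assert len(model) == 10
        gm = read_genotypes_vcf(tmp_path / "case.vcf")
        np.testing.assert_array_equal(
            gm.dosage, study["case_genotypes"].dosage
        )
        pheno = read_cohort_table(tmp_path / "phenotypes.tsv")
        assert len(pheno) == 45
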