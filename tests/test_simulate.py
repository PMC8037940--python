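import numpy as np
import pandas as pd
import pytest
from scipy.special import expit, logit

from fluoropanel import (
    SimulationConfig,
    default_config,
    hwe_exact_test,
    planted_strata_cohort,
    read_genotypes,
    simulate_cohort,
    simulate_genotypes,
    simulate_toxicity,
    write_vcf,
)
from fluoropanel.simulate import ConfigError, DEFAULT_STRATA_COUNTS


class TestConfigValidation:
    def test_frequency_outside_range_rejected(self):
        with pytest.raises(ConfigError, match="allele frequency"):
            SimulationConfig(allele_freq={"rs1": 0.7})

    def test_zero_baseline_prevalence_rejected(self):
        with pytest.raises(ConfigError, match="baseline"):
            SimulationConfig(baseline_grade34={"diarrhoea": 0.0})

    def test_nonpositive_odds_ratio_rejected(self):
        with pytest.raises(ConfigError, match="odds ratio"):
            SimulationConfig(effect_sizes={("rs1", "diarrhoea"): 0.0})

    def test_effect_on_unconfigured_endpoint_is_an_error(self):
        config = SimulationConfig(
            n_samples=10,
            allele_freq={"rs1": 0.1},
            baseline_grade34={"diarrhoea": 0.1},
            effect_sizes={("rs1", "hfs"): 2.0},
        )
        genotypes = simulate_genotypes(config)
        with pytest.raises(ConfigError, match="baseline"):
            simulate_toxicity(genotypes, config)


class TestSimulateGenotypes:
    def test_zero_frequency_gives_all_reference(self):
        config = SimulationConfig(n_samples=50, allele_freq={"rs1": 0.0})
        m = simulate_genotypes(config)
        assert (m.dosage("rs1") == 0).all()

    def test_half_frequency_dosage_mean_near_one(self):
        n = 20000
        config = SimulationConfig(n_samples=n, allele_freq={"rs1": 0.5}, seed=5)
        m = simulate_genotypes(config)
        se = np.sqrt(2 * 0.5 * 0.5 / n)
        assert abs(m.dosage("rs1").mean() - 1.0) < 3 * se

    def test_default_cohort_conforms_to_hwe(self):
        # generator self-consistency: polymorphic variants pass the exact test
        fractions = []
        for seed in (1, 2, 3):
            m = simulate_genotypes(default_config(seed=seed))
            ps = []
            for vid in m.variant_ids:
                counts = m.genotype_counts(vid)
                n_alt = 2 * counts[2] + counts[1]
                if min(n_alt, 2 * sum(counts) - n_alt) == 0:
                    continue
                ps.append(hwe_exact_test(*counts))
            fractions.append(np.mean([p > 0.001 for p in ps]))
        assert np.mean(fractions) >= 0.95

    def test_same_seed_is_byte_identical(self):
        config = default_config(seed=9)
        a = simulate_cohort(config)
        b = simulate_cohort(config)
        assert a.genotypes.dosages.to_csv() == b.genotypes.dosages.to_csv()
        assert a.toxicity.to_csv() == b.toxicity.to_csv()


class TestSimulateToxicity:
    def test_null_model_rate_matches_baseline(self):
        n = 20000
        config = SimulationConfig(
            n_samples=n,
            allele_freq={"rs1": 0.3},
            effect_sizes={},
            seed=3,
        )
        genotypes = simulate_genotypes(config)
        tox = simulate_toxicity(genotypes, config)
        for endpoint, p0 in config.baseline_grade34.items():
            events = tox[(tox.endpoint == endpoint) & (tox.grade >= 3)]
            rate = len(events) / n
            se = np.sqrt(p0 * (1 - p0) / n)
            assert abs(rate - p0) < 4 * se

    def test_carrier_event_rate_matches_logistic_closed_form(self):
        n = 40000
        p0 = 0.05
        config = SimulationConfig(
            n_samples=n,
            allele_freq={"rs1": 0.02},
            baseline_grade34={"diarrhoea": p0},
            grade4_fraction={"diarrhoea": 0.1},
            effect_sizes={("rs1", "diarrhoea"): 4.4},
            seed=11,
        )
        genotypes = simulate_genotypes(config)
        tox = simulate_toxicity(genotypes, config)
        events = (
            tox[tox.endpoint == "diarrhoea"].set_index("sample_id")["grade"] >= 3
        )
        het = genotypes.dosage("rs1") == 1
        expected = expit(logit(p0) + np.log(4.4))
        rate = events[het].mean()
        n_het = int(het.sum())
        se = np.sqrt(expected * (1 - expected) / n_het)
        assert abs(rate - expected) < 3 * se

    def test_panel_sensitivity_matches_generator_expectation(self):
        # a panel containing the sole causal variant, evaluated on its own
        # simulation, recovers the closed-form sensitivity
        n = 30000
        p0, q, oddsratio = 0.08, 0.2, 3.0
        config = SimulationConfig(
            n_samples=n,
            allele_freq={"rs1": q},
            baseline_grade34={"diarrhoea": p0},
            effect_sizes={("rs1", "diarrhoea"): oddsratio},
            seed=21,
        )
        genotypes = simulate_genotypes(config)
        tox = simulate_toxicity(genotypes, config)
        events = (
            tox[tox.endpoint == "diarrhoea"].set_index("sample_id")["grade"] >= 3
        )
        carrier = genotypes.dosage("rs1") >= 1
        # closed form: P(carrier | event) under HWE and the logistic model
        geno_p = np.array([(1 - q) ** 2, 2 * q * (1 - q), q**2])
        event_p = expit(logit(p0) + np.arange(3) * np.log(oddsratio))
        expected_sens = (geno_p[1:] * event_p[1:]).sum() / (geno_p * event_p).sum()
        observed_sens = carrier[events].mean()
        n_events = int(events.sum())
        se = np.sqrt(expected_sens * (1 - expected_sens) / n_events)
        assert abs(observed_sens - expected_sens) < 3 * se

    def test_death_only_among_grade4_events(self):
        cohort = simulate_cohort(default_config(seed=13))
        tox = cohort.toxicity
        deaths = set(
            tox[(tox.endpoint == "death") & (tox.grade == 1)]["sample_id"]
        )
        grade4 = set(tox[(tox.grade == 4) & (tox.endpoint != "death")]["sample_id"])
        assert deaths <= grade4


class TestPlantedStrata:
    def test_default_counts_round_trip_exactly(self, catalog):
        from fluoropanel import activity_score, classify_risk, tier_counts

        cohort = planted_strata_cohort()
        tiers = classify_risk(
            activity_score(cohort.genotypes, catalog), cohort.genotypes
        )
        assert tier_counts(tiers) == DEFAULT_STRATA_COUNTS
        assert (tiers["tier"] == cohort.truth["planted_tier"]).all()

    def test_ten_standard_patients_have_no_risk_alleles(self):
        counts = {"critical": 0, "high": 0, "standard": 10, "standard_high_hfs": 0}
        cohort = planted_strata_cohort(counts)
        assert (cohort.genotypes.dosages.to_numpy() == 0).all()

    def test_single_critical_patient_has_deficient_genotype(self, catalog):
        from fluoropanel import activity_score

        counts = {"critical": 1, "high": 0, "standard": 0, "standard_high_hfs": 0}
        cohort = planted_strata_cohort(counts)
        score = activity_score(cohort.genotypes, catalog)["activity_score"].iloc[0]
        assert score <= 0.5

    def test_negative_counts_rejected(self):
        with pytest.raises(ConfigError):
            planted_strata_cohort({"critical": -1, "high": 0, "standard": 1,
                                   "standard_high_hfs": 0})


class TestParameterRecovery:
    def test_planted_odds_ratio_recovered_at_scale(self):
        # per-allele OR 3.8 for one common variant, n = 50,000
        n = 50000
        config = SimulationConfig(
            n_samples=n,
            allele_freq={"rs1": 0.25},
            baseline_grade34={"global_like": 0.1},
            grade4_fraction={"global_like": 0.0},
            effect_sizes={("rs1", "global_like"): 3.8},
            seed=17,
        )
        genotypes = simulate_genotypes(config)
        tox = simulate_toxicity(genotypes, config)
        event = (
            tox[tox.endpoint == "global_like"]
            .set_index("sample_id")["grade"]
            .ge(3)
            .reindex(genotypes.dosages.index)
            .to_numpy()
        )
        dosage = genotypes.dosage("rs1").to_numpy()
        het, ref = dosage == 1, dosage == 0
        odds = lambda mask: event[mask].mean() / (1 - event[mask].mean())
        empirical = odds(het) / odds(ref)
        assert abs(empirical - 3.8) / 3.8 < 0.10


class TestVcfRoundTrip:
    def test_write_then_read_recovers_dosages(self, catalog, tmp_path):
        cohort = simulate_cohort(default_config(seed=2, n_samples=40))
        path = tmp_path / "cohort.vcf"
        write_vcf(cohort.genotypes, catalog, path)
        again = read_genotypes(path, catalog)
        pd.testing.assert_frame_equal(
            again.dosages[cohort.genotypes.dosages.columns],
            cohort.genotypes.dosages,
        )
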