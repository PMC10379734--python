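import numpy as np
import pandas as pd
import pytest

from polyscore import (
    SimulationConfig,
    VariantRecord,
    default_study_config,
    make_study_cohort,
    simulate_covariates,
    simulate_genotypes,
    simulate_phenotype,
    variance_components,
)
from polyscore.qc import ld_r2
from polyscore.simulate import SimulationError, max_attainable_r2, scale_snp_effects_to_share


def _two_variant_config(eaf_a=0.3, eaf_b=0.4, **kwargs):
    variants = [
        VariantRecord("rsA", "LOC", "1", 100, "A", "G", eaf_a),
        VariantRecord("rsB", "LOC", "1", 200, "C", "T", eaf_b),
    ]
    kwargs.setdefault("missing_rate", 0.0)
    return SimulationConfig(variants=variants, **kwargs)


class TestGenotypeSimulation:
    def test_zero_frequency_gives_all_reference(self):
        cfg = _two_variant_config(eaf_a=0.0, n_individuals=50, seed=3)
        panel = simulate_genotypes(cfg)
        assert (panel.dosage_of("rsA") == 0).all()

    def test_realized_frequency_within_sampling_bound(self):
        """At n=10000 the realized EAF sits within 3 binomial SEs of 0.283."""
        p = 0.283
        cfg = _two_variant_config(eaf_a=p, n_individuals=10_000, seed=11)
        panel = simulate_genotypes(cfg)
        bound = 3 * np.sqrt(p * (1 - p) / (2 * 10_000))
        assert abs(panel.observed_eaf()[0] - p) < bound

    def test_ld_pair_hits_target_r2(self):
        """A pair simulated at r2=0.55 estimates back within +-0.05."""
        cfg = _two_variant_config(n_individuals=10_000, seed=5, ld_pairs=[("rsA", "rsB", 0.55)])
        panel = simulate_genotypes(cfg)
        assert abs(ld_r2(panel, "rsA", "rsB") - 0.55) < 0.05

    def test_infeasible_r2_reports_maximum(self):
        cfg_kwargs = dict(n_individuals=100, seed=0)
        with pytest.raises(SimulationError, match="maximum attainable"):
            simulate_genotypes(
                _two_variant_config(eaf_a=0.05, eaf_b=0.5, ld_pairs=[("rsA", "rsB", 0.9)], **cfg_kwargs)
            )
        assert max_attainable_r2(0.05, 0.5) < 0.9

    def test_inbreeding_depletes_heterozygotes(self):
        """P(het) tracks 2pq(1-F) within sampling error."""
        p, f = 0.4, 0.3
        cfg = _two_variant_config(eaf_a=p, n_individuals=20_000, seed=9, hwe_violations=[("rsA", f)])
        panel = simulate_genotypes(cfg)
        het = (panel.dosage_of("rsA") == 1).mean()
        expected = 2 * p * (1 - p) * (1 - f)
        assert abs(het - expected) < 3 * np.sqrt(expected * (1 - expected) / 20_000)

    def test_hwe_variants_pass_own_exact_test(self):
        """Under equilibrium sampling the exact HWE test rarely fires at alpha=0.001."""
        from polyscore import hwe_exact_test

        rejections = 0
        reps = 300
        for seed in range(reps):
            cfg = _two_variant_config(eaf_a=0.3, n_individuals=500, seed=seed)
            panel = simulate_genotypes(cfg)
            if hwe_exact_test(*panel.genotype_counts("rsA")) < 0.001:
                rejections += 1
        assert rejections / reps <= 0.01

    def test_missingness_rate(self):
        cfg = _two_variant_config(n_individuals=10_000, seed=2, missing_rate=0.1)
        panel = simulate_genotypes(cfg)
        assert abs(np.isnan(panel.dosages).mean() - 0.1) < 0.01

    def test_determinism_under_fixed_seed(self):
        cfg = _two_variant_config(n_individuals=200, seed=42, ld_pairs=[("rsA", "rsB", 0.3)],
                                  missing_rate=0.05)
        a = simulate_genotypes(cfg)
        b = simulate_genotypes(cfg)
        np.testing.assert_array_equal(a.dosages, b.dosages)


class TestCovariateSimulation:
    def test_degenerate_prevalence_all_women(self):
        cfg = default_study_config(n_individuals=30, seed=0)
        cfg.covariate_prevalences["woman"] = 1.0
        table = simulate_covariates(cfg)
        assert (table["sex"] == "woman").all()

    def test_sex_margin_matches_study(self):
        cfg = default_study_config(n_individuals=10_000, seed=4)
        table = simulate_covariates(cfg)
        assert abs((table["sex"] == "woman").mean() - 0.7925) < 0.02

    def test_pbi_category_prevalences_approximate_targets(self):
        cfg = default_study_config(n_individuals=20_000, seed=6)
        table = simulate_covariates(cfg)
        for scale, target in cfg.covariate_prevalences["pbi_high"].items():
            realized = (table[f"{scale}_cat"] == "high").mean()
            assert abs(realized - target) < 0.02, scale

    def test_age_within_range_and_determinism(self):
        cfg = default_study_config(n_individuals=500, seed=8)
        a = simulate_covariates(cfg)
        b = simulate_covariates(cfg)
        assert a["age"].between(18, 25).all()
        pd.testing.assert_frame_equal(a, b)

    def test_bad_ethnicity_probabilities_rejected(self):
        cfg = default_study_config(n_individuals=100, seed=0)
        bad = {k: (dict(v) if isinstance(v, dict) else v) for k, v in cfg.covariate_prevalences.items()}
        bad["ethnicity"] = {"Russian": 0.9, "Tatar": 0.3, "Udmurt": 0.0, "mixed": 0.0}
        with pytest.raises(SimulationError, match="ethnicity"):
            SimulationConfig(variants=cfg.variants, covariate_prevalences=bad)


class TestPhenotypeSimulation:
    def test_no_signal_no_noise_gives_constant(self):
        cfg = _two_variant_config(n_individuals=40, seed=1, noise_sd=0.0, intercept=10.0)
        cfg.covariate_effects = {k: (0.0 if not isinstance(v, dict) else {kk: 0.0 for kk in v})
                                 for k, v in cfg.covariate_effects.items()}
        panel = simulate_genotypes(cfg)
        cohort = simulate_covariates(cfg)
        out = simulate_phenotype(panel, cohort, cfg)
        assert out["depression"].nunique() == 1

    def test_single_snp_effect_monotone_in_dosage(self):
        cfg = _two_variant_config(n_individuals=200, seed=1, noise_sd=0.0, intercept=10.0,
                                  true_snp_betas={"rsA": 2.0})
        cfg.covariate_effects = {k: (0.0 if not isinstance(v, dict) else {kk: 0.0 for kk in v})
                                 for k, v in cfg.covariate_effects.items()}
        panel = simulate_genotypes(cfg)
        cohort = simulate_covariates(cfg)
        out = simulate_phenotype(panel, cohort, cfg)
        means = out.groupby(panel.dosage_of("rsA"))["depression"].mean()
        assert means.is_monotonic_increasing and means.nunique() == len(means)

    def test_depression_bounded_integer(self, study_bundle):
        dep = study_bundle.cohort["depression"]
        assert dep.between(0, 63).all()
        assert (dep == dep.round()).all()

    def test_latent_variance_matches_analytic_decomposition(self):
        """Monte-Carlo variance of the continuous latent score matches the
        analytic component sum."""
        cfg = default_study_config(n_individuals=50_000, seed=13, discretize=False,
                                   exact_frequencies=False, missing_rate=0.0)
        rng = np.random.default_rng(13)
        panel = simulate_genotypes(cfg, rng)
        cohort = simulate_covariates(cfg, rng)
        out = simulate_phenotype(panel, cohort, cfg, rng)
        comps = variance_components(cfg)
        assert abs(out["depression"].var() / comps["total"] - 1) < 0.03

    def test_variance_share_rescaling(self):
        cfg = default_study_config()
        scaled = scale_snp_effects_to_share(cfg, 0.024)
        assert abs(variance_components(scaled)["snp_share"] - 0.024) < 1e-12


class TestStudyBundle:
    def test_dimensions_and_alignment(self, study_bundle):
        assert study_bundle.panel.n_variants == 32
        assert study_bundle.panel.n_individuals == 1065
        assert list(study_bundle.panel.sample_ids) == list(study_bundle.cohort["sample_id"])

    def test_seeds_change_data_not_shape(self, study_bundle):
        other = make_study_cohort(seed=2)
        assert other.panel.dosages.shape == study_bundle.panel.dosages.shape
        a, b = study_bundle.panel.dosages, other.panel.dosages
        assert np.nansum(a != b) > 0

    def test_exact_mode_pins_down_frequencies(self, study_bundle):
        eafs = study_bundle.panel.observed_eaf()
        targets = np.array([v.eaf for v in study_bundle.truth.variants])
        assert np.abs(eafs - targets).max() < 0.01

    def test_yaml_roundtrip(self, tmp_path, study_bundle):
        path = tmp_path / "cfg.yaml"
        study_bundle.truth.to_yaml(path)
        back = SimulationConfig.from_yaml(path)
        assert back.true_snp_betas == study_bundle.truth.true_snp_betas
        assert back.variants == study_bundle.truth.variants
        assert back.ld_pairs == list(study_bundle.truth.ld_pairs)
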