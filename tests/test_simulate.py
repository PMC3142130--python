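"""The synthetic cohort generator reproduces the structure it promises:
Hardy-Weinberg genotypes, the log-linear marker model, and proportional-
hazards event times whose parameters the downstream models can recover."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mrcohort.config import (
    ParameterError,
    SimulationConfig,
    SnpSpec,
    causal_scenario,
    confounded_scenario,
)
from mrcohort.marker import fit_marker_regression
from mrcohort.qc import code_genotypes, hwe_chi2_test
from mrcohort.simulate import (
    AlignmentError,
    generate_cohort,
    generate_covariates,
    generate_genotypes,
    generate_marker,
    generate_survival,
)
from mrcohort.survival import fit_cox


def _config(**kw):
    base = dict(n_subjects=1000, snps=(SnpSpec("s1", 0.25, 0.0),), seed=1)
    base.update(kw)
    return SimulationConfig(**base)


class TestGenotypes:
    def test_hwe_proportions_at_large_n(self):
        cfg = _config(n_subjects=10_000, snps=(SnpSpec("s1", 0.25),))
        d = generate_genotypes(cfg)["s1"]
        props = np.array([(d == k).mean() for k in (0, 1, 2)])
        # p^2, 2pq, q^2 at q=0.25, each within ~4 binomial SEs
        expected = np.array([0.5625, 0.375, 0.0625])
        se = np.sqrt(expected * (1 - expected) / 10_000)
        assert np.all(np.abs(props - expected) < 4 * se)

    def test_zero_maf_gives_all_reference(self):
        cfg = _config(snps=(SnpSpec("s1", 0.0),))
        assert (generate_genotypes(cfg)["s1"] == 0).all()

    def test_invalid_maf_rejected(self):
        with pytest.raises(ParameterError):
            SnpSpec("bad", 0.7)
        with pytest.raises(ParameterError):
            SnpSpec("bad", -0.1)

    def test_maf_recovery_and_hwe_calibration(self):
        """Observed MAF near truth; generator passes its own HWE test."""
        cfg = _config(n_subjects=1000, snps=(SnpSpec("s1", 0.23),), seed=5)
        d = generate_genotypes(cfg)["s1"]
        maf_hat = d.mean() / 2
        se = np.sqrt(0.23 * 0.77 / (2 * 1000))
        assert abs(maf_hat - 0.23) < 3 * se

        # HWE rejection rates must be nominal over replicate seeds: ~5% at
        # alpha=0.05 and ~1% at alpha=0.01, judged against the 99% binomial
        # band rather than a knife-edge count
        n_rep, sig_05, sig_01 = 300, 0, 0
        for seed in range(n_rep):
            d = generate_genotypes(_config(snps=(SnpSpec("s1", 0.23),), seed=seed))["s1"]
            counts = tuple(int((d == k).sum()) for k in (0, 1, 2))
            _, p = hwe_chi2_test(counts)
            sig_05 += p < 0.05
            sig_01 += p < 0.01
        assert sig_05 / n_rep < 0.085  # 0.05 + ~2.6 binomial SE
        assert sig_01 / n_rep < 0.030  # 0.01 + ~3.5 binomial SE

    def test_deterministic_given_seed(self):
        cfg = causal_scenario(n_subjects=500, seed=9)
        a, b = generate_cohort(cfg), generate_cohort(cfg)
        pd.testing.assert_frame_equal(a.genotypes, b.genotypes)
        pd.testing.assert_frame_equal(a.phenotypes, b.phenotypes)
        pd.testing.assert_frame_equal(a.survival, b.survival)


class TestMarker:
    def test_constant_when_no_effects_and_no_noise(self):
        cfg = _config(marker_sd=0.0, age_effect=0.0, sex_effect=0.0, marker_base=0.5)
        geno = generate_genotypes(cfg)
        cov, _ = generate_covariates(cfg)
        m = generate_marker(geno, cov, cfg)
        assert np.allclose(m, np.exp(0.5))

    def test_row_misalignment_raises(self):
        cfg = _config()
        geno = generate_genotypes(cfg)
        cov, _ = generate_covariates(cfg)
        with pytest.raises(AlignmentError):
            generate_marker(geno.iloc[:-3], cov, cfg)

    def test_regression_recovers_per_allele_percent_change(self):
        """Fitted per-allele effect covers the generating +81.3%/allele."""
        cfg = causal_scenario(n_subjects=5000, seed=21)
        cohort = generate_cohort(cfg)
        est = fit_marker_regression(
            cohort.phenotypes["ln_marker"],
            code_genotypes(cohort.genotypes["snp1"], "additive"),
            cohort.phenotypes[["age", "sex"]],
        )["snp1_additive"]
        truth = np.log(1.813)
        assert est.ci_low < truth < est.ci_high
        assert abs(est.beta - truth) < 0.06

    def test_confounder_correlates_with_marker(self):
        cfg = confounded_scenario(n_subjects=5000, seed=2)
        cohort = generate_cohort(cfg)
        r = np.corrcoef(cohort.confounder, cohort.phenotypes["ln_marker"])[0, 1]
        assert r > 0.2


class TestSurvival:
    def test_zero_baseline_hazard_censors_everyone(self):
        cfg = _config(baseline_hazard=0.0, dropout_rate=0.0)
        cohort = generate_cohort(cfg)
        assert cohort.survival["event"].sum() == 0
        assert np.allclose(cohort.survival["time_years"], cfg.admin_censor_years)

    def test_positive_times_and_binary_events(self):
        cohort = generate_cohort(causal_scenario(n_subjects=2000, seed=3))
        assert (cohort.survival["time_years"] > 0).all()
        assert cohort.survival["event"].isin([0, 1]).all()
        assert (cohort.survival["time_years"] <= 8.0).all()

    def test_event_fraction_near_design_target(self):
        """~15% events over 8 years under the causal defaults."""
        cohort = generate_cohort(causal_scenario(n_subjects=20_000, seed=17))
        assert 0.12 < cohort.survival["event"].mean() < 0.18

    def test_cox_recovers_marker_hazard_ratio(self):
        """HR per unit ln(marker) covers the generating 1.33 in >=90% of
        replicates."""
        truth = np.log(1.33)
        covered = 0
        for seed in range(50):
            cohort = generate_cohort(causal_scenario(n_subjects=2000, seed=seed))
            est = fit_cox(
                cohort.survival,
                cohort.phenotypes[["ln_marker"]],
                cohort.phenotypes[["age", "sex"]],
            )["ln_marker"]
            covered += est.ci_low < np.exp(truth) < est.ci_high
        assert covered >= 45


class TestScenarioContrast:
    """The discriminating prediction of the Mendelian-randomization design."""

    def test_causal_genotype_hr_matches_coefficient_product(self):
        """Mean per-allele genotype log-HR tracks beta_g->m * beta_m->d."""
        target = np.log(1.813) * np.log(1.33)
        est = []
        for seed in range(60):
            cohort = generate_cohort(causal_scenario(n_subjects=2000, seed=1000 + seed))
            hz = fit_cox(
                cohort.survival,
                code_genotypes(cohort.genotypes["snp1"], "additive"),
                cohort.phenotypes[["age", "sex"]],
            )["snp1_additive"]
            est.append(hz.log_hr)
        mean, sem = np.mean(est), np.std(est, ddof=1) / np.sqrt(len(est))
        assert abs(mean - target) < 3.5 * sem + 0.01

    def test_pure_confounding_breaks_marker_but_not_genotype(self):
        marker_lhr, geno_lhr = [], []
        for seed in range(30):
            cohort = generate_cohort(confounded_scenario(n_subjects=2000, seed=seed))
            adj = cohort.phenotypes[["age", "sex"]]
            marker_lhr.append(
                fit_cox(cohort.survival, cohort.phenotypes[["ln_marker"]], adj)[
                    "ln_marker"
                ].log_hr
            )
            geno_lhr.append(
                fit_cox(
                    cohort.survival,
                    code_genotypes(cohort.genotypes["snp1"], "additive"),
                    adj,
                )["snp1_additive"].log_hr
            )
        assert np.mean(marker_lhr) > 0.1   # inflated above HR=1 by confounding
        assert abs(np.mean(geno_lhr)) < 0.05  # genotype stays null
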