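"""Marker-stage models: percent-change conversion, ANOVA R^2,
Kruskal-Wallis, adjusted OLS calibration, stepwise CV-PRESS selection and
the weighted genotype score."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from mrcohort.config import SimulationConfig, SnpSpec, causal_scenario
from mrcohort.marker import (
    CollinearityError,
    DegenerateScoreError,
    anova_r2,
    beta_to_pct,
    build_genotype_score,
    fit_marker_regression,
    kruskal_wallis,
    pct_to_beta,
    stepwise_cv_select,
)
from mrcohort.qc import code_genotypes
from mrcohort.simulate import generate_cohort


class TestPercentChange:
    def test_printed_per_allele_effect_maps_to_log_coefficient(self):
        assert pct_to_beta(81.3) == pytest.approx(0.5950, abs=5e-4)

    def test_zero_beta_is_zero_percent(self):
        pc = beta_to_pct(0.0, 0.3)
        assert pc.delta_pct == pytest.approx(0.0)
        assert pc.ci_low_pct < 0 < pc.ci_high_pct

    @pytest.mark.parametrize("pct", [-44.8, 27.7, 199.8])
    def test_round_trip(self, pct):
        assert beta_to_pct(pct_to_beta(pct)).delta_pct == pytest.approx(pct)

    def test_domain_error(self):
        with pytest.raises(ValueError):
            pct_to_beta(-100.0)

    @given(st.floats(-3, 3), st.floats(-3, 3))
    @settings(derandomize=True, max_examples=50)
    def test_strictly_increasing_in_beta(self, b1, b2):
        if abs(b1 - b2) < 1e-9:  # below float resolution of exp(b)-1
            return
        lo, hi = sorted([b1, b2])
        assert beta_to_pct(lo).delta_pct < beta_to_pct(hi).delta_pct


class TestMarkerRegression:
    def test_coverage_at_nominal_rate(self):
        """Per-allele CI covers ln(1.813) in >=93 of 100 replicates."""
        truth = np.log(1.813)
        covered = 0
        for seed in range(100):
            cohort = generate_cohort(causal_scenario(n_subjects=5000, seed=seed))
            est = fit_marker_regression(
                cohort.phenotypes["ln_marker"],
                code_genotypes(cohort.genotypes["snp1"], "additive"),
                cohort.phenotypes[["age", "sex"]],
            )["snp1_additive"]
            covered += est.ci_low < truth < est.ci_high
        assert covered >= 93

    def test_null_p_values_uniform(self):
        """Under a zero-effect generator, p-values are uniform (KS test)."""
        rng = np.random.default_rng(7)
        ps = []
        for _ in range(500):
            n = 200
            x = pd.DataFrame({"dose": rng.integers(0, 3, n).astype(float)})
            y = pd.Series(rng.normal(size=n))
            ps.append(fit_marker_regression(y, x)["dose"].p)
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_scale_shift_invariance(self, causal_cohort):
        design = code_genotypes(causal_cohort.genotypes["snp1"], "additive")
        adj = causal_cohort.phenotypes[["age", "sex"]]
        y = causal_cohort.phenotypes["ln_marker"]
        b1 = fit_marker_regression(y, design, adj)["snp1_additive"].beta
        b2 = fit_marker_regression(y + np.log(3.7), design, adj)["snp1_additive"].beta
        assert b1 == pytest.approx(b2, abs=1e-10)

    def test_collinearity_error_names_columns(self, causal_cohort):
        d = causal_cohort.genotypes["snp1"].astype(float)
        design = pd.DataFrame({"a": d, "b": 2.0 * d})
        with pytest.raises(CollinearityError, match="b"):
            fit_marker_regression(causal_cohort.phenotypes["ln_marker"], design)


class TestAnovaR2:
    def test_identical_group_means_give_zero(self):
        y = pd.Series([1.0, 2.0, 3.0] * 3)
        g = pd.Series([0, 0, 0, 1, 1, 1, 2, 2, 2])
        assert anova_r2(y, g) == pytest.approx(0.0, abs=1e-12)

    def test_zero_within_variance_gives_one(self):
        y = pd.Series([1.0, 1.0, 2.0, 2.0, 5.0, 5.0])
        g = pd.Series([0, 0, 1, 1, 2, 2])
        assert anova_r2(y, g) == pytest.approx(1.0)

    def test_equals_squared_correlation_with_group_means(self):
        rng = np.random.default_rng(3)
        g = pd.Series(rng.integers(0, 3, 300))
        y = pd.Series(rng.normal(size=300) + 0.5 * g)
        pred = y.groupby(g).transform("mean")
        assert anova_r2(y, g) == pytest.approx(np.corrcoef(y, pred)[0, 1] ** 2)

    def test_single_group_undefined(self):
        with pytest.raises(ValueError):
            anova_r2(pd.Series([1.0, 2.0]), pd.Series([0, 0]))


class TestKruskalWallis:
    def test_hand_computed_h(self):
        """Rank sums 6, 15, 24 over n=9 give H = 7.2."""
        v = pd.Series([1, 2, 3, 4, 5, 6, 7, 8, 9], dtype=float)
        g = pd.Series([0, 0, 0, 1, 1, 1, 2, 2, 2])
        h, p = kruskal_wallis(v, g)
        assert h == pytest.approx(7.2, abs=1e-10)
        assert p == pytest.approx(stats.chi2.sf(7.2, 2))

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(5)
        v = pd.Series(rng.exponential(size=120))
        g = pd.Series(rng.integers(0, 3, 120))
        h1, _ = kruskal_wallis(v, g)
        h2, _ = kruskal_wallis(np.log(v), g)
        assert h1 == pytest.approx(h2, rel=1e-12)

    def test_null_p_uniform_under_label_permutation(self):
        rng = np.random.default_rng(9)
        v = pd.Series(rng.normal(size=90))
        ps = []
        for _ in range(500):
            g = pd.Series(rng.permutation(np.repeat([0, 1, 2], 30)))
            ps.append(kruskal_wallis(v, g)[1])
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_all_tied_returns_p_one(self):
        h, p = kruskal_wallis(pd.Series([2.0] * 20), pd.Series([0, 1] * 10))
        assert (h, p) == (0.0, 1.0)


def _selection_config(n=2000, seed=0):
    snps = (SnpSpec("causal", 0.3, 0.5),) + tuple(
        SnpSpec(f"null{i}", 0.2 + 0.02 * i, 0.0) for i in range(8)
    )
    return SimulationConfig(n_subjects=n, snps=snps, seed=seed)


class TestStepwiseSelection:
    def test_recovers_single_causal_snp(self):
        """With one real effect among nine SNPs, it is selected in >=95/100
        seeds."""
        hits = 0
        for seed in range(100):
            cohort = generate_cohort(_selection_config(seed=seed))
            res = stepwise_cv_select(
                cohort.phenotypes["ln_marker"],
                cohort.genotypes,
                cohort.phenotypes[["age", "sex"]],
                seed=seed,
            )
            hits += "causal" in res.selected
        assert hits >= 95

    def test_parsimonious_under_global_null(self):
        sizes = []
        for seed in range(100):
            snps = tuple(SnpSpec(f"n{i}", 0.25, 0.0) for i in range(9))
            cohort = generate_cohort(SimulationConfig(n_subjects=500, snps=snps, seed=seed))
            res = stepwise_cv_select(
                cohort.phenotypes["ln_marker"],
                cohort.genotypes,
                cohort.phenotypes[["age", "sex"]],
                seed=seed,
            )
            sizes.append(len(res.selected))
        assert np.median(sizes) <= 1

    def test_collinear_causal_pair_enters_once(self):
        cohort = generate_cohort(_selection_config(seed=3))
        doses = cohort.genotypes[["causal"]].copy()
        doses["twin"] = doses["causal"]
        res = stepwise_cv_select(
            cohort.phenotypes["ln_marker"], doses,
            cohort.phenotypes[["age", "sex"]], seed=3,
        )
        assert len(res.selected) == 1

    def test_deterministic_given_data_and_seed(self):
        cohort = generate_cohort(_selection_config(n=800, seed=8))
        args = (
            cohort.phenotypes["ln_marker"],
            cohort.genotypes,
            cohort.phenotypes[["age", "sex"]],
        )
        r1 = stepwise_cv_select(*args, seed=5)
        r2 = stepwise_cv_select(*args, seed=5)
        assert r1.selected == r2.selected
        assert r1.cv_press == r2.cv_press


class TestGenotypeScore:
    def test_published_style_weighting(self):
        """betas (0.544, -0.120), doses (1, 2) -> 1 + (-0.120/0.544)*2."""
        doses = pd.DataFrame({"lead": [1], "second": [2]})
        sd, score = build_genotype_score([("lead", 0.544), ("second", -0.120)], doses)
        assert sd.terms[0] == ("lead", 1.0)
        assert score.iloc[0] == pytest.approx(1 + (-0.120 / 0.544) * 2, abs=1e-10)
        assert score.iloc[0] == pytest.approx(0.5588, abs=1e-4)
        assert sd.reference_beta == 0.544

    def test_single_term_score_is_dose(self):
        doses = pd.DataFrame({"s": [0, 1, 2]})
        _, score = build_genotype_score([("s", 0.3)], doses)
        assert score.tolist() == [0.0, 1.0, 2.0]

    def test_all_zero_doses_zero_score(self):
        doses = pd.DataFrame({"a": [0, 0], "b": [0, 0]})
        _, score = build_genotype_score([("a", 0.5), ("b", 0.2)], doses)
        assert (score == 0).all()

    def test_zero_reference_beta_rejected(self):
        with pytest.raises(DegenerateScoreError):
            build_genotype_score([("a", 0.0)], pd.DataFrame({"a": [1]}))


def test_additive_beta_between_null_and_rare_hom(causal_cohort):
    """With dose-monotone effects, the additive slope is bracketed by zero
    and the rare-homozygote contrast (sign-consistent)."""
    y = causal_cohort.phenotypes["ln_marker"]
    adj = causal_cohort.phenotypes[["age", "sex"]]
    d = causal_cohort.genotypes["snp1"]
    add = fit_marker_regression(y, code_genotypes(d, "additive"), adj)["snp1_additive"]
    gen = fit_marker_regression(y, code_genotypes(d, "genotypic"), adj)
    hom = gen["snp1_rarehom"]
    assert 0 < add.beta < hom.beta
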