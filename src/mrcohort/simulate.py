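"""Synthetic secondary-prevention cohorts with known causal structure.

Generates genotype, phenotype and survival tables with the statistical
structure the Mendelian-randomization analysis assumes: Hardy-Weinberg
genotypes, a log-normal serum marker with additive per-allele effects, and
exponential proportional-hazards event times with administrative censoring
and dropout. Three named scenarios (causal, confounded, null) make the
design's discriminating predictions directly testable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .config import ParameterError, SimulationConfig

# independent child streams per generation stage, all derived from the
# single master seed so a cohort is reproducible from (config, seed) alone
_STREAM_GENOTYPES = 1
_STREAM_COVARIATES = 2
_STREAM_MARKER = 3
_STREAM_SURVIVAL = 4


class AlignmentError(ValueError):
    """Row counts of genotype / covariate / marker inputs disagree."""


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(config.seed), stream]))


@dataclass
class Cohort:
    """One simulated cohort plus its hidden generative state.

    ``genotypes``, ``phenotypes`` and ``survival`` are the tables the
    analysis stages see; ``confounder`` is the latent variable, retained
    only for diagnostics and never written to disk.
    """

    genotypes: pd.DataFrame   # subject_id index, one 0/1/2 column per SNP
    phenotypes: pd.DataFrame  # age, sex, marker_conc, ln_marker
    survival: pd.DataFrame    # time_years, event
    confounder: np.ndarray
    config: SimulationConfig


def generate_genotypes(config: SimulationConfig) -> pd.DataFrame:
    """Draw allele-dose (0/1/2) genotypes independently per SNP under HWE.

    Each dose is the sum of two independent Bernoulli(maf) allele draws, so
    genotype frequencies are exactly Hardy-Weinberg (p^2, 2pq, q^2) in
    expectation. Deterministic given the config seed.
    """
    rng = _rng(config, _STREAM_GENOTYPES)
    n = config.n_subjects
    cols = {}
    for snp in config.snps:
        alleles = rng.random((n, 2)) < snp.maf
        cols[snp.snp_id] = alleles.sum(axis=1).astype(np.int64)
    idx = pd.Index([f"S{i:06d}" for i in range(n)], name="subject_id")
    return pd.DataFrame(cols, index=idx)


def generate_covariates(config: SimulationConfig) -> tuple[pd.DataFrame, np.ndarray]:
    """Age (truncated normal 61+/-8 on [30, 70]), sex (15% female), and the
    latent standard-normal confounder."""
    rng = _rng(config, _STREAM_COVARIATES)
    n = config.n_subjects
    a, b = (30 - 61) / 8, (70 - 61) / 8
    age = stats.truncnorm.rvs(a, b, loc=61, scale=8, size=n, random_state=rng)
    sex = (rng.random(n) < 0.15).astype(np.int64)  # 1 = female
    confounder = rng.standard_normal(n)
    idx = pd.Index([f"S{i:06d}" for i in range(n)], name="subject_id")
    cov = pd.DataFrame({"age": age, "sex": sex}, index=idx)
    return cov, confounder


def generate_marker(
    genotypes: pd.DataFrame,
    covariates: pd.DataFrame,
    config: SimulationConfig,
    confounder: np.ndarray | None = None,
) -> pd.Series:
    """Log-normal serum marker with additive per-allele effects.

    ln(marker) = marker_base + sum_k effect_k * dose_k
                 + age_effect*(age-60) + sex_effect*female
                 + confounder_effect_marker*U + N(0, marker_sd).
    """
    if len(genotypes) != len(covariates):
        raise AlignmentError(
            f"genotypes ({len(genotypes)} rows) and covariates "
            f"({len(covariates)} rows) are not row-aligned"
        )
    rng = _rng(config, _STREAM_MARKER)
    n = len(genotypes)
    ln_m = np.full(n, config.marker_base, dtype=float)
    for snp in config.snps:
        ln_m += snp.per_allele_log_effect * genotypes[snp.snp_id].to_numpy(float)
    ln_m += config.age_effect * (covariates["age"].to_numpy(float) - 60.0)
    ln_m += config.sex_effect * covariates["sex"].to_numpy(float)
    if confounder is not None:
        ln_m += config.confounder_effect_marker * np.asarray(confounder, float)
    if config.marker_sd > 0:
        ln_m += rng.normal(0.0, config.marker_sd, size=n)
    return pd.Series(np.exp(ln_m), index=genotypes.index, name="marker_conc")


def generate_survival(
    marker: pd.Series,
    config: SimulationConfig,
    confounder: np.ndarray | None = None,
) -> pd.DataFrame:
    """Exponential event times under proportional hazards with censoring.

    Hazard per subject:
    ``baseline_hazard * exp(beta_marker_hazard*ln(marker)
    + confounder_effect_hazard*U)``; observed time is the minimum of the
    event time, admin censoring at ``admin_censor_years`` and exponential
    dropout; event=1 iff the event time is strictly smallest.
    """
    m = marker.to_numpy(float)
    if np.any(m <= 0):
        raise ParameterError("marker values must be strictly positive")
    rng = _rng(config, _STREAM_SURVIVAL)
    n = len(m)
    log_hazard = np.log(config.baseline_hazard) if config.baseline_hazard > 0 else -np.inf
    eta = config.beta_marker_hazard * np.log(m)
    if confounder is not None:
        eta = eta + config.confounder_effect_hazard * np.asarray(confounder, float)
    hazard = np.exp(log_hazard + eta)
    t_event = np.where(
        hazard > 0,
        rng.exponential(1.0, size=n) / np.maximum(hazard, 1e-300),
        np.inf,
    )
    if config.dropout_rate > 0:
        t_drop = rng.exponential(1.0 / config.dropout_rate, size=n)
    else:
        t_drop = np.full(n, np.inf)
    t_cens = np.minimum(t_drop, config.admin_censor_years)
    time = np.minimum(t_event, t_cens)
    event = (t_event < t_cens).astype(np.int64)
    # guard against zero durations (measure-zero but breaks survival fitters)
    time = np.maximum(time, 1e-9)
    return pd.DataFrame({"time_years": time, "event": event}, index=marker.index)


def generate_cohort(config: SimulationConfig) -> Cohort:
    """Full cohort: genotypes, covariates, marker and survival records."""
    geno = generate_genotypes(config)
    cov, confounder = generate_covariates(config)
    marker = generate_marker(geno, cov, config, confounder)
    surv = generate_survival(marker, config, confounder)
    pheno = cov.copy()
    pheno["marker_conc"] = marker
    pheno["ln_marker"] = np.log(marker)
    return Cohort(geno, pheno, surv, confounder, config)
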