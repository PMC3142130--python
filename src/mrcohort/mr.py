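"""Mendelian-randomization engine: expected-under-causality hazard ratios.

Under no confounding of the genotype-disease relationship, a genotype that
shifts ln(marker) by beta_g->m should shift the log hazard by
beta_g->d = beta_g->m * beta_m->d, so the expected hazard ratio is
exp(beta_g->m * beta_m->d). Confidence intervals for the expected HR are
propagated by Monte Carlo: both stage coefficients are drawn independently
from normal distributions around their point estimates with their standard
errors, and the 2.5th/97.5th percentiles of the exponentiated products are
taken as the empirical 95% interval.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .marker import Z95, EffectEstimate, pct_to_beta
from .survival import HazardEstimate

N_DRAWS_DEFAULT = 1_000_000


def expected_hr(beta_gm: float, beta_md: float) -> float:
    """Expected hazard ratio under causality: exp(beta_g->m * beta_m->d)."""
    if not (np.isfinite(beta_gm) and np.isfinite(beta_md)):
        raise ValueError("stage coefficients must be finite")
    return float(np.exp(beta_gm * beta_md))


def mc_ci(
    mean_gm: float,
    se_gm: float,
    mean_md: float,
    se_md: float,
    n_draws: int = N_DRAWS_DEFAULT,
    seed: int = 0,
    correlation: float = 0.0,
) -> tuple[float, float]:
    """Monte-Carlo 95% CI of the expected HR from the coefficient product.

    Draws ``n_draws`` independent normal pairs (optionally correlated via
    ``correlation``; the default 0 reproduces the standard independent-draw
    propagation even though both stages come from one cohort), forms
    exp(product) per pair, and returns the empirical 2.5th and 97.5th
    percentiles (linear-interpolation definition). Deterministic given seed.
    """
    if se_gm < 0 or se_md < 0:
        raise ValueError("standard errors must be non-negative")
    if not -1.0 <= correlation <= 1.0:
        raise ValueError("correlation must lie in [-1, 1]")
    rng = np.random.default_rng(seed)
    z1 = rng.standard_normal(n_draws)
    z2 = rng.standard_normal(n_draws)
    if correlation != 0.0:
        z2 = correlation * z1 + np.sqrt(1 - correlation**2) * z2
    gm = mean_gm + se_gm * z1
    md = mean_md + se_md * z2
    hr = np.exp(gm * md)
    low, high = np.percentile(hr, [2.5, 97.5])
    return float(low), float(high)


def se_from_ci(ci_low: float, ci_high: float, scale: str = "hr") -> float:
    """Back-derive the log-scale SE from a printed symmetric Wald 95% CI.

    ``scale='hr'`` takes hazard-ratio bounds directly; ``scale='pct'``
    first converts percent changes to geometric-mean ratios (1 + delta/100).
    se = (ln(high) - ln(low)) / (2 * 1.96).
    """
    if scale == "pct":
        ci_low, ci_high = 1.0 + ci_low / 100.0, 1.0 + ci_high / 100.0
    elif scale != "hr":
        raise ValueError(f"unknown scale {scale!r}")
    if not (0 < ci_low < ci_high):
        raise ValueError("CI bounds must be positive and ordered")
    return float((np.log(ci_high) - np.log(ci_low)) / (2 * Z95))


@dataclass
class MrResult:
    """Observed vs expected-under-causality comparison for one instrument."""

    snp_id: str
    coding: str  # additive | het | rare_hom | score
    beta_gm: EffectEstimate
    beta_md: HazardEstimate
    hr_expected: float
    mc_ci_low: float
    mc_ci_high: float
    hr_observed: float | None = None
    obs_ci_low: float | None = None
    obs_ci_high: float | None = None
    n_draws: int = N_DRAWS_DEFAULT
    seed: int = 0

    @property
    def beta_gd_expected(self) -> float:
        return self.beta_gm.beta * self.beta_md.log_hr

    @property
    def consistent(self) -> bool | None:
        """Expected point estimate inside the observed CI."""
        if self.hr_observed is None:
            return None
        return bool(self.obs_ci_low <= self.hr_expected <= self.obs_ci_high)


def mr_result(
    snp_id: str,
    coding: str,
    beta_gm: EffectEstimate,
    beta_md: HazardEstimate,
    observed: HazardEstimate | None = None,
    n_draws: int = N_DRAWS_DEFAULT,
    seed: int = 0,
    correlation: float = 0.0,
) -> MrResult:
    """Assemble one MR comparison: expected HR, MC CI, observed HR."""
    hr_exp = expected_hr(beta_gm.beta, beta_md.log_hr)
    low, high = mc_ci(
        beta_gm.beta, beta_gm.se, beta_md.log_hr, beta_md.se,
        n_draws=n_draws, seed=seed, correlation=correlation,
    )
    kwargs = {}
    if observed is not None:
        kwargs = dict(
            hr_observed=observed.hr,
            obs_ci_low=observed.ci_low,
            obs_ci_high=observed.ci_high,
        )
    return MrResult(
        snp_id=snp_id, coding=coding, beta_gm=beta_gm, beta_md=beta_md,
        hr_expected=hr_exp, mc_ci_low=low, mc_ci_high=high,
        n_draws=n_draws, seed=seed, **kwargs,
    )


def stage_from_printed(
    point: float, ci_low: float, ci_high: float, scale: str, term: str = ""
) -> tuple[float, float]:
    """(log-scale beta, SE) from a printed point estimate and 95% CI.

    ``scale='pct'`` for percent changes in geometric mean, ``'hr'`` for
    hazard ratios. This is how the expected-HR table is regenerated from
    published coefficients alone.
    """
    if scale == "pct":
        beta = pct_to_beta(point)
    elif scale == "hr":
        if point <= 0:
            raise ValueError("hazard ratio must be positive")
        beta = float(np.log(point))
    else:
        raise ValueError(f"unknown scale {scale!r}")
    return beta, se_from_ci(ci_low, ci_high, scale)


def compare_observed_expected(results: list[MrResult]) -> pd.DataFrame:
    """Join observed and expected HRs with a consistency flag per row."""
    rows = []
    for r in results:
        log_obs = np.log(r.hr_observed) if r.hr_observed else np.nan
        log_exp = np.log(r.hr_expected) if r.hr_expected != 1.0 else np.nan
        rows.append(
            {
                "snp_id": r.snp_id,
                "coding": r.coding,
                "hr_observed": r.hr_observed,
                "obs_ci_low": r.obs_ci_low,
                "obs_ci_high": r.obs_ci_high,
                "hr_expected": r.hr_expected,
                "exp_ci_low": r.mc_ci_low,
                "exp_ci_high": r.mc_ci_high,
                "log_hr_ratio": (
                    log_obs / log_exp if np.isfinite(log_obs) and np.isfinite(log_exp) else np.nan
                ),
                "consistent": r.consistent,
            }
        )
    return pd.DataFrame(rows)
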