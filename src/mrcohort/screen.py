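"""Genotype-covariate confounding screen.

The Mendelian-randomization design assumes the genotype-disease
relationship is unconfounded. This module tests every SNP against every
candidate covariate — Kruskal-Wallis for continuous variables, Pearson
chi-square for categorical ones, genotype always an unordered three-level
factor — and summarizes the count of nominal findings against the binomial
expectation under a global null. No multiplicity adjustment is applied;
the summary reports the null expectation instead.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .marker import kruskal_wallis

log = logging.getLogger(__name__)


class DegenerateTableError(ValueError):
    """Contingency table collapses below 2x2 after dropping empty levels."""


def chi2_independence(
    genotype: pd.Series, covariate: pd.Series
) -> tuple[float, float]:
    """Pearson chi-square test of genotype x categorical-covariate
    independence, no continuity correction, df=(r-1)(c-1)."""
    df = pd.DataFrame({"g": genotype, "c": covariate}).dropna()
    table = pd.crosstab(df["g"], df["c"])
    table = table.loc[(table.sum(axis=1) > 0), (table.sum(axis=0) > 0)]
    if table.shape[0] < 2 or table.shape[1] < 2:
        raise DegenerateTableError(
            "need >= 2 genotype and >= 2 covariate levels after dropping empties"
        )
    chi2, p, _, _ = stats.chi2_contingency(table.to_numpy(), correction=False)
    return float(chi2), float(p)


def spearman(x, y) -> float:
    """Tie-aware Spearman rank correlation (Pearson on mid-ranks)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) < 3 or len(x) != len(y):
        raise ValueError("need >= 3 paired finite observations")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("inputs must be finite")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("Spearman correlation undefined for a constant vector")
    rho = stats.spearmanr(x, y).statistic
    return float(rho)


@dataclass
class ScreenSummary:
    n_tests: int
    n_skipped: int
    n_significant: int          # p < 0.05
    expected_under_null: float  # 0.05 * n_tests
    null_interval: tuple[int, int]  # central 95% binomial interval


def screen(
    doses: pd.DataFrame,
    covariates: pd.DataFrame,
    type_map: dict[str, str],
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, ScreenSummary]:
    """Test every SNP against every covariate.

    ``type_map`` marks each covariate ``'continuous'`` (Kruskal-Wallis of
    the covariate across genotype groups) or ``'categorical'`` (chi-square
    of the genotype x covariate table). Single-level covariates are skipped
    with a warning and counted as untested, so
    |results| + |skipped| = n_snps * n_covariates.
    """
    missing = set(covariates.columns) - set(type_map)
    if missing:
        raise ValueError(f"type_map does not cover covariates: {sorted(missing)}")
    rows, n_skipped = [], 0
    for snp in doses.columns:
        g = doses[snp]
        for cov in covariates.columns:
            c = covariates[cov]
            if c.dropna().nunique() < 2:
                log.warning("covariate %s has a single level; skipped", cov)
                n_skipped += 1
                continue
            kind = type_map[cov]
            try:
                if kind == "continuous":
                    stat, p = kruskal_wallis(c, g)
                    test = "kruskal_wallis"
                elif kind == "categorical":
                    stat, p = chi2_independence(g, c)
                    test = "chi2"
                else:
                    raise ValueError(f"unknown covariate type {kind!r} for {cov}")
            except (DegenerateTableError, ValueError) as exc:
                log.warning("screen test %s x %s skipped: %s", snp, cov, exc)
                n_skipped += 1
                continue
            rows.append(
                {"snp_id": snp, "covariate": cov, "test": test,
                 "statistic": stat, "p": p}
            )
    results = pd.DataFrame(rows)
    n_tests = len(results)
    n_sig = int((results["p"] < alpha).sum()) if n_tests else 0
    lo, hi = stats.binom.interval(0.95, n_tests, alpha) if n_tests else (0, 0)
    summary = ScreenSummary(
        n_tests=n_tests,
        n_skipped=n_skipped,
        n_significant=n_sig,
        expected_under_null=alpha * n_tests,
        null_interval=(int(lo), int(hi)),
    )
    return results, summary
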