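"""Genotype -> marker stage: linear models on the log-scale marker.

Age/sex-adjusted OLS on ln(marker) per SNP coding, percent-change
conversion of log-scale coefficients (geometric-mean ratios), one-way
ANOVA R^2, Kruskal-Wallis tests on untransformed concentrations, forward
stepwise multi-locus selection scored by 10-fold cross-validated PRESS,
and the weighted genotype score built from multi-locus coefficients.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .qc import code_genotypes

log = logging.getLogger(__name__)

Z95 = 1.96  # Wald multiplier; CIs are symmetric on the log scale


class CollinearityError(ValueError):
    """The design matrix is rank deficient."""


class DegenerateScoreError(ValueError):
    """The genotype-score reference coefficient is zero."""


@dataclass
class EffectEstimate:
    """A regression coefficient on a stated scale with Wald inference."""

    term: str
    beta: float
    se: float
    p: float
    scale_tag: str = "log_marker"  # or "log_hazard"

    @property
    def ci_low(self) -> float:
        return self.beta - Z95 * self.se

    @property
    def ci_high(self) -> float:
        return self.beta + Z95 * self.se


@dataclass
class PercentChange:
    """Percent change in the geometric mean per coded unit."""

    delta_pct: float
    ci_low_pct: float
    ci_high_pct: float


def beta_to_pct(beta: float, se: float = 0.0) -> PercentChange:
    """Log-scale coefficient -> percent change in geometric mean.

    delta% = 100*(exp(beta)-1); the CI bounds transform the same way from
    the symmetric log-scale Wald interval.
    """
    return PercentChange(
        100.0 * (np.exp(beta) - 1.0),
        100.0 * (np.exp(beta - Z95 * se) - 1.0),
        100.0 * (np.exp(beta + Z95 * se) - 1.0),
    )


def pct_to_beta(delta_pct: float) -> float:
    """Inverse of :func:`beta_to_pct`: beta = ln(1 + delta%/100)."""
    if delta_pct <= -100.0:
        raise ValueError("percent change must exceed -100")
    return float(np.log1p(delta_pct / 100.0))


def _check_rank(X: pd.DataFrame) -> None:
    arr = X.to_numpy(float)
    rank = np.linalg.matrix_rank(arr)
    if rank < arr.shape[1]:
        # identify columns that do not raise the rank when added greedily
        bad, kept = [], []
        for col in X.columns:
            cand = X[kept + [col]].to_numpy(float)
            if np.linalg.matrix_rank(cand) == len(kept) + 1:
                kept.append(col)
            else:
                bad.append(col)
        raise CollinearityError(f"design is rank deficient; offending columns: {bad}")


def fit_marker_regression(
    ln_marker: pd.Series,
    design: pd.DataFrame,
    adjust: pd.DataFrame | None = None,
) -> dict[str, EffectEstimate]:
    """OLS of ln(marker) on SNP design columns, adjusted for covariates.

    Complete cases only. Returns Wald estimates for the design terms; the
    intercept and adjustment coefficients are fitted but not reported.
    """
    frames = [design] if adjust is None else [design, adjust]
    X = pd.concat(frames, axis=1)
    data = pd.concat([ln_marker.rename("_y"), X], axis=1).dropna()
    if data.empty:
        raise ValueError("no complete cases")
    Xc = sm.add_constant(data[X.columns.tolist()].astype(float), has_constant="add")
    _check_rank(Xc)
    fit = sm.OLS(data["_y"].astype(float), Xc).fit()
    return {
        term: EffectEstimate(
            term=term,
            beta=float(fit.params[term]),
            se=float(fit.bse[term]),
            p=float(fit.pvalues[term]),
            scale_tag="log_marker",
        )
        for term in design.columns
    }


def anova_r2(ln_marker: pd.Series, genotype: pd.Series) -> float:
    """One-way ANOVA R^2: between-genotype-group SS over total SS."""
    df = pd.DataFrame({"y": ln_marker, "g": genotype}).dropna()
    groups = df.groupby("g")["y"]
    if groups.ngroups < 2:
        raise ValueError("R^2 undefined with fewer than 2 genotype groups")
    grand = df["y"].mean()
    ss_total = ((df["y"] - grand) ** 2).sum()
    if ss_total == 0:
        raise ValueError("zero total variance")
    ss_between = (groups.size() * (groups.mean() - grand) ** 2).sum()
    return float(ss_between / ss_total)


def kruskal_wallis(values: pd.Series, groups: pd.Series) -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H across genotype groups.

    Applied to untransformed marker values (rank-based, so any monotone
    transform gives the same H). All-tied input returns (0, 1) by
    convention, with a log record.
    """
    df = pd.DataFrame({"v": values, "g": groups}).dropna()
    samples = [grp["v"].to_numpy(float) for _, grp in df.groupby("g")]
    samples = [s for s in samples if len(s) > 0]
    if len(samples) < 2:
        raise ValueError("need >= 2 non-empty groups")
    if df["v"].nunique() == 1:
        log.info("Kruskal-Wallis: all values tied; returning H=0, p=1")
        return 0.0, 1.0
    h, p = stats.kruskal(*samples)
    return float(h), float(p)


def _effect_f_test(fit_full, fit_reduced) -> float:
    """p-value of the nested F-test for the added effect columns."""
    df_num = fit_reduced.df_resid - fit_full.df_resid
    if df_num <= 0:
        return 1.0
    f = (fit_reduced.ssr - fit_full.ssr) / df_num / fit_full.mse_resid
    return float(stats.f.sf(max(f, 0.0), df_num, fit_full.df_resid))


@dataclass
class StepwiseResult:
    selected: list[str]
    coefficients: dict[str, EffectEstimate]
    cv_press: float
    path: list[tuple[frozenset, float]] = field(repr=False, default_factory=list)


def stepwise_cv_select(
    ln_marker: pd.Series,
    doses: pd.DataFrame,
    adjust: pd.DataFrame | None = None,
    coding: str = "additive",
    folds: int = 10,
    seed: int = 0,
    enter_p: float = 0.4,
    stay_p: float = 0.6,
    max_steps: int = 50,
) -> StepwiseResult:
    """Permissive forward stepwise selection scored by CV-PRESS.

    SNP effects enter at p < ``enter_p`` and are pruned at p > ``stay_p``
    (nested F-tests, so genotypic effects are judged jointly on their two
    columns). Every model visited on the path is scored by ``folds``-fold
    cross-validated PRESS with a seed-fixed fold assignment, and the
    path model with the smallest PRESS is refitted on the full data.
    """
    if doses.shape[1] == 0:
        raise ValueError("empty candidate SNP set")
    # materialize design columns per SNP effect
    effect_cols: dict[str, list[str]] = {}
    pieces = []
    for snp in doses.columns:
        coded = code_genotypes(doses[snp], coding)
        effect_cols[snp] = list(coded.columns)
        pieces.append(coded)
    X_all = pd.concat(pieces, axis=1)
    frames = [ln_marker.rename("_y"), X_all]
    if adjust is not None:
        frames.append(adjust)
    data = pd.concat(frames, axis=1).dropna()
    y = data["_y"].to_numpy(float)
    adj_cols = list(adjust.columns) if adjust is not None else []

    def design(snps: list[str]) -> pd.DataFrame:
        cols = [c for s in snps for c in effect_cols[s]] + adj_cols
        X = data[cols].astype(float) if cols else pd.DataFrame(index=data.index)
        return sm.add_constant(X, has_constant="add")

    def ols(snps: list[str]):
        return sm.OLS(y, design(snps)).fit()

    current: list[str] = []
    visited: list[list[str]] = [[]]
    fit_cur = ols(current)
    for _ in range(max_steps):
        changed = False
        # forward: best candidate by nested-F p
        best_p, best_snp, best_fit = np.inf, None, None
        for snp in doses.columns:
            if snp in current:
                continue
            Xc = design(current + [snp])
            if np.linalg.matrix_rank(Xc.to_numpy(float)) < Xc.shape[1]:
                continue  # collinearity guard: adding this SNP adds no rank
            fit_new = sm.OLS(y, Xc).fit()
            p = _effect_f_test(fit_new, fit_cur)
            if p < best_p:
                best_p, best_snp, best_fit = p, snp, fit_new
        if best_snp is not None and best_p < enter_p:
            current = current + [best_snp]
            fit_cur = best_fit
            visited.append(list(current))
            changed = True
        # backward: prune effects whose removal p exceeds stay_p
        while len(current) > 0:
            worst_p, worst_snp = -np.inf, None
            for snp in current:
                reduced = [s for s in current if s != snp]
                p = _effect_f_test(fit_cur, ols(reduced))
                if p > worst_p:
                    worst_p, worst_snp = p, snp
            if worst_p > stay_p:
                current = [s for s in current if s != worst_snp]
                fit_cur = ols(current)
                visited.append(list(current))
                changed = True
            else:
                break
        if not changed:
            break

    # score each distinct visited model by CV-PRESS (fold split fixed once)
    fold_rng = np.random.default_rng(seed)
    n = len(y)
    order = fold_rng.permutation(n)
    fold_of = np.empty(n, dtype=int)
    fold_of[order] = np.arange(n) % folds

    def press_of(snps: list[str]) -> float:
        X = design(snps).to_numpy(float)
        press = 0.0
        for k in range(folds):
            test = fold_of == k
            beta, *_ = np.linalg.lstsq(X[~test], y[~test], rcond=None)
            resid = y[test] - X[test] @ beta
            press += float(resid @ resid)
        return press

    seen: dict[frozenset, list[str]] = {}
    for m in visited:
        seen.setdefault(frozenset(m), m)
    path = [(key, press_of(m)) for key, m in seen.items()]
    best_key, best_press = min(path, key=lambda t: t[1])
    best_model = seen[best_key]

    coef: dict[str, EffectEstimate] = {}
    if best_model:
        cols = [c for s in best_model for c in effect_cols[s]]
        coef = fit_marker_regression(
            data["_y"], data[cols].astype(float),
            data[adj_cols].astype(float) if adj_cols else None,
        )
    return StepwiseResult(best_model, coef, best_press, path)


@dataclass
class ScoreDefinition:
    """Weighted allele score: sum of weight_i * dose_i.

    Weights are multi-locus betas divided by the reference beta (the
    largest in magnitude), so the reference SNP has weight 1 and
    ``reference_beta`` is the score's expected ln-marker effect per unit.
    """

    terms: list[tuple[str, float]]
    reference_beta: float


def build_genotype_score(
    coefficients: list[tuple[str, float]], doses: pd.DataFrame
) -> tuple[ScoreDefinition, pd.Series]:
    """Weighted genotype score from multi-locus regression coefficients."""
    if not coefficients:
        raise ValueError("need at least one score term")
    ref_snp, ref_beta = max(coefficients, key=lambda t: abs(t[1]))
    if ref_beta == 0:
        raise DegenerateScoreError("reference coefficient is zero")
    terms = [(ref_snp, 1.0)] + [
        (snp, beta / ref_beta) for snp, beta in coefficients if snp != ref_snp
    ]
    score = pd.Series(0.0, index=doses.index, name="genotype_score")
    for snp, w in terms:
        score = score + w * doses[snp].astype(float)
    return ScoreDefinition(terms, ref_beta), score


def snp_association_table(
    ln_marker: pd.Series,
    raw_marker: pd.Series,
    table_doses: pd.DataFrame,
    qc_records: pd.DataFrame,
    adjust: pd.DataFrame,
) -> pd.DataFrame:
    """Per-SNP association summary in the layout of a candidate-gene table.

    Columns: n, MAF, HWE p, one-way ANOVA R^2, Kruskal-Wallis p, and
    percent changes (with CIs) for heterozygote, rare-homozygote and
    additive codings, all age/sex adjusted on ln(marker).
    """
    rows = []
    for snp in table_doses.columns:
        d = table_doses[snp]
        try:
            r2 = anova_r2(ln_marker, d)
        except ValueError:
            r2 = np.nan
        try:
            _, kw_p = kruskal_wallis(raw_marker, d)
        except ValueError:
            kw_p = np.nan
        est_add = fit_marker_regression(ln_marker, code_genotypes(d, "additive"), adjust)
        add = next(iter(est_add.values()))
        row = {
            "snp_id": snp,
            "n": int(d.notna().sum()),
            "maf": qc_records.loc[snp, "maf"],
            "hwe_p": qc_records.loc[snp, "hwe_p"],
            "r_squared": r2,
            "kw_p": kw_p,
        }
        gen_design = code_genotypes(d, "genotypic")
        try:
            est_gen = fit_marker_regression(ln_marker, gen_design, adjust)
            for label, col in (("het", gen_design.columns[0]),
                               ("rare_hom", gen_design.columns[1])):
                e = est_gen[col]
                pc = beta_to_pct(e.beta, e.se)
                row[f"{label}_pct"] = pc.delta_pct
                row[f"{label}_pct_lo"] = pc.ci_low_pct
                row[f"{label}_pct_hi"] = pc.ci_high_pct
        except CollinearityError:
            for label in ("het", "rare_hom"):
                row[f"{label}_pct"] = row[f"{label}_pct_lo"] = row[f"{label}_pct_hi"] = np.nan
        pc = beta_to_pct(add.beta, add.se)
        row["additive_pct"] = pc.delta_pct
        row["additive_pct_lo"] = pc.ci_low_pct
        row["additive_pct_hi"] = pc.ci_high_pct
        row["additive_beta"] = add.beta
        row["additive_se"] = add.se
        rows.append(row)
    return pd.DataFrame(rows).set_index("snp_id")
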