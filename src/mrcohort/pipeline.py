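"""End-to-end orchestration: simulate/load -> QC -> marker models ->
survival -> Mendelian randomization -> confounder screen.

A run is fully determined by its :class:`RunConfig` (input tables or a
simulation config, thresholds, Monte-Carlo draws, master seed) and writes a
reproducible artifact set: per-stage TSV tables, a flat machine-readable
summary of every MR comparison, and a log recording seeds, thresholds and
exclusions.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io
from .config import SimulationConfig
from .marker import (
    EffectEstimate,
    build_genotype_score,
    fit_marker_regression,
    snp_association_table,
    stepwise_cv_select,
)
from .mr import MrResult, compare_observed_expected, mr_result, stage_from_printed
from .qc import GenotypeTable, code_genotypes, snp_qc
from .simulate import generate_cohort
from .survival import (
    HazardEstimate,
    NoEventsError,
    genotype_event_model,
    marker_event_model,
    score_event_model,
)

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """One pipeline run: exactly one of input paths or a simulation config."""

    genotypes_path: str | None = None
    phenotypes_path: str | None = None
    survival_path: str | None = None
    simulation: SimulationConfig | None = None
    hwe_alpha: float = 0.05
    mc_draws: int = 100_000
    master_seed: int = 0
    out_dir: str = "results"

    def __post_init__(self) -> None:
        have_paths = all(
            p is not None
            for p in (self.genotypes_path, self.phenotypes_path, self.survival_path)
        )
        if have_paths == (self.simulation is not None):
            raise ValueError(
                "provide exactly one of (input table paths, simulation config)"
            )
        if self.mc_draws < 1000:
            raise ValueError("mc_draws must be >= 1000")


@dataclass
class RunResult:
    qc: pd.DataFrame
    associations: pd.DataFrame
    observed_hrs: pd.DataFrame
    mr_results: list[MrResult]
    comparison: pd.DataFrame
    screen_results: pd.DataFrame
    screen_summary: object
    out_dir: Path = field(default=None)  # type: ignore[assignment]


def _load_inputs(cfg: RunConfig):
    if cfg.simulation is not None:
        cohort = generate_cohort(cfg.simulation)
        return GenotypeTable(cohort.genotypes), cohort.phenotypes, cohort.survival
    geno = io.read_genotypes(cfg.genotypes_path)
    pheno = io.read_phenotypes(cfg.phenotypes_path)
    surv = io.read_survival(cfg.survival_path)
    idx = io.check_alignment(geno.doses, pheno, surv)
    geno = GenotypeTable(geno.doses.loc[idx], geno.snp_meta)
    pheno = pheno.loc[idx].copy()
    if "ln_marker" not in pheno.columns:
        pheno["ln_marker"] = np.log(pheno["marker_conc"].astype(float))
    return geno, pheno, surv.loc[idx]


def run_pipeline(cfg: RunConfig) -> RunResult:
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log.info("pipeline start: seed=%d hwe_alpha=%g mc_draws=%d",
             cfg.master_seed, cfg.hwe_alpha, cfg.mc_draws)

    geno, pheno, surv = _load_inputs(cfg)
    adjust = pheno[["age", "sex"]].astype(float)
    ln_marker = pheno["ln_marker"]
    raw_marker = pheno["marker_conc"]

    # --- genotype QC -------------------------------------------------------
    qc_records = snp_qc(geno, cfg.hwe_alpha)
    qc_records.to_csv(out / "snp_qc.tsv", sep="\t", na_rep=io.NA_REP)
    excluded = list(qc_records.index[qc_records["excluded"]])
    log.info("HWE-excluded SNPs (alpha=%g): %s", cfg.hwe_alpha, excluded or "none")

    # --- genotype -> marker associations (all SNPs, incl. HWE-deviant) ----
    assoc = snp_association_table(ln_marker, raw_marker, geno.doses, qc_records, adjust)
    assoc.to_csv(out / "marker_associations.tsv", sep="\t", na_rep=io.NA_REP)

    # --- marker -> event model (beta_m->d) ---------------------------------
    beta_md = marker_event_model(surv, ln_marker, adjust)
    log.info("marker->event HR per unit ln(marker): %.3f (%.3f-%.3f)",
             beta_md.hr, beta_md.ci_low, beta_md.ci_high)

    # --- per-SNP observed HRs + MR comparisons ----------------------------
    keep = [s for s in geno.snp_ids if s not in excluded]
    obs_rows: list[dict] = []
    results: list[MrResult] = []
    for k, snp in enumerate(keep):
        doses = geno.doses[snp]
        try:
            add_obs = genotype_event_model(surv, doses, "additive", adjust, qc_records)
            gen_obs = genotype_event_model(surv, doses, "genotypic", adjust, qc_records)
        except NoEventsError as exc:
            log.warning("skipping %s in survival stage: %s", snp, exc)
            continue
        gm_add = fit_marker_regression(
            ln_marker, code_genotypes(doses, "additive"), adjust
        )[f"{snp}_additive"]
        gm_gen = fit_marker_regression(
            ln_marker, code_genotypes(doses, "genotypic"), adjust
        )
        stage_pairs = [
            ("additive", gm_add, add_obs[f"{snp}_additive"]),
            ("het", gm_gen[f"{snp}_het"], gen_obs[f"{snp}_het"]),
            ("rare_hom", gm_gen[f"{snp}_rarehom"], gen_obs[f"{snp}_rarehom"]),
        ]
        for j, (coding, gm, obs) in enumerate(stage_pairs):
            obs_rows.append(
                {"snp_id": snp, "coding": coding, "hr": obs.hr,
                 "ci_low": obs.ci_low, "ci_high": obs.ci_high, "p": obs.p}
            )
            results.append(
                mr_result(
                    snp, coding, gm, beta_md, observed=obs,
                    n_draws=cfg.mc_draws,
                    seed=int(np.random.SeedSequence(
                        [cfg.master_seed, 100 + 10 * k + j]).generate_state(1)[0] % (2**31)),
                )
            )

    # --- multi-locus model and weighted genotype score ---------------------
    if keep:
        sel = stepwise_cv_select(
            ln_marker, geno.doses[keep], adjust, coding="additive",
            seed=cfg.master_seed,
        )
        log.info("stepwise-selected SNPs: %s (CV-PRESS %.2f)", sel.selected, sel.cv_press)
        if sel.selected:
            coeffs = [
                (snp, sel.coefficients[f"{snp}_additive"].beta) for snp in sel.selected
            ]
            score_def, score = build_genotype_score(coeffs, geno.doses[sel.selected])
            ref_snp = score_def.terms[0][0]
            ref_est = sel.coefficients[f"{ref_snp}_additive"]
            try:
                score_obs = score_event_model(surv, score, adjust)
                results.append(
                    mr_result(
                        "score", "score",
                        EffectEstimate("score", score_def.reference_beta,
                                       ref_est.se, ref_est.p, "log_marker"),
                        beta_md, observed=score_obs,
                        n_draws=cfg.mc_draws,
                        seed=int(np.random.SeedSequence(
                            [cfg.master_seed, 999]).generate_state(1)[0] % (2**31)),
                    )
                )
            except NoEventsError as exc:
                log.warning("score survival model skipped: %s", exc)

    observed = pd.DataFrame(obs_rows)
    observed.to_csv(out / "observed_hrs.tsv", sep="\t", index=False, na_rep=io.NA_REP)
    comparison = compare_observed_expected(results)
    comparison.to_csv(out / "mr_comparison.tsv", sep="\t", index=False, na_rep=io.NA_REP)

    # --- confounder screen --------------------------------------------------
    from .screen import screen as run_screen

    type_map = {"age": "continuous", "sex": "categorical"}
    extra = [c for c in pheno.columns
             if c not in ("age", "sex", "marker_conc", "marker_act", "ln_marker")]
    for c in extra:
        type_map[c] = "categorical" if pheno[c].dropna().nunique() <= 5 else "continuous"
    scr, scr_summary = run_screen(geno.doses, pheno[list(type_map)], type_map)
    scr.to_csv(out / "screen.tsv", sep="\t", index=False, na_rep=io.NA_REP)
    log.info(
        "confounder screen: %d tests, %d with p<0.05 (null expectation %.1f)",
        scr_summary.n_tests, scr_summary.n_significant, scr_summary.expected_under_null,
    )

    # --- machine-readable summary ------------------------------------------
    summary = {
        "master_seed": cfg.master_seed,
        "hwe_alpha": cfg.hwe_alpha,
        "mc_draws": cfg.mc_draws,
        "hwe_excluded": excluded,
        "marker_event_hr": beta_md.hr,
        "marker_event_ci": [beta_md.ci_low, beta_md.ci_high],
        "mr": [
            {
                "snp_id": r.snp_id,
                "coding": r.coding,
                "beta_gm": r.beta_gm.beta,
                "beta_md": r.beta_md.log_hr,
                "hr_expected": r.hr_expected,
                "mc_ci": [r.mc_ci_low, r.mc_ci_high],
                "hr_observed": r.hr_observed,
                "obs_ci": [r.obs_ci_low, r.obs_ci_high],
                "consistent": r.consistent,
                "n_draws": r.n_draws,
                "seed": r.seed,
            }
            for r in results
        ],
        "screen": {
            "n_tests": scr_summary.n_tests,
            "n_significant": scr_summary.n_significant,
            "expected_under_null": scr_summary.expected_under_null,
        },
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    return RunResult(qc_records, assoc, observed, results, comparison,
                     scr, scr_summary, out)


def expected_table_from_printed(
    entries: list[dict],
    marker_hr: float,
    marker_hr_ci: tuple[float, float],
    n_draws: int = 1_000_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Regenerate an expected-HR table from published coefficients alone.

    Each entry needs ``label``, ``coding``, and either a percent change with
    its CI (``pct``, ``pct_lo``, ``pct_hi``) or a log-scale coefficient
    (``beta``, optional ``se``). ``marker_hr`` with its CI supplies the
    marker->event stage. No subject-level data are touched.
    """
    md_beta, md_se = stage_from_printed(marker_hr, *marker_hr_ci, scale="hr")
    beta_md = HazardEstimate("ln_marker", md_beta, md_se, np.nan)
    rows = []
    for i, e in enumerate(entries):
        if "pct" in e:
            gm_beta, gm_se = stage_from_printed(
                e["pct"], e["pct_lo"], e["pct_hi"], scale="pct"
            )
        else:
            gm_beta, gm_se = float(e["beta"]), float(e.get("se", 0.0))
        gm = EffectEstimate(e["label"], gm_beta, gm_se, np.nan, "log_marker")
        r = mr_result(
            e["label"], e["coding"], gm, beta_md,
            n_draws=n_draws,
            seed=int(np.random.SeedSequence([seed, i]).generate_state(1)[0] % (2**31)),
        )
        rows.append(
            {
                "label": e["label"],
                "coding": e["coding"],
                "hr_expected": round(r.hr_expected, 2),
                "ci_low": round(r.mc_ci_low, 2),
                "ci_high": round(r.mc_ci_high, 2),
            }
        )
    return pd.DataFrame(rows)
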