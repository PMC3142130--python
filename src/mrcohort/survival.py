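"""Marker -> event and genotype -> event Cox proportional-hazards stage.

Thin, contract-checked wrappers around the lifelines Cox partial-likelihood
fitter (Efron tie handling): the fully adjusted marker-event model whose
coefficient is the beta_m->d input to the Mendelian-randomization engine,
and the age/sex-adjusted per-SNP genotype-event models that provide the
observed hazard ratios.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter

from .marker import Z95
from .qc import HweExclusionError, code_genotypes


class NoEventsError(ValueError):
    """The survival data contain no events; the partial likelihood is flat."""


@dataclass
class HazardEstimate:
    """A Cox coefficient with hazard-ratio-scale Wald inference."""

    term: str
    log_hr: float
    se: float
    p: float

    @property
    def hr(self) -> float:
        return float(np.exp(self.log_hr))

    @property
    def ci_low(self) -> float:
        return float(np.exp(self.log_hr - Z95 * self.se))

    @property
    def ci_high(self) -> float:
        return float(np.exp(self.log_hr + Z95 * self.se))


def fit_cox(
    records: pd.DataFrame,
    design: pd.DataFrame,
    adjust: pd.DataFrame | None = None,
) -> dict[str, HazardEstimate]:
    """Cox proportional-hazards fit; one estimate per design column.

    ``records`` needs ``time_years`` and ``event`` columns. Complete cases
    only; Efron handling of tied event times; Wald CIs with z=1.96 on the
    log-hazard scale.
    """
    frames = [records[["time_years", "event"]], design]
    if adjust is not None:
        frames.append(adjust)
    data = pd.concat(frames, axis=1).dropna().astype(float)
    if data.empty:
        raise ValueError("no complete cases")
    if data["event"].sum() == 0:
        raise NoEventsError("no events observed; hazard model has no information")
    for col in design.columns:
        if data[col].nunique() <= 1:
            raise NoEventsError(f"design column {col!r} is constant on complete cases")
    cph = CoxPHFitter()
    cph.fit(data, duration_col="time_years", event_col="event")
    out = {}
    for term in design.columns:
        out[term] = HazardEstimate(
            term=term,
            log_hr=float(cph.params_[term]),
            se=float(cph.standard_errors_[term]),
            p=float(cph.summary.loc[term, "p"]),
        )
    return out


def marker_event_model(
    records: pd.DataFrame,
    ln_marker: pd.Series,
    covariates: pd.DataFrame | None = None,
) -> HazardEstimate:
    """Adjusted HR per unit ln(marker) — the beta_m->d stage of the MR.

    ``covariates`` stands in for the full clinical adjustment set; on
    synthetic cohorts this is age and sex.
    """
    design = ln_marker.rename("ln_marker").to_frame()
    return fit_cox(records, design, covariates)["ln_marker"]


def genotype_event_model(
    records: pd.DataFrame,
    doses: pd.Series,
    scheme: str = "additive",
    covariates: pd.DataFrame | None = None,
    qc_records: pd.DataFrame | None = None,
) -> dict[str, HazardEstimate]:
    """Observed genotype-event HRs, additive or genotypic coding.

    Reference is the common homozygote. SNPs flagged by the
    Hardy-Weinberg exclusion rule are rejected outright rather than
    silently skipped.
    """
    name = doses.name or "snp"
    if qc_records is not None and name in qc_records.index:
        if bool(qc_records.loc[name, "excluded"]):
            raise HweExclusionError(
                f"{name} is excluded from survival analyses by the "
                f"Hardy-Weinberg equilibrium rule (hwe_p < alpha)"
            )
    design = code_genotypes(doses, scheme)
    return fit_cox(records, design, covariates)


def score_event_model(
    records: pd.DataFrame,
    score: pd.Series,
    covariates: pd.DataFrame | None = None,
) -> HazardEstimate:
    """Observed HR per unit of the weighted genotype score."""
    design = score.rename("genotype_score").to_frame()
    return fit_cox(records, design, covariates)["genotype_score"]
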