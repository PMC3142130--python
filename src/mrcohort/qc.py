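"""Genotype ingestion, coding and pre-association quality control.

Covers the QC a candidate-gene association study applies before modelling:
minor allele frequency, a Hardy-Weinberg equilibrium chi-square test,
exclusion of HWE-deviant loci from survival and score analyses, and
pairwise linkage disequilibrium (D', r^2) estimated from unphased dose data
by a two-locus EM algorithm.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

HWE_ALPHA_DEFAULT = 0.05
MIN_HWE_N = 10


class DegenerateInputError(ValueError):
    """Genotype counts are empty or otherwise uninformative."""


class MonomorphicSnpError(ValueError):
    """The locus has a single allele; the requested statistic is undefined."""


class HweExclusionError(ValueError):
    """A Hardy-Weinberg-excluded SNP was requested in a downstream analysis."""


@dataclass
class GenotypeTable:
    """Subjects x SNPs allele-dose matrix with allele metadata.

    ``doses`` holds the count of rare alleles (0/1/2) as a nullable-integer
    frame (``pd.NA`` for failed calls); ``snp_meta`` maps each SNP id to its
    common and rare allele labels. Per-SNP missingness is a first-class
    feature: every QC statistic is computed on called genotypes only.
    """

    doses: pd.DataFrame
    snp_meta: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.doses.index.has_duplicates:
            raise DegenerateInputError("duplicate subject ids in genotype table")
        self.doses = self.doses.astype("Int64")
        bad = ~(self.doses.isin([0, 1, 2]) | self.doses.isna())
        if bad.to_numpy().any():
            raise DegenerateInputError("dose values must be 0, 1, 2 or missing")
        if self.snp_meta is None:
            self.snp_meta = pd.DataFrame(
                {"common_allele": "A", "rare_allele": "a"},
                index=pd.Index(self.doses.columns, name="snp_id"),
            )

    @property
    def snp_ids(self) -> list[str]:
        return list(self.doses.columns)

    def genotype_counts(self, snp_id: str) -> tuple[int, int, int]:
        """(n common-hom, n het, n rare-hom) among called genotypes."""
        d = self.doses[snp_id].dropna()
        return (int((d == 0).sum()), int((d == 1).sum()), int((d == 2).sum()))

    def call_rate(self, snp_id: str) -> float:
        return float(self.doses[snp_id].notna().mean())


def compute_maf(counts: tuple[int, int, int]) -> float:
    """Minor allele frequency from genotype counts (n_AA, n_Aa, n_aa).

    If the nominal rare allele turns out to be the major one (frequency
    above 0.5), alleles are re-labelled so the returned frequency is the
    minor one; a warning records the flip.
    """
    n_aa_, n_het, n_rr = counts
    if any(c < 0 for c in counts):
        raise DegenerateInputError("negative genotype counts")
    total = sum(counts)
    if total == 0:
        raise DegenerateInputError("all genotype counts are zero")
    freq = (n_het + 2 * n_rr) / (2 * total)
    if freq > 0.5:
        warnings.warn(
            "nominal rare allele has frequency > 0.5; alleles re-labelled so "
            "the reported MAF is the minor allele frequency",
            stacklevel=2,
        )
        freq = 1.0 - freq
    return freq


def hwe_chi2_test(counts: tuple[int, int, int]) -> tuple[float, float]:
    """Pearson chi-square test of Hardy-Weinberg proportions, 1 df.

    Expected counts use the sample allele frequency; no continuity
    correction. Raises for monomorphic loci (the test is undefined, not
    p=1) and for fewer than ``MIN_HWE_N`` genotypes.
    """
    n_aa_, n_het, n_rr = counts
    total = sum(counts)
    if total < MIN_HWE_N:
        raise DegenerateInputError(
            f"need >= {MIN_HWE_N} genotypes for the HWE test, got {total}"
        )
    q = (n_het + 2 * n_rr) / (2 * total)  # rare-allele frequency
    if q == 0.0 or q == 1.0:
        raise MonomorphicSnpError("HWE test undefined for a monomorphic SNP")
    p = 1.0 - q
    expected = np.array([p * p, 2 * p * q, q * q]) * total
    observed = np.array(counts, dtype=float)
    chi2 = float(((observed - expected) ** 2 / expected).sum())
    pval = float(stats.chi2.sf(chi2, df=1))
    return chi2, pval


def snp_qc(
    table: GenotypeTable, hwe_alpha: float = HWE_ALPHA_DEFAULT
) -> pd.DataFrame:
    """Per-SNP QC record: call count, MAF, HWE chi2/p, exclusion flag.

    Monomorphic SNPs get ``hwe_p = NaN`` (not testable) and are never
    HWE-excluded here; they fail downstream on their own (constant design
    column).
    """
    rows = []
    for snp in table.snp_ids:
        counts = table.genotype_counts(snp)
        n_called = sum(counts)
        maf = compute_maf(counts) if n_called else np.nan
        try:
            chi2, p = hwe_chi2_test(counts)
        except (MonomorphicSnpError, DegenerateInputError):
            chi2, p = np.nan, np.nan
        rows.append(
            {
                "snp_id": snp,
                "n_called": n_called,
                "call_rate": table.call_rate(snp),
                "maf": maf,
                "hwe_chi2": chi2,
                "hwe_p": p,
            }
        )
    records = pd.DataFrame(rows).set_index("snp_id")
    return apply_hwe_exclusion(records, hwe_alpha)


def apply_hwe_exclusion(
    records: pd.DataFrame, alpha: float = HWE_ALPHA_DEFAULT
) -> pd.DataFrame:
    """Flag SNPs with HWE p strictly below ``alpha`` for exclusion.

    Exclusion applies to survival and genotype-score analyses; excluded
    SNPs stay in the marker-association output. p exactly equal to alpha
    is retained (strict less-than).
    """
    out = records.copy()
    out["excluded"] = (out["hwe_p"] < alpha).fillna(False).astype(bool)
    n_exc = int(out["excluded"].sum())
    if n_exc:
        log.info(
            "HWE exclusion (alpha=%g): %s", alpha,
            ", ".join(out.index[out["excluded"]]),
        )
    return out


def _ld_em_haplotypes(dose_a: np.ndarray, dose_b: np.ndarray,
                      tol: float = 1e-10, max_iter: int = 1000) -> np.ndarray:
    """EM haplotype frequencies (AB, Ab, aB, ab) from unphased doses.

    Capital = common allele, lower-case = rare. Only double heterozygotes
    (dose 1/1) are phase-ambiguous; each EM step splits them between the
    AB/ab and Ab/aB configurations by their current phase odds.
    """
    n = len(dose_a)
    # counts of the nine unphased two-locus genotypes
    counts = np.zeros((3, 3))
    for i, j in zip(dose_a, dose_b):
        counts[i, j] += 1
    # known haplotype contributions (everything except dose (1,1))
    # haplotype order: [AB, Ab, aB, ab] with a=rare at locus A, b=rare at B
    base = np.zeros(4)
    base[0] = 2 * counts[0, 0] + counts[0, 1] + counts[1, 0]
    base[1] = 2 * counts[0, 2] + counts[0, 1] + counts[1, 2]
    base[2] = 2 * counts[2, 0] + counts[1, 0] + counts[2, 1]
    base[3] = 2 * counts[2, 2] + counts[2, 1] + counts[1, 2]
    n_dh = counts[1, 1]
    total = 2.0 * n
    freqs = np.full(4, 0.25)
    # start from linkage equilibrium at the sample allele frequencies
    pa = (base[2] + base[3] + n_dh) / total
    pb = (base[1] + base[3] + n_dh) / total
    freqs = np.array([(1 - pa) * (1 - pb), (1 - pa) * pb, pa * (1 - pb), pa * pb])
    freqs = np.maximum(freqs, 1e-12)
    freqs /= freqs.sum()
    for _ in range(max_iter):
        p_cis = freqs[0] * freqs[3]          # AB/ab configuration
        p_trans = freqs[1] * freqs[2]        # Ab/aB configuration
        denom = p_cis + p_trans
        w = 0.5 if denom == 0 else p_cis / denom
        new = base.copy()
        new[0] += n_dh * w
        new[3] += n_dh * w
        new[1] += n_dh * (1 - w)
        new[2] += n_dh * (1 - w)
        new /= total
        if np.max(np.abs(new - freqs)) < tol:
            freqs = new
            break
        freqs = new
    return freqs


def pairwise_ld(dose_a: pd.Series | np.ndarray,
                dose_b: pd.Series | np.ndarray) -> tuple[float, float]:
    """Standardized linkage disequilibrium (D', r^2) between two loci.

    Haplotype frequencies are estimated from unphased 0/1/2 doses by EM on
    shared complete-case subjects; D = p_ab - p_a*p_b with a, b the rare
    alleles, D' = D/Dmax, r^2 = D^2 / (p_a q_a p_b q_b).
    """
    a = pd.Series(dose_a).astype("Int64")
    b = pd.Series(dose_b).astype("Int64")
    ok = a.notna() & b.notna()
    a, b = a[ok].to_numpy(int), b[ok].to_numpy(int)
    if len(a) < 2:
        raise DegenerateInputError("need >= 2 shared called subjects for LD")
    if len(np.unique(a)) < 2 or len(np.unique(b)) < 2:
        raise MonomorphicSnpError("LD undefined for a monomorphic SNP")
    freqs = _ld_em_haplotypes(a, b)
    pa = freqs[2] + freqs[3]  # rare allele at locus A
    pb = freqs[1] + freqs[3]  # rare allele at locus B
    d = freqs[3] - pa * pb
    if d >= 0:
        dmax = min(pa * (1 - pb), (1 - pa) * pb)
    else:
        dmax = min(pa * pb, (1 - pa) * (1 - pb))
    dprime = 0.0 if dmax == 0 else d / dmax
    r2 = d * d / (pa * (1 - pa) * pb * (1 - pb))
    return float(np.clip(dprime, -1.0, 1.0)), float(min(r2, 1.0))


def ld_matrix(table: GenotypeTable) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise D' and r^2 over all polymorphic SNP pairs in the table."""
    snps = table.snp_ids
    dp = pd.DataFrame(np.eye(len(snps)), index=snps, columns=snps)
    r2 = dp.copy()
    for i, s1 in enumerate(snps):
        for s2 in snps[i + 1:]:
            try:
                d, r = pairwise_ld(table.doses[s1], table.doses[s2])
            except (MonomorphicSnpError, DegenerateInputError):
                d, r = np.nan, np.nan
            dp.loc[s1, s2] = dp.loc[s2, s1] = d
            r2.loc[s1, s2] = r2.loc[s2, s1] = r
    return dp, r2


def code_genotypes(doses: pd.Series, scheme: str = "additive") -> pd.DataFrame:
    """Design columns for one SNP.

    ``additive``: a single 0/1/2 dose column. ``genotypic``: heterozygote
    and rare-homozygote indicators, common homozygote as reference.
    Missing doses propagate as NaN rows.
    """
    d = pd.Series(doses).astype("Float64")
    name = d.name or "snp"
    if scheme == "additive":
        return pd.DataFrame({f"{name}_additive": d.astype(float)})
    if scheme == "genotypic":
        het = (d == 1).astype(float).where(d.notna())
        hom = (d == 2).astype(float).where(d.notna())
        return pd.DataFrame(
            {f"{name}_het": het.astype(float), f"{name}_rarehom": hom.astype(float)}
        )
    raise ValueError(f"unknown coding scheme: {scheme!r}")


def read_vcf(path: str) -> GenotypeTable:
    """Optional VCF ingestion (diploid, biallelic records only).

    Maps GT fields to rare-allele doses; multiallelic records are skipped
    with a warning. Requires the ``cyvcf2`` extra.
    """
    try:
        from cyvcf2 import VCF
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError("VCF ingestion requires cyvcf2 (install extra 'vcf')") from exc
    vcf = VCF(path)
    subjects = list(vcf.samples)
    cols, meta = {}, []
    for rec in vcf:
        if len(rec.ALT) != 1:
            warnings.warn(f"skipping multiallelic record {rec.ID or rec.POS}")
            continue
        snp_id = rec.ID or f"{rec.CHROM}:{rec.POS}"
        gt = np.asarray(rec.gt_types)  # 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
        dose = pd.array(
            [0 if g == 0 else 1 if g == 1 else 2 if g == 3 else pd.NA for g in gt],
            dtype="Int64",
        )
        cols[snp_id] = dose
        meta.append({"snp_id": snp_id, "common_allele": rec.REF, "rare_allele": rec.ALT[0]})
    doses = pd.DataFrame(cols, index=pd.Index(subjects, name="subject_id"))
    return GenotypeTable(doses, pd.DataFrame(meta).set_index("snp_id"))
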