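"""Tab-separated cohort tables: genotypes, phenotypes, survival.

All tables share a ``subject_id`` key column, a header row, and ``.`` for
missing values.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .qc import GenotypeTable

NA_REP = "."


class SchemaError(ValueError):
    """A required column is missing or subject ids do not align."""


def _read(path: str | Path, required: list[str], name: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", na_values=[NA_REP])
    for col in required:
        if col not in df.columns:
            raise SchemaError(f"{name} file {path} is missing column {col!r}")
    if df["subject_id"].duplicated().any():
        raise SchemaError(f"{name} file {path} has duplicate subject ids")
    return df.set_index("subject_id")


def write_genotypes(table: GenotypeTable | pd.DataFrame, path: str | Path) -> None:
    doses = table.doses if isinstance(table, GenotypeTable) else table
    doses.to_csv(path, sep="\t", na_rep=NA_REP)


def read_genotypes(path: str | Path) -> GenotypeTable:
    df = _read(path, ["subject_id"], "genotype")
    return GenotypeTable(df)


def write_phenotypes(pheno: pd.DataFrame, path: str | Path) -> None:
    pheno.to_csv(path, sep="\t", na_rep=NA_REP)


def read_phenotypes(path: str | Path) -> pd.DataFrame:
    return _read(path, ["subject_id", "age", "sex", "marker_conc"], "phenotype")


def write_survival(surv: pd.DataFrame, path: str | Path) -> None:
    surv.to_csv(path, sep="\t", na_rep=NA_REP)


def read_survival(path: str | Path) -> pd.DataFrame:
    df = _read(path, ["subject_id", "time_years", "event"], "survival")
    if not df["event"].dropna().isin([0, 1]).all():
        raise SchemaError(f"survival file {path}: event must be 0/1")
    if (df["time_years"].dropna() <= 0).any():
        raise SchemaError(f"survival file {path}: time_years must be positive")
    return df


def check_alignment(*frames: pd.DataFrame) -> pd.Index:
    """Common subject ids across tables; error if any table is disjoint."""
    idx = frames[0].index
    for f in frames[1:]:
        idx = idx.intersection(f.index)
    if len(idx) == 0:
        raise SchemaError("no subject ids shared across input tables")
    return idx
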