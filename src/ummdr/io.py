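"""Readers and writers for genotype, survival and covariate tables.

Supported genotype formats: delimited text (CSV/TSV, header row of SNP ids,
optional leading sample-id column) and PLINK ``.raw`` allele-dosage exports
(whitespace-delimited, six metadata columns FID IID PAT MAT SEX PHENOTYPE
followed by one dosage column per SNP). No VCF/BGEN support.
"""
from __future__ import annotations

import os

import numpy as np
import pandas as pd

from .datamodel import CovariateMatrix, GenotypeMatrix, SurvivalData, ValidationError

__all__ = [
    "read_genotypes",
    "read_survival",
    "read_covariates",
    "write_genotypes",
    "write_survival",
]

_PLINK_META = ["FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"]
_ID_COLUMN_NAMES = {"sample", "sample_id", "id", "iid", "subject", "subject_id"}


def _infer_dialect(path: str) -> str:
    ext = os.path.splitext(path)[1].lower()
    if ext == ".raw":
        return "plink_raw"
    if ext in (".tsv", ".txt"):
        return "tsv"
    return "csv"


def _impute_modal(col: pd.Series) -> pd.Series:
    if col.isna().all():
        raise ValidationError(f"SNP {col.name!r}: all genotypes missing, cannot impute")
    mode = col.mode().iloc[0]
    return col.fillna(mode)


def read_genotypes(
    path: str,
    dialect: str | None = None,
    impute_missing: bool = False,
) -> GenotypeMatrix:
    """Load an additively coded genotype matrix.

    Missing genotypes are rejected unless ``impute_missing`` is set, in which
    case each SNP's missing entries are filled with that SNP's modal genotype.
    """
    dialect = dialect or _infer_dialect(path)
    if dialect == "plink_raw":
        df = pd.read_csv(path, sep=r"\s+")
        missing_meta = [c for c in _PLINK_META if c not in df.columns]
        if missing_meta:
            raise ValidationError(f"PLINK .raw header lacks columns {missing_meta}")
        sample_ids = df["IID"].astype(str).tolist()
        geno = df.drop(columns=_PLINK_META)
    elif dialect in ("csv", "tsv"):
        df = pd.read_csv(path, sep="," if dialect == "csv" else "\t")
        first = df.columns[0]
        if first.lower() in _ID_COLUMN_NAMES or not pd.api.types.is_numeric_dtype(df[first]):
            sample_ids = df[first].astype(str).tolist()
            geno = df.drop(columns=[first])
        else:
            sample_ids = None
            geno = df
    else:
        raise ValueError(f"unknown genotype dialect {dialect!r}")

    if impute_missing:
        geno = geno.apply(_impute_modal)
    elif geno.isna().any().any():
        col = geno.columns[geno.isna().any()][0]
        row = int(geno.index[geno[col].isna()][0])
        raise ValidationError(
            f"missing genotype at row {row}, SNP {col!r} "
            f"(pass impute_missing=True to impute the per-SNP mode)"
        )
    values = geno.to_numpy()
    bad = ~np.isin(values, (0, 1, 2))
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValidationError(
            f"genotype {values[i, j]!r} at row {i}, SNP {geno.columns[j]!r} "
            "is not in {0, 1, 2}"
        )
    return GenotypeMatrix(values, list(geno.columns), sample_ids)


def _find_id_col(df: pd.DataFrame, id_col: str | None) -> str | None:
    if id_col is not None:
        if id_col not in df.columns:
            raise ValidationError(f"id column {id_col!r} not found")
        return id_col
    for c in df.columns:
        if c.lower() in _ID_COLUMN_NAMES:
            return c
    return None


def read_survival(
    path: str,
    time_col: str = "time",
    status_col: str = "status",
    id_col: str | None = None,
    dialect: str | None = None,
) -> SurvivalData:
    """Load observed time (> 0) and event status {0, 1} from a delimited table."""
    dialect = dialect or _infer_dialect(path)
    df = pd.read_csv(path, sep="," if dialect == "csv" else "\t")
    for c in (time_col, status_col):
        if c not in df.columns:
            raise ValidationError(
                f"column {c!r} not found in {path} (have {list(df.columns)})"
            )
    idc = _find_id_col(df, id_col)
    ids = df[idc].astype(str).tolist() if idc is not None else None
    return SurvivalData(
        df[time_col].to_numpy(dtype=float), df[status_col].to_numpy(), ids
    )


def read_covariates(
    path: str, id_col: str | None = None, dialect: str | None = None
) -> CovariateMatrix:
    """Load a real-valued covariate table; all non-id columns are covariates."""
    dialect = dialect or _infer_dialect(path)
    df = pd.read_csv(path, sep="," if dialect == "csv" else "\t")
    idc = _find_id_col(df, id_col)
    ids = df[idc].astype(str).tolist() if idc is not None else None
    if idc is not None:
        df = df.drop(columns=[idc])
    return CovariateMatrix(df.to_numpy(dtype=float), list(df.columns), ids)


def write_genotypes(G: GenotypeMatrix, path: str, dialect: str | None = None) -> None:
    dialect = dialect or _infer_dialect(path)
    df = pd.DataFrame(G.values, columns=G.snp_ids)
    df.insert(0, "sample_id", G.sample_ids)
    df.to_csv(path, sep="," if dialect == "csv" else "\t", index=False)


def write_survival(surv: SurvivalData, path: str, dialect: str | None = None) -> None:
    dialect = dialect or _infer_dialect(path)
    df = pd.DataFrame({"time": surv.time, "status": surv.status})
    if surv.sample_ids is not None:
        df.insert(0, "sample_id", surv.sample_ids)
    df.to_csv(path, sep="," if dialect == "csv" else "\t", index=False)
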