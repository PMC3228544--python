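"""Readers and writers for genotype/phenotype files.

Two dialects are supported, both samples x SNPs:

* ``tsv`` — delimited text with a header row of SNP identifiers; genotype
  cells are minor-allele counts 0/1/2 (or NA for missing).  A phenotype may
  live in a named column of the same file or in a separate one-column file.
* ``plink_raw`` — the PLINK ``--recode A`` dialect: whitespace-delimited
  with columns FID IID PAT MAT SEX PHENOTYPE followed by one column per SNP
  allele (0/1/2/NA).  The PHENOTYPE column is recoded 1/2 -> 0/1; -9 and NA
  become missing.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from .data import GenotypeMatrix, Phenotype
from .exceptions import ValidationError

_PLINK_META = ["FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"]


class ParseError(ValidationError):
    """File could not be parsed in the declared dialect."""


def _numeric_frame(df: pd.DataFrame, path) -> pd.DataFrame:
    out = df.apply(pd.to_numeric, errors="coerce")
    # a cell is bad if its original non-NA text failed numeric conversion
    orig_na = df.isna() | df.apply(lambda s: s.astype(str).str.upper().isin(["NA", "NAN"]))
    bad = out.isna() & ~orig_na
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise ParseError(
            f"{path}: non-numeric genotype cell {df.iat[r, c]!r} at data line "
            f"{r + 2}, column {df.columns[c]!r}"
        )
    return out


def read_genotypes(path, format: str = "tsv", phenotype: str | None = None,
                   covariates=None):
    """Read a genotype file; returns (GenotypeMatrix, Phenotype | None, covariates | None).

    Parameters
    ----------
    path : str or Path
    format : {"tsv", "plink_raw"}
    phenotype : str, optional
        For the tsv dialect, the name of the phenotype column within the
        file.  Ignored for plink_raw, which has a fixed PHENOTYPE column.
    covariates : list of str, optional
        Column names to return as unpenalised covariates instead of SNPs.
    """
    if format == "tsv":
        try:
            df = pd.read_csv(path, sep="\t", dtype=str)
        except pd.errors.ParserError as exc:
            raise ParseError(f"{path}: {exc}") from exc
        pheno = None
        if phenotype is not None:
            if phenotype not in df.columns:
                raise ParseError(f"{path}: no phenotype column {phenotype!r}")
            pheno = _as_phenotype(pd.to_numeric(df.pop(phenotype), errors="raise"))
        cov = None
        if covariates:
            missing = [c for c in covariates if c not in df.columns]
            if missing:
                raise ParseError(f"{path}: missing covariate columns {missing}")
            cov = df[list(covariates)].apply(pd.to_numeric)
            df = df.drop(columns=list(covariates))
        df = _numeric_frame(df, path)
        G = GenotypeMatrix(values=df.to_numpy(dtype=float),
                           snp_ids=np.asarray(df.columns, dtype=object))
        return G, pheno, cov
    if format == "plink_raw":
        try:
            df = pd.read_csv(path, sep=r"\s+", dtype=str)
        except pd.errors.ParserError as exc:
            raise ParseError(f"{path}: {exc}") from exc
        missing = [c for c in _PLINK_META if c not in df.columns]
        if missing:
            raise ParseError(f"{path}: not plink_raw; missing header columns {missing}")
        pheno_raw = pd.to_numeric(df["PHENOTYPE"].replace({"NA": None}), errors="coerce")
        pheno_raw = pheno_raw.where(pheno_raw != -9, other=np.nan)
        if set(pheno_raw.dropna().unique()) <= {1.0, 2.0}:
            pheno_raw = pheno_raw - 1.0  # case/control 1/2 -> 0/1
        pheno = _as_phenotype(pheno_raw) if pheno_raw.notna().all() else None
        snp_cols = [c for c in df.columns if c not in _PLINK_META]
        geno = _numeric_frame(df[snp_cols], path)
        G = GenotypeMatrix(values=geno.to_numpy(dtype=float),
                           snp_ids=np.asarray(snp_cols, dtype=object))
        return G, pheno, None
    raise ParseError(f"unknown genotype dialect {format!r}")


def _as_phenotype(series) -> Phenotype:
    y = np.asarray(series, dtype=float)
    kind = "binary" if set(np.unique(y)) <= {0.0, 1.0} else "continuous"
    return Phenotype(y=y, kind=kind)


def read_phenotype(path) -> Phenotype:
    """Read a one-column phenotype file (optional header)."""
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] != 1:
        raise ParseError(f"{path}: expected a single phenotype column, got {df.shape[1]}")
    return _as_phenotype(pd.to_numeric(df.iloc[:, 0], errors="raise"))


def write_genotypes_tsv(G: GenotypeMatrix, path, phenotype: Phenotype | None = None,
                        phenotype_col: str = "PHENOTYPE") -> None:
    df = pd.DataFrame(G.values, columns=list(G.snp_ids))
    if phenotype is not None:
        df.insert(0, phenotype_col, phenotype.y)
    df.to_csv(path, sep="\t", index=False)


def write_plink_raw(G: GenotypeMatrix, path, phenotype: Phenotype | None = None) -> None:
    n = G.n_samples
    df = pd.DataFrame({
        "FID": [f"F{i}" for i in range(n)],
        "IID": [f"I{i}" for i in range(n)],
        "PAT": 0, "MAT": 0, "SEX": 0,
        "PHENOTYPE": (phenotype.y + 1).astype(int) if phenotype is not None
                      and phenotype.kind == "binary"
                      else (phenotype.y if phenotype is not None else -9),
    })
    geno = pd.DataFrame(G.values, columns=list(G.snp_ids))
    pd.concat([df, geno], axis=1).to_csv(path, sep=" ", index=False, na_rep="NA")
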