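"""Readers and writers for the pipeline's tabular formats.

Dialects
--------
* Expression: TSV, first column the miRNA name, remaining columns sample
  IDs, non-negative signal values; one file per tissue type.
* Genotypes: TSV, SNP rows x individual columns, additive codes
  0 (homozygote common) / 1 (heterozygote) / 2 (homozygote rare), ``NA``
  for missing. A minimal VCF dialect (GT subfield, phased or unphased)
  is accepted via :func:`read_genotypes_vcf`.
* Covariates: TSV indexed by sample ID with columns ``age``, ``sex``,
  ``center``, ``site`` and optionally ``status`` (0 control / 1 case).
* Pairs: CSV with columns ``snp_id``, ``gene_labels``, ``mirna_name``.

All readers reject ragged tables, duplicated identifiers and non-numeric
signal values with errors naming the offending row or column; genotype
missingness is preserved (pandas nullable ``Int64``), never coerced to 0.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "read_expression",
    "write_expression",
    "read_genotypes",
    "write_genotypes",
    "read_genotypes_vcf",
    "read_covariates",
    "write_covariates",
    "read_pairs",
    "write_pairs",
]


def _check_table(df: pd.DataFrame, path, kind: str) -> None:
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"{kind} file {path}: duplicated row identifiers {dups}")
    # pandas mangles duplicate header names (A -> A.1), so inspect the raw header
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")[1:]
    dups = [name for i, name in enumerate(header) if name in header[:i]]
    if dups:
        raise ValueError(f"{kind} file {path}: duplicated sample IDs {sorted(set(dups))}")


def _check_ragged(df: pd.DataFrame, path, kind: str) -> None:
    # pandas pads short rows with NaN; a ragged table therefore surfaces
    # as missing cells, which none of these formats permit
    if df.isna().any().any():
        mask = df.isna()
        row = df.index[mask.any(axis=1)][0]
        col = df.columns[mask.loc[row]][0]
        raise ValueError(f"{kind} file {path}: missing/ragged cell at row {row!r}, column {col!r}")


def read_expression(path: str | Path) -> pd.DataFrame:
    """Read a miRNA x sample signal matrix from TSV."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0)
    _check_table(df, path, "expression")
    _check_ragged(df, path, "expression")
    for col in df.columns:
        if not pd.api.types.is_numeric_dtype(df[col]):
            bad = df[pd.to_numeric(df[col], errors="coerce").isna()].index[0]
            raise ValueError(
                f"expression file {path}: non-numeric signal at row {bad!r}, column {col!r}"
            )
    return df.astype(float)


def write_expression(matrix: pd.DataFrame, path: str | Path, index_label: str = "mirna") -> None:
    matrix.to_csv(path, sep="\t", index_label=index_label)


def read_genotypes(path: str | Path) -> pd.DataFrame:
    """Read a SNP x individual genotype table (codes 0/1/2, NA missing)."""
    path = Path(path)
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str, keep_default_na=False)
    _check_table(raw, path, "genotype")
    df = raw.replace({"NA": pd.NA, "": pd.NA})
    numeric = df.apply(lambda s: pd.to_numeric(s, errors="coerce"))
    bad = numeric.isna() & df.notna()
    if bad.any().any():
        row = df.index[bad.any(axis=1)][0]
        col = df.columns[bad.loc[row]][0]
        raise ValueError(
            f"genotype file {path}: invalid code {df.loc[row, col]!r} at SNP {row!r}, sample {col!r}"
        )
    out = numeric.astype("Int64")
    invalid = ~out.isin([0, 1, 2]) & out.notna()
    if invalid.any().any():
        row = out.index[invalid.any(axis=1)][0]
        col = out.columns[invalid.loc[row]][0]
        raise ValueError(
            f"genotype file {path}: code {out.loc[row, col]} outside 0/1/2 at SNP {row!r}, sample {col!r}"
        )
    return out


def write_genotypes(genotypes: pd.DataFrame, path: str | Path) -> None:
    genotypes.astype("Int64").to_csv(path, sep="\t", index_label="snp_id", na_rep="NA")


def read_genotypes_vcf(path: str | Path) -> pd.DataFrame:
    """Read additive genotype codes from a minimal VCF (GT subfield only).

    ``0/0`` -> 0, ``0/1`` -> 1, ``1/1`` -> 2; phased separators accepted;
    missing calls (``./.``) preserved as NA. Requires ``cyvcf2``.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows, ids = [], []
    for variant in vcf:
        ids.append(variant.ID if variant.ID not in (None, ".") else
                   f"{variant.CHROM}:{variant.POS}")
        # gt_types: 0 HOM_REF, 1 HET, 2 UNKNOWN, 3 HOM_ALT
        codes = np.array(variant.gt_types, dtype=float)
        mapped = np.select([codes == 0, codes == 1, codes == 3], [0.0, 1.0, 2.0], np.nan)
        rows.append(mapped)
    vcf.close()
    df = pd.DataFrame(rows, index=ids, columns=samples)
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"VCF {path}: duplicated variant IDs {dups}")
    return df.astype("Int64")


def read_covariates(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0)
    _check_table(df, path, "covariate")
    required = {"age", "sex", "center"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"covariate file {path}: missing columns {sorted(missing)}")
    if df[sorted(required)].isna().any().any():
        col = [c for c in required if df[c].isna().any()][0]
        row = df.index[df[col].isna()][0]
        raise ValueError(f"covariate file {path}: missing value at sample {row!r}, column {col!r}")
    return df


def write_covariates(covariates: pd.DataFrame, path: str | Path) -> None:
    covariates.to_csv(path, sep="\t", index_label="sample_id")


def read_pairs(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path)
    required = {"snp_id", "mirna_name"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"pair file {path}: missing columns {sorted(missing)}")
    if "gene_labels" not in df.columns:
        df["gene_labels"] = ""
    df["gene_labels"] = df["gene_labels"].fillna("")
    if df["snp_id"].isna().any() or df["mirna_name"].isna().any():
        row = df.index[df[["snp_id", "mirna_name"]].isna().any(axis=1)][0]
        raise ValueError(f"pair file {path}: missing snp_id/mirna_name at row {row}")
    return df


def write_pairs(pairs: pd.DataFrame, path: str | Path) -> None:
    pairs.to_csv(path, index=False)
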