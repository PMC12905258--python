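"""File formats: TSV dialects, BED, GFF3 genes, GMT, LD matrices.

All tabular formats are tab-separated text with a header.  BED
intervals are 0-based half-open; CpG and SNP coordinates inside TSVs
are 1-based.  Readers validate the declared schema strictly and report
violations with the offending column and 1-based file line number.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .ewas import CohortTable

__all__ = [
    "SchemaError",
    "read_ewas_records", "write_ewas_records",
    "read_meta_records", "write_meta_records",
    "read_summary_stats", "write_summary_stats",
    "read_bed", "write_bed",
    "read_gff3_genes",
    "read_gmt", "write_gmt",
    "read_ld_matrix", "write_ld_matrix",
    "read_cohort", "write_cohort",
    "read_truth", "write_truth",
]


class SchemaError(ValueError):
    """A table violated its declared schema."""


# column -> (dtype kind, validator name) per schema
_SUMMARY_COLUMNS = {
    "snp_id": str, "effect_allele": str, "other_allele": str,
    "eaf": float, "beta": float, "se": float, "p": float, "n": int,
}
_SUMMARY_FILE_COLUMNS = ["SNP", "EA", "NEA", "EAF", "BETA", "SE", "P", "N"]
_EWAS_COLUMNS = {"cpg_id": str, "beta": float, "se": float, "p": float,
                 "n": int, "mean_beta": float, "se_mean": float}
_META_COLUMNS = {"cpg_id": str, "beta": float, "se": float, "z": float,
                 "p": float, "Q": float, "I2": float, "direction": str,
                 "n_cohorts": int, "n_total": int, "q_fdr": float}
_VALID_ALLELES = {"A", "C", "G", "T"}


def _line(idx) -> int:
    return int(idx) + 2  # header is line 1


def _require_columns(df: pd.DataFrame, cols, path):
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")


def _check_range(df, col, ok_mask, path, what):
    bad = ~ok_mask
    if bad.any():
        i = df.index[bad][0]
        raise SchemaError(
            f"{path}: invalid {col} ({what}) at line {_line(i)}: "
            f"{df.loc[i, col]!r}")


def read_summary_stats(path) -> pd.DataFrame:
    """Read a GWAS/mQTL SummaryStats TSV (SNP EA NEA EAF BETA SE P N).

    An optional leading ``CPG`` column carries the CpG id of long-format
    mQTL files.
    """
    df = pd.read_csv(path, sep="\t", dtype={"SNP": str})
    cols = list(_SUMMARY_FILE_COLUMNS)
    rename = dict(zip(_SUMMARY_FILE_COLUMNS,
                      _SUMMARY_COLUMNS))
    if "CPG" in df.columns:
        cols = ["CPG"] + cols
        rename["CPG"] = "cpg_id"
    _require_columns(df, cols, path)
    df = df.rename(columns=rename)
    for col in ("effect_allele", "other_allele"):
        _check_range(df, col, df[col].isin(_VALID_ALLELES), path,
                     "single-base allele in A/C/G/T")
    _check_range(df, "eaf", (df["eaf"] > 0) & (df["eaf"] < 1), path,
                 "EAF in (0, 1)")
    _check_range(df, "se", df["se"] > 0, path, "SE > 0")
    _check_range(df, "p", (df["p"] > 0) & (df["p"] <= 1), path,
                 "p in (0, 1]")
    _check_range(df, "n", df["n"] >= 1, path, "n >= 1")
    return df


def write_summary_stats(df: pd.DataFrame, path):
    out = df.copy()
    rename = {v: k for k, v in zip(_SUMMARY_FILE_COLUMNS, _SUMMARY_COLUMNS)}
    rename["cpg_id"] = "CPG"
    out = out.rename(columns=rename)
    cols = (["CPG"] if "CPG" in out.columns else []) + _SUMMARY_FILE_COLUMNS
    out[cols].to_csv(path, sep="\t", index=False)


def read_ewas_records(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, _EWAS_COLUMNS, path)
    _check_range(df, "se", df["se"] > 0, path, "SE > 0")
    _check_range(df, "p", (df["p"] > 0) & (df["p"] <= 1), path,
                 "p in (0, 1]")
    _check_range(df, "n", df["n"] >= 1, path, "n >= 1")
    _check_range(df, "mean_beta",
                 (df["mean_beta"] >= 0) & (df["mean_beta"] <= 1), path,
                 "mean beta in [0, 1]")
    return df


def write_ewas_records(df: pd.DataFrame, path):
    df[list(_EWAS_COLUMNS)].to_csv(path, sep="\t", index=False)


def read_meta_records(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, _META_COLUMNS, path)
    _check_range(df, "I2", (df["I2"] >= 0) & (df["I2"] <= 100), path,
                 "I2 in [0, 100]")
    return df


def write_meta_records(df: pd.DataFrame, path):
    df[list(_META_COLUMNS)].to_csv(path, sep="\t", index=False)


def read_bed(path) -> pd.DataFrame:
    """BED (0-based half-open); name column optional, no header."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] < 3:
        raise SchemaError(f"{path}: BED needs at least 3 columns")
    df = df.iloc[:, :4] if df.shape[1] >= 4 else df.iloc[:, :3]
    df.columns = ["chrom", "start", "end", "name"][: df.shape[1]]
    bad = df["end"] <= df["start"]
    if bad.any():
        i = df.index[bad][0]
        raise SchemaError(f"{path}: empty interval at line {int(i) + 1}")
    return df


def write_bed(df: pd.DataFrame, path):
    cols = [c for c in ("chrom", "start", "end", "name") if c in df.columns]
    df[cols].to_csv(path, sep="\t", index=False, header=False)


def read_gff3_genes(path) -> pd.DataFrame:
    """Gene features from a GFF3 file as 0-based half-open intervals.

    Only ``gene`` rows are used; the gene id is taken from the ``ID=``
    (or ``gene_id=``) attribute.
    """
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 9:
                raise SchemaError(f"{path}: expected 9 GFF3 columns at "
                                  f"line {ln}")
            if parts[2] != "gene":
                continue
            attrs = dict(kv.split("=", 1) for kv in parts[8].split(";")
                         if "=" in kv)
            gid = attrs.get("ID") or attrs.get("gene_id")
            if gid is None:
                raise SchemaError(f"{path}: gene without ID at line {ln}")
            rows.append({"gene_id": gid, "chrom": parts[0],
                         "start": int(parts[3]) - 1, "end": int(parts[4])})
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end"])


def read_gmt(path) -> dict:
    """GMT gene-set library: term, description, genes... per line."""
    library = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                raise SchemaError(f"{path}: GMT line {ln} has fewer than "
                                  "3 fields")
            library[parts[0]] = set(g for g in parts[2:] if g)
    return library


def write_gmt(library: dict, path):
    with open(path, "w") as fh:
        for term in sorted(library):
            genes = "\t".join(sorted(library[term]))
            fh.write(f"{term}\tna\t{genes}\n")


def read_ld_matrix(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if list(df.index) != list(df.columns):
        raise SchemaError(f"{path}: LD matrix must be square with matching "
                          "row/column SNP ids")
    arr = df.to_numpy()
    if not np.allclose(arr, arr.T, atol=1e-8):
        raise SchemaError(f"{path}: LD matrix not symmetric")
    return df


def write_ld_matrix(ld: pd.DataFrame, path):
    ld.to_csv(path, sep="\t")


def write_cohort(cohort: CohortTable, prefix):
    """One phenotype TSV and one CpG x sample beta-matrix TSV."""
    prefix = Path(prefix)
    ph = cohort.phenotypes.copy()
    ph.index.name = "sample_id"
    ph.to_csv(Path(str(prefix) + ".phenotypes.tsv"), sep="\t")
    b = cohort.beta.copy()
    b.index.name = "cpg_id"
    b.to_csv(Path(str(prefix) + ".beta.tsv"), sep="\t")


def read_cohort(prefix, name: str | None = None,
                technical: tuple = ("plate",),
                lod: float | None = None) -> CohortTable:
    prefix = Path(prefix)
    ph = pd.read_csv(Path(str(prefix) + ".phenotypes.tsv"), sep="\t",
                     index_col="sample_id")
    beta = pd.read_csv(Path(str(prefix) + ".beta.tsv"), sep="\t",
                       index_col="cpg_id")
    beta.index.name = None
    beta.columns.name = ph.index.name
    arr = beta.to_numpy()
    if np.nanmin(arr) < 0 or np.nanmax(arr) > 1:
        raise SchemaError(f"{prefix}: beta-values outside [0, 1]")
    cp = ph.filter(like="cp_")
    base = [c for c in cp.columns
            if c in {"cp_cd8t", "cp_cd4t", "cp_bcell"}]
    extended = [c for c in cp.columns if c not in base]
    if extended:
        s = ph[extended].sum(axis=1)
        bad = ~np.isclose(s, 1.0, atol=1e-9)
        if bad.any():
            i = s.index[bad][0]
            raise SchemaError(f"{prefix}: cell proportions of sample {i} "
                              f"sum to {s[i]!r}, not 1")
    return CohortTable(name=name or prefix.name, phenotypes=ph, beta=beta,
                       technical=technical, lod=lod)


def write_truth(truth: pd.DataFrame, path):
    truth.to_csv(path, sep="\t", index=False)


def read_truth(path) -> pd.DataFrame:
    # "null" is a direction label, not a missing value
    df = pd.read_csv(path, sep="\t", keep_default_na=False,
                     na_values=[""])
    _require_columns(df, ["cpg_id", "direction", "true_effect"], path)
    bad = ~df["direction"].isin(["forward", "reverse", "null"])
    if bad.any():
        i = df.index[bad][0]
        raise SchemaError(f"{path}: unknown direction at line {_line(i)}")
    nz = (df["direction"] == "null") & (df["true_effect"] != 0)
    if nz.any():
        i = df.index[nz][0]
        raise SchemaError(f"{path}: null CpG with nonzero effect at line "
                          f"{_line(i)}")
    return df
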