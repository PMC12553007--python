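"""Readers and writers for the pipeline's tab-delimited file dialects.

Every on-disk artifact is plain TSV (or flat key=value text for run
metadata), so inputs and outputs remain diff-able and platform neutral:

* summary statistics: one row per variant, ``SUMSTAT_COLUMNS`` header;
* LD: square matrix with variant ids as both header and first column;
* expression: samples x features TSV plus a covariate sidecar
  (sample_id, pvi, sex, age, diabetes);
* single-cell: cells x genes TSV plus a cell annotation TSV
  (cell_id, cell_type, cluster);
* gene sets: GMT (set name, description, members, tab-separated);
* druggability: TSV (protein_id, status, drugs, cardiac_indication,
  cardiac_side_effect).
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .containers import SUMSTAT_COLUMNS, LDMatrix, SummaryStatSet


# ---------------------------------------------------------------- sumstats

def read_sumstats(
    path: str | Path,
    trait_id: str,
    trait_class: str,
    locus: tuple[str, int, int] | None = None,
) -> SummaryStatSet:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "variant_id": str})
    return SummaryStatSet(trait_id, trait_class, df, locus)


def write_sumstats(stats: SummaryStatSet, path: str | Path) -> None:
    stats.records[SUMSTAT_COLUMNS].to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------- LD

def read_ld(path: str | Path) -> LDMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if list(df.index) != list(df.columns):
        raise ValueError("LD matrix row and column variant ids differ")
    return LDMatrix(list(df.columns), df.to_numpy(dtype=float))


def write_ld(ld: LDMatrix, path: str | Path) -> None:
    pd.DataFrame(ld.r, index=ld.variant_ids, columns=ld.variant_ids).to_csv(
        path, sep="\t"
    )


# ---------------------------------------------------------------- expression

def read_expression(values_path: str | Path, covariates_path: str | Path):
    """Read a plaque expression table and its covariate sidecar.

    Returns ``(values, covariates)``: a samples x features DataFrame and a
    DataFrame indexed by sample with columns ``pvi, sex, age, diabetes``.
    """
    values = pd.read_csv(values_path, sep="\t", index_col=0)
    cov = pd.read_csv(covariates_path, sep="\t", index_col=0)
    needed = {"pvi", "sex", "age", "diabetes"}
    if not needed <= set(cov.columns):
        raise ValueError(f"covariate sidecar missing {needed - set(cov.columns)}")
    if not values.index.equals(cov.index):
        raise ValueError("expression and covariate sample ids differ")
    return values, cov


def write_expression(values: pd.DataFrame, cov: pd.DataFrame,
                     values_path: str | Path, covariates_path: str | Path) -> None:
    values.to_csv(values_path, sep="\t")
    cov.to_csv(covariates_path, sep="\t")


# ---------------------------------------------------------------- single cell

def read_cell_matrix(values_path: str | Path, annotation_path: str | Path):
    """Read a cells x genes matrix and the cell annotation table."""
    values = pd.read_csv(values_path, sep="\t", index_col=0)
    ann = pd.read_csv(annotation_path, sep="\t", index_col=0)
    if "cell_type" not in ann.columns:
        raise ValueError("cell annotation needs a cell_type column")
    if not values.index.equals(ann.index):
        raise ValueError("cell matrix and annotation cell ids differ")
    return values, ann


def write_cell_matrix(values: pd.DataFrame, ann: pd.DataFrame,
                      values_path: str | Path, annotation_path: str | Path) -> None:
    values.to_csv(values_path, sep="\t")
    ann.to_csv(annotation_path, sep="\t")


# ---------------------------------------------------------------- gene sets

def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Parse a GMT gene-set file: name TAB description TAB member...

    Empty member lists are kept (the caller decides whether to skip them).
    """
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"malformed GMT line: {line[:60]!r}")
            sets[parts[0]] = [m for m in parts[2:] if m]
    return sets


def write_gmt(sets: dict[str, list[str]], path: str | Path,
              description: str = "na") -> None:
    with open(path, "w") as fh:
        for name, members in sets.items():
            fh.write("\t".join([name, description, *members]) + "\n")


# ---------------------------------------------------------------- annotations

def read_drug_table(path: str | Path) -> pd.DataFrame:
    """Read a static druggability annotation table.

    Expected columns: protein_id, status, drugs (';'-separated, may be
    empty), cardiac_indication, cardiac_side_effect (yes/no).
    """
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    needed = {"protein_id", "status", "drugs",
              "cardiac_indication", "cardiac_side_effect"}
    if not needed <= set(df.columns):
        raise ValueError(f"drug table missing {needed - set(df.columns)}")
    return df


# ---------------------------------------------------------------- key-value

def write_keyvalue(mapping: dict, path: str | Path) -> None:
    """Write a flat key=value text file (one pair per line, sorted)."""
    with open(path, "w") as fh:
        for key in sorted(mapping):
            fh.write(f"{key}={mapping[key]}\n")


def read_keyvalue(path: str | Path) -> dict[str, str]:
    out: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, val = line.partition("=")
            out[key] = val
    return out
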