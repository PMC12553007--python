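"""Core data containers shared across the pipeline.

GWAS summary statistics live in pandas DataFrames with a fixed column
schema (``SUMSTAT_COLUMNS``); the thin dataclasses here add the trait-level
metadata (trait class, cis locus) and the linkage-disequilibrium matrix
wrapper that the estimators consume.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Column schema of the tab-delimited summary-statistic dialect.
SUMSTAT_COLUMNS = [
    "variant_id",
    "chrom",
    "pos",
    "effect_allele",
    "other_allele",
    "eaf",
    "beta",
    "se",
    "pval",
    "n",
]

VALID_ALLELES = frozenset("ACGT")

TRAIT_CLASSES = ("metabolite", "protein", "disease")


def validate_sumstats(df: pd.DataFrame) -> pd.DataFrame:
    """Validate one GWAS summary-statistic table against the schema.

    Checks column presence, se > 0, eaf in (0, 1), p in (0, 1],
    non-identical single-nucleotide alleles and unique variant ids.
    Returns the frame with canonical column order.
    """
    missing = [c for c in SUMSTAT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"summary statistics missing columns: {missing}")
    df = df[SUMSTAT_COLUMNS].copy()
    if df["variant_id"].duplicated().any():
        dups = df.loc[df["variant_id"].duplicated(), "variant_id"].tolist()
        raise ValueError(f"duplicate variant ids: {dups[:5]}")
    if (df["se"] <= 0).any():
        raise ValueError("standard errors must be positive")
    if ((df["eaf"] <= 0) | (df["eaf"] >= 1)).any():
        raise ValueError("effect-allele frequencies must lie in (0, 1)")
    if ((df["pval"] <= 0) | (df["pval"] > 1)).any():
        raise ValueError("p-values must lie in (0, 1]")
    for col in ("effect_allele", "other_allele"):
        bad = ~df[col].astype(str).str.upper().isin(VALID_ALLELES)
        if bad.any():
            raise ValueError(f"non-ACGT alleles in {col}")
    if (df["effect_allele"] == df["other_allele"]).any():
        raise ValueError("effect and other allele identical for some variants")
    return df


@dataclass
class SummaryStatSet:
    """One trait's GWAS layer: summary statistics plus trait metadata.

    Parameters
    ----------
    trait_id
        Identifier of the trait (protein, metabolite or disease).
    trait_class
        One of ``metabolite``, ``protein``, ``disease``.
    records
        Summary statistics, one row per variant (``SUMSTAT_COLUMNS``).
    locus
        ``(chrom, start, end)`` of the encoding gene; required for
        proteins, where instrument selection is restricted to the cis
        window around this interval.
    """

    trait_id: str
    trait_class: str
    records: pd.DataFrame
    locus: tuple[str, int, int] | None = None

    def __post_init__(self) -> None:
        if self.trait_class not in TRAIT_CLASSES:
            raise ValueError(f"unknown trait class {self.trait_class!r}")
        if self.trait_class == "protein" and self.locus is None:
            raise ValueError("protein traits require a gene locus")
        self.records = validate_sumstats(self.records)

    def __len__(self) -> int:
        return len(self.records)


@dataclass
class LDMatrix:
    """Symmetric variant-by-variant correlation matrix with unit diagonal."""

    variant_ids: list[str]
    r: np.ndarray

    def __post_init__(self) -> None:
        self.variant_ids = list(self.variant_ids)
        self.r = np.asarray(self.r, dtype=float)
        k = len(self.variant_ids)
        if self.r.shape != (k, k):
            raise ValueError("LD matrix shape does not match variant count")
        if not np.allclose(self.r, self.r.T, atol=1e-8):
            raise ValueError("LD matrix is not symmetric")
        if not np.allclose(np.diag(self.r), 1.0, atol=1e-8):
            raise ValueError("LD matrix diagonal must be 1")
        if np.any(np.abs(self.r) > 1 + 1e-8):
            raise ValueError("LD correlations must lie in [-1, 1]")
        # enforce exact symmetry for downstream linear algebra
        self.r = (self.r + self.r.T) / 2.0

    def restrict(self, ids: list[str]) -> "LDMatrix":
        """Return the sub-matrix over ``ids`` (in the given order)."""
        index = {v: i for i, v in enumerate(self.variant_ids)}
        missing = [v for v in ids if v not in index]
        if missing:
            raise KeyError(f"variants absent from LD matrix: {missing[:5]}")
        idx = [index[v] for v in ids]
        return LDMatrix(list(ids), self.r[np.ix_(idx, idx)])

    def __len__(self) -> int:
        return len(self.variant_ids)


@dataclass
class InstrumentSet:
    """Harmonised instruments for one exposure-outcome MR.

    ``variants`` holds one row per retained variant with columns
    ``variant_id, bx, se_x, by, se_y`` (exposure and outcome effects on
    the exposure's effect allele). ``exclusion_log`` records every
    variant removed on the way here as ``(variant_id, stage, reason)``.
    """

    exposure_id: str
    outcome_id: str
    variants: pd.DataFrame
    ld: LDMatrix
    exclusion_log: list[tuple[str, str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        needed = ["variant_id", "bx", "se_x", "by", "se_y"]
        missing = [c for c in needed if c not in self.variants.columns]
        if missing:
            raise ValueError(f"instrument table missing columns: {missing}")
        if list(self.variants["variant_id"]) != list(self.ld.variant_ids):
            raise ValueError("instrument table and LD matrix disagree on variants")

    def __len__(self) -> int:
        return len(self.variants)
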