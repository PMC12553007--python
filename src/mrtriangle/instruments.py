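"""Instrument selection for summary-statistic Mendelian randomisation.

Turns two GWAS layers (exposure, outcome) and an LD matrix into a
harmonised :class:`~mrtriangle.containers.InstrumentSet`, applying the
filters in a fixed order: cis-window restriction (protein exposures
only) -> minor-allele-frequency filter -> instrument-strength (F)
filter -> greedy LD clumping -> allele harmonisation against the
outcome. Every removed variant is logged with its stage and reason so a
run's variant cascade can be audited.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import InstrumentSet, LDMatrix, SummaryStatSet

#: Strand-ambiguous allele pairs; retained and aligned by labels only.
PALINDROMIC = {frozenset(("A", "T")), frozenset(("C", "G"))}


@dataclass
class InstrumentConfig:
    """Filter thresholds for instrument selection (field defaults are the
    pipeline's reporting defaults: F >= 24, MAF >= 0.01, clump r^2 <= 0.30,
    200 kb cis window)."""

    f_min: float = 24.0
    maf_min: float = 0.01
    r2_max: float = 0.30
    cis: bool = False
    window_bp: int = 200_000


def f_statistic(beta: float, se: float):
    """Instrument-strength F statistic: the squared Wald ratio (beta/se)^2."""
    beta = np.asarray(beta, dtype=float)
    se = np.asarray(se, dtype=float)
    if np.any(se <= 0):
        raise ValueError("se must be positive")
    out = (beta / se) ** 2
    return float(out) if out.ndim == 0 else out


def cis_window(protein: SummaryStatSet, window_bp: int = 200_000) -> SummaryStatSet:
    """Restrict a protein GWAS to the cis window around its encoding gene.

    Retains variants on the gene's chromosome with position in the
    closed interval [start - window_bp, end + window_bp].
    """
    if protein.locus is None:
        raise ValueError("cis restriction requires a gene locus")
    chrom, start, end = protein.locus
    df = protein.records
    keep = (
        (df["chrom"].astype(str) == str(chrom))
        & (df["pos"] >= start - window_bp)
        & (df["pos"] <= end + window_bp)
    )
    return SummaryStatSet(
        protein.trait_id, protein.trait_class, df[keep].reset_index(drop=True),
        protein.locus,
    )


def clump(variants: pd.DataFrame, ld: LDMatrix, r2_max: float = 0.30) -> list[str]:
    """Greedy LD clumping by ascending exposure p-value.

    Repeatedly retain the remaining variant with the smallest p-value
    (ties broken by ascending variant id) and drop all others whose
    squared correlation with it exceeds ``r2_max``. Returns retained
    variant ids in retention order; every retained pair has r^2 <= r2_max.
    """
    missing = set(variants["variant_id"]) - set(ld.variant_ids)
    if missing:
        raise KeyError(f"variants absent from LD matrix: {sorted(missing)[:5]}")
    sub = ld.restrict(list(variants["variant_id"]))
    order = variants.sort_values(
        ["pval", "variant_id"], kind="mergesort"
    )["variant_id"].tolist()
    index = {v: i for i, v in enumerate(sub.variant_ids)}
    retained: list[str] = []
    remaining = set(order)
    for vid in order:
        if vid not in remaining:
            continue
        retained.append(vid)
        remaining.discard(vid)
        row = sub.r[index[vid]]
        for other in list(remaining):
            if row[index[other]] ** 2 > r2_max:
                remaining.discard(other)
    return retained


def harmonise(exposure: SummaryStatSet, outcome: SummaryStatSet):
    """Align outcome effects to the exposure's effect allele.

    Variants are matched on variant id. When the outcome reports the
    same allele pair with effect/other swapped, its beta is negated and
    eaf reflected; incompatible allele pairs are dropped and logged.
    Palindromic variants (A/T, C/G) are aligned by allele labels only
    and noted in the log. Returns ``(quadruples, log)`` where quadruples
    is a DataFrame (variant_id, bx, se_x, by, se_y) in exposure order.
    """
    if len(exposure) == 0 or len(outcome) == 0:
        raise ValueError("harmonise requires non-empty summary-statistic sets")
    log: list[tuple[str, str, str]] = []
    out_by_id = outcome.records.set_index("variant_id")
    rows = []
    for rec in exposure.records.itertuples(index=False):
        if rec.variant_id not in out_by_id.index:
            log.append((rec.variant_id, "harmonise", "no_overlap"))
            continue
        orec = out_by_id.loc[rec.variant_id]
        ea, oa = rec.effect_allele.upper(), rec.other_allele.upper()
        oea, ooa = str(orec["effect_allele"]).upper(), str(orec["other_allele"]).upper()
        if frozenset((ea, oa)) in PALINDROMIC:
            log.append((rec.variant_id, "harmonise", "palindromic_label_aligned"))
        if (oea, ooa) == (ea, oa):
            by, se_y = orec["beta"], orec["se"]
        elif (oea, ooa) == (oa, ea):
            by, se_y = -orec["beta"], orec["se"]
        else:
            log.append((rec.variant_id, "harmonise", "allele_mismatch"))
            continue
        rows.append((rec.variant_id, rec.beta, rec.se, by, se_y))
    quad = pd.DataFrame(rows, columns=["variant_id", "bx", "se_x", "by", "se_y"])
    return quad, log


def select_instruments(
    exposure: SummaryStatSet,
    outcome: SummaryStatSet,
    ld: LDMatrix,
    config: InstrumentConfig | None = None,
) -> InstrumentSet:
    """Apply the full instrument-selection cascade for one MR analysis.

    Order: cis restriction (when ``config.cis``) -> MAF filter on
    min(eaf, 1-eaf) -> F >= f_min -> LD clumping at r^2 <= r2_max ->
    harmonisation against the outcome. An empty result is allowed; the
    estimator layer enforces the minimum variant count.
    """
    config = config or InstrumentConfig()
    log: list[tuple[str, str, str]] = []

    work = exposure
    if config.cis:
        before = set(work.records["variant_id"])
        work = cis_window(work, config.window_bp)
        log += [(v, "cis", "outside_window")
                for v in sorted(before - set(work.records["variant_id"]))]

    df = work.records
    maf = np.minimum(df["eaf"], 1 - df["eaf"])
    keep = maf >= config.maf_min
    log += [(v, "maf", "maf") for v in df.loc[~keep, "variant_id"]]
    df = df[keep]

    fstat = f_statistic(df["beta"].to_numpy(), df["se"].to_numpy())
    keep = fstat >= config.f_min
    log += [(v, "f_filter", "weak") for v in df.loc[~keep, "variant_id"]]
    df = df[keep].reset_index(drop=True)

    if len(df):
        retained = clump(df, ld, config.r2_max)
        clumped_out = set(df["variant_id"]) - set(retained)
        log += [(v, "clump", "ld_clumped") for v in sorted(clumped_out)]
        df = df.set_index("variant_id").loc[retained].reset_index()

    if len(df):
        pruned = SummaryStatSet(work.trait_id, work.trait_class, df, work.locus)
        quad, hlog = harmonise(pruned, outcome)
        log += hlog
    else:
        quad = pd.DataFrame(columns=["variant_id", "bx", "se_x", "by", "se_y"])

    sub_ld = (ld.restrict(list(quad["variant_id"])) if len(quad)
              else LDMatrix([], np.empty((0, 0))))
    return InstrumentSet(
        exposure_id=exposure.trait_id,
        outcome_id=outcome.trait_id,
        variants=quad,
        ld=sub_ld,
        exclusion_log=log,
    )


def write_exclusion_log(log: list[tuple[str, str, str]], path) -> None:
    """Write an exclusion log as TSV (variant_id, stage, reason)."""
    pd.DataFrame(log, columns=["variant_id", "stage", "reason"]).to_csv(
        path, sep="\t", index=False
    )
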