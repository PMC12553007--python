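"""Three-layer screening and directional-concordance triangulation.

The pipeline runs three MR layers — metabolite -> disease (genome-wide),
protein -> metabolite (cis), protein -> disease (cis) — each filtered at
its own Bonferroni threshold alpha / n_effective, where n_effective for
the correlated metabolite family is the number of principal components
explaining 90% of its variance. A protein is triangulated when it
affects a disease-associated metabolite and the disease itself, and the
three effect signs form a consistent causal chain:

    sign(theta_pm) * sign(theta_mc) == sign(theta_pc).

Cross-study replication flags (nominal and Bonferroni-strict, sign
aware) are attached per protein when a second GWAS measured it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .mr import MRFit


@dataclass
class MultiplicityPlan:
    """One layer's multiple-testing plan: threshold = alpha / n_effective."""

    layer: str
    method: str         # bonferroni_pca | bonferroni_count
    n_effective: int
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.n_effective < 1:
            raise ValueError("n_effective must be >= 1")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")

    @property
    def threshold(self) -> float:
        return self.alpha / self.n_effective


@dataclass
class TriangleRecord:
    """One protein-metabolite-disease sign triple with concordance flag."""

    protein_id: str
    metabolite_id: str
    theta_pm: float
    theta_mc: float
    theta_pc: float
    p_pm: float
    p_mc: float
    p_pc: float
    concordant: bool
    source_gwas: str = ""


def effective_tests_pca(values: np.ndarray, variance_target: float = 0.90) -> int:
    """Effective number of independent tests among correlated traits.

    ``values`` is either a traits x observations matrix or a square
    trait correlation matrix. Returns the smallest k such that the top-k
    eigenvalues of the trait correlation matrix account for at least
    ``variance_target`` of the total variance.
    """
    values = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(values)):
        raise ValueError("non-finite values in trait matrix")
    if values.ndim != 2 or values.shape[0] < 2:
        raise ValueError("need at least 2 traits")
    square = values.shape[0] == values.shape[1]
    if square and np.allclose(values, values.T) and np.allclose(np.diag(values), 1.0):
        corr = values
    else:
        corr = np.corrcoef(values)
    eig = np.sort(np.linalg.eigvalsh(corr))[::-1]
    eig = np.clip(eig, 0, None)
    cum = np.cumsum(eig) / eig.sum()
    return int(np.searchsorted(cum, variance_target - 1e-12) + 1)


def bonferroni_threshold(alpha: float, n_effective: int) -> float:
    """Bonferroni-corrected per-test threshold alpha / n_effective."""
    if n_effective < 1:
        raise ValueError("n_effective must be >= 1")
    return alpha / n_effective


def screen_layer(fits: list[MRFit], plan: MultiplicityPlan):
    """Retain fits with selected-model p strictly below the layer threshold.

    Returns ``(surviving fits, log)`` where the log records every
    discarded fit with its p-value and the threshold applied.
    """
    survivors, log = [], []
    for fit in fits:
        if fit.pval < plan.threshold:
            survivors.append(fit)
        else:
            log.append({
                "exposure_id": fit.exposure_id,
                "outcome_id": fit.outcome_id,
                "pval": fit.pval,
                "threshold": plan.threshold,
                "layer": plan.layer,
            })
    return survivors, log


def concordance(theta_pm: float, theta_mc: float, theta_pc: float) -> bool:
    """Directional concordance of a protein-metabolite-disease triple.

    True iff the product of the protein->metabolite and
    metabolite->disease signs equals the protein->disease sign (e.g. a
    protein raising a risk-lowering metabolite must itself lower risk).
    Raises on any zero effect, which has no direction.
    """
    if theta_pm == 0 or theta_mc == 0 or theta_pc == 0:
        raise ValueError("concordance undefined for a zero effect")
    return bool(np.sign(theta_pm) * np.sign(theta_mc) == np.sign(theta_pc))


def triangulate(
    metabolite_chd: list[MRFit],
    protein_metabolite: list[MRFit],
    protein_chd: list[MRFit],
    source_gwas: dict[str, str] | None = None,
) -> list[TriangleRecord]:
    """Join the three screened layers into triangle records.

    For every protein-metabolite pair surviving layer 2 whose metabolite
    survived layer 1 and whose protein survived layer 3, one record is
    emitted with the concordance flag. Pairs whose effects include a
    zero are excluded (indeterminate direction). Unique proteins should
    be counted once for reporting even when concordant via several
    metabolites.
    """
    mc = {f.exposure_id: f for f in metabolite_chd}
    pc = {f.exposure_id: f for f in protein_chd}
    records: list[TriangleRecord] = []
    for fit in protein_metabolite:
        metab, prot = fit.outcome_id, fit.exposure_id
        if metab not in mc or prot not in pc:
            continue
        t_pm, t_mc, t_pc = fit.slope, mc[metab].slope, pc[prot].slope
        if t_pm == 0 or t_mc == 0 or t_pc == 0:
            continue
        records.append(TriangleRecord(
            protein_id=prot,
            metabolite_id=metab,
            theta_pm=t_pm, theta_mc=t_mc, theta_pc=t_pc,
            p_pm=fit.pval, p_mc=mc[metab].pval, p_pc=pc[prot].pval,
            concordant=concordance(t_pm, t_mc, t_pc),
            source_gwas=(source_gwas or {}).get(prot, ""),
        ))
    return records


def concordant_proteins(records: list[TriangleRecord]) -> list[str]:
    """Unique proteins with at least one concordant triangle, sorted."""
    return sorted({r.protein_id for r in records if r.concordant})


def triangles_to_table(records: list[TriangleRecord]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in records])


def replicate(
    primary: dict[str, MRFit],
    secondary: dict[str, MRFit],
    overlap: list[str],
) -> pd.DataFrame:
    """Cross-GWAS replication flags for proteins measured in two studies.

    ``overlap`` lists the proteins available in more than one study; its
    length sets the strict Bonferroni threshold 0.05 / n_overlap.
    Nominal replication requires secondary p <= 0.05 with matching
    effect direction; strict replication uses the Bonferroni threshold.
    Proteins absent from the secondary study are flagged not_testable.
    """
    n_overlap = len(overlap)
    if n_overlap == 0:
        raise ValueError("empty overlap list")
    strict_threshold = 0.05 / n_overlap
    rows = []
    for prot in overlap:
        prim = primary.get(prot)
        sec = secondary.get(prot)
        if prim is None or sec is None:
            rows.append({
                "protein_id": prot, "nominal": False, "strict": False,
                "direction_agrees": False, "status": "not_testable",
            })
            continue
        same_sign = np.sign(prim.slope) == np.sign(sec.slope) != 0
        rows.append({
            "protein_id": prot,
            "nominal": bool(sec.pval <= 0.05 and same_sign),
            "strict": bool(sec.pval <= strict_threshold and same_sign),
            "direction_agrees": bool(same_sign),
            "status": "tested",
        })
    out = pd.DataFrame(rows)
    out.attrs["strict_threshold"] = strict_threshold
    return out


def choose_largest_gwas(protein_id: str,
                        studies: list[tuple[str, int]]) -> str:
    """Pick the study with the largest sample size for a protein.

    Ties break to the lexicographically smallest study id (deterministic
    and logged by the caller).
    """
    if not studies:
        raise ValueError(f"no studies supplied for {protein_id}")
    return min(studies, key=lambda s: (-s[1], s[0]))[0]
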