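"""Over-representation analysis and druggability annotation.

ORA asks whether a hit list (e.g. the prioritised proteins) overlaps a
predefined set (a pathway, a metabolite class) more than chance given a
fixed background universe, via the upper-tail hypergeometric probability
P(X >= k) with N = |universe|, K = |set within universe|, n = |hits|,
k = |hits within set|. The same machinery serves protein pathway sets
(background: all proteins in the considered GWAS) and metabolite sets
(background: a supplied reference list of urine metabolites). BH
correction across sets at FDR 0.05.

Druggability is a static-table join: proteins targeted by an approved
drug are "drugged", by a developmental compound "druggable", and
everything else "not_yet_druggable".
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd
from scipy import stats

from .tissue import bh_adjust

DRUG_STATUSES = ("drugged", "druggable", "not_yet_druggable")


@dataclass
class GeneSetCollection:
    """Named identifier sets plus the background universe they are tested in."""

    sets: dict[str, list[str]]
    universe: list[str]

    def __post_init__(self) -> None:
        self.universe = sorted(set(self.universe))
        if not self.universe:
            raise ValueError("empty universe")


@dataclass
class ORAResult:
    set_name: str
    overlap_k: int
    set_size_K: int
    hits_n: int
    universe_N: int
    pval: float
    qval: float | None = None
    significant: bool | None = None


@dataclass
class DrugAnnotation:
    protein_id: str
    status: str
    drugs: list[str] = field(default_factory=list)
    cardiac_indication: bool = False
    cardiac_side_effect: bool = False

    def __post_init__(self) -> None:
        if self.status not in DRUG_STATUSES:
            raise ValueError(f"unknown druggability status {self.status!r}")
        if self.status == "drugged" and not self.drugs:
            raise ValueError("drugged proteins must list at least one drug")


def ora_test(hits: set[str], geneset: set[str], universe: set[str],
             set_name: str = "") -> ORAResult:
    """Upper-tail hypergeometric over-representation test.

    Members outside the universe are ignored on both sides; hits must be
    drawn from the universe. P(X >= k) includes k itself, so a zero
    overlap gives p = 1.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    hits = set(hits) & universe
    geneset = set(geneset) & universe
    N, K, n = len(universe), len(geneset), len(hits)
    k = len(hits & geneset)
    # sf(k-1) = P(X >= k) for the hypergeometric(N, K, n) draw
    pval = float(min(1.0, stats.hypergeom.sf(k - 1, N, K, n)))
    return ORAResult(set_name, k, K, n, N, pval)


def ora_collection(hits: set[str], collection: GeneSetCollection,
                   fdr: float = 0.05) -> list[ORAResult]:
    """ORA for every non-empty set in a collection, BH-corrected at ``fdr``.

    Empty sets (after intersection with the universe) are skipped.
    Results are sorted by q then p then set name.
    """
    universe = set(collection.universe)
    results = []
    for name, members in collection.sets.items():
        if not set(members) & universe:
            continue
        results.append(ora_test(set(hits), set(members), universe, name))
    if results:
        qvals, sig = bh_adjust([r.pval for r in results], fdr)
        for res, q, s in zip(results, qvals, sig):
            res.qval = float(q)
            res.significant = bool(s)
        results.sort(key=lambda r: (r.qval, r.pval, r.set_name))
    return results


def ora_to_table(results: list[ORAResult]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in results])


def classify_druggability(proteins: list[str],
                          table: pd.DataFrame) -> list[DrugAnnotation]:
    """Join proteins against a static druggability table.

    Proteins absent from the table are not_yet_druggable; duplicate rows
    for one protein are merged with the union of their drug lists (and
    the most advanced status).
    """
    rank = {s: i for i, s in enumerate(DRUG_STATUSES)}
    by_protein: dict[str, DrugAnnotation] = {}
    for row in table.itertuples(index=False):
        drugs = [d for d in str(row.drugs).split(";") if d]
        ann = DrugAnnotation(
            protein_id=row.protein_id,
            status=row.status,
            drugs=drugs,
            cardiac_indication=str(row.cardiac_indication).lower() == "yes",
            cardiac_side_effect=str(row.cardiac_side_effect).lower() == "yes",
        )
        prev = by_protein.get(ann.protein_id)
        if prev is None:
            by_protein[ann.protein_id] = ann
        else:
            merged_status = min(prev.status, ann.status, key=rank.__getitem__)
            prev.drugs = sorted(set(prev.drugs) | set(ann.drugs))
            prev.status = merged_status
            prev.cardiac_indication |= ann.cardiac_indication
            prev.cardiac_side_effect |= ann.cardiac_side_effect
    out = []
    for prot in proteins:
        out.append(by_protein.get(prot) or DrugAnnotation(prot, "not_yet_druggable"))
    return out


def druggability_counts(annotations: list[DrugAnnotation]) -> dict[str, int]:
    """Counts per status, always reporting all three statuses."""
    counts = {s: 0 for s in DRUG_STATUSES}
    for ann in annotations:
        counts[ann.status] += 1
    return counts
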