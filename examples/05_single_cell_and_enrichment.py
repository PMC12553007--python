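"""Cell-type enrichment and pathway over-representation.

Simulates a labelled plaque single-cell matrix with one gene planted as
a smooth-muscle-cell marker, tests it one-vs-rest across cell types and
broad clusters, then runs a hypergeometric over-representation analysis
of a hit list against a background universe.
"""

from mrtriangle import (GeneSetCollection, ora_collection,
                        simulate_single_cell, wilcoxon_one_vs_rest)
from mrtriangle.pipeline import DEFAULT_CELL_PROPS

counts, ann = simulate_single_cell(
    2000, DEFAULT_CELL_PROPS, {"ATP1B2": "SMCs"}, fold=8.0, seed=5)

print("one-vs-rest Wilcoxon for ATP1B2:")
for group in ("SMCs", "T_cells", "structural", "innate_immune"):
    res = wilcoxon_one_vs_rest(counts, ann, "ATP1B2", group)
    print(f"  {group:15s} direction={res.direction:6s} p={res.pval:.2e} "
          f"{'*' if res.significant else ''}")

universe = [f"P{i:03d}" for i in range(100)]
hits = set(universe[:8])
sets = {"planted_pathway": universe[:10],
        "unrelated_pathway": universe[50:70]}
print()
print("over-representation against a 100-protein universe:")
for res in ora_collection(hits, GeneSetCollection(sets, universe), 0.05):
    print(f"  {res.set_name:20s} k={res.overlap_k}/{res.set_size_K} "
          f"p={res.pval:.2e} q={res.qval:.2e}")
print()
print("The SMC marker is 'higher' only in SMCs (and its structural")
print("cluster); the planted pathway captures 8 of 8 testable hits and")
print("dominates the ranking.")
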