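"""Plaque PVI associations, BH, subgroup/interaction, Wilcoxon DE."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from mrtriangle import (
    bh_adjust,
    pvi_association,
    simulate_plaque_table,
    simulate_single_cell,
    subgroup_and_interaction,
    wilcoxon_one_vs_rest,
)
from mrtriangle.tissue import associate_all, de_all, enrichment_matrix


def table_from(pvi, expr, feature="F"):
    n = len(pvi)
    cov = pd.DataFrame({
        "pvi": pvi,
        "sex": ["M"] * (n // 2) + ["F"] * (n - n // 2),
        "age": np.linspace(50, 80, n),
        "diabetes": ["no"] * n,
    }, index=pd.Index([f"S{i}" for i in range(n)], name="sample_id"))
    values = pd.DataFrame({feature: expr}, index=cov.index)
    return values, cov


class TestPviAssociation:
    def test_noiseless_line_recovers_slope(self):
        pvi = np.linspace(-2, 2, 12)
        values, cov = table_from(pvi, 3 + 2 * pvi)
        res = pvi_association(values, cov, "F")
        assert res.beta == pytest.approx(2.0, abs=1e-12)
        assert res.pval < 1e-12

    def test_matches_closed_form_ols_oracle(self, rng):
        pvi = rng.standard_normal(12)
        y = 1.0 + 0.7 * pvi + rng.normal(0, 0.5, 12)
        values, cov = table_from(pvi, y)
        res = pvi_association(values, cov, "F")
        xc = pvi - pvi.mean()
        oracle = float(xc @ (y - y.mean())) / float(xc @ xc)
        assert res.beta == pytest.approx(oracle, rel=1e-12)
        # independent implementation: statsmodels OLS
        import statsmodels.api as sm
        ols = sm.OLS(y, sm.add_constant(pvi)).fit()
        assert res.beta == pytest.approx(ols.params[1], rel=1e-10)
        assert res.se == pytest.approx(ols.bse[1], rel=1e-10)
        assert res.pval == pytest.approx(ols.pvalues[1], rel=1e-8)

    def test_null_rejection_rate_near_nominal(self):
        hits = 0
        reps = 500
        rng = np.random.default_rng(1)
        for _ in range(reps):
            pvi = rng.standard_normal(30)
            values, cov = table_from(pvi, rng.standard_normal(30))
            hits += pvi_association(values, cov, "F").pval < 0.05
        assert abs(hits / reps - 0.05) < 3 * np.sqrt(0.05 * 0.95 / reps)

    def test_scaling_pvi_rescales_slope(self, rng):
        pvi = rng.standard_normal(20)
        y = 0.5 * pvi + rng.normal(0, 0.1, 20)
        v1, c1 = table_from(pvi, y)
        v2, c2 = table_from(3.0 * pvi, y)
        b1 = pvi_association(v1, c1, "F").beta
        b2 = pvi_association(v2, c2, "F").beta
        assert b2 == pytest.approx(b1 / 3.0, rel=1e-10)

    def test_constant_feature_not_detected(self):
        values, cov = table_from(np.linspace(0, 1, 12), np.full(12, 5.0))
        with pytest.raises(ValueError, match="not_detected"):
            pvi_association(values, cov, "F")


def bh_stepup_oracle(pvals, fdr):
    """Brute force: largest k with p_(k) <= k * fdr / m; reject those."""
    m = len(pvals)
    order = np.argsort(pvals)
    k_star = 0
    for k in range(1, m + 1):
        if pvals[order[k - 1]] <= k * fdr / m:
            k_star = k
    reject = np.zeros(m, dtype=bool)
    reject[order[:k_star]] = True
    return reject


class TestBhAdjust:
    def test_four_small_pvalues_all_pass(self):
        qvals, sig = bh_adjust([0.01, 0.02, 0.03, 0.04], fdr=0.1)
        assert sig.all()

    def test_all_ones_none_significant(self):
        _, sig = bh_adjust([1.0, 1.0, 1.0], fdr=0.1)
        assert not sig.any()

    def test_single_pvalue_passthrough(self):
        qvals, sig = bh_adjust([0.05], fdr=0.1)
        assert qvals[0] == pytest.approx(0.05)
        assert sig[0]

    @given(st.integers(0, 200))
    def test_matches_stepup_oracle_on_random_vectors(self, seed):
        rng = np.random.default_rng(seed)
        pvals = rng.uniform(1e-6, 1, int(rng.integers(1, 40)))
        _, sig = bh_adjust(pvals, fdr=0.1)
        np.testing.assert_array_equal(sig, bh_stepup_oracle(pvals, 0.1))

    def test_discoveries_monotone_in_fdr(self, rng):
        pvals = rng.uniform(0, 0.3, 25)
        _, low = bh_adjust(pvals, fdr=0.05)
        _, high = bh_adjust(pvals, fdr=0.2)
        assert set(np.where(low)[0]) <= set(np.where(high)[0])

    def test_empty_input_empty_output(self):
        qvals, sig = bh_adjust([], fdr=0.1)
        assert len(qvals) == 0 and len(sig) == 0


class TestSubgroupInteraction:
    def build(self, slope_m, slope_f, n=60, noise=0.05, seed=0):
        rng = np.random.default_rng(seed)
        pvi = rng.standard_normal(n)
        sex = np.array(["M"] * (n // 2) + ["F"] * (n - n // 2))
        slope = np.where(sex == "M", slope_m, slope_f)
        y = slope * pvi + rng.normal(0, noise, n)
        cov = pd.DataFrame({
            "pvi": pvi, "sex": sex,
            "age": rng.uniform(50, 80, n),
            "diabetes": rng.choice(["yes", "no"], n),
        }, index=pd.Index([f"S{i}" for i in range(n)], name="sample_id"))
        values = pd.DataFrame({"F": y}, index=cov.index)
        return values, cov

    def test_differing_slopes_flagged_by_interaction(self):
        values, cov = self.build(0.0, 2.0, noise=0.1)
        res = subgroup_and_interaction(values, cov, "F", "sex")
        assert res.interaction_p["pvi:sex"] < 1e-6
        assert res.subgroup_betas["F"][0] == pytest.approx(2.0, abs=0.1)
        assert res.subgroup_betas["M"][0] == pytest.approx(0.0, abs=0.1)

    def test_null_interaction_p_uniform(self):
        pvals = [subgroup_and_interaction(
            *self.build(1.0, 1.0, noise=1.0, seed=s), "F", "sex"
        ).interaction_p["pvi:sex"] for s in range(200)]
        rate = np.mean(np.array(pvals) < 0.05)
        assert abs(rate - 0.05) < 3 * np.sqrt(0.05 * 0.95 / 200)

    def test_age_dichotomised_at_65(self):
        values, cov = self.build(1.0, 1.0)
        cov["age"] = np.r_[np.full(30, 64.9), np.full(30, 65.0)]
        res = subgroup_and_interaction(values, cov, "F", "age65")
        assert set(res.subgroup_betas) == {"<65", ">=65"}

    def test_single_stratum_rejected(self):
        values, cov = self.build(1.0, 1.0)
        cov["sex"] = "M"
        with pytest.raises(ValueError, match="single_stratum"):
            subgroup_and_interaction(values, cov, "F", "sex")


def exact_rank_sum_p(x, y):
    """Exhaustive two-sided rank-sum p by enumerating all labelings."""
    pooled = np.concatenate([x, y])
    n1 = len(x)
    ranks = pd.Series(pooled).rank().to_numpy()
    observed = ranks[:n1].sum()
    mean = ranks.sum() * n1 / len(pooled)
    stats = [sum(ranks[list(c)]) for c in
             itertools.combinations(range(len(pooled)), n1)]
    stats = np.array(stats)
    return float(np.mean(np.abs(stats - mean) >= abs(observed - mean) - 1e-12))


class TestWilcoxonOneVsRest:
    def cells(self, x, y):
        counts = pd.DataFrame({"G": np.concatenate([x, y])})
        counts.index = pd.Index([f"c{i}" for i in range(len(counts))],
                                name="cell_id")
        ann = pd.DataFrame({
            "cell_type": ["SMCs"] * len(x) + ["T_cells"] * len(y),
            "cluster": ["structural"] * len(x) + ["adaptive_immune"] * len(y),
        }, index=counts.index)
        return counts, ann

    def test_separated_groups_exact_p(self):
        counts, ann = self.cells([1, 2, 3], [10, 11, 12])
        res = wilcoxon_one_vs_rest(counts, ann, "G", "SMCs", method="exact")
        assert res.pval == pytest.approx(0.10)
        assert res.direction == "lower"

    def test_complete_ties_p_one(self):
        counts, ann = self.cells([5.0, 5.0, 5.0], [5.0, 5.0, 5.0])
        res = wilcoxon_one_vs_rest(counts, ann, "G", "SMCs")
        assert res.pval == 1.0 and res.direction == "undefined"

    @given(st.integers(0, 60))
    def test_normal_approximation_close_to_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n1, n2 = int(rng.integers(3, 9)), int(rng.integers(3, 9))
        x = rng.normal(0, 1, n1).round(3)  # tie-free with prob ~1
        y = rng.normal(0.5, 1, n2).round(3)
        counts, ann = self.cells(x, y)
        approx = wilcoxon_one_vs_rest(counts, ann, "G", "SMCs").pval
        assert abs(approx - exact_rank_sum_p(x, y)) < 0.02

    def test_cluster_level_grouping(self):
        counts, ann = self.cells([9, 9, 9, 8], [1, 1, 2, 1])
        res = wilcoxon_one_vs_rest(counts, ann, "G", "structural")
        assert res.direction == "higher"

    def test_single_type_marker_flags_exactly_one_type(self):
        props = {"SMCs": 0.3, "T_cells": 0.3, "monocytes": 0.2,
                 "foam_cells": 0.2}
        counts, ann = simulate_single_cell(800, props, {"MK": "SMCs"},
                                           fold=12.0, seed=3)
        higher = [g for g in props
                  if (r := wilcoxon_one_vs_rest(counts, ann, "MK", g)
                      ).significant and r.direction == "higher"]
        assert higher == ["SMCs"]

    def test_tiny_group_rejected(self):
        counts, ann = self.cells([1, 2], [3, 4, 5])
        with pytest.raises(ValueError):
            wilcoxon_one_vs_rest(counts, ann, "G", "SMCs")


class TestEnrichmentMatrix:
    def inputs(self):
        from mrtriangle import TriangleRecord
        triangles = [TriangleRecord("P1", "M1", 0.2, 0.1, 0.02,
                                    1e-9, 1e-9, 1e-9, True)]
        values, cov = simulate_plaque_table(30, {"P1": 2.0}, 0.2, seed=5)
        assoc = {"protein": associate_all(values, cov), "mrna": []}
        counts, ann = simulate_single_cell(
            300, {"SMCs": 0.5, "T_cells": 0.5}, {"P1": "SMCs"}, seed=5)
        de = de_all(counts, ann, "cell_type")
        return de, assoc, triangles

    def test_populated_run_shapes_and_content(self):
        de, assoc, triangles = self.inputs()
        matrix = enrichment_matrix(de, assoc, triangles)
        assert list(matrix.columns) == ["P1"]
        assert matrix.loc["chd_effect", "P1"] == "increasing"
        assert matrix.loc["cell:SMCs", "P1"] == "enriched"
        assert matrix.loc["mrna_pvi", "P1"] == "NA"

    def test_regeneration_is_deterministic(self):
        de, assoc, triangles = self.inputs()
        m1 = enrichment_matrix(de, assoc, triangles)
        m2 = enrichment_matrix(de, assoc, triangles)
        pd.testing.assert_frame_equal(m1, m2)

    def test_protein_without_cell_data_gets_na(self):
        de, assoc, triangles = self.inputs()
        de = [r for r in de if r.gene_id != "P1"]
        matrix = enrichment_matrix(de, assoc, triangles)
        assert matrix.loc["cell:SMCs", "P1"] == "NA"
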