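"""Instrument selection: harmonisation, filters, clumping."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from mrtriangle import (
    InstrumentConfig,
    LDMatrix,
    SummaryStatSet,
    cis_window,
    clump,
    f_statistic,
    harmonise,
    select_instruments,
)


def sumstats(rows, trait="T", trait_class="metabolite", locus=None):
    df = pd.DataFrame(rows, columns=[
        "variant_id", "chrom", "pos", "effect_allele", "other_allele",
        "eaf", "beta", "se", "pval", "n"])
    return SummaryStatSet(trait, trait_class, df, locus)


def variant(vid, beta=0.1, se=0.01, eaf=0.3, pval=1e-8, chrom="1",
            pos=1000, ea="A", oa="G", n=10000):
    return (vid, chrom, pos, ea, oa, eaf, beta, se, pval, n)


class TestFStatistic:
    @pytest.mark.parametrize("beta,se,expected", [
        (0.1, 0.02, 25.0),
        (0.0, 0.1, 0.0),
        (-0.3, 0.1, 9.0),
    ])
    def test_squared_wald_ratio(self, beta, se, expected):
        assert f_statistic(beta, se) == pytest.approx(expected)

    def test_nonpositive_se_rejected(self):
        with pytest.raises(ValueError):
            f_statistic(0.1, 0.0)

    def test_boundary_f_exactly_at_threshold_is_retained(self):
        # "at least 24" is a closed bound: F == f_min keeps the variant.
        # The threshold is set to the variant's own computed F so the
        # comparison is exact in floating point.
        beta, se = np.sqrt(24) * 0.01, 0.01
        exp = sumstats([variant(f"rs{i}", beta=beta, se=se, pos=1000 + i)
                        for i in range(3)])
        out = sumstats([variant(f"rs{i}", pos=1000 + i) for i in range(3)])
        ld = LDMatrix([f"rs{i}" for i in range(3)], np.eye(3))
        f_exact = f_statistic(beta, se)
        assert f_exact == pytest.approx(24.0)
        instr = select_instruments(exp, out, ld, InstrumentConfig(f_min=f_exact))
        assert len(instr) == 3
        just_above = select_instruments(exp, out, ld,
                                        InstrumentConfig(f_min=f_exact * (1 + 1e-12)))
        assert len(just_above) == 0


class TestCisWindow:
    locus = ("1", 1000, 2000)

    def make(self, pos, chrom="1"):
        return sumstats([variant("rs1", chrom=chrom, pos=pos)],
                        trait="P", trait_class="protein", locus=self.locus)

    def test_inside_gene_minus_window_retained(self):
        prot = self.make(900)
        assert len(cis_window(prot, 200_000)) == 1

    def test_one_bp_beyond_closed_bound_dropped(self):
        prot = self.make(202_001)
        assert len(cis_window(prot, 200_000)) == 0
        assert len(cis_window(self.make(202_000), 200_000)) == 1

    def test_other_chromosome_dropped(self):
        prot = self.make(1500, chrom="2")
        assert len(cis_window(prot, 200_000)) == 0

    def test_missing_locus_rejected(self):
        met = sumstats([variant("rs1")])
        with pytest.raises(ValueError):
            cis_window(met)


def greedy_clump_oracle(pvals, ids, r, r2_max):
    """Brute-force greedy reference: repeatedly take the best remaining
    variant by (p, id) and delete everything correlated beyond r2_max."""
    remaining = sorted(range(len(ids)), key=lambda i: (pvals[i], ids[i]))
    kept = []
    while remaining:
        best = remaining.pop(0)
        kept.append(ids[best])
        remaining = [j for j in remaining if r[best][j] ** 2 <= r2_max]
    return kept


class TestClump:
    def test_single_variant_retained(self):
        df = pd.DataFrame({"variant_id": ["rs1"], "pval": [0.5]})
        ld = LDMatrix(["rs1"], np.eye(1))
        assert clump(df, ld) == ["rs1"]

    def test_correlated_pair_keeps_smaller_p(self):
        df = pd.DataFrame({"variant_id": ["rs1", "rs2"],
                           "pval": [0.01, 0.001]})
        ld = LDMatrix(["rs1", "rs2"], np.array([[1, 0.6], [0.6, 1]]))
        assert clump(df, ld, 0.30) == ["rs2"]  # r^2 = 0.36 > 0.30

    @given(st.integers(0, 500))
    def test_matches_exhaustive_greedy_oracle(self, seed):
        rng = np.random.default_rng(seed)
        k = int(rng.integers(2, 10))
        ids = [f"rs{i:02d}" for i in range(k)]
        a = rng.uniform(-1, 1, (k, k))
        r = np.clip((a + a.T) / 2, -0.99, 0.99)
        np.fill_diagonal(r, 1.0)
        pvals = rng.uniform(0, 1, k)
        df = pd.DataFrame({"variant_id": ids, "pval": pvals})
        ld = LDMatrix(ids, r)
        assert clump(df, ld, 0.30) == greedy_clump_oracle(
            pvals, ids, r, 0.30)

    def test_invariant_to_input_ordering(self, rng):
        k = 8
        ids = [f"rs{i}" for i in range(k)]
        a = rng.uniform(-0.8, 0.8, (k, k))
        r = (a + a.T) / 2
        np.fill_diagonal(r, 1.0)
        pvals = rng.uniform(0, 1, k)
        df = pd.DataFrame({"variant_id": ids, "pval": pvals})
        ld = LDMatrix(ids, r)
        base = clump(df, ld, 0.3)
        shuffled = df.sample(frac=1, random_state=1)
        assert clump(shuffled, ld, 0.3) == base

    def test_variant_missing_from_ld_rejected(self):
        df = pd.DataFrame({"variant_id": ["rs1", "rsX"], "pval": [0.1, 0.2]})
        ld = LDMatrix(["rs1"], np.eye(1))
        with pytest.raises(KeyError):
            clump(df, ld)


class TestHarmonise:
    def test_matching_alleles_unchanged(self):
        exp = sumstats([variant("rs1", beta=0.2)])
        out = sumstats([variant("rs1", beta=-0.05)], trait="O",
                       trait_class="disease")
        quad, log = harmonise(exp, out)
        assert quad.loc[0, "by"] == pytest.approx(-0.05)

    def test_swapped_alleles_flip_outcome_beta(self):
        exp = sumstats([variant("rs1", ea="A", oa="G", beta=0.2)])
        out = sumstats([variant("rs1", ea="G", oa="A", beta=-0.05, eaf=0.7)],
                       trait="O", trait_class="disease")
        quad, _ = harmonise(exp, out)
        assert quad.loc[0, "by"] == pytest.approx(0.05)

    def test_incompatible_alleles_dropped_and_logged(self):
        exp = sumstats([variant("rs1", ea="A", oa="G")])
        out = sumstats([variant("rs1", ea="C", oa="T")], trait="O",
                       trait_class="disease")
        quad, log = harmonise(exp, out)
        assert len(quad) == 0
        assert ("rs1", "harmonise", "allele_mismatch") in log

    def test_no_overlap_returns_empty_with_log(self):
        exp = sumstats([variant("rs1")])
        out = sumstats([variant("rs2")], trait="O", trait_class="disease")
        quad, log = harmonise(exp, out)
        assert len(quad) == 0
        assert ("rs1", "harmonise", "no_overlap") in log

    def test_idempotent_after_alignment(self):
        exp = sumstats([variant("rs1", ea="A", oa="G", beta=0.2),
                        variant("rs2", ea="C", oa="T", beta=-0.1, pos=1100)])
        out = sumstats([variant("rs1", ea="G", oa="A", beta=0.03, eaf=0.6),
                        variant("rs2", ea="C", oa="T", beta=0.02, pos=1100)],
                       trait="O", trait_class="disease")
        quad1, _ = harmonise(exp, out)
        # re-express the outcome on the exposure's alleles and re-harmonise
        aligned = exp.records.copy()
        aligned["beta"] = quad1["by"].to_numpy()
        aligned["se"] = quad1["se_y"].to_numpy()
        out2 = SummaryStatSet("O", "disease", aligned)
        quad2, _ = harmonise(exp, out2)
        np.testing.assert_allclose(quad1["by"], quad2["by"])


class TestSelectInstruments:
    def build(self, rows):
        exp = sumstats(rows)
        out = sumstats([variant(r[0], pos=r[2], ea=r[3], oa=r[4])
                        for r in rows], trait="O", trait_class="disease")
        ids = [r[0] for r in rows]
        return exp, out, LDMatrix(ids, np.eye(len(ids)))

    def test_rare_variant_excluded_as_maf(self):
        exp, out, ld = self.build([variant("rs1", eaf=0.005),
                                   variant("rs2", pos=1100)])
        instr = select_instruments(exp, out, ld)
        assert list(instr.variants["variant_id"]) == ["rs2"]
        assert ("rs1", "maf", "maf") in instr.exclusion_log

    def test_weak_instrument_excluded(self):
        exp, out, ld = self.build([
            variant("rs1", beta=np.sqrt(20) * 0.01, se=0.01),  # F = 20
            variant("rs2", pos=1100)])
        instr = select_instruments(exp, out, ld)
        assert list(instr.variants["variant_id"]) == ["rs2"]
        assert ("rs1", "f_filter", "weak") in instr.exclusion_log

    def test_all_pass_filters_retained(self):
        rows = [variant(f"rs{i}", pos=1000 + i, pval=1e-8 * (i + 1))
                for i in range(8)]
        exp, out, ld = self.build(rows)
        instr = select_instruments(exp, out, ld)
        assert len(instr) == 8

    def test_retained_count_monotone_in_thresholds(self, rng):
        rows = [variant(f"rs{i}", beta=float(rng.uniform(0.02, 0.2)),
                        eaf=float(rng.uniform(0.005, 0.5)), pos=1000 + i)
                for i in range(20)]
        exp, out, ld = self.build(rows)
        counts_f = [len(select_instruments(exp, out, ld,
                                           InstrumentConfig(f_min=f)))
                    for f in (0, 24, 100, 400)]
        assert counts_f == sorted(counts_f, reverse=True)
        counts_maf = [len(select_instruments(exp, out, ld,
                                             InstrumentConfig(maf_min=m)))
                      for m in (0.001, 0.01, 0.1, 0.3)]
        assert counts_maf == sorted(counts_maf, reverse=True)
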