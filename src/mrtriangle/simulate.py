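"""Synthetic-data generators with known ground truth.

Every pipeline input can be produced here at the summary level, so each
downstream stage is testable without any external GWAS or biobank data:

* block-structured LD matrices (``simulate_ld_matrix``);
* GWAS summary-statistic triplets carrying a true causal chain
  protein -> metabolite -> disease with configurable horizontal
  pleiotropy (``simulate_gwas_chain``);
* plaque expression tables linear in a vulnerability index
  (``simulate_plaque_table``);
* labelled single-cell count matrices with planted cell-type
  enrichment (``simulate_single_cell``).

Generation happens directly on the summary scale (no individual-level
genotypes): per-variant effect estimates are the true marginal effects
plus correlated sampling noise with covariance ``S C S``, where ``C`` is
the LD correlation and ``S = diag(se)`` with ``se = 1/sqrt(2 maf (1-maf) n)``
for a unit-variance trait. This is the standard construction for testing
summary-statistic MR methods and reproduces the F-statistic/sample-size
relationship the instrument filters depend on.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import LDMatrix, SummaryStatSet

# The 13 plaque cell types and their broad clusters. The mapping ships as
# data so it can be overridden from a config file.
CELL_TYPES = [
    "dendritic_cells",
    "endothelial_cells_I",
    "endothelial_cells_II",
    "foam_cells",
    "inflammatory_macrophages",
    "mast_cells",
    "memory_B_cells",
    "monocytes",
    "NK_cells",
    "plasma_B_cells",
    "resident_macrophages",
    "SMCs",
    "T_cells",
]

CLUSTER_MAP = {
    "endothelial_cells_I": "structural",
    "endothelial_cells_II": "structural",
    "SMCs": "structural",
    "dendritic_cells": "innate_immune",
    "foam_cells": "innate_immune",
    "inflammatory_macrophages": "innate_immune",
    "resident_macrophages": "innate_immune",
    "mast_cells": "innate_immune",
    "monocytes": "innate_immune",
    "NK_cells": "innate_immune",
    "memory_B_cells": "adaptive_immune",
    "plasma_B_cells": "adaptive_immune",
    "T_cells": "adaptive_immune",
}

_TINY = np.finfo(float).tiny


@dataclass
class SimulationConfig:
    """Generating parameters for one protein -> metabolite -> disease chain.

    Defaults mirror the scale of the real data layers: cis loci of 25
    variants in blocks of 5 with within-block r = 0.3, exposure GWAS of
    35 000 samples (the largest protein study's order of magnitude), an
    outcome layer with effective n = 180 000, and cis effects spanning
    an order of magnitude (|beta| in 0.1-0.4 SD per allele, the spread
    of a lead signal plus secondary signals) so instruments clear the
    F >= 24 filter while instrument strength varies enough to separate
    the IVW and Egger mean models.
    """

    n_variants_per_locus: int = 25
    ld_block_correlation: float = 0.3
    block_size: int = 5
    maf_range: tuple[float, float] = (0.05, 0.5)
    n_exposure_samples: int = 35_000
    n_outcome_samples: int = 180_000
    theta_pm: float = 0.3          # true protein -> metabolite effect (SD/SD)
    theta_mc: float = 0.2          # true metabolite -> disease effect (log-odds/SD)
    theta_pc: float = 0.0          # direct protein -> disease effect (log-odds/SD)
    pleiotropy_mode: str = "none"  # none | balanced | directional
    pleiotropy_sd: float = 0.03
    effect_magnitude_range: tuple[float, float] = (0.1, 0.4)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_variants_per_locus < 1:
            raise ValueError("n_variants_per_locus must be >= 1")
        if self.block_size < 1:
            raise ValueError("block_size must be >= 1")
        if not 0 <= self.ld_block_correlation < 1:
            raise ValueError("ld_block_correlation must lie in [0, 1)")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must satisfy 0 < lo <= hi <= 0.5")
        if min(self.n_exposure_samples, self.n_outcome_samples) < 1:
            raise ValueError("sample sizes must be >= 1")
        if self.pleiotropy_mode not in ("none", "balanced", "directional"):
            raise ValueError(f"unknown pleiotropy mode {self.pleiotropy_mode!r}")
        if self.pleiotropy_sd < 0:
            raise ValueError("pleiotropy_sd must be >= 0")

    @property
    def theta_pc_total(self) -> float:
        """Total protein -> disease effect: mediated plus direct path."""
        return self.theta_pm * self.theta_mc + self.theta_pc


@dataclass
class TruthRecord:
    """Ground-truth generating parameters of one simulated chain."""

    protein_id: str
    metabolite_id: str
    outcome_id: str
    theta_pm: float
    theta_mc: float
    theta_pc: float
    theta_pc_total: float
    pleiotropy_mode: str
    pleiotropy_sd: float
    n_variants: int
    seed: int

    def to_dict(self) -> dict:
        return dict(self.__dict__)


@dataclass
class ChainData:
    """Output of :func:`simulate_gwas_chain`: three GWAS layers + truth."""

    protein: SummaryStatSet
    metabolite: SummaryStatSet
    outcome: SummaryStatSet
    ld: LDMatrix
    truth: TruthRecord


def simulate_ld_matrix(
    n_variants: int,
    block_sizes: list[int],
    within_block_r: float,
    seed: int = 0,
    variant_ids: list[str] | None = None,
) -> LDMatrix:
    """Build a block-constant LD correlation matrix.

    Within each block every off-diagonal entry equals ``within_block_r``;
    across blocks correlation is zero. The construction is deterministic
    (``seed`` is accepted for interface symmetry with the other
    generators). A block-constant matrix with ``r > -1/(m-1)`` is
    positive semi-definite by construction; if numerical round-off still
    yields a negative eigenvalue, the minimal diagonal inflation
    ``(C + c I)/(1 + c)`` restoring PSD is applied and recorded on the
    returned object as ``.inflation``.
    """
    if n_variants < 1:
        raise ValueError("n_variants must be positive")
    if abs(within_block_r) >= 1:
        raise ValueError("|within_block_r| must be < 1")
    if sum(block_sizes) != n_variants:
        raise ValueError("block sizes must sum to n_variants")
    r = np.zeros((n_variants, n_variants))
    start = 0
    for size in block_sizes:
        block = np.full((size, size), within_block_r, dtype=float)
        np.fill_diagonal(block, 1.0)
        r[start : start + size, start : start + size] = block
        start += size
    inflation = 0.0
    min_eig = np.linalg.eigvalsh(r).min()
    if min_eig < 0:
        inflation = -min_eig + 1e-12
        r = (r + inflation * np.eye(n_variants)) / (1.0 + inflation)
    if variant_ids is None:
        variant_ids = [f"rs{i + 1:05d}" for i in range(n_variants)]
    ld = LDMatrix(variant_ids, r)
    ld.inflation = inflation  # type: ignore[attr-defined]
    return ld


def _default_blocks(n_variants: int, block_size: int) -> list[int]:
    blocks = [block_size] * (n_variants // block_size)
    if n_variants % block_size:
        blocks.append(n_variants % block_size)
    return blocks


def _pleiotropy(rng: np.random.Generator, mode: str, sd: float,
                orient: np.ndarray) -> np.ndarray:
    """Per-variant direct (horizontal) effects on a downstream trait.

    ``balanced`` draws are zero-mean and orientation-free. ``directional``
    draws have mean ``sd`` *relative to the exposure-increasing allele*
    (``orient`` holds the signs of the exposure effects): directional
    pleiotropy is only meaningful, and only detectable by MR-Egger's
    intercept, in a consistent variant orientation — with alleles
    oriented at random, a constant direct effect averages out.
    """
    m = len(orient)
    if mode == "none" or sd == 0:
        return np.zeros(m)
    if mode == "balanced":
        return rng.normal(0.0, sd, m)
    # common-direction direct effects: mean sd, spread sd/2
    return orient * rng.normal(sd, sd / 2, m)


def _correlated_noise(rng: np.random.Generator, chol: np.ndarray,
                      se: np.ndarray) -> np.ndarray:
    return se * (chol @ rng.standard_normal(chol.shape[0]))


def _pvals(beta: np.ndarray, se: np.ndarray) -> np.ndarray:
    p = 2.0 * stats.norm.sf(np.abs(beta) / se)
    return np.clip(p, _TINY, 1.0)


def simulate_gwas_chain(
    config: SimulationConfig,
    protein_id: str = "PROT1",
    metabolite_id: str = "MET1",
    outcome_id: str = "CHD",
    chrom: str = "1",
    gene_start: int = 1_000_000,
    gene_end: int = 1_020_000,
    swap_outcome_alleles: bool = True,
) -> ChainData:
    """Simulate one causal chain as three GWAS summary-statistic layers.

    True marginal variant effects on the protein are drawn with random
    sign and magnitude uniform in ``config.effect_magnitude_range``.
    Metabolite effects are ``theta_pm * bx`` plus pleiotropy; disease
    effects are ``theta_mc * bm + theta_pc * bx`` plus pleiotropy. Each
    layer receives independent LD-correlated sampling noise (the three
    GWAS come from non-overlapping samples). When
    ``swap_outcome_alleles`` is set, a random half of the outcome rows
    is reported on the opposite effect allele (beta negated, eaf
    reflected), which downstream harmonisation must undo.
    """
    rng = np.random.default_rng(config.seed)
    m = config.n_variants_per_locus
    ld = simulate_ld_matrix(
        m,
        _default_blocks(m, config.block_size),
        config.ld_block_correlation,
        variant_ids=[f"rs{protein_id}_{i + 1:04d}" for i in range(m)],
    )
    chol = np.linalg.cholesky(ld.r + 1e-10 * np.eye(m))

    maf = rng.uniform(*config.maf_range, m)
    pos = np.sort(rng.choice(np.arange(gene_start - 150_000, gene_end + 150_000),
                             size=m, replace=False))
    allele_pairs = np.array([["A", "G"], ["C", "T"], ["G", "A"], ["T", "C"]])
    pair_idx = rng.integers(0, len(allele_pairs), m)
    ea, oa = allele_pairs[pair_idx, 0], allele_pairs[pair_idx, 1]

    lo, hi = config.effect_magnitude_range
    bx_true = rng.choice([-1.0, 1.0], m) * rng.uniform(lo, hi, m)
    if np.allclose(bx_true, 0):
        raise ValueError("degenerate chain: all exposure effects are zero")
    orient = np.sign(bx_true)
    bm_true = config.theta_pm * bx_true + _pleiotropy(
        rng, config.pleiotropy_mode, config.pleiotropy_sd, orient
    )
    bc_true = (
        config.theta_mc * bm_true
        + config.theta_pc * bx_true
        + _pleiotropy(rng, config.pleiotropy_mode, config.pleiotropy_sd, orient)
    )

    se_x = 1.0 / np.sqrt(2 * maf * (1 - maf) * config.n_exposure_samples)
    se_m = 1.0 / np.sqrt(2 * maf * (1 - maf) * config.n_exposure_samples)
    se_c = 1.0 / np.sqrt(2 * maf * (1 - maf) * config.n_outcome_samples)

    bx = bx_true + _correlated_noise(rng, chol, se_x)
    bm = bm_true + _correlated_noise(rng, chol, se_m)
    bc = bc_true + _correlated_noise(rng, chol, se_c)

    def layer(beta, se, n, eaf, effect, other):
        return pd.DataFrame({
            "variant_id": ld.variant_ids,
            "chrom": chrom,
            "pos": pos,
            "effect_allele": effect,
            "other_allele": other,
            "eaf": eaf,
            "beta": beta,
            "se": se,
            "pval": _pvals(beta, se),
            "n": n,
        })

    prot_df = layer(bx, se_x, config.n_exposure_samples, maf, ea, oa)
    met_df = layer(bm, se_m, config.n_exposure_samples, maf, ea, oa)

    bc_rep, eaf_rep, ea_rep, oa_rep = bc.copy(), maf.copy(), ea.copy(), oa.copy()
    if swap_outcome_alleles and m > 1:
        flip = rng.random(m) < 0.5
        bc_rep[flip] = -bc_rep[flip]
        eaf_rep[flip] = 1 - eaf_rep[flip]
        ea_rep[flip], oa_rep[flip] = oa[flip], ea[flip]
    out_df = layer(bc_rep, se_c, config.n_outcome_samples, eaf_rep, ea_rep, oa_rep)

    locus = (chrom, gene_start, gene_end)
    truth = TruthRecord(
        protein_id, metabolite_id, outcome_id,
        config.theta_pm, config.theta_mc, config.theta_pc,
        config.theta_pc_total, config.pleiotropy_mode, config.pleiotropy_sd,
        m, config.seed,
    )
    return ChainData(
        protein=SummaryStatSet(protein_id, "protein", prot_df, locus),
        metabolite=SummaryStatSet(metabolite_id, "metabolite", met_df),
        outcome=SummaryStatSet(outcome_id, "disease", out_df),
        ld=ld,
        truth=truth,
    )


@dataclass
class ChainSpec:
    """Declarative description of one protein -> metabolite -> disease chain
    inside a multi-locus study (see :func:`simulate_study`)."""

    protein_id: str
    metabolite_id: str
    theta_pm: float
    theta_mc: float
    theta_pc: float = 0.0
    pleiotropy_mode: str = "none"
    pleiotropy_sd: float = 0.0

    @property
    def theta_pc_total(self) -> float:
        return self.theta_pm * self.theta_mc + self.theta_pc

    @property
    def expected_concordant(self) -> bool | None:
        """Concordance of the *measured* effect signs, or None when any
        layer's true effect is zero (sub-threshold chain)."""
        s_pm, s_mc, s_pc = (np.sign(self.theta_pm), np.sign(self.theta_mc),
                            np.sign(self.theta_pc_total))
        if 0 in (s_pm, s_mc, s_pc):
            return None
        return bool(s_pm * s_mc == s_pc)


@dataclass
class StudyData:
    """Output of :func:`simulate_study`: one full synthetic study."""

    proteins: dict[str, SummaryStatSet]
    metabolites: dict[str, SummaryStatSet]
    outcome: SummaryStatSet
    ld: LDMatrix
    chains: list[ChainSpec]
    truth: dict


def simulate_study(
    chains: list[ChainSpec],
    config: SimulationConfig | None = None,
    n_metabolite_samples: int = 3_000,
    seed: int = 0,
) -> StudyData:
    """Simulate a multi-locus study: one cis and one trans locus per chain.

    Each chain contributes two loci. The protein's cis locus carries the
    protein effects ``bx``; the metabolite there responds with
    ``theta_pm * bx`` and the disease with
    ``(theta_pm * theta_mc + theta_pc) * bx`` (mediated plus direct
    path). The metabolite's own trans locus carries direct metabolite
    effects of full magnitude, and the disease responds with
    ``theta_mc * b_trans``. Metabolite and disease summary statistics
    span every locus (with pure sampling noise off-signal), as a real
    genome-wide file would; each protein file is restricted to its cis
    locus.

    The metabolite GWAS sample size (default 3000, the order of the real
    urinary-metabolite study) makes cis-locus metabolite associations
    too weak for the F >= 24 filter while trans-locus instruments pass,
    so the genome-wide metabolite -> disease MR estimates ``theta_mc``
    from the metabolite's own genetic architecture — which is what lets
    a chain be genuinely discordant.
    """
    config = config or SimulationConfig()
    rng = np.random.default_rng(seed)
    m = config.n_variants_per_locus
    lo, hi = config.effect_magnitude_range

    ids_all: list[str] = []
    blocks_all: list[int] = []
    rows = []  # per-locus metadata
    for ci, chain in enumerate(chains):
        for kind in ("cis", "trans"):
            tag = f"{chain.protein_id}_{kind}"
            ids = [f"rs{tag}_{i + 1:04d}" for i in range(m)]
            ids_all += ids
            blocks_all += _default_blocks(m, config.block_size)
            chrom = str(2 * ci + (1 if kind == "cis" else 2))
            rows.append((chain, kind, ids, chrom))
    total = len(ids_all)
    ld = simulate_ld_matrix(total, blocks_all, config.ld_block_correlation,
                            variant_ids=ids_all)
    chol = np.linalg.cholesky(ld.r + 1e-10 * np.eye(total))

    maf = rng.uniform(*config.maf_range, total)
    allele_pairs = np.array([["A", "G"], ["C", "T"], ["G", "A"], ["T", "C"]])
    pick = rng.integers(0, len(allele_pairs), total)
    ea, oa = allele_pairs[pick, 0], allele_pairs[pick, 1]
    gene_start, gene_end = 1_000_000, 1_020_000
    pos = np.concatenate([
        np.sort(rng.choice(np.arange(gene_start - 150_000, gene_end + 150_000),
                           size=m, replace=False))
        for _ in range(len(rows))
    ])
    chrom_col = np.concatenate([[chrom] * m for _, _, _, chrom in rows])

    # true marginal effects, one vector per trait over all variants
    prot_true = {c.protein_id: np.zeros(total) for c in chains}
    met_true = {c.metabolite_id: np.zeros(total) for c in chains}
    chd_true = np.zeros(total)
    slices = {}
    for li, (chain, kind, ids, chrom) in enumerate(rows):
        sl = slice(li * m, (li + 1) * m)
        slices[(chain.protein_id, kind)] = sl
        eff = rng.choice([-1.0, 1.0], m) * rng.uniform(lo, hi, m)
        if kind == "cis":
            prot_true[chain.protein_id][sl] = eff
            orient = np.sign(eff)
            met_true[chain.metabolite_id][sl] = chain.theta_pm * eff + _pleiotropy(
                rng, chain.pleiotropy_mode, chain.pleiotropy_sd, orient)
            chd_true[sl] += chain.theta_pc_total * eff + _pleiotropy(
                rng, chain.pleiotropy_mode, chain.pleiotropy_sd, orient)
        else:
            met_true[chain.metabolite_id][sl] += eff
            chd_true[sl] += chain.theta_mc * eff

    se_prot = 1.0 / np.sqrt(2 * maf * (1 - maf) * config.n_exposure_samples)
    se_met = 1.0 / np.sqrt(2 * maf * (1 - maf) * n_metabolite_samples)
    se_chd = 1.0 / np.sqrt(2 * maf * (1 - maf) * config.n_outcome_samples)

    def table(beta_true, se, n):
        beta = beta_true + _correlated_noise(rng, chol, se)
        return pd.DataFrame({
            "variant_id": ids_all, "chrom": chrom_col, "pos": pos,
            "effect_allele": ea, "other_allele": oa, "eaf": maf,
            "beta": beta, "se": se, "pval": _pvals(beta, se), "n": n,
        })

    proteins = {}
    for chain in chains:
        full = table(prot_true[chain.protein_id], se_prot,
                     config.n_exposure_samples)
        sl = slices[(chain.protein_id, "cis")]
        cis_chrom = rows[[r[0].protein_id == chain.protein_id and r[1] == "cis"
                          for r in rows].index(True)][3]
        proteins[chain.protein_id] = SummaryStatSet(
            chain.protein_id, "protein",
            full.iloc[sl].reset_index(drop=True),
            (cis_chrom, gene_start, gene_end),
        )
    metabolites = {
        c.metabolite_id: SummaryStatSet(
            c.metabolite_id, "metabolite",
            table(met_true[c.metabolite_id], se_met, n_metabolite_samples))
        for c in chains
    }
    outcome = SummaryStatSet(
        "CHD", "disease", table(chd_true, se_chd, config.n_outcome_samples))

    truth = {
        "seed": seed,
        "n_chains": len(chains),
        "expected_concordant_proteins": sorted(
            c.protein_id for c in chains if c.expected_concordant is True),
    }
    for c in chains:
        truth[f"{c.protein_id}.theta_pm"] = c.theta_pm
        truth[f"{c.protein_id}.theta_mc"] = c.theta_mc
        truth[f"{c.protein_id}.theta_pc_total"] = c.theta_pc_total
        truth[f"{c.protein_id}.expected_concordant"] = c.expected_concordant
    return StudyData(proteins, metabolites, outcome, ld, list(chains), truth)


def simulate_plaque_table(
    n_samples: int,
    feature_effects: dict[str, float],
    noise_sd: float,
    seed: int = 0,
    intercept: float = 10.0,
):
    """Simulate a plaque expression table linear in a vulnerability index.

    The per-sample plaque vulnerability index (PVI) is standard normal;
    expression of each feature is ``intercept + effect * PVI + noise``.
    Covariates mimic the endarterectomy cohort: ~75% male, age ~ N(69, 9)
    years, ~22% diabetic. Returns ``(values, covariates)`` DataFrames
    indexed by sample id.
    """
    if n_samples < 10:
        raise ValueError("n_samples must be >= 10")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    samples = [f"S{i + 1:04d}" for i in range(n_samples)]
    pvi = rng.standard_normal(n_samples)
    cov = pd.DataFrame({
        "pvi": pvi,
        "sex": np.where(rng.random(n_samples) < 0.75, "M", "F"),
        "age": np.clip(rng.normal(69.0, 9.0, n_samples), 40, 95).round(1),
        "diabetes": np.where(rng.random(n_samples) < 0.22, "yes", "no"),
    }, index=pd.Index(samples, name="sample_id"))
    values = pd.DataFrame(
        {
            feat: intercept + eff * pvi + rng.normal(0.0, noise_sd, n_samples)
            for feat, eff in feature_effects.items()
        },
        index=cov.index,
    )
    return values, cov


def simulate_single_cell(
    n_cells: int,
    cell_type_props: dict[str, float],
    enriched: dict[str, str],
    fold: float = 10.0,
    seed: int = 0,
    n_background_genes: int = 10,
    base_rate: float = 2.0,
):
    """Simulate a labelled single-cell count matrix with planted markers.

    Cells are assigned to the 13 plaque cell types with the given
    proportions; counts are Poisson with rate ``base_rate``, multiplied
    by ``fold`` for an enriched gene in its target cell type (or in every
    type of a target broad cluster). Returns ``(counts, annotation)``
    where annotation carries per-cell ``cell_type`` and ``cluster``.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    props = dict(cell_type_props)
    unknown = set(props) - set(CELL_TYPES)
    if unknown:
        raise ValueError(f"unknown cell types: {sorted(unknown)}")
    if abs(sum(props.values()) - 1.0) > 1e-8:
        raise ValueError("cell-type proportions must sum to 1")
    clusters = set(CLUSTER_MAP.values())
    for gene, target in enriched.items():
        if target not in CELL_TYPES and target not in clusters:
            raise ValueError(f"unknown enrichment target {target!r} for {gene}")
    if enriched and fold <= 1:
        raise ValueError("fold must be > 1 for enriched genes")

    rng = np.random.default_rng(seed)
    types = list(props)
    labels = rng.choice(types, size=n_cells, p=[props[t] for t in types])
    ann = pd.DataFrame({
        "cell_type": labels,
        "cluster": [CLUSTER_MAP[t] for t in labels],
    }, index=pd.Index([f"cell{i + 1:05d}" for i in range(n_cells)], name="cell_id"))

    genes = list(enriched) + [f"BG{i + 1:03d}" for i in range(n_background_genes)]
    counts = pd.DataFrame(index=ann.index, columns=genes, dtype=float)
    for gene in genes:
        rate = np.full(n_cells, base_rate)
        target = enriched.get(gene)
        if target is not None:
            if target in clusters:
                mask = ann["cluster"].to_numpy() == target
            else:
                mask = labels == target
            rate[mask] *= fold
        counts[gene] = rng.poisson(rate).astype(float)
    return counts, ann
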