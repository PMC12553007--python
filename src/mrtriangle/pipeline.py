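"""End-to-end orchestration: simulate -> MR layers -> triangulate ->
tissue validation -> enrichment/annotation -> report.

Each stage reads its inputs from, and writes its outputs to, the run
directory, so deleting downstream artifacts and re-running resumes from
files on disk. A run manifest records the config hash, seed, software
version and per-stage row counts, mirroring the cascade of count
reductions (variants filtered, metabolites screened, proteins
triangulated, features validated) that summarises a run.

All thresholds default to the analysis' reporting values: F >= 24,
MAF >= 0.01, clump r^2 <= 0.30, >= 6 variants, leverage > 3x mean,
outlier chi-square > 10.83, alpha 0.05, 90% PCA variance target, plaque
FDR 0.1, pathway FDR 0.05, single-cell nominal 0.05.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, io
from .enrich import (GeneSetCollection, classify_druggability,
                     druggability_counts, ora_collection, ora_to_table)
from .instruments import InstrumentConfig
from .mr import MRConfig, fits_to_table, run_mr, table_to_fits
from .simulate import (ChainSpec, SimulationConfig,
                       simulate_plaque_table, simulate_single_cell,
                       simulate_study)
from .tissue import (associate_all, de_all, enrichment_matrix,
                     subgroup_and_interaction)
from .triangulate import (MultiplicityPlan, concordant_proteins,
                          effective_tests_pca, screen_layer,
                          triangles_to_table, triangulate)

STAGES = ("simulate", "mr", "triangulate", "tissue", "enrich", "report")

#: Default planted scenario: one concordant, one discordant and one
#: sub-threshold chain (the last has a null metabolite -> disease leg).
DEFAULT_CHAINS = [
    {"protein_id": "PROT1", "metabolite_id": "MET1",
     "theta_pm": 0.3, "theta_mc": 0.2, "theta_pc": 0.0},
    {"protein_id": "PROT2", "metabolite_id": "MET2",
     "theta_pm": 0.3, "theta_mc": 0.2, "theta_pc": -0.26},
    {"protein_id": "PROT3", "metabolite_id": "MET3",
     "theta_pm": 0.3, "theta_mc": 0.0, "theta_pc": 0.0},
]

DEFAULT_CELL_PROPS = {
    "SMCs": 0.16, "T_cells": 0.14, "resident_macrophages": 0.12,
    "inflammatory_macrophages": 0.10, "foam_cells": 0.09,
    "endothelial_cells_I": 0.07, "monocytes": 0.06, "NK_cells": 0.05,
    "endothelial_cells_II": 0.05, "memory_B_cells": 0.05,
    "dendritic_cells": 0.04, "plasma_B_cells": 0.04, "mast_cells": 0.03,
}


class StageError(RuntimeError):
    """A pipeline stage failed; earlier artifacts remain on disk."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Structured run configuration; defaults reproduce the reference
    thresholds so an empty override file is a complete configuration."""

    outdir: str = "runs/demo"
    seed: int = 0
    f_min: float = 24.0
    maf_min: float = 0.01
    clump_r2: float = 0.30
    window_bp: int = 200_000
    min_variants: int = 6
    leverage_mult: float = 3.0
    chisq_cut: float = 10.83
    alpha: float = 0.05
    variance_target: float = 0.90
    plaque_fdr: float = 0.1
    ora_fdr: float = 0.05
    sc_alpha: float = 0.05
    simulate: dict | None = field(default_factory=dict)
    ingest: dict | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        blob = yaml.safe_dump(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def instrument_config(self, cis: bool) -> InstrumentConfig:
        return InstrumentConfig(self.f_min, self.maf_min, self.clump_r2,
                                cis, self.window_bp)

    def mr_config(self) -> MRConfig:
        return MRConfig(self.min_variants, self.leverage_mult,
                        self.chisq_cut, self.alpha)


def validate_config(config: RunConfig) -> list[str]:
    """Range / consistency checks; returns a human-readable error list."""
    errors = []
    if not 0 <= config.clump_r2 <= 1:
        errors.append(f"clump_r2 out of range [0, 1]: {config.clump_r2}")
    for name in ("alpha", "plaque_fdr", "ora_fdr", "sc_alpha"):
        val = getattr(config, name)
        if not 0 < val < 1:
            errors.append(f"{name} must lie in (0, 1): {val}")
    if not 0 < config.variance_target <= 1:
        errors.append(f"variance_target must lie in (0, 1]: {config.variance_target}")
    if config.min_variants < 2:
        errors.append("min_variants must be >= 2")
    if config.f_min < 0 or config.maf_min < 0 or config.maf_min >= 0.5:
        errors.append("f_min must be >= 0 and maf_min in [0, 0.5)")
    has_sim = config.simulate is not None
    has_ingest = config.ingest is not None
    if has_sim and has_ingest:
        errors.append("simulate and ingest blocks are mutually exclusive")
    if not has_sim and not has_ingest:
        errors.append("one of simulate or ingest is required")
    if has_ingest:
        for key, path in (config.ingest or {}).items():
            if key.endswith(("_path", "_file")) and not Path(str(path)).exists():
                errors.append(f"ingest path missing: {key}={path}")
    return errors


def _dir(config: RunConfig, stage: str) -> Path:
    path = Path(config.outdir) / stage
    path.mkdir(parents=True, exist_ok=True)
    return path


def _chains(config: RunConfig) -> list[ChainSpec]:
    raw = (config.simulate or {}).get("chains", DEFAULT_CHAINS)
    return [ChainSpec(**c) for c in raw]


# ------------------------------------------------------------------ stages

def stage_simulate(config: RunConfig) -> dict:
    """Generate every pipeline input with known ground truth."""
    out = _dir(config, "sim")
    sim = config.simulate or {}
    chains = _chains(config)
    sim_cfg = SimulationConfig(
        n_variants_per_locus=sim.get("n_variants_per_locus", 25),
        ld_block_correlation=sim.get("ld_block_correlation", 0.3),
        seed=config.seed,
    )
    study = simulate_study(chains, sim_cfg,
                           n_metabolite_samples=sim.get("n_metabolite_samples", 3000),
                           seed=config.seed)

    traits = []
    for pid, stats in study.proteins.items():
        io.write_sumstats(stats, out / f"protein_{pid}.tsv")
        chrom, start, end = stats.locus
        traits.append((pid, "protein", chrom, start, end, f"protein_{pid}.tsv"))
    for mid, stats in study.metabolites.items():
        io.write_sumstats(stats, out / f"metabolite_{mid}.tsv")
        traits.append((mid, "metabolite", "", "", "", f"metabolite_{mid}.tsv"))
    io.write_sumstats(study.outcome, out / "outcome_CHD.tsv")
    traits.append(("CHD", "disease", "", "", "", "outcome_CHD.tsv"))
    pd.DataFrame(traits, columns=["trait_id", "trait_class", "chrom",
                                  "start", "end", "path"]
                 ).to_csv(out / "traits.tsv", sep="\t", index=False)
    io.write_ld(study.ld, out / "ld.tsv")
    io.write_keyvalue(study.truth, out / "truth.txt")

    # metabolite trait correlation (independent synthetic chains -> identity)
    mids = sorted(study.metabolites)
    pd.DataFrame(np.eye(len(mids)), index=mids, columns=mids).to_csv(
        out / "metabolite_correlation.tsv", sep="\t")

    # plaque expression: signal in chains whose measured triple is concordant
    concordant = {c.protein_id for c in chains if c.expected_concordant is True}
    effects = {c.protein_id: (2.0 if c.protein_id in concordant else 0.0)
               for c in chains}
    n_prot = sim.get("n_plaque_protein_samples", 194)
    n_mrna = sim.get("n_plaque_mrna_samples", 632)
    vals_p, cov_p = simulate_plaque_table(n_prot, effects, noise_sd=1.0,
                                          seed=config.seed + 11)
    io.write_expression(vals_p, cov_p, out / "plaque_protein.tsv",
                        out / "plaque_protein_covariates.tsv")
    vals_m, cov_m = simulate_plaque_table(n_mrna, effects, noise_sd=1.0,
                                          seed=config.seed + 12)
    io.write_expression(vals_m, cov_m, out / "plaque_mrna.tsv",
                        out / "plaque_mrna_covariates.tsv")

    # single cell: concordant genes planted as SMC markers
    enriched = {pid: "SMCs" for pid in sorted(concordant)}
    counts, ann = simulate_single_cell(
        sim.get("n_cells", 2000), DEFAULT_CELL_PROPS, enriched,
        fold=sim.get("sc_fold", 8.0), seed=config.seed + 13)
    io.write_cell_matrix(counts, ann, out / "cells.tsv",
                         out / "cell_annotation.tsv")

    # gene sets: one planted set containing the concordant proteins
    rng = np.random.default_rng(config.seed + 14)
    filler = [f"UPROT{i + 1:03d}" for i in range(60)]
    universe = sorted({c.protein_id for c in chains} | set(filler))
    sets = {"PLANTED_PATHWAY": sorted(concordant) + filler[:3]}
    for i in range(4):
        sets[f"RANDOM_SET_{i + 1}"] = sorted(
            rng.choice(filler, size=8, replace=False))
    io.write_gmt(sets, out / "genesets.gmt")
    (out / "universe.txt").write_text("\n".join(universe) + "\n")

    # synthetic druggability table
    drug_rows = []
    for i, pid in enumerate(sorted(concordant)):
        drug_rows.append((pid, "drugged", f"drug_{pid.lower()}",
                          "yes" if i == 0 else "no", "no"))
    pd.DataFrame(drug_rows, columns=["protein_id", "status", "drugs",
                                     "cardiac_indication",
                                     "cardiac_side_effect"]
                 ).to_csv(out / "druggability.tsv", sep="\t", index=False)
    return {"n_chains": len(chains), "n_variants": len(study.ld),
            "n_traits": len(traits)}


def _load_sim(config: RunConfig):
    out = Path(config.outdir) / "sim"
    traits = pd.read_csv(out / "traits.tsv", sep="\t",
                         dtype={"chrom": str}, keep_default_na=False)
    ld = io.read_ld(out / "ld.tsv")
    loaded = {}
    for row in traits.itertuples(index=False):
        locus = None
        if row.trait_class == "protein":
            locus = (str(row.chrom), int(float(row.start)), int(float(row.end)))
        loaded[row.trait_id] = io.read_sumstats(
            out / row.path, row.trait_id, row.trait_class, locus)
    return loaded, ld


def stage_mr(config: RunConfig) -> dict:
    """Run the three MR layers and write one results table per layer."""
    out = _dir(config, "mr")
    traits, ld = _load_sim(config)
    proteins = {t: s for t, s in traits.items() if s.trait_class == "protein"}
    metabolites = {t: s for t, s in traits.items()
                   if s.trait_class == "metabolite"}
    outcome = next(s for s in traits.values() if s.trait_class == "disease")
    mr_cfg = config.mr_config()
    gw = config.instrument_config(cis=False)
    cis = config.instrument_config(cis=True)

    layer1 = [run_mr(m, outcome, ld, gw, mr_cfg)
              for m in metabolites.values()]
    layer2 = [run_mr(p, m, ld, cis, mr_cfg)
              for p in proteins.values() for m in metabolites.values()]
    layer3 = [run_mr(p, outcome, ld, cis, mr_cfg)
              for p in proteins.values()]
    for name, fits in (("layer1_metabolite_chd", layer1),
                       ("layer2_protein_metabolite", layer2),
                       ("layer3_protein_chd", layer3)):
        fits_to_table(fits).to_csv(out / f"{name}.tsv", sep="\t", index=False)
    return {"layer1": len(layer1), "layer2": len(layer2), "layer3": len(layer3)}


def stage_triangulate(config: RunConfig) -> dict:
    """Screen each layer at its multiplicity threshold and join triangles."""
    out = _dir(config, "triangulate")
    mr_dir = Path(config.outdir) / "mr"
    sim_dir = Path(config.outdir) / "sim"
    tables = {
        name: pd.read_csv(mr_dir / f"{name}.tsv", sep="\t")
        for name in ("layer1_metabolite_chd", "layer2_protein_metabolite",
                     "layer3_protein_chd")
    }
    fits1 = table_to_fits(tables["layer1_metabolite_chd"])
    fits2 = table_to_fits(tables["layer2_protein_metabolite"])
    fits3 = table_to_fits(tables["layer3_protein_chd"])

    corr = pd.read_csv(sim_dir / "metabolite_correlation.tsv", sep="\t",
                       index_col=0)
    n_eff1 = (effective_tests_pca(corr.to_numpy(), config.variance_target)
              if len(corr) >= 2 else 1)
    n_proteins = tables["layer3_protein_chd"]["exposure_id"].nunique()
    n_metabolites = len(corr)

    plan1 = MultiplicityPlan("metabolite_chd", "bonferroni_pca", n_eff1,
                             config.alpha)
    surv1, log1 = screen_layer(fits1, plan1)
    # layer 2 uses the full proteins x surviving-metabolites product
    n_eff2 = max(1, n_proteins * len(surv1))
    plan2 = MultiplicityPlan("protein_metabolite", "bonferroni_count", n_eff2,
                             config.alpha)
    surv2, log2 = screen_layer(fits2, plan2)
    plan3 = MultiplicityPlan("protein_chd", "bonferroni_count",
                             max(1, n_proteins), config.alpha)
    surv3, log3 = screen_layer(fits3, plan3)

    records = triangulate(surv1, surv2, surv3)
    table = triangles_to_table(records)
    table.to_csv(out / "triangles.tsv", sep="\t", index=False)
    pd.DataFrame(log1 + log2 + log3).to_csv(out / "screen_log.tsv", sep="\t",
                                            index=False)
    plans = {
        p.layer: {"method": p.method, "n_effective": p.n_effective,
                  "alpha": p.alpha, "threshold": p.threshold}
        for p in (plan1, plan2, plan3)
    }
    (out / "multiplicity_plans.json").write_text(json.dumps(plans, indent=2))
    concordant = concordant_proteins(records)
    (out / "concordant_proteins.txt").write_text(
        "\n".join(concordant) + ("\n" if concordant else ""))
    return {"metabolites_surviving": len(surv1),
            "protein_metabolite_surviving": len(surv2),
            "proteins_chd_surviving": len(surv3),
            "triangles": len(records),
            "concordant_proteins": len(concordant)}


def _read_triangles(config: RunConfig):
    path = Path(config.outdir) / "triangulate" / "triangles.tsv"
    df = pd.read_csv(path, sep="\t")
    from .triangulate import TriangleRecord
    return [TriangleRecord(**{k: row[k] for k in (
        "protein_id", "metabolite_id", "theta_pm", "theta_mc", "theta_pc",
        "p_pm", "p_mc", "p_pc", "concordant", "source_gwas")})
        for _, row in df.fillna({"source_gwas": ""}).iterrows()] if len(df) else []


def stage_tissue(config: RunConfig) -> dict:
    """Plaque PVI associations, subgroup tests and single-cell DE."""
    out = _dir(config, "tissue")
    sim_dir = Path(config.outdir) / "sim"
    triangles = _read_triangles(config)
    assoc = {}
    for family in ("protein", "mrna"):
        vals, cov = io.read_expression(
            sim_dir / f"plaque_{family}.tsv",
            sim_dir / f"plaque_{family}_covariates.tsv")
        results = associate_all(vals, cov, config.plaque_fdr)
        for res in results:
            if res.significant:
                for gv in ("sex", "age65", "diabetes"):
                    sub = subgroup_and_interaction(vals, cov, res.feature_id, gv)
                    res.subgroup_betas.update(
                        {f"{gv}:{k}": v for k, v in sub.subgroup_betas.items()})
                    res.interaction_p.update(sub.interaction_p)
        assoc[family] = results
        rows = [{
            "feature_id": r.feature_id, "beta": r.beta, "se": r.se,
            "pval": r.pval, "qval": r.qval, "significant": r.significant,
            "n": r.n,
            "interaction_p": json.dumps(r.interaction_p),
        } for r in results]
        pd.DataFrame(rows).to_csv(out / f"pvi_{family}.tsv", sep="\t",
                                  index=False)

    counts, ann = io.read_cell_matrix(sim_dir / "cells.tsv",
                                      sim_dir / "cell_annotation.tsv")
    de_types = de_all(counts, ann, "cell_type", config.sc_alpha)
    de_clusters = de_all(counts, ann, "cluster", config.sc_alpha)
    for name, res in (("de_cell_types", de_types),
                      ("de_clusters", de_clusters)):
        pd.DataFrame([r.__dict__ for r in res]).to_csv(
            out / f"{name}.tsv", sep="\t", index=False)

    drug = io.read_drug_table(sim_dir / "druggability.tsv")
    matrix = enrichment_matrix(de_types + de_clusters, assoc, triangles, drug)
    matrix.to_csv(out / "protein_matrix.tsv", sep="\t")
    n_sig = {fam: sum(bool(r.significant) for r in res)
             for fam, res in assoc.items()}
    return {"pvi_protein_significant": n_sig["protein"],
            "pvi_mrna_significant": n_sig["mrna"],
            "de_tests": len(de_types) + len(de_clusters)}


def stage_enrich(config: RunConfig) -> dict:
    """ORA of PVI-validated concordant proteins + druggability counts."""
    out = _dir(config, "enrich")
    sim_dir = Path(config.outdir) / "sim"
    tissue_dir = Path(config.outdir) / "tissue"
    triangles = _read_triangles(config)
    concordant = set(concordant_proteins(triangles))
    validated = set()
    for family in ("protein", "mrna"):
        df = pd.read_csv(tissue_dir / f"pvi_{family}.tsv", sep="\t")
        validated |= set(df.loc[df["significant"] == True, "feature_id"])  # noqa: E712
    hits = sorted(concordant & validated)

    sets = io.read_gmt(sim_dir / "genesets.gmt")
    universe = (sim_dir / "universe.txt").read_text().split()
    collection = GeneSetCollection(sets, universe)
    ora = ora_collection(set(hits), collection, config.ora_fdr)
    ora_to_table(ora).to_csv(out / "ora.tsv", sep="\t", index=False)

    drug = io.read_drug_table(sim_dir / "druggability.tsv")
    annotations = classify_druggability(hits, drug)
    counts = druggability_counts(annotations)
    pd.DataFrame([{
        "protein_id": a.protein_id, "status": a.status,
        "drugs": ";".join(a.drugs),
        "cardiac_indication": "yes" if a.cardiac_indication else "no",
        "cardiac_side_effect": "yes" if a.cardiac_side_effect else "no",
    } for a in annotations]).to_csv(out / "druggability.tsv", sep="\t",
                                    index=False)
    (out / "hits.txt").write_text("\n".join(hits) + ("\n" if hits else ""))
    return {"hits": len(hits),
            "ora_significant": sum(bool(r.significant) for r in ora),
            **{f"druggability_{k}": v for k, v in counts.items()}}


def stage_report(config: RunConfig, stage_counts: dict | None = None) -> dict:
    """Write the run manifest (config hash, seed, version, stage counts)."""
    manifest = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "version": __version__,
        "config": config.to_dict(),
        "stage_counts": stage_counts or {},
    }
    path = Path(config.outdir) / "run_manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return {"manifest": str(path)}


STAGE_FUNCS = {
    "simulate": stage_simulate,
    "mr": stage_mr,
    "triangulate": stage_triangulate,
    "tissue": stage_tissue,
    "enrich": stage_enrich,
}


def run_pipeline(config: RunConfig) -> dict:
    """Run all stages in order; returns the manifest dictionary.

    A stage failure raises :class:`StageError` naming the stage; outputs
    of completed stages are preserved on disk.
    """
    errors = validate_config(config)
    if errors:
        raise ValueError("invalid config: " + "; ".join(errors))
    counts = {}
    for stage in STAGES[:-1]:
        try:
            counts[stage] = STAGE_FUNCS[stage](config)
        except Exception as exc:  # noqa: BLE001 - report stage context
            raise StageError(stage, exc) from exc
    stage_report(config, counts)
    with open(Path(config.outdir) / "run_manifest.json") as fh:
        return json.load(fh)
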