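# mrtriangle

Summary-statistic Mendelian randomisation (MR) triangulation of
**protein → metabolite → disease** causal chains, with downstream tissue
validation. The package re-implements, as a tested and fully synthetic-data
exercisable pipeline, a multi-omic drug-target prioritisation strategy for
coronary heart disease (CHD): genetic effects on urinary metabolites, plasma
proteins and CHD are combined through three layers of MR, proteins with
directionally concordant effects are prioritised, and the survivors are
validated against atherosclerotic-plaque expression, single-cell cell-type
enrichment and pathway/druggability annotation.

It is written for statistical geneticists and biostatisticians who want to
run, stress-test or extend this kind of triangulation design without access
to the original GWAS or biobank data: every input can be simulated with
known ground truth.

## The model

For one exposure–outcome pair, let `bx` and `by` be the harmonised
variant-level effect estimates, `S = diag(se_y)` the outcome standard
errors, and `C` the LD correlation among the instruments. The estimators
are generalised least squares with weight matrix `Ω = S C S`:

```
IVW:    by = θ·bx + ε
Egger:  by = α + θ·bx + ε      (variants oriented so bx ≥ 0)
θ̂ = (XᵀΩ⁻¹X)⁻¹ XᵀΩ⁻¹ by,     Q = (by − Xθ̂)ᵀ Ω⁻¹ (by − Xθ̂)
```

With `C = I` this is the textbook inverse-variance-weighted estimator;
otherwise it corrects for residual LD among clumped instruments.
Instruments must pass F = (β/se)² ≥ 24 and MAF ≥ 0.01, are clumped to
r² ≤ 0.30, and (for protein exposures) restricted to a 200 kb cis window
around the encoding gene. Variants with leverage above 3× the mean or a
whitened squared residual above 10.83 (the 1-df χ² value at p = 0.001) are
excluded once and the model refitted; analyses with fewer than six variants
are discarded. MR-Egger is preferred over IVW only when its Q reduction
exceeds the 1-df χ² critical value at α = 0.05.

A protein is **triangulated** when it affects a disease-associated
metabolite and the disease itself, with consistent signs:
`sign(θ_pm)·sign(θ_mc) = sign(θ_pc)`. Each layer is screened at its own
Bonferroni threshold `α / n_effective`, where the correlated metabolite
family uses the number of principal components explaining 90% of its
variance. Downstream, plaque expression is regressed on the plaque
vulnerability index (BH FDR 0.1), cell-type enrichment uses one-vs-rest
Wilcoxon rank-sum tests (nominal 0.05), and pathway enrichment is an
upper-tail hypergeometric test against a fixed background (BH FDR 0.05).

## Worked example

```python
from mrtriangle import SimulationConfig, simulate_gwas_chain, run_mr

chain = simulate_gwas_chain(SimulationConfig(theta_pm=0.3, seed=7))
fit = run_mr(chain.protein, chain.metabolite, chain.ld)
print(fit.model, fit.slope, fit.ci95)
```

prints (see `examples/01_simulate_and_recover.py`):

```
selected model     : IVW
estimated slope    : 0.2922 (se 0.0072)
95% CI             : [0.2781, 0.3064]
heterogeneity Q    : 27.81 on 24 df
```

The slope estimates the true simulated effect 0.3 SD per SD; Q/df near 1
says the 25 instruments tell a homogeneous story, and the parsimonious IVW
model is kept. The full pipeline runs from the shell:

```bash
mrtriangle all --outdir runs/demo --seed 1
```

which simulates three chains (one concordant, one discordant, one
sub-threshold), runs the three MR layers, screens and joins them, and
validates survivors in simulated plaque and single-cell data. The triangle
table then reads:

```
protein_id metabolite_id  theta_pm  theta_mc  theta_pc  concordant
     PROT1          MET1     0.300     0.194     0.063        True
     PROT2          MET2     0.326     0.194    -0.202       False
```

— exactly the planted concordant chain is flagged, the discordant chain is
rejected by the sign rule, and the sub-threshold chain never reaches the
table. The `examples/` directory has one short script per capability
(simulation and recovery, pleiotropy and model selection, the full
pipeline, plaque validation, single-cell and enrichment).

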