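"""Simulate one protein -> metabolite GWAS chain and recover its effect.

Builds a 25-variant cis locus with block LD, generates protein and
metabolite summary statistics with a true causal effect of 0.3 SD per
SD, then runs the full MR procedure (filters, clumping, GLS fit,
leverage/outlier pruning, model selection).
"""

from mrtriangle import SimulationConfig, run_mr, simulate_gwas_chain

config = SimulationConfig(theta_pm=0.3, pleiotropy_mode="none", seed=7)
chain = simulate_gwas_chain(config)
fit = run_mr(chain.protein, chain.metabolite, chain.ld)

print(f"true effect        : {chain.truth.theta_pm}")
print(f"selected model     : {fit.model}")
print(f"estimated slope    : {fit.slope:.4f} (se {fit.slope_se:.4f})")
print(f"95% CI             : [{fit.ci95[0]:.4f}, {fit.ci95[1]:.4f}]")
print(f"heterogeneity Q    : {fit.Q:.2f} on {fit.Q_df} df")
print(f"variants used      : {fit.n_variants_used} "
      f"(excluded: {fit.excluded or 'none'})")
print()
print("The slope is the causal effect of a 1 SD increase in the protein")
print("on the metabolite; the CI should cover the true 0.3 about 95% of")
print("the time over repeated simulations.")
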