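"""Directional pleiotropy and IVW-vs-Egger model selection.

When every variant carries a direct effect on the outcome in a common
direction (relative to the exposure-raising allele), the no-intercept
IVW slope is biased and heterogeneity inflates. The model-selection
rule prefers MR-Egger when its free intercept buys a goodness-of-fit
improvement beyond the 1-df chi-square critical value (3.84 at 0.05).
"""

from mrtriangle import SimulationConfig, run_mr, simulate_gwas_chain

for mode in ("none", "directional"):
    chain = simulate_gwas_chain(SimulationConfig(
        theta_pm=0.3, pleiotropy_mode=mode, pleiotropy_sd=0.03, seed=11))
    fit = run_mr(chain.protein, chain.metabolite, chain.ld)
    print(f"pleiotropy={mode:11s} model={fit.model:5s} "
          f"slope={fit.slope:.3f} Q/df={fit.Q / fit.Q_df:.1f} "
          f"dQ={fit.selection_stat and round(fit.selection_stat, 1)}")
    if fit.model == "Egger":
        print(f"{'':24s}intercept={fit.intercept:.4f} "
              f"(true pleiotropy mean 0.03)")
print()
print("Under 'none' the parsimonious IVW is kept; under 'directional'")
print("the Q reduction from Egger's intercept exceeds 3.84 and Egger is")
print("selected, its intercept estimating the mean direct effect.")
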