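"""Type-1 error and correction-factor bias across simulation scenarios.

Runs a reduced (20-replicate) grid over the balanced scenario at three
levels of direct-effect correlation, using the fast summary-level generator,
and prints type-1 error over the biased cluster plus the slope bias of each
estimator.  Increase n_replicates (the published protocol used 1000) for
smoother numbers.
"""

from slopehunter import run_grid

grid = run_grid(["sc1"], [0.9, 0.0, -0.9], n_replicates=20, seed=1,
                mode="summary")

t1 = grid[grid.metric == "type1_GI"].pivot(index="rho_d", columns="method",
                                           values="value")
print("type-1 error over SNPs affecting only the conditioning trait")
print("(nominal level 0.05):")
print(t1.round(3).to_string())
print()
sb = grid[grid.metric == "slope_bias"].pivot(index="rho_d", columns="method",
                                             values="value")
print("correction-factor bias (fitted slope minus realised bias slope):")
print(sb.round(3).to_string())
print()
print("The unadjusted analysis is inflated wherever SNPs affect the "
      "conditioning trait; the regression comparator (DHO) corrects only "
      "when direct effects are uncorrelated; the mixture method stays near "
      "the nominal level throughout.")
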