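"""Estimate and apply a collider-bias correction on a simulated study.

Generates one balanced four-cluster study (10,000 SNPs, 20,000 individuals,
50% heritability, a shared confounder explaining 40% of both traits, direct
effects correlated at 0.4), hunts the correction slope, and de-biases every
SNP's conditional association.
"""

from slopehunter import (EMConfig, SelectionConfig, adjust_associations,
                         dho_estimate, hunt_slope, preset_scenario,
                         simulate_individual)

cfg = preset_scenario("fig5b", seed=7)
study = simulate_individual(cfg)
print(f"simulated {cfg.n_snps} SNPs x {cfg.n_individuals} individuals "
      f"(direct-effect correlation {cfg.rho_d})")
print(f"realised collider-bias slope: {study.realized_slope:.3f}")

fit = hunt_slope(study.sumstats, SelectionConfig(lam=1e-3),
                 EMConfig(seed=7, bootstrap_B=200))
print(f"mixture-model correction factor b1 = {fit.b1:.3f} "
      f"(bootstrap se {fit.se_b1:.3f}, "
      f"95% CI {fit.ci_b1[0]:.3f} to {fit.ci_b1[1]:.3f}) "
      f"from {fit.n_snps} selected SNPs")

dho = dho_estimate(study.sumstats)
print(f"regression comparator (Hedges-Olkin corrected): {dho.b_ho:.3f} — "
      "under-corrects here because direct effects are correlated")

adjusted = adjust_associations(study.sumstats, fit.b1, fit.se_b1 or 0.0)
n_sig_before = (study.sumstats["p_P"] < 5e-8).sum()
n_sig_after = (adjusted["p_adj"] < 5e-8).sum()
print(f"genome-wide significant associations: {n_sig_before} before, "
      f"{n_sig_after} after de-biasing")
print("b1 close to the realised slope means the de-biased effects estimate "
      "each SNP's direct effect on the outcome.")
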