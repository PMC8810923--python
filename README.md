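# slopehunter

Collider-bias correction for conditional GWAS summary statistics.

## The problem

Genome-wide association studies are increasingly run *conditional on* a
heritable phenotype: a GWAS of fasting insulin adjusted for BMI, or a GWAS of
disease prognosis that can, by construction, include only disease cases.
Conditioning turns the phenotype into a collider. Any variant G that affects
the conditioning trait I becomes correlated, within the conditioned sample,
with the unmeasured common causes U of I and the outcome P — and therefore
picks up a spurious association with P through the open path G − U → P.
Variants with no effect on I are untouched.

The bias is linear in the variant's effect on I: writing β̂′_GP for the
conditional estimate and β_GP for the direct effect,

    β̂′_GP = β_GP + b·β_GI ,     b = −σ²_U β_UI β_UP / (σ²_U β²_UI + σ²_εI) ,

so a single correction factor de-biases every variant:

    β̂_GP = β̂′_GP − b̂·β̂_GI .

The difficulty is estimating b. Regressing β̂′_GP on β̂_GI over all variants
(regressing over all variants, here with the Hedges–Olkin regression-dilution
correction, "DHO") is unbiased only if effects on I are uncorrelated with
direct effects on P — an assumption ("InCLUDE") violated whenever the two
traits share pathways.

## The method

`slopehunter` estimates b from the cluster of variants that affect **only**
the conditioning trait. After selecting variants associated with I
(p < λ, default 0.001), the pairs (β̂_GI, β̂′_GP) follow a two-component
bivariate Gaussian mixture:

* the I-only cluster G_I· lies on the line β̂′_GP = b₁·β̂_GI, scattered only
  by sampling noise;
* the both-trait cluster G_IP scatters about a second line with slope
  b₁ + σ_IP/σ²_I and extra conditional variance σ²_P − σ²_IP/σ²_I.

The mixture is fitted by EM (multiple seeded restarts, closed-form weighted
least-squares updates), the I-only component is identified as the one
explaining more variation in I — with a residual-noise-consistency guard for
the regime where that assumption is unreliable — and its slope b̂₁, with a
bootstrap standard error, is the correction factor. Identification requires
only that the I-only cluster dominates the modal ratio β̂′_GP/β̂_GI
(a "zero modal residual" assumption), not that effects be uncorrelated.

The package also contains the DHO comparator, a four-cluster simulation
engine (individual-level genotypes or a fast summary-level approximation)
with full ground truth, and an evaluation grid computing type-1 error,
family-wise error, power, bias and MSE per estimator and variant cluster.

## A worked example

```python
from slopehunter import (EMConfig, SelectionConfig, adjust_associations,
                         dho_estimate, hunt_slope, preset_scenario,
                         simulate_individual)

study = simulate_individual(preset_scenario("fig5b", seed=7))
fit = hunt_slope(study.sumstats, SelectionConfig(lam=1e-3),
                 EMConfig(seed=7, bootstrap_B=200))
adjusted = adjust_associations(study.sumstats, fit.b1, fit.se_b1)
```

Running `python examples/hunt_simulated.py` (which does exactly this and
prints what it finds) gives:

```
simulated 10000 SNPs x 20000 individuals (direct-effect correlation 0.4)
realised collider-bias slope: -0.481
mixture-model correction factor b1 = -0.440 (bootstrap se 0.024, 95% CI -0.486 to -0.399) from 335 selected SNPs
regression comparator (Hedges-Olkin corrected): -0.350 — under-corrects here because direct effects are correlated
genome-wide significant associations: 146 before, 117 after de-biasing
```

The realised slope is the bias actually induced in this replicate; the
mixture fit recovers it while the all-variant regression, facing correlated
direct effects, under-corrects by ~27%. The de-biased table drops the
spurious hits among variants that only affect the conditioning trait.

Other narrative scripts in `examples/`: `harmonise_files.py` (allele
alignment and LD pruning of raw text files), `scenario_benchmark.py`
(type-1/bias grid across scenarios), and two real-data recipes
(`real_data_bmi_insulin.py`, `real_data_breast_cancer.py`) with download
instructions for the public BMI/fasting-insulin and breast-cancer datasets.

A thin CLI wraps the same pipeline:

```sh
slopehunter hunt --incidence bmi.tsv --outcome fi.tsv --lambda 0.001 \
    --bootstrap 1000 --seed 1 --out run
slopehunter simulate --scenario sc2 --rho 0.4 --seed 1 --out sim
slopehunter benchmark --scenario sc1 --replicates 100 --seed 1 --out bench
```

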