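# phylocomp

Detecting signatures of interspecific competition in the evolution of
continuous ecomorphological traits across phylogenies.

Most comparative trait models (Brownian motion, Ornstein–Uhlenbeck) assume
lineages evolve independently. `phylocomp` fits and contrasts seven models
on time-calibrated trees — four independent-evolution models and three in
which coexisting lineages interact:

| model | process | free parameters |
|-------|---------|-----------------|
| BM | dz = σ dW | σ², z₀ |
| OU | dz = −α(z − z₀)dt + σ dW | σ², α, z₀ |
| TDlin / TDexp | σ²(t) = σ² + b_t·t or σ²·e^{r_t t} | σ², slope, z₀ |
| DDlin / DDexp | σ²(t) = σ² + b_n·n(t) or σ²·e^{r_n n(t)} | σ², slope, z₀ |
| MC | dz_i = S(μ_i(t) − z_i)dt + σ dW, S ≤ 0 | σ², S, z₀ |

n(t) is the lineages-through-time function and μ_i(t) the mean trait of the
lineages interacting with i. Interactions (and the counts driving DD rates)
can be restricted to species sharing an **ecoguild** — quadrants of the
first two PCA axes of one-hot diet and foraging-stratum categories — with
guild membership through time reconstructed by Mk-model stochastic
character maps. A clade × trait is flagged for competition when a DD or MC
model has the smallest AICc and beats the best independent-evolution model
by ΔAICc > 2. Clade-level results are summarized by prevalence tables and
the Fritz–Purvis D statistic. A replicated false-positive study quantifies
how often competition models are wrongly preferred when the truth is OU.

All likelihoods are exact multivariate-normal computations; the
matching-competition covariance is propagated with closed-form block
exponentials between branching/regime events (see `docs/methods.md`).

## Worked example

```python
import numpy as np
from phylocomp import (
    ModelParams, ModelSpec, simulate_tree, standardize_depth,
    simulate_trait, fit_all_models, compare_models,
)

tree = standardize_depth(simulate_tree(50, birth=1.0, seed=7), 1.0)
truth = ModelSpec("MC", ModelParams(sig2=0.1, S=-5.0, z0=0.0))
x = simulate_trait(tree, truth, seed=7)

fits = fit_all_models(tree, x, clade="demo", trait="pc1")
comp = compare_models(fits)
for name, f in sorted(comp.fits.items(), key=lambda kv: kv[1].aicc):
    print(f"{name:6s} aicc={f.aicc:8.2f} delta={comp.delta_aicc[name]:6.2f}")
print("best:", comp.best_model, " competition flag:", comp.competition_flag)
```

Output:

```
MC     aicc=   48.80 delta=  0.00
TDexp  aicc=   58.31 delta=  9.51
DDexp  aicc=   69.78 delta= 20.98
TDlin  aicc=  120.47 delta= 71.67
DDlin  aicc=  133.11 delta= 84.31
BM     aicc=  207.46 delta=158.65
OU     aicc=  209.72 delta=160.92
best: MC  competition flag: True
```

The repulsion model that generated the data wins by 9.5 AICc units over the
runner-up and by well over 100 over every independent-evolution model, so
the competition flag fires. On data simulated under BM or OU instead,
the flag stays off in ≳95% of replicates (see the false-positive study).

A command-line interface covers the full pipeline
(`phylocomp fixture | guilds | simmap | fit | fpstudy | dstat | subclades |
pipeline`); every run writes a manifest with config, seed and input
checksums, and reruns from the same manifest are bit-identical.

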