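# erkin

Analysis pipeline for the kinetics of dual ERK phosphorylation by MEK:
mass-action modelling, algebraic quasi-steady-state reduction,
likelihood-based identifiability analysis, Bayesian parameter inference,
and topological comparison of posterior distributions across MEK variants.

## The problem

Activated MEK phosphorylates ERK on two sites through the mechanism

    S0 + E <-> C1 -> C2 <-> S1 + E,    C2 -> S2 + E

(mass action; no phosphatase).  Time courses of the three ERK
phosphorylation states — measured at seven time points over `r` replicates
after adding 0.65 μM MEK to 5 μM ERK — constrain the six rate constants
poorly, but constrain well the three parameters of a reduced **Linear
model**

    dS0/dt = -κ1 S0
    dS1/dt = -κ2 S1 + (1-π) κ1 S0
    dS2/dt =  π κ1 S0 + κ2 S1

obtained by an exact algebraic quasi-steady-state elimination of the
enzyme–substrate complexes: `κi` are kinetic efficiencies (1/min) and `π`
is the processivity, the probability that a single enzyme encounter adds
both phosphate groups.  An intermediate **Rational model** keeps the
Michaelis–Menten-type saturation denominator `γ1 S0 + γ2 S1 + 1`.

The package answers, on synthetic data with the experimental design's
structure:

* is the reduction sound (is the reduced dynamics exactly the eliminated
  dynamics on the quasi-steady-state variety, and how far is either reduced
  model from the full one)?
* which models are identifiable — structurally (is the parameter-to-data
  map injective?) and practically (is the likelihood-ratio confidence
  region `U_δ = φ⁻¹(B_ρ)` bounded)?
* what do the parameters look like a posteriori, and do different MEK
  variants' posterior clouds differ in *shape*?  The last question is
  answered topologically: a kernel density estimate on each cloud, a
  Vietoris–Rips complex filtered by negative density, persistent homology
  over F₂, bottleneck distances between barcodes, and empirical p-values
  from resampling.

Audience: systems biologists and applied algebraists working on model
reduction, identifiability and topological data analysis of inference
output.

## Worked example

```python
import numpy as np
from erkin.synthdata import default_scenario, generate_timecourse
from erkin.identifiability import mle_fit, algorithm1_neg_log_kstar, wilks_neg_log_kstar
from erkin.inference import PriorSpec, sample_posterior

z = generate_timecourse(default_scenario("wild-type"), model="linear", seed=3)
fit = mle_fit(z, "linear", seed=0)
print("MLE:", fit.theta_hat.round(4), " sigma_hat:", round(fit.sigma_hat, 4))

nlk = algorithm1_neg_log_kstar(fit.theta_hat, fit.sigma_hat, z.design,
                               "linear", alpha=0.05, n_sim=500, seed=2)
print("bootstrap -log k*:", round(nlk, 3),
      " Wilks:", round(wilks_neg_log_kstar(0.05, 3), 3))

cloud = sample_posterior(z, z.design, "linear", PriorSpec(),
                         n_samples=500, n_chains=4, seed=7)
print("posterior means:", cloud.samples.mean(axis=0).round(4))
```

prints

```
MLE: [0.5027 1.5341 0.2934]  sigma_hat: 0.1016
bootstrap -log k*: 4.336  Wilks: 3.907
posterior means: [0.5023 1.5541 0.286  0.1027]
```

The data were generated at `(κ1, κ2, π) = (0.5, 1.5, 0.3)` with noise
σ = 0.1 μM and 11 replicates: the least-squares MLE lands within one
standard error of the truth, the bootstrap-calibrated likelihood-ratio
critical value agrees with the Wilks χ²₃/2 asymptote to within its
Monte-Carlo error, and the posterior (2000 pooled draws from four
independent chains, convergence-gated) concentrates around the generating
values — including the inferred noise level in the fourth column.

A command-line interface wraps the stages:

```sh
erk simulate --model linear --seed 1 --out tc.csv
erk identify --model linear --data tc.csv --pair kappa1,kappa2 --out region.csv
erk infer --data tc.csv --out posterior.csv
erk all --config config.json --out-dir out/   # full pipeline + manifest
erk report --manifest out/manifest.json
```

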