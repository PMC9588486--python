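# Methods

## The biochemical model

ERK is activated by its kinase MEK through sequential phosphorylation of
two sites.  The mass-action mechanism tracked by the **Full model** has six
species — free substrate in its three phosphorylation states (`S0`, `S1`,
`S2`), the two enzyme–substrate complexes (`C1`, `C2`) and free enzyme
(`E`) — and six rate constants: binding (`kf1`, `kf2`, per μM per min),
unbinding (`kr1`, `kr2`) and catalysis (`kc1`, `kc2`, per min):

    S0 + E <-> C1 -> C2 <-> S1 + E,   C2 -> S2 + E

No phosphatase is present (the experiments omit one), so phosphorylation is
irreversible at the pathway level and the system relaxes to fully
phosphorylated substrate.  Two conservation laws hold: total substrate
`S_tot = S0+S1+S2+C1+C2` and total enzyme `E_tot = E+C1+C2`.  The
experimental condition fixes `S_tot = 5 μM`, `E_tot = 0.65 μM`, with
everything initially unphosphorylated and unbound.

## Quasi-steady-state reduction

The complexes equilibrate fast relative to the substrate states
(`E_tot ≪ S_tot`, Michaelis constants `k_Mi = (k_ci+k_ri)/k_fi ≈ 25 μM`
well above the working concentrations).  The reduction is algebraic rather
than asymptotic: split the state into retained variables `x1 = (S0,S1,S2)`
and eliminated variables `x2 = (C1,C2)`, eliminate `E` through one of the
two conservation laws, and solve `f2(x1,x2) = 0` for `x2` where `D2 f2` is
invertible.  The zero set of `f2` is an invariant manifold of the auxiliary
system

    dx1/dt = f1(x),    dx2/dt = -D2f2(x)^{-1} D1f2(x) f1(x),

and on it the retained dynamics close.  Eliminating `E = E_tot - C1 - C2`
yields the **Rational model**

    dS0/dt = -κ1 S0 / D,  dS1/dt = (-κ2 S1 + (1-π) κ1 S0) / D,
    dS2/dt = (π κ1 S0 + κ2 S1) / D,      D = γ1 S0 + γ2 S1 + 1,

while `E = E_tot - S_tot + S0 + S1 + S2` (exact on the reduced state space,
where the complexes carry no substrate) yields the **Linear model** (`D = 1`).
The reduced parameters are the kinetic efficiencies `κi`, the processivity
`π` (probability that one enzyme encounter adds both phosphates) and the
saturation coefficients `γi`.

The exact elimination gives

    κi = E_tot · kfi·kci/(kci+kri),     π = kc2/(kc2+kr2),
    γ1 = kf1·(kc1+kc2+kr2) / ((kc1+kr1)(kc2+kr2)),
    γ2 = kf2/(kc2+kr2) = 1/k_M2 .

The `kr2` term in `γ1` accounts for the processive feed of the second
complex by the first; simplified forms in the literature print
`γi = kfi(kc1+kc2)/((kc1+kr1)(kc2+kr2))` instead, which agrees only when
`kr2 ≪ kc1+kc2` (for `γ1`) or `kc2 = kr1` (for `γ2`).  We implement the
exact map: it is the one under which the reduced right-hand sides reproduce
the eliminated dynamics to machine precision (this identity is a test).
At `k_Mi = 25 μM` with catalysis and unbinding of comparable size,
`γ1 ≈ 1.5/25` and `γ2 = 1/25` per μM — both small, so the Linear model is a
good approximation of the Rational one.  Over the 20-minute experimental
window at these constants the sup-norm trajectory errors against the Full
model measure ≈ 0.3 μM (Linear) and ≈ 0.06 μM (Rational) out of a 5 μM
budget: the same order, with the Rational model resolving the ~30%
saturation of the initial rates.

The measured channels are physically `S0+C1`, `S1+C2`, `S2`; at
`E_tot/k_M ≈ 0.026` the complex contributions are ≤ 3% and the bare
substrate states are used as observables throughout.

## Identifiability

The prediction map φ sends parameters to the noise-free observables — the
three substrate states at the design's `l` time points, tiled over `r`
replicates (length `3·l·r`).  Measurement noise is i.i.d. Gaussian with one
standard deviation σ, so the MLE is the least-squares fit (multi-start
trust-region over a bounds box, Latin-hypercube starts; the replicate
dimension is collapsed exactly onto the replicate mean) and
`σ̂² = rss/(3lr)` (ML convention, no degrees-of-freedom correction).

*Structural* identifiability of the Linear model is witnessed
constructively: from exact `S0` and `S1` at any three distinct positive
times, `κ1` follows from the log-decay of `S0` (cross-checked across
times), `κ2` from the amplitude-free ratio of two `S1` values (bracketed
scan plus Brent root-finding; the degenerate `κ1 = κ2` branch is evaluated
with a series-stable exponential difference quotient), and `π` from the
amplitude; the third time point validates the solution.  Round-trips
succeed to 1e-8 when the three times span the dynamic range.  With all
three times late relative to `1/κ2`, the map — though injective — flattens
onto the ridge `(1-π)/(κ2-κ1)` and recovery is numerically ill-conditioned;
the tests draw spread triples, as a real design would.

*Practical* identifiability is the boundedness of the likelihood-ratio
confidence region `U_δ = {θ : -log ψ(θ, z*) < δ}`, equivalently the
preimage of the data-space ball of radius
`ρ = sqrt(rss + 2σ̂²·(-log k*))`.  The critical value `-log k*` is
calibrated two ways: a parametric bootstrap (simulate data at the fitted
parameters, refit, take the empirical `(1-α)`-quantile of the negative log
likelihood-ratio; σ held fixed at σ̂) and the Wilks asymptote
`χ²(dof; 1-α)/2` (3.907 for three parameters at α = 0.05).  For
well-specified Gaussian data the likelihood-ratio statistic is pivotal, so
the bootstrap agrees with Wilks at any replicate count here; large
discrepancies on real data indicate model–data misfit inflating σ̂ relative
to replicate scatter rather than a small-sample effect.

The region is explored by accept/reject sampling over a per-parameter
bounds box (uniform proposals, or a factorial grid for very wide boxes) and
classified as `bounded` / `boundary-contact` / `empty` by whether accepted
points approach the proposal bounds in the marginalised pair (margin 2% of
each range).  Default boxes centre on the MLE with half-width six
Gauss–Newton standard errors so that the region is actually resolved by the
proposals; for the Rational model's `γ1` the box is widened to (0, 1000)
per μM.  At the synthetic-data noise level (σ = 0.1 μM) the Linear region
is strictly interior (practically identifiable) while the Rational region
hugs the `γ1 = 0` boundary — the data cannot separate the Rational model
from its Linear submodel, so the saturation parameters are not practically
identifiable, though the region is *finitely* bounded above (γ1 ≲ 0.04).
The escape to arbitrarily large `γ1` (saturated kinetics compensating with
large `κ1`) costs ≈ 0.12 μM RMS misfit and enters the 95% region only when
σ ≳ 0.7 μM; noisy real measurements can therefore show an unbounded region
where this clean synthetic setting does not.

## Bayesian inference

Parameters `(κ1, κ2, π, σ)` carry independent uniform priors —
`κi ~ U(0,10)` per min, `π ~ U(0,1)`, `σ ~ U(0,10)` μM — and the Gaussian
likelihood above.  Sampling is adaptive component-wise random-walk
Metropolis: four independent chains, per-coordinate proposal scales
adapted toward 44% acceptance during 2000 warm-up sweeps only (the
post-warm-up kernel is fixed, hence valid), then 500 draws per chain kept
at thinning 5 and pooled to 2000.  A diagnostics gate — rank-normalised
split-R̂ < 1.05 and bulk ESS > 100 per coordinate — must pass before a
cloud is returned; on failure warm-up and thinning double (twice) before a
hard error.  Everything is deterministic given the seed.  On synthetic
wild-type data the posterior concentrates around the generating values with
σ-level accuracy (z-scores below 3).  Rational/Full-model sampling uses the
same machinery with `γi ~ U(0,1000)`; those posteriors are prior-sensitive
(a symptom of the practical non-identifiability) and are treated as
experimental.

## Topological comparison of posterior clouds

Each variant's posterior sample, marginalised to `(κ1, κ2, π)`, is
summarised topologically:

1. **Density estimate** — Epanechnikov kernel (compactly supported on the
   unit ball, normalised per dimension), bandwidth from a Silverman rule of
   thumb refined by 5-fold cross-validated held-out log-density over a
   multiplicative grid (0.35–2.8×); deterministic per fold seed.
2. **Complex** — Vietoris–Rips at scale equal to the bandwidth
   (incremental clique expansion), dimension capped at `k_max + 1`.
3. **Filtration** — each simplex enters at the negative density of its
   least-dense vertex (a super-level-set filtration of the density:
   high-density regions enter first).
4. **Persistence** — boundary-matrix column reduction over the two-element
   field in filtration order (ties broken by dimension then lexicographic
   vertex tuple); columns are integer bitmasks.  Classes surviving the
   whole filtration are closed at density level 0, where a non-negative
   density's super-level sets are exhausted: an H0 bar then encodes a mode
   (height = −birth, prominence = persistence) and distances between
   clouds with different component counts remain finite.
5. **Bottleneck distance** — exact: binary search over candidate values
   with a bipartite-matching feasibility test (bars may be left unmatched
   at half their persistence; essential bars only match essential bars).
   Cross-checked against exhaustive matching enumeration in tests.
6. **Significance** — the empirical p-value: resample β fresh size-n
   clouds from each of the two sources, form null distances to the
   corresponding base barcode, and report
   `min((#{null ≥ d}+1)/(β+1))` over the two sides.  With β = 99 the
   smallest attainable p-value is 0.01.  (The rank is counted as
   exceedances of the observed distance, so *large* distances get *small*
   p-values; a complementary-rank convention would inert the test.)

A finite-sample recovery bound of Bobrowski–Mukherjee–Taylor type for the
barcode of a KDE filtration is provided (`bobrowski_bound`) for reporting;
the sample sizes it demands for significance are far beyond what persistent
homology can process, which is why the empirical p-value is used.  All
persistent-homology computations run on size-200 subsamples: the density
filtration's barcode is stable under subsampling at this size (unlike a
Vietoris–Rips filtration's, whose bars shrink with sample size), and the
complexes stay tractable.

The synthetic variant suite emulates the comparison study: four variants
(wild-type and three activating mutants) share a unimodal posterior shape
with mildly perturbed spreads and different centres — location does not
affect the density barcode, so these are topologically similar — while the
phosphomimetic variant's cloud concentrates on a tight closed ridge in the
`(κ1, κ2)` plane (the shape of a correlated non-identifiability), carrying
a prominent persistent 1-cycle.  In the all-pairs H1 analysis that variant
dominates every pair it enters and its pairs reach the minimal p-value.

## Numerical choices

- ODE integration: adaptive explicit Runge–Kutta (RK45), `rtol 1e-8`,
  `atol 1e-10`; the systems are non-stiff at the experimental magnitudes.
- `κ1 ≈ κ2` in the closed form: series-stable difference quotient switch at
  `|κ1-κ2| < 1e-9·max(κ1,κ2,1)`.
- Rank test for `D2 f2`: `|det| > 1e-12 ×` product of row ∞-norms
  (scale-free); user-supplied systems fall back to central finite
  differences with step `1e-6·max(1,|x|)`.
- Empirical quantiles interpolate linearly between order statistics.
- Failed integrations inside region tests count as non-members (with a
  warning): conservative region estimates.
- Membership uses strict inequality; boundary points are outside.

## Problem sizes

Simulation studies are sized to run on a laptop-class machine: bootstrap
calibration uses 500 replicates (2000 for the large-replicate asymptotics
check, where the quantile's Monte-Carlo standard error is ≈ 0.1), region
sampling 20 000 proposals, posterior clouds 2000 pooled draws, and the
topological comparison β = 99 resamples of size 200 per variant.

## Known limitations

- The generator's i.i.d. Gaussian noise with a single σ is the analysis'
  own assumption; real replicate structure (batch effects, heteroscedastic
  channels, model–data misfit) is not emulated, so passing tests certify
  the machinery, not robustness to misspecified noise.
- Differential-algebra structural identifiability (characteristic-set or
  ideal-based software) is out of scope; the Linear model's injectivity is
  established constructively and the Rational/Full models are probed only
  numerically.
- The exact bottleneck matcher and the pure-Python reduction are built for
  the n ≈ 200 subsample scale, not for clouds of 10^4+ points.
- Rational/Full-model posteriors depend visibly on their priors; the
  package reports this rather than hiding it.
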