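# Methods

## The question and the models

Competition between closely related species is expected to leave a
signature in how continuous ecomorphological traits (beak shape principal
components, relative beak size, body mass) diversify across a clade:
lineages should be pushed apart in trait space by their coexisting,
ecologically similar relatives. `phylocomp` contrasts the fit of trait
models in which lineages evolve independently with models in which
evolutionary rates, or the drift itself, depend on the other lineages alive
at the same time.

All seven models describe a Gaussian process z(t) along a rooted,
time-calibrated (ultrametric where required) phylogeny with time running
from 0 at the crown root to the depth T at the present:

* **BM** — dz = sigma dW; tip covariance sigma^2 t_ij, with t_ij the shared
  time from the root to the pair's most recent common ancestor.
* **OU** — dz = -alpha (z - z0) dt + sigma dW, with the optimum fixed at the
  root state z0 and the process started at z0 (non-stationary,
  root-conditioned). On an ultrametric tree,
  var = sigma^2/(2 alpha) (1 - e^{-2 alpha T}) and
  cov_ij = sigma^2/(2 alpha)(1 - e^{-2 alpha t_ij}) e^{-2 alpha (T - t_ij)}.
  Non-ultrametric input is rejected rather than silently approximated.
* **TDlin / TDexp** — rate sigma^2(t) = sigma^2 + b_t t or
  sigma^2 e^{r_t t}; covariances are the closed-form integrals of
  sigma^2(u) over the shared path.
* **DDlin / DDexp** — rate sigma^2(t) = sigma^2 + b_n n(t) or
  sigma^2 e^{r_n n(t)}, with n(t) the reconstructed lineages-through-time
  step function (2 at the crown, +1 at every later branching). When a
  regime map is supplied, each lineage's n(t) counts only the lineages
  sharing its regime (ecoguild) state at that instant, and the covariance
  integral is accumulated along each pair's shared root-to-MRCA path.
* **MC** (matching competition) — each lineage is deterministically
  repelled from the mean trait of its interaction set:
  dz_i = S (mu_i(t) - z_i) dt + sigma dW_i with S <= 0. mu_i averages over
  the lineages coexisting with i (same-regime lineages when structured,
  everyone otherwise; always including i itself, so singletons feel no
  drift).

### Exact MC moments

Between two consecutive events (branching times and regime-change times)
the interaction matrix A = S (P - I) is constant and block diagonal by
regime, with P_g = J/n_g inside a block of size n_g. On each block A has
eigenvalue 0 on the constant vector and -S (>= 0: repulsion grows
deviations) on its orthogonal complement, so the propagator and the
integrated process noise have exact projector forms:

    exp(A dt) = J/n_g + e^{-S dt} (I - J/n_g)
    integral_0^dt exp(2 A u) du = dt J/n_g + (e^{-2 S dt} - 1)/(-2S) (I - J/n_g)

The joint covariance of all alive lineages is propagated interval by
interval with V <- E V E^T + sigma^2 W; at a branching the parent row and
column are duplicated. This is exact (no ODE solver, no discretization) and
costs O(events * n^2) per evaluation, which is what makes the replicated
model-selection studies below cheap. A two-tip sanity case decouples into
sum and difference coordinates: at sigma^2 = 1, S = -1, T = 1 the
difference variance is e^2 - 1 and the tip variance (e^2 + 1)/4 ~ 2.0973,
reproduced by the propagation to 1e-10 and by Euler-Maruyama simulation to
Monte-Carlo error.

### Simulation

Gaussian models are simulated by exact per-branch increments (OU by its
exact transition toward z0). MC is simulated by Euler-Maruyama on a shared
global grid of T/2000 steps (refined whenever |S| h > 0.01), duplicating a
lineage's state at each branching. Simulated tip moments agree with the
analytic moments within Monte-Carlo error for every model (the suite's
central consistency oracle); MC tips carry an O(h) discretization bias that
the tests accommodate with a slightly wider gate.

## Fitting

Every model's tip covariance is proportional to sigma^2 once the linear
slopes are expressed relative to it (b = sigma^2 b_rel), and the mean is
z0 * 1. Both are therefore concentrated out of the likelihood analytically:
z0 by GLS, sigma^2 by its closed-form ML value q/n. What remains is at most
one shape parameter per model, maximized over a transformed coordinate with
documented bounds — log alpha in [-10, 7]; S in [-50, 0] searched on a
log(1 - S) scale so resolution concentrates near the BM boundary; slopes
and exponents bounded so the relative rate factor stays within
[1e-8, 1e6] over the tree — by a deterministic coarse grid (8 start points)
plus bounded Brent refinement. This is strictly more robust than a
multi-start quasi-Newton search in the full parameter space and two orders
of magnitude faster; the parameter count used by AICc is still the model's
full count (BM 2; all others 3). Degenerate effective rates (DDlin/TDlin
below 1e-8 of sigma^2) are rejected as out of domain during the search.

AICc = -2 lnL + 2k + 2k(k+1)/(n-k-1). A clade x trait is **flagged for
competition** when the smallest-AICc model is DDlin, DDexp or MC and it
beats the best independent-evolution model (BM/OU/TDlin/TDexp) by more than
2 AICc units; ties within 1e-8 prefer fewer parameters, then alphabetical
order. When a model is fitted under a collection of stochastic regime maps,
it is fitted separately per map and the map-mean AICc, log-likelihood and
parameters are reported (per-map fits are retained), treating map
uncertainty symmetrically.

Relative beak size is the residual of a phylogenetic GLS regression of size
on body mass under the unit-rate BM correlation structure (statsmodels GLS
behind the interface).

## Ecoguilds and stochastic maps

Species carry one of 8 diet labels and one of 9 foraging-stratum labels.
The one-hot species x 17 indicator matrix is column centered and
decomposed by SVD (computed on a canonically row-sorted copy so the result
is exactly permutation invariant); the quadrant of each species' scores on
the first two axes is its ecoguild (at most 4). Axis signs are fixed by
forcing the largest-magnitude loading positive; guild labels are therefore
arbitrary but stable, which suffices because only co-membership enters the
structured models. Guild histories are reconstructed with an Mk model
(default ER — one rate; richer flavors are rarely identifiable with four
states on clades of a few dozen tips) fitted by pruning, root prior equal
by default. Stochastic maps draw node states from the joint conditional
distribution and fill in each edge by *exact endpoint-conditioned
uniformization*: the number of uniformized jumps is drawn from its exact
conditional law (support capped at 1000 jumps; exceeding the cap raises a
diagnostic sampling error), then the bridge states from the R-power
factorization. Reconstructions averaging more than 10 state changes per
tree-depth of branch length are flagged as suspect.

## The false-positive study

Traits are simulated under OU (sigma^2 = 0.1; alpha = 1 or 5; z0 = 0) on
pure-birth trees standardized to depth 1 — sizes 25/51/112/195 by default,
mirroring small-to-large empirical clades; the first two sizes are used in
the replicated studies at desk scale. Each replicate is fitted with OU and
the competition models; a false positive is a competition model beating OU
by more than 2 AICc units. Rates come with 95% Wilson intervals. In the
guild arm, 4-state guild histories are simulated under ER Mk (rate 0.5 per
unit depth), the Mk model is re-fitted to the tip states and 10 maps
sampled per tree.

Measured behavior: false-positive rates are below 5% at alpha = 1 (with and
without guild structure) and remain near zero at alpha = 5. We find no
intrinsic inflation of DDexp false positives under strong constraint: as
the constraint (or the diversity-dependent acceleration) grows, both models
approach the same iid-tips limit, and the exactly-maximized OU likelihood
dominates — across 200 strong-constraint replicates the DDexp log-likelihood
never exceeded OU's by more than 1.33, while an AICc win of 2 requires more
than 1. Large DDexp false-positive rates (tens of percent) reappear only
when the OU fit is handicapped, e.g. its constraint parameter bounded below
the generating value, as some legacy optimizer defaults do; a regression
test demonstrates exactly this mechanism. Conclusions drawn from inflated
DDexp support under strong constraints should therefore be checked against
the OU optimizer's bounds before being attributed to the data.

Two further calibration facts worth knowing. First, the guild-structured
arm is slightly *noisier* than the unstructured one against an exact OU
fit: across replicates the AICc difference (OU minus structured DDexp) is
centered near -2 with a spread of ~3 units, so a 3-7% tail lands beyond
the +2 flagging threshold — structured false-positive rates hover around
the 5% mark rather than clearly below it. The map-derived covariance is a
genuinely different, somewhat more flexible family, and averaging over 10
maps does not remove replicate-level fluctuation. Second, the ML estimate
of the OU constraint is biased upward at weak constraint: at alpha*T = 1
with 100 tips the median fitted alpha across trees is ~1.2-1.4 (a 20-40%
upward median bias, varying with tree shape). This is a small-sample
property of the estimator, not an optimizer artifact; recovery checks on
alpha should be read with that bias in mind, while sigma^2 (BM), r_n
(DDexp) and S (MC) medians recover their generating values within a few
percent at the same sizes.

## Clade-level synthesis

Binary competition flags across clades are summarized by prevalence tables
(per trait and "any trait") and by the Fritz-Purvis D statistic on a
clade-level tree (each named clade collapsed to one lineage attached at its
stem and terminating at the present). d is the sum over internal nodes of
absolute contrasts between daughter values, daughters estimated as means of
their children; D rescales d between the mean under label shuffling (D = 1)
and under a threshold-BM process matched to the observed prevalence
(D = 0). Calibration on a 64-tip tree reproduces both anchors within 0.02
at 500 replicates.

## Synthetic data

The generator emulates a multi-clade comparative dataset: birth-death trees
conditioned on tip count (Gillespie forward simulation, one extra
exponential hold so pure birth matches the Yule crown-depth expectation
sum_{k=2}^{n} 1/(lambda k), extinct lineages pruned), clades of 21+ tips,
guild histories under ER Mk with guild-consistent diet/forage labels
(optional label noise), and traits under any configured model with true
parameters recorded in a manifest. It does not emulate measurement error,
intraspecific variation, missing data, fossil information or correlated
evolution among traits — so passing tests demonstrate correctness of the
machinery under the models' own assumptions, not robustness of the method
on real data.

## Problem sizes and numerical choices

Replicated studies use 200 replicates (100 in the guild arm) on 25- and
51-tip trees, 100 replicates for recovery medians at 100 tips, 500
replicates for D calibration and 10000 sampled maps for the posterior
check; these sizes keep every Monte-Carlo interval comfortably inside the
tolerances asserted. Covariances are Cholesky-factorized with a single
trace-scaled jitter (1e-10 trace/n) retry; ultrametricity is enforced to
1e-6 relative; zero-length edges (from deterministic polytomy resolution)
contribute zero variance and no integration steps.
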