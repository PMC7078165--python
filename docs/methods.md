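# Methods

This note documents the models implemented in chronodiv, the defaults and
why they were chosen, the numerical choices that matter, and what the
synthetic-data experiments do and do not demonstrate.

## Soft-bounded calibration densities

A fossil calibration constrains a node age with a minimum and/or maximum
(Ma). The induced prior is proper and piecewise closed-form:

* **Interval [m, M]:** a uniform core on [m, M] carrying 1 − s of the
  probability; an exponential tail below m truncated at 0 (decay scale
  0.1·m) carrying s/2; a Lomax (shifted-Pareto) tail above M (shape 2,
  scale 0.1·M) carrying s/2. Default soft mass s = 0.05, i.e. 5% of the
  prior lies outside the stated bounds.
* **Minimum-only:** the whole s below m; above m a heavier, broader Lomax
  (shape 1.5, scale 0.5·m) as the diffuse upper shape.
* **Maximum-only:** uniform on (0, M] carrying 1 − s; the Lomax tail above
  M carrying s.

The 2.5/2.5 split of the soft mass for interval calibrations, and the tail
shapes, are conventions (configurable via `SoftBoundShape`); exponential-
below/heavy-above follows common dating-software practice, the heavy upper
tail acknowledging that maxima are weaker statements than minima. Because
each segment has closed-form cdf/ppf, total mass and tail masses are exact
by construction, sampling is by inverse-cdf, and quadrature is used only as
an independent check. s = 0 degenerates to hard bounds (density exactly
zero outside). Equal min and max is accepted as a point calibration at the
data-model level (the generator's zero-slack edge case) but has no density.

## Birth–death node-age prior

Conditioned on the root age t₁ and n extant samples with sampling fraction
ρ, the n − 2 non-root internal ages are iid with density F′(t)/F(t₁) on
(0, t₁), where

F(t) = ρλ(1 − e^{−ct}) / (ρλ + (λ(1 − ρ) − μ) e^{−ct}),  c = λ − μ.

At μ = 0, ρ = 1 this is the truncated-exponential Yule order-statistics
density; the critical case λ = μ uses its exact limit F(t) = ρλt/(1 + ρλt)
(switched below |c| < 10⁻¹² relative), so the density is continuous as
λ → μ. The prior is restricted to λ ≥ μ; the calibration × tree-prior
product is renormalized only up to a constant, which suffices for MCMC.
A useful exact property: with a single calibration on the root, the joint
prior marginalizes back to the calibration density at the root — this is
what the prior-only audit tests against a direct sampler.

## Clock models and likelihood

Branch rates (subst/site/My):

* **strict** — one global rate m.
* **UGAM** — rate_b = m·g_b, g_b ~ Gamma(1/v, v) iid (mean 1, variance v).
* **CIR** — node-wise instantaneous rates follow the mean-reverting
  square-root diffusion dr = θ(m − r)dt + σ√r dW with stationary
  Gamma(m²/v, v/m) (mean m, variance v) and σ² = 2θv/m; transitions are
  sampled and evaluated by the exact noncentral-chi-square law (Bessel
  function via exponentially scaled `ive` for stability; central-chi-square
  limit below noncentrality 10⁻¹⁰). The branch rate is the arithmetic mean
  of its endpoint node rates — the standard discretization for
  autocorrelated clocks, documented as an approximation.

The likelihood links data to rate × duration per branch. Default data are
estimated branch lengths over L sites treated as Poisson counts
k_b = round(length·L) with intensity L·r_b·d_b (a Gaussian mode with given
standard errors is available); an amino-acid alignment can be scored
exactly by Felsenstein pruning under the 20-state equal-exchangeability
(Poisson) model, whose transition matrix reduces to scaled sums — the
site-heterogeneous mixture models used for real phylogenomic matrices are
deliberately out of scope.

## MCMC

Metropolis-within-Gibbs, one chain per seed-derived stream: sliding-window
proposals on each internal age within its (oldest child, parent) window;
a multiplier move on the root age above its oldest child; a joint *scale*
move multiplying all internal ages by f and dividing all rates by f
(Jacobian-corrected) — without it the time/rate ridge of node dating mixes
very slowly; multiplier moves on rates and hyperparameters. Step sizes
adapt during burn-in toward 20–40% acceptance and are frozen afterwards.
Burn-in defaults to the first 30% of sweeps. Hyperpriors are weakly
informative and documented in code: lognormal (sd 2) on m centred on a
crude total-length/total-duration estimate, Exponential(1) on v,
Exponential(mean 0.1) on θ, λ and μ. Convergence reporting follows the
tracecomp convention: ESS per scalar trace (autocorrelation-time estimate
via arviz) and relative difference 2|m₁ − m₂|/(s₁ + s₂) across two chains;
verdict passes iff every relative difference < 1 and every ESS > 50.
Prior-only mode drops the data term and is the recommended audit of the
effective joint prior induced by a calibration set.

## Clock-model cross-validation

Ten random learning/test splits; in each, both models are fit on the
learning fraction and scored by held-out predictive log-likelihood; the
summary is the per-replicate score differences, their mean ± SE, and a
majority verdict. With Poisson branch-length data a site split is exact
binomial thinning of each branch count. Scoring is closed form:

* strict — plug-in Poisson at the pooled rate estimate;
* UGAM — gamma–Poisson conjugacy: hyperparameters (m, v) maximize the
  negative-binomial marginal of the learning counts; the test counts score
  against the per-branch posterior-predictive negative binomial;
* CIR — a gamma filter down the tree: each branch's prior mean and
  variance shrink toward its parent branch's posterior with weight
  e^{−θ·Δ} (Δ = mid-branch separation), hyperparameters (m, v, θ) maximize
  the prequential marginal. This is an approximation to the integrated CIR
  predictive; sibling branches share information only through their parent.

The default learning fraction is 0.9. Distinguishing *prior structures*
(autocorrelated vs exchangeable) needs splits in which the prior carries
weight in prediction — with 90% learning data the per-branch counts
dominate both priors and the comparison degenerates toward a tie — so the
CIR-vs-UGAM recovery experiment uses a 0.5 split; the fraction is an
explicit argument.

## Rate-through-time estimators

Estimator 1 divides relative branch lengths (subst/site) by branch
durations. Estimator 2 reconstructs marginal ancestral states at every
internal node under the equal-exchangeability model (branch lengths =
durations × a 1-D ML global rate), counts positions whose most-probable
states differ between the branch's endpoints, and divides by effective
sites × duration. Ties in a child's posterior are broken in fixed alphabet
order and count as no change when the parent state attains the tied
maximum; gap positions at a leaf are excluded from both the change count
and the effective length of that branch. Gross-change counting saturates
on long branches (at most one change per site per branch), so estimator 2
is mildly downward-biased when rate × duration per site is not small.

The rate curve bins [0, root age] into equal widths (default 10, matching
the diversification bins); each branch contributes to every bin it
overlaps, weighted by overlapping duration. The duration-weighted curve
mean therefore equals the duration-weighted branch-rate mean exactly.
Binning (rather than smoothing) is one documented choice for turning
branch rates into a time series.

## Episodic birth–death model

B equal bins over [0, root age] (binning over the observed root age is a
documented choice; a fixed span is possible by constructing the bin edges
directly). Prior, moving backward in time: youngest-bin log λ and log μ
uniform on [−10, 10] — natural log assumed, as the scale is not otherwise
determined — then normal increments with mean inherited from the previous
(younger) bin and sd σ ~ Exponential(mean 1); extinction receives the same
autocorrelated structure as speciation. The likelihood composes, across
bin boundaries, the closed-form solutions of the Riccati equation for the
extinction probability E(t) and the log propagation factor of the
reconstructed-tree recursion, with speciation factors at internal nodes,
ρ at the tips, and conditioning on the root age and on both root lineages
surviving. The critical case λ_b = μ_b uses its exact limit. Splitting a
bin without changing rates leaves the likelihood exactly invariant, and a
single bin equals the constant-rate closed form — both are tested.

Incomplete sampling: uniform ρ (default for synthetic work) or clade
diversity counts reduced to per-clade fractions with the pooled fraction
(total sampled / total described) entering E(t) — a uniform-ρ
approximation of empirical taxon sampling; the exact per-clade integration
performed by specialized diversification software is not reimplemented.
The packaged diversity table lists all twelve clades verbatim, including
Pycnogonida (outside Arachnida); inclusion is left to the caller.

MCMC is single-component random-walk Metropolis on the 2B + 1 log
parameters (log-Jacobian applied for σ), 30% burn-in, thinning 10,
reporting per-bin posterior medians and 95% HPDs.

## Synthetic-data generator

* **Constant-rate trees, tip-count mode:** the coalescent-point-process
  construction — n − 1 iid tip-separating depths from F (closed-form
  inverse), tree = Cartesian (max-at-top) tree over the depth sequence —
  which is exactly the conditioned reconstructed-tree distribution, and
  directly matches the node-age prior above. With a fixed root age the
  root depth is placed at a uniform position among the n − 1.
* **Stopping-age and episodic trees:** forward event simulation from one
  origin lineage with piecewise-constant rates switching at bin edges,
  pruning of extinct lineages, independent ρ-sampling of tips, and up to
  1000 retries on failure (attempt count surfaced in the error). The
  constant-rate stopping-age simulator *is* the single-bin episodic
  simulator, so their equivalence is definitional, and E[tips] = e^{λT}
  for pure birth holds when single-tip outcomes are permitted.
* **Rates:** strict / UGAM / CIR as in the inference model (CIR by exact
  transitions, not Euler steps, which is what makes distributional tests
  possible).
* **Substitution data:** Poisson counts over L sites (so short branches
  behave correctly; SE = √(length/L)) or alignments evolved site-wise
  under the equal-exchangeability model.
* **Calibrations:** per chosen node, min ~ U[(1 − slack)·age, age] and
  optionally max ~ U[age, (1 + slack)·age], so every generated calibration
  contains the truth.

What the generator does *not* emulate: site-heterogeneous substitution
processes, indels or alignment error, fossil (non-extant) tips,
lineage-specific sampling biases, and topology uncertainty. Passing
recovery tests therefore validates the estimators under their own model
assumptions — the appropriate target for a reimplementation — not
robustness to the violations real phylogenomic data exhibit.

## Validation experiment sizes

The experiments in `tests/test_acceptance.py` use: prior-only audit on an
8-tip tree (2 × 20,000 sweeps); root-age recovery on 100 replicates of
20-tip trees with 5 interval calibrations (slack 0.15) and L = 5000
Poisson data, 2500 sweeps each, expecting ≥ 90/100 HPD coverage;
cross-validation recovery on 40–100-tip trees with 10 splits;
rate-estimator agreement on a 30-tip tree at L = 10⁴ (r > 0.9);
diversification-shift recovery on 20 replicates of ~150–400-tip trees
simulated with a 3× speciation boost in the two youngest of ten bins
(50,000 iterations each — the single-component random-walk sampler needs
that long to relax the sparsely informed oldest bins from their common
starting value), expecting ≥ 16/20 recovered orderings, plus a
20-replicate constant-rate null whose mean log-rate slope CI must cover
zero. These sizes keep the full suite comfortably within a desktop run
while leaving each check statistically meaningful.

## Known limitations

* The CIR branch rate as the endpoint mean is a discretization; the exact
  integrated-rate law is not used.
* The calibration × birth–death prior product is unnormalized across
  calibration configurations; Bayes-factor comparison of calibration sets
  is out of scope.
* Alignment-mode MCMC recomputes the full pruning likelihood per move and
  is only practical for small trees and short alignments; branch-length
  mode is the intended path at scale.
* The cross-validation CIR score is a filter approximation (no sibling
  pooling); it is used for model ranking, not for parameter inference.
* No topology estimation, no tip dating / fossilized birth–death, no
  mass-extinction point events.
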