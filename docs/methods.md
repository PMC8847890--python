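# Methods

## The model family

Cocoa bean fermentation is driven by a three-phase microbial succession in
the bean pulp: yeasts (Y) ferment glucose (Glc) and fructose (Fru) to
ethanol (EtOH); lactic acid bacteria (LAB) convert glucose to lactic acid
(LA) and acetic acid (Ac); acetic acid bacteria (AAB) oxidize ethanol and
lactate to acetate.  The baseline model couples these eight states through
ordinary differential equations with

* Monod growth rates `v = mu_max * S/(S+K) * X` for Y on Glc/Fru, LAB on
  Glc, and AAB on EtOH;
* one Contois rate for AAB on LA, `v5 = mu * LA/(LA + K*AAB) * AAB`, whose
  half-saturation scales with biomass;
* Chick–Watson mortality terms `k_Y*[Y][EtOH]`, `k_LAB*[LAB][LA]`,
  `k_AAB*[AAB][Ac]^2` — each population is killed by the product that
  accumulates in its own phase, with second-order acetate kinetics for AAB;
* yield coefficients `Y_a|b` linking each unit of biomass growth to the
  metabolite it consumes or produces.

That gives 24 baseline parameters: 5 maximum specific growth rates, 5
saturation constants, 3 mortality constants and 11 yield coefficients.
Five optional mechanisms extend the baseline:

| mechanism | process | extra parameters |
|---|---|---|
| M1 | abiotic decay of EtOH, LA, Ac (evaporation, diffusion into beans) | 3 |
| M2 | fructose consumption by LAB with EtOH/LA/Ac side-products | 7 |
| M3 | acetate production by yeast during sugar growth | 2 |
| M4 | lactate consumption by yeast, producing EtOH | 4 |
| M5 | acetate over-oxidation by AAB | 3 |

Every subset of `{M1..M5}` is a variant, labelled `MI(0)` … `MI(1,2,3,4,5)`
(32 in total; 24–43 free parameters).  Internally a variant is an index set
into the full 43-parameter table; inactive entries are fixed at zero, which
removes their rates identically, so the reduced and the zero-extended
models produce bit-identical trajectories.

## Numerics

Trajectories are integrated with an adaptive Dormand–Prince 5(4)
Runge–Kutta stepper (relative and absolute tolerance 1e-6, at most 1e4
steps), compiled with numba because a posterior fit requires on the order
of 1e5 solves.  Two independent oracles check it in the test suite: a
fixed-step RK4 at h = 0.001 h and scipy's `solve_ivp` RK45 at tolerance
1e-9.  Agreement is measured per state relative to that trajectory's own
scale (`max_t |diff| / max_t |oracle|`), because states such as AAB decay
to ~1e-5 where a pointwise relative error is meaningless at any tolerance.

Depleted substrates are treated as contributing zero growth (`S <= 0` ⇒
rate 0), which makes the vector field continuous across the axis.  After
each accepted step, components in `[-1e-4, 0)` (100·atol) are projected to
0; a component below that aborts the solve.  Undershoot at
substrate-depletion crossings routinely exceeds the bare atol while still
being a tolerance-level artifact, hence the 100× slack.

## Preprocessing and the unit map

Microbial counts arrive as log10 CFU per g pulp and are converted to
biomass with per-group cell masses (defaults 5e-8 mg for yeast, 1e-9 mg
for LAB and AAB — order-of-magnitude cell dry weights; they cancel under
max-scaling, so only original-unit reporting depends on them).  Each
series is then divided by its own maximum.  Parameter estimates on the
scaled space are mapped back to original units by dimensional analysis:
growth and decay rates (h⁻¹) pass through; a Monod K is multiplied by its
substrate's maximum; the Contois K by the LA/AAB maximum ratio; a yield
`Y_a|b` by (max of a)/(max of biomass b); mortality constants are divided
by the relevant product maximum (squared for AAB).  The map is pinned by a
test asserting dynamical equivalence: integrating in raw units and then
scaling equals integrating the transformed parameters from scaled initial
conditions, for all 32 variants.

## Bayesian fitting

Observations are modelled as Normal around the ODE solution with one
shared standard deviation σ across all series and times (scaled units);
missing entries are simply omitted.  The trajectory starts at the first
scaled observation row (the initial state is not estimated).  Priors are
`theta_k ~ N(0.5, 0.3)` truncated to positives and `sigma ~ Cauchy(0, 1)`
truncated likewise — weakly informative on the scaled space where all
plausible values lie in roughly (0, 1.3).

Sampling uses emcee's ensemble MCMC with `2*ndim + 2` walkers, a 0.8/0.2
mixture of differential-evolution and stretch moves, 3000 iterations per
walker with 1000 warm-up by default, and draws thinned to about
`chains × (iterations − warmup)` rows.  The snooker move is deliberately
not used: in the installed emcee version it demonstrably contracts a
stationary Gaussian ensemble (a bug we detect in a stationarity check),
which silently narrows credible intervals.  Walkers are initialized in
tight log-normal balls around the posterior modes found by multi-start
L-BFGS-B in log-parameter space; all local optima within 25 log-posterior
units of the best are retained and walkers are spread across them, because
these posteriors are frequently multimodal (e.g. partial exchanges of the
two sugar-uptake channels) and a single-mode start would miss real
posterior mass.  With a flat likelihood (prior-only sampling) walkers
start at exact prior draws, and a test verifies the sampled marginals
against the closed-form truncated densities.

Convergence follows the standard split-R̂/ESS criteria: success requires
max R̂ < 1.05, minimum bulk- and tail-ESS > 100, and mean bulk-ESS over
the number of retained draws above 12.5%.  If bulk- or tail-ESS fails, the
fit is rerun once with doubled iterations before a non-convergence verdict.
A fit that needed a non-default prior is never labelled successful.
Integration failures during sampling are treated as log-posterior −∞.
Note that the ESS/N ratio criterion was designed around NUTS, whose draws
are nearly independent; an ensemble sampler's thinned draws carry more
autocorrelation, so formal "success" is rarer here at equal draw counts —
the verdict is reported as-is rather than re-tuned.

## Model assessment

Per dataset, competing variants are compared by PSIS-LOO (via arviz) on
the stored pointwise log-likelihood matrix, with the relative efficiency
estimated from the chain structure.  Pseudo-BMA weights are the softmax of
elpd values over the variants that succeeded on that dataset (the basic
estimator, no Bayesian-bootstrap correction).  `BMA_w` averages those
weights over all datasets fitted by at least one variant, counting zero
where a variant failed.  OSR is successes over that same denominator; ESR,
defined for multi-mechanism variants, is the product of the stand-alone
OSRs of the constituent mechanisms.  Rounding to two decimals happens only
at report time.

## Feature classification

For one variant fitted across many trials, posterior draws are rescaled to
original units (so trials with different measurement scales are
comparable), filtered per chain to the joint central-95% box — a draw is
retained only if every coordinate lies inside its own parameter's
per-chain 95% interval, keeping draw vectors intact for PCA — and pooled.
PCA is run on mean-centred, unscaled columns (full SVD, signs fixed so
each component's largest-magnitude loading is positive), either on all
parameters or on subgroups: maximum growth rates, mortality rates, yield
coefficients, or Y/LAB/AAB-related parameters (a parameter belongs to a
group if its definition names that microbial group; saturation constants
appear only in "all" and the related-group sets).  Class separation on
(PC1, PC2) is the pairwise squared Mahalanobis distance between class
centroids under the pooled within-class covariance, summarized by the
median over pairs.

## The synthetic-data generator

The generator emulates the statistical structure of literature-digitized
fermentation trials: 6–17 observation times over 0–160 h (uniform or
jittered-uniform grid), the three-phase succession, and Gaussian noise on
the scaled space.  Noise sd is specified relative to each series' own
trajectory maximum, so after the pipeline's max-scaling the shared-σ
observation model holds with σ ≈ `noise_sd` on every series — the noise
the fit assumes is the noise the generator produces.  The first
observation row is left noise-free by default because the fitting
convention anchors the initial state there; noise on that anchor would
perturb the initial condition of every comparison against ground truth
(a flag restores noise at t0).  Negative noisy values are clipped to zero
(to a 1e-6 floor for microbial series, which must survive the log10 CFU
transform).  Raw units come from nominal series maxima (sugars ~50 mg/g,
ethanol 18, lactate 7, acetate 10 mg/g; microbial biomass consistent with
peak counts near 10^8–10^9 CFU/g).

The default "true" parameter preset produces the canonical succession
(yeast peak near 40 h, LAB near 46 h, AAB near 66 h; glucose exhausted
first, fructose partially; ethanol then acetate accumulating before
oxidation).  The preset makes the two sugar channels deliberately
asymmetric — glucophilic yeast with fast low-K glucose uptake and slow
high-K fructose uptake — both because that is the observed regime in cocoa
pulp and because a symmetric choice creates an exact label-exchange
degeneracy (two posterior modes with sugar roles swapped) that makes
parameter recovery ill-posed for any sampler.

Ground-truth records store the generating parameters, σ, scale factors and
the noise-free trajectory.  Because a refit max-scales by the observed
(noisy) maxima rather than the generator's nominal ones, truths are
compared in "fit space" via the exact unit map (raw units as the
intermediate step).

What passing synthetic tests do **not** show: the generator has no
digitization error, no temperature dynamics, no irregular missingness
patterns, and its noise is exactly the model's noise — real-data
performance (success rates, identifiability) will be worse than the
synthetic results, as the high failure rates on real trials reported for
this class of models suggest.

## Known limitations

* Practical non-identifiability is intrinsic: with ~136 observations and
  24–43 parameters, the likelihood has soft ridges (growth-rate/saturation
  trade-offs) along which the prior locates the posterior.  Credible
  intervals for a *fixed* truth far from the prior's choice on a ridge can
  therefore miss it even for a perfectly converged posterior; coverage
  statements are calibrated in the Bayesian (prior-averaged) sense.
* The ensemble sampler meets the R̂ and ESS floors on routine fits, but
  the 12.5% ESS/N ratio bar — natural for NUTS — typically requires the
  doubled-length rerun or longer.
* The shared-σ noise model treats all series as equally noisy on the
  scaled space; per-series σ is deliberately not implemented.
* Problem sizes in the test-suite and the reproduction script (chain
  lengths of 250–4000 iterations, 2–5 seeds, cohorts of 4–6 trials) are
  chosen to keep the full suite fast while leaving every statistical
  check properly powered; they are smaller than what one would use in a
  production analysis of real trials.
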