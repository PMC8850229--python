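# Methods

## The problem

Regulatory toxicology studies need a defensible upper dose. The kinetically
derived maximum dose (KMD) is the exposure at which systemic elimination
kinetics begin to saturate: doses on either side of that boundary engage
different modes of action, so a study should stay on one side of it. kmdkit
locates the KMD not as a point but as a *region*, because the transition to
saturation is gradual — there is no concentration where the kinetics "break".

## Model

Elimination is treated as a single system-wide saturable process,

    dC/dt = -Vmax * C / (Km + C),

with C the blood concentration (mg/dL), Vmax the asymptotic maximum
elimination rate and Km the concentration at half-maximal rate. This is the
aggregate Michaelis–Menten behaviour of all the transporters and enzymes that
drive elimination, not the kinetics of any single protein. The ODE has an
exact solution through the principal Lambert-W branch,

    C(t) = Km * W0( (C0/Km) * exp((C0 - Vmax*t)/Km) ),

which the package evaluates in log space (so large C0/Km never overflows) and
uses both as an oracle for the numeric solver and as the likelihood curve in
fitting. The numeric path uses LSODA with rtol = atol = 1e-9; the two agree
to better than 1e-6 relative error over the elimination phase, and tiny
negative solver excursions are clamped to zero.

A note on units: the worked example quotes Vmax in mg/kg-hr while
concentrations are in mg/dL. Dimensional consistency of dC/dt requires rate
units of concentration per time, so kmdkit treats Vmax as mg/dL per hour
throughout and regards the per-kg label as display provenance of the source
value.

## Estimating (Vmax, Km) from data

Observed concentrations y_i at times t_i are modelled as

    y_i ~ Normal(C(t_i), sigma)
    Vmax ~ Normal(m_v, s_v) truncated to (0, inf)
    Km   ~ Normal(m_k, s_k) truncated to (0, inf)
    sigma ~ HalfCauchy(1)

with C(t) the Lambert-W curve above. The starting concentration C(0) is a
fourth parameter with a weak prior, Normal(y_0, 0.1*y_0) truncated to
positive values, centred on the first observation. Fixing C(0) *to* the first
observation is offered as an option (`c0_mode="fixed"`) but is not the
default: the anchor observation carries measurement error, and propagating it
deterministically into the curve biases both Vmax and Km (in simulation at 5%
proportional noise, the Km estimator's mean shifts from 12.6 to 15.4 and its
sd quadruples).

For the alcohol example the default priors are Vmax ~ N(175, 20) and
Km ~ N(11.8, 3) (both truncated at zero): wide enough for the data to
dominate, centred on literature values for hepatic alcohol dehydrogenase.
Any `PriorSpec` can be supplied instead; the likelihood is unchanged.

Sampling uses emcee's ensemble MCMC with a differential-evolution move
mixture (80% DEMove, 20% DESnookerMove), which cuts the autocorrelation time
to ~15 steps on this posterior. Defaults: 4 independent ensembles of 16
walkers, 2500 warmup + 2500 retained steps per walker, base seed 2022, all
chain seeds derived by `SeedSequence`. Walkers are initialised in a small
ball around the least-squares optimum whose radius scales with the estimated
noise level, so that near-noiseless data (whose posterior is an extremely
narrow spike in (Vmax, Km) with sigma collapsing toward zero) start inside
the high-probability region. Diagnostics treat every walker as a chain:
rank-normalized split R-hat and ESS from arviz. Any R-hat above 1.01 flags
the fit non-converged; the summary is returned with the flag set and the KMD
step refuses it unless forced. Exactly noiseless data are a known degenerate
case: the sigma posterior is improper (it piles up at zero), so such fits
recover the parameters but legitimately flag non-convergence.

Credible intervals are equal-tailed central 95% (2.5/97.5 percentiles of the
pooled draws). The maximum-likelihood mode profiles the same Normal
likelihood: multi-start trust-region least squares over (Vmax, Km, C0) with
sigma_hat = sqrt(RSS/n); starts span two orders of magnitude around the
initial guess.

## Finding the knee

On the window [0, Smax], kneedle min–max normalizes the Michaelis–Menten
curve to the unit square and takes the thresholded local maximum of
d(x) = y_norm - x_norm (Satopaa sensitivity S = 1; for the smooth noiseless
curves used here this is simply argmax d). The continuous limit has the
closed form

    knee = sqrt(Km * (Km + Smax)) - Km,

verified in the tests by brute-force grid maximization. Two properties
matter in practice: the knee is independent of Vmax (it cancels in the
y-normalization — supplied Vmax bounds affect nothing but the rate value at
the knee), and it is *not* scale-invariant — it moves with the window edge,
which is why every knee is anchored to a stated Vmax fraction. The discrete
path evaluates 10,001 uniform grid points and reports the grid argmax without
sub-grid interpolation (resolution Smax/10^4, i.e. ~0.02 mg/dL for the worked
example); the closed form is available where exactness matters.

## Assembling the KMD region

With the Km posterior summarized by (mean, 95% CI) and windows anchored at
the 90% and 95%-of-Vmax concentrations (9*Km_anchor and 19*Km_anchor):

- lower bound  = knee at Km = CI lower, window [0, 9*Km_anchor]
- upper bound  = knee at Km = CI upper, window [0, 19*Km_anchor]
- midpoint     = knee at Km = posterior mean, window [0, 14*Km_anchor]

Km_anchor defaults to the posterior mean Km — on real data the true Km is
unknown — and can be overridden (e.g. with a known simulation truth) to
reproduce published anchors exactly. Reports carry both raw and
nearest-integer bounds; the worked example's raw upper knee is ~42.5 mg/dL,
which honestly rounds either way (the source prints both 42 and 43).

## The synthetic-data generator

`default_example_dataset` emulates a single-subject elimination study for the
alcohol example: truth Vmax = 175, Km = 11.8 mg/dL, starting concentration
c0 = 19*Km = 224.2 mg/dL (the 95%-of-Vmax anchor), 49 samples, proportional
Gaussian noise with CV = 5%, negative draws truncated at zero (never
triggered at CV <= 0.1). The 49 samples span the elimination phase — time
zero to 99% elimination, about 1.58 h under these kinetics — because the
information about Km lives in the curved transition from zero-order to
first-order decay; sampling long after the compound is gone adds structural
zeros and nothing else. What the generator does not emulate: absorption or
distribution phases, multi-dose designs, inter-individual variability,
heteroscedasticity-aware error models beyond the proportional noise itself,
or assay quantification limits. Passing tests therefore demonstrate recovery
under a clean single-compartment elimination design, not under the full
messiness of in-vivo toxicokinetics.

## Test design notes

- Parameter-recovery acceptance: 20 replicates at CV = 5%, n = 49, default
  sampler settings; replicate-averaged posterior means within 5% of truth and
  CI coverage >= 17/20.
- The noise-monotonicity check (posterior error shrinks with CV) uses weak
  priors so the data dominate: under informative priors the shrinkage masks
  the noise effect at small replicate counts.
- Reduced sampler settings (2 chains, 1200+1200 steps) are used in tests that
  need only posterior means; convergence-flag behaviour is tested at default
  settings.
- The first-order-limit check compares against c0*exp(-Vmax*t/Km) at
  c0 = Km/1000, where that approximation is itself accurate only to
  O(c0/Km) = 1e-3.

## Known limitations

- Single-compartment, elimination-only; no PBPK structure.
- The Normal likelihood is homoscedastic while the default generator noise is
  proportional; at CV = 5% this mild misspecification does not visibly hurt
  coverage, but at much larger CV a weighted or log-scale likelihood would be
  preferable.
- Km is intrinsically less identified than Vmax in an elimination design:
  its credible intervals are several-fold wider, and shrink only with denser
  sampling of the transition region.
- The KMD region inherits the posterior's calibration; it is a plausibility
  region, not a probability interval for a well-defined functional.
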