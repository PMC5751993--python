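# Methods

This note records the statistical models, the numerical choices, and what
the synthetic test bed does and does not establish.

## Survey data model

A *station* is a pair of facing cameras treated as one trap location with
projected-km coordinates; all distances are Euclidean. Surveys run 90 days
by default, day 1 being the first survey day (1-based closed intervals).
Prey photo events carry minute-resolution timestamps and a group count;
predator captures are day-resolution records of identified individuals.
Detection histories use 10-day occasions (9 per survey) for occupancy and
3-day occasions (30 per survey) for capture–recapture. If a survey length
is not divisible by the occasion length the final short occasion is kept
and its reduced effort recorded (flagged in the log). Camera-failure days
produce zero-effort station-occasions, which enter the occupancy likelihood
as missing at random.

## Occupancy

The likelihood is the standard single-season mixture over latent presence.
Covariates are used in raw units (km, m, 0/1) so coefficients are directly
comparable to untransformed published estimates; an optional standardised
mode exists for ill-conditioned data and reports back-transformed
coefficients. Maximisation is multi-start L-BFGS (start at zero, at
naive-occupancy-informed values, and at two perturbations; gradient
tolerance 1e-8); standard errors come from the numerically differentiated
observed information (central differences, relative step 1e-4). Station
predictions Ψ̂ are unconditional covariate predictions, and site values are
arithmetic means over the site's stations with a delta-method SE.

The candidate set is all 2³ Ψ-covariate subsets × {p(.), p(DC)} = 16
models; a *strict-15* mode drops the saturated Ψ(RR+ST+H)p(DC) model to
yield a 15-model set (which combination the classical 15-model analyses
omitted is undocumented; neither mode is asserted as their intent). AICc
uses the station count as effective sample size (a config knob), with ties
broken by smaller K then model label. Non-converged fits are excluded from
ranking and logged.

## Biomass index

BI = Σ_i n_i w_i / t per station, with t the station's active days.
Independence filtering uses a fixed 1-h window anchored at the opening
photo; photos inside the window merge to one event carrying the maximum
group count, and the first photo at or beyond the window opens the next
one. A rolling-gap variant (clock restarts at each photo) is available
behind a flag. Prey classes (all terrestrial ≥ 1 kg, ungulates,
non-ungulates; pumas excluded) are configurable data, seeded with the
standard Amazonian jaguar-prey roster; body masses ship as an editable
table because published analyses rarely print the exact values used, and
any replication of biomass tables is conditional on mass choices.
Kruskal–Wallis uses the tie-corrected H with a chi-square p (identical data
return H = 0, p = 1). The Bayesian-bootstrap correlation draws
Dirichlet(1,…,1) weights per resample, computes the weighted Pearson r, and
reports the narrowest interval containing 95% of draws (HDI); the point
estimate is the ordinary sample correlation.

## Spatially explicit capture–recapture

State space: a regular grid (default 1 centre/km²) over the trap-array
envelope buffered by 15 km, rectangle mode by default for deterministic
centre counts, convex-hull mode optional; each centre carries a binary
suitability flag (all-suitable by default). Detection is Bernoulli per
trap-occasion with p(d) = 1 − exp(−λ₀ e^{−d²/2σ²}) — a half-normal
encounter rate composed through a complementary-log-log link, matching the
"Bernoulli process with baseline λ₀" convention of the classical Bayesian
SECR implementations. Data augmentation adds all-zero histories up to
M = 30× the observed individuals (20–40× allowed); ψ_aug ~ Uniform(0,1),
and σ, λ₀ carry diffuse uniform priors on (0.05, 30) km and (1e-4, 5)
(config knobs, logged).

Sampler: Metropolis-within-Gibbs. σ and λ₀ move by log-scale random walks
(with the log-uniform Jacobian term) adapted toward 20–40% acceptance
during burn-in only; ψ_aug and the inclusion indicators z are conjugate
Gibbs steps; centres of active individuals move by uniform proposals over
grid neighbours within 3.5 km with the neighbourhood-size Hastings
correction, while centres of excluded individuals are redrawn from the
uniform prior. Defaults: burn-in 50%, thinning 10. Convergence is the
Geweke z on each thinned chain (first 10% vs last 50%, Newey–West spectral
SEs, |z| < 1.6); the runner can escalate iterations by doubling up to
600,000 and reports a non-converged posterior honestly if the cap is hit.
Density per draw is N_super / (suitable area) × 100. With no individual
recaptured at distinct traps, σ is weakly identified and the run proceeds
with a prominent warning.

## Non-spatial density

N̂ uses the Burnham–Overton M_h jackknife, orders 1–5 from the
capture-frequency counts, with the closed-form coefficient table; variance
is Σ(a_ik+1)² f_i − N̂. Order selection follows the sequential
normal-approximation test on successive differences (α = 0.05): the
selected order m is the first non-significant test, and the reported
estimate interpolates between N_m and N_{m+1} with weight
(1 − P_m)/(1 − α) clipped to [0, 1], so a marginal test leans toward the
higher order. The exact interpolation rule of the classical CAPTURE program
is not fully documented, so this smooth variant is the package's own
documented choice; integer-order and fixed-order results are always
available in the result object. Raw jackknife estimators can fall below
the observed count S for unusual frequency vectors; the reported estimate
is clamped at S (logged).

Closure is checked with a span-based test: for each individual captured
≥ 2 times, the span between first and last capture occasion; the total
span is compared against a Monte-Carlo null in which each individual's
capture occasions are a uniform random subset (two-sided MC p with the +1
correction). MMDM is the mean over individuals captured at ≥ 2 distinct
stations of their maximum pairwise station distance, pooled across sites
(SE = sd/√n); same-station recaptures never qualify. ETA is the exact
polygonal union of disks of radius MMDM around the stations (shapely,
64 quadrant segments; relative polygonisation error ~1e-4), with SE from
recomputing at MMDM ± SE (half-range). Density D̂ = N̂/ETA × 100 km² with
Var(D̂) = D̂²[Var(N̂)/N̂² + Var(Â)/Â²]. Full (not half) MMDM is the buffer,
the conservative choice for wide-ranging felids.

## Synthetic data generator

The generator reproduces the sampled design: four sites ordered from
remote to accessible, 25 stations per site in a ~10.2 × 10.3 km polygon,
placed on jittered transect rows 2–3 km apart; accessibility covariates are
feature-based by default (distance to a site-calibrated road line, river
line and settlement point, matching the observed site-level means of
roughly 74/32/12/2 km to roads, 7/2/2/2 km to rivers and 12/15/3/4 km to
settlements), with a direct-draw mode as an alternative. Prey presence is
Bernoulli in the logit-linear model with the best-fit published effect
sizes as defaults (e.g. white-lipped peccary Ψ: intercept −5.73,
β_ST = 0.77; detection: intercept −2.78, β_DC = 0.19); given presence,
photo events arrive as a daily Poisson stream whose rate is chosen so the
induced per-occasion detection probability equals the closed-form p —
published analyses do not quantify photo rates given presence, so this
link is the package's documented free choice. Group sizes are
zero-truncated Poisson with species-specific means (also free choices).
The predator population is a Binomial point process with
N = round(D·|S|/100) on the buffered rectangle (fixed-N override
available), observed through the same half-normal/Bernoulli process the
SECR model assumes. Default densities follow the system's accessibility
gradient (5.44, 1.7, 2.3 and 0.29 individuals/100 km² from the remote to
the road-side site; the two middle values are interpolated from the
observed capture totals), with σ = 2.5 km and λ₀ = 0.02 per occasion,
calibrated once so the remote site observes about 13 individuals with
roughly two captures each over the 30 three-day occasions — the sparsity
regime this kind of survey actually produces. A single ``density`` value
overrides the gradient for controlled recovery experiments.

What the test bed does not emulate: animal movement within home ranges
(centres are static), temporal clustering of photo bursts beyond the
optional within-hour clustering, behavioural responses to traps, spatial
autocorrelation of presence between stations, and open-population dynamics.
Passing recovery tests therefore demonstrates correctness of the
estimators under their own assumptions, not robustness to these real-data
violations.

## Problem sizes and numerical choices

Recovery checks run at the study's scale: 100 stations × 9 occasions for
occupancy (200 replicate surveys for CI coverage), and 25-trap sites with
30 occasions for SECR (20 replicate sites, 10,000 MCMC iterations each,
which the Geweke diagnostic shows is adequate at this sparsity for the
population-size chains; production analyses default to 50,000 with
escalation). Likelihood oracles compare against exhaustive latent-state
enumeration on ≤ 6 × 4 instances (tolerance 1e-10); jackknife orders are
verified against an exact-rational generalized-jackknife construction
(tolerance 1e-9 relative); disk-union areas are verified against ~10⁶-point
Sobol quadrature (tolerance 0.5%). All randomness flows from one seed via
named SeedSequence substreams, so every stage is bit-reproducible.

## Known limitations

- The SECR sampler assumes a single season, no behavioural response, and
  density constant across the state space; covariates on density or
  detection are out of scope.
- σ and λ₀ mix slowly at very sparse capture data (3–6 individuals); the
  escalation path mirrors the classical practice of raising iterations
  until the population-size chains pass Geweke, and honestly reports
  failure for the detection parameters when it occurs.
- N̂/ETA densities are sensitive to trap spacing and recapture counts; the
  package reports them alongside SECR rather than asserting agreement.
- Spreadsheet input assumes the documented single-sheet column layout;
  only minor header variants are tolerated.
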