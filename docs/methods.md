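# Methods

## The scientific problem

As climate warms, southerly species shift their ranges poleward, but the
landscape in between — how much breeding habitat there is and how it is
arranged — can speed or stall that expansion.  The analytical design
implemented here treats the first arrival of a species at a continuously
monitored trap location outside its historic range as a time-to-event
outcome: traps that were never reached while operating contribute
right-censored observations.  Arrival time is then modelled against
attributes of the species, of the trap's immediate surroundings, and of the
landscape the species had to cross.

## Pipeline

### Analysable pairs and expansion zones

A species' *baseline distribution* is its set of occupied 1-km cells during
a reference period.  A species-trap pair is analysable only if the trap is
at least 20 km (inclusive) from every baseline cell, so that an arrival
indicates genuine range extension.  For each pair, the *expansion zone* is
the set of 10-km cells whose centers `c` satisfy

    d(c, nearest record) + d(c, trap) < 100 km + D_min,

with `D_min` the minimum trap-record distance and a strict inequality.  For
a single record this is an ellipse interior with the record and trap as
foci; with scattered records the zone flexes around the range margin.  Cells
are evaluated at their centers on a grid aligned to the landscape origin.

The distance covariate is the arithmetic mean of the Euclidean distances
from the trap to its three nearest *distinct* baseline cells, in 100-km
units.  (Mean rather than sum is a package choice; both are simple linear
rescalings of each other and the unit is configurable.)

### Landscape and climate covariates

Eight zone summaries: proportional cover of broadleaf/mixed woodland,
coniferous woodland, suburban land and protected areas, plus mean and
variance of growing degree-days above 5 °C (GDD5) and of elevation.
Proportions are computed from 1-km fractional-cover rasters that are exact
block aggregates of the 25-m landcover, so cover is area-exact; means and
variances are taken over the 1-km cells inside member 10-km cells.
Variances are population variances (the zone is exhaustively enumerated,
not sampled); a sample-variance switch exists.  GDD5 per cell is
`sum_m max(0, T_m - 5) * days_m` with calendar month lengths of a 365-day
year — degree-day conventions differ, and this one is stated and tested.
Zone cells overhanging the mapped raster are ignored (the analogue of zones
implicitly clipped to land).  Trap buffers are proportions of 25-m cells
whose centers lie within 1 km of the trap, by class.

### Habitat-network conductance

Woodland cells at 1-km resolution (area `A_i` km², from the fractional
cover) are network nodes; every pair is linked by a per-generation
colonisation rate

    k_ij = C · A_i · A_j · exp(-d_ij / alpha),   alpha = delta / 2,

a negative-exponential dispersal kernel whose 2-D mean displacement is the
mean dispersal distance `delta` (5, 10 or 20 km per generation; habitat is
broadleaf/mixed woodland with or without conifer — six variants).  Emigration
scales with source area and settlement with target area; the exponents and
kernel form are config-exposed because incidence-function parameterisations
vary.  Edges beyond `5·delta` are dropped (under 0.7 % of kernel mass),
keeping the matrix sparse; a no-truncation mode exists for oracle
comparisons.

Treating `k_ij` as electrical conductances, all baseline records within
`D_min + 100` km of the trap (inclusive) are merged into one source
terminal — records not on a habitat node snap to the nearest node within
10 km, else drop — and the trap's cell is the target.  The two-terminal
*effective conductance* is the current at unit potential difference,
obtained by solving the reduced graph Laplacian (sparse direct solve on the
connected component of the target).  Disconnected pairs have conductance 0.
The regression covariate is the natural log of conductance, floored at
1e-12 for disconnected pairs; conductance spans orders of magnitude, so a
log scale is the natural effect scale.

### Survival model

Constant-hazard (exponential) regression on the log-mean-time scale:

    E[T_st] = exp(x_st' beta + b_s),

with an event contributing `log(lambda) - lambda·t` and a censored row
`-lambda·t` to the log-likelihood (`lambda = 1/E[T]`).  Negative
coefficients mean faster colonisation.  The frailty `b_s` is a zero-mean
Gaussian log-time offset per species; at fixed variance the joint penalized
likelihood in (beta, b) is strictly convex and is maximized by a damped
Newton iteration with analytic gradient and Hessian, and the variance is
chosen by a bounded one-dimensional search on the Laplace-approximate
marginal likelihood (checked against exact Gauss–Hermite integration during
development).  A gamma frailty on the hazard, whose marginal likelihood is
closed-form per species, is provided as an alternative; with moderate
frailty variance the two give nearly identical fixed effects, and neither is
asserted to be the "correct" convention.

Numerical choices: Newton convergence at gradient max-norm 1e-10 (tight but
cheap; makes the intercept-only fit agree with the closed form
events/exposure to 1e-10); standard errors from the observed information of
the full (beta, b) system; AIC = -2·loglik + 2·(fixed effects + 1 for the
frailty variance), a documented convention with the extra degree of freedom
configurable.  Collinear designs are rejected with the offending columns
named.  Observed colonisation curves use yearly life-table hazards
`d_t / n_t` (colonisations over traps still operating), cumulated as
`1 - prod(1 - h)`.

### Model selection and effect sizes

Forward stepwise addition over a candidate list, entering the term that
lowers AIC most and stopping when nothing improves.  Interactions come from
an a-priori whitelist of (habitat-affiliation flag × landscape covariate)
pairs; an interaction may enter only once the flag's main effect is present
and is parameterized as the two conditional slopes (`flag:cov`, `!flag:cov`)
replacing the covariate's main effect, so each slope is tested against zero
within its species group.  Declared correlated pairs (e.g. GDD5 variance vs
elevation variance) never co-occur, and candidate pairs with |r| > 0.7 are
excluded automatically.  After the search, each selected covariate is
replaced one-by-one by its correlated alternatives and every model within
2 AIC of the best is retained; Akaike weights
`w_m = exp(-Delta_m/2)/sum` average predictions across the retained models
on the log-time scale (geometric-mean semantics, matching a geometric-mean
predicted arrival time).

Effect sizes contrast geometric-mean predicted time between the top and
bottom 20 % of observed landscapes for a focal covariate: whole rows of the
zone-covariate block are resampled (preserving their covariation), distance
is fixed at 1.00 (100 km), flags set per species group and all other
covariates held at their medians.  Resampling is exhaustive over observed
rows unless the table exceeds a configurable size, then seeded subsampling.

## Synthetic data: what it emulates and what it does not

The generator provides every input with known ground truth: a 25-m
categorical landcover built by ranking smoothed Gaussian random fields
(cover fractions realized exactly; the correlation length `clump_km`
controls patch structure independently of amount), a protected-area overlay,
1-km elevation and monthly temperature (UK-like seasonal means, a
north-south gradient of −0.006 °C/km, an elevation lapse of −0.006 °C/m and
a smooth anomaly), species with independent woodland/farmland flags,
northern range limits, Gaussian frailties and baseline occupancy of suitable
cells, traps in the northern half with right-censoring from early closure,
and arrival times drawn from the exponential model itself.  A mechanistic
check simulates per-generation colonisation on the habitat network (an empty
node is colonised with probability `1 - exp(-sum of rates from occupied
nodes)`) and confirms that effective conductance rank-correlates with spread
speed.

It does **not** emulate: real geography or coastlines (all-land landscapes,
planar km coordinates), observation error in baseline records, species
phenology or abundance, spatial autocorrelation between traps, or
non-constant hazards.  Passing tests therefore demonstrate correctness of
the estimators and geometry under the stated model, not robustness to those
real-data complications.

Default study conditions for the end-to-end run (scripts/acceptance.py): an
80-km landscape at the default cover fractions, 25 species, 40 traps
observed for 27 years, frailty SD 0.5, and generating coefficients
(distance +1.0 per 100 km, log-conductance −0.4, woodland flag −0.5) whose
signs and magnitudes mirror the effect scale the survival model is meant to
detect.  These sizes keep the full run near a minute while leaving all
coefficients identifiable; the distance coefficient is the noisiest (SE
≈ 0.4) because distance varies mostly between species and competes with the
frailty term.  The conductance effect-size contrast is computed over pairs
whose network connects source and target: the floored log-conductance of a
disconnected pair is a sentinel, not a measured landscape value, and
including it would make the quintile contrast depend on the floor constant.

## Known limitations

* The Gaussian-frailty variance is a Laplace/PQL-style estimate; with very
  few species or very few events per species it is shrunk toward zero, and
  what is estimable is the realized spread of the frailties rather than the
  population variance.
* Effective conductance of very large landscapes (≫ 10^5 habitat nodes) would
  need an iterative solver; the direct sparse factorization used here is
  sized for the 1-km national-scale networks of this design.
* The stepwise search asserts end-state semantics (AIC-minimal model plus
  near-ties), not a unique search path; with strongly correlated candidates
  different entry orders can retain different but AIC-equivalent models.
* Raster I/O is plain-text ASCII grid, adequate for the synthetic scale;
  there is no nodata mosaic handling beyond a single sentinel.
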