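# Methods

`forestfolio` models the economic planning problem of a large forest
enterprise: allocate area shares of S stand types (monocultures and
two-species mixtures) to P internally homogeneous planning units so as to
maximize a risk-averse objective, the Conditional Value at Risk (CVaR) of
the enterprise's annuity, under stand-level disturbances, spatially
correlated extreme weather events, and fluctuating wood markets.  This note
documents the model, its assumptions, the synthetic data it runs on, and
the numerical choices.

## The planning model

**Objective.** Each Monte-Carlo replicate i yields a joint annuity
realization

R_i(w) = Σ_p (A_p / A) Σ_s w_{p,s} R_{p,s,i},

where w is the P×S allocation array (rows sum to 1), A_p the unit areas,
and R_{p,s,i} the annuity of stand type s in unit p.  The objective is
CVaR_α(w), the mean of the realizations below the empirical α-quantile
(VaR) of {R_i(w)}; α = 0.10 by default (a conservative level, since CVaR is
stricter than VaR at the same quantile).  *Top-down* planning maximizes the
enterprise CVaR over all rows jointly; *bottom-up* planning maximizes each
unit's own CVaR independently, after which the concatenated allocation is
evaluated at enterprise level.  At α = 1 the problem is linear and solved
exactly (full weight per unit on the stand type with the highest mean).

**Valuation.** A stand type's annuity is R = r·LEV with interest rate
r = 1.5 % per year.  The land expectation value LEV is approximated by the
net present value of 500 simulated years of cash flows on the decade grid
t = 0, 10, …, 500: planting costs, thinning revenues/costs, and final or
salvage harvest revenues/costs, discounted at (1+r)^−t.  At t = 500 the
remaining discount weight is ≈ 6×10⁻⁴, so truncation error is negligible
relative to Monte-Carlo noise.

**Three-stage design.** To keep the allocation problem tractable,
management is pre-optimized per stand type: (1) rotations by a
deterministic risk-integrated Faustmann criterion (below); (2) mixture
shares on a 10 %-grid by stand-level CVaR under common random numbers;
(3) the main allocation optimization.  Stages 1–2 are repeated per
planning unit (climates differ) and stage 2 per extreme-event scenario.
Rotations and shares stay fixed during stage 3.

## Disturbance model

**Stand-level hazards.** Species survival is two-parameter Weibull,
S(a) = exp(−(a_eff/b)^c) with effective age a_eff = a·exp(score), where the
score is a species-specific linear function of the unit's temperature and
precipitation covariates (an accelerated-failure-time form).  The
per-decade hazard at age a is h = 1 − S(a+10)/S(a), applied as the
probability of stand-replacing damage in the next period, followed by
salvage harvest and replanting.  Default half-lives (reference climate):
spruce 60 a, Douglas-fir 80 a, pine 90 a, beech 120 a, oak 150 a, with
shapes 1.3–1.8; spruce is the most climate-sensitive species.  Where a
unit's climate score exceeds the species envelope, the species is treated
as barely viable: the survival curve is power-rescaled (S → S^β) so that
monoculture survival to age 100 is exactly 1 %.  A power transform is used
because it preserves S(0) = 1 and monotonicity, which a constant multiplier
cannot.

**Mixture stabilization.** In a two-species stand the hazard of a
stabilized conifer (spruce, Douglas-fir) is multiplied by
m(q) = 1 − δ·q^η with admixed share q, δ = 0.5 and η = 0.35 — a strong
effect already at 10 % admixture, consistent with the idea that a small
broadleaf share stabilizes conifer stands.  Deciduous species carry no
multiplier.  The stand fails as a whole; its hazard is the share-weighted
mean of the species hazards.

**Extreme weather events.** Events per decade are Poisson(λ) over a study
region of A_region = 100,000 km² (buffer included); each event is a disc of
radius a at a uniform center.  A planning unit (represented as an
equal-area disc) covered by an event has each of its stands affected with
probability equal to the covered area fraction; an affected stand's hazard
is an affine rescale of its stand-level hazard from the attainable range
[h_lo, h_hi] (minimum/maximum decade hazard over species × age × the
enterprise's climates) onto the band [0.7, 0.99] — more stable stands stay
relatively more stable under events.  Stand-level and event channels
combine as one Bernoulli draw at max(h_stand, h_event), which preserves
both channels without double counting.  Scenarios are calibrated by the
closed form p_dam = 1 − (1 − πa²/A_region·p̄)^λ from the baseline anchor
(2 % per decade, λ = 1, a = 28.9 km): "larger events" solve for the radius
at fixed λ, "more events" for λ at fixed radius.  When the event square
must be inflated beyond √A_region to keep a full buffer, the Poisson
intensity is scaled with the area ratio so the event density per km² (and
the closed-form damage probability of interior stands) is unchanged.

**Ordering within a period.** Growth, thinning, disturbance draw, planned
final harvest.  A disturbance therefore salvages the post-thinning stock,
and a stand at rotation age that is hit in the same period is salvaged
rather than harvested as planned.  Replanting (same stand type, keeping the
portfolio stationary) happens in the same period at a cost reduced by the
natural-regeneration share of the removed stand's age.

## Markets

External price risk is a bootstrapped multiplicative index: each decade
draws one year of a 10-year floating average of per-species relative price
series (mean one), the same year for all species so cross-species
correlations carry over; the draw is shared by all stands of a replicate.
Endogenous feedback: the salvage-harvest area of a market group (softwood =
spruce/pine/Douglas-fir, deciduous = beech/oak) relative to the expected
final-harvest area without disturbances, A_salv,rel, lowers the group's
prices by factor 1 − 0.05·A (softwood) or 1 − 0.03·A (deciduous), floored
at 0; A_salv,rel ≥ 2 adds a 10 % logging-cost surcharge (capacity
shortage).  Salvage harvests additionally lose 15 % (deciduous) or 5 %
(softwood) of revenue to quality and cost 15 % more to harvest.  Because
the allocation is unknown at simulation time, the regional salvage supply
weights all simulated stands equally — an approximation that makes the
feedback allocation-independent.  The simulation runs in two passes: pass
one resolves all (price-independent) disturbance dynamics and accumulates
the salvage supply; pass two replays identical dynamics (same substreams)
and prices the cash flows.

Wood value uses a parametric net-revenue model: gross price per m³ rising
logistically in log diameter and harvest cost per m³ falling as a power law
of diameter, calibrated so that per-m³ net revenue at typical mature
diameters orders Douglas-fir > spruce > pine and oak > beech.

## Pre-optimization details

**Rotations.** For each candidate T on the 40–180 a decade grid the
expected value of one stochastic rotation is computed by weighting each
possible salvage age (decade-wise termination probabilities from the
hazards) and the planned harvest at T:
LEV(T) = −c_init + E[NPV]/(1 − E[(1+r)^−τ]), τ = min(first disturbance, T).
Re-establishment costs enter at the termination age.  The candidate
maximizing r·LEV(T) is chosen (ties to the shorter rotation).  With zero
hazards this reduces exactly to the classical Faustmann rotation, which the
tests verify by independent enumeration; a Monte-Carlo cross-validation
checks the risk integration against simulation within 3 standard errors.
Mixed stands use a single common rotation for both species — the stand
carries one age and is harvested jointly — optimized on the mixture's
hazard.

**Mixture shares.** Candidates 10/90 … 90/10 are simulated with identical
uniforms (the stand-level random stream is keyed by unit and species pair,
not by share), scored by stand-level CVaR_α, ties broken toward the larger
conifer share.  This stage includes external price risk and the scenario's
event field but not the endogenous market feedback, which is undefined for
a stand in isolation.

## Optimization algorithm

Differential evolution (scipy's implementation, vectorized, seeded) over
the box [0,1]^{P×S}; inside the objective each population member's rows are
divided by their sums (all-zero rows reset to uniform), so the simplex
constraint holds exactly by construction and the search geometry stays a
box.
Defaults: population 10× dimension, mutation 0.8, crossover 0.9, best1bin,
L-BFGS-B polish of the incumbent; convergence by scipy's population-spread
criterion (std of objectives ≤ tol·|mean|) or the generation cap.  The
desk profile caps generations at 300, the paper-scale profile at 2,000.
On small instances the optimizer is validated against exhaustive grid
search at 1 % resolution and, at α = 1, against the exact linear-program
solution.  The empirical CVaR (mean of the ⌊αn⌋ smallest realizations;
VaR as the ⌈αn⌉-th order statistic) is concave in w, which a property test
exercises.

## Synthetic data: what it emulates, what it does not

The generators reproduce the *statistical structure* the analysis needs,
not any particular forest: unit areas uniform on 5,500–19,000 ha; climate
covariates on smooth spatial gradients plus noise (neighbouring units
similar — the substrate for β-diversity); per-species site indices
log-linear in climate with at least a two-fold spread across the default 24
units; Chapman–Richards yield tables scaled by site index with 30 % of each
decade's increment thinned from age 20; planting costs ordering spruce
(3,000 €/ha) cheapest and oak (12,000 €/ha) dearest, with natural
regeneration rising with stand age and inventory-style shares for old
stands (Douglas-fir always fully planted at first establishment);
AR(1)-based mean-one price indices with high within-group and moderate
cross-group correlation.

They do *not* emulate: real geometries or polygon exposure (units are
equal-area discs), empirically fitted survival or valuation functions,
site-index models with soil/deposition covariates, assortment-level
pricing, or non-stationary climate.  Passing tests therefore demonstrate
the *mechanisms* — risk-driven allocation shifts, the cost of spatial
correlation, diversification patterns by planning perspective — not
numerical predictions for any real enterprise.  Printed economic levels
depend on the synthetic calibration; only directions and closed-form
quantities are asserted.

## Numerical choices and degenerate inputs

* Random streams: one root seed spawns named substreams (event field,
  price bootstrap, one per unit × stand-type family), so event fields and
  price paths are shared across all stand types within a replicate and
  mixture-share candidates see common random numbers.  Reruns are
  bit-identical.
* Hazards are clipped to [0,1]; S(a) = 0 yields hazard 1; a degenerate
  attainable-hazard range maps onto the band midpoint.
* The empirical VaR uses the order-statistic (type-1) quantile; n·α < 1 is
  rejected.
* Evenness defines 0·ln 0 = 0 and returns 0 for S = 1; stand-type counts
  apply a 1 % reporting threshold because continuous optimization leaves
  numerical dust.
* Expected forest structure uses the stationary renewal argument on the
  empirical harvest-age tables (age-class share ∝ survival-weighted
  residence time, one cycle per E[τ] years) rather than time-averaging a
  single 500-a path — equivalent in the long-run limit and much less
  noisy.  Cycles censored by the horizon are ignored.
* Desk-scale default profile: 6 units, 1,000 replicates, 400 pre-
  optimization replicates; the paper-scale profile (24 units, 10,000
  replicates, all six scenario variants) is the study setting.  Problem
  sizes are the package's own defaults chosen to keep a full four-scenario
  run around a minute on one core.

## Known limitations

* The market feedback is allocation-independent (equal weighting of all
  simulated stands); a strongly skewed optimal allocation would see a
  somewhat different endogenous price response than simulated.
* Mixed stands carry one rotation for both species; species-specific
  harvest timing inside mixtures is not represented.
* Bottom-up and top-down planning share one annuity matrix, so
  comparisons are paired; absolute levels inherit the synthetic
  calibration.
* No pest spread or stand-to-stand contagion beyond the disc-shaped event
  fields; no liquidity or financing constraints (LEV assumes a perfect
  capital market).
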