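# Methods

This note documents the models, algorithms and design choices behind
`batforage`, in the order the pipeline runs them.

## Coordinates and conventions

All analysis happens in a local metric transverse-Mercator projection of
WGS84 (default: the UTM 17N central meridian, appropriate for the Bocas
del Toro archipelago; configurable via `StudyConfig.utm_zone`). The
forward and inverse maps are the 4th-order Krüger series, with round-trip
error far below 1e-6° and planar-vs-geodesic distance error below 0.1%
over the ~100 km study scale — negligible against GPS error.

Bearings to/from the roost use a south-zero, clockwise-positive
convention on (−π, π]; compass degrees are `rad·180/π + 180` (0 rad →
180° = due south, π/2 → 270° = due west). This convention is fixed
package-wide and is asserted by the paired radian/degree columns every
summary table prints. Turning angles use the ordinary mathematical
convention (counterclockwise positive).

A *bat-night* is the half-open local-time window [18:00, 06:00) (tags
record only at night for this species); fixes outside it are dropped
with a logged count.

## Track cleaning

* **Speed filter** — fixes implying > 15 m/s from the *last retained*
  fix are removed sequentially. The sequential form means a single bad
  position removes one fix, not its two flanking segments. 15 m/s is
  beyond sustained flight speed for this species.
* **Range filter** — over-water fixes farther than 60 km from the roost
  are removed. The threshold is a package default (config key
  `max_range_km`), chosen beyond any plausible commute for a
  15–25 km-range forager; there is no canonical field value.
* **Downsampling** keeps the fix nearest each grid time (tolerance half
  an interval, each fix used once); **regularization** snaps fixes to
  the grid and inserts explicit missing slots, so step lengths and
  turning angles live on an arithmetic 2-min (configurable) grid.
* A night is **complete** when its first and last fixes lie within
  500 m of the roost and the track left that radius in between; only
  complete nights enter time-budget analyses. The 500 m radius
  operationalizes "complete outbound and inbound commutes"; it is a
  config key, not a measured quantity.

## Movement HMM

Per hidden state: gamma step lengths (shape k, scale β, metres per
interval) and wrapped Cauchy turning angles (location μ, concentration
ρ ∈ [0,1)); a homogeneous transition matrix Γ; the initial distribution
fixed to the stationary distribution of Γ (the data carry no information
about a separate δ on one night, and pooling across nights makes a
shared δ meaningless).

With two states the biological labels are *foraging* — short tortuous
movement, deliberately absorbing rest — and *commuting* — long straight
flight. Labels are assigned after fitting by mean step length (state 1 =
smaller), which breaks the likelihood's permutation symmetry
deterministically. A three-state fit is supported (`n_states=3`) and on
three-regime data has the lower AIC, but two states is the default
analysis resolution: at 2–3 min sampling the slow-foraging/rest
distinction is not recoverable.

Numerics: fitting is direct L-BFGS maximization of the pooled forward
log-likelihood under log/logit transforms (not EM) — simpler to pool
across series and standard in movement ecology. The forward recursion is
run scaled (not in log space) and batched across series. Missing slots
contribute emission probability 1, i.e. a pure transition step; this is
exactly the likelihood of the observed data under the model. Steps of
exactly 0 m are nudged to half the smallest positive step so gamma
densities with shape < 1 stay finite. Restarts (default 5) start from
moment-matched quantile splits of the pooled steps with randomized
perturbations.

Decoding returns both the Viterbi path and forward–backward smoothing
probabilities; slots with no observation get the Viterbi bridge state
and an `imputed` flag.

## Foraging metrics

* **Straightness index** SI = net displacement / path length ∈ [0, 1],
  computed over the commuting-state segment from the first departure
  out of the roost radius (outbound) and the last return run (inbound).
  Whether the "commute" should instead span roost-to-first-foraging is
  ambiguous; the commuting-state segment is used because it is defined
  by the HMM rather than by an extra radius parameter.
* **Foraging locations** — one anchor per maximal foraging-state run of
  length > 1 (singletons are decoding noise), taken at the run's first
  location. The same extraction function serves observed and simulated
  tracks, so provenance comparisons cannot diverge by implementation.
* **On/off-island time budget** — foraging slots classified by
  point-in-polygon against the home island; per-night binomial counts
  feed a logit-link GLM (statsmodels) with tracking period and foraging
  location (or sex) as fixed effects. Aggregated counts, not per-slot
  Bernoulli rows: the likelihood is identical and the design matrix
  tiny. "Off-island" is defined purely by polygon membership, not by a
  distance cutoff.
* **Balsa energetics** — a colony of N bats with each flowering tree
  feeding m to M bats per night needs between ⌈N/M⌉ and ⌊N/m⌋ trees.

## Null-track simulation

Null tracks are generative draws from a fitted (pooled colony × season)
HMM kernel, blind to resources, under physical constraints only:

(a) a proposed transition *into* foraging while over water is rejected
    (the chain stays commuting);
(b) steps come from the state's gamma, headings from the state's
    wrapped Cauchy around the previous heading, initial heading uniform;
(c) from a configurable fraction of the night (default 0.5), commuting
    headings are re-centred on the bearing to the roost, and while the
    bat is farther than 2 km from the roost new foraging bouts are
    suppressed — together these close the trip like a central-place
    excursion (≥ 90% of nights end within 2 km of the roost);
(d) proposals leaving the padded study bounding box trigger heading
    resampling (up to 100 attempts, then a reflection toward the box
    centre); a deadlocked night is resampled from the next substream.

This is a *reconstruction* of a constrained-simulation procedure whose
exact original specification is not available; every choice above sits
behind a `NullConstraints` field so alternatives can be swapped in.
Conclusions drawn from the null cohort should be read as qualitative
(spread of available directions versus used directions), not as a
calibrated availability model. Simulated foraging locations over water
are additionally dropped (with a logged rate) before analysis.

## Hierarchical distance/angle model

Per colony × season × provenance, with i indexing individuals and j
locations within individual (off-island locations only, the dominant
share of foraging):

    d_ij ~ Normal(μ_d + b_i, σ_d),   b_i ~ Normal(0, τ_d)
    θ_ij ~ VonMises(μ_θ + a_i, κ),   a_i ~ Normal(0, τ_θ)

Priors (weakly regularizing): μ_d ~ N(20, 20) km; σ_d, τ_d ~
HalfNormal(10) km; μ_θ ~ N(0, 2) rad; κ ~ HalfNormal(10); τ_θ ~
HalfNormal(1) rad. Prior-predictive distances fall mostly in (0, 80) km.
The von Mises is used for the angle likelihood (tractable concentration
parameter; a wrapped-Cauchy variant would need only a different
log-density). Distance is not truncated at zero: observed distances sit
15–25 km from the roost with modest spread, so the truncation mass is
negligible. The two components share only the individual index; no
cross-correlation parameter is fitted.

Reported quantities per group:

* population means μ_d (km) and μ_θ (rad, plus compass degrees), with
  central 95% credibility intervals; angular summaries are computed
  wrap-safely (centre on the circular mean, summarize deviations);
* **effective standard deviation** — the spread of the marginal
  observation-level predictive: √(σ_d² + τ_d²) for distance and, for
  angle, the circular SD √(−2 ln A(κ) + τ_θ²) where A(κ) = I₁(κ)/I₀(κ).
  The angle form follows from the factorization of the marginal mean
  resultant length, R̄ = A(κ)·exp(−τ_θ²/2); a Monte-Carlo estimator
  (`effective_circular_sd`) is provided and agrees with the closed form;
* **individual-level variability** — the random-intercept SDs τ_d, τ_θ;
* draw-wise **contrasts** between any two fits (wet − dry, observed −
  simulated), with angular differences wrapped to (−π, π].

Sampling: the random intercepts are marginalized out of the likelihood —
analytically for the Normal component (per-individual compound-symmetry
Gaussian), by 25-node Gauss–Hermite quadrature for the von Mises
component (exact to machine precision at these concentrations, using
only the per-individual sufficient statistics Σcos θ, Σsin θ). Each
component then has three free parameters, sampled with an
affine-invariant ensemble (emcee; differential-evolution move mixture,
24 walkers, 3500 steps after 1000 burn-in by default, vectorized
posterior). Scale parameters are sampled unconstrained and folded
(τ = |t|), equivalent to the half-normal prior while avoiding the
log-scale funnel when the posterior concentrates at zero. Split-R̂ and
ESS are computed across walkers (arviz); any R̂ > 1.05 raises by
default. Marginalization replaces the more common non-centred
random-intercept parameterization: the posterior over the reported
quantities is identical, and a 3-dimensional target is far more reliable
for an ensemble sampler than a ~2·n_individuals-dimensional one.

With a single individual the τ parameters are prior-dominated; the fit
proceeds with a warning. With wrap-point data (μ_θ near ±π) walkers are
initialized at the sample circular mean, and summaries wrap correctly.

## Foraging-area maps and overlap

A fitted group becomes a raster (default 500 m cells over the landscape
box padded 5 km) by evaluating at each cell centre the product of the
posterior-averaged marginal predictive densities of distance and bearing
— the "scaled product" construction. The polar Jacobian 1/r is *not*
applied by default (flag available): the map is a visualization of the
model estimates, not a normalized planar density. The 95%
highest-density region accumulates cells in descending value order (ties
broken by flat cell index for determinism); overlap between two
colonies' regions is reported asymmetrically as
100·area(A∩B)/area(A) and /area(B) after clipping both to land.
Contours are computed before land clipping (product → contour →
coastline); the opposite order is available in config. Raster cells
rather than contour polygons are used for the area arithmetic —
deterministic and grid-exact.

## Synthetic data generator

The generator produces the structure the pipeline assumes: an irregular
home island, a mainland annular sector across a ≥ 10 km water gap,
roosts near the island centre, and per-night trips of
roost → (optional on-island foraging) → straight outbound commute →
foraging bouts with short relocations at an individual- and
night-specific target → inbound commute → roost. Commutes are biased
correlated walks (bias weight 0.8) so straightness indices match the
near-1 values of real commutes. Night bearings are
colony mean + individual offset (N(0, τ)) + night noise; wet-season
scenarios double the angular SDs and shorten distances. Defaults mirror
the study conditions: three colonies at 16–24 km mean range with
distinct commute bearings (1.54, 1.43, 0.09 rad), ~30% of foraging time
on the home island, 2-min sampling over 12 h nights (360 slots).
Commuting steps are capped at 1700 m/slot (~14.2 m/s) so clean tracks
never trip the 15 m/s filter and cleaning is an identity on
uncorrupted data. Optional corruptions: per-fix dropout, speed-spike
displacements (8–15 km), and stray over-water fixes at 65–80 km — each
logged with its timestamp for precision/recall tests.

What it does **not** emulate: GPS position noise within the plausible
range, tag failure patterns, wind, resource depletion, social
interaction between bats, or irregular duty cycles. Passing tests
therefore demonstrate the pipeline's correctness on data satisfying its
assumptions, not robustness to every field pathology.

All randomness descends from one integer seed via `numpy` seed
sequences; per-night substreams are indexed by (colony, individual,
night), so datasets are byte-reproducible and any night can be
regenerated in isolation.

## Problem sizes

Test and acceptance runs use deliberately small instances chosen to
exercise every code path at desk scale: typically 2–4 individuals ×
2–3 nights per colony for end-to-end runs, 10 nights × 360 slots for HMM
parameter recovery, 50 replicates of 20 individuals × 8 locations for
hierarchical interval-coverage checks (at reduced draw counts), and 20
replicate cohorts for the null-spread comparison. Estimates from such
sizes carry the wide intervals the summaries report; conclusions about
the method (oracle agreement, coverage, qualitative contrasts) are what
the suite asserts, not field-scale effect sizes.

## Known limitations

* The null-simulation procedure is a documented reconstruction (above).
* The hierarchical model fits distance and angle as conditionally
  independent components; a joint covariance ("do far-commuting bats
  also deviate in angle?") is not modelled.
* No covariates enter the HMM emissions or transitions (time-of-night,
  wind); no Kalman smoothing of positions.
* Split-R̂ across ensemble walkers is slightly optimistic relative to
  independent chains; the DE move mixture and thinned long chains keep
  measured autocorrelation times ~60 steps against 2500 retained steps.
* Overlap percentages depend on cell size at the contour boundary;
  500 m cells change pairwise overlaps by < 2% against 250 m in the
  grid-refinement check.
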