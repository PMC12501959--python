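# Methods

This note documents the statistical models, the numerical choices, the
synthetic-data generator and the known limitations of `camtrap-cooccur`.

## Detection-history engineering

*Independence filter.* A trigger is retained iff at least 30 min (default)
elapsed since the previously **retained** trigger of the same species at
the same station.  Anchoring on the retained event — rather than the
previous raw trigger — treats a burst of triggers as one behavioural event
and makes the filter idempotent; a raw-predecessor rule would let a long
chain of closely spaced triggers extend an "event" indefinitely and is not
idempotent.

*Occasion grid.* Occasions are consecutive 10-day blocks anchored at the
global survey start shared by all stations, so occasion indices align
across sites; a trailing partial occasion shorter than one day is dropped.
A station contributes NA only when it was inactive for the entire occasion;
any active day makes the occasion scoreable.  This maximizes data use at
the cost of slight detection-probability heterogeneity in edge occasions
(a station active 1 of 10 days has less exposure); with 10-day occasions
and year-long deployments the effect is negligible.

*Grazing covariate.* An occasion is flagged `Time = 1` iff the majority of
its days fall inside May 1 – Sep 30.  The season is configurable; the
majority rule resolves occasions straddling the boundaries.

*Covariate screen.* Continuous covariates are standardized (sample mean 0,
SD 1); categoricals are contrast-coded with fixed vocabularies
(binary → ±1; aspect sunny/shady/flat → 1/−1/0).  Screening first drops,
iteratively, the lower-priority member of the worst pair with Pearson
|r| > 0.5, then drops low-priority covariates until every VIF < 3
(statsmodels' `variance_inflation_factor` with an intercept), then
re-verifies the correlation condition.  The priority list is the user's
statement of ecological meaningfulness; its default ordering puts the seven
habitat covariates (Dtr, Ele, Slo, Dtw, Vt, Asp, Td) ahead of raw
longitude/latitude, which in mountain terrain ride the elevation gradient
and are the expected casualties of the screen.

## Single-species occupancy

Standard single-season model: logit ψ = x′β_ψ (site covariates),
logit p = w′β_p (occasion covariates, e.g. `Time`).  Site likelihood
ψ Π_t p^y (1−p)^(1−y) + (1−ψ) I(no detections), NA occasions dropped,
all-NA sites contributing nothing.  Fitting is L-BFGS-B from 5 jittered
starts (ftol 1e-11, gtol 1e-7); the `converged` flag additionally requires
the centred finite-difference gradient below 0.05 in max norm — a pragmatic
threshold, since finite-difference noise on a log-likelihood of magnitude
10²–10³ rules out machine-level gradient norms.  Wald SEs come from the
inverse numerical Hessian at the MLE.  Boundary estimates (any fitted
|logit| > 10) are flagged, never clamped.

Model selection uses AICc with n = the number of sites entering the model;
this convention reproduces the model-table arithmetic of small camera-trap
studies exactly (e.g. logLik −430.935, K = 5, n = 27 → AICc 874.7).
All-subsets enumeration is capped at 10 candidates (2¹⁰ models); an
explicit spec list is accepted where a hand-picked candidate set is wanted.

## Multi-species occupancy

The joint occupancy layer is a multivariate Bernoulli in natural-parameter
form: first-order terms f_i(x) = x′β_i per species, second-order pairwise
intercepts f_ij (no covariates on interactions, no third-order terms), all
2^S states enumerated exactly (S = 4 → 16 states; no variational
shortcuts).  Detection given the latent state is independent across species
and occasions with per-species logit-linear p.  The site likelihood
marginalizes the latent state; detections force z_s = 1 automatically
because the z_s = 0 branch then carries zero likelihood (implemented as a
finite very-negative log-likelihood so that 0 · (−∞) never contaminates the
state sum).

The model is fitted in two steps: per-species covariates are first fixed to
the single-species AICc winners, then the joint model estimates all β, the
pairwise intercepts, and detection coefficients together.  SEs/z/p are Wald
from the numerical Hessian.  Non-convergence after all starts is flagged on
the returned fit, not raised, so a screening pipeline can keep moving.

*Odds ratios.* ORsp is the change in log-odds of focal-species presence
between a conditioning species' presence and absence, covariates at
baseline x = 0 (standardized scale).  Two conditioning modes exist because
the definition is genuinely ambiguous with S > 2: the default **pairwise**
mode toggles one partner and marginalizes the bystanders (pair-specific
importance values); the **all-others** mode toggles every non-focal species
together.  For S = 2 the pairwise log-ORsp equals f_12 exactly — a useful
identity test.  ORh is the log-odds change of focal presence for a
covariate step Δx (default 1 SD) with all other species absent, which
reduces to β_h·Δx.  The importance table assembles |log OR| values, species
× (species ∪ covariates).

## Activity overlap

Times of day map to angles 2π·s/86400.  Densities are von Mises KDEs whose
kernel concentration follows the plug-in rule

  ν = [ 3 n κ̂² I₂(2κ̂) / (4 √π I₀(κ̂)²) ]^{2/5},

with κ̂ the largest von Mises concentration implied by the first three
trigonometric moments of the sample.  Taking the max over moments matters:
a crepuscular (bimodal, near-antipodal) sample has first-moment resultant
length near zero, and a first-moment-only rule would flatten its two peaks
into a nearly uniform density and inflate every overlap estimate.  The
adjustment constant c (default 1 for Δ̂₄, the convention for large samples;
0.8 is conventional for Δ̂₁) multiplies ν.  Exponentially scaled Bessel
functions keep all of this finite at large κ.

Δ̂₁ integrates min(f̂₁, f̂₂) on a 512-point grid; Δ̂₄ averages
min(f̂_other/f̂_own, 1) over both samples' observed points and is exactly 1
on identical samples.  Bootstrap CIs are percentile with 999 resamples.
The randomization test pools both samples, re-splits at the original sizes,
and reports the plain proportion of permuted Δ at or below the observed Δ
(no +1 smoothing — the proportion convention is applied uniformly across
all of the package's randomization tests).  Validation: on the generator's
default crepuscular-vs-midday mixtures, |mean Δ̂₄ − ∫min(f₁,f₂)| ≈ 0.02 at
n = 1000 (the acceptance suite asserts < 0.03), and the permutation test
rejects at 3–6% of nominal-5% replicates under the null.

*Solar utility.* Sunrise/sunset via the NOAA low-accuracy equations
(zenith 90.833°), circularly averaged over the first day of each month;
refuses |lat| ≥ 66.5° where days without sunrise/sunset exist.  Analyses
run in clock time — the utility anchors interpretation (are peaks
crepuscular?) and no double-anchoring transform is applied by default.

## Spatiotemporal avoidance

Per co-occurring station, the minimum |t_A − t_B| over the full
cross-product of the pair's detection times (order-agnostic; a directed
variant is a flag away).  The test statistic is the median of per-station
minima (even counts: midpoint of the central pair).

A literal null that merely reassigns the *observed* encounter times to
stations leaves their median invariant and cannot generate a distribution.
The implemented null therefore randomizes detection **days**: species A is
held fixed and each of species B's detections gets a day redrawn uniformly
over that station's active deployment days, time of day preserved,
1000 draws.  p = proportion of simulated medians strictly greater than the
observed median, so p near 0 indicates stronger-than-chance temporal
separation and p near 1 aggregation.  With a one-day deployment the null is
degenerate and p lands at 0 or 1 without error.

The distance check computes, for each station holding species A, the
Euclidean distance (planar metre coordinates) to the nearest station
holding B, averaged over stations and symmetrized over directions.  The
null reassigns presence labels uniformly across the analysis stations
preserving each species' station count; p = proportion of null means at or
below the observed mean.  Both tests calibrate to 3.5–6.5% rejections at
nominal 5% under their own nulls (200-replicate studies).

Co-occurrence percentages divide shared-station counts by the number of
analysis stations (those recording any target species) and are reported to
2 dp as exact division.

## Synthetic-data generator

The generator emulates the survey structure every module assumes, not any
particular landscape: 39 stations on 15 transects (500 m along-transect
spacing with jitter, 1 km between transects, minimum spacing 400 m
enforced), 360-day deployments with a 15% early-failure rate, elevation
drawn N(1600, 150) m with longitude/latitude deliberately collinear to it
(r ≈ 0.7–0.8) so the covariate screen has real work to do.

Occupancy states are drawn exactly from the multivariate-Bernoulli joint
distribution at each station's standardized covariates.  The default regime
echoes a grazing-pressure community: positive elevation/aspect/cover
effects for the deer, low-elevation wild boar and cattle, strongly negative
cattle–deer interaction intercepts (−2.5), a weaker cattle–boar one (−0.8),
and mild structure among the wild species.  Detection is simulated daily
(logit p_day = intercept + season effect on May–Sep days; intercepts −3 to
−6, season effects +0.7 to +3.5, cattle essentially summer-only) and the
same event stream feeds both the occasion-binned occupancy analyses and the
timestamp-level temporal analyses, mirroring how one camera dataset feeds
every analysis in a real study.  Detection days get times of day from
per-species von Mises mixtures (wild ungulates: equal-weight components at
08:30 and 21:00, κ = 3; cattle: single component at 12:30, κ = 3), and each
detection spawns Poisson(0.8) repeat triggers within 30 min to exercise the
independence filter.

What the generator does **not** emulate: spatial autocorrelation of
occupancy beyond shared covariates, animal movement and home ranges, camera
viewshed/detection-distance geometry, weather-driven activity shifts, and
observer effects.  Passing tests therefore demonstrate the estimators are
correct under the models' own assumptions — not that those assumptions hold
in any particular field system.

## Validation studies and problem sizes

The evaluation harnesses (shared by the test suite and
`scripts/acceptance.py`) use these sizes, chosen to make the Monte-Carlo
error small relative to the thresholds they check:

- **Likelihood oracles**: 100 random micro-instances (≤ 4 species, ≤ 4
  sites, ≤ 3 occasions) against explicit latent-state enumeration,
  agreement to 1e-10.
- **Parameter recovery**: 20 replicates of 500 stations × 36 occasions,
  4 species, occupancy simulated from the generator's default truth and
  detection drawn at the occasion scale (logit p = −0.85 + 0.8·Time,
  mid-range probabilities); ≥ 90% of occupancy coefficients and interaction
  intercepts within 3 Wald SE (observed: ~99%).
- **Δ̂₄ bias**: 50 replicates at n = 1000 per sample against the 4096-point
  grid integral of the true mixture min.
- **Null calibrations**: 200 replicates each with 199 inner
  randomizations; the inner count keeps p-value granularity at 1/199 —
  ample for checking the 2–9% rejection band — at a fraction of the cost of
  1000 draws, which remain the default for data analysis.

## Known limitations

- Interaction intercepts are constant (no covariate-dependent f_ij) and
  third-order interactions are excluded; with 4 species and tens of sites,
  richer structure is not estimable anyway.
- Wald intervals from a numerical Hessian misbehave near boundaries
  (separated occupancy states, ψ̂ → 1); such fits are flagged rather than
  profiled.
- The encounter null conditions on the observed number of detections per
  station and randomizes days only; detection-rate heterogeneity within a
  deployment (e.g. seasonal p) is not part of that null.
- Timestamps are naive local clock time throughout; no timezone or
  daylight-saving arithmetic.
- The all-subsets enumeration refits every model independently; no score
  tests or stepwise shortcuts.
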