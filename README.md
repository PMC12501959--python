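# camtrap-cooccur

Spatiotemporal co-occurrence analysis for camera-trap surveys: how do
sympatric species — here three wild ungulates (red deer, roe deer, wild
boar) and free-ranging cattle — partition space and time within a shared
landscape?  The package implements the complete analysis chain a
camera-trap community study needs, and ships a seeded synthetic-survey
generator so the full pipeline runs and is tested without any field data.

## What it computes

**Detection histories.** Raw triggers are reduced to independent detections
(a trigger within 30 min of the previously retained trigger of the same
species at the same station is a continuation of one event), then binned
into 10-day occasions: 1 = detected, 0 = active but undetected, NA =
station inactive for the whole occasion.  Occasions overlapping the May 1 –
Sep 30 grazing season (majority of days) carry a `Time = 1` detection
covariate.  Continuous habitat covariates are standardized, categorical
ones contrast-coded {1, −1, 0}, and the set is screened to pairwise
Pearson |r| ≤ 0.5 and VIF < 3.

**Single-species occupancy.** The classic single-season model with logit
links: site i is occupied with probability ψ_i and, if occupied, detected
on occasion t with probability p_it; the likelihood marginalizes the latent
state.  All-subsets candidate sets are ranked by
AICc = −2 logL + 2K + 2K(K+1)/(n−K−1), with ΔAICc ≤ 2 equivalence and
Akaike weights w_i ∝ exp(−Δ_i/2).

**Multi-species occupancy with interactions.** Joint occupancy of S species
follows a multivariate Bernoulli with log-linear natural parameters

    ψ(z | x) ∝ exp( Σ_i f_i(x) z_i + Σ_{i<j} f_ij z_i z_j ),   z ∈ {0,1}^S,

where f_i(x) = x′β_i carries the covariate effects and the pairwise
intercepts f_ij measure co-occurrence beyond covariates (f_ij < 0 =
avoidance); third- and higher-order terms are zero.  The marginalized
likelihood sums the 2^S latent states exactly.  Derived summaries:
conditional occupancy Pr(z_focal | z_other, x), the odds ratio for another
species' presence (ORsp; pairwise with bystanders marginalized, or
all-others-toggled behind a flag), the odds ratio for a covariate step
(ORh, which reduces to β_h·Δx with other species absent), and the |log OR|
relative-importance table.

**Activity overlap.** Detection times become angles on the 24-h circle;
each species' diel density is a von Mises kernel estimate with a plug-in
bandwidth.  Pairwise similarity is the overlap coefficient
Δ = ∫ min(f₁, f₂), estimated with Δ̂₄ (the two-sample ratio estimator,
appropriate above ~75 detections) or Δ̂₁ on a grid, with a percentile
bootstrap CI, a label-permutation test of a common pattern, and the
low (Δ ≤ 0.5) / moderate (≤ 0.75) / high classification.  A NOAA
solar-geometry utility gives mean sunrise/sunset for the study area.

**Spatiotemporal avoidance.** At stations where a pair co-occurs, the
minimum |t_A − t_B| over all detection pairs is the time-to-encounter; the
observed median is tested against a 1000-simulation null that redraws one
species' detection days uniformly over each station's deployment (times of
day preserved), p = proportion of simulated medians above the observed.
A companion 1000-rep bootstrap compares mean nearest-station distances
between the species' station sets against random label placement.

## Worked example

The numbered scripts under `analysis/` run the whole study on a simulated
39-station, 360-day survey (results land under `results/`):

```bash
python analysis/01_simulate_survey.py
python analysis/02_detection_histories.py
python analysis/03_occupancy_models.py
python analysis/04_activity_overlap.py
python analysis/05_spatiotemporal_interactions.py
python analysis/06_validation_studies.py
```

`02` reports the detection-history shape and the covariate screen — the
collinear longitude/latitude columns are dropped, leaving seven covariates:

```
39 sites x 36 occasions per species
grazing-season occasions: 15
kept covariates: Dtr, Ele, Slo, Dtw, Vt, Asp, Td
dropped Lat: |r|=0.779 with Ele > 0.5
dropped Lon: |r|=0.720 with Ele > 0.5
```

`03` fits the two-step occupancy models; every cattle interaction intercept
comes out negative, echoing the generative regime of grazing pressure:

```
multi-species fit: logLik=-1233.88, K=30, converged=True
  interaction red_deer:cattle = -0.622
  interaction roe_deer:cattle = -1.443
  interaction wild_boar:cattle = -0.829
```

`04` shows the temporal side of the same story — the three crepuscular wild
ungulates overlap strongly with each other and weakly with midday-active
cattle (p is the permutation test of a shared activity pattern):

```
  red_deer vs roe_deer   Delta=0.963 [0.876, 0.967] p=0.895 (high)
  red_deer vs cattle     Delta=0.382 [0.305, 0.445] p=0.000 (low)
 wild_boar vs cattle     Delta=0.424 [0.341, 0.496] p=0.000 (low)
```

`05` prints the per-pair co-occurrence counts, encounter-time test and
distance bootstrap in one table.

A `camtrap-cooccur` console script exposes the same stages
(`simulate`, `prepare`, `occupancy`, `temporal`, `interactions`) for
arbitrary event/station CSVs driven by a YAML config; one global seed makes
a run bit-reproducible.

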