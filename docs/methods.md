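# Methods

## Model structure

The analysis treats a bird's wintering area as a hidden state observed
through a multievent (hidden-Markov) capture–recapture model
conditioned on first release. The hidden space is the product of
wintering area (4 levels), geolocator status (none / functioning /
failed) and awareness (aware / unaware), plus one absorbing dead state
— 25 states in the full configuration. "Awareness" makes
trap-dependence first-order Markov: a bird is aware at an occasion if
and only if it was captured there, so events are a deterministic 0/1
function of the state and all randomness sits in the transition.

The annual transition between consecutive arrival (inter) occasions is
the product of four row-stochastic steps, applied in a fixed order:
survival → area change → device update → detection. The order is a
modelling choice (any factorisation order defines a valid chain); this
one keeps each step interpretable and makes the stay probability of the
symmetric change design exactly 1 − 3c. Departure (intra) occasions
carry no likelihood term: geolocator release is a field decision
recorded in the data, and it enters the model as a known device action
(deploy / remove / none) on the following interval.

Assumptions worth stating explicitly:

* **Emission determinism.** A captured bird carrying a functioning
  device always yields its current area; a failed device yields a
  distinguishable "failed" capture. Consequently a reveal event can
  only occur at a capture occasion. Winters archived by a device
  carried across several years without capture enter the *assignment
  table* (used by the fidelity analysis) when the device is finally
  recovered, but not the encounter history.
* **First-encounter effect.** Survival over the interval following
  first capture is φ·(1 − δ), a multiplicative reduction. The excess
  mortality δ absorbs both true mortality and permanent dispersal after
  the first observed breeding attempt; the two are confounded in
  apparent survival.
* **Initial conditions.** At first capture the bird is aware, carries
  no device, and its area is a draw from the simplex π. Later reveals
  pin the area path through the emissions; no separate conditioning is
  needed.
* **Device reliability.** A deployed device functions with probability
  ρ, fixed by default at 147/182 (the informative fraction of recovered
  devices), not estimated: with reveal-sparse data, freeing ρ degrades
  the identifiability of the change and initial-state parameters
  without changing survival.

## Parameters, links, defaults

| parameter | meaning | link | default (generator) |
|---|---|---|---|
| φ_a | annual apparent survival in area a | logit | 0.841 (mean model); 0.961/0.428/0.821/0.903 (area model) |
| δ | excess first-interval mortality | logit | 0.088 |
| c | per-destination annual change probability | multinomial logit, stay as reference | 0.07 |
| γ₁ | wNAO slope on the change score | identity (link scale) | 0 |
| β_SOI | SOI slope on logit survival | identity (link scale) | 0 |
| π_Canary | initial probability of the Canary Current | logit (others equal) | 0.28 |
| p_aware / p_unaware | recapture after capture / after a miss | logit + trap offset | 0.60 / 0.40 |
| ρ | device provides data | fixed | 147/182 |

The change probability uses a multinomial logit with the stay category
as reference (c = e^η/(1+3e^η)) rather than a plain logit: it is
feasible (3c < 1) for every coefficient value, which matters for
unconstrained quasi-Newton optimisation, and it generalises directly to
destination- or origin-specific designs. Climate covariates are
z-scored over the study years before entering any linear predictor;
interval *t → t+1* uses the covariates of the arrival year *t+1* (the
winter the interval spans). Coefficients are capped at |15| on the link
scale purely to avoid overflow; estimates near the cap trigger a
boundary warning.

Model structures are declared per parameter family (survival: constant,
area, Canary-vs-others, SOI, area+SOI, area×SOI, device effect; change:
constant, wNAO, SOI, to-area, from-area; initial: equal,
Canary-vs-others, area; recapture: constant or time-varying, both with
the trap offset), and each resolves to an explicit coefficient layout
whose count is known before fitting.

## Fitting and uncertainty

The likelihood is evaluated by a scaled forward pass vectorised across
individuals; per year it batches individuals by (first-interval flag,
device action), so one evaluation at study scale (1104 × 23) costs a
few milliseconds. Optimisation is L-BFGS-B from a zero start plus
seeded uniform(−2, 2) restarts (default 10 starts; the surface has been
well-behaved in all simulation checks, and the recovery tests use 2).
Standard errors come from the central-difference observed information
at the optimum; real-parameter 95% intervals are monotone
back-transforms of single-coefficient Wald intervals, and derived
quantities (stay probability, first-year survival, survival at a given
SOI) use exact transforms or the delta method. Singular information is
reported, not fatal. Profile intervals and random effects are out of
scope.

## Goodness of fit and model selection

GOF runs on histories collapsed to detected/not-detected at the inter
occasions. Two components are computed: an immediate trap-dependence
test (per-occasion 2×2 tables of capture at t × capture at t+1 among
animals marked before t and known alive after t, with a signed z
positive for trap-happiness) and a transience test (newly vs previously
marked × ever reseen). 2×2 tables with any expected cell below 2 are
dropped rather than pooled — a 2×2 has no cells to merge — and the
component df counts the informative tables. Both tests hold their
nominal 5% size on null simulations (checked in the suite).

ĉ defaults to total χ²/df; because trap-dependence is subsequently
modelled through the awareness states, the residual inflation used for
QAICc is (total χ² − trap χ²)/(total df − trap df), with an explicit
override. QAICc = deviance/ĉ + 2·np + 2·np(np+1)/(n_eff − np − 1) with
n_eff the number of releases (capture events), a standard
capture–recapture convention. Weights are exp(−Δ/2) normalised over the
fitted set; failed fits are excluded and warned about.

## Repeatability

Krippendorff's alpha uses individuals as units, the individual's winter
areas across years as repeated nominal observations, and the
coincidence-matrix formulation α = 1 − D_o/D_e over pairable values.
The implementation is cross-checked in the tests against an independent
pair-enumeration oracle. The bootstrap CI resamples individuals (the
records within an individual are the repeated measures), percentile
2.5/97.5, 10 000 iterations by default. Tracks outside the four-area
scheme carry an "excluded" marker: they count as tracks and as a
change of area, but are dropped from area shares and from alpha.

## What the generator emulates — and what it does not

`default_paper_config()` fixes the study conditions: 1104 adults
recruited uniformly over 2000–2021, 23 annual occasions, geolocator
deployment in 2002 and 2009–2014 with per-capture probability 0.26
(calibrated once so expected deployments ≈ 258 and informative
recoveries ≈ 147), device reliability 147/182, and generating
parameters from the table above. Recapture probabilities (0.60/0.40)
were chosen to give roughly three captures per bird over its lifetime,
a realistic colony-monitoring intensity with clear trap-happiness.
Climate series are independent standard normals unless a real series is
supplied.

The generator shares its transition definitions with the likelihood, so
recovery tests confirm self-consistency of the implementation, not
robustness to model misspecification. Real data differ in ways the
generator deliberately ignores: per-year variation in marking and
deployment effort, heterogeneity in detection beyond the trap effect,
device-induced mortality, immigration, and any spatial structure within
wintering areas. Passing recovery tests therefore validates the
estimator and its uncertainty statements under the stated model, and
nothing more.

## Numerical choices and problem sizes

The forward pass renormalises the state vector at every occasion and
accumulates log-scale mass, so no underflow occurs over 23 occasions.
An event incompatible with every positive-mass state raises an
impossible-history error naming the individual and occasion.
Ties in QAICc rank by fewer parameters. Simulation-based tests in the
suite use sizes chosen for precision per unit runtime: 5-replicate
recovery at 1500 individuals (the scaled variant of the 20-replicate
coverage protocol), 200-replicate type-I-error checks at n = 500, and
100-replicate ĉ calibration at n = 1000. The acceptance script uses 20
replicates (12 for the area model) at 1500 individuals and reports the
mean recovered value across replicates.

## Known limitations

* Wald intervals on boundary-adjacent survivals (e.g. a true 0.96 with
  sparse reveals) can be asymmetric and slightly undercover; profile
  likelihood would do better and is not implemented.
* ρ is fixed, not estimated; misspecifying it biases the split between
  "functioning" and "failed" reveal paths, though not survival.
* The time-varying recapture design adds one coefficient per interval
  and is fit-tested only at small scale.
* Multi-year archives enter the fidelity analysis but the encounter
  histories carry reveals only at capture occasions; with deployment
  concentrated in consecutive years this loses little information, but
  a design with long gaps between deployment and recovery would be
  served poorly.
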