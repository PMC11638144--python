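# multievent

Multievent (hidden-Markov) capture–recapture models for estimating
wintering-area-specific adult survival, wintering-site fidelity and
climate-covariate effects in migratory seabirds — together with a
synthetic encounter-history generator so that every stage of the
analysis can be exercised and validated without access to a long-term
field dataset.

The package is aimed at population ecologists working with individual
encounter histories from a breeding colony in which a subsample of birds
carries archival geolocators: the wintering area of a bird is a *hidden*
state, revealed only when a functioning device is recovered at
recapture.

## The model

Each bird occupies one of 25 states: the product of 4 wintering areas
(Canary Current, pelagic Equatorial Atlantic, Gulf of Guinea,
Angola–Benguela Front), 3 device statuses (none, functioning, failed)
and 2 awareness levels (aware/unaware, encoding trap-dependence), plus
an absorbing dead state. Each study year splits into an arrival (inter)
and a departure (intra) occasion — 23 years become 45 coded occasions.
Events observed at the colony (not captured; captured without device;
captured with a device revealing area *a*; captured with a failed
device) are a deterministic function of the state, and all stochasticity
lives in the annual transition, which factorises into row-stochastic
steps:

1. **survival** φ_{a,t} = logit⁻¹(β·x(a, SOI_t)), reduced to
   φ·(1 − δ) over the interval following first encounter;
2. **area change** with per-destination probability
   c_t = e^{η_t}/(1 + 3e^{η_t}), η_t = γ₀ + γ₁·wNAO_t (stay
   probability 1 − 3c_t);
3. **device update** (deploy/remove, driven by the intra events; a
   deployed device functions with probability ρ);
4. **detection**: the bird arrives aware (captured) with probability
   p_aware or p_unaware according to its previous capture.

The likelihood of a history is the forward-algorithm sum over state
paths conditional on first release; models are fitted by maximum
likelihood on link-scale coefficients, compared by QAICc with a
variance-inflation factor ĉ estimated from Cormack–Jolly–Seber
goodness-of-fit components (trap-dependence and transience), and
wintering-site repeatability is quantified by Krippendorff's alpha with
a bootstrap CI.

## Worked example

`examples/03_fit_survival.py` simulates a study-scale dataset (1104
individuals, 23 years) with generating truth φ = 0.841, δ = 0.088,
c = 0.07, π_Canary = 0.28, and refits the generating model:

```
real parameters (95% Wald CI):
  phi                0.843  (0.829-0.856)
  delta              0.114  (0.076-0.169)
  c                  0.060  (0.029-0.112)
  pi_Canary          0.331  (0.203-0.491)
  p_unaware          0.418  (0.384-0.452)

derived stay probability: 0.820 (0.663-0.914); truth 0.79
derived first-year survival: 0.747 (0.712-0.781); truth 0.841*(1-0.088) = 0.767
```

Every generating value is covered by its interval: mean adult survival
is recovered tightly, while the change probability and the initial
Canary share are driven by the (deliberately sparse) geolocator reveals
and carry wide intervals, as they do in real deployments. The other
example scripts cover the state-space enumeration, the simulator's
study design, goodness-of-fit/model selection, and the fidelity
analysis; each prints the numbers it computes and what they mean.

A thin CLI wraps the same functions:

```sh
multievent simulate --n-individuals 1104 --seed 1 --out sim/
multievent gof --data sim/encounters.txt --out gof/
multievent repeatability --assignments sim/assignments.tsv --out rep/
```

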