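# Methods

## Model and assumptions

The core model is a three-state hidden Markov chain on an annual time step
(breeder B, nonbreeder NB, dead D) observed through 8 composite events per
year. The state process factorizes into survival followed by conditional
breeding, so the transition matrix is the product of a diagonal survival
matrix and a breeding matrix; death is absorbing. The observation process
is the product of three row-stochastic stage matrices — moult/winter
detection (3×4), uneven-week detection (4×6), and even-week detection
(6×8) — whose 3×8 product gives the per-state event distribution. The
order of the three stages does not affect the composite; modelling the
nonbreeding period first merely keeps intermediate dimensions small.
For a live breeder the composite row factorizes into three independent
Bernoulli detections (one per capture period); this closed form is used in
the test suite as an independent oracle for entry placement in the stage
matrices.

Structural assumptions, inherited from the sampling design:

* Nonbreeders are not available for capture during the breeding season;
  their only detection channel is the moult/winter period (probability
  m_NB).
* No mortality occurs between the breeding season and the moult of the
  same seal year: the event matrices condition on the state at the
  *breeding season*, so an animal dying between breeding and moult is
  treated as alive-and-missed in that year's κ^M. The consequence is a
  downward bias in moult detection, not in annual survival, where the
  death is simply recorded one interval later.
* Tag loss is not modelled; apparent survival is therefore survival ×
  retention of at least one tag.
* Histories are conditioned on the first breeding-season capture
  (first event ∈ {1,2,3,5,6,7}). The initial state is breeder with
  probability one and the first occasion contributes no detection factor.
  Sightings in pre-recruitment years (e.g. a moult-only event the year
  before first breeding) are discarded by the encoder; this is a
  deliberate design choice, since the model has no prebreeder state to
  absorb them.

## Parameters

| family | meaning | indexed by | default pattern |
|---|---|---|---|
| φ (phi) | apparent annual survival | interval t→t+1, departure state | constant |
| ψ (psi) | P(breed at t+1 \| survive), Markovian | interval, departure state | constant |
| m | moult/winter capture probability | occasion, state | constant |
| p^u (pu) | breeding-season capture, uneven weeks (breeders only) | occasion | constant |
| b^e (be) | breeding-season capture, even weeks (breeders only) | occasion | constant |

All parameters are probabilities in [0,1]; the working scale is logit for
every slot (each stage-matrix row has at most one free parameter, so no
multinomial link is needed). Variation patterns per family are constant /
time / state / state×time, declared either programmatically or with
strings such as `"phi(.) psi(state*t) m(state*t) pu(t) be(t)"`; a family
can instead be fixed at a constant (e.g. `m(=1)` for perfect detection).
The working-vector layout is family-major (phi, psi, m, pu, be), then
state-major (B before NB), then time-ordered, and is stable across
versions. Time-varying detection families carry T−1 slots covering
occasions 2..T; occasion-1 detection is conditioned away by the
first-capture convention and is stored as a copy of the occasion-2 value.
`parameter_count` reports raw slot counts; the numerically estimated
Hessian rank is reported next to it, since published parameter counts for
such models embed software-specific identifiability conventions that a raw
count does not reproduce.

## Likelihood and inference

The forward recursion starts at the first capture with state distribution
(1, 0, 0), and per occasion applies transition then emission, rescaling
the forward vector and accumulating the log scale so arbitrarily long
histories do not underflow. Identical histories are pooled with
multiplicities before evaluation. A brute-force path-enumeration oracle
(≤ 12 occasions, 3^(L−1) paths) is kept alongside as the independent
check; forward and oracle agree to 1e−10 absolute over fuzzed cases.
Histories that a parameter value makes impossible yield −∞ (with the
offending ids reported), not an exception.

Fitting minimizes the deviance with L-BFGS-B from `n_starts` random
starting vectors drawn uniformly on [−2, 2] on the working scale
(≈ [0.12, 0.88] as probabilities; configurable). Multi-start quasi-Newton
addresses the local-minimum risk of state-uncertainty likelihoods without
an EM stage: both methods share stationary points, and the multi-start log
is retained so non-convergent starts are visible rather than dropped.
Convergence uses ftol 1e−12 / gtol 1e−8. Standard errors come from the
pseudo-inverse of the numerically differentiated Hessian of the negative
log-likelihood (`statsmodels.tools.numdiff.approx_hess`); the numerical
rank (SVD threshold dim·eps·s_max) flags parameter-redundant directions,
whose SEs are reported as unavailable. Wald intervals are computed on the
working scale and back-transformed, so they respect [0,1]; estimates at
the boundary (|working value| > 9.2, i.e. within ~1e−4 of 0 or 1) are
flagged and their intervals suppressed rather than fabricated.

Model comparison uses QAIC = deviance/ĉ + 2·np with Akaike weights;
ĉ < 1 is clamped to 1 with a warning. ĉ may be supplied directly (when an
external goodness-of-fit analysis provides it) or estimated by a median
parametric bootstrap: simulate from the fitted model conditional on the
observed first-capture occasions, refit (one start at the MLE), and take
observed deviance / median bootstrap deviance. This estimator is a
transparent, testable choice — on model-true data it returns 1 within
bootstrap noise — but it is not guaranteed to match overdispersion
estimates produced by other GOF decompositions, so the comparison tools
always accept ĉ as an input.

## Synthetic data

The generator works at two levels. The event-level generator recruits
cohorts of first-time breeders (all individuals enter in state B, matching
a population conditioned on first reproduction), evolves states by the
transition matrix, draws events from the composite matrix, and applies the
same first-capture conditioning as the encoder. The weekly-level generator
additionally simulates the raw survey layer: breeders draw an arrival week
from a unimodal distribution over weeks 1–5 peaking in week 3 (mirroring a
mid-October peak in attendance), stay for a 4-week residence window
(clipped at week 8 with a counter), and are detected independently each
week with probability `p_week`; moult/winter detection is state-specific.
A 4-week window always spans two uneven and two even survey weeks, so the
implied period-level detection is 1 − (1 − p_week)², and the two levels
produce matching event marginals under that calibration (verified by
simulation).

Default generating values for the bundled fixtures are chosen as typical
for a long-lived colonial capital breeder: survival 0.76–0.8, breeding
probability 0.84–0.85 after breeding and 0.65–0.66 after skipping,
moult detection 0.6–0.75, breeding-season period detection 0.6–0.7.
The `marion_like` fixture uses a 28-year axis (1986–2013 labels) with
cohorts growing over the first decade.

What the generator does *not* emulate: individual heterogeneity (random
effects or mixtures), tag loss, environmental covariates on rates,
within-season mortality, spatial structure, and prebreeder dynamics.
Passing recovery tests therefore demonstrate internal consistency of
encoder, likelihood and optimizer under the model's own assumptions — not
robustness to the violations real resight data may exhibit.

## Numerical and design choices

* Composite-event codes, stage-matrix zeros, and the conditioning rule are
  frozen as data (dictionaries/arrays), and each has a closed-form test
  oracle: the Bernoulli factorization for matrices, path enumeration for
  the likelihood, empirical transition frequencies for the MLE under
  perfect detection.
* Problem sizes in the test suite (e.g. 2,000 individuals × 15 occasions
  for recovery, 100 bootstrap replicates at ~1,000 individuals for the ĉ
  null calibration, 50 replicates for interval coverage) are chosen so
  Monte-Carlo error is small relative to the tested tolerances while the
  whole suite stays interactive (a few minutes).
* Dead animals emit "not seen" with probability 1 through the printed
  moult-stage row; there is no dead-recovery event.
* Degenerate inputs: empty datasets, empty structures, out-of-range
  probabilities, histories exceeding the enumeration cap, and zero-boot
  requests are rejected with named errors; impossible histories propagate
  −∞.

## Known limitations

* Only the four variation patterns (constant, time, state, state×time) are
  supported — no additive state+time decompositions and no covariates.
* The bootstrap ĉ assumes refits at the MLE start converge; refit failures
  above 20% flag the estimate unreliable.
* Recomputing ΔQAIC from *rounded* published deviances and ĉ will not
  reproduce a published ΔQAIC column to the last digit; the comparison
  command therefore never asserts equality with an externally printed
  ΔQAIC, only recomputes weights from whatever deviances it is given.
* Wald intervals are symmetric on the logit scale; profile intervals are
  available only as a diagnostic (`profile_deviance`), not as a first-class
  interval type.
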