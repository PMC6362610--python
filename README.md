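# mered — multievent robust-design capture–recapture

`mered` estimates **annual breeding probability** and **apparent survival**
in populations where nonbreeders avoid the breeding grounds, by combining
robust-design breeding-season surveys with auxiliary sightings made at
other times of the year. The motivating system is capital-breeding female
southern elephant seals: breeders haul out for ~4 weeks during a
synchronous spring breeding season and are surveyed weekly; both breeders
and nonbreeders are seen again at the moult and occasionally in winter.
Analyzing all of these surveys together makes the nonbreeder state
*observable*, which permits state-dependent survival estimation and sharper
breeding-probability estimates than unobservable-state multistate models.

## Model

Each female occupies one latent state per year: breeder **B**, nonbreeder
**NB**, or dead **D** (absorbing). The annual transition matrix is the
product of a survival step and a conditional breeding step,

```
        B                    NB                   D
B   ( φ_B ψ^{B–B}      φ_B (1 − ψ^{B–B})      1 − φ_B  )
NB  ( φ_NB ψ^{NB–B}    φ_NB (1 − ψ^{NB–B})    1 − φ_NB )
D   (      0                  0                   1     )
```

with φ the apparent annual survival and ψ the breeding probability
conditional on survival and on the previous state (Markovian breeding).

Observations are collapsed into three capture periods per "seal year"
(September–August): the odd breeding-season survey weeks (κ^U), the even
weeks (κ^E), and all moult/winter sightings (κ^M). Collapsing *alternating*
weeks guarantees every breeding female — however staggered her attendance —
is exposed to effort in both breeding-season periods. The subset of periods
with at least one sighting defines one of 8 composite events per year
(0 = not seen, 1 = MUE, 2 = MU, 3 = ME, 4 = M, 5 = UE, 6 = U, 7 = E).
The state→event probabilities are the product of three row-stochastic
matrices (moult/winter with capture probabilities m_B, m_NB; uneven weeks
with p^u; even weeks with b^e); nonbreeders are assumed unavailable during
the breeding season. Event 4 (seen only outside the breeding season) is the
state-ambiguous observation: it can come from an undetected breeder or a
detected nonbreeder, and the hidden Markov likelihood resolves it
probabilistically.

Histories are conditioned on the first breeding-season capture. The
likelihood is the usual scaled forward recursion; models are compared with
QAIC (= deviance/ĉ + 2·np) and Akaike weights, and ĉ can be estimated by a
median parametric bootstrap.

## Worked example

```python
import numpy as np
from mered import (ParameterSet, EncounterHistory, history_loglik,
                   make_fixture, fit, ModelStructure)

# a 2-occasion history: seen in both breeding periods, then only at moult
params = ParameterSet(2, phi_b=0.8, phi_nb=0.8, psi_bb=0.5, psi_nbb=0.5,
                      m_b=0.8, m_nb=0.5, p_u=0.6, b_e=0.7)
h = EncounterHistory("F042", 0, (5, 4))
print(np.exp(history_loglik(h, params)))   # 0.23840000000000006

# fit a constant-parameter model to a simulated 500-female dataset
dataset, config = make_fixture("recovery_small")
structure = ModelStructure.parse("phi(.) psi(state) m(state) pu(.) be(.)")
result = fit(dataset, structure, n_starts=3, seed=1)
print(result.estimates[["family", "state", "estimate", "se"]])
```

The first number is the exact two-path sum
0.8·0.5·(0.8·0.4·0.3) + 0.8·0.5·0.5 = 0.2384: after surviving, the female
either bred again and was seen only at the moult, or skipped and was seen
as a nonbreeder. The fit prints (truth in parentheses):

```
  family state  estimate        se
0    phi     .  0.809477  0.009343   (0.80)
1    psi     B  0.855598  0.021986   (0.85)
2    psi    NB  0.572154  0.062995   (0.65)
3      m     B  0.699031  0.014046   (0.70)
4      m    NB  0.603057  0.045621   (0.60)
5     pu     .  0.599632  0.018492   (0.60)
6     be     .  0.608497  0.018572   (0.60)
```

every estimate within two standard errors of its generating value.

A command-line interface mirrors the library: `mered encode` (raw resights
→ event histories), `mered simulate`, `mered fit`, `mered compare` (QAIC
table) and `mered gof` (bootstrap ĉ).

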