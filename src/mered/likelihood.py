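"""Forward hidden-Markov likelihood of conditioned encounter histories.

Each history starts at the first breeding-season capture, so the initial
latent state is breeder with probability one and the first occasion
contributes no detection term.  From the next occasion onward the forward
vector is propagated through the annual transition matrix and multiplied
by the event-emission column of the observed code, with per-occasion
rescaling so long histories do not underflow.

A brute-force path-enumeration oracle is provided for short histories; it
sums the probability of every latent state sequence explicitly and is the
independent check on the forward recursion.
"""

from __future__ import annotations

import itertools
import warnings

import numpy as np

from .errors import ValidationError
from .events import Dataset, EncounterHistory
from .model import ParameterSet

_INIT = np.array([1.0, 0.0, 0.0])  # conditioned start: breeder w.p. 1

#: Longest history accepted by the enumeration oracle (3^(L-1) paths).
BRUTE_FORCE_MAX_LEN = 12


def _check_axes(history: EncounterHistory, params: ParameterSet):
    if history.first_occasion + len(history.events) > params.T:
        raise ValidationError(
            f"{history.animal_id}: history extends past the parameter axis "
            f"(T = {params.T})")


def history_loglik(history: EncounterHistory, params: ParameterSet) -> float:
    """Log probability of one encounter history given expanded parameters.

    Returns ``-inf`` (rather than raising) for histories the parameters
    make impossible, e.g. a moult-only sighting under zero moult detection.
    """
    _check_axes(history, params)
    phi = params.transition_matrices()
    b = params.event_matrices()
    alpha = _INIT.copy()
    logscale = 0.0
    t0 = history.first_occasion
    for k, event in enumerate(history.events[1:], start=1):
        t = t0 + k
        alpha = (alpha @ phi[t - 1]) * b[t][:, event]
        total = alpha.sum()
        if total <= 0.0:
            return -np.inf
        alpha /= total
        logscale += np.log(total)
    return logscale


def brute_force_history_prob(history: EncounterHistory, params: ParameterSet) -> float:
    """History probability by explicit enumeration of latent state paths.

    Sums over all 3^(L-1) state sequences that start in the breeder state
    at first capture.  Only for short histories; the forward algorithm is
    the production path.
    """
    _check_axes(history, params)
    L = len(history.events)
    if L > BRUTE_FORCE_MAX_LEN:
        raise ValidationError(
            f"history of length {L} exceeds the enumeration cap "
            f"({BRUTE_FORCE_MAX_LEN}); use history_loglik instead")
    phi = params.transition_matrices()
    b = params.event_matrices()
    t0 = history.first_occasion
    total = 0.0
    for path in itertools.product(range(3), repeat=L - 1):
        prob = 1.0
        prev = 0  # breeder at first capture
        for k, state in enumerate(path, start=1):
            t = t0 + k
            prob *= phi[t - 1][prev, state] * b[t][state, history.events[k]]
            prev = state
        total += prob
    return total if L > 1 else 1.0


def total_loglik(dataset: Dataset, params: ParameterSet) -> float:
    """Multiplicity-weighted log likelihood of a dataset.

    If any history has zero probability the total is ``-inf`` and the
    offending animal ids are reported in a warning.
    """
    if dataset.n_occasions != params.T:
        raise ValidationError(
            f"dataset has {dataset.n_occasions} occasions, parameters {params.T}")
    first, events, counts = dataset.dense_arrays()
    ll, bad = _forward_batch(first, events, counts,
                             params.transition_matrices(), params.event_matrices())
    if bad.size:
        ids = [dataset.histories[i].animal_id for i in bad]
        warnings.warn(
            f"{bad.size} history(ies) impossible under these parameters "
            f"(log-likelihood -inf): {ids[:10]}{'...' if len(ids) > 10 else ''}")
        return -np.inf
    return float(ll)


def deviance(dataset: Dataset, params: ParameterSet) -> float:
    """``-2 x`` total log likelihood."""
    return -2.0 * total_loglik(dataset, params)


def _forward_batch(first: np.ndarray, events: np.ndarray, counts: np.ndarray,
                   phi: np.ndarray, b: np.ndarray) -> tuple[float, np.ndarray]:
    """Vectorized scaled forward pass over all histories at once.

    Returns (weighted total log-likelihood, indices of impossible histories).
    """
    n, T = events.shape
    alpha = np.zeros((n, 3))
    logscale = np.zeros(n)
    dead = np.zeros(n, dtype=bool)  # histories that hit probability zero
    alpha[first == 0, 0] = 1.0
    for t in range(1, T):
        active = first < t
        if active.any():
            a = alpha[active] @ phi[t - 1]
            a *= b[t][:, events[active, t]].T
            s = a.sum(axis=1)
            zero = s <= 0.0
            s_safe = np.where(zero, 1.0, s)
            alpha[active] = a / s_safe[:, None]
            logscale[active] += np.log(s_safe)
            idx = np.flatnonzero(active)
            dead[idx[zero]] = True
        alpha[first == t, 0] = 1.0
    bad = np.flatnonzero(dead)
    if bad.size:
        return -np.inf, bad
    return float(np.dot(counts, logscale)), bad
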