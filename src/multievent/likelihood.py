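"""Conditional-on-first-release forward likelihood.

The model is a hidden Markov chain over the 25 states with annual
transitions between inter occasions and deterministic emissions, so the
likelihood of a history is the forward-algorithm sum over state paths,
conditioned on the first capture-and-release: the initial distribution
spreads the wintering-area simplex ``pi`` over (area, no device, aware)
states and later reveal events pin the area through the 0/1 emissions.

Two implementations are provided: a per-individual reference loop
(:func:`history_loglik`) and a vectorised dataset pass
(:func:`dataset_loglik`) that batches individuals sharing the same
(first-interval, device-action) transition within each year.
"""

from __future__ import annotations

import numpy as np

from .dataset import EncounterDataset
from .matrices import (ACTIONS, build_transition_tensor, event_state_mask,
                       symmetric_change_matrix, assemble_transition,
                       survival_vector)
from .params import Design, ModelSpec, ParameterSet, resolve_design
from .states import StateSpace


class ImpossibleHistoryError(ValueError):
    def __init__(self, individual, occasion):
        self.individual = individual
        self.occasion = occasion
        super().__init__(
            f"history of {individual!r} is impossible under the model at "
            f"inter occasion (year index) {occasion}")


def initial_alpha(space: StateSpace, pi: np.ndarray) -> np.ndarray:
    """State distribution at first capture: pi over (area, none, aware)."""
    pi = np.asarray(pi, dtype=float)
    alpha = np.zeros(space.n_states)
    for a in range(space.n_areas):
        alpha[space.index_of(a, 0, 0)] = pi[a]
    return alpha


def transition_tensor_from_params(space: StateSpace, params: ParameterSet,
                                  covariates) -> np.ndarray:
    """(n_intervals, 2, 3, S, S) transitions from real parameters."""
    z = covariates.zscored()
    ni = covariates.n_years - 1
    S = space.n_states
    out = np.empty((ni, 2, len(ACTIONS), S, S))
    for i in range(ni):
        soi_z, wnao_z = z.soi[i + 1], z.wnao[i + 1]
        phi = np.array([params.phi(a, soi_z) for a in range(space.n_areas)])
        change = symmetric_change_matrix(params.change_prob(wnao_z),
                                         space.n_areas)
        for f, d in ((0, 0.0), (1, params.delta)):
            surv = survival_vector(space, phi, d)
            for a in ACTIONS:
                out[i, f, a] = assemble_transition(
                    space, surv, change, a, params.rho,
                    params.p_aware, params.p_unaware)
    return out


def history_loglik(space: StateSpace, inter_events: np.ndarray, entry: int,
                   actions: np.ndarray, tensor: np.ndarray,
                   pi: np.ndarray, individual: str = "?") -> float:
    """Reference forward pass for one individual (plain Python loop).

    ``tensor`` is indexed (interval, first-flag, action); ``actions``
    gives the device action per interval.  Returns the log-probability
    of the events after first capture, conditional on the release.
    """
    Y = len(inter_events)
    mask = event_state_mask(space)
    alpha = initial_alpha(space, pi)
    loglik = 0.0
    for y in range(entry, Y - 1):
        alpha = alpha @ tensor[y, int(y == entry), int(actions[y])]
        alpha = alpha * mask[int(inter_events[y + 1])]
        s = alpha.sum()
        if s <= 0.0:
            raise ImpossibleHistoryError(individual, y + 1)
        loglik += np.log(s)
        alpha = alpha / s
    return float(loglik)


def _forward_batch(space, inter, entry, actions, tensor, pi,
                   ids=None) -> np.ndarray:
    n, Y = inter.shape
    S = space.n_states
    mask = event_state_mask(space)
    alpha = np.zeros((n, S))
    loglik = np.zeros(n)
    init = initial_alpha(space, pi)
    alpha[entry == 0] = init
    for y in range(Y - 1):
        started = entry <= y
        if started.any():
            is_first = entry == y
            act = actions[:, y]
            for f in (0, 1):
                for a in ACTIONS:
                    g = started & (is_first == bool(f)) & (act == a)
                    if g.any():
                        alpha[g] = alpha[g] @ tensor[y, f, a]
        newly = entry == y + 1
        if newly.any():
            alpha[newly] = init
        live = entry <= y + 1
        if not live.any():
            continue
        sub = alpha[live] * mask[inter[live, y + 1]]
        s = sub.sum(axis=1)
        if np.any(s <= 0.0):
            i = int(np.where(live)[0][np.argmax(s <= 0.0)])
            raise ImpossibleHistoryError(
                ids[i] if ids is not None else i, y + 1)
        alpha[live] = sub / s[:, None]
        loglik[live] += np.log(s)
    return loglik


def dataset_loglik(data: EncounterDataset, params: ParameterSet,
                   per_individual: bool = False):
    """Log-likelihood of a dataset under real-scale parameters."""
    tensor = transition_tensor_from_params(data.space, params,
                                           data.covariates)
    ll = _forward_batch(data.space, data.inter, data.entry, data.actions(),
                        tensor, params.pi, data.ids)
    return ll if per_individual else float(ll.sum())


def loglik_from_design(data: EncounterDataset, design: Design,
                       theta, per_individual: bool = False):
    """Log-likelihood under a coefficient vector of a resolved design."""
    tensor = build_transition_tensor(design, theta)
    ll = _forward_batch(data.space, data.inter, data.entry, data.actions(),
                        tensor, design.initial_pi(theta), data.ids)
    return ll if per_individual else float(ll.sum())


def dataset_loglik_spec(data: EncounterDataset, spec: ModelSpec,
                        theta) -> float:
    """Convenience: resolve ``spec`` against the dataset and evaluate."""
    design = resolve_design(spec, data.space, data.covariates)
    return loglik_from_design(data, design, theta)
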