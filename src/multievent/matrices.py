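"""Transition and emission matrices of the multievent model.

The annual transition between consecutive inter (arrival) occasions
factorises into four row-stochastic steps, applied in this order:

1. survival — area-specific, reduced by the excess first-interval
   mortality ``delta`` over the interval following first encounter;
2. area change — per-destination probability ``c`` to each other area;
3. device update — a data-driven action (none / deploy / remove);
   deployment yields a functioning device with probability ``rho``;
4. detection/awareness — the bird arrives *aware* (captured) with
   probability ``p_aware`` or ``p_unaware`` according to its current
   awareness, which encodes trap-dependence.

Events are then a deterministic function of the state, so emission
matrices are 0/1 and all detection stochasticity lives inside the
transition.
"""

from __future__ import annotations

import numpy as np

from .params import CovariateSeries, ParameterSet
from .states import (EV_CAPTURED_NO_DEVICE, EV_NOT_CAPTURED, EV_REVEAL_BASE,
                     INTER, INTRA, IV_NOT_HANDLED,
                     IV_RELEASED_WITH_DEVICE, IV_RELEASED_WITHOUT_DEVICE,
                     EventAlphabet, InvalidConfigurationError, StateSpace)

ACTION_NONE, ACTION_DEPLOY, ACTION_REMOVE = 0, 1, 2
ACTIONS = (ACTION_NONE, ACTION_DEPLOY, ACTION_REMOVE)


class NumericalDomainError(ValueError):
    pass


class InfeasibleParameterError(ValueError):
    pass


def symmetric_change_matrix(c: float, n_areas: int) -> np.ndarray:
    """Area-change matrix with probability ``c`` to each other area."""
    if not 0.0 <= c <= 1.0:
        raise NumericalDomainError(f"change probability {c} outside [0, 1]")
    stay = 1.0 - (n_areas - 1) * c
    if stay < -1e-12:
        raise InfeasibleParameterError(
            f"(A-1)*c = {(n_areas - 1) * c:.4f} > 1: moves exceed unit mass")
    M = np.full((n_areas, n_areas), c)
    np.fill_diagonal(M, max(stay, 0.0))
    return M


def _area_block(space: StateSpace, change: np.ndarray) -> np.ndarray:
    return np.kron(change, np.eye(space.n_device * space.n_awareness))


def _device_block(space: StateSpace, action: int, rho: float) -> np.ndarray:
    D = space.n_device
    if not 0.0 <= rho <= 1.0:
        raise NumericalDomainError(f"rho={rho} outside [0, 1]")
    if action == ACTION_NONE:
        dm = np.eye(D)
    elif action == ACTION_DEPLOY:
        # any prior status -> freshly deployed device
        dm = np.zeros((D, D))
        dm[:, 1] = rho
        dm[:, 2] = 1.0 - rho
        if D < 3:  # degenerate space without a failure status
            dm = np.zeros((D, D))
            dm[:, min(1, D - 1)] = 1.0
    elif action == ACTION_REMOVE:
        dm = np.zeros((D, D))
        dm[:, 0] = 1.0
    else:
        raise InvalidConfigurationError(f"unknown device action {action}")
    return np.kron(np.eye(space.n_areas),
                   np.kron(dm, np.eye(space.n_awareness)))


def _awareness_block(space: StateSpace, p_aware: float,
                     p_unaware: float) -> np.ndarray:
    for name, p in (("p_aware", p_aware), ("p_unaware", p_unaware)):
        if not 0.0 <= p <= 1.0:
            raise NumericalDomainError(f"{name}={p} outside [0, 1]")
    if space.n_awareness == 1:
        return np.eye(space.n_areas * space.n_device)
    pm = np.array([[p_aware, 1.0 - p_aware],
                   [p_unaware, 1.0 - p_unaware]])
    return np.kron(np.eye(space.n_areas * space.n_device), pm)


def assemble_transition(space: StateSpace, survival: np.ndarray,
                        change: np.ndarray, action: int, rho: float,
                        p_aware: float, p_unaware: float) -> np.ndarray:
    """Full transition matrix from per-live-state survival and the blocks.

    ``survival`` has one entry per live state (already including any
    first-interval reduction).  The dead state is absorbing.
    """
    S = space.n_states
    L = S - 1
    if np.any(survival < 0) or np.any(survival > 1):
        raise NumericalDomainError("survival probabilities outside [0, 1]")
    M = (_area_block(space, change)
         @ _device_block(space, action, rho)
         @ _awareness_block(space, p_aware, p_unaware))
    T = np.zeros((S, S))
    T[:L, :L] = survival[:, None] * M
    T[:L, L] = 1.0 - survival
    T[L, L] = 1.0
    return T


def survival_vector(space: StateSpace, phi_area_device: np.ndarray,
                    delta: float = 0.0) -> np.ndarray:
    """Per-live-state survival from an (n_areas, n_device) table."""
    phi = np.asarray(phi_area_device, dtype=float)
    if phi.ndim == 1:
        phi = np.repeat(phi[:, None], space.n_device, axis=1)
    vec = np.repeat(phi.reshape(-1), space.n_awareness)
    return vec * (1.0 - delta)


def build_transition_matrix(space: StateSpace, params: ParameterSet,
                            year_index: int = 0,
                            covariates: CovariateSeries | None = None,
                            first_interval: bool = False,
                            action: int = ACTION_NONE) -> np.ndarray:
    """Annual inter-to-inter transition matrix from real parameters.

    ``year_index`` selects the interval; its covariates are those of the
    arrival year ``year_index + 1`` (z-scored over the series).  With no
    covariates the SOI/wNAO effects are evaluated at zero.
    """
    soi_z = wnao_z = 0.0
    if covariates is not None:
        if not 0 <= year_index < covariates.n_years - 1:
            raise KeyError(f"interval {year_index} outside covariate series")
        z = covariates.zscored()
        soi_z, wnao_z = z.soi[year_index + 1], z.wnao[year_index + 1]
    phi = np.array([params.phi(a, soi_z) for a in range(space.n_areas)])
    surv = survival_vector(space, phi,
                           params.delta if first_interval else 0.0)
    change = symmetric_change_matrix(params.change_prob(wnao_z),
                                     space.n_areas)
    return assemble_transition(space, surv, change, action, params.rho,
                               params.p_aware, params.p_unaware)


def build_emission_matrix(space: StateSpace,
                          occasion_kind: str = INTER) -> np.ndarray:
    """Deterministic state-to-event emission matrix (rows sum to 1).

    Inter occasions: aware birds are captured and the event reports
    their device (functioning devices reveal the state's area); unaware
    and dead birds yield "not captured".  Intra occasions report the
    release status of handled (aware) birds.
    """
    alphabet = EventAlphabet(space.n_areas)
    if occasion_kind == INTER:
        n_events = alphabet.n_inter_events
    elif occasion_kind == INTRA:
        n_events = alphabet.n_intra_events
    else:
        raise InvalidConfigurationError(
            f"unknown occasion kind {occasion_kind!r}")
    E = np.zeros((space.n_states, n_events))
    for s in range(space.n_states):
        tup = space.tuple_of(s)
        if occasion_kind == INTER:
            if tup is None or tup[2] != 0:      # dead or unaware
                E[s, EV_NOT_CAPTURED] = 1.0
            else:
                a, d, _ = tup
                if d == 1:
                    E[s, EV_REVEAL_BASE + a] = 1.0
                elif d == 2:
                    E[s, alphabet.failed_event] = 1.0
                else:
                    E[s, EV_CAPTURED_NO_DEVICE] = 1.0
        else:
            if tup is None or tup[2] != 0:
                E[s, IV_NOT_HANDLED] = 1.0
            elif tup[1] == 0:
                E[s, IV_RELEASED_WITHOUT_DEVICE] = 1.0
            else:
                E[s, IV_RELEASED_WITH_DEVICE] = 1.0
    return E


def event_state_mask(space: StateSpace) -> np.ndarray:
    """(n_inter_events, n_states) 0/1 compatibility mask, rows by event."""
    return build_emission_matrix(space, INTER).T.copy()


def build_transition_tensor(design, theta) -> np.ndarray:
    """All annual transitions for a coefficient vector.

    Returns an array of shape (n_intervals, 2, 3, S, S) indexed by
    (interval, first-interval flag, device action).  This is the shared
    machinery behind the vectorised likelihood: matrices are built once
    per evaluation and reused across individuals.
    """
    space = design.space
    S = space.n_states
    ni = design.n_intervals
    phi = design.survival_probs(theta)          # (ni, A, D)
    delta = design.delta(theta)
    change = design.change_matrices(theta)      # (ni, A, A)
    p = design.recapture_probs(theta)           # (ni, 2)
    out = np.empty((ni, 2, len(ACTIONS), S, S))
    for i in range(ni):
        blocks = [
            _area_block(space, change[i])
            @ _device_block(space, act, design.spec.rho)
            @ _awareness_block(space, p[i, 0], p[i, 1])
            for act in ACTIONS
        ]
        for f, d in ((0, 0.0), (1, delta)):
            surv = survival_vector(space, phi[i], d)
            for a, M in zip(ACTIONS, blocks):
                T = out[i, f, a]
                T[:] = 0.0
                T[:S - 1, :S - 1] = surv[:, None] * M
                T[:S - 1, S - 1] = 1.0 - surv
                T[S - 1, S - 1] = 1.0
    return out
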