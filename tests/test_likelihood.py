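"""Forward likelihood: closed forms, enumeration oracle, invariances."""

import numpy as np
import pytest

import multievent as me
from multievent.likelihood import (ImpossibleHistoryError, _forward_batch,
                                   initial_alpha,
                                   transition_tensor_from_params)
from multievent.params import CovariateSeries, ParameterSet

from conftest import random_params


def _tensor(space, params, n_years, seed=0):
    rng = np.random.default_rng(seed)
    cov = CovariateSeries(np.arange(2000, 2000 + n_years),
                          rng.standard_normal(n_years),
                          rng.standard_normal(n_years))
    return me.transition_tensor_from_params(space, params, cov), cov


def brute_force_loglik(space, events, entry, actions, tensor, pi):
    """Independent oracle: exhaustive sum over all state paths."""
    mask = me.event_state_mask(space)
    Y = len(events)
    S = space.n_states
    alpha = initial_alpha(space, pi)
    total = 0.0
    # enumerate full state paths from entry+1 .. Y-1
    steps = Y - 1 - entry
    for path in np.ndindex(*([S] * steps)):
        prob = 0.0
        for s0 in range(S):
            p = alpha[s0]
            prev = s0
            for k, s in enumerate(path):
                y = entry + k
                p *= (tensor[y, int(y == entry), int(actions[y])][prev, s]
                      * mask[int(events[y + 1]), s])
                prev = s
            prob += p
        total += prob
    return np.log(total)


def test_capture_at_last_occasion_contributes_zero(space):
    params = random_params(np.random.default_rng(1))
    tensor, _ = _tensor(space, params, 4)
    events = np.array([0, 0, 0, 1])
    ll = me.history_loglik(space, events, 3, np.zeros(3, dtype=int), tensor,
                           params.pi)
    assert ll == 0.0


def test_two_occasion_closed_form(space):
    """captured, then captured without device: likelihood = phi * p."""
    params = ParameterSet.from_probs(phi=[0.5] * 4, c=0.0, delta=0.0,
                                     p_aware=0.5, p_unaware=0.1)
    tensor, _ = _tensor(space, params, 2)
    ll = me.history_loglik(space, np.array([1, 1]), 0,
                           np.zeros(1, dtype=int), tensor, params.pi)
    assert ll == pytest.approx(np.log(0.25), abs=1e-12)


def test_not_seen_then_seen_closed_form(space):
    """captured, missed, captured: phi*(1-p_aw) * phi*p_un with c=0."""
    params = ParameterSet.from_probs(phi=[0.8] * 4, c=0.0, delta=0.0,
                                     p_aware=0.6, p_unaware=0.3)
    tensor, _ = _tensor(space, params, 3)
    ll = me.history_loglik(space, np.array([1, 0, 1]), 0,
                           np.zeros(2, dtype=int), tensor, params.pi)
    assert ll == pytest.approx(np.log(0.8 * 0.4 * 0.8 * 0.3), abs=1e-12)


@pytest.mark.parametrize("seed", range(6))
def test_matches_exhaustive_enumeration(space, seed):
    """Forward pass equals the 25^2-path sum on 3-occasion instances."""
    rng = np.random.default_rng(seed)
    params = random_params(rng)
    tensor, _ = _tensor(space, params, 3, seed)
    entry = int(rng.integers(0, 2))
    events = np.zeros(3, dtype=int)
    events[entry] = 1
    # capture-without-device events constrain actions to non-deploy
    actions = rng.choice([0, 2], size=2)
    for y in range(entry + 1, 3):
        events[y] = rng.choice([0, 1])
    ll = me.history_loglik(space, events, entry, actions, tensor, params.pi)
    oracle = brute_force_loglik(space, events, entry, actions, tensor,
                                params.pi)
    assert ll == pytest.approx(oracle, abs=1e-10)


def test_reveal_history_matches_enumeration(space):
    """A deploy-then-reveal history agrees with the path enumeration."""
    rng = np.random.default_rng(5)
    params = random_params(rng)
    tensor, _ = _tensor(space, params, 3, 5)
    events = np.array([1, 3, 0])               # reveal of area 2 in year 2
    actions = np.array([1, 2])                 # deploy, then remove
    ll = me.history_loglik(space, events, 0, actions, tensor, params.pi)
    oracle = brute_force_loglik(space, events, 0, actions, tensor,
                                params.pi)
    assert ll == pytest.approx(oracle, abs=1e-10)


def test_impossible_history_raises(space):
    """A reveal without a deployment has zero probability."""
    params = random_params(np.random.default_rng(2))
    tensor, _ = _tensor(space, params, 3)
    with pytest.raises(ImpossibleHistoryError) as err:
        me.history_loglik(space, np.array([1, 2, 0]), 0,
                          np.zeros(2, dtype=int), tensor, params.pi,
                          individual="B1")
    assert err.value.occasion == 1


def test_dataset_loglik_additive_and_permutation_invariant(small_dataset):
    data, _, _ = small_dataset
    params = me.default_paper_config().params
    total = me.dataset_loglik(data, params)
    per_ind = me.dataset_loglik(data, params, per_individual=True)
    assert total == pytest.approx(per_ind.sum(), abs=1e-9)
    rng = np.random.default_rng(3)
    perm = rng.permutation(data.n_individuals)
    assert me.dataset_loglik(data.subset(perm), params) == pytest.approx(
        total, abs=1e-9)


def test_vectorised_matches_reference_loop(small_dataset):
    """The batched forward pass equals the per-individual reference."""
    data, _, _ = small_dataset
    params = me.default_paper_config().params
    tensor = transition_tensor_from_params(data.space, params,
                                           data.covariates)
    per_ind = me.dataset_loglik(data, params, per_individual=True)
    actions = data.actions()
    for i in range(0, data.n_individuals, 17):
        ref = me.history_loglik(data.space, data.inter[i],
                                int(data.entry[i]), actions[i], tensor,
                                params.pi, data.ids[i])
        assert per_ind[i] == pytest.approx(ref, abs=1e-9)


def test_trap_marginalisation_invariance():
    """With p_aware = p_unaware, equal survivals and no devices, the
    25-state likelihood collapses to the closed-form single-state CJS
    likelihood of the detection histories."""
    from dataclasses import replace

    from multievent.simulate import DeploymentSchedule

    cfg = me.default_paper_config(n_individuals=150, seed=9)
    cfg = replace(cfg,
                  params=replace(cfg.params, p_aware=0.45, p_unaware=0.45),
                  deployment=DeploymentSchedule(prob=0.0))
    data, _, _ = me.simulate_dataset(cfg)
    ll = me.dataset_loglik(data, cfg.params)

    phi0 = float(1 / (1 + np.exp(-cfg.params.phi_logit[0])))
    delta, p = cfg.params.delta, 0.45
    h = data.detection_matrix()
    Y = h.shape[1]
    ll_cjs = 0.0
    for row in h:
        occs = np.flatnonzero(row)
        f, last = occs[0], occs[-1]
        for y in range(f, last):
            s = phi0 * (1 - delta) if y == f else phi0
            ll_cjs += np.log(s * (p if row[y + 1] else 1 - p))
        chi = 1.0                          # P(never seen after `last`)
        for t in range(Y - 2, last - 1, -1):
            s = phi0 * (1 - delta) if t == f else phi0
            chi = 1 - s + s * (1 - p) * chi
        ll_cjs += np.log(chi)
    assert ll == pytest.approx(ll_cjs, abs=1e-8)


def test_empty_dataset_loglik_is_zero(space):
    cov = CovariateSeries(np.arange(2000, 2003), np.zeros(3), np.zeros(3))
    data = me.EncounterDataset([], np.zeros((0, 3)), np.zeros((0, 3)),
                               np.zeros(0, dtype=int), cov, space)
    assert me.dataset_loglik(data, me.default_paper_config().params) == 0.0
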