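"""Synthetic-data generator: study-design defaults, empirical rates,
truth consistency, determinism."""

from dataclasses import replace

import numpy as np
import pytest

import multievent as me
from multievent.states import EV_REVEAL_BASE


def test_covariates_reproducible_and_sized():
    a = me.simulate_covariates(23, seed=5)
    b = me.simulate_covariates(23, seed=5)
    assert a.n_years == 23
    np.testing.assert_array_equal(a.soi, b.soi)
    assert not np.array_equal(a.soi, me.simulate_covariates(23, seed=6).soi)


def test_covariates_standard_normal_mean():
    pooled = np.concatenate([me.simulate_covariates(23, seed=s).soi
                             for s in range(100)])
    assert abs(pooled.mean()) < 3 / np.sqrt(len(pooled))


def test_default_config_reflects_study_design():
    cfg = me.default_paper_config()
    assert cfg.n_individuals == 1104
    assert cfg.n_years == 23
    assert cfg.params.pi.sum() == pytest.approx(1.0)
    assert cfg.params.pi[0] == pytest.approx(0.28)
    assert cfg.params.phi(0) == pytest.approx(0.841)
    assert cfg.params.delta == pytest.approx(0.088)
    assert cfg.params.change_prob() == pytest.approx(0.07)
    assert cfg.params.rho == pytest.approx(147 / 182)
    assert cfg.schedule().sum() == 1104
    area = me.default_paper_config(survival="area").params
    assert [round(area.phi(a), 3) for a in range(4)] == \
        [0.961, 0.428, 0.821, 0.903]


def test_deterministic_under_seed():
    cfg = me.default_paper_config(n_individuals=120, seed=8)
    d1, t1, a1 = me.simulate_dataset(cfg)
    d2, t2, a2 = me.simulate_dataset(cfg)
    np.testing.assert_array_equal(d1.inter, d2.inter)
    np.testing.assert_array_equal(d1.intra, d2.intra)
    np.testing.assert_array_equal(t1.area, t2.area)
    assert a1.records.equals(a2.records)


def test_perfect_detection_degenerate_case():
    params = me.ParameterSet.from_probs(phi=[1.0] * 4, c=0.0, delta=0.0,
                                        p_aware=1.0, p_unaware=1.0,
                                        pi=[0.25] * 4, rho=1.0)
    cfg = me.SimulationConfig(n_individuals=40, n_years=6, params=params,
                              seed=3,
                              deployment=me.DeploymentSchedule(prob=0.0))
    data, truth, _ = me.simulate_dataset(cfg)
    years = np.arange(6)[None, :]
    after_entry = years >= data.entry[:, None]
    assert np.array_equal(data.inter > 0, after_entry)
    # no area changes ever
    for i in range(40):
        areas = truth.area[i, data.entry[i]:]
        assert len(set(areas.tolist())) == 1


def test_empirical_annual_survival():
    """Large-n survival frequency matches phi = 0.841 (delta = 0)."""
    cfg = me.default_paper_config(n_individuals=4000, seed=12)
    cfg = replace(cfg, params=replace(cfg.params, delta=0.0))
    _, truth, _ = me.simulate_dataset(cfg)
    alive = truth.alive
    at_risk = alive[:, :-1].sum()
    survived = (alive[:, :-1] & alive[:, 1:]).sum()
    rate = survived / at_risk
    se = np.sqrt(0.841 * 0.159 / at_risk)
    assert abs(rate - 0.841) < 3 * se


def test_empirical_stay_fraction():
    """c = 0.07 gives ~79% same-area winters in consecutive years."""
    cfg = me.default_paper_config(n_individuals=4000, seed=13)
    _, truth, _ = me.simulate_dataset(cfg)
    both = truth.alive[:, :-1] & truth.alive[:, 1:]
    same = (truth.area[:, :-1] == truth.area[:, 1:]) & both
    frac = same.sum() / both.sum()
    se = np.sqrt(0.79 * 0.21 / both.sum())
    assert abs(frac - 0.79) < 4 * se


def test_empirical_first_interval_excess_mortality():
    cfg = me.default_paper_config(n_individuals=6000, seed=14)
    data, truth, _ = me.simulate_dataset(cfg)
    first_alive = truth.alive[np.arange(6000), data.entry]
    entered_before_last = data.entry < 22
    nxt = np.minimum(data.entry + 1, 22)
    survived_first = truth.alive[np.arange(6000), nxt] & entered_before_last
    rate = survived_first.sum() / entered_before_last.sum()
    expected = 0.841 * (1 - 0.088)
    se = np.sqrt(expected * (1 - expected) / entered_before_last.sum())
    assert abs(rate - expected) < 3.5 * se


def test_deployment_and_recovery_counts_at_study_scale():
    """Expected deployments ~258 and informative recoveries ~147."""
    deps, infs = [], []
    for seed in range(5):
        cfg = me.default_paper_config(n_individuals=1104, seed=40 + seed)
        data, _, _ = me.simulate_dataset(cfg)
        deps.append((data.intra == 2).sum())
        infs.append(((data.inter >= 2) & (data.inter <= 5)).sum())
    assert abs(np.mean(deps) - 258) < 40
    assert abs(np.mean(infs) - 147) < 35


def test_reveal_events_match_truth():
    """Every reveal event in the histories names the true area, and every
    assignment-table record matches the truth log."""
    cfg = me.default_paper_config(n_individuals=500, seed=21)
    data, truth, table = me.simulate_dataset(cfg)
    idx = {ind: k for k, ind in enumerate(data.ids)}
    rev = np.argwhere((data.inter >= 2) & (data.inter <= 5))
    assert len(rev) > 0
    for i, y in rev:
        assert data.inter[i, y] - EV_REVEAL_BASE == truth.area[i, y]
    y0 = int(data.covariates.year[0])
    for _, r in table.records.iterrows():
        assert truth.area[idx[r["individual"]], int(r["year"]) - y0] == \
            list(data.space.areas).index(r["area"])


def test_archived_winters_cover_multi_year_carriage():
    """Assignment records may cover winters with no capture (archival
    reveal at recovery), and always fall between deployment and
    recovery."""
    cfg = me.default_paper_config(n_individuals=1500, seed=22)
    data, truth, table = me.simulate_dataset(cfg)
    idx = {ind: k for k, ind in enumerate(data.ids)}
    y0 = int(data.covariates.year[0])
    uncaptured = sum(
        not truth.captured[idx[r["individual"]], int(r["year"]) - y0]
        for _, r in table.records.iterrows())
    assert uncaptured > 0
    assert len(table.records) > ((data.inter >= 2)
                                 & (data.inter <= 5)).sum() * 0.9


def test_infeasible_config_rejected():
    with pytest.raises(ValueError):
        me.ParameterSet.from_probs(phi=[0.8] * 4, c=0.4)
    cfg = me.default_paper_config(n_individuals=10, seed=0)
    with pytest.raises(ValueError):
        replace(cfg, recruits_per_year=(5,) * 23).schedule()


def test_truth_no_events_after_death():
    cfg = me.default_paper_config(n_individuals=400, seed=33)
    data, truth, _ = me.simulate_dataset(cfg)
    dead = ~truth.alive
    assert not (data.inter[dead] > 0).any()
    assert not truth.captured[dead].any()
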