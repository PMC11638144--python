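"""Fidelity summaries, Krippendorff's alpha and its bootstrap CI."""

import itertools

import numpy as np
import pytest

import multievent as me
from multievent.fidelity import EXCLUDED, UndefinedAlphaError


def make_table(seqs, start_year=2009):
    rows = []
    for ind, areas in seqs.items():
        for k, a in enumerate(areas):
            rows.append((ind, start_year + k, a))
    return me.AssignmentTable.from_records(rows)


def pairwise_alpha_oracle(seqs):
    """Independent oracle: alpha from explicit within-unit pair counts.

    D_o = sum over ordered within-unit pairs, weighted 1/(m_u - 1); D_e
    from all ordered pairs of the pooled margin totals.
    """
    units = [v for v in seqs if len(v) >= 2]
    num = den_margin = 0.0
    margins: dict[str, float] = {}
    for v in units:
        m = len(v)
        for i, j in itertools.permutations(range(m), 2):
            num += (v[i] != v[j]) / (m - 1)
        for a in v:
            margins[a] = margins.get(a, 0.0) + 1.0
    n = sum(margins.values())
    exp = sum(margins[a] * margins[b]
              for a in margins for b in margins if a != b) / (n - 1)
    if exp == 0:
        return 1.0
    return 1.0 - num / exp


def test_paper_scale_track_accounting():
    """The printed cycle histogram (34/15/11/4/7) totals 148 tracks from
    71 individuals, 37 of them multi-tracked."""
    hist = {1: 34, 2: 15, 3: 11, 4: 4, 5: 7}
    seqs = {}
    k = 0
    for cycles, count in hist.items():
        for _ in range(count):
            seqs[f"I{k}"] = ["Canary"] * cycles
            k += 1
    summary = me.fidelity_summary(make_table(seqs))
    assert summary["n_tracks"] == 148
    assert summary["n_individuals"] == 71
    assert summary["n_multi"] == 37
    assert summary["cycles_histogram"] == hist


def test_area_shares_on_printed_counts():
    """Counts 64/11/32/40 of 147 give shares 43.5/7.5/21.8/27.2%."""
    counts = {"Canary": 64, "Equatorial": 11, "Guinea": 32, "Angola": 40}
    seqs = {}
    k = 0
    for area, c in counts.items():
        for _ in range(c):
            seqs[f"I{k}"] = [area]
            k += 1
    seqs["IX"] = [EXCLUDED]  # the out-of-scheme track
    summary = me.fidelity_summary(make_table(seqs))
    assert summary["n_tracks"] == 148
    assert summary["n_excluded"] == 1
    shares = {a: round(p, 1) for a, p in summary["area_percents"].items()}
    assert shares == {"Canary": 43.5, "Equatorial": 7.5, "Guinea": 21.8,
                      "Angola": 27.2}


def test_consistency_counts():
    seqs = {"A": ["Canary", "Canary"], "B": ["Canary", "Guinea"],
            "C": ["Angola"] * 3, "D": ["Guinea"]}
    s = me.fidelity_summary(make_table(seqs))
    assert (s["n_multi"], s["n_consistent"], s["n_changed"]) == (3, 2, 1)
    assert s["percent_consistent"] == pytest.approx(200 / 3)


def test_single_track_individual_consistency_absent():
    s = me.fidelity_summary(make_table({"A": ["Canary"]}))
    assert s["n_multi"] == 0
    assert "percent_consistent" not in s


def test_duplicate_individual_year_rejected():
    with pytest.raises(ValueError, match="duplicate"):
        me.AssignmentTable.from_records(
            [("A", 2009, "Canary"), ("A", 2009, "Guinea")])


def test_alpha_perfect_consistency_is_one():
    seqs = {"A": ["Canary"] * 3, "B": ["Guinea"] * 2, "C": ["Angola"] * 4}
    assert me.krippendorff_alpha(make_table(seqs)) == pytest.approx(1.0)


def test_alpha_matches_pairwise_oracle_on_micro_example():
    """Two consistent and two discordant pairs over two areas with equal
    margins: alpha equals the hand-computable pair-counting value."""
    seqs = {"A": ["Canary", "Canary"], "B": ["Guinea", "Guinea"],
            "C": ["Canary", "Guinea"], "D": ["Guinea", "Canary"]}
    alpha = me.krippendorff_alpha(make_table(seqs))
    oracle = pairwise_alpha_oracle(list(seqs.values()))
    assert alpha == pytest.approx(oracle, abs=1e-12)
    # by hand: o_cc = o_gg = o_cg = o_gc = 2, margins n_c = n_g = 4, n = 8
    # D_o = 4, D_e = 2 * 4 * 4 / 7, alpha = 1 - 4 / (32 / 7) = 1/8
    assert alpha == pytest.approx(0.125, abs=1e-12)


@pytest.mark.parametrize("seed", range(3))
def test_alpha_matches_oracle_on_random_tables(seed):
    rng = np.random.default_rng(seed)
    areas = ["Canary", "Equatorial", "Guinea", "Angola"]
    seqs = {f"I{i}": [areas[k] for k in
                      rng.integers(0, 4, size=rng.integers(1, 6))]
            for i in range(25)}
    alpha = me.krippendorff_alpha(make_table(seqs))
    oracle = pairwise_alpha_oracle(list(seqs.values()))
    assert alpha == pytest.approx(oracle, abs=1e-12)


def test_alpha_relabelling_invariance():
    seqs = {"A": ["Canary", "Canary", "Guinea"], "B": ["Angola", "Angola"],
            "C": ["Guinea", "Canary"]}
    relabel = {"Canary": "x", "Guinea": "y", "Angola": "z"}
    seqs2 = {k: [relabel[a] for a in v] for k, v in seqs.items()}
    assert me.krippendorff_alpha(make_table(seqs)) == pytest.approx(
        me.krippendorff_alpha(make_table(seqs2)), abs=1e-12)


def test_alpha_shuffled_assignments_near_zero():
    """Assignments shuffled across individuals: mean alpha ~ 0."""
    rng = np.random.default_rng(11)
    areas = ["Canary", "Equatorial", "Guinea", "Angola"]
    values = []
    for _ in range(100):
        labels = rng.choice(areas, size=200,
                            p=[0.435, 0.075, 0.218, 0.272])
        seqs = {f"I{i}": list(labels[2 * i:2 * i + 2]) for i in range(100)}
        values.append(me.krippendorff_alpha(make_table(seqs)))
    assert abs(np.mean(values)) < 0.05


def test_alpha_undefined_without_pairable_values():
    with pytest.raises(UndefinedAlphaError):
        me.krippendorff_alpha(make_table({"A": ["Canary"], "B": ["Guinea"]}))


def test_bootstrap_ci_perfect_table_degenerate():
    seqs = {"A": ["Canary"] * 2, "B": ["Guinea"] * 3}
    lo, hi = me.alpha_bootstrap_ci(make_table(seqs), n_boot=200, seed=1)
    assert (lo, hi) == (1.0, 1.0)


def test_bootstrap_ci_deterministic_under_seed():
    rng = np.random.default_rng(4)
    areas = ["Canary", "Guinea"]
    seqs = {f"I{i}": [areas[k] for k in rng.integers(0, 2, size=3)]
            for i in range(20)}
    t = make_table(seqs)
    assert me.alpha_bootstrap_ci(t, 300, seed=5) == \
        me.alpha_bootstrap_ci(t, 300, seed=5)


def test_bootstrap_ci_covers_population_alpha():
    """Markov-chain area sequences with stay probability 0.79: the CI
    covers the large-sample alpha in most replicates."""
    areas = np.arange(4)

    def markov_seqs(rng, n_ind, length):
        seqs = {}
        for i in range(n_ind):
            a = rng.choice(areas, p=[0.28, 0.24, 0.24, 0.24])
            v = [int(a)]
            for _ in range(length - 1):
                if rng.random() > 0.79:
                    a = rng.choice([x for x in areas if x != a])
                v.append(int(a))
            seqs[f"I{i}"] = [f"area{x}" for x in v]
        return seqs

    rng = np.random.default_rng(2024)
    mega = markov_seqs(rng, 4000, 3)
    alpha_pop = me.krippendorff_alpha(make_table(mega))
    covered = 0
    n_rep = 30
    for _ in range(n_rep):
        t = make_table(markov_seqs(rng, 60, 3))
        lo, hi = me.alpha_bootstrap_ci(t, n_boot=300,
                                       seed=int(rng.integers(2 ** 31)))
        covered += lo <= alpha_pop <= hi
    assert covered >= 0.9 * n_rep - 2   # >= 25 of 30


def test_stay_probability_values():
    assert me.stay_probability(0.07, 4) == pytest.approx(0.79)
    assert me.stay_probability(0.0, 7) == 1.0
    assert me.stay_probability(1 / 3, 4) == pytest.approx(0.0)
    with pytest.raises(ValueError):
        me.stay_probability(0.5, 4)


def test_duplicated_individual_weighting_against_oracle():
    """Duplicating one individual n times changes alpha exactly as the
    pair-counting oracle predicts."""
    base = {"A": ["Canary", "Guinea"], "B": ["Canary", "Canary"]}
    dup = dict(base, **{f"A{k}": base["A"] for k in range(3)})
    assert me.krippendorff_alpha(make_table(dup)) == pytest.approx(
        pairwise_alpha_oracle(list(dup.values())), abs=1e-12)
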