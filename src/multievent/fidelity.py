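"""Wintering-site fidelity and repeatability of area assignments.

Inputs are nominal per-individual, per-winter area labels (from
recovered geolocators).  Fidelity summaries are direct counts; the
repeatability coefficient is Krippendorff's alpha with individuals as
units, that individual's winter areas across years as the repeated
observations, and the nominal difference function.  An "excluded" label
marks tracks outside the four-area scheme: they count as tracks (and as
a change of area for consistency purposes) but are dropped from area
shares and from alpha.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

EXCLUDED = "excluded"


class UndefinedAlphaError(ValueError):
    pass


@dataclass
class AssignmentTable:
    """Individual x winter-year nominal wintering-area labels."""

    records: pd.DataFrame  # columns: individual, year, area

    def __post_init__(self):
        df = self.records
        missing = {"individual", "year", "area"} - set(df.columns)
        if missing:
            raise ValueError(f"assignment table missing columns {missing}")
        dup = df.duplicated(subset=["individual", "year"], keep=False)
        if dup.any():
            offenders = df.loc[dup, ["individual", "year"]]
            raise ValueError("duplicate individual-year assignments:\n"
                             + offenders.to_string(index=False))

    @property
    def n_records(self) -> int:
        return len(self.records)

    def sequences(self, drop_excluded: bool = True) -> dict[str, list[str]]:
        """Per-individual area sequences ordered by winter year."""
        df = self.records.sort_values(["individual", "year"])
        if drop_excluded:
            df = df[df["area"] != EXCLUDED]
        return {ind: list(g["area"]) for ind, g in df.groupby("individual")}

    @classmethod
    def from_records(cls, rows) -> "AssignmentTable":
        return cls(pd.DataFrame(rows,
                                columns=["individual", "year", "area"]))


def fidelity_summary(table: AssignmentTable) -> dict:
    """Track totals, cycle histogram, consistency and per-area shares.

    Area shares use the non-excluded track count as denominator;
    consistency is assessed among individuals with more than one track,
    treating an excluded track as a distinct (changed) destination.
    """
    df = table.records
    if df.empty:
        raise ValueError("empty assignment table")
    n_tracks = len(df)
    per_ind = df.groupby("individual").size()
    cycles = per_ind.value_counts().sort_index().to_dict()
    multi = per_ind[per_ind >= 2].index
    n_multi = len(multi)
    seq_all = {ind: list(g["area"])
               for ind, g in df.groupby("individual") if len(g) >= 2}
    n_consistent = sum(len(set(v)) == 1 for v in seq_all.values())
    n_changed = n_multi - n_consistent
    valid = df[df["area"] != EXCLUDED]
    area_counts = valid["area"].value_counts().to_dict()
    denom = len(valid)
    area_percents = {a: 100.0 * c / denom for a, c in area_counts.items()}
    out = {
        "n_tracks": n_tracks,
        "n_excluded": n_tracks - denom,
        "n_individuals": int(per_ind.size),
        "cycles_histogram": {int(k): int(v) for k, v in cycles.items()},
        "n_multi": int(n_multi),
        "n_consistent": int(n_consistent),
        "n_changed": int(n_changed),
        "area_counts": area_counts,
        "area_percents": area_percents,
    }
    if n_multi > 0:
        out["percent_consistent"] = 100.0 * n_consistent / n_multi
        out["percent_changed"] = 100.0 * n_changed / n_multi
    return out


def _alpha_from_sequences(sequences) -> float:
    units = [v for v in sequences if len(v) >= 2]
    if not units:
        raise UndefinedAlphaError("no individual has two pairable "
                                  "assignments")
    labels = sorted({a for v in units for a in v})
    k = len(labels)
    idx = {a: i for i, a in enumerate(labels)}
    o = np.zeros((k, k))
    for v in units:
        m = len(v)
        counts = np.zeros(k)
        for a in v:
            counts[idx[a]] += 1
        pair = np.outer(counts, counts) - np.diag(counts)
        o += pair / (m - 1)
    n_c = o.sum(axis=1)
    n = n_c.sum()
    d_o = o.sum() - np.trace(o)
    d_e = (np.outer(n_c, n_c).sum() - (n_c ** 2).sum()) / (n - 1)
    if d_e <= 0:
        # all observations share one label: perfect agreement by fiat
        return 1.0
    return float(1.0 - d_o / d_e)


def krippendorff_alpha(table: AssignmentTable) -> float:
    """Krippendorff's alpha (nominal) for within-individual repeatability.

    alpha = 1 - D_o / D_e, with observed and expected disagreement taken
    from the coincidence matrix over pairable values within individuals.
    1 means perfect fidelity; 0 means area choice is exchangeable across
    individuals; negative values mean systematic switching.
    """
    return _alpha_from_sequences(table.sequences().values())


def alpha_bootstrap_ci(table: AssignmentTable, n_boot: int = 10_000,
                       seed: int = 0) -> tuple[float, float]:
    """Percentile 95% CI, resampling individuals with replacement."""
    import warnings
    if n_boot < 100:
        warnings.warn(f"n_boot={n_boot} is small for a percentile interval",
                      stacklevel=2)
    seqs = list(table.sequences().values())
    rng = np.random.default_rng(seed)
    stats = []
    for _ in range(n_boot):
        take = rng.integers(0, len(seqs), size=len(seqs))
        try:
            stats.append(_alpha_from_sequences([seqs[i] for i in take]))
        except UndefinedAlphaError:
            continue
    if not stats:
        raise UndefinedAlphaError("alpha undefined in every resample")
    lo, hi = np.percentile(stats, [2.5, 97.5])
    return float(lo), float(hi)


def stay_probability(change_per_destination: float, n_areas: int) -> float:
    """1 - (A-1)c: chance of wintering in the same area as last year."""
    c = change_per_destination
    if c < 0 or (n_areas - 1) * c > 1 + 1e-12:
        raise ValueError(f"infeasible change probability {c} for "
                         f"{n_areas} areas")
    return 1.0 - (n_areas - 1) * c
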