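"""Plain-text file formats.

Encounter histories serialise one individual per line: an id followed
by one token per study year.  The first character is the inter-occasion
event (0 not captured, 1 captured without device, 2..1+A captured with
a functioning device revealing area 1..A, 2+A captured with a failed
device); the second character records the departure (0 released without
device, 1 released with device).  The last study year has no intra
occasion, so its token is the single inter character; a bare "0" is
accepted anywhere for a not-captured year.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .dataset import EncounterDataset, HistoryValidationError
from .fidelity import AssignmentTable
from .params import CovariateSeries
from .states import (EV_NOT_CAPTURED, IV_NOT_HANDLED,
                     IV_RELEASED_WITH_DEVICE, IV_RELEASED_WITHOUT_DEVICE,
                     StateSpace, build_state_space)


class EncounterParseError(ValueError):
    pass


def write_encounter_file(data: EncounterDataset, path) -> None:
    lines = ["# multievent encounter histories",
             f"# years: {int(data.covariates.year[0])}-"
             f"{int(data.covariates.year[-1])}",
             f"# areas: {','.join(data.space.areas)}"]
    Y = data.n_years
    for i, ind in enumerate(data.ids):
        toks = []
        for y in range(Y):
            ev = int(data.inter[i, y])
            if y == Y - 1:
                toks.append(str(ev))
            elif ev == EV_NOT_CAPTURED:
                toks.append("00")
            else:
                dep = data.intra[i, y] == IV_RELEASED_WITH_DEVICE
                toks.append(f"{ev}{int(dep)}")
        lines.append(ind + " " + " ".join(toks))
    Path(path).write_text("\n".join(lines) + "\n")


def read_encounter_file(path, covariates: CovariateSeries | None = None
                        ) -> EncounterDataset:
    """Parse an encounter-history file.

    Without an explicit covariate series, a zero (climate-neutral)
    series over the header's study years is attached.
    """
    text = Path(path).read_text().splitlines()
    first_year, areas = 2000, None
    records = []
    for ln, raw in enumerate(text, start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line.lstrip("# ").strip()
            if body.startswith("years:"):
                a, b = body.removeprefix("years:").strip().split("-")
                first_year = int(a)
            elif body.startswith("areas:"):
                areas = tuple(s.strip() for s in
                              body.removeprefix("areas:").split(","))
            continue
        parts = line.split()
        records.append((ln, parts[0], parts[1:]))
    space = build_state_space(n_areas=len(areas) if areas else 4,
                             areas=areas)
    if not records:
        warnings.warn(f"{path}: no encounter histories found", stacklevel=2)
        Y = 1
        cov = covariates or CovariateSeries(np.array([first_year]),
                                            np.zeros(1), np.zeros(1))
        return EncounterDataset([], np.zeros((0, cov.n_years)),
                                np.zeros((0, cov.n_years)),
                                np.zeros(0, dtype=int), cov, space)
    Y = len(records[0][2])
    max_ev = 2 + space.n_areas
    ids, inter, intra, entry = [], [], [], []
    for ln, ind, toks in records:
        if len(toks) != Y:
            raise EncounterParseError(f"line {ln}: expected {Y} year "
                                      f"tokens, got {len(toks)}")
        ev_row = np.zeros(Y, dtype=np.int64)
        iv_row = np.zeros(Y, dtype=np.int64)
        for y, tok in enumerate(toks):
            if not tok.isdigit() or len(tok) > 2:
                raise EncounterParseError(f"line {ln}: bad token {tok!r}")
            ev = int(tok[0])
            if ev > max_ev:
                raise EncounterParseError(
                    f"line {ln}: inter event {ev} out of range")
            ev_row[y] = ev
            if y < Y - 1 and ev != EV_NOT_CAPTURED:
                if len(tok) != 2 or tok[1] not in "01":
                    raise EncounterParseError(
                        f"line {ln}: capture token {tok!r} needs a "
                        f"release character")
                iv_row[y] = (IV_RELEASED_WITH_DEVICE if tok[1] == "1"
                             else IV_RELEASED_WITHOUT_DEVICE)
        captures = np.flatnonzero(ev_row)
        if captures.size == 0:
            raise EncounterParseError(f"line {ln}: {ind} never captured")
        ids.append(ind)
        inter.append(ev_row)
        intra.append(iv_row)
        entry.append(int(captures[0]))
    cov = covariates or CovariateSeries(
        np.arange(first_year, first_year + Y), np.zeros(Y), np.zeros(Y))
    try:
        return EncounterDataset(ids, np.array(inter), np.array(intra),
                                np.array(entry, dtype=np.int64), cov, space)
    except HistoryValidationError as exc:
        raise EncounterParseError(str(exc)) from exc


def write_covariates(cov: CovariateSeries, path) -> None:
    cov.to_frame().to_csv(path, sep="\t", index=False)


def read_covariates(path) -> CovariateSeries:
    df = pd.read_csv(path, sep="\t")
    if df[["soi", "wnao"]].isna().any().any():
        raise ValueError(f"{path}: missing covariate values")
    return CovariateSeries.from_frame(df)


def write_assignments(table: AssignmentTable, path) -> None:
    table.records.to_csv(path, sep="\t", index=False)


def read_assignments(path) -> AssignmentTable:
    return AssignmentTable(pd.read_csv(path, sep="\t",
                                       dtype={"individual": str}))


def write_data_dictionary(space: StateSpace, path) -> None:
    """Audit export of the state and event enumerations."""
    from .states import EventAlphabet
    lines = ["# states (label index tuple)"]
    for label, idx, tup in space.data_dictionary():
        lines.append(f"{label}\t{idx}\t{tup}")
    alph = EventAlphabet(space.n_areas)
    lines.append("# inter events")
    lines += [f"{l}\t{i}" for i, l in enumerate(alph.inter_labels())]
    lines.append("# intra events")
    lines += [f"{l}\t{i}" for i, l in enumerate(alph.intra_labels())]
    Path(path).write_text("\n".join(lines) + "\n")
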