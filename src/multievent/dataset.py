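"""Encounter-history dataset container.

Histories are stored as dense per-year integer arrays: one inter
(arrival) event code per study year and one intra (departure) event code
per year except the last.  Device handling is data-driven: the intra
events determine, for each annual interval, whether a geolocator was
deployed, removed, or left as is.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .matrices import ACTION_DEPLOY, ACTION_NONE, ACTION_REMOVE
from .params import CovariateSeries
from .states import (EV_NOT_CAPTURED, IV_RELEASED_WITH_DEVICE,
                     IV_RELEASED_WITHOUT_DEVICE, StateSpace)


class HistoryValidationError(ValueError):
    pass


@dataclass
class EncounterDataset:
    """Individual encounter histories over the study years.

    ``inter`` is an (n, n_years) array of inter-occasion event codes
    (0 = not captured); ``intra`` an (n, n_years) array of intra codes
    (the last column is ignored).  ``entry[i]`` is the year index of
    individual i's first capture; events before it are meaningless.
    """

    ids: list[str]
    inter: np.ndarray
    intra: np.ndarray
    entry: np.ndarray
    covariates: CovariateSeries
    space: StateSpace = field(default_factory=StateSpace)

    def __post_init__(self):
        self.inter = np.asarray(self.inter, dtype=np.int64)
        self.intra = np.asarray(self.intra, dtype=np.int64)
        self.entry = np.asarray(self.entry, dtype=np.int64)
        n, Y = self.inter.shape
        if len(self.ids) != n or self.intra.shape != (n, Y):
            raise HistoryValidationError("ragged dataset arrays")
        if self.covariates.n_years != Y:
            raise HistoryValidationError(
                f"covariates cover {self.covariates.n_years} years, "
                f"histories {Y}")
        self.validate()

    @property
    def n_individuals(self) -> int:
        return len(self.ids)

    @property
    def n_years(self) -> int:
        return self.inter.shape[1]

    @property
    def n_releases(self) -> int:
        """Total number of capture events (QAICc effective sample size)."""
        cols = np.arange(self.n_years)[None, :]
        return int(((self.inter > EV_NOT_CAPTURED)
                    & (cols >= self.entry[:, None])).sum())

    def validate(self) -> None:
        n, Y = self.inter.shape
        reveal_lo, reveal_hi = 2, 1 + self.space.n_areas  # inclusive
        failed = 2 + self.space.n_areas
        for i in range(n):
            e = self.entry[i]
            if not 0 <= e < Y:
                raise HistoryValidationError(f"{self.ids[i]}: bad entry {e}")
            if self.inter[i, e] == EV_NOT_CAPTURED:
                raise HistoryValidationError(
                    f"{self.ids[i]}: first coded occasion is not a capture")
            carrying = False
            for y in range(e, Y):
                ev = self.inter[i, y]
                if (reveal_lo <= ev <= failed) and not carrying and y > e:
                    raise HistoryValidationError(
                        f"{self.ids[i]}: device event in year {y} without "
                        f"a prior release with device")
                if reveal_lo <= ev <= failed and y == e:
                    raise HistoryValidationError(
                        f"{self.ids[i]}: first capture cannot carry a device")
                if ev != EV_NOT_CAPTURED and y < Y - 1:
                    iv = self.intra[i, y]
                    carrying = iv == IV_RELEASED_WITH_DEVICE

    def actions(self) -> np.ndarray:
        """(n, n_years - 1) device action per annual interval."""
        intra = self.intra[:, :-1]
        out = np.full(intra.shape, ACTION_NONE, dtype=np.int64)
        out[intra == IV_RELEASED_WITH_DEVICE] = ACTION_DEPLOY
        out[intra == IV_RELEASED_WITHOUT_DEVICE] = ACTION_REMOVE
        return out

    def subset(self, idx) -> "EncounterDataset":
        idx = np.asarray(idx)
        return EncounterDataset(
            ids=[self.ids[int(i)] for i in idx],
            inter=self.inter[idx], intra=self.intra[idx],
            entry=self.entry[idx], covariates=self.covariates,
            space=self.space)

    def detection_matrix(self) -> np.ndarray:
        """Histories collapsed to 0/1 detection at inter occasions.

        This is the single-state view the CJS goodness-of-fit machinery
        consumes; years before first capture are zero.
        """
        cols = np.arange(self.n_years)[None, :]
        return ((self.inter > EV_NOT_CAPTURED)
                & (cols >= self.entry[:, None])).astype(np.int64)
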