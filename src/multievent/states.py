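"""Hidden-state space, event alphabet and occasion coding.

The biological state of a bird is a triple (wintering area, geolocator
status, awareness), plus one absorbing dead state.  "Awareness" encodes
trap-dependence: a bird is *aware* at an occasion iff it was captured at
that occasion, so detection is a stochastic step inside the annual
transition and the event emitted at an occasion is a deterministic
function of the state.
"""

from __future__ import annotations

from dataclasses import dataclass, field

DEFAULT_AREAS = ("Canary", "Equatorial", "Guinea", "Angola")
DEVICE_STATUSES = ("none", "functioning", "failed")
AWARENESS_LEVELS = ("aware", "unaware")

# inter-occasion event codes (first character of a history token)
EV_NOT_CAPTURED = 0
EV_CAPTURED_NO_DEVICE = 1
# codes 2 .. 1+n_areas: captured, functioning device reveals area (code-2)
EV_REVEAL_BASE = 2


def ev_captured_device_failed(n_areas: int) -> int:
    """Event code for capture with a device that failed to provide data."""
    return EV_REVEAL_BASE + n_areas


# intra-occasion event codes
IV_NOT_HANDLED = 0
IV_RELEASED_WITHOUT_DEVICE = 1
IV_RELEASED_WITH_DEVICE = 2


class InvalidConfigurationError(ValueError):
    """Raised when a state space or occasion structure cannot be built."""


@dataclass(frozen=True)
class StateSpace:
    """Enumeration of hidden states: (area, device, awareness) tuples + dead.

    The live-state index is ``area*|device|*|awareness| + device*|awareness|
    + awareness``; the dead state has the highest index.
    """

    areas: tuple[str, ...] = DEFAULT_AREAS
    device_statuses: tuple[str, ...] = DEVICE_STATUSES
    awareness_levels: tuple[str, ...] = AWARENESS_LEVELS
    dead_state: str = "Dead"

    def __post_init__(self) -> None:
        if not (self.areas and self.device_statuses and self.awareness_levels):
            raise InvalidConfigurationError("every state axis needs >= 1 level")

    @property
    def n_areas(self) -> int:
        return len(self.areas)

    @property
    def n_device(self) -> int:
        return len(self.device_statuses)

    @property
    def n_awareness(self) -> int:
        return len(self.awareness_levels)

    @property
    def n_states(self) -> int:
        return self.n_areas * self.n_device * self.n_awareness + 1

    @property
    def dead_index(self) -> int:
        return self.n_states - 1

    def index_of(self, area: int, device: int, awareness: int) -> int:
        """Integer index of the live state (area, device, awareness)."""
        if not (0 <= area < self.n_areas and 0 <= device < self.n_device
                and 0 <= awareness < self.n_awareness):
            raise IndexError("state tuple out of range")
        return (area * self.n_device + device) * self.n_awareness + awareness

    def tuple_of(self, index: int) -> tuple[int, int, int] | None:
        """Inverse of :meth:`index_of`; ``None`` for the dead state."""
        if index == self.dead_index:
            return None
        awareness = index % self.n_awareness
        rest = index // self.n_awareness
        return rest // self.n_device, rest % self.n_device, awareness

    def state_label(self, index: int) -> str:
        tup = self.tuple_of(index)
        if tup is None:
            return self.dead_state
        a, d, w = tup
        return f"{self.areas[a]}/{self.device_statuses[d]}/{self.awareness_levels[w]}"

    def area_of_state(self, index: int) -> int | None:
        tup = self.tuple_of(index)
        return None if tup is None else tup[0]

    def data_dictionary(self) -> list[tuple[str, int, tuple | None]]:
        """Plain enumeration (label, index, tuple) for audit exports."""
        return [(self.state_label(i), i, self.tuple_of(i))
                for i in range(self.n_states)]


def build_state_space(n_areas: int = 4, n_device: int = 3,
                      n_awareness: int = 2,
                      areas: tuple[str, ...] | None = None) -> StateSpace:
    """Build the hidden-state space with a dead state appended.

    With the default configuration (4 areas x 3 device statuses x
    2 awareness levels) the space has 25 states.
    """
    if min(n_areas, n_device, n_awareness) < 1:
        raise InvalidConfigurationError(
            f"state axis counts must be >= 1, got "
            f"({n_areas}, {n_device}, {n_awareness})")
    if areas is None:
        areas = (DEFAULT_AREAS[:n_areas] if n_areas <= len(DEFAULT_AREAS)
                 else tuple(f"area{i+1}" for i in range(n_areas)))
    if len(areas) != n_areas:
        raise InvalidConfigurationError("area label count mismatch")
    return StateSpace(
        areas=tuple(areas),
        device_statuses=DEVICE_STATUSES[:n_device] if n_device <= 3
        else tuple(f"dev{i}" for i in range(n_device)),
        awareness_levels=AWARENESS_LEVELS[:n_awareness] if n_awareness <= 2
        else tuple(f"aw{i}" for i in range(n_awareness)),
    )


@dataclass(frozen=True)
class EventAlphabet:
    """Event codes for inter (arrival) and intra (departure) occasions."""

    n_areas: int = 4

    @property
    def n_inter_events(self) -> int:
        # not captured, captured w/o device, one reveal per area, failed device
        return 3 + self.n_areas

    @property
    def n_intra_events(self) -> int:
        return 3

    def reveal_event(self, area: int) -> int:
        if not 0 <= area < self.n_areas:
            raise IndexError("area out of range")
        return EV_REVEAL_BASE + area

    @property
    def failed_event(self) -> int:
        return ev_captured_device_failed(self.n_areas)

    def inter_labels(self) -> list[str]:
        return (["not_captured", "captured_no_device"]
                + [f"captured_device_reveals_area_{a+1}"
                   for a in range(self.n_areas)]
                + ["captured_device_failed"])

    def intra_labels(self) -> list[str]:
        return ["not_handled", "released_without_device",
                "released_with_device"]


INTER = "inter"
INTRA = "intra"


@dataclass(frozen=True)
class OccasionCoding:
    """Alternating inter/intra coding of annual capture occasions.

    Each study year contributes an inter (arrival) occasion; every year but
    the last also contributes an intra (departure) occasion, giving
    2*n_years - 1 coded occasions (45 for a 23-year study).
    """

    n_years: int
    first_year: int = 2000
    coded_kinds: tuple[str, ...] = field(init=False)

    def __post_init__(self) -> None:
        if self.n_years < 1:
            raise InvalidConfigurationError("n_years must be >= 1")
        kinds = []
        for y in range(self.n_years):
            kinds.append(INTER)
            if y < self.n_years - 1:
                kinds.append(INTRA)
        object.__setattr__(self, "coded_kinds", tuple(kinds))

    @property
    def n_coded(self) -> int:
        return 2 * self.n_years - 1

    def kind_of(self, coded: int) -> str:
        return self.coded_kinds[coded]

    def year_of(self, coded: int) -> int:
        if not 0 <= coded < self.n_coded:
            raise IndexError("coded occasion out of range")
        return self.first_year + coded // 2

    def year_index_of(self, coded: int) -> int:
        return coded // 2

    def inter_occasion(self, year_index: int) -> int:
        return 2 * year_index

    def intra_occasion(self, year_index: int) -> int:
        if year_index >= self.n_years - 1:
            raise IndexError("last year has no intra occasion")
        return 2 * year_index + 1

    @property
    def years(self) -> list[int]:
        return [self.first_year + i for i in range(self.n_years)]


def encode_occasions(n_years: int, first_year: int = 2000) -> OccasionCoding:
    """Split ``n_years`` annual occasions into 2*n_years - 1 coded ones."""
    return OccasionCoding(n_years=n_years, first_year=first_year)
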