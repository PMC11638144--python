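"""Real parameters, covariates, model designs and coefficient layouts.

Two layers:

* :class:`ParameterSet` holds *real-scale* parameters (survival per area,
  trap-dependent recapture, per-destination change probability, initial
  area simplex, device reliability).  The simulator and the matrix
  builders consume it directly.
* :class:`ModelSpec` + :func:`resolve_design` map a flat coefficient
  vector on the link scale to real parameters per study year, which is
  what the maximum-likelihood fitter optimises.

Links: survival, excess first-interval mortality, recapture and the
Canary-vs-others initial probability use the logit; area change uses a
multinomial logit with "stay" as the reference category, so the
per-destination probability c = exp(eta) / (1 + (A-1) exp(eta)) is
feasible (sum of moves < 1) for every coefficient value.  Climate
covariates are z-scored over the study years before entering any linear
predictor.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .states import StateSpace

# link-scale coefficients are capped to avoid exp overflow; generous
# enough that capped fits are flagged as boundary cases, not silently bent
COEF_CAP = 15.0


def expit(x):
    return 1.0 / (1.0 + np.exp(-np.clip(x, -COEF_CAP * 2, COEF_CAP * 2)))


def logit(p):
    p = np.asarray(p, dtype=float)
    with np.errstate(divide="ignore"):  # logit(0/1) = -/+inf is fine
        return np.log(p) - np.log1p(-p)


def change_prob_from_eta(eta, n_areas: int = 4):
    """Per-destination change probability from its multinomial-logit score."""
    e = np.exp(np.clip(eta, -COEF_CAP * 2, COEF_CAP * 2))
    return e / (1.0 + (n_areas - 1) * e)


def eta_from_change_prob(c, n_areas: int = 4):
    """Inverse of :func:`change_prob_from_eta`; requires (A-1)*c < 1."""
    c = np.asarray(c, dtype=float)
    stay = 1.0 - (n_areas - 1) * c
    if np.any(stay <= 0):
        raise ValueError("infeasible change probability: (A-1)*c >= 1")
    return np.log(c / stay)


@dataclass(frozen=True)
class CovariateSeries:
    """Annual climate covariates: mean SOI and winter (Dec-Mar) NAO."""

    year: np.ndarray
    soi: np.ndarray
    wnao: np.ndarray

    def __post_init__(self):
        for name in ("year", "soi", "wnao"):
            object.__setattr__(self, name,
                               np.asarray(getattr(self, name), dtype=float))
        if not (len(self.year) == len(self.soi) == len(self.wnao)):
            raise ValueError("covariate columns must have equal length")
        if np.any(~np.isfinite(self.soi)) or np.any(~np.isfinite(self.wnao)):
            raise ValueError("covariate series contains missing values")

    @property
    def n_years(self) -> int:
        return len(self.year)

    def zscored(self) -> "CovariateSeries":
        def z(x):
            s = x.std()
            return (x - x.mean()) / s if s > 0 else x - x.mean()
        return CovariateSeries(self.year, z(self.soi), z(self.wnao))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"year": self.year.astype(int),
                             "soi": self.soi, "wnao": self.wnao})

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "CovariateSeries":
        return cls(df["year"].to_numpy(), df["soi"].to_numpy(),
                   df["wnao"].to_numpy())


@dataclass(frozen=True)
class ParameterSet:
    """Real-scale parameters of the multievent model.

    ``phi_logit`` holds per-area survival intercepts on the logit scale;
    ``phi_soi_slope`` a shared SOI slope (per z-scored unit).  ``delta``
    is the excess mortality over the interval after first encounter:
    first-interval survival is phi * (1 - delta).  ``change_eta`` is the
    multinomial-logit score of moving to any one other area, with
    ``change_wnao_slope`` its wNAO slope.  ``pi`` is the initial
    wintering-area simplex and ``rho`` the probability a deployed
    geolocator functions (provides data).
    """

    phi_logit: np.ndarray
    phi_soi_slope: float = 0.0
    delta: float = 0.0
    p_aware: float = 0.5
    p_unaware: float = 0.5
    change_eta: float = -np.inf  # c = 0 by default
    change_wnao_slope: float = 0.0
    pi: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))
    rho: float = 1.0

    def __post_init__(self):
        object.__setattr__(self, "phi_logit",
                           np.atleast_1d(np.asarray(self.phi_logit, float)))
        object.__setattr__(self, "pi", np.asarray(self.pi, dtype=float))
        for name, v in (("delta", self.delta), ("p_aware", self.p_aware),
                        ("p_unaware", self.p_unaware), ("rho", self.rho)):
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if abs(self.pi.sum() - 1.0) > 1e-12 or np.any(self.pi < 0):
            raise ValueError("pi must be a probability simplex")

    @property
    def n_areas(self) -> int:
        return len(self.pi)

    @classmethod
    def from_probs(cls, phi, c=0.0, **kw) -> "ParameterSet":
        """Build from probability-scale survival and change values."""
        phi = np.atleast_1d(np.asarray(phi, dtype=float))
        n_areas = len(kw.get("pi", np.zeros(4)))
        eta = (-np.inf if c == 0
               else float(eta_from_change_prob(c, n_areas)))
        return cls(phi_logit=logit(phi), change_eta=eta, **kw)

    def phi(self, area: int, soi_z: float = 0.0,
            first_interval: bool = False) -> float:
        """Survival probability for ``area`` at a z-scored SOI value."""
        idx = area if len(self.phi_logit) > 1 else 0
        p = float(expit(self.phi_logit[idx] + self.phi_soi_slope * soi_z))
        return p * (1.0 - self.delta) if first_interval else p

    def change_prob(self, wnao_z: float = 0.0) -> float:
        """Per-destination annual probability of changing wintering area."""
        if np.isneginf(self.change_eta):
            return 0.0
        return float(change_prob_from_eta(
            self.change_eta + self.change_wnao_slope * wnao_z, self.n_areas))

    def stay_prob(self, wnao_z: float = 0.0) -> float:
        return 1.0 - (self.n_areas - 1) * self.change_prob(wnao_z)


@dataclass(frozen=True)
class ModelSpec:
    """A testable model structure: one design choice per parameter family.

    survival: constant | area | canary_others | soi | area+soi | area*soi
              | device
    first_encounter: none | constant
    change: constant | wnao | soi | to_area | from_area
    initial: equal | canary_others | area
    recapture: trap | time_trap
    ``rho`` is the fixed device-reliability constant (not estimated).
    """

    survival: str = "constant"
    first_encounter: str = "none"
    change: str = "constant"
    initial: str = "canary_others"
    recapture: str = "trap"
    rho: float = 147.0 / 182.0
    name: str | None = None

    _SURVIVAL = ("constant", "area", "canary_others", "soi", "area+soi",
                 "area*soi", "device")
    _FIRST = ("none", "constant")
    _CHANGE = ("constant", "wnao", "soi", "to_area", "from_area")
    _INITIAL = ("equal", "canary_others", "area")
    _RECAPTURE = ("trap", "time_trap")

    def __post_init__(self):
        for val, allowed, fam in ((self.survival, self._SURVIVAL, "survival"),
                                  (self.first_encounter, self._FIRST,
                                   "first_encounter"),
                                  (self.change, self._CHANGE, "change"),
                                  (self.initial, self._INITIAL, "initial"),
                                  (self.recapture, self._RECAPTURE,
                                   "recapture")):
            if val not in allowed:
                raise ValueError(f"unknown {fam} design {val!r}")

    @property
    def label(self) -> str:
        return self.name or (f"phi({self.survival}"
                             + ("+1st" if self.first_encounter != "none"
                                else "")
                             + f") c({self.change}) pi({self.initial}) "
                             f"p({self.recapture})")


class MissingCovariateError(KeyError):
    pass


@dataclass
class Design:
    """Coefficient layout resolved from a :class:`ModelSpec`.

    Maps a flat link-scale coefficient vector ``theta`` to the per-year
    real parameters the likelihood needs.  ``n_intervals`` annual
    transitions connect ``n_years`` inter occasions; interval ``i`` uses
    the covariates of its arrival year ``i + 1`` (the winter it spans).
    """

    spec: ModelSpec
    space: StateSpace
    covariates: CovariateSeries
    names: list[str] = field(init=False)
    _slices: dict = field(init=False)

    def __post_init__(self):
        A = self.space.n_areas
        ni = self.covariates.n_years - 1
        if ni < 1:
            raise MissingCovariateError("need covariates for >= 2 years")
        z = self.covariates.zscored()
        self.soi_z = z.soi[1:]      # covariate of the arrival year
        self.wnao_z = z.wnao[1:]
        names: list[str] = []
        sl: dict[str, slice] = {}

        def add(family, labels):
            start = len(names)
            names.extend(f"{family}:{l}" for l in labels)
            sl[family] = slice(start, len(names))

        s = self.spec.survival
        if s == "constant":
            add("phi", ["int"])
        elif s == "area":
            add("phi", list(self.space.areas))
        elif s == "canary_others":
            add("phi", [self.space.areas[0], "others"])
        elif s == "soi":
            add("phi", ["int", "soi"])
        elif s == "area+soi":
            add("phi", list(self.space.areas) + ["soi"])
        elif s == "area*soi":
            add("phi", list(self.space.areas)
                + [f"soi.{a}" for a in self.space.areas])
        elif s == "device":
            add("phi", ["int", "device"])
        if self.spec.first_encounter == "constant":
            add("delta", ["int"])
        c = self.spec.change
        if c == "constant":
            add("c", ["int"])
        elif c in ("wnao", "soi"):
            add("c", ["int", c])
        elif c == "to_area":
            add("c", [f"to.{a}" for a in self.space.areas])
        elif c == "from_area":
            add("c", [f"from.{a}" for a in self.space.areas])
        if self.spec.initial == "canary_others":
            add("pi", [self.space.areas[0]])
        elif self.spec.initial == "area":
            add("pi", list(self.space.areas[1:]))
        if self.spec.recapture == "trap":
            add("p", ["int", "trap"])
        else:
            add("p", [f"t{i+1}" for i in range(ni)] + ["trap"])
        self.names = names
        self._slices = sl
        self.n_intervals = ni

    @property
    def n_coef(self) -> int:
        return len(self.names)

    def coef(self, theta, family):
        theta = np.asarray(theta, dtype=float)
        return theta[self._slices[family]] if family in self._slices else None

    # ---- real-parameter builders -------------------------------------

    def survival_probs(self, theta):
        """(n_intervals, n_areas, n_device) survival probabilities."""
        A, D = self.space.n_areas, self.space.n_device
        b = self.coef(theta, "phi")
        s = self.spec.survival
        eta = np.empty((self.n_intervals, A, D))
        if s == "constant":
            eta[:] = b[0]
        elif s == "area":
            eta[:] = b[None, :, None]
        elif s == "canary_others":
            per_area = np.concatenate([[b[0]], np.full(A - 1, b[1])])
            eta[:] = per_area[None, :, None]
        elif s == "soi":
            eta[:] = (b[0] + b[1] * self.soi_z)[:, None, None]
        elif s == "area+soi":
            eta[:] = (b[None, :A, None]
                      + (b[A] * self.soi_z)[:, None, None])
        elif s == "area*soi":
            eta[:] = (b[None, :A, None]
                      + self.soi_z[:, None, None] * b[None, A:2 * A, None])
        elif s == "device":
            eta[:] = b[0]
            eta[:, :, 1:] += b[1]   # carried device (functioning or failed)
        return expit(np.clip(eta, -COEF_CAP, COEF_CAP))

    def delta(self, theta) -> float:
        d = self.coef(theta, "delta")
        return float(expit(np.clip(d[0], -COEF_CAP, COEF_CAP))) if d is not None else 0.0

    def change_matrices(self, theta):
        """(n_intervals, A, A) row-stochastic area-change matrices."""
        A = self.space.n_areas
        g = self.coef(theta, "c")
        c = self.spec.change
        out = np.zeros((self.n_intervals, A, A))
        if c in ("constant", "wnao", "soi"):
            if c == "constant":
                eta = np.full(self.n_intervals, g[0])
            else:
                cov = self.wnao_z if c == "wnao" else self.soi_z
                eta = g[0] + g[1] * cov
            prob = change_prob_from_eta(eta, A)
            out[:] = prob[:, None, None]
            idx = np.arange(A)
            out[:, idx, idx] = 1.0 - (A - 1) * prob[:, None]
        else:
            # multinomial logit, stay as reference for each origin row
            for i in range(self.n_intervals):
                for a in range(A):
                    if c == "to_area":
                        w = np.exp(np.clip(np.delete(g, a), -COEF_CAP, COEF_CAP))
                    else:  # from_area: symmetric moves per origin
                        w = np.full(A - 1, np.exp(np.clip(g[a], -COEF_CAP,
                                                          COEF_CAP)))
                    denom = 1.0 + w.sum()
                    row = np.empty(A)
                    row[a] = 1.0 / denom
                    row[np.arange(A) != a] = w / denom
                    out[i, a] = row
        return out

    def recapture_probs(self, theta):
        """(n_intervals, 2): columns (p_aware, p_unaware) per interval."""
        b = self.coef(theta, "p")
        out = np.empty((self.n_intervals, 2))
        if self.spec.recapture == "trap":
            out[:, 1] = expit(b[0])
            out[:, 0] = expit(b[0] + b[1])
        else:
            out[:, 1] = expit(b[:-1])
            out[:, 0] = expit(b[:-1] + b[-1])
        return out

    def initial_pi(self, theta):
        A = self.space.n_areas
        b = self.coef(theta, "pi")
        if self.spec.initial == "equal":
            return np.full(A, 1.0 / A)
        if self.spec.initial == "canary_others":
            pc = float(expit(b[0]))
            return np.concatenate([[pc], np.full(A - 1, (1 - pc) / (A - 1))])
        w = np.exp(np.clip(np.concatenate([[0.0], b]), -COEF_CAP, COEF_CAP))
        return w / w.sum()

    # ---- reporting ----------------------------------------------------

    def real_estimates(self, theta, vcov=None, z=1.959963984540054):
        """Real-parameter point estimates with Wald CIs where available.

        CIs are monotone back-transforms of single-coefficient Wald
        intervals on the link scale; entries built from several
        coefficients carry ``None`` bounds.
        """
        theta = np.asarray(theta, dtype=float)
        se = (np.sqrt(np.maximum(np.diag(vcov), 0.0))
              if vcov is not None else np.full(len(theta), np.nan))

        def tr1(fun, i):
            lo, hi = theta[i] - z * se[i], theta[i] + z * se[i]
            a, b_ = fun(lo), fun(hi)
            return fun(theta[i]), min(a, b_), max(a, b_)

        A = self.space.n_areas
        out: dict[str, tuple] = {}
        sl = self._slices
        s = self.spec.survival
        if s in ("constant", "soi", "device"):
            out["phi"] = tr1(lambda x: float(expit(x)), sl["phi"].start)
        elif s in ("area", "area+soi", "area*soi"):
            for a in range(A):
                out[f"phi_{self.space.areas[a]}"] = tr1(
                    lambda x: float(expit(x)), sl["phi"].start + a)
        elif s == "canary_others":
            out[f"phi_{self.space.areas[0]}"] = tr1(
                lambda x: float(expit(x)), sl["phi"].start)
            out["phi_others"] = tr1(lambda x: float(expit(x)),
                                    sl["phi"].start + 1)
        if "delta" in sl:
            out["delta"] = tr1(lambda x: float(expit(x)), sl["delta"].start)
        if self.spec.change in ("constant", "wnao", "soi"):
            out["c"] = tr1(lambda x: float(change_prob_from_eta(x, A)),
                           sl["c"].start)
        if self.spec.initial == "canary_others":
            out[f"pi_{self.space.areas[0]}"] = tr1(lambda x: float(expit(x)),
                                                   sl["pi"].start)
        p0 = sl["p"].start
        if self.spec.recapture == "trap":
            out["p_unaware"] = tr1(lambda x: float(expit(x)), p0)
        return out


def resolve_design(spec: ModelSpec, space: StateSpace,
                   covariates: CovariateSeries) -> Design:
    """Resolve a model structure into an explicit coefficient layout."""
    return Design(spec=spec, space=space, covariates=covariates)


def params_from_design(design: Design, theta, year_interval: int = 0,
                       first_interval: bool = False) -> ParameterSet:
    """Real :class:`ParameterSet` implied by coefficients for one interval.

    Convenience bridge used by matrix builders and reports; device-effect
    survival designs collapse to the no-device column here.
    """
    phi = design.survival_probs(theta)[year_interval, :, 0]
    cm = design.change_matrices(theta)[year_interval]
    off = cm[0, 1:]  # per-destination from area 0 (symmetric designs)
    p = design.recapture_probs(theta)[year_interval]
    c = float(off.mean())
    A = design.space.n_areas
    return ParameterSet(
        phi_logit=logit(np.clip(phi, 1e-12, 1 - 1e-12)),
        delta=design.delta(theta) if first_interval else 0.0,
        p_aware=float(p[0]), p_unaware=float(p[1]),
        change_eta=(float(eta_from_change_prob(c, A)) if c > 0 else -np.inf),
        pi=design.initial_pi(theta), rho=design.spec.rho)
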