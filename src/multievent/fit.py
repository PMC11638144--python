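"""Maximum-likelihood fitting of multievent models.

Coefficients live on unconstrained link scales, so optimisation is a
plain quasi-Newton search (L-BFGS-B) from several seeded starts.
Standard errors come from the observed information (central-difference
Hessian of the negative log-likelihood at the optimum); real-parameter
95% confidence intervals are monotone back-transforms of link-scale
Wald intervals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .dataset import EncounterDataset
from .likelihood import ImpossibleHistoryError, loglik_from_design
from .params import (COEF_CAP, Design, ModelSpec, change_prob_from_eta,
                     expit, resolve_design)

_Z95 = 1.959963984540054


class FitFailureError(RuntimeError):
    pass


@dataclass
class FitResult:
    """Outcome of one maximum-likelihood fit."""

    spec: ModelSpec
    design: Design
    theta: np.ndarray
    log_likelihood: float
    np_: int
    se: np.ndarray | None
    vcov: np.ndarray | None
    converged: bool
    n_starts: int
    message: str = ""
    real: dict = field(default_factory=dict)

    @property
    def deviance(self) -> float:
        return -2.0 * self.log_likelihood

    def estimate(self, name: str) -> tuple[float, float, float]:
        """(point, lo95, hi95) for a named real parameter."""
        return self.real[name]

    def covers(self, name: str, truth: float) -> bool:
        _, lo, hi = self.real[name]
        return lo <= truth <= hi

    def report(self) -> str:
        lines = [f"model: {self.spec.label}",
                 f"np: {self.np_}   logL: {self.log_likelihood:.3f}   "
                 f"deviance: {self.deviance:.3f}",
                 f"converged: {self.converged} ({self.n_starts} starts)",
                 "", "coefficients (link scale):"]
        se = self.se if self.se is not None else [np.nan] * self.np_
        for name, th, s in zip(self.design.names, self.theta, se):
            lines.append(f"  {name:<18s} {th: .4f}  (se {s:.4f})")
        lines.append("")
        lines.append("real parameters (95% Wald CI):")
        for name, (pt, lo, hi) in self.real.items():
            lines.append(f"  {name:<18s} {pt:.3f}  ({lo:.3f}-{hi:.3f})")
        return "\n".join(lines)


def _numeric_hessian(f, x, h: float = 1e-4) -> np.ndarray:
    n = len(x)
    H = np.empty((n, n))
    hi = np.maximum(h, h * np.abs(x))
    for i in range(n):
        for j in range(i, n):
            ei = np.zeros(n); ei[i] = hi[i]
            ej = np.zeros(n); ej[j] = hi[j]
            fpp = f(x + ei + ej)
            fpm = f(x + ei - ej)
            fmp = f(x - ei + ej)
            fmm = f(x - ei - ej)
            H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4 * hi[i] * hi[j])
    return H


def fit_model(data: EncounterDataset, spec: ModelSpec, n_starts: int = 10,
              seed: int = 0, tolerance: float = 1e-9,
              start: np.ndarray | None = None,
              compute_se: bool = True) -> FitResult:
    """Fit a model by maximising the conditional forward likelihood.

    The first start is the zero vector (all real parameters at the
    centre of their link scale); the rest are seeded uniform(-2, 2)
    draws.  Boundary estimates (|coefficient| near the cap) are warned
    about, not failed.
    """
    design = resolve_design(spec, data.space, data.covariates)
    k = design.n_coef

    def nll(theta):
        if np.any(np.abs(theta) > COEF_CAP):
            return 1e12 + float(np.sum(np.abs(theta)))
        try:
            return -loglik_from_design(data, design, theta)
        except (ImpossibleHistoryError, FloatingPointError):
            return 1e12

    rng = np.random.default_rng(seed)
    starts = [np.zeros(k) if start is None else np.asarray(start, float)]
    starts += [rng.uniform(-2, 2, size=k) for _ in range(n_starts - 1)]

    best = None
    messages = []
    for x0 in starts:
        res = optimize.minimize(nll, x0, method="L-BFGS-B",
                                options={"maxiter": 1000, "ftol": tolerance,
                                         "gtol": 1e-7})
        messages.append(str(res.message))
        if np.isfinite(res.fun) and res.fun < 1e11 and (
                best is None or res.fun < best.fun - 1e-9):
            best = res
    if best is None:
        raise FitFailureError(
            "no start converged to a finite likelihood: "
            + "; ".join(sorted(set(messages))))

    theta = best.x
    if np.any(np.abs(theta) > COEF_CAP - 1.0):
        warnings.warn("coefficient near the link-scale cap: boundary "
                      "estimate, Wald intervals unreliable", stacklevel=2)

    se = vcov = None
    if compute_se:
        H = _numeric_hessian(nll, theta)
        try:
            vcov = np.linalg.inv(H)
            d = np.diag(vcov)
            if np.any(d < 0):
                raise np.linalg.LinAlgError("negative variance")
            se = np.sqrt(d)
        except np.linalg.LinAlgError:
            warnings.warn("singular observed information: standard errors "
                          "unavailable", stacklevel=2)
            vcov = se = None

    real = design.real_estimates(theta, vcov)
    return FitResult(spec=spec, design=design, theta=theta,
                     log_likelihood=-float(best.fun), np_=k, se=se,
                     vcov=vcov, converged=bool(best.success),
                     n_starts=len(starts), message=str(best.message),
                     real=real)


def derived_parameter(fit: FitResult, target: str,
                      area: int = 0, soi_value: float = 0.0):
    """Plug-in derived estimates with delta-method / transform CIs.

    Targets: ``stay_probability`` (1 - (A-1)c), ``area_survival``
    (survival for ``area`` at a z-scored SOI value) and
    ``first_year_survival`` (phi * (1 - delta)).
    """
    design = fit.design
    A = design.space.n_areas
    sl = design._slices
    theta, vcov = fit.theta, fit.vcov

    def wald1(fun, i):
        if vcov is None:
            return fun(theta[i]), np.nan, np.nan
        s = np.sqrt(max(vcov[i, i], 0.0))
        vals = sorted((fun(theta[i] - _Z95 * s), fun(theta[i] + _Z95 * s)))
        return fun(theta[i]), vals[0], vals[1]

    if target == "stay_probability":
        if design.spec.change not in ("constant", "wnao", "soi"):
            raise ValueError("stay probability needs a symmetric change "
                             "design")
        return wald1(lambda g: 1.0 - (A - 1)
                     * float(change_prob_from_eta(g, A)), sl["c"].start)

    if target == "area_survival":
        s = design.spec.survival
        if s in ("constant", "soi", "device"):
            i = sl["phi"].start
        else:
            i = sl["phi"].start + area
        if soi_value == 0.0 or s in ("constant", "area", "canary_others",
                                     "device"):
            return wald1(lambda b: float(expit(b)), i)
        slope_i = (sl["phi"].stop - 1 if s in ("soi", "area+soi")
                   else sl["phi"].start + A + area)
        g = np.zeros(len(theta)); g[i] = 1.0; g[slope_i] = soi_value
        eta = float(theta @ g)
        if vcov is None:
            return float(expit(eta)), np.nan, np.nan
        s_eta = float(np.sqrt(max(g @ vcov @ g, 0.0)))
        return (float(expit(eta)), float(expit(eta - _Z95 * s_eta)),
                float(expit(eta + _Z95 * s_eta)))

    if target == "first_year_survival":
        if "delta" not in sl:
            raise ValueError("model has no first-encounter effect")
        i_phi, i_d = sl["phi"].start, sl["delta"].start

        def fun(th):
            return float(expit(th[i_phi]) * (1.0 - expit(th[i_d])))

        pt = fun(theta)
        if vcov is None:
            return pt, np.nan, np.nan
        g = np.zeros(len(theta))
        h = 1e-6
        for i in (i_phi, i_d):
            e = np.zeros(len(theta)); e[i] = h
            g[i] = (fun(theta + e) - fun(theta - e)) / (2 * h)
        s_d = float(np.sqrt(max(g @ vcov @ g, 0.0)))
        return pt, pt - _Z95 * s_d, pt + _Z95 * s_d

    raise ValueError(f"unknown derived target {target!r}")
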