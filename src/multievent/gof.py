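"""Goodness-of-fit of the Cormack-Jolly-Seber base model.

Works on detection histories collapsed to seen/not-seen at the inter
occasions.  Two components are computed, the two the downstream model
structure reacts to:

* an immediate trap-dependence component (TEST2.CT-style): does capture
  at one occasion change the odds of recapture at the next?
* a transience component (TEST3.SR-style): are newly marked animals
  reseen less often than previously marked ones?

Their pooled chi-square over degrees of freedom estimates the variance
inflation factor (c-hat) used to correct deviance-based model
selection.  Tables with any expected cell below 2 are uninformative for
a 2x2 chi-square and are dropped.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

MIN_EXPECTED = 2.0


@dataclass
class GofComponent:
    name: str
    chi2: float
    df: int
    z: float | None = None   # signed statistic where direction is defined

    @property
    def p_value(self) -> float:
        if self.df < 1:
            return np.nan
        return float(stats.chi2.sf(self.chi2, self.df))


@dataclass
class GofResult:
    components: list[GofComponent]

    @property
    def total_chi2(self) -> float:
        return float(sum(c.chi2 for c in self.components))

    @property
    def total_df(self) -> int:
        return int(sum(c.df for c in self.components))

    @property
    def chat(self) -> float:
        return self.total_chi2 / self.total_df if self.total_df else np.nan

    def chat_without(self, name: str) -> float:
        """c-hat after removing one component (e.g. trap-dependence once
        it is modelled explicitly)."""
        chi2 = sum(c.chi2 for c in self.components if c.name != name)
        df = sum(c.df for c in self.components if c.name != name)
        return chi2 / df if df else np.nan


def build_marray(histories: np.ndarray) -> np.ndarray:
    """Release/first-recapture matrix.

    ``m[i, j]`` (j > i) counts animals released at occasion i whose next
    recapture is at occasion j; ``m[i, i]`` holds the releases at i.
    """
    h = np.asarray(histories)
    n, Y = h.shape
    if Y < 2:
        raise ValueError("need at least two occasions")
    m = np.zeros((Y, Y), dtype=np.int64)
    for i in range(n):
        occs = np.flatnonzero(h[i])
        for a, b in zip(occs[:-1], occs[1:]):
            m[a, b] += 1
        for a in occs:
            m[a, a] += 1
    return m


def _chi2_2x2(table: np.ndarray) -> tuple[float, float] | None:
    """Pearson chi-square and signed association for a 2x2 table.

    Returns None when any expected cell is below MIN_EXPECTED.
    """
    t = np.asarray(table, dtype=float)
    rows, cols, n = t.sum(1), t.sum(0), t.sum()
    if n == 0 or np.any(rows == 0) or np.any(cols == 0):
        return None
    expected = np.outer(rows, cols) / n
    if expected.min() < MIN_EXPECTED:
        return None
    chi2 = float(((t - expected) ** 2 / expected).sum())
    sign = 1.0 if t[0, 0] > expected[0, 0] else -1.0
    return chi2, sign * np.sqrt(chi2)


def test_trap_dependence(histories: np.ndarray) -> GofComponent:
    """Immediate trap-dependence contingency test.

    For each occasion t, among animals marked before t and known alive
    after t, cross-tabulates capture at t against capture at t+1.  The
    signed z is positive when animals captured at t are recaptured more
    often at t+1 (trap-happiness).
    """
    h = np.asarray(histories)
    n, Y = h.shape
    if Y < 3:
        raise ValueError("need at least three occasions")
    first = np.array([np.flatnonzero(r)[0] if r.any() else Y for r in h])
    chi2_total, df, zsum = 0.0, 0, 0.0
    for t in range(1, Y - 1):
        marked_before = first < t
        seen_after = h[:, t + 1:].any(axis=1) | (h[:, t + 1] == 1)
        known = marked_before & seen_after
        if not known.any():
            continue
        x = h[known, t] == 1
        y = h[known, t + 1] == 1
        table = np.array([[np.sum(x & y), np.sum(x & ~y)],
                          [np.sum(~x & y), np.sum(~x & ~y)]])
        res = _chi2_2x2(table)
        if res is None:
            continue
        chi2_total += res[0]
        zsum += res[1]
        df += 1
    z = zsum / np.sqrt(df) if df else None
    return GofComponent("trap_dependence", chi2_total, df, z)


def test_transience(histories: np.ndarray) -> GofComponent:
    """Transience contingency test (newly vs previously marked).

    For each occasion t, among animals captured at t, cross-tabulates
    "newly marked at t" against "ever reseen after t".  The signed z is
    positive when new animals are reseen *less* (transience / excess
    first-interval mortality).
    """
    h = np.asarray(histories)
    n, Y = h.shape
    if Y < 3:
        raise ValueError("need at least three occasions")
    first = np.array([np.flatnonzero(r)[0] if r.any() else Y for r in h])
    chi2_total, df, zsum = 0.0, 0, 0.0
    for t in range(1, Y - 1):
        at_t = h[:, t] == 1
        if not at_t.any():
            continue
        new = first[at_t] == t
        reseen = h[at_t, t + 1:].any(axis=1)
        table = np.array([[np.sum(new & ~reseen), np.sum(new & reseen)],
                          [np.sum(~new & ~reseen), np.sum(~new & reseen)]])
        res = _chi2_2x2(table)
        if res is None:
            continue
        chi2_total += res[0]
        zsum += res[1]
        df += 1
    z = zsum / np.sqrt(df) if df else None
    return GofComponent("transience", chi2_total, df, z)


def cjs_gof(histories: np.ndarray) -> GofResult:
    """Both retained components on collapsed detection histories."""
    return GofResult([test_trap_dependence(histories),
                      test_transience(histories)])


def fit_cjs(histories: np.ndarray) -> tuple[float, float, float]:
    """Constant-parameter CJS fit on detection histories.

    Maximises the conditional likelihood over (phi, p) by quasi-Newton
    on the logit scale; returns (phi, p, log-likelihood).  Used to
    parametrise the null model when calibrating c-hat by simulation.
    """
    from scipy import optimize

    h = np.asarray(histories)
    n, Y = h.shape
    first = np.array([np.flatnonzero(r)[0] for r in h])
    last = np.array([np.flatnonzero(r)[-1] for r in h])
    # sufficient statistics: detections/gaps inside [first, last], and
    # per-occasion counts still at risk after the last detection
    inside_caps = inside_total = 0
    for i in range(n):
        if last[i] > first[i]:
            seg = h[i, first[i] + 1:last[i] + 1]
            inside_caps += int(seg.sum())
            inside_total += len(seg)
    tail_len = (Y - 1) - last  # occasions remaining after last sighting

    def nll(x):
        phi, p = 1 / (1 + np.exp(-x[0])), 1 / (1 + np.exp(-x[1]))
        # chi(k): P(never seen again | alive, k occasions remaining)
        chi = np.ones(Y)
        for k in range(1, Y):
            chi[k] = 1 - phi + phi * (1 - p) * chi[k - 1]
        ll = (inside_caps * np.log(phi * p)
              + (inside_total - inside_caps) * np.log(phi * (1 - p))
              + np.log(chi[tail_len]).sum())
        return -ll

    res = optimize.minimize(nll, np.zeros(2), method="L-BFGS-B")
    phi, p = 1 / (1 + np.exp(-res.x[0])), 1 / (1 + np.exp(-res.x[1]))
    return float(phi), float(p), -float(res.fun)
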