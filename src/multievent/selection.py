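"""Overdispersion-corrected model selection (QAICc and Akaike weights)."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dataset import EncounterDataset
from .fit import FitFailureError, FitResult, fit_model
from .params import ModelSpec


def qaicc(deviance: float, np_: int, chat: float, n_eff: int) -> float:
    """Quasi-AIC with small-sample correction.

    deviance/chat + 2*np + 2*np*(np+1)/(n_eff - np - 1); ``n_eff`` is
    the number of releases (capture events).
    """
    if chat <= 0:
        raise ValueError("chat must be positive")
    if n_eff <= np_ + 1:
        raise ValueError(f"n_eff={n_eff} too small for np={np_}: "
                         "small-sample correction undefined")
    return (deviance / chat + 2.0 * np_
            + 2.0 * np_ * (np_ + 1.0) / (n_eff - np_ - 1.0))


def akaike_weights(qaicc_values) -> np.ndarray:
    """w_i = exp(-delta_i / 2) normalised over the model set."""
    q = np.asarray(qaicc_values, dtype=float)
    if q.size == 0:
        raise ValueError("empty QAICc list")
    if np.any(~np.isfinite(q)):
        raise ValueError("non-finite QAICc value")
    delta = q - q.min()
    w = np.exp(-delta / 2.0)
    return w / w.sum()


@dataclass
class ModelTable:
    """Ranked model-comparison table (rows sorted by QAICc)."""

    frame: pd.DataFrame
    fits: dict[str, FitResult]

    def __str__(self) -> str:
        return self.frame.to_string(index=False,
                                    float_format=lambda v: f"{v:.3f}")

    @property
    def best(self) -> FitResult:
        return self.fits[self.frame.iloc[0]["model"]]

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)


def run_model_set(data: EncounterDataset, specs: list[ModelSpec],
                  chat: float = 1.0, n_eff: int | None = None,
                  **fit_kw) -> ModelTable:
    """Fit a set of model structures and rank them by QAICc.

    Failed fits are recorded with missing QAICc and excluded from the
    weights.  Ties in QAICc are broken in favour of fewer parameters.
    """
    if n_eff is None:
        n_eff = data.n_releases
    rows = []
    fits: dict[str, FitResult] = {}
    for j, spec in enumerate(specs):
        label = spec.name or f"M{j+1}"
        try:
            fit = fit_model(data, spec, **fit_kw)
        except FitFailureError as exc:
            warnings.warn(f"model {label} failed to fit: {exc}",
                          stacklevel=2)
            rows.append({"model": label, "np": None, "deviance": np.nan,
                         "qaicc": np.nan})
            continue
        fits[label] = fit
        rows.append({"model": label, "np": fit.np_,
                     "deviance": fit.deviance,
                     "qaicc": qaicc(fit.deviance, fit.np_, chat, n_eff)})
    df = pd.DataFrame(rows)
    ok = df["qaicc"].notna()
    if ok.any():
        w = akaike_weights(df.loc[ok, "qaicc"].to_numpy())
        df.loc[ok, "delta_qaicc"] = (df.loc[ok, "qaicc"]
                                     - df.loc[ok, "qaicc"].min())
        df.loc[ok, "weight"] = w
    df = df.sort_values(["qaicc", "np"],
                        na_position="last").reset_index(drop=True)
    return ModelTable(frame=df, fits=fits)
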