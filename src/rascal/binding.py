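"""Steady-state 1:1 binding-isotherm fitting.

Surface plasmon resonance steady-state responses follow the Langmuir model
R(C) = Rmax * C / (K_D + C) for a 1:1 interaction between an immobilised
partner and an analyte at concentration C. ``fit_kd`` recovers (K_D, Rmax) by
deterministic least squares; ``fold_change`` compares affinities across a
mutant panel (ratio > 1 means weaker binding than the reference).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

__all__ = ["IsothermData", "KDFit", "langmuir", "fit_kd", "fold_change", "fit_panel"]


def langmuir(conc: np.ndarray, kd: float, rmax: float) -> np.ndarray:
    """Steady-state 1:1 binding response, same units as rmax."""
    conc = np.asarray(conc, float)
    return rmax * conc / (kd + conc)


@dataclass
class IsothermData:
    """Analyte concentrations (M) and steady-state responses (RU)."""

    concentrations: np.ndarray
    responses: np.ndarray
    replicate: str | int | None = None

    def __post_init__(self) -> None:
        self.concentrations = np.asarray(self.concentrations, float)
        self.responses = np.asarray(self.responses, float)
        if self.concentrations.shape != self.responses.shape:
            raise ValueError("concentration and response arrays differ in length")
        if np.any(self.concentrations <= 0):
            raise ValueError("analyte concentrations must be positive")

    @property
    def spans_decade(self) -> bool:
        c = self.concentrations
        return float(c.max() / c.min()) >= 10.0

    def fittable(self) -> bool:
        """>= 4 concentrations spanning >= 1 order of magnitude, non-flat."""
        if self.concentrations.size < 4 or not self.spans_decade:
            return False
        if np.allclose(self.responses, 0.0):
            return False
        if np.ptp(self.responses) < 1e-9 * max(1.0, abs(self.responses).max()):
            return False
        return True


@dataclass
class KDFit:
    kd: float                   # M
    rmax: float                 # RU
    rss: float                  # residual sum of squares, RU^2
    kd_se: float
    rmax_se: float
    converged: bool
    n_points: int = 0

    def to_dict(self) -> dict:
        return {"kd_M": self.kd, "rmax_RU": self.rmax, "rss": self.rss,
                "kd_se_M": self.kd_se, "rmax_se_RU": self.rmax_se,
                "converged": self.converged, "n_points": self.n_points}


def _failed_fit(n: int) -> KDFit:
    return KDFit(kd=float("nan"), rmax=float("nan"), rss=float("nan"),
                 kd_se=float("nan"), rmax_se=float("nan"), converged=False,
                 n_points=n)


def fit_kd(data: IsothermData) -> KDFit:
    """Deterministic least-squares fit of the 1:1 model.

    Start values: Rmax at 1.1x the largest response; K_D at the concentration
    whose response is nearest half of that Rmax estimate. Underdetermined or
    flat data returns a non-converged fit with no parameters rather than
    raising.
    """
    if not data.fittable():
        return _failed_fit(int(data.concentrations.size))
    conc = data.concentrations
    resp = data.responses
    rmax0 = 1.1 * float(resp.max())
    half = rmax0 / 2.0
    kd0 = float(conc[np.argmin(np.abs(resp - half))])
    try:
        popt, pcov = curve_fit(langmuir, conc, resp, p0=[kd0, rmax0],
                               bounds=([0.0, 0.0], [np.inf, np.inf]),
                               maxfev=10000)
    except (RuntimeError, ValueError):
        return _failed_fit(int(conc.size))
    kd, rmax = float(popt[0]), float(popt[1])
    if not (kd > 0 and rmax > 0 and np.all(np.isfinite(popt))):
        return _failed_fit(int(conc.size))
    resid = resp - langmuir(conc, kd, rmax)
    ses = np.sqrt(np.clip(np.diag(pcov), 0.0, None))
    return KDFit(kd=kd, rmax=rmax, rss=float(resid @ resid),
                 kd_se=float(ses[0]), rmax_se=float(ses[1]),
                 converged=True, n_points=int(conc.size))


def fold_change(kd_variant: float, kd_reference: float) -> float:
    """K_D ratio variant/reference; > 1 means weaker binding."""
    if kd_variant <= 0 or kd_reference <= 0:
        raise ValueError("dissociation constants must be positive")
    return kd_variant / kd_reference


def fit_panel(isotherms: list[IsothermData]):
    """Fit replicates independently; summarise mean ± SD of K_D per group.

    Grouping is by the ``replicate`` label's group part: replicates of one
    variant should share a label (e.g. "WT", "R89L"). Returns a DataFrame
    with columns variant, n, kd_mean_M, kd_sd_M, rmax_mean_RU.
    """
    import pandas as pd
    rows = []
    for iso in isotherms:
        fit = fit_kd(iso)
        rows.append({"variant": iso.replicate if iso.replicate is not None else "",
                     "kd": fit.kd, "rmax": fit.rmax, "converged": fit.converged})
    df = pd.DataFrame(rows)
    ok = df[df["converged"]]
    out = ok.groupby("variant", sort=True).agg(
        n=("kd", "size"), kd_mean_M=("kd", "mean"), kd_sd_M=("kd", "std"),
        rmax_mean_RU=("rmax", "mean")).reset_index()
    return out
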