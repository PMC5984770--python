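"""Michaelis–Menten kinetics fitting and thermostability activity tables.

Rates v(S) = Vmax·S / (Km + S) are fitted by nonlinear least squares in
log-parameter space (log Km, log Vmax), which keeps both parameters
positive without constraints.  Initialization follows the usual reading of
the curve: Vmax0 is the largest observed rate and Km0 the substrate
concentration at half of it (linear interpolation).  Standard errors are
the asymptotic (Jacobian-based) estimates at the optimum.

Catalytic efficiency kcat/Km is reported in /s/μM at one decimal.  The
turnover number kcat is accepted directly (converting Vmax requires the
enzyme's molar mass, which is an optional input).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares

from .errors import ValidationError


@dataclass
class KineticsDataset:
    """Initial-rate data: substrate concentrations (μM, increasing) and
    rates (μmol/min/mg)."""

    substrate_conc: np.ndarray
    rate: np.ndarray
    enzyme: str = ""

    def __post_init__(self) -> None:
        self.substrate_conc = np.asarray(self.substrate_conc, dtype=float)
        self.rate = np.asarray(self.rate, dtype=float)
        if self.substrate_conc.size != self.rate.size:
            raise ValidationError("conc and rate lengths differ")
        if self.substrate_conc.size < 5:
            raise ValidationError("need >= 5 points")
        if np.any(self.substrate_conc <= 0):
            raise ValidationError("concentrations must be positive")
        if np.any(np.diff(self.substrate_conc) <= 0):
            raise ValidationError("concentrations must be strictly increasing")


@dataclass
class MMFit:
    Km: float                  # μM
    Vmax: float                # μmol/min/mg
    se_Km: float
    se_Vmax: float
    converged: bool
    kcat: float | None = None  # /s, requires molar mass
    kcat_over_Km: float | None = None
    message: str = ""

    def __post_init__(self) -> None:
        if self.converged and not (self.Km > 0 and self.Vmax > 0):
            raise ValidationError("converged fit must have positive parameters")
        if self.kcat is not None:
            self.kcat_over_Km = self.kcat / self.Km


def michaelis_menten(S: np.ndarray, Km: float, Vmax: float) -> np.ndarray:
    S = np.asarray(S, dtype=float)
    return Vmax * S / (Km + S)


def _default_init(data: KineticsDataset) -> tuple[float, float]:
    vmax0 = float(data.rate.max())
    half = vmax0 / 2.0
    S, v = data.substrate_conc, data.rate
    km0 = float(S[np.argmin(np.abs(v - half))])
    # refine by linear interpolation across the half-max crossing
    above = np.nonzero(v >= half)[0]
    if above.size and above[0] > 0:
        i = above[0]
        s0, s1, v0, v1 = S[i - 1], S[i], v[i - 1], v[i]
        if v1 != v0:
            km0 = float(s0 + (half - v0) * (s1 - s0) / (v1 - v0))
    return max(km0, 1e-6), vmax0


def fit_michaelis_menten(data: KineticsDataset,
                         init: tuple[float, float] | None = None,
                         molar_mass: float | None = None) -> MMFit:
    """Fit Km and Vmax by log-parameterized nonlinear least squares.

    With ``molar_mass`` (g/mol) the turnover number kcat = Vmax·M/60·1e-6
    (per second, for Vmax in μmol/min/mg) and kcat/Km are filled in.
    Non-convergence and degenerate inputs return ``converged=False`` with
    the last iterate and a diagnostic message rather than raising.
    """
    if np.any(data.rate < 0):
        raise ValidationError("rates must be non-negative")
    if data.rate.max() <= 0:
        return MMFit(Km=float("nan"), Vmax=float("nan"), se_Km=float("nan"),
                     se_Vmax=float("nan"), converged=False,
                     message="all rates are zero; curve is degenerate")
    km0, vmax0 = init if init is not None else _default_init(data)
    if not (km0 > 0 and vmax0 > 0):
        raise ValidationError("initial Km and Vmax must be positive")
    S, v = data.substrate_conc, data.rate

    def residuals(theta: np.ndarray) -> np.ndarray:
        km, vmax = np.exp(theta)
        return michaelis_menten(S, km, vmax) - v

    res = least_squares(residuals, x0=np.log([km0, vmax0]),
                        method="lm", xtol=1e-12, ftol=1e-12, gtol=1e-12,
                        max_nfev=500 * 3)
    km, vmax = np.exp(res.x)
    # asymptotic covariance in log space, delta-method back to natural scale
    dof = max(S.size - 2, 1)
    s2 = float(2 * res.cost) / dof
    try:
        cov_log = s2 * np.linalg.inv(res.jac.T @ res.jac)
        se_km = float(np.sqrt(cov_log[0, 0]) * km)
        se_vmax = float(np.sqrt(cov_log[1, 1]) * vmax)
    except np.linalg.LinAlgError:
        se_km = se_vmax = float("nan")
    kcat = None
    if molar_mass is not None:
        # μmol/min/mg * g/mol -> /s : (Vmax [μmol/min/mg]) * M [g/mol] * 1e-6 / 60
        kcat = float(vmax * molar_mass * 1e-6 / 60.0)
    fit = MMFit(Km=float(km), Vmax=float(vmax), se_Km=se_km, se_Vmax=se_vmax,
                converged=bool(res.success), kcat=kcat,
                message=str(res.message))
    return fit


def catalytic_efficiency(Km: float, kcat: float,
                         decimals: int | None = 1) -> float:
    """kcat/Km in /s/μM, rounded to reporting precision (1 decimal).

    Pass ``decimals=None`` for the unrounded quotient.
    """
    if not Km > 0:
        raise ValidationError("Km must be > 0")
    eff = kcat / Km
    return round(eff, decimals) if decimals is not None else eff


@dataclass
class ResidualActivityRecord:
    enzyme: str
    temperature: float       # °C
    incubation: float        # minutes
    residual_pct: float      # % of untreated activity
    sd_pct: float = float("nan")

    def __post_init__(self) -> None:
        if self.residual_pct < 0:
            raise ValidationError("residual activity cannot be negative")


def residual_activity(treated: float | Sequence[float],
                      untreated: float | Sequence[float],
                      enzyme: str = "", temperature: float = float("nan"),
                      incubation: float = 60.0) -> ResidualActivityRecord:
    """Residual activity after thermal stress, as % of the untreated assay.

    Replicate inputs yield the mean residual percentage and its sample SD.
    """
    treated_arr = np.atleast_1d(np.asarray(treated, dtype=float))
    untreated_arr = np.atleast_1d(np.asarray(untreated, dtype=float))
    if np.any(untreated_arr <= 0):
        raise ValidationError("untreated activity must be positive")
    if treated_arr.size != untreated_arr.size:
        if untreated_arr.size == 1:
            untreated_arr = np.full_like(treated_arr, untreated_arr[0])
        else:
            raise ValidationError("replicate counts differ")
    pct = 100.0 * treated_arr / untreated_arr
    sd = float(np.std(pct, ddof=1)) if pct.size > 1 else float("nan")
    return ResidualActivityRecord(
        enzyme=enzyme, temperature=temperature, incubation=incubation,
        residual_pct=float(pct.mean()), sd_pct=sd,
    )
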