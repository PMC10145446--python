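"""Supersaturation bookkeeping and first-order precipitation kinetics.

A weak base emptied from the acidic stomach into the neutral intestine is
transiently supersaturated.  Two parameters describe its fate:

* ``CSR`` — critical supersaturation ratio, the critical supersaturation
  concentration (CSC) divided by the equilibrium solubility.  Below the CSC
  the solution is metastable and nothing precipitates.
* ``PRC`` — first-order precipitation rate constant (1/h) applied to the
  excess ``C - S_eq`` once the CSC has been breached.

The CSC acts as a latch: after the dissolved concentration first reaches
``CSR * S_eq``, precipitation continues whenever ``C > S_eq`` even if the
concentration has fallen back below the CSC.  ``CSR = 1`` with a large PRC
reproduces immediate precipitation: the dissolved concentration can never
appreciably exceed the equilibrium solubility.

``estimate_csr_prc`` inverts a measured intestinal concentration–time curve
(e.g. from a two-stage transfer experiment) into these two parameters.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares

from .errors import InsufficientDataError, InvalidInputError

PRC_CEILING_PER_H = 1000.0  # largest admissible first-order rate constant


@dataclass(frozen=True)
class PrecipitationParams:
    CSR: float = 1.0
    PRC_per_h: float = PRC_CEILING_PER_H

    def __post_init__(self) -> None:
        if self.CSR < 1.0:
            raise InvalidInputError("CSR must be >= 1")
        if self.PRC_per_h < 0.0:
            raise InvalidInputError("PRC must be >= 0")


@dataclass
class SupersaturationState:
    """Dissolved concentration vs the local equilibrium solubility."""

    C_mg_mL: float
    S_eq_mg_mL: float
    csc_breached: bool = False

    def __post_init__(self) -> None:
        if self.C_mg_mL < 0:
            raise InvalidInputError("concentration must be >= 0")
        if self.S_eq_mg_mL <= 0:
            raise InvalidInputError("equilibrium solubility must be positive")


def csc(params: PrecipitationParams, S_eq_mg_mL: float) -> float:
    """Critical supersaturation concentration ``CSR * S_eq`` in mg/mL."""
    if S_eq_mg_mL <= 0:
        raise InvalidInputError("S_eq must be positive")
    return params.CSR * S_eq_mg_mL


def precipitation_rate(state: SupersaturationState, params: PrecipitationParams) -> float:
    """Instantaneous precipitation rate in mg/mL/h (updates the latch)."""
    threshold = csc(params, state.S_eq_mg_mL)
    if state.C_mg_mL >= threshold:
        state.csc_breached = True
    if not state.csc_breached or state.C_mg_mL <= state.S_eq_mg_mL:
        return 0.0
    return params.PRC_per_h * (state.C_mg_mL - state.S_eq_mg_mL)


@dataclass(frozen=True)
class PrecipitationEstimate(PrecipitationParams):
    CSC_mg_mL: float = 0.0
    S_eq_mg_mL: float = 0.0
    fit_rmse: float | None = None

    def to_dict(self) -> dict:
        return {"CSR": self.CSR, "PRC": self.PRC_per_h, "CSC": self.CSC_mg_mL,
                "S_eq": self.S_eq_mg_mL, "fit_rmse": self.fit_rmse}


def estimate_csr_prc(t_min: Sequence[float], conc_mg_mL: Sequence[float],
                     S_eq_mg_mL: float, prc_ceiling_per_h: float = PRC_CEILING_PER_H,
                     exceed_rtol: float = 0.02) -> PrecipitationEstimate:
    """Estimate (CSR, PRC) from an intestinal concentration–time curve.

    If the curve never meaningfully exceeds the equilibrium solubility
    (within ``exceed_rtol`` relative, an allowance for assay noise and
    solver tolerance), the drug precipitated as fast as it arrived:
    ``CSR = 1`` and PRC is reported at the ceiling.  Otherwise the CSC is
    the observed peak, CSR follows by definition, and PRC is fitted by
    least squares to the first-order relaxation of the post-peak excess
    ``C(t) = S_eq + (C_peak - S_eq) * exp(-PRC * (t - t_peak))``.
    """
    t = np.asarray(t_min, dtype=float)
    c = np.asarray(conc_mg_mL, dtype=float)
    if S_eq_mg_mL <= 0:
        raise InvalidInputError("S_eq must be positive")
    if t.shape != c.shape or t.size == 0:
        raise InvalidInputError("need matching, nonempty time/concentration arrays")
    c_max = float(np.max(c))
    if c_max <= S_eq_mg_mL * (1.0 + exceed_rtol):
        return PrecipitationEstimate(CSR=1.0, PRC_per_h=prc_ceiling_per_h,
                                     CSC_mg_mL=S_eq_mg_mL, S_eq_mg_mL=S_eq_mg_mL)
    i_peak = int(np.argmax(c))
    csr = c_max / S_eq_mg_mL
    post_t = (t[i_peak:] - t[i_peak]) / 60.0  # hours since peak
    post_c = c[i_peak:]
    if post_t.size < 3:
        raise InsufficientDataError("need >= 3 points from the peak onward to fit PRC")
    excess0 = c_max - S_eq_mg_mL

    def residual(theta: np.ndarray) -> np.ndarray:
        prc = theta[0]
        return S_eq_mg_mL + excess0 * np.exp(-prc * post_t) - post_c

    sol = least_squares(residual, x0=np.array([1.0]), bounds=(0.0, prc_ceiling_per_h))
    prc = float(sol.x[0])
    rmse = float(np.sqrt(np.mean(sol.fun**2)))
    return PrecipitationEstimate(CSR=float(csr), PRC_per_h=prc, CSC_mg_mL=c_max,
                                 S_eq_mg_mL=S_eq_mg_mL, fit_rmse=rmse)
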