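"""pH- and bile-salt-dependent equilibrium solubility of an ionizable drug.

The aqueous part follows the Henderson–Hasselbalch description: total
solubility is the intrinsic (neutral-species) solubility ``S0`` multiplied by
``1 + sum of ionized/neutral ratios``.  For an ampholyte with a basic pKa
``pKa_b`` and an acidic pKa ``pKa_a`` the ratio term is
``10**(pKa_b - pH) + 10**(pH - pKa_a)``.

Bile-salt micelles add a second reservoir.  The micelle-bound amount at
saturation is taken proportional to each dissolved species concentration,
with separate micelle:water partition coefficients for the neutral and the
ionized species (``logKmw_neutral``, ``logKmw_ion``) and the bile-salt
concentration expressed as a mole fraction against water (55.5 mol/L):

    S_total = S_aq(pH)
            + [BS]/55.5 * S0 * (10**logKmw_neutral
                                + 10**logKmw_ion * ionized_ratio(pH))

Calibration helpers estimate ``S0`` from bile-free buffers (closed-form
single-parameter least squares) and the two partition coefficients from
biorelevant media (FaSSGF/FaSSIF/FeSSIF-style fluids).
"""

from __future__ import annotations

import io
import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .errors import InvalidInputError, UnderdeterminedError, UnderdeterminedWarning

WATER_MOLARITY = 55.5  # mol/L, fixed; bile-salt input in mM is converted internally

SpeciesType = Literal["ampholyte", "monoprotic_base", "monoprotic_acid", "neutral"]


@dataclass(frozen=True)
class IonizationSpec:
    """Ionization constants of the drug.

    For an ampholyte both pKa values are used; for a monoprotic base or acid
    only the corresponding one enters the solubility ratio.
    """

    pka_acid: float = math.inf
    pka_base: float = -math.inf
    species_type: SpeciesType = "ampholyte"

    def __post_init__(self) -> None:
        if self.species_type == "ampholyte":
            if not (math.isfinite(self.pka_acid) and math.isfinite(self.pka_base)):
                raise InvalidInputError("ampholyte requires finite pKa_acid and pKa_base")
            if self.pka_acid <= self.pka_base:
                raise InvalidInputError("ampholyte requires pKa_acid > pKa_base")

    def ionized_ratio(self, pH):
        """Total ionized:neutral concentration ratio at a given pH."""
        pH = np.asarray(pH, dtype=float)
        base = 10.0 ** (self.pka_base - pH)
        acid = 10.0 ** (pH - self.pka_acid)
        if self.species_type == "ampholyte":
            return base + acid
        if self.species_type == "monoprotic_base":
            return base
        if self.species_type == "monoprotic_acid":
            return acid
        return np.zeros_like(pH)


@dataclass(frozen=True)
class SolubilityParams:
    """Equilibrium-solubility parameters: intrinsic solubility and bile partition."""

    S0: float  # mg/mL, neutral species
    logKmw_neutral: float = -math.inf
    logKmw_ion: float = -math.inf
    water_molarity: float = WATER_MOLARITY

    def __post_init__(self) -> None:
        if not (np.isfinite(self.S0) and self.S0 > 0):
            raise InvalidInputError(f"S0 must be positive and finite, got {self.S0}")
        if self.water_molarity <= 0:
            raise InvalidInputError("water_molarity must be positive")


@dataclass(frozen=True)
class Medium:
    """A dissolution medium: label, pH, bile-salt content and volume."""

    name: str
    pH: float
    bile_salt_mM: float = 0.0
    volume_mL: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 < self.pH < 14.0:
            raise InvalidInputError(f"pH {self.pH} outside (0, 14)")
        if self.bile_salt_mM < 0:
            raise InvalidInputError("bile_salt_mM must be >= 0")
        if self.volume_mL < 0:
            raise InvalidInputError("volume_mL must be >= 0")


#: Measured shake-flask equilibrium solubilities of albendazole at 37 °C
#: (mean ± SD of triplicates) in buffered aqueous systems and biorelevant media.
ABZ_SOLUBILITY_MEASUREMENTS: tuple[tuple[str, float, float, float, float], ...] = (
    ("pH 1.2 HCl buffer", 1.2, 0.0, 0.515, 0.045),
    ("pH 2.0 HCl buffer", 2.0, 0.0, 0.025, 0.005),
    ("pH 4.5 acetate buffer", 4.5, 0.0, 0.008, 0.002),
    ("pH 6.8 phosphate buffer", 6.8, 0.0, 0.005, 0.001),
    ("FaSSGF", 1.6, 0.08, 0.146, 0.012),
    ("FaSSIF", 6.5, 3.0, 0.008, 0.001),
    ("FeSSIF", 5.0, 15.0, 0.021, 0.004),
)

TABLE_COLUMNS = ["medium", "pH", "bile_mM", "solubility_mg_per_mL", "sd"]


class SolubilityTable:
    """Tabulated measured solubilities, one row per medium (or replicate)."""

    def __init__(self, frame: pd.DataFrame):
        missing = [c for c in TABLE_COLUMNS[:4] if c not in frame.columns]
        if missing:
            raise InvalidInputError(f"solubility table missing columns: {missing}")
        if "sd" not in frame.columns:
            frame = frame.assign(sd=np.nan)
        if (frame["solubility_mg_per_mL"] <= 0).any():
            raise InvalidInputError("measured solubilities must be positive")
        self.frame = frame.reset_index(drop=True)

    @classmethod
    def reference_abz(cls) -> "SolubilityTable":
        return cls(pd.DataFrame(ABZ_SOLUBILITY_MEASUREMENTS, columns=TABLE_COLUMNS))

    @classmethod
    def from_rows(cls, rows: Iterable[Sequence]) -> "SolubilityTable":
        return cls(pd.DataFrame(list(rows), columns=TABLE_COLUMNS))

    @classmethod
    def read_csv(cls, path) -> "SolubilityTable":
        return cls(pd.read_csv(path))

    def to_csv(self, path_or_buf=None):
        return self.frame.to_csv(path_or_buf, index=False)

    def bile_free(self) -> "SolubilityTable":
        return SolubilityTable(self.frame[self.frame["bile_mM"] == 0.0])

    def biorelevant(self) -> "SolubilityTable":
        return SolubilityTable(self.frame[self.frame["bile_mM"] > 0.0])

    def collapsed(self) -> pd.DataFrame:
        """Replicates collapsed to their mean per (pH, bile) condition."""
        return (
            self.frame.groupby(["medium", "pH", "bile_mM"], as_index=False)
            .agg(solubility_mg_per_mL=("solubility_mg_per_mL", "mean"), sd=("sd", "mean"))
            .sort_values(["bile_mM", "pH"], kind="stable")
            .reset_index(drop=True)
        )

    def __len__(self) -> int:
        return len(self.frame)

    def __repr__(self) -> str:
        buf = io.StringIO()
        self.frame.to_string(buf, index=False)
        return f"SolubilityTable(\n{buf.getvalue()}\n)"


def aqueous_solubility(pH, ion: IonizationSpec, S0: float):
    """Henderson–Hasselbalch aqueous solubility, mg/mL.

    ``S0 * (1 + ionized_ratio(pH))``; never below the intrinsic solubility.
    """
    pH_arr = np.asarray(pH, dtype=float)
    if not np.all(np.isfinite(pH_arr)):
        raise InvalidInputError("pH must be finite")
    if not (np.isfinite(S0) and S0 > 0):
        raise InvalidInputError("S0 must be positive and finite")
    out = S0 * (1.0 + ion.ionized_ratio(pH_arr))
    return float(out) if np.isscalar(pH) or np.ndim(pH) == 0 else out


def micellar_solubility(pH, bile_salt_mM, ion: IonizationSpec, params: SolubilityParams):
    """Bile-micelle-bound contribution to total solubility, mg/mL."""
    bile = np.asarray(bile_salt_mM, dtype=float)
    if np.any(bile < 0):
        raise InvalidInputError("bile_salt_mM must be >= 0")
    frac = bile / 1000.0 / params.water_molarity  # mole fraction vs water
    kn = 10.0 ** params.logKmw_neutral if np.isfinite(params.logKmw_neutral) else 0.0
    ki = 10.0 ** params.logKmw_ion if np.isfinite(params.logKmw_ion) else 0.0
    out = frac * params.S0 * (kn + ki * ion.ionized_ratio(np.asarray(pH, dtype=float)))
    return float(out) if np.ndim(out) == 0 else out


def total_solubility(medium: Medium | None, ion: IonizationSpec, params: SolubilityParams,
                     *, pH: float | None = None, bile_salt_mM: float | None = None):
    """Aqueous plus micelle-bound equilibrium solubility in a medium, mg/mL.

    Accepts either a :class:`Medium` or explicit ``pH=``/``bile_salt_mM=``.
    Reduces to :func:`aqueous_solubility` at zero bile and is monotone
    non-decreasing in the bile-salt concentration.
    """
    if medium is not None:
        pH, bile_salt_mM = medium.pH, medium.bile_salt_mM
    if pH is None or bile_salt_mM is None:
        raise InvalidInputError("need a Medium or explicit pH and bile_salt_mM")
    return aqueous_solubility(pH, ion, params.S0) + micellar_solubility(pH, bile_salt_mM, ion, params)


@dataclass(frozen=True)
class SolubilityFit:
    """Result of a solubility-model calibration."""

    S0: float
    logKmw_neutral: float | None
    logKmw_ion: float | None
    r_squared: float
    scale: str
    residuals: np.ndarray = field(repr=False, default_factory=lambda: np.empty(0))

    def to_dict(self) -> dict:
        return {
            "S0": self.S0,
            "logKmw_neutral": self.logKmw_neutral,
            "logKmw_ion": self.logKmw_ion,
            "r_squared": self.r_squared,
            "scale": self.scale,
        }


def _r_squared(y: np.ndarray, pred: np.ndarray) -> float:
    ss_res = float(np.sum((y - pred) ** 2))
    ss_tot = float(np.sum((y - np.mean(y)) ** 2))
    return 1.0 - ss_res / ss_tot


def fit_intrinsic_solubility(table: SolubilityTable, ion: IonizationSpec,
                             scale: Literal["linear", "log"] = "linear") -> SolubilityFit:
    """Estimate the intrinsic solubility from bile-free pH/solubility data.

    With the pKa values held fixed the model is linear in ``S0`` and the
    linear-scale least-squares solution is closed form:
    ``S0 = sum(f_i * y_i) / sum(f_i**2)`` with ``f_i = 1 + ionized_ratio(pH_i)``.
    The log-scale variant (geometric-mean estimator) is available because the
    choice of objective scale visibly changes the estimate on real data.
    """
    data = table.collapsed()
    if (data["bile_mM"] > 0).any():
        raise InvalidInputError("fit_intrinsic_solubility expects bile-free media only")
    if len(data) < 2:
        raise UnderdeterminedError("need at least 2 bile-free media to fit S0")
    pH = data["pH"].to_numpy()
    y = data["solubility_mg_per_mL"].to_numpy()
    f = 1.0 + ion.ionized_ratio(pH)
    if scale == "linear":
        S0 = float(np.sum(f * y) / np.sum(f * f))
        pred = S0 * f
        r2 = _r_squared(y, pred)
        resid = y - pred
    elif scale == "log":
        S0 = float(np.exp(np.mean(np.log(y) - np.log(f))))
        pred = S0 * f
        r2 = _r_squared(np.log(y), np.log(pred))
        resid = np.log(y) - np.log(pred)
    else:
        raise InvalidInputError(f"unknown scale {scale!r}")
    return SolubilityFit(S0=S0, logKmw_neutral=None, logKmw_ion=None,
                         r_squared=r2, scale=scale, residuals=resid)


def fit_bile_partition(table: SolubilityTable, ion: IonizationSpec, S0: float,
                       scale: Literal["linear", "log"] = "linear") -> SolubilityFit:
    """Estimate micelle:water partition coefficients from biorelevant media.

    ``S0`` and the pKa values are held fixed; the two log partition
    coefficients are fitted by least squares on the chosen concentration
    scale.  With a single distinct bile concentration the two coefficients
    are not separable and only the neutral coefficient is fitted (a
    warning is emitted).
    """
    data = table.collapsed()
    data = data[data["bile_mM"] > 0]
    if len(data) < 2:
        raise UnderdeterminedError("need at least 2 biorelevant media")
    pH = data["pH"].to_numpy()
    bile = data["bile_mM"].to_numpy()
    y = data["solubility_mg_per_mL"].to_numpy()
    single_bile = len(np.unique(bile)) < 2
    if single_bile:
        warnings.warn("single bile concentration: fitting neutral coefficient only",
                      UnderdeterminedWarning, stacklevel=2)

    def predict(logkn: float, logki: float) -> np.ndarray:
        p = SolubilityParams(S0=S0, logKmw_neutral=logkn, logKmw_ion=logki)
        return aqueous_solubility(pH, ion, S0) + micellar_solubility(pH, bile, ion, p)

    def residual(theta: np.ndarray) -> np.ndarray:
        logkn = theta[0]
        logki = theta[1] if not single_bile else -np.inf
        pred = predict(logkn, logki)
        if scale == "log":
            return np.log(np.maximum(pred, 1e-300)) - np.log(y)
        return pred - y

    x0 = np.array([3.0]) if single_bile else np.array([3.0, 5.0])
    lo = -2.0 * np.ones_like(x0)
    hi = 9.0 * np.ones_like(x0)
    sol = least_squares(residual, x0, bounds=(lo, hi), xtol=1e-14, ftol=1e-14)
    logkn = float(sol.x[0])
    logki = None if single_bile else float(sol.x[1])
    pred = predict(logkn, logki if logki is not None else -np.inf)
    r2 = _r_squared(np.log(y), np.log(pred)) if scale == "log" else _r_squared(y, pred)
    return SolubilityFit(S0=S0, logKmw_neutral=logkn, logKmw_ion=logki,
                         r_squared=r2, scale=scale, residuals=np.asarray(sol.fun))
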