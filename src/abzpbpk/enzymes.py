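"""Michaelis–Menten enzyme kinetics and in vitro → in vivo scaling helpers."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import InvalidInputError


@dataclass(frozen=True)
class EnzymeKinetics:
    """One enzymatic pathway: turnover kinetics plus total organ abundance.

    ``vmax`` is per pmol of enzyme (pmol substrate/min/pmol enzyme);
    ``abundance_pmol`` is the total amount of enzyme in the organ of
    interest (for liver: abundance per mg microsomal protein x MPPGL x
    liver mass).
    """

    name: str
    vmax_pmol_min_pmol: float
    km_uM: float
    abundance_pmol: float

    def __post_init__(self) -> None:
        if min(self.vmax_pmol_min_pmol, self.km_uM) <= 0 or self.abundance_pmol < 0:
            raise InvalidInputError("enzyme kinetics require positive Vmax/Km and abundance >= 0")


def metabolism_rate_mg_h(enzymes: Sequence[EnzymeKinetics], c_unbound_uM: float,
                         mw_g_mol: float) -> float:
    """Summed Michaelis–Menten metabolic rate at an unbound concentration."""
    cu = max(float(c_unbound_uM), 0.0)
    v_pmol_min = sum(e.vmax_pmol_min_pmol * e.abundance_pmol * cu / (e.km_uM + cu)
                     for e in enzymes)
    return v_pmol_min * 60.0 * mw_g_mol * 1e-9  # pmol/min -> mg/h


def intrinsic_clearance_L_h(enzymes: Sequence[EnzymeKinetics],
                            c_unbound_uM: float = 0.0) -> float:
    """Unbound intrinsic clearance sum(Vmax*abund/(Km + Cu)), in L/h.

    At ``c_unbound_uM = 0`` this is the linear limit sum(Vmax/Km) scaled by
    abundance; at high concentrations it falls toward the Vmax-limited
    plateau.
    """
    cu = max(float(c_unbound_uM), 0.0)
    ul_min = sum(e.vmax_pmol_min_pmol * e.abundance_pmol / (e.km_uM + cu) for e in enzymes)
    return ul_min * 60.0 / 1e6  # µL/min -> L/h
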