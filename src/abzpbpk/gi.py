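"""Multi-segment gastrointestinal transit, dissolution, precipitation and uptake.

A compartmental absorption model in the ACAT/ADAM tradition: an ordered
chain of well-mixed luminal segments (stomach, seven small-intestinal
segments, colon), each with its own pH, bile-salt level, fluid volume and
mean transit time.  In every segment the drug is partitioned between an
unreleased dose form, polydisperse solid particle bins, dissolved drug and
a precipitate pool.  Processes:

* first-order transit of all species down the chain (stomach empties at
  ``1/MRT``; colon exits to an unabsorbed-outflow ledger),
* optional first-order release (wetting/disintegration) of the dose form,
* diffusion-layer dissolution of each particle bin against the segment's
  bile-aware equilibrium solubility,
* supersaturation-latched first-order precipitation (intestinal segments),
  with optional redissolution of precipitate as fine particles,
* passive uptake into a lumped enterocyte compartment at
  ``ka = 2 * Peff / R`` (no uptake from the stomach; reduced colonic
  permeability), followed by gut-wall Michaelis–Menten metabolism in
  competition with villous blood flow to the portal vein,
* first-order luminal degradation of dissolved drug in the intestine.

``fa`` is the fraction of the dose entering the enterocyte; ``fg`` the
fraction of that which escapes gut-wall metabolism.  Everything is a pure
exchange between pools, so total mass is conserved to solver tolerance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from ._ode import probe_sparsity, solve_stiff

from .enzymes import EnzymeKinetics, metabolism_rate_mg_h
from .errors import InvalidInputError
from .particles import (DLMParams, WeibullPSD, bin_mass_mg, discretize_psd,
                        dissolution_rates_mg_h, monodisperse_bins)
from .precipitation import PrecipitationParams
from .solubility import IonizationSpec, SolubilityParams, total_solubility


@dataclass(frozen=True)
class Segment:
    name: str
    pH: float
    bile_mM: float
    volume_mL: float
    radius_cm: float
    transit_h: float
    absorbing: bool = True
    peff_scale: float = 1.0
    precipitating: bool = True
    lumen_degrading: bool = True

    def __post_init__(self) -> None:
        if self.transit_h <= 0:
            raise InvalidInputError("transit time must be positive")
        if not 1.0 < self.pH < 9.0:
            raise InvalidInputError(f"segment pH {self.pH} outside (1, 9)")


# Fasted-state defaults: small-intestinal pH rising 6.0 -> 7.4, bile salts
# tapering 3 -> 0.5 mM, total SI transit 3.3 h.  Static fluid volumes
# (total SI fluid 426 mL) stand in for dynamic secretion/reabsorption and
# were calibrated, together with the colonic absorption parameters, against
# the clinical verification dataset (middle-out; see the methods note).
_SI_TEMPLATE = (
    # name,        pH,  bile, V_mL, R_cm, T_h
    ("duodenum",   6.0, 3.0,  33.0, 1.25, 0.26),
    ("jejunum I",  6.2, 2.0, 112.0, 1.25, 0.80),
    ("jejunum II", 6.4, 1.5,  92.0, 1.25, 0.70),
    ("ileum I",    6.6, 1.0,  66.0, 1.25, 0.55),
    ("ileum II",   6.9, 0.8,  53.0, 1.25, 0.45),
    ("ileum III",  7.1, 0.6,  40.0, 1.25, 0.30),
    ("ileum IV",   7.4, 0.5,  30.0, 1.25, 0.24),
)


@dataclass(frozen=True)
class GIPhysiology:
    """Gastrointestinal physiology; gastric pH and MRT are first-class knobs."""

    gastric_pH: float = 1.5
    gastric_MRT_h: float = 0.4
    gastric_volume_mL: float = 250.0  # dose taken with a glass of water
    colon_pH: float = 6.5
    colon_volume_mL: float = 100.0
    colon_transit_h: float = 17.0
    colon_peff_scale: float = 0.45
    si_segments: tuple = _SI_TEMPLATE

    def build_segments(self) -> list[Segment]:
        segs = [Segment("stomach", self.gastric_pH, 0.0, self.gastric_volume_mL,
                        radius_cm=10.0, transit_h=self.gastric_MRT_h, absorbing=False,
                        precipitating=False, lumen_degrading=False)]
        for name, pH, bile, v, r, t in self.si_segments:
            segs.append(Segment(name, pH, bile, v, r, t))
        segs.append(Segment("colon", self.colon_pH, 0.0, self.colon_volume_mL,
                            radius_cm=2.5, transit_h=self.colon_transit_h,
                            peff_scale=self.colon_peff_scale))
        return segs


@dataclass(frozen=True)
class FormulationParams:
    """Dose amount and particle presentation of the administered form."""

    dose_mg: float = 400.0
    psd: WeibullPSD | None = field(default_factory=lambda: WeibullPSD(1.014, 8.732))
    monodisperse_radius_um: float | None = None
    release_rate_per_h: float | None = 6.0  # first-order wetting/disintegration
    n_bins: int = 6


@dataclass(frozen=True)
class DrugAbsorptionParams:
    """Permeability, gut-wall metabolism and luminal-stability parameters."""

    peff_1e4_cm_s: float = 8.03          # effective human jejunal permeability
    fu_gut: float = 1.0
    lumen_clint_uL_h_g: float = 2000.0   # vs dissolved drug, per g luminal content
    gut_enzymes: tuple[EnzymeKinetics, ...] = ()
    enterocyte_volume_L: float = 0.3
    villous_flow_L_h: float = 18.0
    stomach_absorption: bool = False

    def __post_init__(self) -> None:
        if self.peff_1e4_cm_s < 0:
            raise InvalidInputError("Peff must be >= 0")
        if not 0 < self.fu_gut <= 1:
            raise InvalidInputError("fu_gut must lie in (0, 1]")

    def ka_per_h(self, seg: Segment) -> float:
        if not seg.absorbing or (seg.name == "stomach" and not self.stomach_absorption):
            return 0.0
        peff_cm_s = self.peff_1e4_cm_s * 1e-4 * seg.peff_scale
        return 2.0 * peff_cm_s / seg.radius_cm * 3600.0


@dataclass
class GIOptions:
    precipitate_redissolves: bool = False
    precipitate_radius_um: float = 10.0
    t_end_h: float = 48.0
    rtol: float = 1e-8
    n_eval: int = 481


@dataclass
class GIResult:
    times_h: np.ndarray
    portal_flux_mg_h: np.ndarray          # parent flux into the portal vein
    gut_metabolite_flux_mg_h: np.ndarray  # parent mass metabolized in the gut wall
    fa: float
    fg: float
    absorbed_mg: float
    gut_metabolized_mg: float
    lumen_degraded_mg: float
    unabsorbed_outflow_mg: float
    mass_balance_error_mg: float
    segment_dissolved: pd.DataFrame | None = None


class GIModel:
    """Assembled right-hand side of the luminal + enterocyte ODE system.

    The state vector is, in order: unreleased dose U (per segment), solid
    bin masses M (segment x bin), solid bin counts N, dissolved D,
    precipitate P, then the enterocyte amount and five cumulative ledgers
    (entered enterocyte, gut metabolized, lumen degraded, colon outflow of
    dissolved drug, colon outflow of everything solid).
    """

    def __init__(self, physiology: GIPhysiology, sol: SolubilityParams, ion: IonizationSpec,
                 formulation: FormulationParams, dlm: DLMParams, precip: PrecipitationParams,
                 absorb: DrugAbsorptionParams, mw_g_mol: float,
                 options: GIOptions | None = None):
        self.opts = options or GIOptions()
        self.segments = physiology.build_segments()
        self.ns = len(self.segments)
        self.dlm = dlm
        self.precip = precip
        self.absorb = absorb
        self.mw = mw_g_mol
        self.formulation = formulation
        dose = formulation.dose_mg
        if dose < 0:
            raise InvalidInputError("dose must be >= 0")
        if formulation.monodisperse_radius_um is not None:
            bins = monodisperse_bins(formulation.monodisperse_radius_um, max(dose, 1.0),
                                     dlm.density_g_cm3)
        elif formulation.psd is not None:
            bins = discretize_psd(formulation.psd, max(dose, 1.0), dlm.density_g_cm3,
                                  formulation.n_bins)
        else:
            raise InvalidInputError("formulation needs a psd or a monodisperse radius")
        scale = dose / max(dose, 1.0)
        self.nb = len(bins)
        self.r0 = np.array([b.r0_cm for b in bins])
        self.m_init = np.array([b.mass_mg(dlm.density_g_cm3) for b in bins]) * scale
        self.N_init = np.array([b.N for b in bins]) * scale
        self.m0_particle = bin_mass_mg(1.0, self.r0, dlm.density_g_cm3)
        self.w = self.m_init / dose if dose > 0 else np.full(self.nb, 1.0 / self.nb)

        self.S_eq = np.array([total_solubility(None, ion, sol, pH=s.pH, bile_salt_mM=s.bile_mM)
                              for s in self.segments])
        self.ka = np.array([absorb.ka_per_h(s) for s in self.segments])
        self.kt = np.array([1.0 / s.transit_h for s in self.segments])
        self.V = np.array([s.volume_mL for s in self.segments])
        self.kdeg = np.array([absorb.lumen_clint_uL_h_g * 1e-3 * s.volume_mL
                              if s.lumen_degrading else 0.0 for s in self.segments])  # mL/h
        self.precipitating = np.array([s.precipitating for s in self.segments])
        # per-mass redissolution coefficient of the (fixed-radius) precipitate
        r_p = self.opts.precipitate_radius_um * 1e-4
        h_p = min(r_p, dlm.h_cap_um * 1e-4)
        per_particle = dlm.S_scalar * 4.0 * np.pi * dlm.D_eff_cm2_s * r_p * (r_p + h_p) / h_p * 3600.0
        self.k_redissolve = per_particle / bin_mass_mg(1.0, r_p, dlm.density_g_cm3)  # 1/h per mg/mL
        self.eps = max(dose, 1.0) * 1e-9
        self.csc = precip.CSR * self.S_eq

        ns, nb = self.ns, self.nb
        self.iU = slice(0, ns)
        self.iM = slice(ns, ns + ns * nb)
        self.iN = slice(ns + ns * nb, ns + 2 * ns * nb)
        self.iD = slice(ns + 2 * ns * nb, 2 * ns + 2 * ns * nb)
        self.iP = slice(2 * ns + 2 * ns * nb, 3 * ns + 2 * ns * nb)
        base = 3 * ns + 2 * ns * nb
        self.i_ent = base
        self.i_entered = base + 1
        self.i_gutmet = base + 2
        self.i_deg = base + 3
        self.i_out_diss = base + 4
        self.i_out_solid = base + 5
        self.n_states = base + 6

    def probe_states(self, n_extra: int = 0) -> list[np.ndarray]:
        """All-positive states in the sub- and supersaturated regimes, used to
        derive a structural Jacobian sparsity pattern (appended systemic
        states, if any, are set positive too)."""
        probes = []
        for sat in (0.1, 10.0):
            y = np.ones(self.n_states + n_extra)
            M = np.ones((self.ns, self.nb))
            N = M / self.m0_particle[None, :]
            y[self.iM] = M.ravel()
            y[self.iN] = N.ravel()
            y[self.iD] = sat * self.S_eq * self.V
            probes.append(y)
        return probes

    def initial_state(self) -> np.ndarray:
        y = np.zeros(self.n_states)
        if self.formulation.release_rate_per_h is None:
            M = np.zeros((self.ns, self.nb)); N = np.zeros((self.ns, self.nb))
            M[0] = self.m_init; N[0] = self.N_init
            y[self.iM] = M.ravel(); y[self.iN] = N.ravel()
        else:
            y[self.iU.start] = self.formulation.dose_mg
        return y

    # -- right-hand side -------------------------------------------------
    def rhs(self, t: float, y: np.ndarray, latched: np.ndarray) -> np.ndarray:
        ns, nb = self.ns, self.nb
        U = y[self.iU]
        M = y[self.iM].reshape(ns, nb)
        N = y[self.iN].reshape(ns, nb)
        D = y[self.iD]
        P = y[self.iP]
        A_ent = y[self.i_ent]
        dy = np.zeros_like(y)
        dU = np.zeros(ns); dM = np.zeros((ns, nb)); dN = np.zeros((ns, nb))
        dD = np.zeros(ns); dP = np.zeros(ns)

        krel = self.formulation.release_rate_per_h
        if krel is not None:
            rel = krel * np.maximum(U, 0.0)
            dU -= rel
            dM += rel[:, None] * self.w[None, :]
            dN += rel[:, None] * (self.w / self.m0_particle)[None, :]

        C = np.maximum(D, 0.0) / self.V
        diss = dissolution_rates_mg_h(M, N, self.S_eq[:, None], C[:, None], self.dlm, self.eps)
        dM -= diss
        dD += diss.sum(axis=1)

        # precipitation above solubility once the CSC latch is set
        excess = np.maximum(C - self.S_eq, 0.0)
        active = self.precipitating & (latched | (self.precip.CSR <= 1.0))
        prate = np.where(active, self.precip.PRC_per_h * excess * self.V, 0.0)
        dD -= prate
        dP += prate
        if self.opts.precipitate_redissolves:
            deficit = np.maximum(self.S_eq - C, 0.0)
            soft = P * P / (P * P + self.eps * self.eps)
            rrate = self.k_redissolve * np.maximum(P, 0.0) * deficit * soft
            dP -= rrate
            dD += rrate

        # uptake into the enterocyte and luminal degradation
        J = self.ka * np.maximum(D, 0.0)
        deg = self.kdeg * C
        dD -= J + deg

        # transit down the chain; colon exits to the outflow ledgers
        fU = self.kt * U; fD = self.kt * D; fP = self.kt * P
        fM = self.kt[:, None] * M; fN = self.kt[:, None] * N
        dU -= fU; dD -= fD; dP -= fP; dM -= fM; dN -= fN
        dU[1:] += fU[:-1]; dD[1:] += fD[:-1]; dP[1:] += fP[:-1]
        dM[1:] += fM[:-1]; dN[1:] += fN[:-1]

        cu_uM = self.absorb.fu_gut * (A_ent / self.absorb.enterocyte_volume_L) / self.mw * 1000.0
        gutmet = metabolism_rate_mg_h(self.absorb.gut_enzymes, cu_uM, self.mw)
        kout = self.absorb.villous_flow_L_h / self.absorb.enterocyte_volume_L
        portal = kout * max(A_ent, 0.0)

        dy[self.iU] = dU
        dy[self.iM] = dM.ravel()
        dy[self.iN] = dN.ravel()
        dy[self.iD] = dD
        dy[self.iP] = dP
        dy[self.i_ent] = J.sum() - portal - gutmet
        dy[self.i_entered] = J.sum()
        dy[self.i_gutmet] = gutmet
        dy[self.i_deg] = deg.sum()
        dy[self.i_out_diss] = fD[-1]
        dy[self.i_out_solid] = fU[-1] + fP[-1] + fM[-1].sum()
        return dy

    def portal_flux(self, y: np.ndarray) -> float:
        kout = self.absorb.villous_flow_L_h / self.absorb.enterocyte_volume_L
        return kout * max(float(y[self.i_ent]), 0.0)

    def gut_metabolism_flux(self, y: np.ndarray) -> float:
        cu = self.absorb.fu_gut * (float(y[self.i_ent]) / self.absorb.enterocyte_volume_L) / self.mw * 1000.0
        return metabolism_rate_mg_h(self.absorb.gut_enzymes, cu, self.mw)

    def luminal_total(self, y: np.ndarray) -> float:
        return float(y[self.iU].sum() + y[self.iM].sum() + y[self.iD].sum() + y[self.iP].sum())


def _integrate_with_latches(model: GIModel, rhs, y0: np.ndarray, t_end: float,
                            rtol: float, atol: float, jac_sparsity=None):
    """Piecewise integration restarting whenever a segment breaches its CSC."""
    latched = np.zeros(model.ns, dtype=bool)
    need_latch = model.precip.CSR > 1.0
    segments = []
    t, y = 0.0, y0

    def make_event(i):
        def ev(tt, yy, *args):
            return yy[model.iD][i] / model.V[i] - model.csc[i]
        ev.terminal = True
        ev.direction = 1
        return ev

    while t < t_end - 1e-12:
        events = []
        idx_map = []
        if need_latch:
            for i in range(model.ns):
                if model.precipitating[i] and not latched[i]:
                    events.append(make_event(i))
                    idx_map.append(i)
        sol = solve_stiff(rhs, (t, t_end), y, args=(latched,),
                          events=events or None, rtol=rtol, atol=atol,
                          jac_sparsity=jac_sparsity)
        if not sol.success:
            raise RuntimeError(f"GI ODE failed at t={t}: {sol.message}")
        segments.append((sol.sol, t, sol.t[-1]))
        t, y = sol.t[-1], sol.y[:, -1]
        if events:
            for k, te in enumerate(sol.t_events):
                if te.size:
                    latched[idx_map[k]] = True
    return segments, y


def simulate_gi(physiology: GIPhysiology, sol: SolubilityParams, ion: IonizationSpec,
                formulation: FormulationParams, dlm: DLMParams, precip: PrecipitationParams,
                absorb: DrugAbsorptionParams, mw_g_mol: float,
                options: GIOptions | None = None, keep_trajectory: bool = False) -> GIResult:
    """Run the luminal model alone and report fa, fg and the portal-flux series."""
    model = GIModel(physiology, sol, ion, formulation, dlm, precip, absorb, mw_g_mol, options)
    opts = model.opts
    y0 = model.initial_state()
    dose = formulation.dose_mg
    atol = max(dose, 1.0) * 1e-12

    def rhs(t, y, latched):
        return model.rhs(t, y, latched)

    all_latched = np.ones(model.ns, dtype=bool)
    sparsity = probe_sparsity(rhs, model.probe_states(), args=(all_latched,))
    segs, y_end = _integrate_with_latches(model, rhs, y0, opts.t_end_h, opts.rtol, atol,
                                          jac_sparsity=sparsity)
    times = np.linspace(0.0, opts.t_end_h, opts.n_eval)

    def state_at(t):
        for interp, t0, t1 in segs:
            if t0 - 1e-9 <= t <= t1 + 1e-9:
                return interp(np.clip(t, t0, t1))
        return segs[-1][0](segs[-1][2])

    states = np.column_stack([state_at(t) for t in times])
    portal = np.array([model.portal_flux(states[:, k]) for k in range(times.size)])
    gutflux = np.array([model.gut_metabolism_flux(states[:, k]) for k in range(times.size)])

    entered = float(y_end[model.i_entered])
    gutmet = float(y_end[model.i_gutmet])
    fa = entered / dose if dose > 0 else 0.0
    fg = 1.0 - gutmet / entered if entered > 0 else 1.0
    # mass balance: lumen + enterocyte + (portal out = entered - gutmet - A_ent)
    # + gut metabolized + degraded + colon outflow must equal the dose
    balance = (model.luminal_total(y_end) + float(y_end[model.i_ent])
               + (entered - gutmet - float(y_end[model.i_ent]))
               + gutmet + float(y_end[model.i_deg])
               + float(y_end[model.i_out_diss]) + float(y_end[model.i_out_solid]))
    traj = None
    if keep_trajectory:
        ns = model.ns
        rows = []
        for k, t in enumerate(times):
            D = states[model.iD, k]
            for i, s in enumerate(model.segments):
                rows.append((t, s.name, D[i], D[i] / model.V[i]))
        traj = pd.DataFrame(rows, columns=["t_h", "segment", "dissolved_mg", "conc_mg_per_mL"])
    return GIResult(times_h=times, portal_flux_mg_h=portal, gut_metabolite_flux_mg_h=gutflux,
                    fa=fa, fg=fg, absorbed_mg=entered, gut_metabolized_mg=gutmet,
                    lumen_degraded_mg=float(y_end[model.i_deg]),
                    unabsorbed_outflow_mg=float(y_end[model.i_out_diss] + y_end[model.i_out_solid]),
                    mass_balance_error_mg=abs(balance - dose), segment_dissolved=traj)


def bioavailability_chain(fa: float, fg: float, fh: float) -> float:
    """Absolute oral bioavailability F = fa * fg * fh."""
    for name, v in (("fa", fa), ("fg", fg), ("fh", fh)):
        if not 0.0 <= v <= 1.0:
            raise InvalidInputError(f"{name} must lie in [0, 1], got {v}")
    return fa * fg * fh
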