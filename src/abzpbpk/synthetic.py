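"""Synthetic-data generators with known ground truth.

Every estimator in the pipeline has a generator here that produces the
kind of data it consumes — replicate solubility measurements, transfer
concentration–time curves, plasma profiles — from a known parameter set,
with multiplicative log-normal noise (concentrations are positive and
assay error scales with level).  Fixing the seed makes every generator
bit-reproducible, so parameter-recovery tests run without any external
data.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import InvalidInputError
from .gi import DrugAbsorptionParams, FormulationParams, GIPhysiology
from .particles import DLMParams, WeibullPSD, psd_quantile
from .precipitation import PrecipitationParams
from .solubility import (IonizationSpec, Medium, SolubilityParams, SolubilityTable,
                         total_solubility)
from .systemic import MetabolitePK, ParentPK, TrialDesign
from .transfer import TransferConfig, TransferResult, simulate_transfer

#: The seven measurement systems of the reference solubility study.
DEFAULT_MEDIA = (
    Medium("pH 1.2 HCl buffer", 1.2, 0.0),
    Medium("pH 2.0 HCl buffer", 2.0, 0.0),
    Medium("pH 4.5 acetate buffer", 4.5, 0.0),
    Medium("pH 6.8 phosphate buffer", 6.8, 0.0),
    Medium("FaSSGF", 1.6, 0.08),
    Medium("FaSSIF", 6.5, 3.0),
    Medium("FeSSIF", 5.0, 15.0),
)


@dataclass(frozen=True)
class GeneratorConfig:
    seed: int = 0
    noise_cv: float = 0.05
    n_replicates: int = 3

    def __post_init__(self) -> None:
        if self.noise_cv < 0:
            raise InvalidInputError("noise_cv must be >= 0")
        if self.n_replicates < 1:
            raise InvalidInputError("n_replicates must be >= 1")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def _lognormal_factors(rng: np.random.Generator, cv: float, n: int) -> np.ndarray:
    if cv <= 0:
        return np.ones(n)
    sigma = math.sqrt(math.log(1.0 + cv * cv))
    return rng.lognormal(-0.5 * sigma * sigma, sigma, size=n)


def gen_solubility_table(truth_sol: SolubilityParams, ion: IonizationSpec,
                         cfg: GeneratorConfig,
                         media: Sequence[Medium] = DEFAULT_MEDIA) -> SolubilityTable:
    """Replicate shake-flask measurements from a known solubility model."""
    if not media:
        raise InvalidInputError("media list must be nonempty")
    rng = cfg.rng()
    rows = []
    for med in media:
        s = total_solubility(med, ion, truth_sol)
        for f in _lognormal_factors(rng, cfg.noise_cv, cfg.n_replicates):
            rows.append((med.name, med.pH, med.bile_salt_mM, s * f, np.nan))
    return SolubilityTable.from_rows(rows)


def gen_psd_quantiles(truth: WeibullPSD, cfg: GeneratorConfig) -> tuple[float, float, float]:
    """Noisy d10/d50/d90 from a known Weibull volume distribution."""
    rng = cfg.rng()
    d = psd_quantile(np.array([0.1, 0.5, 0.9]), truth)
    d = d * _lognormal_factors(rng, cfg.noise_cv, 3)
    d = np.sort(d)
    return float(d[0]), float(d[1]), float(d[2])


def gen_precipitation_curve(truth: PrecipitationParams, S_eq_mg_mL: float,
                            t_min: Sequence[float], cfg: GeneratorConfig,
                            t_peak_min: float = 0.0) -> pd.DataFrame:
    """First-order supersaturation-relaxation curve from known (CSR, PRC).

    The curve starts at the critical supersaturation concentration
    ``CSR * S_eq`` at ``t_peak_min`` and relaxes toward ``S_eq`` at the
    rate PRC — the exact model family the closed-form estimator inverts,
    so noiseless generation is an exact round trip.
    """
    t = np.asarray(t_min, dtype=float)
    csc = truth.CSR * S_eq_mg_mL
    c = S_eq_mg_mL + (csc - S_eq_mg_mL) * np.exp(-truth.PRC_per_h * np.maximum(t - t_peak_min, 0) / 60.0)
    rng = cfg.rng()
    frames = []
    for rep in range(cfg.n_replicates):
        f = _lognormal_factors(rng, cfg.noise_cv, t.size)
        frames.append(pd.DataFrame({"t_min": t, "replicate": rep + 1,
                                    "conc_mg_per_mL": c * f}))
    return pd.concat(frames, ignore_index=True)


def gen_transfer_curves(truth_precip: PrecipitationParams, config: TransferConfig,
                        sol: SolubilityParams, ion: IonizationSpec, dlm: DLMParams,
                        cfg: GeneratorConfig) -> tuple[pd.DataFrame, TransferResult]:
    """Noisy replicate intestinal curves from a simulated transfer experiment.

    The deterministic simulation is run once; measurement noise is applied
    per replicate.  Returns the tidy replicate table (t_min, replicate,
    conc_mg_per_mL) plus the underlying noiseless result.
    """
    result = simulate_transfer(config, sol, ion, dlm, truth_precip)
    rng = cfg.rng()
    curve = result.intestinal_curve
    frames = []
    for rep in range(cfg.n_replicates):
        f = _lognormal_factors(rng, cfg.noise_cv, len(curve))
        frames.append(pd.DataFrame({
            "t_min": curve["t_min"], "replicate": rep + 1,
            "conc_mg_per_mL": curve["conc_mg_per_mL"].to_numpy() * f}))
    return pd.concat(frames, ignore_index=True), result


def gen_plasma_profiles(design: TrialDesign, physiology: GIPhysiology,
                        sol: SolubilityParams, ion: IonizationSpec,
                        formulation: FormulationParams, dlm: DLMParams,
                        precip: PrecipitationParams, absorb: DrugAbsorptionParams,
                        parent: ParentPK, met: MetabolitePK,
                        cfg: GeneratorConfig, residual_cv: float = 0.1,
                        sampling_times_h: Sequence[float] | None = None,
                        options=None) -> pd.DataFrame:
    """Virtual-trial plasma profiles with proportional residual error.

    Subjects are simulated per the trial design (inter-individual
    variability at the design CVs, driven by ``design.seed``); residual
    assay noise at ``residual_cv`` is layered on top using the generator
    seed.  Returns tidy rows (subject, analyte, t_h, conc_ng_per_mL).
    """
    from .systemic import simulate_subject  # local import avoids cycle at module load

    rng = cfg.rng()
    trial_rng = np.random.default_rng(design.seed)

    def lognorm(mean, cv):
        if cv <= 0:
            return mean
        sigma = math.sqrt(math.log(1.0 + cv * cv))
        return mean * trial_rng.lognormal(-0.5 * sigma * sigma, sigma)

    from dataclasses import replace as _replace
    rows = []
    for i in range(design.n_subjects):
        male = i < design.n_male
        bw = lognorm(design.bw_mean_male_kg if male else design.bw_mean_female_kg,
                     design.bw_cv)
        clint_mult = lognorm(1.0, design.cv_hepatic_clint)
        enzymes = tuple(_replace(e, abundance_pmol=e.abundance_pmol * clint_mult)
                        for e in parent.hepatic_enzymes)
        parent_i = _replace(parent, vss_L_kg=lognorm(parent.vss_L_kg, design.cv_vss_parent),
                            hepatic_enzymes=enzymes)
        met_i = _replace(met, vss_L_kg=lognorm(met.vss_L_kg, design.cv_vss_metabolite),
                         cl_systemic_L_h=lognorm(met.cl_systemic_L_h, design.cv_cl_metabolite))
        phys_i = _replace(physiology,
                          gastric_MRT_h=lognorm(physiology.gastric_MRT_h, design.cv_gastric_mrt))
        res = simulate_subject(design.dose_mg, phys_i, sol, ion, formulation, dlm, precip,
                               absorb, parent_i, met_i, body_weight_kg=bw, options=options)
        prof = res.profile
        if sampling_times_h is not None:
            grid = np.asarray(sampling_times_h, dtype=float)
            out = []
            for analyte, grp in prof.groupby("analyte"):
                c = np.interp(grid, grp["t_h"], grp["conc_ng_per_mL"])
                out.append(pd.DataFrame({"t_h": grid, "analyte": analyte,
                                         "conc_ng_per_mL": c}))
            prof = pd.concat(out, ignore_index=True)
        noise = _lognormal_factors(rng, residual_cv, len(prof))
        prof = prof.assign(conc_ng_per_mL=prof["conc_ng_per_mL"].to_numpy() * noise,
                           subject=i + 1)
        rows.append(prof)
    return pd.concat(rows, ignore_index=True)


def make_synthetic(outdir: str | Path, seed: int = 0, noise_cv: float = 0.05) -> dict:
    """Write a complete fixture directory (CSV data + truth JSON); returns paths."""
    from .config import albendazole_default

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    model = albendazole_default()
    cfg = GeneratorConfig(seed=seed, noise_cv=noise_cv)
    paths = {}

    tab = gen_solubility_table(model.solubility, model.ion, cfg)
    paths["solubility_csv"] = str(out / "solubility.csv")
    tab.to_csv(paths["solubility_csv"])

    tcfg = TransferConfig(dose_mg=400.0, psd=model.formulation.psd,
                          release_rate_per_h=model.formulation.release_rate_per_h)
    curves, _ = gen_transfer_curves(model.precip, tcfg, model.solubility, model.ion,
                                    model.dlm, cfg)
    paths["transfer_csv"] = str(out / "transfer_intestinal.csv")
    curves.to_csv(paths["transfer_csv"], index=False)

    d10, d50, d90 = gen_psd_quantiles(model.formulation.psd, cfg)
    paths["psd_csv"] = str(out / "psd_quantiles.csv")
    pd.DataFrame([{"d10_um": d10, "d50_um": d50, "d90_um": d90}]).to_csv(
        paths["psd_csv"], index=False)

    truth = {"seed": seed, "noise_cv": noise_cv,
             "solubility": {"S0": model.solubility.S0,
                            "logKmw_neutral": model.solubility.logKmw_neutral,
                            "logKmw_ion": model.solubility.logKmw_ion},
             "precipitation": {"CSR": model.precip.CSR, "PRC": model.precip.PRC_per_h},
             "psd": {"alpha": model.formulation.psd.alpha,
                     "beta": model.formulation.psd.beta}}
    paths["truth_json"] = str(out / "truth.json")
    Path(paths["truth_json"]).write_text(json.dumps(truth, indent=2))
    return paths
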