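"""End-to-end pipeline runner and reproducible run records.

Ties the stages together in the order the workflow prescribes: calibrate
the solubility model from measured tables, fit the particle-size
distribution, simulate the transfer experiment and estimate precipitation
parameters, simulate the oral PK (mean subject and virtual trial), verify
against an observed exposure table, and run the standard sensitivity
sweeps.  Any subset of stages can be selected.  Every run emits a
RunRecord JSON capturing the full configuration, package version, seed and
output paths, sufficient to reproduce the run.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .config import (OBSERVED_CLINICAL_PK, ModelConfig, albendazole_default,
                     from_yaml, to_dict)
from .errors import ConfigurationError
from .sensitivity import standard_sweeps
from .solubility import SolubilityTable, fit_bile_partition, fit_intrinsic_solubility
from .systemic import fold_error, nca, run_trial, simulate_subject
from .transfer import TransferConfig, analyze_transfer, simulate_transfer

ALL_STAGES = ("fit-solubility", "fit-psd", "transfer", "simulate", "verify", "sensitivity")


@dataclass
class RunRecord:
    version: str
    seed: int
    started: str
    finished: str = ""
    stages: list = field(default_factory=list)
    config: dict = field(default_factory=dict)
    input_digests: dict = field(default_factory=dict)
    outputs: dict = field(default_factory=dict)
    defaulted_parameters: dict = field(default_factory=dict)

    def write(self, path: Path) -> None:
        path.write_text(json.dumps(dataclasses.asdict(self), indent=2, default=str))


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: ModelConfig | str | Path | None, outdir: str | Path,
                 stages=ALL_STAGES, seed: int = 0,
                 solubility_csv: str | Path | None = None,
                 observed: dict | None = None) -> RunRecord:
    """Execute the selected stages and write artifacts + a RunRecord to outdir."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    if config is None:
        model = albendazole_default()
    elif isinstance(config, ModelConfig):
        model = config
    else:
        model = from_yaml(config)
    unknown = [s for s in stages if s not in ALL_STAGES]
    if unknown:
        raise ConfigurationError(f"unknown stages {unknown}; valid: {list(ALL_STAGES)}")
    rec = RunRecord(version=__version__, seed=seed,
                    started=time.strftime("%Y-%m-%dT%H:%M:%S"),
                    stages=list(stages), config=to_dict(model))

    if solubility_csv is not None:
        table = SolubilityTable.read_csv(solubility_csv)
        rec.input_digests[str(solubility_csv)] = _digest(Path(solubility_csv))
    else:
        table = SolubilityTable.reference_abz()

    if "fit-solubility" in stages:
        aq = fit_intrinsic_solubility(table.bile_free(), model.ion)
        bile = fit_bile_partition(table, model.ion, aq.S0)
        p = out / "solubility_fit.json"
        p.write_text(json.dumps({"aqueous": aq.to_dict(), "biorelevant": bile.to_dict()},
                                indent=2))
        rec.outputs["fit-solubility"] = str(p)

    if "fit-psd" in stages:
        from .particles import psd_quantile
        psd = model.formulation.psd
        p = out / "psd_fit.json"
        payload = {"alpha": psd.alpha, "beta": psd.beta,
                   "mean_diameter_um": psd.mean_diameter_um,
                   "d10": psd_quantile(0.1, psd), "d50": psd_quantile(0.5, psd),
                   "d90": psd_quantile(0.9, psd)}
        p.write_text(json.dumps(payload, indent=2))
        rec.outputs["fit-psd"] = str(p)

    if "transfer" in stages:
        tcfg = TransferConfig(dose_mg=400.0, psd=model.formulation.psd,
                              release_rate_per_h=model.formulation.release_rate_per_h)
        res = simulate_transfer(tcfg, model.solubility, model.ion, model.dlm, model.precip)
        est = analyze_transfer(res)
        res.intestinal_curve.to_csv(out / "transfer_intestinal.csv", index=False)
        res.gastric_curve.to_csv(out / "transfer_gastric.csv", index=False)
        (out / "precipitation_estimate.json").write_text(json.dumps(est.to_dict(), indent=2))
        rec.outputs["transfer"] = str(out / "precipitation_estimate.json")

    if "simulate" in stages or "verify" in stages:
        sub = simulate_subject(model.formulation.dose_mg, model.physiology, model.solubility,
                               model.ion, model.formulation, model.dlm, model.precip,
                               model.absorb, model.parent, model.metabolite,
                               options=model.options)
        sub.profile.to_csv(out / "mean_subject_profile.csv", index=False)
        rec.outputs["simulate"] = str(out / "mean_subject_profile.csv")

    if "verify" in stages:
        obs = observed or OBSERVED_CLINICAL_PK
        rows = {}
        for analyte, key in (("parent", "parent"), ("metabolite", "metabolite")):
            p = sub.profile[sub.profile["analyte"] == analyte]
            m = nca(p["t_h"].to_numpy(), p["conc_ng_per_mL"].to_numpy())
            rows[key] = {
                "cmax_pred": m.cmax, "auc_pred": m.auc0_inf,
                "cmax_obs": obs[key]["cmax_ng_mL"], "auc_obs": obs[key]["auc0_inf_ng_h_mL"],
                "fold_error_cmax": fold_error(m.cmax, obs[key]["cmax_ng_mL"]),
                "fold_error_auc": fold_error(m.auc0_inf, obs[key]["auc0_inf_ng_h_mL"]),
            }
        trial = run_trial(dataclasses.replace(model.trial, seed=seed), model.physiology,
                          model.solubility, model.ion, model.formulation, model.dlm,
                          model.precip, model.absorb, model.parent, model.metabolite,
                          options=model.options)
        trial.subjects.to_csv(out / "trial_subjects.csv", index=False)
        (out / "verification.json").write_text(json.dumps(
            {"mean_subject": rows,
             "trial_means": trial.mean_metrics.to_dict(orient="records")}, indent=2))
        rec.outputs["verify"] = str(out / "verification.json")

    if "sensitivity" in stages:
        sweeps = standard_sweeps(model)
        frames = []
        for name, sw in sweeps.items():
            t = sw.table.copy()
            t.insert(0, "sweep", name)
            frames.append(t)
        pd.concat(frames, ignore_index=True).to_csv(out / "sensitivity.csv", index=False)
        rec.outputs["sensitivity"] = str(out / "sensitivity.csv")

    rec.finished = time.strftime("%Y-%m-%dT%H:%M:%S")
    rec.write(out / "run_record.json")
    return rec
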