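# abzpbpk

Mechanistic oral-absorption and PBPK modeling of **albendazole (ABZ)** and
its active metabolite **albendazole sulfoxide (ABZ_SO)** — an open,
testable re-implementation of the in vitro → in silico workflow used to
guide formulation development for a poorly soluble weak base.

ABZ is a BCS class II ampholyte (pKa 2.8 / 10.26): it dissolves readily in
the acidic stomach, precipitates on transfer into the neutral small
intestine, and is almost completely removed by first-pass CYP3A4/FMO3
sulfoxidation, so the clinically relevant exposure is that of ABZ_SO.
The package chains the pieces a formulation scientist needs:

* **Solubility** — Henderson–Hasselbalch aqueous solubility
  `S(pH) = S0·(1 + 10^(pKa_b−pH) + 10^(pH−pKa_a))` plus species-based
  bile-micelle solubilization, with least-squares calibration of `S0` and
  the micelle:water partition coefficients from shake-flask tables.
* **Particles** — Weibull volume distributions (fit from d10/d50/d90),
  equal-mass discretization, and the Wang–Flanagan diffusion-layer
  dissolution law `dm/dt = −N·S·4πD·r(r+h)/h·(S_surf−C_bulk)` with the
  Hintz–Johnson layer `h = min(r, 30 µm)`.
* **Precipitation kinetics** — critical supersaturation ratio (CSR) with
  latch semantics and a first-order precipitation rate constant (PRC),
  estimated from two-stage transfer-experiment curves (closed-form or
  inverse-simulation refit).
* **Transfer experiment** — a two-vessel USP-II simulator (FaSSGF donor →
  FaSSIF acceptor, 7 mL/min pump from 30 min).
* **GI absorption** — a nine-segment compartmental model (stomach, seven
  small-intestinal segments, colon) with transit, dissolution,
  precipitation, luminal degradation, `ka = 2·Peff/R` uptake and gut-wall
  metabolism; yields fa and fg.
* **Systemic PK** — well-stirred-liver parent disposition with
  Michaelis–Menten enzyme kinetics, metabolite formation and minimal
  disposition, virtual trials with log-normal variability, NCA
  (Cmax/Tmax/AUC/λz) and fold-error verification; `F = fa·fg·fh`.
* **Sensitivity engine** — one- and two-parameter sweeps (gastric pH,
  gastric residence time, particle size, solubility, CSR × PRC) on
  metabolite exposure.
* **Synthetic data** — seeded generators with known ground truth for every
  estimator.

See `docs/methods.md` for model equations, default parameters, calibration
provenance and known limitations.

## Worked example

Simulate a 400 mg single oral dose in the mean fasted subject:

```bash
abzpbpk simulate-pk --dose 400 --out profile.csv
```

```
fa=0.281 fg=0.943 fh=0.0193 F=0.00511
parent: Cmax=5.3 ng/mL  Tmax=4.00 h  AUC0-inf=44 ng*h/mL
metabolite: Cmax=350.3 ng/mL  Tmax=4.00 h  AUC0-inf=3011 ng*h/mL
```

Reading: 28% of the dose dissolves and crosses into the gut wall (fa),
94% of that escapes gut-wall metabolism (fg), but only ~2% survives the
hepatic first pass (fh), so absolute parent bioavailability F is ~0.5% —
the parent plasma profile peaks near 5 ng/mL while the sulfoxide, which
receives essentially all metabolized parent, peaks near 350 ng/mL. Both
analytes fall within two-fold of the observed single-dose exposure in
healthy volunteers (observed: 9.55 / 53 ng·h/mL parent Cmax/AUC, 193.5 /
3475 for the metabolite).

The same workflow from Python:

```python
from abzpbpk import simulate_subject, nca
from abzpbpk.config import albendazole_default

m = albendazole_default()
sub = simulate_subject(400.0, m.physiology, m.solubility, m.ion, m.formulation,
                       m.dlm, m.precip, m.absorb, m.parent, m.metabolite, 70.0)
met = sub.profile[sub.profile.analyte == "metabolite"]
print(nca(met.t_h.to_numpy(), met.conc_ng_per_mL.to_numpy()))
```

Other entry points: `abzpbpk fit-solubility`, `fit-psd`,
`simulate-transfer`, `estimate-precipitation`, `verify`,
`sensitivity --param physiology.gastric_pH --range 1.2 4.5 --steps 10`,
`run-pipeline`, `make-synthetic`, and `config` (dump the fully annotated
default model as YAML).

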