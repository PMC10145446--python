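# Methods

`abzpbpk` implements a mechanistic oral-absorption / PBPK workflow for
albendazole (ABZ), a poorly soluble, highly permeable (BCS class II) weak
base whose systemic pharmacology is carried by its first-pass metabolite
albendazole sulfoxide (ABZ_SO). This note documents the models, their
assumptions, the default parameter values and where they come from, the
numerical choices, and the known limitations — in particular which observed
behaviors of the real system the model family can and cannot reproduce.

## Solubility model

Aqueous solubility follows the Henderson–Hasselbalch treatment of an
ampholyte (basic pKa 2.8, acidic pKa 10.26):

    S_aq(pH) = S0 * (1 + 10^(pKa_b − pH) + 10^(pH − pKa_a))

Bile-salt micelles add a species-based solubilization term with separate
micelle:water partition coefficients for the neutral and ionized species,
with the bile-salt concentration expressed as a mole fraction against
water (55.5 mol/L):

    S_total = S_aq + [BS]/55.5 * S0 * (10^logKmw,n + 10^logKmw,i * ionized_ratio(pH))

No activity-coefficient, common-ion or salt/polymorph effects are modeled.

**Calibration.** With the pKa values fixed, the intrinsic solubility is a
single linear parameter and the bile-free fit has the closed-form solution
`S0 = Σ f_i y_i / Σ f_i²`. The default objective is linear-scale least
squares: on the packaged shake-flask table it returns S0 = 0.0123 mg/mL
(R² = 0.9765), consistent with the reported calibration (0.012, R² 0.9771).
Log-scale fitting is implemented as an option; it down-weights the acidic
media and yields S0 ≈ 0.0064 mg/mL, so it is deliberately not the default.
The two partition coefficients are fitted by bounded least squares with S0
and pKa held fixed. Replicates are collapsed to their means before any fit;
the SD column is reporting-only.

## Particle-size distribution and dissolution

Laser-diffraction volume distributions are modeled as a Weibull
distribution over particle diameter (shape α = 1.014, scale β = 8.732 µm
for the reference powder). `fit_weibull` solves the three-quantile
(d10/d50/d90) constraints by least squares in the linearizing log domain;
note the printed reference parameters and the printed quantiles are not
mutually consistent (no Weibull passes through all three), so refitting the
quantiles gives α ≈ 0.97, β ≈ 8.1 — the shipped default uses the reported
parameters, refit mode is available.

For simulation the distribution is discretized into equal-mass bins at
volume-quantile midpoints (6 bins by default; total bin mass equals the
dose to machine precision). Each bin dissolves under the diffusion-layer
model in its Wang–Flanagan form

    dm/dt = −N · S_scalar · 4π D_eff · r (r + h_eff)/h_eff · (S_surf − C_bulk)

with the Hintz–Johnson effective boundary layer `h_eff = min(r, 30 µm)`.
Defaults: D_eff = 8×10⁻⁶ cm²/s (generic small-molecule aqueous
diffusivity), true density 1.2 g/cm³, dissolution scalar 1. In the
`h_eff = r` regime this law admits the closed-form shrinking-sphere
solution `r² = r0² − 4 D S t/ρ`, which serves as the analytic oracle for
the integrator. (The classical `2 D S t/ρ` constant belongs to the plain
`4πr²·D/h` area form; the `(r+h)/h` surface correction doubles it.)

**Numerical form.** Inside the solvers the same law is evaluated per unit
bin mass, `dm/dt = −m · 3 D (r+h)/(ρ r² h) · ΔC`, which is linear (hence
Lipschitz) near depletion. Two regularizations bound the Jacobian where
submicron material flows into an undersaturated compartment and dissolves
quasi-instantaneously: the coefficient is evaluated at a radius floor of
0.05 µm, and the per-mass rate constant is harmonically capped at 500 h⁻¹
(a ~7 s dissolution timescale — far below any transit or sampling
timescale; it perturbs slowly dissolving bins by <0.3%).

## Supersaturation and precipitation

Above the local equilibrium solubility the solution is metastable until it
first reaches the critical supersaturation concentration CSC = CSR·S_eq;
from then on (latch semantics) the excess `C − S_eq` precipitates at the
first-order rate PRC. `CSR = 1` with PRC at its 1000 h⁻¹ ceiling encodes
immediate precipitation: the dissolved concentration can never appreciably
exceed S_eq. Precipitated material is inert by default (no redissolution);
a flag re-exposes it as 10 µm particles. The estimator inverts an
intestinal concentration–time curve: if the curve never exceeds S_eq
beyond a 2% allowance the immediate-precipitation parameterization is
returned; otherwise the peak is read as the CSC and PRC is fitted to the
post-peak first-order relaxation. Because a slowly precipitating vessel
keeps rising past the CSC while the donor still feeds it, the peak
estimator is biased high for CSR; `analyze_transfer(method="refit")`
removes the bias by re-simulating the experiment over candidate
(CSR, log PRC) and is the recommended route for supersaturating
formulations.

## Transfer experiment

Two well-mixed vessels: 250 mL FaSSGF-like donor (pH 1.6, 0.08 mM bile),
500 mL FaSSIF-like acceptor (pH 6.5, 3 mM bile), pump 7 mL/min starting at
30 min, sampling at the standard 5–120 min schedule. Dissolved drug and
(by default) suspended solids are convected in proportion to the volume
flux; the acceptor pH/bile are held constant (high-buffer-capacity
assumption); precipitation is active only in the acceptor; paddle speed is
metadata. The donor volume declines linearly; when 0.5 mL remains, the
residual contents are moved to the acceptor in one step to avoid the
singular terms of a vanishing volume. The dosed powder enters through a
first-order release (wetting/disintegration) step at 6 h⁻¹, calibrated so
that a 40 mg sink-condition dose is essentially fully dissolved by 30 min,
matching the in vitro observation; an ideal DLM run without it would
dissolve the fine reference powder in seconds.

## Gastrointestinal absorption

A nine-segment compartmental chain (stomach; duodenum; jejunum I–II;
ileum I–IV; colon) in the ACAT/ADAM tradition, with first-order transit of
every species, per-segment bile-aware solubility, DLM dissolution,
latched precipitation (intestinal segments), uptake at `ka = 2 Peff/R`
into a lumped enterocyte compartment (villous blood flow 18 L/h, volume
0.3 L) in competition with gut-wall Michaelis–Menten metabolism, and
first-order luminal degradation of dissolved drug (2000 µL/h per g of
luminal content, content mass taken as fluid volume × 1 g/mL; the acidic
stomach is excluded from degradation and from absorption). fa is the
fraction of dose entering the enterocyte; fg the fraction of that escaping
gut metabolism; F = fa·fg·fh.

Fasted defaults: gastric pH 1.5, MRT 0.4 h, 250 mL gastric fluid (dose
taken with water); SI pH 6.0→7.4, bile 3→0.5 mM, total SI transit 3.3 h,
radius 1.25 cm; colon pH 6.5, 17 h transit, radius 2.5 cm with
permeability scaled by 0.45. The static SI fluid volumes (426 mL total)
and the colonic absorption parameters were calibrated middle-out against
the clinical verification dataset (below): static volumes have to stand in
for dynamic secretion/reabsorption and micro-mixing, and sit between
classical compartmental-absorption conventions (~600 mL) and fasted MRI
estimates (~100 mL).

## Systemic disposition and the virtual trial

The parent distributes in a single compartment honoring the reported
Vss (2.59 L/kg) — tissue-composition Kp prediction is out of scope — in
series with a quasi-steady well-stirred liver: portal absorption flux plus
recirculating hepatic blood flow (87 L/h) are extracted with
`E = fuB·CLint,u/(Q + fuB·CLint,u)`, CLint,u summing the CYP3A4
(Vmax 369 pmol/min/pmol, Km 10.1 µM) and FMO3 (1103, 9.6) pathways scaled
by abundance × MPPGL (40 mg/g) × liver mass (1650 g). The saturable CLint
is evaluated at the liver-outflow unbound concentration by fixed-point
iteration (concentrations here are ≫100-fold below Km, so the linear limit
applies in practice). All metabolized parent (gut + liver) forms ABZ_SO
(MW-corrected), which distributes in 2.3 L/kg and is cleared at the
reported fitted 40 L/h. ABZ_SO is never dosed; its own absorption
parameters are stored but unused.

**Middle-out calibration.** Enzyme-abundance scalars are not fixed by any
in-house experiment, and published estimates span wide ranges (hepatic
CYP3A4 roughly 90–140 pmol/mg across meta-analyses; hepatic FMO3 from a
few to tens of pmol/mg; intestinal totals similarly uncertain). Following
the same middle-out practice used to set the luminal CLint and the
metabolite disposition in the source workflow, the defaults — CYP3A4
100 pmol/mg, FMO3 2.5 pmol/mg, effective gut-wall totals 0.5 nmol CYP3A4 /
0.05 nmol FMO3, together with the fluid-volume/colon parameters above —
were chosen so that the mean-subject prediction brackets the observed
single-dose (400 mg, 10 healthy volunteers) exposure of both analytes
within two-fold. With the printed enzymology alone and mechanistic
abundance defaults, the parent:metabolite exposure ratio is structurally
~1.5× low and intestinal extraction is overpredicted; the calibrated
values absorb that discrepancy and are all overridable.

The virtual trial samples log-normal inter-individual variability (body
weight 15%; hepatic CLint 30%; parent and metabolite Vss 20%; metabolite
CL 30%; gastric MRT 30%) around the mean subject for 10 subjects
(6 male / 4 female, 21–44 y), reproducibly under a fixed seed. NCA uses
linear-up/log-down trapezoids, λz by log-linear regression over the last
3–5 points maximizing adjusted R², and AUC extrapolation by C_last/λz.

## Sensitivity engine

Sweeps re-simulate the deterministic mean subject per grid point (no
population sampling) over dotted configuration paths, reporting Cmax,
AUC0–∞ and parabolic-interpolated Tmax of ABZ_SO (and ABZ) plus percent
change versus the reference point (gastric pH 1.5, MRT 0.4 h). The
particle-size sweep uses monodisperse particles; the solubility sweep
compares the measured profile against a hypothetical ten-fold-higher S0
applied multiplicatively.

## Synthetic data

Generators emulate each measured input with multiplicative log-normal
noise: replicate shake-flask tables from a known solubility model, noisy
PSD quantiles, transfer curves (one deterministic simulation plus
per-replicate noise), first-order supersaturation-relaxation curves in the
estimator's own model family, and virtual-trial plasma profiles with
proportional residual error. They emulate assay noise only — no systematic
bias, no LOD censoring (an optional floor is off by default), no
between-day drift — so estimator-recovery tests demonstrate statistical
identifiability under the stated designs, not robustness to real-world
artifacts.

## Numerical choices

Stiff integration uses BDF with an explicit small first step (scipy's
automatic initial-step heuristic fails on states mixing particle counts
~10¹² with milligram amounts) and a structural Jacobian sparsity pattern
probed at sub- and supersaturated states; Radau is the fallback. Relative
tolerance 10⁻⁸, absolute tolerance 10⁻¹²×dose; fa changes by <0.1% between
rtol 10⁻⁶ and 10⁻⁹. CSC latching is handled by terminal events with
piecewise restarts. All transfers between pools are antisymmetric
exchanges, so mass conservation holds to solver tolerance (observed
≲10⁻¹⁰ of dose; the suite enforces 10⁻⁶). Simulations run to 48 h
(120 h where the metabolite AUC×CL mass-balance identity is checked to
1%), on a 481-point output grid.

## Known limitations

* **Gastric pH direction.** The published sensitivity analysis reports
  that raising gastric pH from 1.5 to 4.5 cuts ABZ_SO exposure by tens of
  percent *under the immediate-precipitation parameterization
  (CSR = 1, PRC = 1000 h⁻¹)*. In this model family that combination is
  mechanistically unreachable: drug pre-dissolved in an acidic stomach
  arrives in the duodenum ~30-fold above its solubility, and with a 3.6 s
  precipitation time constant at most ~0.5% of the excess can be absorbed
  before it precipitates, so gastric pre-dissolution is never rewarded —
  with an inert precipitate it is actively penalized (precipitated mass is
  lost), and exposure *rises* mildly with gastric pH. Reproducing a strong
  negative pH effect would require either sustained supersaturated
  absorption (contradicting PRC = 1000 h⁻¹) or dissolution slow enough
  that the stomach is the dominant dissolution site (contradicting the
  observed insensitivity to particle size below ~40 µm). The package
  reports what its mechanism implies; the discrepancy is stated rather
  than papered over.
* **Particle-size flat window.** Exposure is flat within ±5% only up to
  ~20 µm monodisperse diameter; at 40 µm the model already loses ~12%
  because the static luminal volumes needed to reproduce the clinical
  exposure make saturation maintenance marginal for coarser powders. The
  strong decline above 50–100 µm is reproduced.
* The ~6-fold gastric supersaturation observed in vitro for the 400 mg
  tablet (~0.9 mg/mL dissolved vs 0.146 mg/mL measured FaSSGF solubility)
  is not reproducible with equilibrium solubility and is not modeled.
* No fluid-volume dynamics, fed-state physiology, regional transporters,
  enterohepatic recycling, renal/biliary elimination, or
  nucleation-theoretic precipitation.
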