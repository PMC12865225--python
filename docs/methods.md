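# Methods

This note documents the models implemented in `transporter-ddi`, their
assumptions, the default parameter choices, and the known limits of what
the synthetic-data-driven tests demonstrate.

## 1. Assay data reduction

**Cell assays.** Raw per-well amounts from transporter-overexpressing and
control (mock-transduced) HEK293 cells are reduced per experiment: the
mean control-cell signal at each inhibitor concentration is subtracted
from the mean transporter-cell signal, and the difference is normalised
to the vehicle (0 μM inhibitor) net signal, which defines 100% transport
activity. Per-experiment activities are then averaged across experiments.
Activities above 100% or below 0% are retained unclipped — clipping would
bias the subsequent IC50 fit. A vehicle net uptake ≤ 0 is treated as a
non-functional assay and raises an error rather than producing a
meaningless normalisation.

**Vesicle assays.** Inside-out membrane vesicles transport substrate only
when ATP is present; wells energised with AMP measure the non-transport
background. Net active transport is mean(ATP) − mean(AMP) per inhibitor
concentration, normalised to the vehicle net transport.

## 2. Curve fits and confidence intervals

All fits are unweighted nonlinear least squares on per-concentration
means (scipy `least_squares`, trust-region reflective, with up to three
jittered restarts if the optimum is not found or sits on the search
boundary).

* **IC50.** `activity = 100/(1 + 10^(log10 I − log10 IC50))` — a
  log-logistic curve with the Hill slope fixed at 1 and asymptotes fixed
  at 0 and 100%. log10(IC50) is the single free parameter, started at the
  log-midpoint of the tested range. A fit is flagged non-convergent when
  activity does not decline with concentration or the optimum hits the
  boundary. This parameterisation makes inhibition exactly 50% at
  I = IC50 and monotone in I.
* **Michaelis–Menten.** Km and Vmax are fit on the log10 scale (which
  enforces positivity); concentrations named in an explicit exclusion
  list are omitted from the objective and recorded in the result. The
  exclusion list is deliberately manual/config-driven — mirroring how
  saturation-deviant high concentrations are handled in practice — rather
  than an automatic outlier rule.
* **Competitive Ki.** `v = Vmax·S/(Km·(1+I/Ki)+S)` fit globally over a
  substrate × inhibitor grid (log-scale parameters). The grid must
  contain ≥ 2 substrate levels and ≥ 2 inhibitor levels including 0;
  otherwise Ki is unidentifiable and an error is raised.

**Confidence intervals.** 95% CIs are Wald intervals computed on the
log10 parameter scale and back-transformed, which yields the customary
asymmetric intervals. For IC50 fits, the pure residual-based Wald
variance is provably too small under the assay's error structure: every
activity value shares the same noisy vehicle normalisation anchor, and a
coherent rescaling of the whole curve shifts the IC50 estimate while
barely changing the residuals. The reduction step therefore estimates the
fractional standard error of the pooled anchor from vehicle-well
replicate scatter, and the fit adds its delta-method contribution
`(∂log10 IC50/∂scale)²·se²` to the Wald variance. In simulation (200
replicates of the 7-concentration, triplicate, two-experiment design at
10% noise) this brings the CI coverage from ~71% to ~95% with no effect
on the point estimate.

## 3. FDA static risk model

Exposure metrics for an orally dosed inhibitor:

* liver inlet, unbound: `I_in,max,u = fu,p·(Cmax + Fa·Fg·ka·Dose/(Qh·RB))`
  with the worst-case defaults Fa·Fg = 1 and ka = 0.1 min⁻¹, hepatic
  blood flow Qh = 1.62 L/min;
* systemic unbound: `I_max,u = fu,p·Cmax`;
* intestinal lumen: `I_gut = Dose / 0.25 L`.

R-values and cut-offs: hepatic basolateral `1 + I_in,max,u/IC50` ≥ 1.1;
intestinal apical `I_gut/IC50` ≥ 10; renal basolateral `I_max,u/IC50`
≥ 0.1; renal apical `I_max,u/IC50` ≥ 0.02 (the MATE cut-off, borrowed for
the apically expressed OAT4 and kept configurable). OATP2B1 is evaluated
under both the hepatic and the intestinal mechanism because it is
expressed at both sites.

R-values are reported rounded to two significant figures (half away from
zero), but threshold flags always use the unrounded value — relevant at
the cut-off itself. An IC50 known only as a lower bound ("≥ x μM")
propagates to an R-value marked as an upper bound and still compared
against the threshold: a flagged upper bound means risk cannot be
excluded. Dose is converted with the free-acid molecular weights 470.33
(dicloxacillin) and 453.87 g/mol (flucloxacillin). Note that recomputing
the liver-inlet metric from its stated inputs gives 5.38/15.31 μM for
dicloxacillin/flucloxacillin — about 2.5% below the commonly quoted
5.51/15.7 μM, a discrepancy attributable to intermediate rounding in the
quoted values; all downstream R-values agree at two significant figures
either way.

## 4. PBPK DDI simulator

### Topology

The smallest whole-body structure exposing every inhibition site of
interest:

```
gut lumen → enterocyte → portal vein → liver extracellular
                ↑  (apical efflux back to lumen)   ⇅ (sinusoidal uptake)
                                             liver intracellular → elimination
portal ← central ⇄ peripheral; renal elimination from central
```

States are amounts (μmol); concentrations are plasma-referenced (flows
between blood compartments carry `Q_blood·RB·C_plasma`). Default
physiology (70 kg): hepatic blood flow 97.2 L/h, villous blood flow
18 L/h, enterocyte 0.3 L, portal 1 L, liver extracellular 0.7 L, liver
intracellular 1.1 L.

* **Absorption.** The lumen empties first-order with rate constant `ka`
  (the observed absorption constant); a fraction `fa·fg` of that flux
  enters the enterocyte, the rest is an unabsorbed loss. A configurable
  fraction of the absorbed flux is carried by apical OATP2B1 and is
  inhibitable; the remainder is passive. Apical efflux (BCRP/P-gp
  intrinsic clearances) returns drug from the enterocyte to the lumen,
  where it is subject to the same loss — so efflux inhibition increases
  availability, and uptake inhibition decreases it.
* **Liver.** Sinusoidal uptake intrinsic clearance is split across
  OATP1B1/1B3/2B1 and a passive (bidirectional, non-inhibitable)
  component; fractions must sum to 1. Intracellular elimination
  (metabolic + biliary, lumped) acts on unbound intracellular drug. The
  unbound fraction `fu,p` is used on both sides of the hepatocyte
  membrane (no differential intracellular binding).
* **Inhibition.** Competitive throughout: `CLint/(1 + I/Ki)`, evaluated
  at every solver step. Site concentrations of the precipitant: apical
  gut transporters see the absorption flux diluted into villous blood
  (`ka_abs·A_lumen/Q_villous`); hepatic OATPs see the unbound portal
  concentration `fu·(C_systemic + ka_abs·A_lumen/(Qh·RB))` — the dynamic
  analogue of the static liver-inlet estimate; renal transporters would
  see the unbound systemic concentration (none of the shipped victims has
  an inhibitable renal pathway, so this site is defined but unused).
  Scenarios also accept a constant `I/Ki` ratio per transporter for
  reduced-model analyses.
* **Numerics.** LSODA with rtol 1e-8, atol 1e-10 μmol, restarted at every
  dose event; output on a fixed 0.01 h grid. Mass balance (in-body +
  eliminated + unabsorbed = cumulative dose) holds to <0.1% in every run
  and is checked in the result object. AUC is trapezoidal on the output
  grid; terminal half-life comes from a log-linear fit over the last
  declining concentration decade.

A drug may instead be declared `one_compartment` (lumen → central ⇄
peripheral with a plasma clearance): its gut-lumen and systemic states
still drive victim inhibition. The two precipitants are shipped this way —
their disposition is described empirically against clinical data, while
the victims use the full topology, which is where the inhibitable
clearances live. Engine verification includes an exact closed-form
(Bateman) oracle for the one-compartment oral model and, for the full
topology, the well-stirred identity that the oral AUC of a purely
uptake-cleared victim scales exactly with `1 + I/Ki` under constant
inhibitor exposure.

### Drug models

Shipped as editable YAML configs:

* **dicloxacillin / flucloxacillin** (precipitants): one-compartment oral
  models calibrated to clinical anchors for 1000 mg oral dosing (total
  Cmax ≈ 67/46 μM, half-lives ≈ 0.8/1.0 h, availability ≈ 0.7/0.6).
  Simulated Cmax lands within ~8%/3% of the anchors. Inhibition constants
  are the in vitro values: the measured competitive Ki for OATP1B1
  (3.65 μM, dicloxacillin), IC50s elsewhere, with unbound incubation
  assumed (Ki = IC50). The flucloxacillin P-gp entry is a lower-bound
  IC50 used at its bound, making its simulated P-gp effect an upper
  bound.
* **rosuvastatin_surrogate / dabigatran_surrogate / digoxin_surrogate**
  (victims): openly parameterised stand-ins for proprietary compound
  models, built from literature-typical PK (for the statin surrogate:
  fa 0.5 with OATP2B1-mediated intestinal uptake fraction 0.4 and BCRP
  efflux, hepatic uptake split 0.55/0.25/0.10/0.10 passive, moderate
  hepatic extraction, renal ≈ 28% of clearance, terminal half-life
  ≈ 20 h). They are labelled synthetic in their files and are fit for
  qualitative DDI simulation only — not for quantitative prediction of
  the victims' absolute exposure.

No population variability is simulated: a single representative subject,
deterministic throughout. CYP induction/inhibition, P-gp induction,
preincubation effects, and hepatic-accumulation/toxicity modelling are
out of scope.

## 5. Synthetic-data generators

The generators mirror the study design the analyses assume: 7-point
half-log inhibitor series plus vehicle, triplicate wells, two independent
experiments for cell assays (kinetics: 7–8 substrate concentrations;
vesicle assays: ATP/AMP triplicates). Noise is multiplicative lognormal
with mean 1, parameterised by a fractional CV — replicate scatter in this
kind of plate data is roughly proportional to signal. The default
cv = 0.1 is a plausible placeholder (replicate variability is rarely
reported numerically) and is exposed in every config. Control-cell
background is modelled as inhibitor-independent passive uptake at a
configurable fraction (default 0.1) of the vehicle signal, consistent
with subtracting control means per concentration. The vehicle is encoded
as 0 μM and never plotted/fit on the log axis.

What passing tests on these data do and do not show: they demonstrate
correctness of the estimators under the stated error model (unbiased
median recovery, calibrated CIs, agreement with brute-force oracles), not
robustness to real-plate pathologies — position effects, carryover,
heteroscedasticity beyond the multiplicative model, or LC–MS calibration
drift are all outside the generator.

## 6. Problem sizes used in the shipped checks

Recovery/calibration checks use 200 seeded replicates of the
two-experiment triplicate design; grid-search oracles use 0.001 steps in
log10 parameter space; DDI simulations run 72 h with q8h precipitant
dosing and a single victim dose. These sizes make the whole suite run in
well under a minute while leaving the Monte-Carlo tolerances comfortably
resolved.
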