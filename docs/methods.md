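# Methods

## Scope and model structure

`ondapbpk` is a whole-body physiologically based pharmacokinetic (PBPK)
model of ondansetron, built to predict systemic exposure in healthy adults
and in liver-cirrhosis patients graded by Child-Pugh (CP) class, and to
derive exposure-matched dose reductions for the cirrhotic classes.

The body is a closed circulatory loop of 14 compartments — venous blood,
lung, arterial blood, and eleven perfusion-limited tissues (heart, brain,
muscle, adipose, skin, bone, liver, gut, spleen, kidney, rest-of-body) —
plus a gut-lumen absorption depot and a cumulative-elimination audit state
(16 states in total). Each tissue obeys

    V_t dC_t/dt = Q_t (C_in − C_t · BP / Kp_t)

with tissue volume `V_t` (L), regional blood flow `Q_t` (L/min), tissue:plasma
partition coefficient `Kp_t` and blood:plasma concentration ratio `BP`. Gut
and spleen drain through the portal vein into the liver, which also receives
hepatic arterial blood; orally absorbed drug empties first-order (rate `ka`)
from the depot into the hepatic inflow, so first-pass extraction and the
oral/IV exposure ratio emerge mechanistically rather than being imposed.

Elimination is (i) a well-stirred metabolic term on the liver outflow
concentration, `CLint · fu_b · C_liver,out`, which at steady state reproduces
the well-stirred liver model `CL_h = Q_h fu_b CLint / (Q_h + fu_b CLint)`,
and (ii) renal clearance drawn from arterial plasma (specific value
0.13 mL/min/kg scaled by body weight and GFR status).

## Anatomy and partitioning

A single documented reference adult (73 kg, cardiac output 6.5 L/min,
hematocrit 0.47, GFR 116 mL/min) ships as a structured data file with
ICRP-style organ volumes/flows and published tissue composition fractions
(water, neutral lipid, phospholipid). Subjects are derived allometrically:
organ volumes and flows proportional to body weight. Sex and age are
recorded and validated (40–150 kg, 18–85 y) but do not alter anatomy in this
version — a simplification the virtual-trial demographics tolerate because
exposure in this linear model is driven by weight-scaled clearance.

Tissue:plasma partition coefficients use the Poulin–Theil composition-based
equation. The lipid-phase affinity for non-adipose tissue is the pH-7.4
octanol:water **distribution** coefficient (logD, Henderson–Hasselbalch from
logP 2.25 and pKa 7.40): ondansetron is ~70% ionized at plasma pH and using
the neutral-species logP overweights membrane lipid, inflating steady-state
volume of distribution to ~3.4 L/kg and terminal half-life to ~8.5 h, versus
~2.5 L/kg and ~6.1 h with logD (literature: 1.8 L/kg, 3.8 ± 1 h). Adipose
uses the olive-oil variant (log Pvo = 1.115 logD − 1.35) with unit tissue
unbound fraction; elsewhere fu_tissue defaults to fu_plasma so the
unbound-fraction ratio cancels. The blood:plasma ratio assumes unit
concentration ratio between plasma water and erythrocyte water:
`BP = (1 − Hct) + Hct · 0.63/0.96` (≈ 0.84 at Hct 0.47, close to the
literature ~0.83); both water fractions are configurable.

## Clearance parameterization and calibration

The published per-pathway intrinsic clearances (CYP1A2 0.21, CYP3A4
0.03 L/min) are simulator-internal quantities whose absolute scale is not
recoverable; they are treated as relative pathway weights. One global
multiplicative `calibration_factor` is fitted once — by root-finding on the
simulated reference subject — so the healthy 73 kg adult's 8 mg IV (5-min
infusion) AUC0-inf equals the published model's central healthy prediction,
312.4 ng·h/mL (equivalently plasma CL 5.85 mL/min/kg; the published healthy
predicted CL range is 5.70–6.76). The fitted factor (9.5009) is frozen in
the packaged drug file; `ondapbpk.calibration.run_calibration()` reproduces
it from scratch. The absorption constant `ka` (0.9925 /h) is fitted the same
way to the mean published predicted healthy oral Cmax (28.61 ng/mL) with
`Fa = 1`. The resulting oral bioavailability is ≈ 0.68, inside the known
60–70% clinical range; the published predictions imply F ≈ 0.83, which
conflicts with that range, and the physiologic value was preferred — oral
exposure predictions are correspondingly ~18% below the published ones but
remain well within the twofold qualification band.

## Cirrhosis physiology

Child-Pugh A/B/C scaler sets (packaged one file per class) modify a healthy
physiology: functional liver mass (0.69/0.55/0.28), CYP abundances, albumin
(0.84/0.69/0.53 of control, entering unbound fraction as
`fu' = fu / (alb·(1−fu) + fu)`), hematocrit set absolutely
(0.39/0.37/0.35), portal flow collapse (×0.4/0.36/0.04) with
hepatic-arterial compensation (×1.3/2.3/3.4), a hyperdynamic increase of all
non-hepatic non-renal flows (×1.75/2.25/2.75), reduced renal flow and GFR.
Cardiac output is recomputed as the sum of scaled regional flows.

The two CYP scaler families come from different source literatures and are
interpreted accordingly: the CYP1A2 values are whole-liver activity
fractions applied as-is, whereas the CYP3A4 values are abundances per unit
functional liver mass and are multiplied by functional liver mass
(total CP-C CYP3A4 capacity = 0.4 × 0.28). The alternative uniform readings
fail independent checks: multiplying *both* pathways by functional liver
mass drops CP-C clearance to ~0.65 mL/min/kg, pushing the predicted CP-C
AUC to ~2800 ng·h/mL and breaking the twofold criterion against the observed
value, while applying *neither* compresses the severity gradient
(CP-C AUC ~940). The mixed reading reproduces the published CP-A/B/C
predicted clearances (3.81/2.28/1.51 mL/min/kg) to within ~4% with no
disease-specific fitting.

## Numerics

The assembled system is linear and time-invariant with piecewise-constant
inputs, so the default solver propagates the exact solution with cached
matrix exponentials segment by segment (augmented-matrix form for the
infusion inhomogeneity). Mass balance holds to ~1e-13 relative and
superposition/dose-linearity to solver round-off; an LSODA route
(rtol 1e-10) is retained as an independent cross-check. Output grids refine
during infusion and the first hours (0.02 h steps to 3 h, 0.1 h to 12 h,
0.5 h thereafter) so that infusion-end peaks are sampled exactly. The
simulation horizon defaults to ~8 analytic half-lives (Vss/CL), keeping the
NCA extrapolated AUC fraction below ~1%.

NCA uses the linear-up/log-down trapezoid (with a C(0)=0 convention when a
profile lacks a pre-dose sample), and a terminal log-linear regression whose
window maximizes adjusted R² over all suffixes of ≥3 points after Tmax
(ties to the longer window). CL is dose/AUC0-inf per kg; for oral dosing
this is CL/F.

## Virtual populations

Each verification study contributes its dosing regimen and demographics
(sex split, age and weight ranges or mean ± SD; uniform sampling within
ranges, normal for mean ± SD, clipped to the supported envelope). Studies
that print no weights — including the cirrhosis study — use an aggregate
healthy-adult envelope (18–43 y, 57.5–90.5 kg) formed from the union of the
printed healthy ranges. Inter-individual variability is log-normal with
median 1: CV 30% on intrinsic clearance, 20% on ka, 15% on a global Kp
scale. These CVs are not printed in the source material; they were chosen
once so the healthy 5–95% exposure envelope spans roughly the spread of the
per-study predictions, and they are exposed on `PopulationSpec`. Envelopes
report median, 5–95 (default) and 10–90 percentiles plus min/max, pointwise.
Production populations use n = 1000 per scenario; a fixed seed makes every
subject table and PK summary bit-reproducible.

## Qualification statistics

For each study and parameter the ratio R = observed/predicted is computed;
the acceptance band is the inclusive twofold range [0.5, 2.0]. Summary
metrics per route × parameter: the arithmetic mean ratio (this is what the
published per-parameter "AFE" columns numerically contain), the geometric
average fold error 10^mean(log10 R) (the two differ, e.g. 0.98 vs 0.965 for
healthy IV AUC; both are reported and labelled), and RMSE. Two-decimal
half-up rounding is applied only at rendering. A handful of printed values
carry final-digit defects that cannot be re-derived from the printed inputs
(two ratio entries off by one ulp; the oral AUC/CL RMSEs; two oral percent
increases off by ≤0.03); tests pin the recomputed values and bound the
deviation from print.

## Dose adjustment

Exposure increases are reported as 100·(AUC_cp − AUC_healthy)/AUC_cp — the
form that reproduces the published percentages (the conventional
healthy-denominator form does not). Dose adjustment exploits linearity:
adjusted dose = base dose × target/achieved median AUC, snapped to 0.5 mg
resolution, then verified by re-simulating the same subjects (tolerance 10%
of target). For CP-C IV this yields 2.0 mg against the 2.07 mg linear
preview from the published medians.

## Synthetic observed data

The clinical concentration–time series used for the original qualification
were digitized from literature figures and are not printed; the
`synthetic` module generates stand-ins from closed-form one- or
two-compartment disposition (IV infusion or first-order oral), multiplied by
log-normal assay noise and censored at a configurable LLOQ (default
0.5 ng/mL, a typical bioanalytical floor). An ondansetron-like
parameterization (two-compartment, CL 28.5 L/h so 8 mg gives
AUC ≈ 280 ng·h/mL, β half-life ≈ 4 h) anchors the NCA-recovery tests:
median AUC/CL recovery error < 5% across 200 replicates at 15% assay CV.
These synthetic profiles share the compartmental form of the generator, not
the full physiology, so passing recovery tests demonstrates correctness of
the NCA pipeline — not fidelity of the PBPK model to real digitized data.

## Known limitations

* Cmax after short (5-min) infusions is governed by early mixing and is the
  least identifiable output: predictions exceed the observed peaks by more
  than twofold for the same two table entries where the published model
  itself printed sub-0.5 ratios (0.47 healthy, 0.35 CP-A); the package's
  maximum fold deviation (≈2.76) stays below the published model's own
  (≈2.84).
* Liver volume is not shrunk in cirrhosis (functional mass enters through
  enzyme capacity only); distribution effects of the smaller liver are
  negligible for these endpoints.
* No CYP2D6 pathway, transporters, metabolites, saturable kinetics,
  pediatric/pregnancy physiology, or PD (QT) modeling.
* Sex- and age-specific anatomy is not modeled; demographics affect only
  weight scaling and bookkeeping.
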