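# ondapbpk

Whole-body physiologically based pharmacokinetic (PBPK) simulation of
**ondansetron** in healthy adults and in **liver-cirrhosis patients**
(Child-Pugh classes A/B/C), with virtual-population trials,
noncompartmental analysis (NCA), model-qualification statistics and
exposure-matched dose adjustment.

Ondansetron, a 5-HT3 antagonist given for chemotherapy-, radiation- and
surgery-associated nausea, is cleared almost entirely by hepatic CYP1A2/
CYP3A4 metabolism (renal clearance < 5%). In cirrhosis, reduced functional
liver mass and enzyme abundance, portal-flow collapse, hypoalbuminemia and
a hyperdynamic circulation raise systemic exposure several-fold, so doses
need adjustment by disease severity. This package is for PK modelers and
clinical-pharmacology researchers who want an open, fully scripted, tested
re-implementation of that drug-disease model — no proprietary simulator
required.

## Model

The body is a closed loop of 14 perfusion-limited compartments (blood
pools, lung, and eleven tissues) plus an oral absorption depot and a
mass-balance audit state. Each tissue follows

    V_t dC_t/dt = Q_t (C_in − C_t · BP / Kp_t)

with Poulin–Theil partition coefficients Kp (octanol logD for tissues,
olive-oil variant for adipose). Hepatic elimination is the well-stirred
liver model

    CL_h = Q_h · fu_b · CL_int / (Q_h + fu_b · CL_int)

on portal + arterial inflow, with renal clearance (0.13 mL/min/kg, GFR
scaled) on arterial plasma. Child-Pugh physiology scalers transform flows,
hematocrit, albumin, GFR and enzyme capacity per class. The system is
linear, so the solver propagates the exact matrix-exponential solution.
Model qualification uses observed/predicted ratios R (twofold band
0.5 ≤ R ≤ 2.0), arithmetic mean ratio, geometric average fold error
AFE = 10^mean(log10 R), and RMSE. See `docs/methods.md` for assumptions,
the one-time clearance/absorption calibration, and known limitations.

## Worked example

```python
import ondapbpk as o
from ondapbpk.nca import pk_summary

drug = o.load_ondansetron()                       # packaged, calibrated
phys = o.build_reference_physiology(body_weight=73.0, age=30.0, sex="male")
iv = o.DosingRegimen(route="iv_infusion", dose=8.0, infusion_duration=5.0)

pk = pk_summary(o.simulate_individual(o.build_model(drug, phys, iv)), iv, 73.0)
print(pk.auc_0inf, pk.cl, pk.t_half)

for cp in "ABC":
    sick = o.apply_cirrhosis(phys, o.load_cp_scalers(cp))
    pk_cp = pk_summary(o.simulate_individual(o.build_model(drug, sick, iv)),
                       iv, 73.0)
    print(cp, pk_cp.auc_0inf, pk_cp.cl)
```

prints (formatted):

```
healthy:  AUC0-inf   312.4 ng·h/mL   CL 5.85 mL/min/kg   t1/2 6.1 h
CP-A:     AUC0-inf   461.3 ng·h/mL   CL 3.96 mL/min/kg   +32.3%
CP-B:     AUC0-inf   745.0 ng·h/mL   CL 2.45 mL/min/kg   +58.1%
CP-C:     AUC0-inf  1236.0 ng·h/mL   CL 1.48 mL/min/kg   +74.7%
```

The healthy 8 mg IV exposure (AUC0-inf 312.4 ng·h/mL, plasma clearance
5.85 mL/min/kg) reflects the calibrated disposition model; exposure rises
monotonically with Child-Pugh severity — roughly 4-fold in CP-C — and the
final column is the percent increase relative to the cirrhotic exposure.
Scaling the CP-C dose by 312.4/1236 (≈ 2 mg instead of 8 mg) restores
healthy-equivalent median exposure; `ondapbpk.dose.optimize_dose` does this
population-wide with re-simulation.

Virtual trials, qualification reports, dose adjustment and synthetic
observed profiles are also available from the command line:

```bash
ondapbpk simulate --scenario scenario.yaml --out out/ --seed 1
ondapbpk evaluate --comparisons comparisons.csv --out out/
ondapbpk optimize-dose --cp-class C --out out/ --seed 1
ondapbpk make-synthetic --spec profile.yaml --out profile.csv
```

## Layout

| Path | Contents |
| --- | --- |
| `src/ondapbpk/physiology.py` | reference anatomy, Child-Pugh scalers |
| `src/ondapbpk/drug.py` | drug parameters, Kp, binding, clearances |
| `src/ondapbpk/engine.py` | ODE assembly and exact simulation |
| `src/ondapbpk/population.py` | virtual populations, envelopes |
| `src/ondapbpk/nca.py` | noncompartmental analysis |
| `src/ondapbpk/evaluation.py` | ratios, AFE, RMSE, twofold checks |
| `src/ondapbpk/dose.py` | exposure comparison, dose adjustment |
| `src/ondapbpk/synthetic.py` | synthetic observed profiles, table fixtures |
| `src/ondapbpk/scenarios.py` | study designs, qualification table |
| `src/ondapbpk/calibration.py` | one-time clearance/absorption calibration |
| `src/ondapbpk/data/` | reference human, CP scalers, printed-table CSVs |
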