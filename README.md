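# spakit

Transport analysis for peritoneal dialysis dwells: the complete
computational pipeline of a **standard peritoneal permeability assessment
(SPA)** — a 2 L, 4 h, 1.36 %-glucose dwell with timed dialysate sampling
and venous draws at 0/120/240 min — together with a seeded kinetic dwell
simulator so that every estimator in the package can be verified by
parameter recovery against a known ground truth.

It is written for experimental nephrology groups running dialysis dwells
in large-animal models (the defaults describe a uremic pig with a slow
peritoneal membrane) and for anyone who needs the classical SPA
arithmetic as tested, reusable code rather than a spreadsheet.

## What it computes

For each dwell, from the measured sample table:

* **Residual volume** before and after the dwell by indicator dilution of
  endogenous albumin: `RV = V_in · C_t0 / (C_drain − C_t0)`, where
  `C_drain` is the albumin concentration of the previous effluent (or end
  drain) and `C_t0` that of the freshly mixed dialysate (or flush).
* **Net ultrafiltration** from the volume ledger:
  `UFV = V_t240 + RV_t240 + V_sample − (V_instilled + RV_pre)`; negative
  values mean net fluid absorption.
* **Mass transfer area coefficient (MTAC)** of urea, creatinine,
  phosphate and potassium by the simplified Garred formula
  `MTAC = (V_t/t) · ln[V_0 (P − D_0) / (V_t (P − D_t))]`,
  with `P` the mean of the 0/120/240 min plasma values (single interior
  gaps linearly interpolated, missing endpoints carried and flagged).
* **Total solute removal** `TSR = C_t·V_t − C_0·V_0` and **clearance**
  `Cl = TSR / (C_av · t)` in mL/min.
* **D/P ratios at 4 h** (urea, creatinine), **D/D0 glucose**, and
  body-surface-area normalization (× 1.73/BSA, porcine power-law BSA).
* **Peritonitis classification** by the 2-of-3 case definition (positive
  effluent culture, cloudy effluent, effluent leukocytes > 0.1 × 10⁹/L on
  a ≥ 2 h dwell), with three-valued logic for unknown findings, and
  stratified mean ± SD / median (IQR) summary tables by peritonitis
  status.

Anything that cannot be computed (marker failure, plasma/dialysate
gradient crossover, missing samples) is *flagged*, never silently dropped
or clamped.

The simulator (`spakit.simulate`) integrates a two-pool model per solute,
`d(VD)/dt = MTAC(P − D) + S·Qu(t)·P − L·D`, with exponentially decaying
ultrafiltration `Qu`, constant lymphatic absorption `L`, scheduled
aliquot removal and multiplicative measurement noise — and carries a
ground-truth ledger (integrated flows, transported masses) kept strictly
apart from the noisy observables.

## Worked example

```python
from spakit import analyze_spa, classify_peritonitis, scenario_preset, simulate_dwell

config = scenario_preset("low_transporter", seed=7)
dwell = simulate_dwell(config)
result = analyze_spa(dwell.observables)

print(f"residual volume pre/post: {result.rv_pre:.0f} / {result.rv_post:.0f} mL")
print(f"net ultrafiltration:      {result.ufv_net:+.0f} mL over 4 h")
for solute in ("urea", "creatinine", "phosphate", "potassium"):
    rec = result.solutes[solute]
    print(f"MTAC {solute:10s} {rec.mtac:5.2f} mL/min   "
          f"({rec.mtac_normalized:5.2f} mL/min/1.73 m2)   "
          f"clearance {rec.clearance:4.2f} mL/min")
print(f"D/P creatinine 4 h: {result.dp_creatinine_4h:.2f}   "
      f"D/D0 glucose 4 h: {result.dd0_glucose_4h:.2f}")
print("classification:", classify_peritonitis(dwell.observables.diagnostics))
```

prints

```
residual volume pre/post: 285 / 331 mL
net ultrafiltration:      +245 mL over 4 h
MTAC urea        6.72 mL/min   (10.79 mL/min/1.73 m2)   clearance 5.32 mL/min
MTAC creatinine  2.61 mL/min   ( 4.19 mL/min/1.73 m2)   clearance 3.04 mL/min
MTAC phosphate   1.71 mL/min   ( 2.74 mL/min/1.73 m2)   clearance 2.36 mL/min
MTAC potassium  13.25 mL/min   (21.28 mL/min/1.73 m2)   clearance 7.29 mL/min
D/P creatinine 4 h: 0.36   D/D0 glucose 4 h: 0.65
classification: no_peritonitis
```

The residual volumes scatter around the true 300 mL because this dwell
carries 5 % assay noise; the D/P creatinine of 0.36 and D/D0 of 0.65 are
the signature of a slow ("low transporter") membrane; the estimated
MTACs sit somewhat below the generating values (8.3 / 3.3 / 2.3 /
18.6 mL/min) — the documented downward bias of the Garred estimator when
ultrafiltration, lymphatic absorption and a residual volume are present
(see `docs/methods.md`).

### Command line

```sh
spakit simulate --preset low_transporter --n 12 --seed 7 --out run/
spakit compute  --input run/dwells.csv --out run/
spakit report   --results run/results.json --out run/
```

produces a tidy `dwells.csv`, the ground-truth ledger `truth.json`, a
`results.json` with every report, its flags, the configuration echo and
seed, and a `summary.csv` in the parameter × group (all / no peritonitis
/ peritonitis) layout. Identical seeds reproduce identical bytes.

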