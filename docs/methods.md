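# Methods

## The assessment

A standard peritoneal permeability assessment (SPA) instils a fresh 2 L
bag of 1.36 % glucose dialysate into the peritoneal cavity after complete
drainage of an overnight dwell, samples the dialysate at 0, 10, 30, 60,
120, 180 and 240 min (a 100–200 mL aliquot is drained, 2–7 mL retained,
the rest re-instilled), draws venous blood at 0, 120 and 240 min, and
ends with a complete drain followed by a flush with a fresh bag. From
these measurements the package derives residual volumes, net
ultrafiltration, solute MTACs, removals, clearances and the 4 h
concentration ratios.

## Formulas and conventions

**Units.** Minutes, mL, mM for small solutes (urea, creatinine,
phosphate, potassium, sodium, glucose) and g/L for albumin and total
protein, everywhere inside the package; conversions (µM, L, g/dL, h …)
happen once at ingest in `spakit.io`. Concentration × volume is then
µmol (mg); amounts are reported in mmol (g).

**Residual volume.** `RV = V_in·C_t0/(C_drain − C_t0)` with albumin as
the endogenous marker. `C_drain ≤ C_t0` is an error state (indicator
dilution failed), reported as a flag — never clamped — mirroring how
real assessments with inaccurate residual-volume measurements must be
excluded rather than repaired.

**Net ultrafiltration.** `UFV = V_t240 + RV_t240 + V_sample − V_t0`,
where `V_t0` is the instilled volume plus the pre-dwell residual volume.
The post-dwell residual volume comes from applying the same dilution
formula to the flush; the flush volume is a field of the dwell record
and defaults to the instilled volume (a fresh bag).

**MTAC (Garred).** `MTAC = (V_t/t)·ln[V_0(P − D_0)/(V_t(P − D_t))]` with
`V_0` the instilled volume and `V_t` the drained volume at 240 min —
both taken literally as drained/instilled rather than total
intraperitoneal volumes. Using total intraperitoneal volume (adding the
residual volumes) would be a defensible alternative; the literal reading
was chosen because it is what the formula's inputs denote and what a
clinical calculator would use, and the resulting bias is quantified
below rather than hidden. `P` is the mean of the 0/120/240 min plasma
values. If `(P − D)` changes sign between the start and end of the dwell
the single-pool diffusion model underlying the formula is violated and
the MTAC is flagged non-computable instead of taking a complex
logarithm. MTAC is computed for urea, creatinine, phosphate and
potassium; sodium and the proteins are carried as measured series only.

**Plasma imputation.** A missing 120 min value is linearly interpolated
between the endpoints; a missing endpoint is carried from the nearest
available draw (interpolation is impossible there). Every imputation is
recorded in the result's flags.

**TSR and clearance.** `TSR = C_t·V_t − C_0·V_0` with *intraperitoneal*
volumes (drain + residual; instilled + residual) since the solute mass
resides in the whole cavity. Clearance is implemented as
`Cl = TSR/(C_av·t)`: the printed form TSR/(C_av/t) found in some write-ups
is dimensionally inconsistent with mL/min, and the product form
reproduces the expected clearance < MTAC ordering for purely diffusive
transport.

**D/P denominator.** The plasma value at 240 min by default; the
0/120/240 mean is available (`dp_denominator="mean"`) since published
assessment protocols differ on this point. With plasma constant within
a dwell the two coincide.

**BSA normalization.** `× 1.73/BSA` with `BSA = k·W^a`, defaulting to the
porcine power law `k = 0.0734, a = 0.656` (m², kg). The coefficients are
exposed because the porcine literature carries more than one fit; with
these defaults a 56 kg pig has BSA ≈ 1.04 m², making normalized values
≈ 1.67 × raw, consistent with published porcine transport tables.

**Peritonitis.** 2-of-3 rule: positive effluent culture, cloudy effluent,
effluent leukocytes > 0.1 × 10⁹/L. The dwell-duration qualifier is read
as attaching to the leukocyte criterion only (its textual position in
the case definition): a count from a dwell shorter than 120 min does not
satisfy the criterion, because short dwells have not accumulated an
interpretable cell count. Unknown findings use three-valued logic; the
call is `indeterminate` exactly when both outcomes remain possible.
Quantiles in the stratified summaries are linear-interpolation (type-7)
quantiles; SD is the n−1 sample estimate and is reported as undefined
for n = 1.

## The simulator

The generative model is this package's own construction (no deposited
dwell-level data exist to fit): per solute,

    d(V·D)/dt = MTAC·(P − D) + S·Qu(t)·P − L·D
    dV/dt     = Qu(t) − L,     Qu(t) = q0·exp(−t/τ)

with constant plasma `P` within a dwell, sieving coefficient `S` on the
convective flux, constant lymphatic absorption `L` removing fluid at
dialysate composition, instantaneous removal of the retained aliquot at
each sample time, and multiplicative Gaussian noise (truncated at zero)
on measured concentrations only. It is deliberately the *simplest* model
whose diffusive limit (q0 = L = 0, no residual volume, no sampling) is
exactly the closed form `D(t) = P + (D0 − P)·e^(−MTAC·t/V)` assumed by
the Garred estimator. That gives a clean oracle hierarchy: recovery must
be exact (≤ 1e−9 relative, limited only by ODE tolerance) on the limit,
and carries a bounded, reproducible bias off it.

**Defaults** are the study conditions of a uremic pig at the
acute-on-chronic uremia peak: MTACs urea 8.3, creatinine 3.3, phosphate
2.3, potassium 18.6 mL/min (the quiescent-membrane group means of the
porcine transport table); plasma urea 16.7 mM, creatinine 932 µM,
phosphate 2.6 mM, potassium 4.4 mM; fresh-bag glucose 75 mM and sodium
132 mM; residual volume 300 mL at 2.3 g/L albumin; q0 = 3.8 mL/min,
τ = 90 min, L = 0.5 mL/min (net UF ≈ +200 mL/4 h); 5 mL retained per
sample; noise CV 5 %; body weight 60 kg. The `peritonitis` preset moves
urea/creatinine/phosphate MTAC to the inflamed-group means (12.6 / 7.7 /
6.0), leaves potassium essentially unchanged (17.4), speeds glucose
absorption, and sets q0 = 1.5, L = 1.2 so that net fluid balance is
negative (≈ −160 mL/4 h) — reproducing the direction of every group
contrast of the published table.

**Overnight dwell.** The residual fluid's small-solute composition is the
constant-volume closed form evaluated over an 8 h overnight dwell; its
albumin concentration is set directly by `residual_albumin` rather than
derived from the dwell-scale albumin MTAC, because overnight effluent
protein reflects cumulative leak, not four-hour diffusion kinetics. The
end drain leaves the same residual volume behind as the overnight drain
(same cavity and catheter), which keeps the post-dwell dilution
inversion exactly solvable at zero noise.

**Numerics.** Explicit high-order Runge–Kutta (DOP853) with rtol 1e−11 /
atol 1e−9, integrating segment-by-segment between sample times with the
aliquot removal applied as a discrete event (volume removed at unchanged
concentration). Cumulative diffusive influx and lymphatic efflux are
carried as extra quadrature states; the convective integral has a closed
form. The truth ledger's mass and volume balance identities close to
≈ 1e−12 relative, comfortably within the 1e−8 tolerance asserted by the
tests. A configuration whose flows drive the cavity volume toward zero
aborts with a diagnostic rather than producing unphysical output.

**Uremia trajectories.** Daily plasma concentrations for an
acute-on-chronic kidney-injury episode rise from the chronic baseline to
the peak along a smoothstep ramp (maximum exactly at `peak_day`, default
day 12) and relax exponentially with a 5.5-day time constant, so
near-baseline (within 25 %) is only reached around four weeks — the
defaults are urea 3.6 → 16.7 mM and creatinine 212 → 932 µM.

## What the tests do and do not show

Parameter-recovery tests prove the implementation is a correct inverse
of its own generative model, and quantify estimator bias under the
convective conditions the assessment is actually used in: with the
default flows and residual volume the Garred estimate sits ≈ 14 % below
truth (dominated by using the instilled rather than the total
intraperitoneal volume as `V_0`), and the bias shrinks monotonically to
numerical zero as the fluid flows are scaled away. Real dwells add
intra-dwell plasma drift, osmotically coupled (not prescribed)
ultrafiltration, three-pore membrane behaviour, glucose degradation and
assay-specific error structure, none of which the simulator claims to
emulate; no dwell-level raw profiles are published for the target
animal model, so simulator realism beyond group summary statistics is
not claimed. Passing tests therefore certify the arithmetic and its
documented bias envelope, not membrane physiology.

## Known limitations

* Effective lymphatic absorption rate is not estimated from data (no
  reliable intraperitoneal volume marker exists); it is a simulator
  input only.
* No three-pore/Pyle–Popovich model fitting, sodium-sieving analysis, or
  inferential statistics — the summary layer exposes group vectors so
  any statistics package can be applied downstream.
* The porcine BSA coefficients are one published power law among
  several; they are configurable and their choice scales only the
  normalized columns.
* Scale of the verification studies: 200 random configurations for the
  conservation suite, 500 noise seeds for the residual-volume Monte
  Carlo, 12 + 5 dwells for the group-contrast batch — sizes chosen to
  make each check statistically decisive while keeping the whole suite
  fast enough to run on every change.
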