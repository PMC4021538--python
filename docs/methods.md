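# Methods

## Model structure

`crcsurv` simulates a cohort of patients who have just undergone curative
resection for colorectal cancer. Two interacting submodels drive each
patient's five-year course.

**Disease progression (continuous time).** At baseline each patient is
assigned a future recurrence status (Bernoulli with probability `p_recur`)
and, if recurring, an anatomic site drawn from a categorical distribution
over combinations of local status (locoregional, anastomotic-only,
intraluminal/metachronous) and metastasis status (liver, lung,
multiple/other organs). Recurrences are considered present from the moment
of surgery; three continuous milestones follow:

* `D ~ Exponential(r_d)` — earliest time the recurrence is detectable by
  testing. The exponential hazard reproduces the empirically declining
  incidence of recurrence with time since surgery.
* `U = D + x_du·(1 + r_u·D)` — loss of resectability. `x_du` is the window
  width at `D = 0`; positive `r_u` makes later-appearing (more indolent)
  recurrences stay operable longer.
* `S = D + x_ds·(1 + r_s·D) + ε`, `ε ~ N(0, σ_ds)` — symptom onset, which
  can fall on either side of `U`. Under no surveillance at all, only
  patients with `S < U` can still be cured.

**Surveillance and re-treatment (discrete time).** A five-state Markov loop
(no known recurrence, recurrence curatively treated, recurrence palliatively
treated, dead of cancer, dead of other causes) advances in 3-month cycles
over a 20-cycle (5-year) horizon. A binary cycle × modality schedule matrix
says which of seven tests (CEA assay, chest X-ray, hepatic and
other-abdominal CT, hepatic ultrasound, colonoscopy, clinical
interview/exam) are administered at each visit. Within a cycle, events
resolve in a fixed order:

1. *Symptomatic interval detection*: if `S` falls inside the cycle, the
   recurrence is diagnosed at the continuous time `S`.
2. *Scheduled testing at the cycle boundary*: a test returns positive with
   probability equal to its sensitivity when the patient has a detectable
   recurrence (`t ≥ D`) within the modality's anatomic reach, and with
   probability 1 − specificity otherwise. Any positive triggers one full
   workup with combined sensitivity and specificity of 100%: it diagnoses
   any detectable recurrence — including at sites the firing test cannot
   see — and otherwise rules recurrence out with no lasting effect. False
   positives therefore never create false diagnoses, but do surface true
   disease elsewhere.
3. *Background mortality*: a per-cycle probability `p` with
   `(1 − p)^20 = 1 − m`, applied in every living state.

On diagnosis, re-treatment is curative (salvage surgery) when the diagnosing
cycle **begins** before the continuous unresectability time `U` and the site
is operable; otherwise palliative. The cycle-level comparison — rather than
comparing the exact boundary diagnosis time with `U` — mirrors the
discrete-time re-treatment decision of the original two-submodel design and
is what reproduces its published predictions; with a strict boundary
comparison the achievable salvage proportion is analytically capped below
the reported values. Operability: local-only disease and liver metastases
are operable within the window, lung metastases with probability 0.5, and
multiple/other-organ metastases never. The diagnosed patient receives a
fixed life expectancy (21 months after salvage, 8 months if unresectable)
and dies of cancer deterministically at diagnosis time + life expectancy if
that falls within the horizon; background mortality competes each cycle and
the first death wins. Curatively treated patients remain under the schedule
but have no second recurrence to find (second primaries are out of scope).

## Time units and conversions

All internal times are continuous 3-month cycles: 1 cycle = 13 weeks =
3 months, 1 year = 4 cycles. Rates (`r_d`, `r_u`, `r_s`, per-cycle
mortality) are per cycle; window parameters (`x_du`, `x_ds`, `σ_ds`) are
specified in weeks and converted on use; life expectancies are specified in
months or years. Serialized scenarios carry explicit unit suffixes
(`x_du_weeks`, `post_salvage_months`, …).

## Default parameter values

Calibrated progression/background parameters (the packaged
`CALIBRATED_PARAMS` set): `r_d = 0.092`/cycle, `x_du = 6` weeks,
`r_u = 0.11`/cycle, `x_ds = 17` weeks, `r_s = 0.07`/cycle, `σ_ds = 11`
weeks, `m = 1.6%` five-year cumulative. Test characteristics
(sensitivity/specificity): CEA .64/.90, chest X-ray .76/.95, hepatic CT
.83/.93, other-abdominal CT .46/.98, hepatic ultrasound .62/.85, colonoscopy
.95/1.00, clinical exam .42/.95. Life expectancies: 20.7 years with no
recurrence (never binding within the horizon, carried for completeness),
21 months post-salvage, 8 months post-unresectable-diagnosis. All of these
are the published point estimates; the sensitivity-analysis ranges shipped
in `SENSITIVITY_RANGES` are the published plausible ranges.

Modality → site reach (the published sources split CT performance by
target): CEA and clinical exam see every site; chest X-ray sees lung
metastases; hepatic CT and hepatic ultrasound see liver metastases;
other-abdominal CT sees locoregional disease and multiple/other metastases;
colonoscopy sees anastomotic-only and intraluminal recurrences. A scheduled
abdominal/pelvic CT administers its hepatic and other-abdominal components
as one visit.

## Packaged trial scenarios

`pietra_intensive` (calibration arm): recurrence probability 39.4%,
metastasis split liver/lung/other = 26.7/0.0/73.3 (exactly 4/15, 0/15,
11/15), background mortality 1.6%, visits every 3 months for two years then
every 6 months (clinical exam, CEA, hepatic ultrasound) with annual CT,
chest X-ray and colonoscopy. `pietra_minimal` (validation arm): recurrence
probability 40.4%, split 14.2/4.8/81.0 (3/21, 1/21, 17/21), visits every 6
months for one year then annually, no CT, and background mortality
1.6% + 14.0pp = 15.6% — the published attribution of the residual
between-arm DFS difference to non-cancer mortality (the companion "3.4pp
annual increment" phrasing is treated as descriptive).

Visit months are anchored to surgery with no cycle-0 visit: "every 3 months
for 2 years" → cycles 1–8, "every 6 months thereafter" → cycles 10, 12, …,
20; "every 12 months" → cycles 4, 8, …, 20; minimal-arm "every 6 months for
1 year" → cycles 2, 4, "every 12 months thereafter" → cycles 8, 12, 16, 20.

The split of recurrences between local-only and metastatic disease is not
published directly. The printed metastasis distributions are exact fractions
over 15 (intensive) and 21 (minimal) metastatic patients, and the printed
recurrence rates imply 41 and ~42 recurrers, pinning the local-only shares
at 26/41 ≈ 63.4% and 21/42 = 50%. Within the local share, locoregional :
anastomotic-only is assumed 2 : 1. Both shares are ordinary scenario inputs
and can be overridden.

## Calibration

`calibrate` runs rounds of: build an evenly spaced grid over the seven
parameter ranges (3–8 points per parameter, endpoints included; the shipped
starting ranges are the published ones) → simulate every combination →
filter sequentially by target in priority order DFS5, OS5, OS4, OS3,
salvage, OS2, OS1 (OS2/OS1 last as most event-sparse), dropping candidates
more than 1pp from the observed value, falling back to 2pp when a step would
empty the pool, and passing the step through with a warning if even 2pp
eliminates everyone → narrow each range to the survivors' [min, max] padded
by one previous grid step per side, clipped to the starting range → repeat
until the round's best unweighted sum of squared differences (percentage
scale, all seven targets) stops improving, then keep the previous round's
survivors. The final set is the survivor closest to the final ranges'
midpoints (total width-normalized distance, ties resolved
parameter-by-parameter). Each candidate runs with a sub-seed derived from
(master seed, round, candidate index), so a calibration is reproducible end
to end and candidates are independent.

The default *desk* profile uses 3-point grids, 2,000 patients per
combination and at most 3 rounds (≈1 minute on one CPU); these sizes are the
package's default working scale, chosen so the whole exercise — including
the parameter-recovery test, which regenerates targets from the simulator
itself and checks the final ranges contain the generating values — runs
interactively. The *full* CLI profile (4-point grids, 10,000 patients, up to
9 rounds) mirrors the original exercise's cohort size and round count; the
original 276,960-combination search is reachable via config but not a test
requirement.

## Sensitivity analysis

`one_way_sweep` runs baseline/low/high with one shared seed. All random
draws are indexed by patient, cycle and test position rather than consumed
conditionally, so a common seed acts as true common random numbers: varying
one parameter changes only the thresholds the same uniforms are compared
against. Reported changes are *relative* (percent of base case), matching
the "within 5% of the base case" reading; endpoints only are evaluated.
Rankings sort by the maximum absolute relative change of the primary outcome
(salvage proportion by default) with a stable input-order tie-break.

## Randomness and reproducibility

Every public entry point takes an integer seed. Cohort runs derive named
child streams (profiles, test results, lung-operability, background
mortality) from `numpy.random.SeedSequence(seed)`, and patient *i* always
reads the *i*-th slot of each stream, so enlarging a cohort appends patients
without reshuffling existing ones, and identical (scenario, seed) pairs are
bitwise identical. A scalar per-patient reference implementation
(`simulate_patient`) mirrors the vectorized engine's event ordering; the two
are checked against each other exactly in deterministic settings and
statistically otherwise, and the engine is checked against an independent
brute-force event enumeration and against numerical integration of the
no-surveillance salvage probability.

## Numerical choices and degenerate inputs

* `ε` can push `S` below `D`; `S` is clipped to `D` (not resampled),
  preserving the error distribution above the boundary; the unclipped draw
  is retained for inspection.
* Symptoms falling in the same cycle as a scheduled visit resolve first
  (symptom onset is continuous and precedes the boundary); a cancer death
  and a background death in the same cycle resolve to cancer (the
  background draw is the cycle's last event).
* Survival at year *k* is evaluated at exactly cycle 4*k*, after that
  cycle's events; DFS counts a patient event-free when neither a diagnosis
  nor a death of any cause occurred by the horizon.
* Recurrers whose `D` exceeds the horizon are never diagnosable and count
  as disease-free; width-zero calibration ranges collapse to a single grid
  value without error; an all-zero schedule or empty test list disables
  surveillance but leaves symptomatic detection active.

## Synthetic scenarios and what tests show

`generate_synthetic_scenario` draws valid random scenarios (parameter ranges
spanning the calibration starting ranges, Dirichlet site distributions,
Bernoulli schedule matrices) for property-based testing. It emulates the
*structure* of the study conditions — not real patient heterogeneity: there
are no covariates, no stage/age effects, no adherence gaps, and test
performance is site-homogeneous. Green property tests therefore demonstrate
internal consistency (invariants, coupling, oracle agreement), not clinical
validity on modern cohorts.

## Known limitations

* Second primary (metachronous) cancers, costs, quality-of-life adjustment
  and re-recurrence after salvage are not modeled.
* The local/metastatic fixture split is reconstructed, not published; the
  salvage proportion is the output most sensitive to it, and the model
  over-predicts the validation arm's observed salvage (as did the original:
  10% predicted vs 6% observed).
* With the published test characteristics, per-visit detection in the
  intensive arm is nearly saturated by the co-scheduled site-agnostic exam
  and the false-positive → workup channel, so the model reproduces the
  published *ranking* of influential parameters (CEA sensitivity first,
  clinical-exam sensitivity next, site-targeted specificities acting
  inversely, life expectancies dominating overall survival) but yields
  smaller relative CEA-sweep magnitudes (≈±3% vs the published ≈±8%).
* Cancer death is deterministic at diagnosis + assigned life expectancy; no
  survival distribution is applied around it.
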