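# smartdrive

In-cabin sensor analytics for driving-based screening of early cognitive
decline.

Driving is a cognitively demanding task, which makes a car a natural setting
for unobtrusive cognitive assessment. This package implements the analysis
stack of a "smart driving" sensor system for a standardized parking-lot test
(10 laps of a 540 m circuit: four left 90° turns, a U-turn, three right 90°
turns per lap, driven first at normal 8–12 mph and then at aggressive
15–21 mph speeds, after a parked baseline phase):

* **Metabolic rate from cabin CO₂.** While the cabin recirculates, the
  driver's exhaled CO₂ accumulates against a first-order air-exchange leak,

  `C(t) = C₀ + (k_gen/λ)(1 − e^{−λt}) + (Cᵢ − C₀) e^{−λt}`,

  with a speed-dependent exchange rate `λ = 0.2534·v[mph] + 10.323 h⁻¹`.
  Fitting `k_gen` on rising segments and converting through the cabin volume,
  an STPD correction (Antoine vapor pressure) and a fixed-RQ Weir combination
  (`EE = 3.941·VCO₂/RQ + 1.106·VCO₂`, RQ = 0.85) yields the driving energy
  expenditure per phase. Drivers with mild cognitive impairment (MCI) show a
  blunted EE rise (< 16 %) from normal to aggressive driving.
* **Turn kinematics.** Peak detection on the 10 Hz gyroscope z channel
  extracts every maneuver's peak angular velocity, angular-acceleration
  extremes, interpolated 1 Hz GPS speed at the peak, and the U-turn period,
  aggregated into 16 session-level driving signatures.
* **Path discrepancy.** The driven GPS track is matched to the designated
  route; missed / unplanned / consecutive U-turns, off-path excursions
  (≥ 8× the 1 m GPS error) and perimeter exits are counted and scored.
* **Classification.** A random forest over 12 per-subject features (10
  signatures plus two engineered indicators, including
  `speed²·EEchange/(0.1·speed) + path deviation`) is evaluated with 100
  stratified 70/30 resampling iterations, an accumulated confusion matrix,
  univariate ROC analyses and a held-out-subject protocol.
* **Synthetic drive simulator.** Generates complete sessions — gyroscope,
  GPS, cabin CO₂/temperature/humidity/pressure, ventilation actuation — for
  parameterized normal-cognition and MCI driver profiles, with a ground-truth
  ledger of injected path errors, so the whole stack is testable without
  vehicle hardware or a study cohort.

## Worked example

```python
from smartdrive.simulate import DriverProfile, simulate_subject
from smartdrive.pipeline import analyze_subject

profile = DriverProfile(cognition="mci", ee_gain_aggressive=0.08,
                        path_error_rates={"off_path": 2.0, "uturns_missed": 1.0})
subject = simulate_subject(profile, subject_id="demo", seed=7)
art = analyze_subject(subject)
for phase in ("parked", "normal", "aggressive"):
    est = art.metabolic[phase]
    print(f"{phase:10s} EE = {est.ee:7.1f} kcal/day   (k_gen = {est.k_gen:6.0f} ppm/h)")
print(f"EE change normal->aggressive: {art.indicators.ee_change_pct:.1f} %")
print(f"speed x EE change:            {art.indicators.speed_x_ee:.0f} mph.%")
print(f"path-deviation score:         {art.path_report.total_score:.0f}")
```

prints

```
parked     EE =  1402.3 kcal/day   (k_gen =   4837 ppm/h)
normal     EE =  1540.3 kcal/day   (k_gen =   5312 ppm/h)
aggressive EE =  1661.7 kcal/day   (k_gen =   5731 ppm/h)
EE change normal->aggressive: 7.9 %
speed x EE change:            142 mph.%
path-deviation score:         4
```

The recovered EE trajectory matches the simulated profile (parked 1400,
+10 % normal, +8 % aggressive), the 7.9 % EE change falls below the 16 %
MCI decision threshold, the hybrid indicator falls below its 160 mph·%
threshold, and the path score reflects the injected missed U-turn (3 points)
and off-path excursion (1 point) that the detector found.

A full synthetic cohort (13 normal + 8 MCI) with the resampled random-forest
evaluation:

```python
from smartdrive.pipeline import run_cohort_analysis
analysis = run_cohort_analysis(13, 8, seed=1, n_iterations=100)
print(analysis.report.accuracy_pct)   # 98.7 on this seed
```

The same steps are scriptable from the shell: `smartdrive simulate`,
`smartdrive extract-turns`, `smartdrive metabolic`, `smartdrive path-score`,
`smartdrive occupancy`, `smartdrive train`, `smartdrive roc` (see
`smartdrive --help`).

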