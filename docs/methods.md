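# Methods

This note documents the models, defaults and numerical choices behind the
package, and what the synthetic data can and cannot show.

## Cabin CO₂ accumulation and energy expenditure

During recirculation the cabin is treated as a single well-mixed compartment
with a first-order leak to outdoor air:

    dC/dt = k_gen − λ (C − C₀)

whose solution from an initial concentration `Cᵢ` is

    C(t) = C₀ + (k_gen/λ)(1 − e^{−λt}) + (Cᵢ − C₀) e^{−λt}.

`C` is in ppm, `k_gen` (ppm·h⁻¹) is the occupant CO₂ source, `C₀` = 450 ppm
is the outdoor level, and the air-exchange rate follows the calibrated
speed trendline `λ(v) = 0.2534·v[mph] + 10.323 h⁻¹` (a parked cabin leaks
with a ~5.8 min time constant; driving increases it).

**Segment extraction.** Within each protocol phase, rising stretches of the
CO₂ trace during recirculation are found by smoothing (31 s moving average)
and keeping maximal runs whose smoothed slope exceeds −60 ppm·h⁻¹ — a small
negative tolerance so sensor noise near steady state does not fragment a
segment, while a fresh-air purge (an order of magnitude faster) is always
excluded. Runs closer than 30 s merge; the first 10 s of a segment are
dropped as the sensor transient; segments shorter than 120 s (or 8 samples)
are discarded.

**Fitting.** `(k_gen, Cᵢ)` are estimated per segment by trust-region least
squares with `λ` held fixed at the trendline value for the segment's mean
GPS speed and `C₀` fixed. Initialization uses the first sample for `Cᵢ` and
the exact `t = 0` identity `k_gen = slope₀ + λ(Cᵢ − C₀)`. Near steady state
the level itself, `C∞ − C₀ = k_gen/λ`, identifies `k_gen`, so plateau
segments remain informative. A negative fitted rate is clipped to zero with
a warning.

**Conversion to EE.** The fitted rate is bias-corrected (`k_gen' =
k_gen·CF_env`, CF_env = 1.143; a config switch reads the correction as a
division instead), converted to a volume rate with ppm read as 10⁻⁶ volume
fraction — `VCO₂ [mL/min] = k_gen'·10⁻⁶·V_cabin[mL]·CF_STPD/60` — and
passed through a fixed-RQ Weir combination, `EE = 3.941·VCO₂/RQ +
1.106·VCO₂` with RQ = 0.85. The classic Weir expression carries a further
1.44 min→day factor; the default omits it so EE is on the same scale as the
simplified formula above (`include_144_factor=True` restores it; all EE
values in this package are internally consistent either way).
`CF_STPD = (P_bar − P_H₂O)/760 · 273/(T+273)` with `P_H₂O` from Antoine's
equation (A = 8.07131, B = 1730.63, C = 233.426; mmHg/°C, valid 1–100 °C)
scaled by relative humidity.

**Indicators.** The headline indicator is the percent EE change from normal
to aggressive driving (decision threshold 16 %: above it is the
normal-cognition response). Multiplying by the aggressive speed gives the
hybrid indicator with threshold 160 mph·%. The composite feature is read as
the fraction `speed²·EEchange/(0.1·speed) + path_deviation =
10·speed·EEchange + path_deviation`; the typography of the source formula
admits a product reading, which remains selectable (`reading="product"`),
and the EE change enters as a percent, matching the mph·% unit of its
precursor.

## Turn detection and driving signatures

The 10 Hz gyroscope z channel is smoothed with a 5-sample moving average;
peaks of the absolute value above 0.15 rad/s separated by ≥ 3 s are turn
candidates (`scipy.signal.find_peaks`). Around each peak a ±15-sample
window is analyzed: angular acceleration is the centered difference of the
smoothed series; the turn angle is the trapezoidal integral of the raw
series between the zero crossings bracketing the peak; the reported peak
angular velocity is read from the raw series (the smoothed peak is biased
low by a few percent). Events with |angle| ≥ 135° are U-turns, other events
above the 54° minor cutoff are left/right 90° turns by sign (left =
positive under the ENU convention; a config flag flips it), and events
inside a detected U-turn's extent are relabeled minor and excluded from
aggregates. None of these constants come from the source system — they were
chosen once so the noiseless standardized circuit yields exactly its 8
maneuvers per lap, and all are configurable.

The U-turn period is the time spent above 10 % of the peak angular
velocity, with sub-sample interpolation of the crossings. For the
simulator's raised-cosine pulse of duration `T` this equals
`T·(1 − (2/π)·asin(√frac))`, the closed form frozen in the tests.

Speeds are attached by linear interpolation of the 1 Hz GPS speed at each
10 Hz peak time; events outside GPS coverage are flagged and excluded from
speed aggregates. The 16 session signatures are per-kind means; combined
left+right values average the two side means (equal side weight even though
the circuit has 4 left and 3 right turns per lap), so with one side absent
the combined value equals the present side.

## Path discrepancy

Five criteria are scored against the designated route: missed U-turns,
unplanned U-turns, consecutive U-turn pairs (no 90° turn between two
180° events; pair members are not double-counted as unplanned), off-path
excursions (point-to-polyline distance ≥ 8× the 1 m GPS error, merged over
gaps < 3 fixes, inside the lot perimeter) and exits of the perimeter (such
a run is not also counted off-path). Because the chained circuit repeats
its pose every four laps (the stated turn sequence nets +270° per lap),
planned U-turn locations of different laps coincide in XY; U-turn matching
therefore works in route coordinates — a monotone windowed projection of
the track onto the route polyline — with planned turns defined as
arc-length spans. A span traversed with no 180° event during the traversal
counts as missed.

The official per-criterion scoring guide is not publicly documented, so the
default score table is a stand-in: 3 points per missed U-turn, 2 per
unplanned, 2 per consecutive pair, 1 per off-path event, 4 per exit, linear
in counts. It is loaded from JSON so a verbatim table can replace it; all
scoring is monotone in every count.

## Ventilation and occupancy

The ventilation controller is a two-threshold hysteresis switch: fresh-air
purge above 900 ppm, recirculation below 600 ppm (the defaults bracket the
resting-phase band; both are user-set). Occupancy divides the fitted total
generation rate by a nominal per-person rate (the rate a 1700 kcal/day
adult implies in the configured cabin), rounded and clamped to ≥ 1. There
is no reference output for this estimator; only simulator-based checks
apply.

## Classification harness

The cognitive feature layout has 12 per-subject features (two engineered
indicators plus ten signatures across the two driving phases); the
driving-performance layout has 7 signatures per session-condition row. The
evaluation repeats a stratified 70/30 split 100 times (stratified because 8
MCI subjects make one-class unstratified training sets likely), fits a
100-tree random forest per iteration (fresh per-iteration seeds spawned
from one master seed), accumulates the test confusion matrix, and averages
accuracy/sensitivity/specificity/precision over iterations, skipping an
iteration for any metric whose denominator is empty. Sensitivity is recall
of the positive class (MCI, configurable). The hold-out protocol trains on
a stratified 40 % sample per iteration and reports the fraction of
iterations classifying one held-out subject correctly.

The univariate ROC is an exhaustive threshold sweep over midpoints of
sorted unique values with sentinels; the best threshold maximizes accuracy
with ties broken toward higher specificity; AUC is the trapezoid over the
swept staircase (equal to the rank-statistic AUC, cross-checked against
scikit-learn in the tests). Paired condition comparisons default to the
two-sided Wilcoxon signed-rank test (exact null for ≤ 25 untied pairs;
paired t-test selectable); identical paired columns report p = 1.
Correlation matrices are Pearson, with the binary target coded 1 = normal.

## Synthetic data: what it emulates and what it does not

The simulator reproduces the standardized protocol: a 600 s parked baseline,
then 10 laps at normal speed, then 10 at aggressive speed. One lap is 540 m
(±0.5 m) with the stated turn sequence; since that sequence nets +270° of
heading per lap, laps are chained head-to-tail rather than closed, and the
designated path is the full chained polyline. Corners are raised-cosine
angular-velocity pulses whose integral is exactly the corner angle; segment
boundaries snap to the 10 Hz grid so the sampled pulse integrates exactly
too (the trapezoid rule is exact over a whole cosine period). Corner radii
are 6 m (90° and U-turn); at smaller U-turn radii the arc apex sits too
close to the adjacent straights for planned-turn zones to be meaningful
under 1 m GPS noise. Two of the nine straight sections per lap are long
(the rectangle's long sides), which is where injected events are placed.

Cabin CO₂ is integrated per sample with the exact exponential update of the
first-order balance (machine-precision agreement with the closed form at
constant speed), the controller in the loop acting on the measured (noisy)
value, and a purge exchange rate of 15× the recirculation rate — strong
enough that the hysteresis band remains reachable with up to four
occupants. Default measurement noise: gyro 0.05 rad/s, GPS 1 m per axis,
speed 0.2 mph, CO₂ 1 % multiplicative.

Cognition enters through two families of defaults chosen to mirror the
qualitative group separation the device targets: the normal→aggressive EE
gain is drawn from N(0.25, 0.06) truncated ≥ 0.16 for normal cognition and
N(0.08, 0.05) truncated < 0.16 for MCI, and path-error Poisson rates are
positive only for MCI (0.6 missed, 0.7 unplanned, 0.4 consecutive pairs,
1.2 off-path, 0.4 exits per session). Between-subject variances are
stand-ins for the effect direction, not calibrated magnitudes. Injected
U-turn errors are realized on the gyroscope channel (deleting or inserting
pulses) with the GPS track left on the route; lateral excursions are
realized on GPS and validated against the actual path geometry before
being applied, so the ground-truth ledger is exactly recoverable at the
default noise level. The deleted-pulse idealization means a "missed"
U-turn's GPS still loops — adequate for detector testing, not a
vehicle-dynamics model.

Consequently, passing tests show that the estimators recover what the
forward models generate (EE round trip within 0.1 % noiseless / 10 % at 95 %
of noisy replicates; exact ledger agreement for path criteria; ≥ 80 %
classifier accuracy on the default 13+8 cohort with chance-level permuted
labels). They do not certify performance on real vehicle data, where air
mixing is imperfect, turn profiles are not raised cosines, GPS error is
correlated, and cohort effect sizes are unknown. Desk-scale problem sizes
(10-lap sessions at 10 Hz/1 Hz, 21-subject cohorts, 100 resampling
iterations) keep the full suite under a few minutes on one CPU.

## Known limitations

* The lap cannot geometrically close with the stated turn sequence; lap
  chaining is a modeling convention, and route-coordinate matching exists
  precisely to cope with the resulting self-proximity of the path.
* The default score table is invented (documented above) pending an
  official guide.
* Eq-style ambiguities (composite-feature reading, bias-correction
  direction, Weir day factor) are resolved by documented defaults with
  config switches; results that depend on them should state the switch.
* The occupancy estimator and the ventilation purge kinetics have no
  external reference; they are validated only against the simulator.
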