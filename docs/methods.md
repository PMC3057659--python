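# Methods

## Problem and data model

A multi-pressure tonometry session applies five increasing hold-down
pressures to the radial artery (device setpoints averaging 37, 73, 108, 143,
181 mmHg with between-subject SDs of 6, 10, 13, 17, 21 mmHg), holds each for
five seconds, and records the pulsatile waveform; the session is repeated at
the three palpation positions Chon, Gwan and Cheok. Pulse depth is encoded
in the **P-H curve** — pulse strength `H` as a function of hold-down
pressure `P`: a floating pulse peaks at low pressure, a sunken pulse at high
pressure, a middle-depth pulse near average blood pressure.

## Waveform reduction (preprocess)

Per record the chain is: plateau segmentation → baseline alignment →
ensemble beat averaging → peak-to-trough amplitude.

* **Segmentation.** Explicit step boundaries win when supplied. Otherwise
  plateaus are detected by thresholding the absolute first difference of a
  median-filtered (0.25 s kernel) pressure trace at 2% of the trace range,
  keeping stable runs of at least 1 s. Exactly five plateaus are required;
  any other count is an error naming the count found. The first and last
  0.25 s of each plateau are discarded as actuator settle time.
* **Baseline alignment** uses a 5th-order polynomial, fitted *per pressure
  step* (a single global polynomial cannot follow the pressure staircase's
  DC offsets, and the respiration component at ~0.25 Hz is only within
  reach of a 5th-order fit on a 5-s window). Two anchors are available:
  * `anchor="samples"`: subtract the least-squares fit of the raw samples.
  * `anchor="feet"` (pipeline default): detect beats on the sample-wise
    detrended copy, locate one pre-systolic foot per beat (the minimum in
    the 0.45-period window before each peak, its value averaged over
    ±25 ms), and subtract a polynomial of order `min(5, n_feet − 1)` fitted
    through the foot values of the original segment.

  The foot-anchored form is the package's deliberate default: a
  least-squares fit of the raw samples partially tracks the beats
  themselves and measurably removes 0.3–2% of pulse amplitude on clean
  5-s windows (the fraction depends on heart rate and window phase),
  whereas the diastolic feet trace the true baseline, so a drift-free
  record is restored exactly and polynomial drift sampled at the feet is
  removed to the degree the beat count allows. Fitting polynomials
  through beat onsets is standard practice for pulse/PPG baseline-wander
  removal.
* **Beat averaging.** Systolic peaks are picked with a minimum peak
  distance of one beat at 180 beats/min and a prominence threshold of 25%
  of the segment peak-to-trough; beats are aligned on their peaks and
  averaged point-wise over one median beat period (40% pre-peak, 60%
  post-peak), discarding beats whose window runs off the segment. Fewer
  than two usable beats is an error naming the step.
* **Pulse strength** `H` is the peak-to-trough amplitude (max − min) of the
  averaged beat. The quantity is not defined more specifically by the
  measurement convention this package follows; peak-to-trough is chosen
  because it behaves like the published P-H curves and is linear under
  amplitude scaling. Units are device-specific and never converted.

Per-location strengths are averaged element-wise over the three positions,
`H_i = (H_Chon,i + H_Gwan,i + H_Cheok,i)/3`, before any coefficient is
computed — matching the clinician's simultaneous three-finger palpation.

## Depth coefficients

* **Interpolated argmax** (`cfs_lee`): the five (P, H) points are
  interpolated with a monotone shape-preserving piecewise cubic (PCHIP) and
  `C_fs = (P_opt − P_0)/(P_max − P_0)` where `P_opt` is the interpolant's
  argmax on `[P_0, P_max]`. PCHIP is used precisely because an
  unconstrained spline can overshoot and move the argmax off the data
  pattern, which is the known failure mode of this coefficient. The argmax
  is found exactly from the stationary points of the cubic pieces (checked
  in the tests against a 10⁴-point grid scan); plateau ties take the
  smallest pressure, biasing toward floating, deterministically. The
  coefficient is computed on the location-averaged profile for symmetry
  with the strength-ratio method.
* **Strength ratio** (`cfs_new`):
  `C_fs = ½(1 + (H_deep − H_shallow)/(H_deep + H_shallow))
        = H_deep/(H_shallow + H_deep)`,
  with variants **v1** `(H_shallow, H_deep) = ((H₁+H₂)/2, (H₄+H₅)/2)` and
  **v2** `(H₁, H₄)`. Only these two selections are implemented. Both
  strengths zero raises an error rather than returning ½: no detectable
  pulse is a data problem, not a middle-depth pulse.

## Decision rules and sweeps

Single threshold: `C_fs ≤ C*` → floating, else sunken (the boundary belongs
to floating). Dual thresholds `C_f* ≤ C_s*`: `≤ C_f*` floating, `> C_s*`
sunken, otherwise middle-depth; at `C_f* = C_s*` the rule reduces exactly
to the single rule. The selection rate is the fraction of subjects given a
floating or sunken decision.

Sweeps evaluate a grid of step 0.01 over [0, 1] (thresholds are quoted to
two decimals in this field). Single-rule sweeps report concordant counts,
accuracy and MCC per threshold; among accuracy ties the smallest threshold
is primary. Dual-rule sweeps evaluate all pairs `C_f* ≤ C_s*`; MCC is not
reported there because it is poorly defined with an undetermined band.
Among dual-rule accuracy ties the pair with the highest selection rate is
primary (decide as many subjects as possible). The frontier table gives,
for each achievable number of decided subjects, the maximal concordant
count. Small-sample anomalies in the sweep surface (e.g. accuracy spikes at
extreme thresholds where few subjects are decided) are left visible.

## Agreement and group statistics

The 2×2 agreement table is oriented `a` both-floating / `d` both-sunken.
Accuracy is `(a+d)/n`; MCC is `(ad − bc)/√((a+b)(a+c)(d+b)(d+c))`, defined
as 0 when a marginal vanishes (the conventional limit). Pearson correlation
and the two-sample T-test are delegated to scipy; Welch's unequal-variance
form is the default (group SDs in pulse cohorts differ visibly), the pooled
form is behind `equal_var=True`, p-values are two-sided, and no
multiple-testing correction is applied across covariates.

## Synthetic generator: the stated world

Each subject carries a Gaussian P-H envelope
`H(P) = A·exp(−(P − μ)²/2w²)` with width `w = 70 mmHg`; the peak location
`μ` encodes depth. Subject-level draws:

| parameter | floating | sunken | source of the value |
|---|---|---|---|
| envelope peak μ (mmHg) | 98.6 ± 15 | 115.8 ± 20 | means from the closed-form calibration below; SDs chosen as plausible between-subject spread |
| amplitude A (device units) | 157.6 ± 39.2 | 146.9 ± 35.3 | reference cohort's maximal pulse strength |
| heart rate (beats/min) | 81.6 ± 13.5 | 78.6 ± 11.5 | reference cohort |
| BMI, systolic/average BP | group-shifted normals | — | reference cohort (optional covariates, no causal model) |

Step pressures are drawn per location from the device distributions
(37 ± 6 … 181 ± 21 mmHg), sorted and kept at least 5 mmHg apart; the
envelope peak gets an independent ±5 mmHg per-location offset; measured
strengths carry multiplicative lognormal noise with a 10% coefficient of
variation (the device's stated repeatability). Waveform synthesis adds a
hold-down-pressure DC offset, a two-Gaussian beat train (systolic peak +
dicrotic bump) scaled so its peak-to-trough equals the envelope value, a
respiration sinusoid (0.25 Hz, 5% of amplitude), slow random drift (sum of
sub-0.1 Hz sinusoids, 5%) and white noise (2%).

**Calibration.** The group means of μ are not free: they are derived in
closed form so that the *cohort-level* group means of the v2 coefficient
land on the reference anchors 0.54 (floating) and 0.63 (sunken). Since
`C_v2 = logistic(ln(H₄/H₁))` and, for the Gaussian envelope,
`E[ln(H₄/H₁)] = ((P₁−P₄)(P₁+P₄−2μ) + (Var P₁ − Var P₄))/(2w²)`
over the step-pressure sampling noise, inverting at the target coefficient
gives μ = 98.6 / 115.8 mmHg. Note both anchors sit above ½ — in the
reference cohort even the floating group's strength at 143 mmHg slightly
exceeds that at 37 mmHg on average — so the envelope peaks sit above the
naive "floating peaks well below mean arterial pressure" picture; the
anchors are measured data and win.

**Numerical choice.** The beat period is quantized to an integer number of
samples and the beat template's Gaussians are placed so both tails fall
below 1e-8 at the period boundaries. Without this, sub-sample phase jitter
and floor tilt put a ~1e-3 floor under the reduction error of even a
noise-free record; with it, the full chain reproduces injected strengths to
machine precision, so the noise-free recovery test isolates the algorithmic
chain rather than sampling artifacts.

**What a green test does and does not establish.** The generator reproduces
the P-H envelope behaviour, the device's pressure-step and repeatability
statistics, and the reference cohort's group-level coefficient
distributions. It does not model hemodynamics (no Windkessel or wave
reflection), sensor-array geometry, arrhythmia, motion artifacts beyond
smooth drift, or any correlation structure between covariates and the
envelope beyond group membership. End-to-end accuracy on this cohort
(≈69% at the optimal single threshold, with between-group Welch P ≪ .05)
therefore shows the algorithm recovers the depth structure the generator
states — not that it would achieve the same numbers on any real cohort.

## Degenerate inputs and errors

Fewer/more than five plateaus, fewer than two beats in a step, segments too
short for the polynomial fit, non-increasing pressures, non-binary labels
where binary ones are required, empty tables, zero-variance correlation
inputs and inverted dual thresholds all raise descriptive `ValueError`s;
pipeline stages attach the pressure-step index. Waveform CSVs are rejected
when the sampling-period jitter exceeds 2% of the median period (device
clocks stay well under 1%; more indicates dropped samples).

## Known limitations

* "Pulse strength" as peak-to-trough of the averaged beat is one of several
  defensible operationalizations (peak height above foot and mean pulse
  pressure are others); all downstream results are invariant to the common
  scale but not necessarily to this choice.
* The baseline polynomial is fitted per pressure step, not per recording;
  with fewer than seven beats per plateau the foot-anchored fit cannot
  reach order 5 and high-order drift is only partially removed.
* The dual-threshold sweep is exhaustive over the grid; its O(grid²)
  table is fine at step 0.01 but not meant for much finer grids.
* Coefficients from cohorts with very weak pulses are noise-dominated;
  the package flags all-zero strengths but not near-zero ones.
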