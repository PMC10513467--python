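# Methods

## The measurement model

Two IMUs are worn at the distal shanks, one per leg, sampling linear
acceleration (±4 g), angular velocity (±2 000 deg/s) and an onboard
sensor-fusion orientation quaternion at 100 Hz. The package treats the
quaternion as ground truth for orientation: no strapdown gyro integration,
Kalman smoothing or magnetometer handling is performed. Quaternions are
Hamilton, scalar-first (w, x, y, z), sensor-to-world; the world frame is
Z-up, and the AP axis is defined per stride by heading alignment.

## Event detection

Events are found from the shanks' sagittal angular kinematics only. The
sagittal shank angle θ is the inclination of the sensor's long axis from
vertical, extracted from the quaternion and unwrapped; the sagittal rate ω
is read directly from the gyro pitch axis. The decision rules are given in
the README. Three numerical choices matter:

* a local extremum is a sample strictly greater (smaller) than its left
  neighbour and not smaller (greater) than its right one, so plateaus
  resolve deterministically to their first sample;
* the Δθ used for each leg is ipsilateral-minus-contralateral, with the
  contralateral angle linearly interpolated onto the ipsilateral clock, so
  the rule is symmetric across legs and tolerates independent clocks;
* the 0.5 s refractory window is scoped per event type and side. Scoping it
  globally would suppress legitimate IC→TO pairs inside one cycle.

The positive rotation direction is a mounting convention the hardware does
not fix; `flip_gyro` accommodates sensors mounted the other way. The
detector expects the convention in which IC/TO are rate maxima and
mid-swing the minimum.

Candidate thresholds: ω threshold 100 deg/s (shared), refractory 0.5 s
(shared), angle band 5–15° tuned per participant by step length in the
source protocol — the default is the 10° midpoint and it is configurable.
The same angle band gates mid-swing (the band's role there is to reject
rate minima occurring while the shanks are far apart, i.e. outside
mid-swing); whether a separate threshold was intended is not documented,
so one parameter serves both.

## Per-stride dead reckoning

Integration windows are FF-to-FF rather than TO-to-IC because flat-foot is
the zero-velocity anchor. Gravity is removed on the vertical world axis
only; horizontal leakage from orientation error is accepted. Velocity
drift is removed as a linear ramp pinned to zero at both FF anchors;
position is then re-integrated from the corrected velocity, its origin
reset at the first FF, and the vertical component linearly detrended to
zero at the second FF (the minimal correction consistent with level
ground; horizontal endpoints carry the stride's real displacement and stay
free). Heading alignment rotates each stride about vertical so its net
horizontal displacement points along +AP — per-stride rather than to a lab
axis, because overground heading varies. These guarantees are contractual
and asserted on every stride: v = 0 at both FFs, p = 0 at the start,
p_vert = 0 at the end, to 1e-9.

g = 9.81 m/s² by default, configurable.

## Spatiotemporal metrics

Definitions as in the README. The swing interval for CD and MVD is
[TO, next IC] of the same side; CD uses the absolute lateral excursion
(magnitude, side-agnostic). FC is defined as the height at mid-swing (the
"methods" definition) even though it is sometimes reported as minimum
clearance; MVD ≥ FC then holds by construction whenever both exist.
Temporal strides (IC-to-IC) and spatial windows (FF-to-FF) are joined on
the stride's closing IC; strides missing an interior event, or touched by
sensor clipping, are flagged incomplete and excluded from summaries.
StP + SwP = 100 exactly because SwP is computed as the complement.

## Validation statistics

MAE, Pearson r (two-sided t-test on r with n−2 df) and the two-way
single-measure ICCs in McGraw & Wong's nomenclature, from the ANOVA mean
squares (MSR rows/subjects, MSC columns/systems, MSE residual):

    ICC(C,1) = (MSR − MSE) / (MSR + (k−1) MSE)
    ICC(A,1) = (MSR − MSE) / (MSR + (k−1) MSE + (k/n)(MSC − MSE))

with k = 2 systems. Consistency ignores a fixed offset between systems;
agreement penalises it, so ICC(C,1) ≥ ICC(A,1) whenever MSC ≥ MSE. No
multiple-testing correction is applied. Stride-level pairing aligns the
first strides by start time and pairs by index, dropping unmatched tails;
session-level pairing compares per-session means. Constant series (e.g. a
zero-variability reference) make r and ICC undefined; the report then still
carries n and MAE plus an explanatory note instead of NaNs.

## The adaptive controller

The controller regresses the peak knee flexion torque τ on the variation
of the paretic MVD from its unassisted baseline, ΔMVD = MVD − mean MVD at
0 Nm. The 0 Nm condition is the natural reference and is required to be
present. Note the deliberate inverse-regression caveat: experimentally τ is
set and MVD responds, while the fitted map runs ΔMVD → τ, matching the
control flow (therapist sets a target metric; the model emits a torque).

Training: random 80/20 split stratified within each (participant,
condition) cell, deterministic under seed; cells with one step go wholly
to training. The linear model is OLS. The MLP (default 1 hidden layer × 5
ReLU units, linear output) trains on standardised inputs with L-BFGS to an
MSE loss, deterministic under seed; prediction always runs through an
explicit forward pass over the stored weights so serialised models predict
identically after reload. AICc uses test residuals with
k = free parameters + 1 (error variance): k = 3 for the linear model,
weights + biases + 1 for the MLP. A perfect fit is floored at RSS = 1e-12
and flagged rather than reported as −∞.

Grid search evaluates all 774 cells (3 activations × (6 + 36 + 216)
layer/width layouts). "Best" is lowest validation MAE; architectures
within 0.05 Nm (~1 % of the 0–4 Nm command range) are treated as tied and
resolved by lowest AICc, then fewest parameters — without a tie window a
deeper net winning by a meaningless 10⁻⁴ Nm would defeat the parsimony
comparison the AICc exists for.

The control step converts the therapist's target MVD to a variation,
evaluates the model, and clips the command to the tested 0–4 Nm range. The
measured variation (mean of the last 3 strides by default) is computed for
logging and can be selected as the model input instead
(`input_mode="measured"`).

## The synthetic-gait generator

The generator emulates what the shank sensors observe during steady
hemiparetic walking; it contains no neuromuscular model, treadmill-belt
dynamics or soft-tissue artifacts — asymmetry enters purely through
per-side parameters.

**Angular model.** Each side's shank angle follows plateaus connected by
raised-cosine rotation pulses: 24° absorbed at IC and at TO, 48° returned
at mid-swing, around a 25° terminal-swing plateau. This makes the rate
signal a sequence of clean threshold-crossing extrema and gives the
inter-shank angle difference the exact sign pattern the detector keys on
(+12° at IC, −12° at TO, 0 at MSw). Pulse widths scale with swing duration
(15 % for IC/TO, 25 % for MSw). The two legs share one stride period with
a half-cycle offset; per-leg period jitter is deliberately absent because
it would desynchronise the contralateral-angle rule — a known idealisation
of the generator, so passing tests say nothing about badly phase-jittered
real data.

**Spatial model.** The sensor is stationary during stance (the flat-foot
idealisation; real stance has heel-pivot micro-motion) and moves during
swing along C²-continuous closed-form paths, chosen so the sampled
accelerations carry no jump discontinuities into the trapezoidal
quadrature: AP is a 7th-order smoothstep spanning SL; the vertical arc is
z = u²(FC + β(1−u)) over the warped phase u = sin²(πs), which is exactly
FC at mid-swing with zero slope, and whose maximum 4(FC+β)³/27β² is
calibrated to MVD by a bracketed root; the lateral lobe is CD·u² (a
raised-cosine-squared lobe rather than a plain half-sine, which would
start the swing with a velocity jump). Acceleration is the analytic second
derivative rotated into the sensor frame with gravity added; the sensor is
mounted with a half-turn about the shank long axis, making the gyro pitch
read −dθ/dt, consistent with the detection convention.

**Variability and noise.** Per-stride targets are drawn with ±2.5σ
truncated Gaussians (defaults: SL 20 mm, FC 4 mm, CD 3 mm); MVD co-varies
proportionally with the drawn clearance (same limb elevation) plus a 2 mm
residual. Sensor noise is white Gaussian (defaults 0.05 m/s², 1 deg/s)
added per axis and clipped at the sensor ranges, with clipped samples
flagged; quaternions are left untouched. Requested kinematics that would
exceed ±4 g before noise raise an error instead of silently clipping the
ground truth.

**Default conditions.** Stride time 1.62 s; stance 71.2 %GC paretic /
72 %GC non-paretic; SL 0.483/0.470 m; MVD 0.071/0.080 m; FC 0.056/0.062 m;
CD 0.043/0.006 m. These follow the hemiparetic treadmill pattern the
pipeline targets (slow gait, longer sound-side stance, marked paretic
circumduction) with one adjustment: the non-paretic stance share and
clearance are kept moderate because the most extreme observed combination
(77 %GC stance with a 0.088 m arc inside a 0.38 s swing) demands
accelerations beyond the ±4 g sensor itself — the generator refuses
configurations whose truth the sensor could not record.

**Controller study conditions.** The torque sweep runs 0–4 Nm with the
assisted-gait effect (+2.75 mm MVD, +1.75 mm FC, +1.5 mm CD, +0.8 %GC
stance per Nm on the paretic side), paretic MVD baseline 0.079 m, stance
0.65/0.68 (so the 4 Nm condition's longer stance keeps the swing arc
feasible), 40 strides per condition, reduced sensor noise (0.01 m/s²,
0.2 deg/s). The low-variability regime uses 0.3 mm clearance/MVD residual
stds (marginal stride-to-stride MVD σ ≈ 0.5 mm, far below the 11 mm effect
range); the inflated regime raises the clearance std to 14 mm (marginal
MVD σ ≈ 19 mm, ~170 % of the effect range), which destroys stride-level
predictability of the torque — the qualitative failure mode expected when
stride variability dominates the effect.

## Problem sizes

The test suite and acceptance script run: 50-stride noiseless and noisy
walks for event/trajectory checks; a 9-point parameter grid (SL 0.3–0.7 m,
ST 1.2–2.0 s, MVD 0.05–0.12 m with FC = 0.79·MVD, CD 0–0.08 m) at 12
strides per point; 100 random instances for the statistics oracle; 5 × 40
strides per controller regime; and the full 774-cell grid search at a
10-iteration training budget on 40 synthetic steps. These sizes were
chosen as the smallest that exercise every guarantee with clear margins;
the whole suite completes in seconds.

## Known limitations

* The generator's stance is perfectly stationary; real flat-foot phases
  are only quasi-stationary, so real-data drift residuals will exceed the
  numerically exact endpoint contracts shown here.
* Orientation is trusted from the onboard filter; orientation error leaks
  gravity into the horizontal axes and is not corrected (gravity is
  removed on the vertical axis only, by design).
* Stride pairing for validation assumes the two systems observe the same
  walk with a shared clock to within a fraction of a stride.
* The controller models a single scalar input (ΔMVD); participant
  heterogeneity is represented only through the optional participant
  column in the dataset, not modelled.
* Torque is bounded to the tested 0–4 Nm range by clipping; the physical
  torque-profile waveform and its real-time execution are out of scope.
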