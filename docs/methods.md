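# Methods

## Model and assumptions

Each plantarflexor musculotendon unit (MTU) is a passive Hill-type muscle: a
muscle fibre in series with an elastic tendon, with no activation, no
force–velocity dependence and no fibre damping. The stretch being modelled is
quasi-static (manual rotation at roughly 15°/s, slow enough not to provoke a
stretch reflex), so at every ankle angle the fibre and tendon are in static
force equilibrium along the tendon line of action. Pennation follows the
fixed-height model: the fibre's height above the aponeurosis,
h = l_o^f · sin α_opt, is constant, so sin α = h/l_f at any fibre length.
Setting a muscle's pennation default to 0 disables the mechanism.

Both force–length curves are built from quintic Bézier "corner" segments: a
corner blends two straight lines (entry line with entry slope, exit line with
exit slope) with control points placed a fraction c = 0.1 + 0.8·curviness of
the way towards their intersection, so end values and end slopes hold exactly
by construction and curviness sweeps the shape from nearly straight to a
tight corner. The fibre curve uses two corners: from the engagement point
(1 + ε_zero^f, force 0, slope 0) through a short run-in span where the slope
reaches K_low^f, then up to (1 + ε_one^f, 1) with slope K_one^f. The tendon
curve uses one corner from the slack point (1, 0, slope 0) to the toe end
(where the force is F_toe^t and the slope K_one^t), followed by an exactly
linear span through (1 + ε_one^t, 1). Beyond the one-norm-force point both
curves continue linearly with their end slope; below engagement they are
exactly zero. The stiffnesses are dependent quantities, never set directly:

    K_one^f = 2/(ε_one^f − ε_zero^f),  K_low^f = x/(ε_one^f − ε_zero^f),
    K_one^t = 1.375/ε_one^t,

where x is the low-force stiffness scaling factor (default 0.14; note the
derived default K_low^f is therefore 0.2 — the factor and the stiffness are
reported separately because they are easily conflated).

The muscle path replaces 3D wrapping geometry with a per-muscle polynomial
l_mt(θ) (degree ≤ 3) at the fixed 20° knee flexion of the measurement
posture, valid over −45° to +40° of ankle angle (dorsiflexion positive, 0 =
neutral). The plantarflexion moment arm is the analytic derivative
r(θ) = dl_mt/dθ, which makes torque integration exactly consistent with the
stored elastic energy (virtual work). The default coefficients put each
default MTU's engagement in slight plantarflexion (−10° to −13°) with moment
arms of 4.6–5.0 cm at the generic adult size; they are configuration inputs,
not constants of the method.

## Parameters

Nine independent parameters, shared by all three MTUs (the measurement
cannot separate the muscles' contributions; fascicle length is measured only
for GASM). Defaults and closed optimisation bounds:

| name | meaning | default | bounds |
|---|---|---|---|
| `lof_scale` | optimal fibre length scaling (dimensionless) | 1.0 | [0.5, 2] |
| `eps_zero_f` | fibre strain at zero force | 0.0 | [−0.5, 0.5] |
| `eps_one_f` | fibre strain at one norm force | 0.70 | [0.5, 1.5] |
| `k_low_scale` | low-force stiffness factor x | 0.14 | [0.01, 0.99] |
| `curviness_f` | fibre curve shape | 0.75 | [0, 1] |
| `lst_scale` | tendon slack length scaling (dimensionless) | 1.0 | [0.5, 2] |
| `eps_one_t` | tendon strain at one norm force (compliance) | 0.049 | [0.01, 5] |
| `f_toe_t` | norm force at toe end | 0.67 | [0.01, 0.99] |
| `curviness_t` | tendon toe shape | 0.5 | [0, 1] |

Lengths are optimised as scaling factors applied after subject scaling, so
they are comparable across subjects. Generic absolute lengths are set so that
the tibia-normalised defaults are l_s^t/tibia = {GASM 1.00, GASL 0.95, SOL
0.70} and l_o^f/tibia = {0.13, 0.15, 0.11}; generic maximal isometric forces
are {1558, 683, 3549} N with a 75.3 kg generic body mass, scaled by
(m/m_generic)^(2/3). Pennation defaults: 9.9° (GASM), 12.0° (GASL), 28.3°
(SOL).

## Preprocessing

Raw trials carry channels at their native rates (angle 120 Hz, load-cell
200 Hz, fascicle 60 Hz, sEMG envelopes 1600 Hz). Steps: (1) net ankle moment
from the load-cell channels under the quasi-static moment balance
M = F_x·d_y + F_y·d_x + M_handle + M_orthosis (foot/footplate inertia
neglected); (2) trials whose EMG envelope RMS exceeds 10% of MVC on any
muscle are discarded as non-passive (whole-trial RMS; the window is
configurable); (3) all channels linearly interpolated to the 120 Hz angle
timeline; angle and torque filtered with a zero-phase 2nd-order 6 Hz
Butterworth (zero-phase avoids angle–torque lag distortion; the fascicle
channel is left unfiltered); (4) each stretch time-normalised to 101 samples
and averaged channel-wise over the accepted stretches; (5) curves expressed
against angle on a uniform 0.5° grid and cropped from the point where the
internal plantarflexion moment becomes *and stays* positive up to maximal
dorsiflexion. The "stays positive" form makes the crop deterministic under
measurement noise, where a literal first-crossing rule would trigger on the
first noise excursion; on noise-free traces the two coincide. A subject with
no loaded range raises a subject-excluded error.

## Equilibrium solver

The force imbalance f_t − f_f·cos α is strictly monotone in fibre length
(both curves monotone), so the root is unique. It is bracketed between
max(h, 0.01·l_o^f) and the fibre length at zero tendon length, and found by
42 bisection iterations, vectorised over the angle grid and over MTUs that
share curve parameters. The inner loop evaluates the curves through a
32769-point dense-table interpolant (error a few 1e-9 over the curved spans;
the linear tail and zero region exact); final states and residuals are
computed with the exact curves, and residuals stay below the 1e-8·F_max
tolerance. In the zero-force band (tendon at or below slack length, fibre at
or below engagement) the split is indeterminate; the convention is tendon at
slack length, fibre takes the remainder (clamped to a minimal positive
along-tendon component for degenerate l_mt < l_s^t inputs). The solver is
deterministic: identical inputs give bit-identical outputs.

## Fitting and stepwise selection

`fit_parameters` minimises the concatenated residual vector [torque in Nm;
fascicle in mm] — millimetres put the two channels on the same order of
magnitude, weighting them roughly equally — with scipy's bounded
trust-region-reflective least squares, cold-started at the defaults, ftol =
xtol = gtol = 1e-12. Non-convergence is flagged, never silent. Reported
RMSEs are torque/body-mass (Nm/kg) and fascicle/tibia-length
(dimensionless).

Stepwise selection is greedy forward search: each remaining candidate is
fitted jointly with the already-selected set for every subject and scored by
the sum of the two default-normalised median RMSEs (equal weighting,
mirroring the fit cost); ties break in parameter-table order, so the
procedure is deterministic. Selection stops when both medians fall below 10%
of their default-parameter medians; an absolute floor (1e-6 Nm/kg, 1e-7
/tibia) handles cohorts whose default fit is already essentially exact,
where a purely relative rule could never trigger. Per-round fits are
cold-started from defaults (no warm starting across rounds). Group models
take per-parameter medians and IQRs with linear interpolation between order
statistics. Group statistics are two-sided at α = 0.05: one-sample Wilcoxon
signed-rank against the default (degenerate all-zero differences are flagged
rather than tested), Mann–Whitney U between groups (exact for small
tie-free samples, normal approximation otherwise — scipy's automatic
policy), and a Kolmogorov–Smirnov normality check on standardised values.

## Synthetic data generator

The generator emulates the instrumented stretch experiment: prone subject,
knee fixed at 20°, manual rotation from 30° plantarflexion to maximal
dorsiflexion at a peak velocity drawn from N(15, 5²)°/s (cosine velocity
profile with short holds), three stretches per subject. Anthropometry comes
from truncated normals with the published group means/SDs (CP: 37.5 ± 19.0
kg, 143.7 ± 21.4 cm, tibia 34.2 ± 0.6 cm; TD: 39.2 ± 14.4 kg, 143.7 ± 17.6
cm, tibia 33.0 ± 0.5 cm); foot and leg lengths are fixed proportions of the
tibia. True parameters are drawn per group around the published personalised
medians (CP: lst 1.03, lof 0.81, ε_one^t 0.23, ε_zero^f 0.089; TD: 1.00,
1.15, 0.16, −0.055) with SD = IQR/1.349, clipped to the bounds; the other
five parameters stay at their defaults. Channels carry additive i.i.d.
Gaussian noise at the instruments' standard errors of measurement (0.72 Nm
torque, 2.0 mm fascicle length, 0.1° angle), and EMG envelopes sit at a 2%
MVC baseline (optionally one trial at 20% MVC to exercise the gate).

Two design choices condition the cohort on being measurable, as any real
stretch study implicitly is. First, the end of range of motion is
torque-defined: the examiner stretches until the resisting torque reaches a
per-subject end-range torque drawn from U(10, 25) Nm, with the resulting
dorsiflexion clipped to [5°, 30°]. An independently drawn ROM would produce
subjects that are never loaded (no crop possible) or that would need >100 Nm
of manual torque. Second, parameter draws whose model develops less than
2 Nm anywhere within the reachable range are redrawn — such a subject could
not produce a torque–angle curve at all.

What the generator does *not* emulate: correlated or rate-dependent noise
(tracking errors in real fascicle data are smooth, not white), reflex
activity, between-stretch hysteresis, model-structure mismatch (the
generating model is the fitted model), and per-muscle parameter differences.
Passing round-trip tests therefore demonstrate identifiability and pipeline
correctness under the stated noise, not robustness to structural error.

## Numerical choices and known limitations

* Bézier inversion: 65-point lookup plus 4 Newton steps; anchor points are
  exact to ~1e-15 because segment endpoints are control points.
* Rigid-tendon limit: the closed-form error converges first order in
  ε_one^t with a geometry-dependent constant (~21·ε for the ankle-like
  tendon-to-fibre length ratio of 7), reaching 1% at ε_one^t ≈ 2.5e-4.
* Identifiability ridge: `lof_scale` and `eps_zero_f` jointly set the fibre
  engagement length, so under measurement noise their individual estimates
  can trade off along a ridge (noise-free fits recover both exactly; noisy
  fits recover the length scalings to within a few percent while
  `eps_zero_f`'s *relative* error can be large when its true value is near
  zero). This is the same redundancy the stepwise procedure exposes when a
  fifth parameter is added.
* Noise floor: with i.i.d. 2.0 mm fascicle noise, averaging three stretches
  leaves a ~0.9 mm RMSE floor that bounds the attainable RMSE reduction;
  groups whose default-parameter misfit is modest (TD) sit near an 88%
  ceiling for the fascicle channel, while CP (larger default misfit) clears
  90%. The acceptance script reports both.
* "Bodyweight" torque normalisation uses mass in kg (units Nm/kg).
* Problem sizes in the shipped tests and acceptance script (cohorts of 5–20
  subjects, 0.5° angle grids) are chosen as desk-scale analogues of the
  13-per-group study; all quantities they report are computed at run time.
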