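# Methods

`liftrisk` is a data-driven simulation for a question in occupational
ergonomics: how accurately can low-back-disorder (LBD) risk over a material
handling workday be estimated from wearable-obtainable signals — trunk motion
alone (one trunk IMU) versus trunk motion plus under-foot force (trunk IMU +
pressure insoles)?  Ground-truth risk comes from a fatigue-failure ergonomic
model (LiFFT) driven by laboratory-grade biomechanics; the wearable estimates
come from machine-learned lumbar-moment regressors fed idealized sensor
channels.  Because the corresponding laboratory dataset is not openly
deposited, a synthetic lifting-biomechanics generator stands in for it,
reproducing the statistical structure the analysis depends on.

## The synthetic lifting generator

Each trial is a symmetric sagittal-plane lift modelled as a single rigid
head–arms–trunk (HAT) segment rotating about a fixed L5/S1 pivot, with a
static lower body.  The movement is: quiet stand → minimum-jerk flexion to a
shelf-height-dependent peak angle → grasp dwell (the box is acquired at the
dwell midpoint) → minimum-jerk extension with the box → stand holding the
box.  Minimum-jerk trajectories are the standard smooth model of point-to-
point human movement and give analytic velocities and accelerations.

**Anthropometry.** Participants draw body mass and stature uniformly
(defaults 60–100 kg, 1.60–1.90 m).  The HAT carries 67.8 % of body mass; its
centre of mass (COM) sits 0.17·stature from the pivot; its inertia is that of
a rectangular prism (height 0.6·stature/1.75, depth 0.20 m), both about its
COM and, via the parallel-axis theorem, about the pivot.  These are standard
anthropometric magnitudes; every one is configurable.

**Ground-truth lumbar moment** is computed by planar Newton–Euler about the
pivot:

    M(t) = I·α(t) + m_HAT·g·x(t) + m_HAT·(−ẍ(t))·z(t) + box terms (while held)

with I the HAT inertia about the pivot and (x, z) the HAT-COM position
relative to the pivot.  In default mode the box is co-located with the HAT
COM (the same simplification the downstream load-moment conversion assumes);
a sensitivity mode places it 0.25 m anterior along the trunk instead.

**Ground forces.** Total vertical force follows Newton's second law for the
supported masses, so quiet standing carries exactly body weight and a
quasi-static held-box sample carries body + box weight.  The combined centre
of pressure (COP) is placed by inverting the ground-wrench moment balance
about the pivot axis (the lower-body COM lies on the pivot vertical), which
reduces to the quasi-static whole-body COM projection at low acceleration and
makes the independent bottom-up moment recomputation agree with the
Newton–Euler truth exactly at zero noise.  Force is split between feet by a
seeded per-trial asymmetry factor (0.5 ± 0.05 SD), and per-foot COP carries
additive Gaussian noise (σ = 5 mm).

**Key statistical structure.** Box mass never enters the kinematics: trunk
channels are identical for a 5 kg and a 23 kg lift from the same shelf,
while the force channels carry the box weight during the hold.  This is the
property the whole study interrogates.

**Flexion mapping and variability.** Peak flexion maps linearly from shelf
height (90° at 40 cm to 20° at 160 cm), plus a per-participant style offset
(± 8°) and a per-trial jitter (± 2°), capped at a 90° postural ceiling
(trunk flexion beyond horizontal is not physiological, and the cap keeps
peak moment monotone in shelf height under style offsets).  The jitter is
seeded by (participant, shelf height, repetition) — technique responds to
the shelf, not to the box mass the lifter has not yet felt — which preserves
exact mass-independence of the kinematics.

**Idealized wearable channels.**  Nine trunk channels (three intrinsic
X–Y–Z orientation angles in degrees, three gravity-free linear accelerations
at a trunk-mounted point halfway up the trunk, three angular velocities) and
six under-foot channels (per foot: foot-normal force, anteroposterior and
mediolateral COP in the foot frame).  Sagittal channels are exact analytic
derivatives of the generated kinematics; the non-sagittal channels carry
band-limited seeded sensor jitter (sums of sinusoids, so their derivatives
are also exact).  No IMU noise, bias, drift, or insole calibration error is
modelled: the study quantifies what the signals can support in principle.

## Moment estimation

Gradient-boosted decision-tree regressors map instantaneous per-sample
channel values to the lumbar moment, one model per signal condition (9
trunk channels; 15 trunk+force channels).  The implementation is
scikit-learn's histogram-based gradient boosting with 100 boosting stages,
learning rate 0.1, maximum depth 3; training is seeded and deterministic.
Features are raw per-sample values (no windows or lags).

Training keeps only samples whose target exceeds 100 Nm, prioritising
accuracy at the damaging high moments; prediction runs on full trials.
Evaluation is leave-one-participant-out throughout: every trial's prediction
comes from a model that never saw that participant.

**Peak extraction** searches the held grasp-dwell window (deepest flexion,
box in hand) rather than the full trial.  The load moment is the moment
created by the held object, so boxless and upright samples are not valid
candidates; moreover, a regressor trained only above 100 Nm extrapolates to
~100 Nm at upright standing, and for shallow tasks whose true peak is below
the threshold a full-trial argmax would select such a sample and the
conversion below would receive a near-zero horizontal distance.  User data
may supply an explicit lift-window column.

## Lumbar-to-load conversion

LiFFT consumes the *load* moment — the contribution of the lifted object —
not the full lumbar moment.  The conversion subtracts the trunk terms at the
peak sample:

    M_load = M_lumbar − [m_HAT·(a + g)·L + m_box·a·L] − I·α

where L is the horizontal pivot-to-HAT-COM distance at the peak sample
(r·sin θ from the trunk angle channel), a the vertical trunk acceleration
and α the differentiated sagittal angular velocity, both read from the
idealized trunk channels at that sample.  Applied to the true lumbar series
the conversion recovers m_box·g·L at the peak to ~1e-14 relative (the peak
falls in the quasi-static dwell); applied to predictions it inherits their
errors and can go negative, in which case the damage stage clamps to zero
and logs the count.

## Fatigue-failure damage and risk

Per-lift damage follows an exponential fatigue law in the peak load moment
M_i (Nm), summed over a workday:

    D = (1/902416) · Σ_i exp(0.038·M_i + 0.32)
    Y = 1.72 + log10(D),    R = e^Y / (1 + e^Y)

R is the probability of membership in a high-risk job under an
epidemiology-calibrated logistic model, not an individual injury
probability.  The flattened rendering of the damage equation is ambiguous
about the 0.32 constant; the default keeps it inside the exponent (a
per-cycle intercept, consistent with fatigue damage-per-cycle laws) and the
alternative grouping `(exp(0.038·M_i) + 0.32)/902416` is available behind
`eq4_grouping="additive_constant"`.  D = 0 maps to the exact limit R = 0.

## Workday Monte Carlo

A workday draws its lift count uniformly from [800, 2000] and samples that
many lifts uniformly with replacement from the participant's per-lift peak
lookup table.  The same lift sequence feeds the lab, trunk, and trunk+force
columns, isolating estimator error from sampling noise.  Defaults: 1000
workdays per participant, 10 participants.  Per-day RNG substreams are keyed
on (seed, participant, day), so results are independent of execution order.
A lift-counter baseline charges every lift a constant 75 Nm nominal load
moment.  A sensitivity flag (`moment_type="lumbar"`) reruns the whole
simulation on peak lumbar instead of load moments.

## Evaluation

Risks are scored on the 0–100 scale: per-participant RMSE of daily risk;
fraction of days within an inclusive ±10-point band of lab risk; Pearson r
per participant, pooled via Fisher z averaging (tanh of the mean atanh).
Between-condition statistics: a Kolmogorov–Smirnov normality check against a
normal with the sample mean/SD (Lilliefors-corrected p, noted in the
output), a paired t-test on per-participant RMSEs, and Cohen's d with the
pooled-SD definition (mean difference over √((s₁² + s₂²)/2)); the d
definition is recorded in the output metadata because published d values for
paired designs are not always reconstructible from summary statistics.
Trunk-risk drivers (correlation with daily lift count and mean bend angle)
quantify what a bend-counting IMU actually tracks.

## Problem sizes and determinism

The default study is 10 participants × 50 tasks (5 box masses 5–23 kg × 10
shelf heights 40–160 cm) × 1 repetition at 100 Hz (~420 samples per 4.2 s
trial), with 1000 workdays per participant; a full run takes well under a
minute on one CPU.  Every random draw descends from the single run seed, and
a fixed seed reproduces every output file bit-for-bit on one platform.

## What the generator does and does not establish

Passing tests on synthetic data show that the pipeline is internally
correct and that the *qualitative* information asymmetry (force channels see
box weight; trunk channels do not) propagates to risk estimates.  They do
not certify accuracy on real data.  Known gaps between this generator and
real lifting:

* **Load-moment scale.**  With the box co-located at the HAT COM and
  r = 0.17·stature, load moments cannot exceed m_box·g·r ≈ 72 Nm — below
  the 75 Nm nominal "average" lift used by the lift-counter baseline and
  well below real load moments, where the load sits anterior of the spine.
  Per-lift damage therefore spans a narrower range than in field data,
  day-level risks compress into a ~10-point band, and the trunk-vs-
  trunk+force contrast at the *risk* level is weaker than reported on real
  data, even though it is robust at the moment level.
* **Shallow lifts vs the training threshold.**  High-shelf lifts here can
  peak below 100 Nm, so the threshold (meant to exclude upright standing)
  excludes whole lifts and the regressors extrapolate for them.
* **Determinism.**  Real movement varies within task and day; the noise-free
  deterministic channels let a participant whose anthropometry matches the
  training population be predicted almost perfectly from trunk angles alone,
  which does not happen with real signals.
* No 3D/asymmetric lifting, no gait or carrying, no muscle co-contraction,
  no real sensor artefacts.

## Numerical choices

g = 9.81 m/s².  Differentiation of sampled channels uses central differences
with one-sided endpoint stencils.  Peak ties take the first maximum.
Negative converted load moments clamp to 0 with a logged count.  Undefined
correlations (zero variance) are excluded from Fisher pooling with a
warning; |r| = 1 raises rather than pooling an infinite z.  Degenerate
configurations (single participant, empty task ranges, phases shorter than
two samples, flexion mapping outside (0°, 135°]) raise configuration errors
rather than being clamped silently.
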