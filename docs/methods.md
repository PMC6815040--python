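# Methods

This note documents the models behind `exopark`: what the synthetic
cohort generator simulates and why, how the task parameters are defined
numerically, and the statistical conventions of the analysis layer. It is
the package's own account of its design choices; every number quoted here
is computed by the test suite or `scripts/acceptance.py`.

## Clinical layer

The clinical table schema (one CSV row per subject) is fixed by
`exopark/data/clinical_schema.json`; sex and handedness encodings are
taken from the schema, never inferred from data. The packaged 26-subject
cohort table carries per-subject age, sex, disease duration, levodopa
dose, co-medication, UPDRS Part III OFF/ON totals and MoCA. Per-subject
handedness is not part of the published per-row data; the fixture assigns
four left-dominant subjects (PD03, PD09, PD14, PD22) to match the cohort's
stated 22 right / 4 left split, and analyses that use handedness treat it
as a covariate only. The cohort's stated mean levodopa dose (750 mg)
disagrees with the arithmetic mean of the per-subject dose column
(649 mg); the fixture keeps the per-subject values and does not reconcile
the summary.

UPDRS subscores are exact sums over item maps stored per body side
(bradykinesia items 23–26, maximum 32; upper-extremity variants items
23–25, maximum 12 per side; rigidity item 22 over five entries, maximum
20; posture item 30). Missing items raise — no silent zero-fill.
Asymmetries are right minus left over the lateralized entries.

The responder criterion (minimal clinical difference) is strict:
OFF − ON > 6 points. A subject improving by exactly 6 points is a
non-responder; the partition of the PD cohort is exhaustive and disjoint.

## Synthetic cohort

No public recordings exist for this battery, so the generator is
first-class, tested code. It aims to reproduce *group-level* effect
structure, not individual behaviour.

### Limb and servo model (passive stretch)

Each arm is a single rigid segment about the elbow:

    I·ω̇ = τ_robot − b·ω − k_s·(θ − θ_start) − τ₀·S(ω)

with inertia `I` (0.06 kg·m²), viscosity `b`, a small reflex stiffness
`k_s` (1% of the postural stiffness `k`), and a velocity-independent tone
torque `τ₀` with sign function `S` that holds a constant resting bias —
so a toned limb loads the robot even during the pre-movement hold, which
is what the hold-torque parameter measures. The robot tracks a
minimum-jerk command (bell-shaped velocity, peak `1.875·Δθ/T`) with
inertial feedforward, a nominal viscous feedforward (0.05 N·m·s/rad, the
healthy median), and PD correction (Kp = 25 N·m/rad, Kd = 1.5 N·m·s/rad).
With these gains a healthy limb reaches 99.2% of the commanded peak speed,
and the velocity deficit grows with `b`, `k_s` and `τ₀` — the rigid-limb
signature. Integration is semi-implicit Euler at the configured sample
rate (default 1 kHz); divergence raises instead of returning garbage.

The `movement_end` event is placed 0.25 s after the commanded endpoint so
the limb is at rest and the deceleration phase is fully captured. This
makes two identities exact for ideal limbs, which the tests verify: for a
purely inertial limb both phase totals equal `I·ω_peak` (impulse–
momentum, measured error 0.002%), and adding viscosity `b` makes the
start-minus-end difference equal `b·Δθ` (measured error 0.06–0.2%).

The reflex stiffness fraction is deliberately small: a position-anchored
spring strong enough to matter makes the robot *push* (rather than brake)
through late deceleration in severely rigid limbs, which would invert the
end-total-torque group difference. Stretch resistance is therefore
viscosity- and tone-dominated.

### Hitting tasks

Objects fall from 10 bins across a 0.8 m × 0.5 m workspace with a linear
speed ramp (0.10 → 0.50 m/s over the spawn sequence; non-decreasing by
construction). Each hand pursues the nearest active object on its half of
the workspace with a speed-capped first-order lag (lag 0.1 s), skipping
balls that cannot plausibly be intercepted before the floor. A hit is
logged once per object when its center passes within
`(paddle 0.05 m + ball 0.02 m)/2` of a hand; contact mechanics are not
modeled. Distractors are engaged with probability `p_err` (drawn once per
object) and are otherwise transparent to the paddles, so `p_err = 0`
guarantees zero distractor hits.

Two couplings carry the disease effects into the measured parameters. The
hand-speed *cap* (healthy 0.45 m/s) is the binding constraint during
pursuit, so the measured mean hand speed scales with it. Pursuit
*amplitude* scales with the ratio of a subject's cap to the healthy cap
(speed–amplitude coupling): bradykinetic subjects also make smaller
excursions. Without the second coupling the convex-hull movement area — a
maximum statistic — would be insensitive to slowing, because even a slow
hand eventually visits the workspace extremes.

### Unloading task

The subject holds the hand on a target against a constant joint torque
(±0.5 N·m elbow, ±1 N·m shoulder). After a uniform random delay (1–3 s)
the load vanishes; the still-active muscle torque displaces the limb
until, one reaction delay later (120 ms), it relaxes (τ = 100 ms) and a
soft corrective controller (Kp = 5 N·m/rad, Kd = 0.8 N·m·s/rad) returns
the hand. The corrective gains are deliberately low so the passive
stiffness `k` dominates both excursion amplitude and timing — stiffer
(more rigid) limbs travel less and peak earlier, the parkinsonian
direction. Without visual feedback the perceived target is offset by a
per-trial proprioceptive error (SD 6 mm), which is what the endpoint-error
parameter measures. With the corrective controller disabled the model is
a pure spring–damper step response, giving the closed forms used in
tests: undamped peak `2L/k`, critically damped peak `→ L/k` from below.

### Planted group effects

Disease state is a per-subject latent severity `s ~ N(1, 0.2)` (clipped to
[0.4, 1.8]); the most-affected arm (random side) gets `s` multiplied by
the asymmetry factor 1.3. Session multipliers `m` act as
`1 + (m − 1)·s` on the latent parameters:

| latent parameter | OFF | ON | rationale (direction of the measured effect) |
| --- | --- | --- | --- |
| hand-speed cap | ×0.59 | ×0.76 | hand speed ~40% slower OFF; partial recovery ON |
| tone τ₀ | ×3.6 | ×2.2 | hold torque several-fold greater; reduced by DRT |
| viscosity b | ×3.0 | ×2.9 | end total torque lower, torque difference higher; essentially unchanged by DRT |
| stiffness k | ×1.45 | ×1.25 | max displacement ~30% shorter, deceleration faster; displacement ~10% greater ON |
| distractor error p_err | ×1.0 | ×1.6 | distractor hits similar to controls OFF, elevated ON |

Synthetic UPDRS-III totals are tied to the same severity
(`OFF ≈ 6 + 24·s`, improvement `≈ 11·s`), so clinical and robotic
measures co-vary and the responder filter partitions realistically
(roughly three-quarters responders).

What the generator does **not** emulate: tremor and dyskinesia (the
exoskeleton cannot measure them), two-joint arm kinematics, fatigue and
learning across the session, attention lapses, and any individual-level
behavioural realism beyond group means. Passing tests therefore
demonstrate that the *pipeline* recovers planted group structure, not
that the simulator matches real patients.

## Feature definitions and numerical choices

* Torque phase totals are unsigned phase integrals `|∫τ dt|`
  (trapezoidal), split at the sample of peak |ω| (earliest on ties).
  This convention keeps all parameters nonnegative, makes the
  impulse–momentum and `b·Δθ` identities hold exactly, and reads "lower
  end total torque" as less braking effort by the robot. The hold torque
  integrates over [onset − 1.5 s, onset − 0.5 s]; at least 2 s of
  pre-movement data are required.
* Stretch parameters average the flexion and extension repetitions of the
  600 ms condition (the faster stretches discriminate better; the 1500 ms
  condition is simulated when configured but not used in scoring).
* Movement area is the sum of per-hand convex hulls; degenerate
  (collinear) trajectories score 0 with a warning.
* Unloading return criterion: hand inside the target radius (15 mm) at
  speed below 0.02 m/s; a hand that never returns yields NaN (flagged
  missing), never infinity. Deceleration time is release → argmax
  displacement.
* Subsampling a smooth recording 10× changes no stretch parameter by more
  than 1% (verified).

## Normative scoring

Models are OLS fits of each parameter on age (linear) plus sex and
handedness indicators over controls only (minimum 20 by default);
degenerate covariate columns (e.g. single-sex cohorts) are dropped with a
warning, and a zero-variance response is an error. The residual SD uses
an `n − p` denominator. Z-scores are signed raw residuals — no flipping
toward an "abnormality" direction — so by construction the fitting
controls have mean 0 (machine precision) and SD within [0.95, 1.05] at
n = 250. A log transform is available for right-skewed parameters but
defaults off.

The cumulative score refuses missing components rather than silently
shrinking the component set. The DRT-sensitive component selection runs
normality-gated paired tests per parameter on responders' OFF/ON z-scores
at α = 0.05 and refuses fewer than 5 pairs; a frozen six-parameter list
(hit counts in both hitting tasks, hand speed and movement area under
distractor load, hold torque, maximum displacement) is available to make
runs comparable across cohorts.

## Statistics

* Normality gate: Shapiro–Wilk at α = 0.05 per sample (or on paired
  differences); constant samples are routed to the rank test. Student's
  t (equal variances) / Mann–Whitney; paired t / Wilcoxon (exact for
  ≤ 15 non-zero differences, otherwise normal approximation with
  continuity correction). Identical samples short-circuit to p = 1.
  Under the null the composite procedure holds its level: measured type-I
  error 0.048 over 5000 replicates.
* AUC is the Mann–Whitney identity `U/(n₁n₀)` with ties worth ½, exactly
  equal to brute-force pairwise concordance; the reported orientation
  keeps AUC ≥ 0.5 with a flip flag. CIs use the DeLong structural-
  components variance; ROC-curve differences are DeLong z² reported as
  χ²(1). The empirical curve's trapezoidal area equals the U-statistic
  AUC to 10⁻¹².
* Significance thresholds are configuration keys: α = 0.01 for
  control-vs-PD group means, 0.05 elsewhere. No multiple-testing
  correction is applied; the report records the number of tests run.

## Problem sizes

Default task configuration matches the full battery (300 balls over
150 s; 200 + 100 in avoid mode; 5 repetitions per stretch direction at
two movement times; 16 unloading trials per load condition on elbow and
shoulder; 1 kHz sampling). The Monte-Carlo self-checks use a reduced
battery chosen as a package default for quick studies — 8 controls + 8 PD
per cohort, 100 Hz sampling, 90/60+30-ball hitting blocks over 45 s,
three stretch repetitions per direction at 600 ms only, and a 3-trial
elbow-only unloading block — under which 50 seeded cohorts complete in
about two minutes on one CPU while reproducing the full expected
group-difference sign pattern and the OFF > ON > control cumulative-score
ordering in 100% of cohorts.

## Known limitations

* The simulators are single-joint/planar caricatures; magnitudes of the
  synthetic group differences are in the right direction and rough size
  but are not calibrated to any individual dataset.
* The hitting policy is deterministic given the seed and omniscient
  within its feasibility filter; distractor errors are a single Bernoulli
  rate, not a model of impulsivity.
* DeLong CIs are asymptotic and can degenerate (zero width) under perfect
  separation at small n.
* The normative model is linear in age with additive offsets; no
  quantile or nonlinear normative modelling.
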