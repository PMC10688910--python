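# Methods

## The problem

A limb has more muscles than degrees of freedom, so inverse analyses that
recover individual muscle forces from recorded motion are underdetermined:
the muscle redundancy problem.  The standard resolution is static
optimization — at each time step, choose the activation vector of minimum
"effort" that reproduces the measured joint accelerations.  At the shoulder
this formulation has a known blind spot: the glenohumeral (GH) joint has no
bony socket, and nothing in an unconstrained minimum-effort solution stops
the joint reaction force (JRF) from pointing somewhere no real glenoid
could resist.  Deep stabilizing muscles (the rotator cuff, in the real
shoulder) exist largely to prevent exactly that, and because their moment
arms are small they are nearly free in the effort cost — an unconstrained
optimizer simply leaves them off.

This package implements a per-frame redundancy solver in which the JRF
direction can be constrained to a stability cone, together with the minimal
musculoskeletal machinery (Hill-type rigid-tendon muscles, a rigid-body
tree, a Newton–Euler reaction oracle), the trajectory-conditioning chain,
and the comparison statistics needed to ask: *which muscles change when the
stability constraint is switched on?*

## The per-frame optimization

At each frame k with kinematic state (q_k, q̇_k) fixed from the input
trajectories, the solver finds muscle activations a ∈ [0,1]^{N_m} and
reserve controls c ∈ [−1,1]^{N_q} minimizing

    J(a, c) = Σ_i w a_i²  +  Σ_j v c_j²,        w = 1, v = 10

subject to

1. **Acceleration matching** — A_acc [a; c] = q̈_exp − q̈_passive, where
   column i of A_acc is the coordinate acceleration produced by a unit
   activation/control of actuator i and q̈_passive collects gravity,
   velocity products and passive muscle force.  Because the tendon force is
   affine in activation at fixed muscle kinematics (below) and M(q)⁻¹ is a
   fixed linear map at fixed q, this equality is *exact*, not a first-order
   expansion.  Verified against brute-force forward dynamics to 1e−10
   rad/s² on random states.
2. **Activation-rate bounds** — first-order activation dynamics with the
   neural excitation pinned at its extremes are integrated one explicit
   Euler step between frames:

       l = a₀ − a₀ (½ + 3/2 a₀) Δt/τ_deact
       u = a₀ + (1 − a₀) Δt / ((½ + 3/2 a₀) τ_act)

   with τ_act = 10 ms, τ_deact = 40 ms, both bounds clipped to [0,1].  The
   effective time constant shrinks with activation when activating and
   grows when deactivating, which is the standard calcium-kinetics
   asymmetry.  One Euler step differs from exact integration of the
   underlying ODE by O(Δt) in the admissible increment (≈6% at Δt = 1 ms at
   a₀ = 0.5) and O(Δt²) in the bound value (≈0.4%); at the 10 ms frame
   spacing of 100 Hz data the bounds are intentionally permissive envelopes,
   not integrators.
3. **Stability cone (optional)** — the JRF at the glenoid, F = A_F [a; c] +
   F0 (exact affine, same argument as above; reserve columns are zero
   because ideal torque actuators carry no force), must make an angle
   θ ≤ θ_max with the glenoid axis: (θ/θ_max)² − 1 ≤ 0, default
   θ_max = 20°, the conservative cadaveric estimate of how far a reaction
   can tilt before leaving the fossa rim.

Reserves exist so the equality is always feasible: an ideal torque
generator per coordinate, ten times more costly than muscle per unit
squared control, whose usage is an error metric (a per-coordinate
"reserve share" of total generalized force is reported; on consistent toy
data it stays below 1%).

Frames are solved sequentially with SLSQP, warm-started from the previous
frame; the first frame uses the full [0,1] box and initial guess 0.1.  With
the cone inactive the problem is a strictly convex QP, so the minimizer is
unique; a failed attempt is retried from the cold start, and frames that
remain unconverged are flagged in the result rather than dropped.

### Cone numerics

The cone is handed to the SQP in second-order-cone form,
F·d − cos(θ_max)·‖F‖ ≥ 0, which describes the identical feasible set as the
squared-angle form but has bounded derivatives (the arccos form's curvature
explodes near the axis and near anti-alignment and stalls the line search).
Two regularizations are applied, both far below physiological force
resolution: ‖F‖ is smoothed to sqrt(‖F‖² + ε²) with ε = 0.1 N, and a small
absolute margin (1e−6 in force-scaled units) is subtracted.  The smoothing
matters scientifically, not just numerically: on adversarial tasks the
minimum-effort optimum otherwise parks the reaction at the cone *apex*
(‖F‖ ~ 1e−6 N), where its direction — the very quantity being constrained —
is numerical noise.  With the regularization any feasible reaction keeps
‖F‖ ≳ ε/tan(θ_max) ≈ 0.3 N and the reported angle satisfies θ ≤ θ_max
strictly at every frame.

### Reaction-force convention

The reaction oracle returns the force transmitted to the *distal* subtree
(Newton balance of all bodies beyond the joint: inertial minus gravity
minus the via-point forces applied by muscles crossing the cut).  Under
that convention a compressive, stable reaction on the humeral side points
*from* the glenoid *toward* the humeral head, so the glenoid axis stored in
a model is the outward fossa normal.  Reaction moments are not computed
anywhere; only the 3-vector force enters the cone.  Subtree inertial terms
are evaluated at the experimental accelerations in both the oracle and the
linearization — the acceleration equality makes the two coincide at the
solution, and this choice keeps F exactly affine in (a, c).

## Muscle model

Rigid tendon: tendon length is fixed at slack length, so fiber kinematics
follow algebraically from musculotendon length and speed, and the tendon
force decomposes exactly as

    F(a) = F_iso · fL(l̃) · fV(ṽ) · cos α · a  +  F_iso · fPE(l̃) · cos α

— an activation gain plus a passive offset.  Pennation uses the
constant-thickness model (fiber height l_opt·sin α_opt invariant).  Curve
shapes are the conventional smooth family: Gaussian active force–length
exp(−(l̃−1)²/0.45); exponential passive force–length normalized to reach 1
at 60% fiber strain (k = 4); hyperbolic Hill shortening branch with
fV(−1) = 0 and a saturating lengthening branch capped at 1.4 with matched
slope at zero velocity.  The solver's correctness does not depend on these
shapes — only on affinity in activation, which holds for any of the common
parameterizations — so the constants are chosen for smoothness and
plausibility, not fitted to any dataset.  Passive force deliberately does
not scale with activation; the affine decomposition requires it.

## Rigid-body engine

Models are trees of rigid segments connected by pin and 3-DoF gimbal
joints, compiled internally to elementary revolute axes (a gimbal becomes
three axes with massless intermediate frames; locked coordinates keep a
fixed angle and vanish from the generalized coordinates, mirroring the
practice of locking indeterminate coordinates near gimbal lock).  Inverse
dynamics is recursive Newton–Euler; the mass matrix is assembled from unit
accelerations and inverted once per frame via Cholesky, with forward
dynamics and both linearizations sharing the same inverse so the affine
maps agree with the brute-force route to reassociation-level rounding.
Moment arms are tendon-excursion derivatives r_j = −∂L/∂q_j; the public
operation uses a 1e−6 rad central difference, while hot paths use the
analytic via-point Jacobian (dP/dq_j = ω̂_j × (P − o_j) for ancestor axes),
and the two agree to < 1e−8 m in tests.  A hand-held load is a point mass
merged into the distal segment's mass, center of mass and inertia.

## Trajectory conditioning

Storage files use the plain-text STO/MOT dialect (key=value header,
`endheader`, whitespace-delimited block, first column `time`; optional
`inDegrees=yes`).  Writing uses 17 significant digits so round-trips are
bit-lossless.  Angles are low-pass filtered with a zero-phase
(forward–backward) 4th-order Butterworth at 3 Hz — two-pass magnitude
|H|² = 1/(1+(f/f_c)⁸), i.e. ≥ 80 dB attenuation at 10 Hz for 100 Hz data —
then differentiated analytically through an interpolating natural cubic
spline.  Endpoint samples carry spline boundary error and are excluded from
accuracy guarantees.  Speeds and accelerations are not filtered again.

Kinematic-uncertainty ensembles add band-limited Gaussian jitter directly
to the angle trajectories: white noise is passed through the same 3 Hz
zero-phase filter and rescaled by the filter's theoretical noise gain so
the per-sample standard deviation equals the requested sigma.  This stands
in for marker-placement uncertainty propagated through inverse kinematics,
which would require marker data and a marker-based model; the intent —
testing whether conclusions survive plausible kinematic error — is
preserved, the mechanism is not.  Default sigma in the acceptance analysis
is 0.01 rad (≈0.6°, the scale of ~1 cm marker error over typical segment
lengths).

## Comparison statistics

Each condition contributes an ensemble of activation trajectories
(trials × 101 time-normalized samples per muscle), paired per perturbation
replicate.  Per muscle:

* **Effect size**: difference of condition means per timepoint; its peak
  absolute value summarizes the muscle.
* **Pointwise paired t**: mean(d)/(sd(d)/√n) with n−1 denominator;
  zero-variance timepoints map to 0 (zero mean) or ±∞ (nonzero mean).
* **Cluster inference**: a sign-flip permutation test.  Under the paired
  null the difference trials are sign-symmetric; the pointwise (1−α)
  quantile of permuted |t| forms the cluster threshold, observed
  supra-threshold clusters are scored by their |t| mass against the
  permutation distribution of the maximal cluster mass, and p-values use
  (1 + count)/(1 + n_perm), which keeps the test level-valid at finite
  n_perm.  Measured type-I rate over 500 null simulations at α = 0.01 is
  ≤ 2%.  This replaces random-field-theory SPM: same null hypothesis, same
  α, no external statistical package, exactly reproducible from a seed; the
  random-field t-threshold machinery itself is not reproduced.
* **Significance rule**: a muscle is flagged only if some cluster has
  p < α = 0.01 *and* the peak effect size exceeds 0.1 — a conjunction, so
  statistically detectable but physiologically trivial shifts do not flag.
  The 0.1 bar matches the MAE level conventionally read as an excellent
  match between estimated and EMG-derived activation, provided by `mae`.

## The synthetic world

`build_toy_shoulder` constructs the stated world all tests run in: a
ground-fixed scapula, a 3-DoF gimbal humerus (mass 2 kg, length 0.3 m, rod
inertia), an optional 2 kg hand load at the distal end, and 8 muscles —

* 4 **stabilizers** (F_iso 500 N): straight lines from the humeral head
  (≤ 5 mm from the joint center, so moment arms < 6 mm) to a ring of
  scapular anchors placed so tension presses the head along the glenoid
  axis;
* 3 **prime movers** (F_iso 1200 N): deltoid-like elevators with moment
  arms ≥ 2 cm whose pull shears the reaction off the glenoid axis as a
  side effect;
* 1 **antagonist** (F_iso 800 N) for negative elevation torque;

plus a 10 N·m reserve per coordinate and a 20° stability cone.  Elevation
is deliberately the *first* gimbal axis: the gimbal's singular pose sits at
±90° of the middle axis, which all generated motions keep near zero, so the
toy sweeps elevation through 90° without approaching gimbal lock.  Optimal
fiber lengths are calibrated at build time to 1.02× the maximum path length
over the 0–120° elevation range, so fibers never go slack and never develop
passive force during the tasks the generator emits — a convenience that
keeps the toy's force balance easy to reason about, not a claim about real
muscle.

Motions are minimum-jerk profiles (elevation 10°→110°, zero end velocity
and acceleration; a locked-humerus "shrug analog" exercises the
coordinate-locking path), with spectral content below 2 Hz for durations
≥ 2 s so the 3 Hz filter passes them nearly unchanged.
`forward_consistency_data` integrates the model's own dynamics (RK45,
rtol 1e−10) to produce dynamically consistent ground truth for recovery
tests, and `adversarial_gh_task` verifies *at build time* — by running the
unconstrained solver — that the loaded elevation actually drives the
reaction angle past 20° on at least 20% of frames, raising if the fixture
fails to be adversarial.

What the toy does *not* emulate: marker trajectories and inverse
kinematics, model scaling, muscle wrapping surfaces, scapulothoracic and
clavicular kinematics, tendon compliance, EMG.  A green test establishes
that the solver machinery behaves as specified on a system with the same
*structure* as a shoulder analysis (redundancy, stabilizer/prime-mover
geometry, a binding stability cone); it does not validate any anatomical
prediction.

## Numerical choices

* Equality rows scaled by max(1, per-row ‖A_acc‖∞); SLSQP ftol 1e−10,
  max 300 iterations, cold-start retry at 2× on failure.
* Feasibility classification: equality residual ≤ 1e−7 (scaled), cone
  value ≤ 1e−7; non-convergent frames are reported with diagnostics, and a
  frame whose residual exceeds 1e−3 raises (or is flagged and retained
  under `keep_going`).
* Zero-force reactions (‖F‖ < 1e−6 N) are defined stable and report 0°.
* Mass-matrix Cholesky failure (singular/near-gimbal-lock configuration)
  raises a configuration error rather than returning garbage.
* Determinism: every stochastic operation (perturbation, permutation test)
  takes an explicit seed; solver runs are bit-reproducible.

## Limitations

The engine handles rotational tree joints only — no closed loops, contact,
wrapping or translational joints — and the reaction is a pure force.  The
activation-rate bounds are one-step Euler envelopes, accurate to ~1% in
value at 100 Hz but not a substitute for integrating activation dynamics
when Δt/τ_act is large.  The cone regularization excludes reactions below
~0.3 N, a deliberate trade against a direction constraint on a vanishing
vector.  Statistical power and effect sizes measured on the toy transfer to
real analyses only in kind, not in magnitude.
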