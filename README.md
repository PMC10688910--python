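# rmrsolver

Per-frame muscle redundancy solving with joint-stability constraints, on
synthetic toy-shoulder models.

Inverse analyses of recorded movement must distribute the required joint
torques across more muscles than there are degrees of freedom.  Static
optimization resolves this by picking, frame by frame, the activations of
minimum effort that reproduce the measured accelerations — but at a joint
like the glenohumeral (GH) joint, which has no bony socket, nothing stops
that solution from demanding a joint reaction force (JRF) no real glenoid
could resist, and the deep stabilizing muscles that prevent this in life
are left switched off because their moment arms make them useless for
torque production.  This package is for researchers in musculoskeletal
simulation who want to study that failure mode quantitatively: it solves
the redundancy problem with an optional stability cone on the JRF
direction, and ships the synthetic models, data conditioning and
statistics needed to measure how the constraint redistributes muscle
activity.

## The method

At each frame k, with the kinematic state (qₖ, q̇ₖ) fixed from the input
trajectories, solve for activations **a** ∈ [0,1]^{N_m} and reserve
controls **c** ∈ [−1,1]^{N_q}:

```
minimize    Σᵢ w aᵢ²  +  Σⱼ v cⱼ²                  (w = 1, v = 10)

subject to  A_acc [a; c] = q̈_exp − q̈_passive       (track accelerations)
            lₖ(aₖ₋₁)  ≤  a  ≤  uₖ(aₖ₋₁)             (activation dynamics)
            (θ(F)/θ_max)² − 1 ≤ 0,   F = A_F [a; c] + F₀    (optional cone)
```

Because a rigid-tendon Hill muscle produces a force affine in its
activation at fixed length and velocity, both A_acc (accelerations) and
A_F/F₀ (the glenoid reaction force) are *exact* affine maps, assembled once
per frame — no multibody queries inside the optimization loop.  The bounds
l, u integrate first-order activation dynamics (τ_act = 10 ms,
τ_deact = 40 ms) one Euler step between frames, and θ_max defaults to 20°.
Reserve actuators (ideal per-coordinate torques, ten times costlier than
muscle) guarantee feasibility; their share of the applied generalized force
is the model-consistency error metric.  Details, conventions and numerical
choices are in `docs/methods.md`.

## Worked example

Solve a loaded (2 kg in hand) elevation of the toy shoulder with and
without the stability cone and compare the two solutions:

```python
import numpy as np
import rmrsolver as rmr

model = rmr.build_toy_shoulder(rmr.ToyShoulderConfig(hand_load=2.0))
angles = rmr.generate_motion("elevation", duration=2.0, rate_hz=100.0)
filtered = rmr.lowpass_filter(angles, cutoff_hz=3.0)
speeds, accels = rmr.differentiate(filtered)

results = {}
for enforce in (False, True):
    settings = rmr.SolverSettings(enforce_gh=enforce)
    results[enforce] = rmr.solve_motion(model, filtered, speeds, accels, settings)

for enforce, label in ((False, "without cone"), (True, "with cone   ")):
    res = results[enforce]
    theta = np.degrees(res.theta_series)
    frac, excess = rmr.violation_report(theta, 20.0)
    print(f"{label}: converged={res.all_converged}  "
          f"violations={100*frac:.0f}% of frames  max theta={theta.max():.1f} deg  "
          f"max reserve share={res.reserve_share.max():.4f}")

A0, A1 = results[False].activations, results[True].activations
names = results[False].muscle_names
stab = [i for i, n in enumerate(names) if n.startswith("stab")]
print(f"stabilizer-group peak effect size: "
      f"{np.abs(A1[:, stab].sum(1) - A0[:, stab].sum(1)).max():.3f}")
```

Output:

```
without cone: converged=True  violations=100% of frames  max theta=179.8 deg  max reserve share=0.0028
with cone   : converged=True  violations=0% of frames  max theta=20.0 deg  max reserve share=0.0171
stabilizer-group peak effect size: 0.510
```

Read: the unconstrained minimum-effort solution points the glenoid
reaction outside the 20° fossa cone on every frame (up to 179.8° — the
force would pull the joint apart); enforcing the cone removes every
violation at the cost of recruiting the stabilizer group, whose summed
activation rises by up to 0.51, while each prime mover changes by less
than 0.05.  Reserve shares below ~2% mean the muscles, not the ideal
actuators, did the work.

## Command-line tools

```sh
rmr-fixtures --task adversarial --load 2 --out fixtures/   # model + motion files
rmr-solve --model fixtures/model.json --motion fixtures/motion.sto \
          --out run_gh/ --enforce-gh                       # activations.sto, jrf.sto, summary.json
rmr-compare --condition-a run_gh/ --condition-b run_nogh/ --alpha 0.01 \
            --effect-threshold 0.1 --n-perm 1000 --seed 1  # per-muscle report CSV
```

Models are versioned JSON (bodies, joints, via-point muscles, reserves,
glenoid geometry); motions are the plain-text STO/MOT storage dialect.

## Acceptance script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

rebuilds the toy shoulder, solves a 5-replicate kinematic-uncertainty
ensemble of the loaded elevation under both stability conditions, and
recomputes the headline quantities from scratch: cone-violation fractions
for each condition, the stabilizer-group significance decision (sign-flip
permutation cluster test at α = 0.01 joined with the 0.1 peak-effect
threshold) and per-muscle peak effect sizes, printing each to stdout and
writing the target JSON to `--out`.
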