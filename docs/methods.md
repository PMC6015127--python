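# Methods

## Model

A surgical thread is modeled as a discrete Cosserat rod solved with
position-based dynamics (PBD). The centerline is a chain of `n + 1` particles
(positions `x_i`, velocities, inverse masses `w_i`); each consecutive pair
bounds a *rod element* carrying a unit quaternion `q_k` (the material frame,
scalar-first Hamilton convention; rotating a vector v is `q (0,v) q̄`), an
angular velocity and a scalar inverse inertia. An inverse mass or inertia of
exactly 0 marks a held degree of freedom (pin or instrument grip).

Two vector-valued elastic constraints act on this state:

* **shear–stretch** (per element):
  `C_s = (p₂ − p₁)/l − R(q) e₃`, coupling the segment vector to the frame's
  tangent director `d₃ = R(q) e₃`. It vanishes when the segment has rest
  length *l* and lies along `d₃`.
* **bend–twist** (per adjacent element pair):
  `C_b = ℑ(q̄u − q̄⁰u⁰)`, the deviation of the discrete Darboux vector
  (imaginary part of the relative quaternion) from its rest value. The first
  two components are bending strain, the third is twist about the tangent.

Every solver step runs: explicit (symplectic) Euler prediction → continuous
collision detection → a fixed count of Gauss–Seidel projection iterations →
velocity update from the corrections → damping. Per iteration the projection
order is shear–stretch, bend–twist, contacts, friction, then the direct
distance solve last, so inextensibility is the binding constraint at the end
of every iteration.

Each constraint is projected with the mass-weighted Newton step
`λ = −(∇C W ∇Cᵀ)⁻¹ C`, `Δp = W ∇Cᵀ λ`. Quaternions are differentiated as 4
raw components (the rotation matrix is evaluated in its homogeneous quadratic
form, so analytic Jacobians equal raw-component finite differences) and
renormalized after every correction; for unit quaternions both constraint
families have `∇C W ∇Cᵀ` proportional to the identity, so the per-constraint
solve is a scalar division. Stiffnesses scale the correction per iteration:
`K_s` for shear–stretch, and `(K_b, K_b, K_t)` componentwise for the bend
(first two) and twist (third) components of the bend–twist correction.
When the current relative quaternion `q̄u` has negative 4-dot with the rest
product, the freer quaternion is negated first (the same rotation on the
other branch of the double cover) so projection takes the short way around.

## Direct distance constraint (DDC)

The chain distance constraints `C_i = ‖p_i − p_{i+1}‖ − d` couple only
neighbouring multipliers, so `∇C W ∇Cᵀ` is tridiagonal: diagonal
`w_i + w_{i+1}`, off-diagonal `−w_{i+1} n_i·n_{i+1}` with `n_i` the unit
segment offsets. We assemble this matrix and solve `A λ = −C` with the Thomas
algorithm in O(n) once per projection iteration (the negated form with a
−1/−2 diagonal is the same system multiplied by −1). Interior held particles
split the thread into independently solved sub-chains; an all-held sub-chain
is a no-op.

One refinement proved necessary: the raw Newton step can overshoot and cycle
on folded, compressed configurations, so each solve applies the largest
backtracking factor (1, 1/2, … 1/64) that reduces `‖C‖²` — the Newton
direction is always a descent direction for that norm because the
linearization is exact. The uniform scaling preserves `Σ mᵢ Δpᵢ = 0`.
Convergence to machine-precision segment lengths is reached across the
step's projection iterations.

## Collision detection and response

Collision primitives are per-node spheres of radius `r` = half the thread
thickness; the element length defaults to `2r` so the spheres are closely
packed, and same-rod neighbours within two chain positions are excluded
(they overlap permanently by construction). The pipeline per step:

* **wide phase** — swept AABBs (min/max over the pre-step and predicted
  centers, expanded by `r`) hashed into a uniform grid of cell size 2×
  sphere diameter; only same-cell pairs are candidates;
* **narrow phase** — earliest time of impact of the two moving spheres from
  one quadratic; the contact normal is taken between the centers at impact;
* **response** — position-level constraints projected during the remaining
  iterations: the contact inequality `C_c = (p₁ − p₂)·n − d ≥ 0` (corrected
  only when violated) and, while the pair is touching, the friction
  constraint `C_f = k ‖(p₁−p₂)/‖p₁−p₂‖ × n‖` projected toward zero with a
  central-finite-difference gradient. Near `C_f`'s maximum that gradient
  vanishes and the raw step diverges, so the per-projection friction
  displacement is capped at 0.2 × the contact separation. `k = 0` leaves
  sliding free; `k = 1` pins the offset to the collision-time normal.

Static rigid colliders (plane, sphere, cylinder) produce the same contact
type through signed-distance queries, with an infinite-mass anchor at the
surface projection of the particle's *pre-step* position — friction then
measures (and can cancel) the tangential motion accumulated during the step,
which is what makes a `k = 1` contact stick rather than creep.

## Damping

After the velocity update, `v ← (1 − d_v)^Δt v` and `ω ← (1 − d_a)^Δt ω`:
the factors are the fraction of the corresponding velocity dissipated per
second, independent of the time step.

## Parameters and defaults

| parameter | default | meaning |
|---|---|---|
| `dt` | 1/60 s | step for interactive-scale scenes; drop scenes need finer (below) |
| `iterations` | 10 | Gauss–Seidel projection count per step |
| `K_b`, `K_t` | 0.05, 0.25 | bend/twist correction per iteration, in (0, 1] |
| `K_s` | 1.0 | shear–stretch correction per iteration |
| `d_v`, `d_a` | 0.1 | damping per second of linear/angular velocity |
| mass | 1 per particle | uniform; constraint dynamics depend only on ratios |
| inertia | 500 · m · d² | per element, isotropic (see below) |
| `friction_k` | 0.5 | friction strength in [0, 1] |
| `cell_size` | 4r | spatial-hash cell, 2× sphere diameter |

Two defaults deserve explanation:

**Time step.** For a thread discretized at millimetre scale, a free drop at
`dt = 1/60` moves each particle ≈ 2 segment lengths per step under gravity
alone; no projection scheme recovers gracefully from that regime (a 30-line
reference PBD chain shows the same blow-up). Drop-style scenes therefore use
a step satisfying `g·dt² ≲ 0.2 d` — `dt = 1/600` for the 1.25 mm segments of
the hanging-spiral scene, `dt = 1/240` for the cylinder-binding scene. Scenes
without gravity-driven free flight (knot tightening) run at coarser steps.

**Element inertia.** The scalar inertia sets how shear–stretch corrections
split between moving particles and rotating frames. We deliberately make
frames heavy (500 · m · d²): the orientation field then carries its own slow
dynamics and the positions follow it through the shear–stretch coupling.
This is the regime in which the bend/twist stiffnesses control shape and the
angular damping factor controls settling, which is how this family of models
is tuned in practice. The physically "correct" slender-rod inertia
(`m d²/12`) was tested: it slaves frames to positions, making `d_a` inert
(damping a slaved variable has no effect because projection overwrites it
each step).

## Validation scenes (what the synthetic scenes do and do not show)

All experiment inputs are generated programmatically; "frame" means one
solver step. Scenes are deterministic — identical configs give bit-identical
trajectories; the seed is plumbed through configs for reproducibility
bookkeeping but no scene draws random numbers at run time.

* **Hanging spiral** (120 elements, 15 cm, helical rest shape of radius
  4 mm / pitch 8 mm per turn ≈ 5.7 turns, one end pinned, gravity, 10 s):
  max percent elongation per frame, swept over 5/10/20/40 iterations with
  and without the DDC. With the DDC the maximum stays ≤ 0.04%; without it,
  elongation is far larger and decreases with the iteration count.
* **Compression–release** (49 elements, 2 cm, no gravity/friction,
  `d_v = 0`): the held end moves 1 cm inward over 1 s and is released; the
  metric is the summed particle distance to the pre-compression state over
  500 frames. Conditions chosen once: `dt = 1/240`, soft `K_b = 0.01` so the
  recovery spans the recorded horizon, a 0.5 mm multi-harmonic 3-D
  imperfection to seed buckling (a single pure mode would let the whole
  thread swing coherently through its initial state, transiently zeroing the
  metric), and a clamped root orientation so the straight rest line is the
  unique recovery target.
* **Twist winding** (40 elements, slack thread between pins at 50% of its
  length, right end frame ramped 10π about the pin chord over 8 s, high
  damping 0.5 so the coil shape persists): out-of-plane deflection and a
  winding count (sign changes of the out-of-plane deflection beyond one
  radius). Twist coupling lifts the thread > 1 diameter out of its sag
  plane; with `K_t = 0` nothing leaves the plane.
* **Knot tightening**: a pre-formed open-trefoil (overhand) centerline whose
  held ends are pulled apart — a deterministic stand-in for interactive
  tying. Contacts keep the minimum non-adjacent sphere separation bounded
  (no tunneling) and the knot persists.
* **Cylinder binding**: a thread whose *rest shape* is a 2-turn helix around
  a rigid cylinder (a "set" thread standing in for a knot closure), with
  unequal hanging tails driving slip. With `k = 1` the wrapped region's
  axial drift stays below one thread diameter; with `k = 0` the thread
  slides off.

These scenes exercise the solver's mechanics under controlled conditions;
they do not calibrate against measured thread moduli (the constraint
stiffnesses have no closed-form mapping to physical moduli), do not model
aerodynamics, plasticity or thread–tissue interaction, and the scripted
scenes replace a human operator's instrument motions with deterministic
waypoint paths.

## Numerical choices and degenerate inputs

* Rod construction requires ≥ 2 distinct points and segment uniformity
  within 1% (the discretization assumes fixed-length segments); curve
  fixtures are resampled to equal *chord* lengths (iterative redistribution)
  before construction.
* Rest frames are shortest-arc rotations from `e₃` to the segment direction
  (twist-free); the antiparallel case uses a half-turn about `e₁`.
* Thomas sweeps guard pivots at 1e−12 and raise on singularity; an all-held
  sub-chain is reported as a no-op rather than an error.
* Sphere–sphere impact returns t = 0 for initially overlapping pairs and
  "miss" when the quadratic has no root in [0, 1].
* Quaternion norms are restored after every correction and stay within
  1e−9 of unity after every step.
* A swept AABB spanning more than 65536 hash cells raises immediately — it
  almost always means the state has diverged.

## Known limitations

* Single linear chains only; no branched thread topologies.
* Friction is the position-level directional constraint above, not a Coulomb
  model with a normal-force-dependent cone.
* Collision response between a thread and a *dynamic* rigid body is not
  modeled (static colliders only).
* Per-iteration stiffness semantics mean effective rigidity depends on the
  iteration count and time step, as in all non-compliant PBD formulations.
* The elongation claims hold in the stated dt regimes; pushing drop scenes
  to interactive steps trades accuracy for speed like any PBD system.
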