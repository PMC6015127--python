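"""Position-based dynamics step loop.

Each step: predict positions/orientations by explicit Euler, detect contacts
continuously between the previous and predicted states, run a fixed count of
Gauss–Seidel projection iterations (shear–stretch, bend–twist, contacts,
friction, then the direct distance solve last so inextensibility is the
binding constraint), update velocities from the corrections, and apply
time-step-independent damping.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from . import quaternion as quat
from ._kernels import (
    bend_twist_pass,
    contact_pass,
    friction_pass,
    shear_stretch_pass,
)
from .collision import (
    FRICTION_ACTIVE_GAP,
    Contact,
    broad_phase,
    narrow_phase,
    pack_contacts,
    static_contacts,
)
from .ddc import distance_constraint_values, project_ddc_inplace
from .state import OrientationState, ParticleState, Rod, SimConfig

__all__ = [
    "World",
    "StepReport",
    "predict_state",
    "project_constraints",
    "update_velocities",
    "apply_damping",
    "step",
]


@dataclass
class StepReport:
    """Per-step diagnostics."""

    iterations: int
    residuals: dict[str, float]
    contacts: int
    time: float


class World:
    """All simulation state: global particle/orientation arrays, the rods
    indexing into them, static colliders and boundary scripts.

    Scripts are callables ``script(world, t)`` invoked at the start of each
    step with the step's end time; they prescribe held (w = 0) positions and
    orientations.
    """

    def __init__(
        self,
        particles: ParticleState,
        orientations: OrientationState,
        rods: Sequence[Rod],
        config: SimConfig | None = None,
        colliders: Sequence = (),
        scripts: Sequence[Callable[["World", float], None]] = (),
    ):
        self.particles = particles
        self.orientations = orientations
        self.rods = list(rods)
        self.config = config if config is not None else SimConfig()
        self.colliders = list(colliders)
        self.scripts = list(scripts)
        self.t = 0.0
        n = particles.count
        self.radii = np.zeros(n)
        self.rod_ids = np.full(n, -1, dtype=np.int64)
        self.chain_positions = np.zeros(n, dtype=np.int64)
        for ri, rod in enumerate(self.rods):
            sl = slice(rod.particle_start, rod.particle_start + rod.particle_count)
            self.radii[sl] = rod.radius
            self.rod_ids[sl] = ri
            self.chain_positions[sl] = np.arange(rod.particle_count)

    # -- array accessors -------------------------------------------------
    @property
    def x(self) -> np.ndarray:
        return self.particles.positions

    @property
    def v(self) -> np.ndarray:
        return self.particles.velocities

    @property
    def winv(self) -> np.ndarray:
        return self.particles.inverse_masses

    @property
    def q(self) -> np.ndarray:
        return self.orientations.quaternions

    @property
    def omega(self) -> np.ndarray:
        return self.orientations.angular_velocities

    @property
    def winv_q(self) -> np.ndarray:
        return self.orientations.inverse_inertias

    @classmethod
    def from_rods(
        cls,
        rod_states: Sequence[tuple[Rod, ParticleState, OrientationState]],
        config: SimConfig | None = None,
        colliders: Sequence = (),
        scripts: Sequence[Callable[["World", float], None]] = (),
    ) -> "World":
        """Merge standalone (rod, particles, orientations) triples into one
        world with global state arrays and per-rod offsets."""
        rods = []
        xs, vs, ws, qs, oms, wqs = [], [], [], [], [], []
        p_off = e_off = 0
        for rod, ps, os_ in rod_states:
            rods.append(rod.with_offsets(p_off, e_off))
            xs.append(ps.positions)
            vs.append(ps.velocities)
            ws.append(ps.inverse_masses)
            qs.append(os_.quaternions)
            oms.append(os_.angular_velocities)
            wqs.append(os_.inverse_inertias)
            p_off += ps.count
            e_off += os_.count
        particles = ParticleState(
            np.concatenate(xs), np.concatenate(vs), np.concatenate(ws)
        )
        orientations = OrientationState(
            np.concatenate(qs), np.concatenate(oms), np.concatenate(wqs)
        )
        return cls(particles, orientations, rods, config, colliders, scripts)

    def rod_slices(self, rod: Rod) -> tuple[slice, slice]:
        return (
            slice(rod.particle_start, rod.particle_start + rod.particle_count),
            slice(rod.element_start, rod.element_start + rod.element_count),
        )


def predict_state(world: World, config: SimConfig | None = None) -> None:
    """Explicit (symplectic) Euler prediction, in place.

    ``v ← v + Δt W F_ext`` then ``x ← x + Δt v``; quaternions advance by
    ``q ← normalize(q + (Δt/2)(0, ω) ⊗ q)``.  Fixed variables (zero inverse
    mass/inertia) are left untouched.  External torque is zero for threads.
    """
    cfg = config if config is not None else world.config
    dt = cfg.dt
    free = world.winv > 0
    world.v[free] += dt * cfg.gravity
    world.x[free] += dt * world.v[free]
    freeq = world.winv_q > 0
    if np.any(freeq):
        om = world.omega[freeq]
        omq = np.concatenate([np.zeros((om.shape[0], 1)), om], axis=1)
        qn = world.q[freeq] + 0.5 * dt * quat.multiply(omq, world.q[freeq])
        world.q[freeq] = quat.normalize(qn)


def detect_contacts(
    world: World, x_begin: np.ndarray, config: SimConfig
) -> list[Contact]:
    """Continuous collision detection between the pre-step and predicted
    states, plus signed-distance contacts against static colliders."""
    if not config.collision_enabled:
        return []
    cell = config.cell_size
    if cell is None:
        rmax = float(world.radii.max()) if world.radii.size else 0.0
        if rmax <= 0.0:
            return []
        cell = 4.0 * rmax  # 2× sphere diameter
    cands = broad_phase(
        x_begin,
        world.x,
        world.radii,
        cell,
        rod_ids=world.rod_ids,
        chain_positions=world.chain_positions,
    )
    contacts = narrow_phase(cands, x_begin, world.x, world.radii, config.friction_k)
    contacts += static_contacts(
        world.colliders, world.x, world.radii, config.friction_k, x_begin=x_begin
    )
    return contacts


def project_constraints(
    world: World,
    contacts: list[Contact] | None = None,
    config: SimConfig | None = None,
) -> None:
    """Fixed-count Gauss–Seidel projection of all constraint families.

    Order per iteration: shear–stretch, bend–twist, contacts, friction, then
    the direct distance solve (when enabled) so segment lengths are exact at
    the end of every iteration.  Fixed variables never move; a sub-system with
    no free variables is skipped rather than fatal.
    """
    cfg = config if config is not None else world.config
    packed = pack_contacts(contacts) if contacts else None
    for _ in range(cfg.iterations):
        for rod in world.rods:
            psl, esl = world.rod_slices(rod)
            x = world.x[psl]
            q = world.q[esl]
            shear_stretch_pass(
                x, q, world.winv[psl], world.winv_q[esl],
                rod.rest_length, rod.stiffness_stretch,
            )
            if rod.element_count > 1:
                bend_twist_pass(
                    q, world.winv_q[esl], rod.rest_relative,
                    rod.stiffness_bend, rod.stiffness_twist,
                )
        if packed is not None:
            ia, ib, anchor, normal, dsep, kf = packed
            contact_pass(world.x, world.winv, ia, ib, anchor, normal, dsep)
            friction_pass(
                world.x, world.winv, ia, ib, anchor, normal, dsep, kf,
                FRICTION_ACTIVE_GAP,
            )
        if cfg.use_ddc:
            for rod in world.rods:
                psl, _ = world.rod_slices(rod)
                project_ddc_inplace(world.x[psl], world.winv[psl], rod.rest_length)


def update_velocities(
    world: World, x_begin: np.ndarray, q_begin: np.ndarray, dt: float
) -> None:
    """``v = Δx/Δt``; ``ω = 2 ℑ(q_new q̄_old)/Δt`` (small-angle form), signed
    so that predict ∘ update is idempotent on constraint-free motion."""
    world.v[:] = (world.x - x_begin) / dt
    rel = quat.multiply(world.q, quat.conjugate(q_begin))
    world.omega[:] = 2.0 * quat.imaginary(rel) / dt


def apply_damping(
    velocities: np.ndarray,
    angular_velocities: np.ndarray,
    d_v: float,
    d_a: float,
    dt: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Time-step-independent damping: the factors are the fraction of the
    corresponding velocity dissipated per second, so the per-step decay is
    ``(1 − d)^Δt``."""
    if not (0.0 <= d_v <= 1.0 and 0.0 <= d_a <= 1.0):
        raise ValueError("damping factors must lie in [0, 1]")
    fv = (1.0 - d_v) ** dt
    fa = (1.0 - d_a) ** dt
    return velocities * fv, angular_velocities * fa


def compute_residuals(world: World, contacts: list[Contact] | None = None) -> dict:
    """Max constraint-violation magnitudes per family (diagnostics)."""
    res = {"shear_stretch": 0.0, "bend_twist": 0.0, "distance": 0.0, "contact": 0.0}
    e3 = np.array([0.0, 0.0, 1.0])
    for rod in world.rods:
        psl, esl = world.rod_slices(rod)
        x = world.x[psl]
        q = world.q[esl]
        cs = np.diff(x, axis=0) / rod.rest_length - quat.rotate(q, e3)
        res["shear_stretch"] = max(res["shear_stretch"], float(np.abs(cs).max()))
        if rod.element_count > 1:
            rel = quat.multiply(quat.conjugate(q[:-1]), q[1:])
            sign = np.where(np.sum(rel * rod.rest_relative, axis=1) < 0, -1.0, 1.0)
            cb = quat.imaginary(sign[:, None] * rel - rod.rest_relative)
            res["bend_twist"] = max(res["bend_twist"], float(np.abs(cb).max()))
        cdist = distance_constraint_values(x, rod.rest_length)
        res["distance"] = max(res["distance"], float(np.abs(cdist).max()))
    if contacts:
        for ct in contacts:
            pb = world.x[ct.id_b] if ct.id_b >= 0 else ct.anchor
            gap = float((world.x[ct.id_a] - pb) @ ct.normal - ct.separation)
            res["contact"] = max(res["contact"], max(0.0, -gap))
    return res


def step(
    world: World, config: SimConfig | None = None, compute_report: bool = True
) -> StepReport:
    """Advance the world by one time step.

    Deterministic given identical inputs: predict → continuous collision
    detection → constraint projection → velocity update → damping.
    """
    cfg = config if config is not None else world.config
    dt = cfg.dt
    t_next = world.t + dt
    x_begin = world.x.copy()
    q_begin = world.q.copy()
    for script in world.scripts:
        script(world, t_next)
    predict_state(world, cfg)
    contacts = detect_contacts(world, x_begin, cfg)
    project_constraints(world, contacts, cfg)
    update_velocities(world, x_begin, q_begin, dt)
    for rod in world.rods:
        psl, esl = world.rod_slices(rod)
        world.v[psl], world.omega[esl] = apply_damping(
            world.v[psl], world.omega[esl],
            rod.damping_linear, rod.damping_angular, dt,
        )
    world.t = t_next
    if compute_report:
        residuals = compute_residuals(world, contacts)
    else:
        residuals = {}
    return StepReport(
        iterations=cfg.iterations,
        residuals=residuals,
        contacts=len(contacts),
        time=world.t,
    )
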