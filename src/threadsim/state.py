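"""Discrete rod state: particles, element orientations, rod topology.

A surgical thread is discretized as a chain of centerline particles.  Each
consecutive particle pair bounds one *rod element* carrying an orientation
quaternion (the material frame).  The rest configuration stores, per element,
the quaternion that rotates the reference tangent ``e3 = (0, 0, 1)`` onto the
rest segment direction, and per adjacent element pair the rest relative
quaternion ``q̄⁰ u⁰`` whose imaginary part is the (scaled) rest Darboux vector.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import brentq

from . import quaternion as quat
from .errors import (
    DegenerateGeometryError,
    DiscretizationError,
    InvalidTopologyError,
)

__all__ = [
    "ParticleState",
    "OrientationState",
    "Rod",
    "SimConfig",
    "build_rod",
    "make_spiral_centerline",
    "conform_to_centerline",
]

E3 = np.array([0.0, 0.0, 1.0])


@dataclass
class ParticleState:
    """Centerline nodes: positions (m), velocities (m/s), inverse masses.

    An inverse mass of exactly 0 marks a fixed or instrument-held particle.
    """

    positions: np.ndarray
    velocities: np.ndarray
    inverse_masses: np.ndarray

    def __post_init__(self) -> None:
        self.positions = np.atleast_2d(np.asarray(self.positions, dtype=float))
        self.velocities = np.atleast_2d(np.asarray(self.velocities, dtype=float))
        self.inverse_masses = np.asarray(self.inverse_masses, dtype=float).ravel()
        n = self.positions.shape[0]
        if self.velocities.shape != (n, 3) or self.positions.shape != (n, 3):
            raise ValueError("positions and velocities must both be (n, 3)")
        if self.inverse_masses.shape != (n,):
            raise ValueError("inverse_masses must have one entry per particle")
        if np.any(self.inverse_masses < 0):
            raise ValueError("inverse masses must be nonnegative")

    @property
    def count(self) -> int:
        return self.positions.shape[0]


@dataclass
class OrientationState:
    """Rod-element material frames: unit quaternions (scalar-first),
    angular velocities (rad/s) and scalar inverse inertias."""

    quaternions: np.ndarray
    angular_velocities: np.ndarray
    inverse_inertias: np.ndarray

    def __post_init__(self) -> None:
        self.quaternions = np.atleast_2d(np.asarray(self.quaternions, dtype=float))
        self.angular_velocities = np.atleast_2d(
            np.asarray(self.angular_velocities, dtype=float)
        )
        self.inverse_inertias = np.asarray(self.inverse_inertias, dtype=float).ravel()
        k = self.quaternions.shape[0]
        if self.quaternions.shape != (k, 4):
            raise ValueError("quaternions must be (k, 4) scalar-first")
        if self.angular_velocities.shape != (k, 3):
            raise ValueError("angular_velocities must be (k, 3)")
        if self.inverse_inertias.shape != (k,):
            raise ValueError("inverse_inertias must have one entry per element")
        if np.any(self.inverse_inertias < 0):
            raise ValueError("inverse inertias must be nonnegative")

    @property
    def count(self) -> int:
        return self.quaternions.shape[0]


@dataclass
class Rod:
    """Topology and material parameters of one discretized thread.

    ``particle_start``/``element_start`` locate this rod's slices inside the
    global state arrays of a :class:`~threadsim.solver.World`; a standalone rod
    has both equal to 0.
    """

    element_count: int
    rest_length: float  # per-element rest length d (m); defaults to 2·radius
    radius: float  # collision-sphere / half-thickness radius r (m)
    rest_quaternions: np.ndarray  # (k, 4) rest material frames
    rest_relative: np.ndarray  # (k-1, 4) rest products q̄⁰ᵢ u⁰ᵢ₊₁
    stiffness_bend: float = 0.05
    stiffness_twist: float = 0.25
    stiffness_stretch: float = 1.0
    damping_linear: float = 0.1
    damping_angular: float = 0.1
    particle_start: int = 0
    element_start: int = 0
    name: str = "rod"

    def __post_init__(self) -> None:
        if self.element_count < 1:
            raise InvalidTopologyError("a rod needs at least one element")
        if self.rest_length <= 0 or self.radius <= 0:
            raise ValueError("rest_length and radius must be positive")
        for attr in ("stiffness_bend", "stiffness_twist", "stiffness_stretch"):
            v = getattr(self, attr)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{attr} must lie in [0, 1]")
        for attr in ("damping_linear", "damping_angular"):
            v = getattr(self, attr)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{attr} must lie in [0, 1]")

    @property
    def particle_count(self) -> int:
        return self.element_count + 1

    @property
    def particle_indices(self) -> np.ndarray:
        """Global indices of this rod's particles, in chain order."""
        return np.arange(self.particle_start, self.particle_start + self.particle_count)

    @property
    def total_rest_length(self) -> float:
        return self.element_count * self.rest_length

    def with_offsets(self, particle_start: int, element_start: int) -> "Rod":
        return replace(self, particle_start=particle_start, element_start=element_start)


@dataclass
class SimConfig:
    """Global solver settings.

    dt is the simulation time step in seconds; ``iterations`` the fixed
    Gauss–Seidel constraint-projection count per step.  ``use_ddc`` toggles the
    direct tridiagonal distance solve that runs in every projection iteration.
    """

    dt: float = 1.0 / 60.0
    iterations: int = 10
    use_ddc: bool = True
    gravity: np.ndarray = field(default_factory=lambda: np.array([0.0, -9.81, 0.0]))
    friction_k: float = 0.5
    cell_size: float | None = None  # None → 2× largest sphere diameter
    seed: int = 0
    collision_enabled: bool = True

    def __post_init__(self) -> None:
        self.gravity = np.asarray(self.gravity, dtype=float).reshape(3)
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        if not 0.0 <= self.friction_k <= 1.0:
            raise ValueError("friction_k must lie in [0, 1]")
        if self.cell_size is not None and self.cell_size <= 0:
            raise ValueError("cell_size must be positive")


def build_rod(
    centerline_points: np.ndarray,
    radius: float,
    *,
    stiffness_bend: float = 0.05,
    stiffness_twist: float = 0.25,
    stiffness_stretch: float = 1.0,
    damping_linear: float = 0.1,
    damping_angular: float = 0.1,
    mass: float = 1.0,
    inertia: float | None = None,
    name: str = "rod",
    uniformity_tol: float = 0.01,
) -> tuple[Rod, ParticleState, OrientationState]:
    """Discretize a centerline polyline into connected rod elements.

    Each consecutive point pair becomes one element whose rest quaternion is
    the shortest-arc rotation taking ``e3`` onto the unit segment direction.
    Segment lengths must be uniform within ``uniformity_tol`` (relative), since
    the discrete model assumes fixed-length rod segments.  Velocities start at
    zero; every particle gets mass ``mass`` and every element a scalar
    (isotropic) inertia, by default ``500 · mass · d²`` — deliberately heavy
    relative to the slender-rod scale so the orientation field carries its own
    slow dynamics (bending stiffness and angular damping then control shape
    evolution; see the methods note).
    """
    pts = np.atleast_2d(np.asarray(centerline_points, dtype=float))
    if pts.ndim != 2 or pts.shape[1] != 3 or pts.shape[0] < 2:
        raise InvalidTopologyError("need at least 2 centerline points of dimension 3")
    segs = np.diff(pts, axis=0)
    lengths = np.linalg.norm(segs, axis=1)
    if np.any(lengths < 1e-12):
        raise DegenerateGeometryError("centerline contains a zero-length segment")
    d = float(lengths.mean())
    if np.max(np.abs(lengths - d)) > uniformity_tol * d:
        raise DiscretizationError(
            "segment lengths deviate more than "
            f"{uniformity_tol:.0%} from uniform (d = {d:.3e} m)"
        )
    dirs = segs / lengths[:, None]
    k = pts.shape[0] - 1
    q0 = np.empty((k, 4))
    for i in range(k):
        q0[i] = quat.from_two_vectors(E3, dirs[i])
    rest_rel = quat.multiply(quat.conjugate(q0[:-1]), q0[1:]) if k > 1 else np.empty((0, 4))
    rod = Rod(
        element_count=k,
        rest_length=d,
        radius=float(radius),
        rest_quaternions=q0,
        rest_relative=rest_rel,
        stiffness_bend=stiffness_bend,
        stiffness_twist=stiffness_twist,
        stiffness_stretch=stiffness_stretch,
        damping_linear=damping_linear,
        damping_angular=damping_angular,
        name=name,
    )
    particles = ParticleState(
        positions=pts.copy(),
        velocities=np.zeros_like(pts),
        inverse_masses=np.full(pts.shape[0], 1.0 / mass),
    )
    if inertia is None:
        inertia = 500.0 * mass * d * d
    orientations = OrientationState(
        quaternions=q0.copy(),
        angular_velocities=np.zeros((k, 3)),
        inverse_inertias=np.full(k, 1.0 / inertia),
    )
    return rod, particles, orientations


def make_spiral_centerline(
    total_length: float,
    n_elements: int,
    helix_radius: float,
    pitch: float,
    *,
    axis: np.ndarray = (0.0, 0.0, 1.0),
    origin: np.ndarray = (0.0, 0.0, 0.0),
) -> np.ndarray:
    """Uniformly spaced points on a helix with exact polyline length.

    ``pitch`` is the axial advance per full turn (m).  ``helix_radius = 0``
    degenerates to a straight line along ``axis``.  The returned polyline has
    ``n_elements + 1`` points, constant consecutive spacing, and total length
    equal to ``total_length`` to within floating-point error.
    """
    if total_length <= 0:
        raise ValueError("total_length must be positive")
    if n_elements < 2:
        raise InvalidTopologyError("need at least 2 elements")
    r = float(helix_radius)
    c = float(pitch) / (2.0 * np.pi)  # axial rise per radian
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    origin = np.asarray(origin, dtype=float)
    seg = total_length / n_elements

    if r == 0.0 and c == 0.0:
        raise DegenerateGeometryError("helix_radius and pitch cannot both be zero")
    if r == 0.0:
        ts = np.arange(n_elements + 1) * seg
        pts_local = np.zeros((n_elements + 1, 3))
        pts_local[:, 2] = ts
    else:
        def chord(dth: float) -> float:
            return 2.0 * np.hypot(r * np.sin(dth / 2.0), c * dth / 2.0)

        hi = np.pi
        while chord(hi) < seg:
            hi *= 2.0
            if hi > 1e6:
                raise DegenerateGeometryError("cannot fit requested segment length")
        dth = brentq(lambda t: chord(t) - seg, 1e-15, hi, xtol=1e-15, rtol=1e-15)
        th = np.arange(n_elements + 1) * dth
        pts_local = np.column_stack([r * np.cos(th) - r, r * np.sin(th), c * th])

    rot = quat.from_two_vectors(E3, axis)
    return origin + quat.rotate(rot, pts_local)


def conform_to_centerline(
    rod: Rod,
    particles: ParticleState,
    orientations: OrientationState,
    points: np.ndarray,
) -> None:
    """Move a built rod into a new shape without touching its rest state.

    Positions are set to ``points`` and each element quaternion to the
    shortest-arc frame aligning ``e3`` with the new segment direction, so the
    shear–stretch constraint is satisfied in the new pose while bend–twist
    strain is measured against the original rest configuration.  Used to pose
    a straight-rest thread into an arc, coil or pre-formed knot.
    """
    pts = np.asarray(points, dtype=float)
    if pts.shape != (rod.particle_count, 3):
        raise InvalidTopologyError("points must match the rod's particle count")
    segs = np.diff(pts, axis=0)
    lengths = np.linalg.norm(segs, axis=1)
    if np.any(lengths < 1e-12):
        raise DegenerateGeometryError("zero-length segment in new centerline")
    sl = slice(rod.particle_start, rod.particle_start + rod.particle_count)
    el = slice(rod.element_start, rod.element_start + rod.element_count)
    particles.positions[sl] = pts
    dirs = segs / lengths[:, None]
    qs = np.empty((rod.element_count, 4))
    for i in range(rod.element_count):
        qs[i] = quat.from_two_vectors(E3, dirs[i])
    orientations.quaternions[el] = qs
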