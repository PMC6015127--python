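"""Continuous sphere–sphere collision detection and position-level response.

The thread is discretized as closely packed spheres (one per centerline node,
radius = half the thread thickness).  A step's collision pipeline is:

* wide phase — swept AABBs hashed into a uniform grid; only same-cell pairs
  are candidates,
* middle phase — swept AABB overlap test,
* narrow phase — earliest time of impact of the two moving spheres (a single
  quadratic per pair),
* response — position-level contact and friction constraints projected during
  the remaining solver iterations of the step.

Adjacent and next-adjacent spheres of the same rod permanently overlap by
construction (segment length equals the thickness) and are excluded.
Static rigid colliders (plane, sphere, cylinder) enter through signed-distance
queries that produce the same :class:`Contact` type with an infinite-mass
anchor point.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np

from ._kernels import contact_pass, friction_pass
from .errors import DegenerateGeometryError

__all__ = [
    "Contact",
    "HashGrid",
    "sphere_sphere_toi",
    "swept_aabb",
    "broad_phase",
    "narrow_phase",
    "static_contacts",
    "contact_constraint",
    "friction_constraint",
    "narrow_phase_and_respond",
    "pack_contacts",
    "PlaneCollider",
    "SphereCollider",
    "CylinderCollider",
]

# friction activates while the contact gap is within this distance of touching
FRICTION_ACTIVE_GAP = 1e-9


@dataclass
class Contact:
    """A detected collision pair.

    ``id_b < 0`` marks a static collider; the counterpart is then the fixed
    ``anchor`` point (infinite mass).  ``normal`` is the unit contact normal
    at the time of impact, ``separation`` the target distance along it (sum of
    radii), ``toi`` the impact time within the step in [0, 1].
    """

    id_a: int
    id_b: int
    normal: np.ndarray
    separation: float
    toi: float
    friction_k: float
    anchor: np.ndarray = field(default_factory=lambda: np.zeros(3))


def sphere_sphere_toi(x_a, x_a_pred, x_b, x_b_pred, r_a, r_b):
    """Earliest t in [0, 1] at which the moving spheres first touch.

    Solves the single quadratic ``‖d0 + t Δ‖ = r_a + r_b``.  Returns ``None``
    on a miss; returns 0.0 when the spheres already overlap at t = 0.
    """
    x_a = np.asarray(x_a, dtype=float)
    x_b = np.asarray(x_b, dtype=float)
    d0 = x_a - x_b
    dv = (np.asarray(x_a_pred, dtype=float) - x_a) - (
        np.asarray(x_b_pred, dtype=float) - x_b
    )
    rsum = r_a + r_b
    c = float(d0 @ d0) - rsum * rsum
    if c <= 0.0:
        return 0.0
    a = float(dv @ dv)
    if a < 1e-20:
        return None
    b = 2.0 * float(d0 @ dv)
    disc = b * b - 4.0 * a * c
    if disc < 0.0:
        return None
    t = (-b - np.sqrt(disc)) / (2.0 * a)
    if 0.0 <= t <= 1.0:
        return float(t)
    return None


def swept_aabb(x, x_pred, r):
    """Axis-aligned box covering the whole swept sphere: min/max over both
    endpoints expanded by the radius."""
    if r <= 0:
        raise ValueError("radius must be positive")
    x = np.asarray(x, dtype=float)
    x_pred = np.asarray(x_pred, dtype=float)
    lo = np.minimum(x, x_pred) - r
    hi = np.maximum(x, x_pred) + r
    return lo, hi


class HashGrid:
    """Uniform spatial hash: each primitive is inserted into every cell its
    swept AABB overlaps; only same-cell pairs become candidates."""

    def __init__(self, cell_size: float):
        if cell_size <= 0:
            raise ValueError("cell_size must be positive")
        self.cell_size = float(cell_size)
        self.table: dict[tuple[int, int, int], list[int]] = {}

    def insert(self, pid: int, lo: np.ndarray, hi: np.ndarray) -> None:
        cs = self.cell_size
        i0, j0, k0 = (int(np.floor(v / cs)) for v in lo)
        i1, j1, k1 = (int(np.floor(v / cs)) for v in hi)
        n_cells = (i1 - i0 + 1) * (j1 - j0 + 1) * (k1 - k0 + 1)
        if n_cells > 65536:
            raise DegenerateGeometryError(
                f"swept AABB of primitive {pid} spans {n_cells} hash cells; "
                "state has likely diverged or cell_size is far too small"
            )
        for i in range(i0, i1 + 1):
            for j in range(j0, j1 + 1):
                for k in range(k0, k1 + 1):
                    self.table.setdefault((i, j, k), []).append(pid)

    def candidate_pairs(self) -> list[tuple[int, int]]:
        pairs: set[tuple[int, int]] = set()
        for ids in self.table.values():
            if len(ids) > 1:
                for a, b in combinations(ids, 2):
                    pairs.add((a, b) if a < b else (b, a))
        return sorted(pairs)


def broad_phase(
    x: np.ndarray,
    x_pred: np.ndarray,
    radii: np.ndarray,
    cell_size: float,
    rod_ids: np.ndarray | None = None,
    chain_positions: np.ndarray | None = None,
    neighbor_exclusion: int = 2,
) -> list[tuple[int, int]]:
    """Candidate pairs whose swept AABBs share a hash cell and overlap.

    A superset of all truly AABB-overlapping pairs, deterministically sorted.
    Pairs on the same rod within ``neighbor_exclusion`` chain positions are
    excluded (closely packed neighbours permanently overlap by construction).
    """
    x = np.asarray(x, dtype=float)
    x_pred = np.asarray(x_pred, dtype=float)
    radii = np.asarray(radii, dtype=float)
    n = x.shape[0]
    lo = np.minimum(x, x_pred) - radii[:, None]
    hi = np.maximum(x, x_pred) + radii[:, None]
    grid = HashGrid(cell_size)
    for i in range(n):
        grid.insert(i, lo[i], hi[i])
    out = []
    for a, b in grid.candidate_pairs():
        if rod_ids is not None and rod_ids[a] == rod_ids[b]:
            if abs(int(chain_positions[a]) - int(chain_positions[b])) <= neighbor_exclusion:
                continue
        if np.all(lo[a] <= hi[b]) and np.all(lo[b] <= hi[a]):
            out.append((a, b))
    return out


def contact_constraint(p1, p2, normal, d) -> float:
    """``C_c = (p1 − p2)·normal − d``; projection only acts when negative."""
    normal = np.asarray(normal, dtype=float)
    return float((np.asarray(p1, dtype=float) - np.asarray(p2, dtype=float)) @ normal - d)


def friction_constraint(p1, p2, normal, k) -> float:
    """``C_f = k ‖(p1 − p2)/‖p1 − p2‖ × normal‖``: zero when the pair offset
    is parallel to the collision-time normal."""
    diff = np.asarray(p1, dtype=float) - np.asarray(p2, dtype=float)
    n = np.linalg.norm(diff)
    if n < 1e-14:
        raise DegenerateGeometryError("coincident contact points")
    return float(k * np.linalg.norm(np.cross(diff / n, np.asarray(normal, dtype=float))))


def narrow_phase(
    candidates,
    x: np.ndarray,
    x_pred: np.ndarray,
    radii: np.ndarray,
    friction_k: float,
) -> list[Contact]:
    """Run the continuous sphere–sphere test on each candidate pair and build
    contacts with the normal taken at the time of impact."""
    contacts: list[Contact] = []
    x = np.asarray(x, dtype=float)
    x_pred = np.asarray(x_pred, dtype=float)
    for a, b in candidates:
        toi = sphere_sphere_toi(x[a], x_pred[a], x[b], x_pred[b], radii[a], radii[b])
        if toi is None:
            continue
        pa = x[a] + toi * (x_pred[a] - x[a])
        pb = x[b] + toi * (x_pred[b] - x[b])
        diff = pa - pb
        nrm = np.linalg.norm(diff)
        normal = diff / nrm if nrm > 1e-12 else np.array([1.0, 0.0, 0.0])
        contacts.append(
            Contact(
                id_a=int(a),
                id_b=int(b),
                normal=normal,
                separation=float(radii[a] + radii[b]),
                toi=float(toi),
                friction_k=float(friction_k),
            )
        )
    return contacts


class PlaneCollider:
    """Static half-space ``{p : p·normal ≥ offset}`` boundary."""

    def __init__(self, normal, offset: float, friction_k: float | None = None):
        self.normal = np.asarray(normal, dtype=float)
        self.normal = self.normal / np.linalg.norm(self.normal)
        self.offset = float(offset)
        self.friction_k = friction_k

    def signed_distance(self, p: np.ndarray):
        p = np.atleast_2d(np.asarray(p, dtype=float))
        sd = p @ self.normal - self.offset
        normals = np.broadcast_to(self.normal, p.shape).copy()
        return sd, normals


class SphereCollider:
    """Static rigid sphere."""

    def __init__(self, center, radius: float, friction_k: float | None = None):
        self.center = np.asarray(center, dtype=float)
        if radius <= 0:
            raise ValueError("radius must be positive")
        self.radius = float(radius)
        self.friction_k = friction_k

    def signed_distance(self, p: np.ndarray):
        p = np.atleast_2d(np.asarray(p, dtype=float))
        diff = p - self.center
        dist = np.linalg.norm(diff, axis=1)
        safe = np.maximum(dist, 1e-12)
        return dist - self.radius, diff / safe[:, None]


class CylinderCollider:
    """Static rigid cylinder of infinite extent along ``axis``."""

    def __init__(self, point, axis, radius: float, friction_k: float | None = None):
        self.point = np.asarray(point, dtype=float)
        self.axis = np.asarray(axis, dtype=float)
        self.axis = self.axis / np.linalg.norm(self.axis)
        if radius <= 0:
            raise ValueError("radius must be positive")
        self.radius = float(radius)
        self.friction_k = friction_k

    def signed_distance(self, p: np.ndarray):
        p = np.atleast_2d(np.asarray(p, dtype=float))
        rel = p - self.point
        axial = rel @ self.axis
        radial = rel - axial[:, None] * self.axis
        dist = np.linalg.norm(radial, axis=1)
        safe = np.maximum(dist, 1e-12)
        return dist - self.radius, radial / safe[:, None]


def static_contacts(
    colliders,
    x_pred: np.ndarray,
    radii: np.ndarray,
    friction_k: float,
    proximity: float = 1.05,
    x_begin: np.ndarray | None = None,
) -> list[Contact]:
    """Contacts of particles against static rigid colliders.

    A contact is generated when the signed distance at the predicted position
    falls below ``proximity × r``.  The anchor is the surface projection of the
    particle's *pre-step* position (when given): friction then measures — and
    can cancel — the tangential motion accumulated during the step, which is
    what makes a k = 1 contact stick instead of creeping.
    """
    contacts: list[Contact] = []
    x_pred = np.asarray(x_pred, dtype=float)
    x_ref = x_pred if x_begin is None else np.asarray(x_begin, dtype=float)
    for ci, col in enumerate(colliders):
        sd, normals = col.signed_distance(x_pred)
        sd_ref, normals_ref = col.signed_distance(x_ref)
        k = col.friction_k if col.friction_k is not None else friction_k
        for i in np.nonzero(sd < proximity * radii)[0]:
            anchor = x_ref[i] - sd_ref[i] * normals_ref[i]
            contacts.append(
                Contact(
                    id_a=int(i),
                    id_b=-1 - ci,
                    normal=normals_ref[i].copy(),
                    separation=float(radii[i]),
                    toi=0.0,
                    friction_k=float(k),
                    anchor=anchor,
                )
            )
    return contacts


def pack_contacts(contacts: list[Contact]):
    """Flatten contacts into the arrays the compiled passes consume."""
    m = len(contacts)
    ia = np.empty(m, dtype=np.int64)
    ib = np.empty(m, dtype=np.int64)
    anchor = np.zeros((m, 3))
    normal = np.empty((m, 3))
    dsep = np.empty(m)
    kf = np.empty(m)
    for c, ct in enumerate(contacts):
        ia[c] = ct.id_a
        ib[c] = ct.id_b
        anchor[c] = ct.anchor
        normal[c] = ct.normal
        dsep[c] = ct.separation
        kf[c] = ct.friction_k
    return ia, ib, anchor, normal, dsep, kf


def narrow_phase_and_respond(
    candidates,
    x: np.ndarray,
    x_pred: np.ndarray,
    radii: np.ndarray,
    inverse_masses: np.ndarray,
    friction_k: float,
    iterations: int = 10,
) -> tuple[list[Contact], np.ndarray]:
    """Detect contacts on the candidates and project the contact + friction
    constraints for ``iterations`` sweeps on a copy of the predicted state.

    Standalone entry point mirroring the step pipeline's collision handling;
    the full solver interleaves the same passes with the rod constraints.
    """
    contacts = narrow_phase(candidates, x, x_pred, radii, friction_k)
    corrected = np.array(x_pred, dtype=float)
    if contacts:
        ia, ib, anchor, normal, dsep, kf = pack_contacts(contacts)
        w = np.asarray(inverse_masses, dtype=float)
        for _ in range(iterations):
            contact_pass(corrected, w, ia, ib, anchor, normal, dsep)
            friction_pass(
                corrected, w, ia, ib, anchor, normal, dsep, kf, FRICTION_ACTIVE_GAP
            )
    return contacts, corrected
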