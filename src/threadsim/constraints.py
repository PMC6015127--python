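"""Cosserat constraint functions and their Jacobians.

Two vector-valued constraints model the thread's elasticity:

* shear–stretch: ``C_s(p1, p2, q) = (p2 − p1)/l − R(q) e3`` couples the
  segment vector to the element frame's tangent director.  It vanishes when
  the segment has rest length *and* lies along ``d3``.
* bend–twist: ``C_b(q, u) = ℑ(q̄ u − q̄⁰ u⁰)`` measures the deviation of the
  discrete Darboux vector (imaginary part of the relative quaternion between
  adjacent frames) from its rest value.  Its first two components are bending
  strain, the third is twist about the tangent.

Quaternion degrees of freedom are differentiated as 4 raw components; the
solver renormalizes after every correction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import quaternion as quat
from .errors import InvalidOrientationError

__all__ = [
    "ConstraintEval",
    "shear_stretch_constraint",
    "bend_twist_constraint",
    "shear_stretch_jacobian",
    "bend_twist_jacobian",
    "distance_jacobian",
    "constraint_jacobian",
]

_UNIT_TOL = 1e-6


def _check_unit(*qs: np.ndarray) -> None:
    for q in qs:
        if abs(np.linalg.norm(q) - 1.0) > _UNIT_TOL:
            raise InvalidOrientationError(
                f"quaternion norm {np.linalg.norm(q):.8f} deviates from 1"
            )


@dataclass
class ConstraintEval:
    """Constraint value with its Jacobian blocks.

    ``jacobian_blocks`` maps a state-variable id (e.g. ``"p1"``, ``"q"``) to
    the ``(dim × dof)`` block of ∂C/∂variable; variables the constraint does
    not touch are simply absent.
    """

    value: np.ndarray
    jacobian_blocks: dict[str, np.ndarray] = field(default_factory=dict)
    stiffness: float = 1.0


def shear_stretch_constraint(
    p1: np.ndarray, p2: np.ndarray, q: np.ndarray, l: float
) -> np.ndarray:
    """``(1/l)(p2 − p1) − R(q) e3``; zero at the rest configuration."""
    if l <= 0:
        raise ValueError("element rest length l must be positive")
    _check_unit(q)
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    # homogeneous form: polynomial in the raw quaternion components, so the
    # analytic Jacobian matches raw-component finite differences
    d3 = quat.to_matrix(q) @ np.array([0.0, 0.0, 1.0])
    return (p2 - p1) / l - d3


def bend_twist_constraint(
    q: np.ndarray, u: np.ndarray, q0: np.ndarray, u0: np.ndarray
) -> np.ndarray:
    """``ℑ(q̄ u − q̄⁰ u⁰)`` for adjacent element frames (q, u)."""
    _check_unit(q, u, q0, u0)
    rel = quat.multiply(quat.conjugate(q), u)
    rel0 = quat.multiply(quat.conjugate(q0), u0)
    return quat.imaginary(rel - rel0)


def _skew(v: np.ndarray) -> np.ndarray:
    x, y, z = v
    return np.array([[0.0, -z, y], [z, 0.0, -x], [-y, x, 0.0]])


def _d3_jacobian(q: np.ndarray) -> np.ndarray:
    """∂(R(q) e3)/∂q for the homogeneous rotation form, shape (3, 4)."""
    w, x, y, z = q
    return 2.0 * np.array(
        [
            [y, z, w, x],
            [-x, -w, z, y],
            [w, -x, -y, z],
        ]
    )


def shear_stretch_jacobian(
    p1: np.ndarray, p2: np.ndarray, q: np.ndarray, l: float, stiffness: float = 1.0
) -> ConstraintEval:
    value = shear_stretch_constraint(p1, p2, q, l)
    eye = np.eye(3)
    return ConstraintEval(
        value=value,
        jacobian_blocks={
            "p1": -eye / l,
            "p2": eye / l,
            "q": -_d3_jacobian(np.asarray(q, dtype=float)),
        },
        stiffness=stiffness,
    )


def bend_twist_jacobian(
    q: np.ndarray,
    u: np.ndarray,
    q0: np.ndarray,
    u0: np.ndarray,
    stiffness: float = 1.0,
) -> ConstraintEval:
    value = bend_twist_constraint(q, u, q0, u0)
    q = np.asarray(q, dtype=float)
    u = np.asarray(u, dtype=float)
    qw, qv = q[0], q[1:]
    uw, uv = u[0], u[1:]
    jq = np.empty((3, 4))
    jq[:, 0] = uv
    jq[:, 1:] = -uw * np.eye(3) + _skew(uv)
    ju = np.empty((3, 4))
    ju[:, 0] = -qv
    ju[:, 1:] = qw * np.eye(3) - _skew(qv)
    return ConstraintEval(
        value=value, jacobian_blocks={"q": jq, "u": ju}, stiffness=stiffness
    )


def distance_jacobian(p1: np.ndarray, p2: np.ndarray, d: float) -> ConstraintEval:
    """Scalar chain distance constraint ``‖p1 − p2‖ − d`` with gradient ±n."""
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    diff = p1 - p2
    norm = np.linalg.norm(diff)
    if norm < 1e-12:
        from .errors import DegenerateGeometryError

        raise DegenerateGeometryError("coincident particles: distance gradient undefined")
    n = diff / norm
    return ConstraintEval(
        value=np.array([norm - d]),
        jacobian_blocks={"p1": n[None, :], "p2": -n[None, :]},
    )


_DISPATCH = {
    "shear_stretch": shear_stretch_jacobian,
    "bend_twist": bend_twist_jacobian,
    "distance": distance_jacobian,
}


def constraint_jacobian(constraint_id: str, **states) -> ConstraintEval:
    """Evaluate a constraint and its Jacobian blocks by name.

    ``constraint_id`` is one of ``"shear_stretch"`` (p1, p2, q, l),
    ``"bend_twist"`` (q, u, q0, u0) or ``"distance"`` (p1, p2, d).
    """
    try:
        fn = _DISPATCH[constraint_id]
    except KeyError:
        raise ValueError(f"unknown constraint id: {constraint_id!r}") from None
    return fn(**states)
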