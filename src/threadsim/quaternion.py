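"""Scalar-first Hamilton quaternion algebra.

Convention used throughout the package: a quaternion is ``(w, x, y, z)`` with
Hamilton product, and rotating a vector ``v`` means ``q (0, v) q̄``.  All
functions broadcast over leading axes, so they accept a single quaternion of
shape ``(4,)`` or a stack of shape ``(k, 4)``.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "normalize",
    "multiply",
    "conjugate",
    "rotate",
    "imaginary",
    "from_axis_angle",
    "from_two_vectors",
    "to_matrix",
    "identity",
]


def identity(k: int | None = None) -> np.ndarray:
    """Identity quaternion, or a stack of ``k`` identities."""
    if k is None:
        return np.array([1.0, 0.0, 0.0, 0.0])
    q = np.zeros((k, 4))
    q[:, 0] = 1.0
    return q


def normalize(q: np.ndarray) -> np.ndarray:
    q = np.asarray(q, dtype=float)
    return q / np.linalg.norm(q, axis=-1, keepdims=True)


def conjugate(q: np.ndarray) -> np.ndarray:
    q = np.asarray(q, dtype=float)
    out = q.copy()
    out[..., 1:] *= -1.0
    return out


def multiply(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Hamilton product ``a ⊗ b`` (scalar-first)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    aw, av = a[..., 0], a[..., 1:]
    bw, bv = b[..., 0], b[..., 1:]
    w = aw * bw - np.sum(av * bv, axis=-1)
    v = aw[..., None] * bv + bw[..., None] * av + np.cross(av, bv)
    return np.concatenate([w[..., None], v], axis=-1)


def imaginary(q: np.ndarray) -> np.ndarray:
    """Imaginary (vector) part of a quaternion."""
    return np.asarray(q, dtype=float)[..., 1:]


def rotate(q: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Rotate vector(s) ``v`` by unit quaternion(s) ``q`` via ``q (0,v) q̄``."""
    q = np.asarray(q, dtype=float)
    v = np.asarray(v, dtype=float)
    qw, qv = q[..., 0], q[..., 1:]
    t = 2.0 * np.cross(qv, v)
    return v + qw[..., None] * t + np.cross(qv, t)


def from_axis_angle(axis: np.ndarray, angle: float | np.ndarray) -> np.ndarray:
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis, axis=-1, keepdims=True)
    angle = np.asarray(angle, dtype=float)
    half = angle / 2.0
    w = np.cos(half)
    v = axis * np.sin(half)[..., None]
    return np.concatenate([w[..., None], v], axis=-1)


def _perpendicular(a: np.ndarray) -> np.ndarray:
    """A unit vector perpendicular to ``a``, preferring e1 then e2."""
    for e in (np.array([1.0, 0.0, 0.0]), np.array([0.0, 1.0, 0.0])):
        p = e - a * np.dot(a, e)
        n = np.linalg.norm(p)
        if n > 1e-6:
            return p / n
    raise ValueError("could not construct a perpendicular vector")


def from_two_vectors(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Shortest-arc rotation taking unit direction ``a`` onto ``b``.

    The antiparallel case is resolved deterministically by a 180° rotation
    about a perpendicular axis (e1 when possible), so mapping e3 to −e3 uses
    a half-turn about e1.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    a = a / np.linalg.norm(a)
    b = b / np.linalg.norm(b)
    c = float(np.dot(a, b))
    if c < -1.0 + 1e-12:
        return from_axis_angle(_perpendicular(a), np.pi)
    q = np.concatenate([[1.0 + c], np.cross(a, b)])
    return q / np.linalg.norm(q)


def to_matrix(q: np.ndarray) -> np.ndarray:
    """Rotation matrix of quaternion(s) in the homogeneous (quadratic) form.

    For unit quaternions this is the rotation matrix; for non-unit input it
    scales by ``|q|²``.  The quadratic form keeps the matrix a polynomial in
    the raw components, so its analytic derivatives match finite differences
    taken without renormalization.
    """
    q = np.asarray(q, dtype=float)
    w, x, y, z = q[..., 0], q[..., 1], q[..., 2], q[..., 3]
    m = np.empty(q.shape[:-1] + (3, 3))
    m[..., 0, 0] = w * w + x * x - y * y - z * z
    m[..., 0, 1] = 2 * (x * y - w * z)
    m[..., 0, 2] = 2 * (x * z + w * y)
    m[..., 1, 0] = 2 * (x * y + w * z)
    m[..., 1, 1] = w * w - x * x + y * y - z * z
    m[..., 1, 2] = 2 * (y * z - w * x)
    m[..., 2, 0] = 2 * (x * z - w * y)
    m[..., 2, 1] = 2 * (y * z + w * x)
    m[..., 2, 2] = w * w - x * x - y * y + z * z
    return m
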