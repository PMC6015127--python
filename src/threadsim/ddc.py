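"""Direct distance constraint (DDC): inextensibility via a tridiagonal solve.

The chain distance constraints ``C_i = ‖p_i − p_{i+1}‖ − d`` of a serial rod
couple only neighbouring Lagrange multipliers, so the projected system
``(∇C W ∇Cᵀ) λ = −C`` is tridiagonal and can be solved exactly per iteration
with the Thomas algorithm in O(k) instead of Gauss–Seidel sweeps.  Interior
particles with zero inverse mass (instrument grips) split the thread into
independent inextensible sub-chains.

Sign convention: we assemble ``A = ∇C W ∇Cᵀ`` itself (diagonal
``+(wᵢ + wᵢ₊₁)``, off-diagonal ``−wᵢ₊₁ nᵢ·nᵢ₊₁``) and solve ``A λ = −C``.
Multiplying both sides by −1 gives the equivalent negated form sometimes
written with a −1/−2 diagonal; the resulting corrections are identical.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._kernels import ddc_kernel, thomas_kernel
from .errors import DegenerateGeometryError, SingularSystemError

__all__ = [
    "TridiagonalSystem",
    "distance_constraint_values",
    "assemble_tridiagonal",
    "thomas_solve",
    "apply_ddc",
    "split_chains",
]


@dataclass
class TridiagonalSystem:
    """Bands and right-hand side of one chain's projected system."""

    sub: np.ndarray  # (k-1,)
    diag: np.ndarray  # (k,)
    sup: np.ndarray  # (k-1,)
    rhs: np.ndarray  # (k,)

    def __post_init__(self) -> None:
        k = self.diag.shape[0]
        if self.rhs.shape != (k,) or self.sub.shape != (k - 1,) or self.sup.shape != (k - 1,):
            raise ValueError("band/rhs lengths are inconsistent")
        for arr in (self.sub, self.diag, self.sup, self.rhs):
            if not np.all(np.isfinite(arr)):
                raise ValueError("tridiagonal system contains non-finite entries")

    @property
    def size(self) -> int:
        return self.diag.shape[0]

    def dense(self) -> np.ndarray:
        a = np.diag(self.diag)
        k = self.size
        for i in range(k - 1):
            a[i + 1, i] = self.sub[i]
            a[i, i + 1] = self.sup[i]
        return a


def _segment_normals(positions: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    pts = np.atleast_2d(np.asarray(positions, dtype=float))
    if pts.shape[0] < 2:
        raise DegenerateGeometryError("chain needs at least 2 particles")
    diff = pts[:-1] - pts[1:]
    norms = np.linalg.norm(diff, axis=1)
    if np.any(norms < 1e-12):
        raise DegenerateGeometryError("coincident consecutive particles in chain")
    return diff / norms[:, None], norms


def distance_constraint_values(positions: np.ndarray, d: float) -> np.ndarray:
    """``C_i = ‖p_i − p_{i+1}‖ − d`` for each consecutive pair."""
    if d <= 0:
        raise ValueError("rest distance d must be positive")
    _, norms = _segment_normals(positions)
    return norms - d


def assemble_tridiagonal(
    positions: np.ndarray, inverse_masses: np.ndarray, d: float
) -> TridiagonalSystem:
    """Assemble ``(∇C W ∇Cᵀ) λ = −C`` for one chain.

    With the start pinned (w₁ = 0) and unit masses elsewhere the diagonal is
    ``[1, 2, 2, …]`` and the off-diagonals are ``−nᵢ·nᵢ₊₁`` — the projected
    system's familiar tridiagonal pattern up to a global sign.
    """
    normals, _ = _segment_normals(positions)
    w = np.asarray(inverse_masses, dtype=float).ravel()
    c = distance_constraint_values(positions, d)
    k = c.shape[0]
    if w.shape[0] != k + 1:
        raise ValueError("inverse_masses must have one entry per particle")
    diag = w[:-1] + w[1:]
    dots = np.sum(normals[:-1] * normals[1:], axis=1) if k > 1 else np.empty(0)
    off = -w[1:-1] * dots if k > 1 else np.empty(0)
    return TridiagonalSystem(sub=off.copy(), diag=diag, sup=off.copy(), rhs=-c)


def thomas_solve(system: TridiagonalSystem) -> np.ndarray:
    """Solve the tridiagonal system in O(k) (forward elimination + back
    substitution).  Raises :class:`SingularSystemError` when a pivot magnitude
    falls below 1e−12 during the sweep."""
    k = system.size
    out = np.empty(k)
    sub = system.sub if k > 1 else np.zeros(1)
    sup = system.sup if k > 1 else np.zeros(1)
    status = thomas_kernel(
        np.ascontiguousarray(sub, dtype=float),
        np.ascontiguousarray(system.diag, dtype=float),
        np.ascontiguousarray(sup, dtype=float),
        np.ascontiguousarray(system.rhs, dtype=float),
        out,
    )
    if status != 0:
        raise SingularSystemError("vanishing pivot in Thomas sweep")
    return out


def split_chains(inverse_masses: np.ndarray) -> list[tuple[int, int]]:
    """Split a chain at interior zero-inverse-mass particles.

    Returns ``(start, stop)`` particle index ranges (stop exclusive) of the
    independent sub-chains; each held interior particle belongs to both of its
    neighbouring sub-chains but, having w = 0, never moves.
    """
    w = np.asarray(inverse_masses, dtype=float).ravel()
    n = w.shape[0]
    cuts = [i for i in range(1, n - 1) if w[i] == 0.0]
    bounds = [0] + cuts + [n - 1]
    return [(a, b + 1) for a, b in zip(bounds[:-1], bounds[1:]) if b > a]


def apply_ddc(
    positions: np.ndarray,
    inverse_masses: np.ndarray,
    d: float,
    held_mask: np.ndarray | None = None,
) -> np.ndarray:
    """One linearized direct solve of all chain distance constraints.

    Returns corrected positions (input untouched).  Held particles (w = 0 or
    ``held_mask``) never move; interior held particles decouple the two sides.
    One call performs a single Newton-like solve — the solver loops it into
    every projection iteration, where it converges across iterations.
    """
    x = np.array(positions, dtype=float)
    w = np.array(inverse_masses, dtype=float).ravel()
    if held_mask is not None:
        w = np.where(np.asarray(held_mask, dtype=bool), 0.0, w)
    if x.shape[0] != w.shape[0]:
        raise ValueError("positions and inverse_masses disagree on particle count")
    project_ddc_inplace(x, w, d)
    return x


def project_ddc_inplace(x: np.ndarray, w: np.ndarray, d: float) -> None:
    """In-place variant used by the solver's hot loop."""
    for a, b in split_chains(w):
        status = ddc_kernel(x[a:b], w[a:b], d)
        if status == 1:
            raise SingularSystemError("vanishing pivot in DDC Thomas sweep")
        if status == 2:
            raise DegenerateGeometryError("coincident consecutive particles in chain")
        # status 3: all-held sub-chain, reported as no-op
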