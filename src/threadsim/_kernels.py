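"""Compiled inner loops of the constraint projection.

These kernels implement the sequential (Gauss–Seidel) projection passes over
one rod's contiguous state slices, the direct tridiagonal distance solve, and
the contact/friction passes.  They mutate their array arguments in place.
Python-level orchestration (ordering of families, chain splitting, contact
detection) lives in :mod:`threadsim.solver` and :mod:`threadsim.ddc`.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# ---------------------------------------------------------------------------
# quaternion helpers (scalar-first)
# ---------------------------------------------------------------------------


@njit(cache=True, inline="always")
def _normalize4(q):
    n = np.sqrt(q[0] * q[0] + q[1] * q[1] + q[2] * q[2] + q[3] * q[3])
    if n > 0.0:
        q[0] /= n
        q[1] /= n
        q[2] /= n
        q[3] /= n


@njit(cache=True, inline="always")
def _d3(q, out):
    # R(q) e3 for unit q (homogeneous form)
    w, x, y, z = q[0], q[1], q[2], q[3]
    out[0] = 2.0 * (x * z + w * y)
    out[1] = 2.0 * (y * z - w * x)
    out[2] = w * w - x * x - y * y + z * z


# ---------------------------------------------------------------------------
# shear–stretch pass (Gauss–Seidel over elements of one rod)
# ---------------------------------------------------------------------------


@njit(cache=True)
def shear_stretch_pass(x, q, winv, winvq, l, k_stretch):
    """One sequential projection sweep of C_s = (p2 - p1)/l - R(q) e3.

    x: (n,3) particle positions of the rod (chain order)
    q: (k,4) element quaternions, k = n-1
    winv/winvq: inverse masses / inverse inertias for those slices
    """
    k = q.shape[0]
    d3 = np.empty(3)
    for i in range(k):
        w1 = winv[i]
        w2 = winv[i + 1]
        wq = winvq[i]
        denom = (w1 + w2) / (l * l) + 4.0 * wq
        if denom <= 0.0:
            continue
        _normalize4(q[i])
        _d3(q[i], d3)
        c0 = (x[i + 1, 0] - x[i, 0]) / l - d3[0]
        c1 = (x[i + 1, 1] - x[i, 1]) / l - d3[1]
        c2 = (x[i + 1, 2] - x[i, 2]) / l - d3[2]
        s = -k_stretch / denom
        l0 = s * c0
        l1 = s * c1
        l2 = s * c2
        # particle corrections: dp1 = -(w1/l) λ, dp2 = +(w2/l) λ
        x[i, 0] -= (w1 / l) * l0
        x[i, 1] -= (w1 / l) * l1
        x[i, 2] -= (w1 / l) * l2
        x[i + 1, 0] += (w2 / l) * l0
        x[i + 1, 1] += (w2 / l) * l1
        x[i + 1, 2] += (w2 / l) * l2
        if wq > 0.0:
            # dq = wq * (-J_d3)^T λ  with J_d3 = 2[[y,z,w,x],[-x,-w,z,y],[w,-x,-y,z]]
            w, xx, yy, zz = q[i, 0], q[i, 1], q[i, 2], q[i, 3]
            q[i, 0] -= wq * 2.0 * (yy * l0 - xx * l1 + w * l2)
            q[i, 1] -= wq * 2.0 * (zz * l0 - w * l1 - xx * l2)
            q[i, 2] -= wq * 2.0 * (w * l0 + zz * l1 - yy * l2)
            q[i, 3] -= wq * 2.0 * (xx * l0 + yy * l1 + zz * l2)
            _normalize4(q[i])


# ---------------------------------------------------------------------------
# bend–twist pass
# ---------------------------------------------------------------------------


@njit(cache=True)
def bend_twist_pass(q, winvq, rest_rel, k_bend, k_twist):
    """One sequential sweep of C_b = Im(q̄u - q̄⁰u⁰) over adjacent elements.

    The bend components (1st, 2nd) of the correction are scaled by k_bend and
    the twist component (3rd, about d3) by k_twist.  When the current relative
    quaternion lands on the far branch of the double cover (negative 4-dot
    with the rest product), the freer quaternion is negated first — the same
    rotation, but projection then takes the short way around.
    """
    k = q.shape[0]
    for i in range(k - 1):
        wq = winvq[i]
        wu = winvq[i + 1]
        wsum = wq + wu
        if wsum <= 0.0:
            continue
        _normalize4(q[i])
        _normalize4(q[i + 1])
        qw, qx, qy, qz = q[i, 0], q[i, 1], q[i, 2], q[i, 3]
        uw, ux, uy, uz = q[i + 1, 0], q[i + 1, 1], q[i + 1, 2], q[i + 1, 3]
        # rel = conj(q) ⊗ u
        rw = qw * uw + qx * ux + qy * uy + qz * uz
        rx = qw * ux - uw * qx - (qy * uz - qz * uy)
        ry = qw * uy - uw * qy - (qz * ux - qx * uz)
        rz = qw * uz - uw * qz - (qx * uy - qy * ux)
        dot = (
            rw * rest_rel[i, 0]
            + rx * rest_rel[i, 1]
            + ry * rest_rel[i, 2]
            + rz * rest_rel[i, 3]
        )
        if dot < 0.0:
            if wu > 0.0:
                for c in range(4):
                    q[i + 1, c] = -q[i + 1, c]
            else:
                for c in range(4):
                    q[i, c] = -q[i, c]
            qw, qx, qy, qz = q[i, 0], q[i, 1], q[i, 2], q[i, 3]
            uw, ux, uy, uz = q[i + 1, 0], q[i + 1, 1], q[i + 1, 2], q[i + 1, 3]
            rw = qw * uw + qx * ux + qy * uy + qz * uz
            rx = qw * ux - uw * qx - (qy * uz - qz * uy)
            ry = qw * uy - uw * qy - (qz * ux - qx * uz)
            rz = qw * uz - uw * qz - (qx * uy - qy * ux)
        c0 = rx - rest_rel[i, 1]
        c1 = ry - rest_rel[i, 2]
        c2 = rz - rest_rel[i, 3]
        # λ = -(stiffness-scaled C)/(wq + wu);  A = (wq+wu) I for unit q,u
        l0 = -k_bend * c0 / wsum
        l1 = -k_bend * c1 / wsum
        l2 = -k_twist * c2 / wsum
        # dq = wq J_q^T λ; J_q = [uv | -uw I + skew(uv)]
        q[i, 0] += wq * (ux * l0 + uy * l1 + uz * l2)
        q[i, 1] += wq * (-uw * l0 - (uy * l2 - uz * l1))
        q[i, 2] += wq * (-uw * l1 - (uz * l0 - ux * l2))
        q[i, 3] += wq * (-uw * l2 - (ux * l1 - uy * l0))
        # du = wu J_u^T λ; J_u = [-qv | qw I - skew(qv)]
        q[i + 1, 0] += wu * (-(qx * l0 + qy * l1 + qz * l2))
        q[i + 1, 1] += wu * (qw * l0 + (qy * l2 - qz * l1))
        q[i + 1, 2] += wu * (qw * l1 + (qz * l0 - qx * l2))
        q[i + 1, 3] += wu * (qw * l2 + (qx * l1 - qy * l0))
        _normalize4(q[i])
        _normalize4(q[i + 1])


# ---------------------------------------------------------------------------
# direct distance constraint: assembly + Thomas sweep + correction
# ---------------------------------------------------------------------------


@njit(cache=True)
def thomas_kernel(sub, diag, sup, rhs, out):
    """Solve a tridiagonal system in O(k); returns 0 on success, 1 if a pivot
    magnitude falls below 1e-12."""
    k = diag.shape[0]
    cp = np.empty(k)
    dp = np.empty(k)
    piv = diag[0]
    if np.abs(piv) < 1e-12:
        return 1
    cp[0] = sup[0] / piv if k > 1 else 0.0
    dp[0] = rhs[0] / piv
    for i in range(1, k):
        piv = diag[i] - sub[i - 1] * cp[i - 1]
        if np.abs(piv) < 1e-12:
            return 1
        cp[i] = sup[i] / piv if i < k - 1 else 0.0
        dp[i] = (rhs[i] - sub[i - 1] * dp[i - 1]) / piv
    out[k - 1] = dp[k - 1]
    for i in range(k - 2, -1, -1):
        out[i] = dp[i] - cp[i] * out[i + 1]
    return 0


@njit(cache=True)
def _chain_residual_sq(x, dp, alpha, d):
    k = x.shape[0] - 1
    res = 0.0
    for i in range(k):
        dx = (x[i, 0] + alpha * dp[i, 0]) - (x[i + 1, 0] + alpha * dp[i + 1, 0])
        dy = (x[i, 1] + alpha * dp[i, 1]) - (x[i + 1, 1] + alpha * dp[i + 1, 1])
        dz = (x[i, 2] + alpha * dp[i, 2]) - (x[i + 1, 2] + alpha * dp[i + 1, 2])
        r = np.sqrt(dx * dx + dy * dy + dz * dz) - d
        res += r * r
    return res


@njit(cache=True)
def ddc_kernel(x, winv, d):
    """One damped-Newton direct solve of all chain distance constraints.

    Assembles A = ∇C W ∇Cᵀ (tridiagonal: diag wᵢ+wᵢ₊₁, off-diag
    −wᵢ₊₁ nᵢ·nᵢ₊₁), solves A λ = −C with the Thomas sweep and applies
    Δp = W ∇Cᵀ λ, scaled by the largest backtracking factor that reduces the
    max length violation (the full step can overshoot and cycle on folded,
    compressed configurations; uniform scaling keeps Σ mᵢΔpᵢ = 0).  Returns 0
    on success, 1 on a singular pivot, 2 on a degenerate (coincident-particle)
    chain, 3 for an all-held no-op.
    """
    n = x.shape[0]
    k = n - 1
    if k < 1:
        return 3
    nx = np.empty((k, 3))
    c = np.empty(k)
    for i in range(k):
        dx = x[i, 0] - x[i + 1, 0]
        dy = x[i, 1] - x[i + 1, 1]
        dz = x[i, 2] - x[i + 1, 2]
        ln = np.sqrt(dx * dx + dy * dy + dz * dz)
        if ln < 1e-12:
            return 2
        nx[i, 0] = dx / ln
        nx[i, 1] = dy / ln
        nx[i, 2] = dz / ln
        c[i] = ln - d
    diag = np.empty(k)
    sub = np.empty(max(k - 1, 1))
    sup = np.empty(max(k - 1, 1))
    allzero = True
    for i in range(k):
        diag[i] = winv[i] + winv[i + 1]
        if diag[i] > 1e-12:
            allzero = False
    if allzero:
        return 3
    for i in range(k - 1):
        dot = (
            nx[i, 0] * nx[i + 1, 0]
            + nx[i, 1] * nx[i + 1, 1]
            + nx[i, 2] * nx[i + 1, 2]
        )
        sub[i] = -winv[i + 1] * dot
        sup[i] = sub[i]
    rhs = -c
    lam = np.empty(k)
    status = thomas_kernel(sub, diag, sup, rhs, lam)
    if status != 0:
        return 1
    dp = np.zeros((n, 3))
    for i in range(k):
        wi = winv[i]
        wj = winv[i + 1]
        dp[i, 0] += wi * lam[i] * nx[i, 0]
        dp[i, 1] += wi * lam[i] * nx[i, 1]
        dp[i, 2] += wi * lam[i] * nx[i, 2]
        dp[i + 1, 0] -= wj * lam[i] * nx[i, 0]
        dp[i + 1, 1] -= wj * lam[i] * nx[i, 1]
        dp[i + 1, 2] -= wj * lam[i] * nx[i, 2]
    # Backtracking line search on ‖C‖²: the Newton direction is always a
    # descent direction for it, so some step scale improves the residual.
    old = _chain_residual_sq(x, dp, 0.0, d)
    best_alpha = 0.0
    alpha = 1.0
    for _ in range(7):
        res = _chain_residual_sq(x, dp, alpha, d)
        if res < old:
            best_alpha = alpha
            break
        alpha *= 0.5
    if best_alpha > 0.0:
        for i in range(n):
            x[i, 0] += best_alpha * dp[i, 0]
            x[i, 1] += best_alpha * dp[i, 1]
            x[i, 2] += best_alpha * dp[i, 2]
    return 0


# ---------------------------------------------------------------------------
# contact and friction passes
# ---------------------------------------------------------------------------


@njit(cache=True)
def contact_pass(x, winv, ia, ib, anchor, normal, dsep):
    """Project inequality contacts C_c = (p1 - p2)·n - d ≥ 0 (corrected only
    when violated).  ib < 0 marks a static counterpart with position
    ``anchor`` and infinite mass."""
    m = ia.shape[0]
    for c in range(m):
        i = ia[c]
        j = ib[c]
        nx_, ny_, nz_ = normal[c, 0], normal[c, 1], normal[c, 2]
        if j >= 0:
            bx, by, bz = x[j, 0], x[j, 1], x[j, 2]
            wb = winv[j]
        else:
            bx, by, bz = anchor[c, 0], anchor[c, 1], anchor[c, 2]
            wb = 0.0
        wa = winv[i]
        wsum = wa + wb
        if wsum <= 0.0:
            continue
        cc = (
            (x[i, 0] - bx) * nx_
            + (x[i, 1] - by) * ny_
            + (x[i, 2] - bz) * nz_
            - dsep[c]
        )
        if cc >= 0.0:
            continue
        lam = -cc / wsum
        x[i, 0] += wa * lam * nx_
        x[i, 1] += wa * lam * ny_
        x[i, 2] += wa * lam * nz_
        if j >= 0:
            x[j, 0] -= wb * lam * nx_
            x[j, 1] -= wb * lam * ny_
            x[j, 2] -= wb * lam * nz_


@njit(cache=True, inline="always")
def _cf(rx, ry, rz, nx_, ny_, nz_, k):
    ln = np.sqrt(rx * rx + ry * ry + rz * rz)
    if ln < 1e-14:
        return -1.0
    ux, uy, uz = rx / ln, ry / ln, rz / ln
    cx = uy * nz_ - uz * ny_
    cy = uz * nx_ - ux * nz_
    cz = ux * ny_ - uy * nx_
    return k * np.sqrt(cx * cx + cy * cy + cz * cz)


@njit(cache=True)
def friction_pass(x, winv, ia, ib, anchor, normal, dsep, kf, active_gap):
    """Project C_f = k‖(p1-p2)/‖p1-p2‖ × n‖ toward zero for contacts whose
    gap is within ``active_gap`` of touching.  The gradient is computed by
    central finite differences on the offset r = p1 − p2."""
    m = ia.shape[0]
    for c in range(m):
        k = kf[c]
        if k <= 0.0:
            continue
        i = ia[c]
        j = ib[c]
        nx_, ny_, nz_ = normal[c, 0], normal[c, 1], normal[c, 2]
        if j >= 0:
            bx, by, bz = x[j, 0], x[j, 1], x[j, 2]
            wb = winv[j]
        else:
            bx, by, bz = anchor[c, 0], anchor[c, 1], anchor[c, 2]
            wb = 0.0
        wa = winv[i]
        wsum = wa + wb
        if wsum <= 0.0:
            continue
        rx = x[i, 0] - bx
        ry = x[i, 1] - by
        rz = x[i, 2] - bz
        gap = rx * nx_ + ry * ny_ + rz * nz_ - dsep[c]
        if gap > active_gap:
            continue
        cf = _cf(rx, ry, rz, nx_, ny_, nz_, k)
        if cf < 1e-12:
            continue
        rn = np.sqrt(rx * rx + ry * ry + rz * rz)
        h = 1e-7 * rn + 1e-12
        gx = (
            _cf(rx + h, ry, rz, nx_, ny_, nz_, k)
            - _cf(rx - h, ry, rz, nx_, ny_, nz_, k)
        ) / (2.0 * h)
        gy = (
            _cf(rx, ry + h, rz, nx_, ny_, nz_, k)
            - _cf(rx, ry - h, rz, nx_, ny_, nz_, k)
        ) / (2.0 * h)
        gz = (
            _cf(rx, ry, rz + h, nx_, ny_, nz_, k)
            - _cf(rx, ry, rz - h, nx_, ny_, nz_, k)
        ) / (2.0 * h)
        g2 = gx * gx + gy * gy + gz * gz
        if g2 < 1e-20:
            continue
        lam = -cf / (wsum * g2)
        # near the constraint's maximum the gradient vanishes and the raw
        # Newton step diverges; cap the per-projection displacement at a
        # fraction of the contact separation
        disp = np.abs(lam) * np.sqrt(g2) * (wa if wa > wb else wb)
        cap = 0.2 * dsep[c]
        if disp > cap:
            lam *= cap / disp
        x[i, 0] += wa * lam * gx
        x[i, 1] += wa * lam * gy
        x[i, 2] += wa * lam * gz
        if j >= 0:
            x[j, 0] -= wb * lam * gx
            x[j, 1] -= wb * lam * gy
            x[j, 2] -= wb * lam * gz
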