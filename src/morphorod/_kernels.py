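"""Compiled hot paths: frame integration and the elastic fixed point.

These are plain loop-style routines jitted with numba when available (it is a
declared dependency); the identical Python source runs uncompiled otherwise,
so numerical behavior does not depend on the JIT.
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*args, **kwargs):  # type: ignore[misc]
        def wrap(func):
            return func

        if args and callable(args[0]):
            return args[0]
        return wrap


@njit(cache=True)
def frame_path(s, u, R0):
    """Integrate the rod kinematics d_j' = u x d_j, p' = d3 along the grid.

    Per interval the strain vector is frozen at the midpoint average, and the
    exact rigid-motion (SE(3)) exponential of that constant strain is applied:
    the director frame stays orthonormal to machine precision and the chord of
    each segment is consistent with its arc length by construction.

    Parameters: s (n,) arc length; u (n, 3) strain components in the local
    director basis; R0 (3, 3) base frame with directors as columns.
    Returns (R, p): R (n, 3, 3) director matrices (columns d1, d2, d3) and
    p (n, 3) centerline points with p[0] = 0.
    """
    n = s.shape[0]
    R = np.empty((n, 3, 3))
    p = np.empty((n, 3))
    for a in range(3):
        p[0, a] = 0.0
        for b in range(3):
            R[0, a, b] = R0[a, b]
    for i in range(n - 1):
        h = s[i + 1] - s[i]
        w1 = 0.5 * (u[i, 0] + u[i + 1, 0]) * h
        w2 = 0.5 * (u[i, 1] + u[i + 1, 1]) * h
        w3 = 0.5 * (u[i, 2] + u[i + 1, 2]) * h
        th2 = w1 * w1 + w2 * w2 + w3 * w3
        th = np.sqrt(th2)
        if th < 1e-6:
            # series for sin/cos coefficients, accurate to ~1e-24 here
            a_c = 1.0 - th2 / 6.0
            b_c = 0.5 - th2 / 24.0
            c_c = 1.0 / 6.0 - th2 / 120.0
        else:
            a_c = np.sin(th) / th
            b_c = (1.0 - np.cos(th)) / th2
            c_c = (th - np.sin(th)) / (th2 * th)
        # Rodrigues rotation exp([w]x)
        r00 = 1.0 - b_c * (w2 * w2 + w3 * w3)
        r01 = -a_c * w3 + b_c * w1 * w2
        r02 = a_c * w2 + b_c * w1 * w3
        r10 = a_c * w3 + b_c * w1 * w2
        r11 = 1.0 - b_c * (w1 * w1 + w3 * w3)
        r12 = -a_c * w1 + b_c * w2 * w3
        r20 = -a_c * w2 + b_c * w1 * w3
        r21 = a_c * w1 + b_c * w2 * w3
        r22 = 1.0 - b_c * (w1 * w1 + w2 * w2)
        # displacement of the segment in the body frame at node i:
        # h * (I + b[w]x + c[w]x^2) e3
        d0 = h * (b_c * w2 + c_c * w1 * w3)
        d1 = h * (-b_c * w1 + c_c * w2 * w3)
        d2 = h * (1.0 + c_c * (w3 * w3 - th2))
        for a in range(3):
            p[i + 1, a] = (
                p[i, a] + R[i, a, 0] * d0 + R[i, a, 1] * d1 + R[i, a, 2] * d2
            )
            R[i + 1, a, 0] = R[i, a, 0] * r00 + R[i, a, 1] * r10 + R[i, a, 2] * r20
            R[i + 1, a, 1] = R[i, a, 0] * r01 + R[i, a, 1] * r11 + R[i, a, 2] * r21
            R[i + 1, a, 2] = R[i, a, 0] * r02 + R[i, a, 1] * r12 + R[i, a, 2] * r22
    return R, p


@njit(cache=True)
def gravity_moment(s, R, q, gdir):
    """Contact couple m(s) = -int_s^L q (L - sigma) g x d3(sigma) dsigma.

    Composite trapezoid accumulated from the tip, so m(L) = 0 exactly.
    Returns m (n, 3) in lab components.
    """
    n = s.shape[0]
    L = s[n - 1]
    f = np.empty((n, 3))
    for i in range(n):
        w = q * (L - s[i])
        d3x = R[i, 0, 2]
        d3y = R[i, 1, 2]
        d3z = R[i, 2, 2]
        f[i, 0] = w * (gdir[1] * d3z - gdir[2] * d3y)
        f[i, 1] = w * (gdir[2] * d3x - gdir[0] * d3z)
        f[i, 2] = w * (gdir[0] * d3y - gdir[1] * d3x)
    m = np.empty((n, 3))
    for a in range(3):
        m[n - 1, a] = 0.0
    for i in range(n - 2, -1, -1):
        h = s[i + 1] - s[i]
        for a in range(3):
            m[i, a] = m[i + 1, a] - 0.5 * h * (f[i, a] + f[i + 1, a])
    return m


@njit(cache=True)
def equilibrium_fixed_point(s, u_star, K, q, gdir, R0, u_init, tol_tip, max_iter, relax):
    """Solve the quasi-static rod equilibrium under distributed gravity.

    Fixed point of: integrate frames from u -> moment m from the shape ->
    u = u_star + m_body / K, with under-relaxation. Convergence is declared
    when the tip position moves less than tol_tip between iterations.

    Returns (u, R, p, m, iters, converged); R, p, m are consistent with the
    returned u (one final frame integration and moment evaluation).
    """
    n = s.shape[0]
    u = u_init.copy()
    tip0 = 1e30
    tip1 = 1e30
    tip2 = 1e30
    iters = 0
    converged = False
    for it in range(max_iter):
        R, p = frame_path(s, u, R0)
        iters = it + 1
        dx = p[n - 1, 0] - tip0
        dy = p[n - 1, 1] - tip1
        dz = p[n - 1, 2] - tip2
        if it > 0 and dx * dx + dy * dy + dz * dz < tol_tip * tol_tip:
            converged = True
            break
        tip0 = p[n - 1, 0]
        tip1 = p[n - 1, 1]
        tip2 = p[n - 1, 2]
        m = gravity_moment(s, R, q, gdir)
        for i in range(n):
            mb0 = R[i, 0, 0] * m[i, 0] + R[i, 1, 0] * m[i, 1] + R[i, 2, 0] * m[i, 2]
            mb1 = R[i, 0, 1] * m[i, 0] + R[i, 1, 1] * m[i, 1] + R[i, 2, 1] * m[i, 2]
            mb2 = R[i, 0, 2] * m[i, 0] + R[i, 1, 2] * m[i, 1] + R[i, 2, 2] * m[i, 2]
            u[i, 0] = (1.0 - relax) * u[i, 0] + relax * (u_star[i, 0] + mb0 / K[i, 0])
            u[i, 1] = (1.0 - relax) * u[i, 1] + relax * (u_star[i, 1] + mb1 / K[i, 1])
            u[i, 2] = (1.0 - relax) * u[i, 2] + relax * (u_star[i, 2] + mb2 / K[i, 2])
    R, p = frame_path(s, u, R0)
    m = gravity_moment(s, R, q, gdir)
    return u, R, p, m, iters, converged
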