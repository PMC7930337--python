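"""Compiled inner loops for the neural, muscle and body integrators.

Everything here is plain-array numerics so the same source runs under
numba's nopython JIT (the normal path) or as ordinary Python if numba is
unavailable. Wrappers in :mod:`wormcpg.simulation` and
:mod:`wormcpg.body` own array allocation, validation and unit handling.

Conventions
-----------
* Rod i has center (x_i, y_i) and orientation phi_i; the rod's unit
  vector u = (cos phi, sin phi) points toward the dorsal side, so the
  dorsal endpoint is center + w_i*u and the ventral endpoint is
  center - w_i*u.
* Generalized coordinates per rod are (x, y, phi); forces are assembled
  as generalized forces (f_x, f_y, torque).
* The body is overdamped: drag(v) balances elastic + muscle forces at
  every instant. Each substep solves the linear system
  (D + sum_e (c_e + dt*k_e) s_e s_e^T) v = F_el(q), then q += dt*v,
  i.e. a semi-implicit backward-Euler step with implicit damping and
  the dominant (axial) elastic stiffness, explicit geometry.
* Drag acts at the two rod endpoints (half the rod coefficient each),
  decomposed along the local body-midline tangent/normal frame, which
  yields rotational as well as translational damping.
"""
from __future__ import annotations

import math

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    NUMBA = True
except ImportError:  # pragma: no cover
    NUMBA = False

    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]

        def deco(f):
            return f

        return deco


@njit(cache=True)
def _inv3(M, out):
    """Invert a 3x3 matrix via the adjugate. Returns determinant."""
    a, b, c = M[0, 0], M[0, 1], M[0, 2]
    d, e, f = M[1, 0], M[1, 1], M[1, 2]
    g, h, i = M[2, 0], M[2, 1], M[2, 2]
    A = e * i - f * h
    B = -(d * i - f * g)
    C = d * h - e * g
    det = a * A + b * B + c * C
    if det == 0.0:
        return 0.0
    inv = 1.0 / det
    out[0, 0] = A * inv
    out[0, 1] = -(b * i - c * h) * inv
    out[0, 2] = (b * f - c * e) * inv
    out[1, 0] = B * inv
    out[1, 1] = (a * i - c * g) * inv
    out[1, 2] = -(a * f - c * d) * inv
    out[2, 0] = C * inv
    out[2, 1] = -(a * h - b * g) * inv
    out[2, 2] = (a * e - b * d) * inv
    return det


@njit(cache=True, fastmath=True)
def _solve_block_tridiag_ws(diag, lower, upper, rhs, out, cp, dp):
    """Solve a block-tridiagonal system with 3x3 blocks (block Thomas).

    diag: (n,3,3); lower[i] couples row i+1 to i; upper[i] couples row i
    to i+1; rhs: (n,3). Solution written to out; cp (n-1,3,3) and dp
    (n,3) are caller-provided workspaces. Returns 0 on success, 1 on a
    singular pivot.
    """
    n = diag.shape[0]
    Minv = np.zeros((3, 3))
    M = np.zeros((3, 3))
    if _inv3(diag[0], Minv) == 0.0:
        return 1
    for r in range(3):
        dp[0, r] = Minv[r, 0] * rhs[0, 0] + Minv[r, 1] * rhs[0, 1] + Minv[r, 2] * rhs[0, 2]
    if n > 1:
        for r in range(3):
            for s in range(3):
                cp[0, r, s] = (Minv[r, 0] * upper[0, 0, s]
                               + Minv[r, 1] * upper[0, 1, s]
                               + Minv[r, 2] * upper[0, 2, s])
    for i in range(1, n):
        # M = diag[i] - lower[i-1] @ cp[i-1]
        for r in range(3):
            for s in range(3):
                acc = diag[i, r, s]
                for t in range(3):
                    acc -= lower[i - 1, r, t] * cp[i - 1, t, s]
                M[r, s] = acc
        if _inv3(M, Minv) == 0.0:
            return 1
        # dp[i] = Minv @ (rhs[i] - lower[i-1] @ dp[i-1])
        t0 = rhs[i, 0] - (lower[i - 1, 0, 0] * dp[i - 1, 0]
                          + lower[i - 1, 0, 1] * dp[i - 1, 1]
                          + lower[i - 1, 0, 2] * dp[i - 1, 2])
        t1 = rhs[i, 1] - (lower[i - 1, 1, 0] * dp[i - 1, 0]
                          + lower[i - 1, 1, 1] * dp[i - 1, 1]
                          + lower[i - 1, 1, 2] * dp[i - 1, 2])
        t2 = rhs[i, 2] - (lower[i - 1, 2, 0] * dp[i - 1, 0]
                          + lower[i - 1, 2, 1] * dp[i - 1, 1]
                          + lower[i - 1, 2, 2] * dp[i - 1, 2])
        for r in range(3):
            dp[i, r] = Minv[r, 0] * t0 + Minv[r, 1] * t1 + Minv[r, 2] * t2
        if i < n - 1:
            for r in range(3):
                for s in range(3):
                    acc = 0.0
                    for t in range(3):
                        acc += Minv[r, t] * upper[i, t, s]
                    cp[i, r, s] = acc
    for r in range(3):
        out[n - 1, r] = dp[n - 1, r]
    for i in range(n - 2, -1, -1):
        for r in range(3):
            acc = dp[i, r]
            for s in range(3):
                acc -= cp[i, r, s] * out[i + 1, s]
            out[i, r] = acc
    return 0


@njit(cache=True)
def solve_block_tridiag(diag, lower, upper, rhs, out):
    """Convenience wrapper around the workspace version."""
    n = diag.shape[0]
    cp = np.zeros((n - 1, 3, 3))
    dp = np.zeros((n, 3))
    return _solve_block_tridiag_ws(diag, lower, upper, rhs, out, cp, dp)


@njit(cache=True)
def _midline_tangents(x, y, tx, ty):
    """Unit tangent of the body midline at each rod (one-sided at ends)."""
    n = x.shape[0]
    for i in range(n):
        i0 = i - 1 if i > 0 else i
        i1 = i + 1 if i < n - 1 else i
        dx = x[i1] - x[i0]
        dy = y[i1] - y[i0]
        nrm = math.sqrt(dx * dx + dy * dy)
        if nrm < 1e-30:
            tx[i] = 1.0
            ty[i] = 0.0
        else:
            tx[i] = dx / nrm
            ty[i] = dy / nrm


@njit(cache=True)
def element_forces(x, y, phi, vx, vy, vphi, w,
                   ea, side_a, side_b, ke, ce, L0, kind,
                   act_d, act_v, f_max, fl_width, fv_vmax, fv_b,
                   fgen):
    """Generalized forces (fx, fy, torque per rod) from all damped-spring
    elements plus muscle tensions, at the given state and velocities.

    Returns 0 on success, 2 if an element degenerated to zero length.
    """
    n_rod = x.shape[0]
    for i in range(n_rod):
        fgen[i, 0] = 0.0
        fgen[i, 1] = 0.0
        fgen[i, 2] = 0.0
    n_el = ea.shape[0]
    for e in range(n_el):
        a = ea[e]
        b = a + 1
        uax = math.cos(phi[a])
        uay = math.sin(phi[a])
        ubx = math.cos(phi[b])
        uby = math.sin(phi[b])
        rax = side_a[e] * w[a] * uax
        ray = side_a[e] * w[a] * uay
        rbx = side_b[e] * w[b] * ubx
        rby = side_b[e] * w[b] * uby
        dx = (x[b] + rbx) - (x[a] + rax)
        dy = (y[b] + rby) - (y[a] + ray)
        ell = math.sqrt(dx * dx + dy * dy)
        if ell < 1e-12:
            return 2
        ex = dx / ell
        ey = dy / ell
        # velocity mapping rows: s_a = -(ex, ey, ra x e), s_b = +(ex, ey, rb x e)
        sa2 = rax * ey - ray * ex
        sb2 = rbx * ey - rby * ex
        dldt = (-(ex * vx[a] + ey * vy[a] + sa2 * vphi[a])
                + (ex * vx[b] + ey * vy[b] + sb2 * vphi[b]))
        tension = ke[e] * (ell - L0[e]) + ce[e] * dldt
        if kind[e] == 0 or kind[e] == 1:
            act = act_d[a] if kind[e] == 0 else act_v[a]
            if act != 0.0:
                strain = (ell - L0[e]) / (fl_width * L0[e])
                fl = 1.0 - strain * strain
                if fl < 0.0:
                    fl = 0.0
                ush = -dldt  # shortening speed
                if ush > 0.0:
                    if ush >= fv_vmax:
                        fv = 0.0
                    else:
                        fv = (1.0 - ush / fv_vmax) / (1.0 + fv_b * ush / fv_vmax)
                else:
                    fv = 1.0
                tension += f_max * act * fl * fv
        # generalized force = -tension * s  (positive tension contracts)
        fgen[a, 0] += tension * ex
        fgen[a, 1] += tension * ey
        fgen[a, 2] += tension * sa2
        fgen[b, 0] -= tension * ex
        fgen[b, 1] -= tension * ey
        fgen[b, 2] -= tension * sb2
    return 0


@njit(cache=True, fastmath=True)
def body_substeps(x, y, phi, vx, vy, vphi, w,
                  ea, side_a, side_b, ke, ce, L0, kind,
                  act_d, act_v, f_max, fl_width, fv_vmax, fv_b,
                  drag_t, drag_n, dt, n_sub):
    """Advance the body n_sub semi-implicit steps with frozen muscle drive.

    State arrays are updated in place. Returns 0 on success, 1 on a
    singular solve, 2 on a degenerate element.
    """
    n_rod = x.shape[0]
    n_el = ea.shape[0]
    diag = np.zeros((n_rod, 3, 3))
    lower = np.zeros((n_rod - 1, 3, 3))
    upper = np.zeros((n_rod - 1, 3, 3))
    rhs = np.zeros((n_rod, 3))
    sol = np.zeros((n_rod, 3))
    tx = np.zeros(n_rod)
    ty = np.zeros(n_rod)
    cp_ws = np.zeros((n_rod - 1, 3, 3))
    dp_ws = np.zeros((n_rod, 3))
    ct = 0.5 * drag_t
    cn = 0.5 * drag_n
    for _ in range(n_sub):
        for i in range(n_rod):
            for r in range(3):
                rhs[i, r] = 0.0
                for s in range(3):
                    diag[i, r, s] = 0.0
        for i in range(n_rod - 1):
            for r in range(3):
                for s in range(3):
                    lower[i, r, s] = 0.0
                    upper[i, r, s] = 0.0
        _midline_tangents(x, y, tx, ty)
        # endpoint drag -> generalized damping matrix per rod
        for i in range(n_rod):
            ux = math.cos(phi[i])
            uy = math.sin(phi[i])
            # local 2x2 drag matrix C = ct*t t^T + cn*n n^T, n = perp(t)
            c00 = ct * tx[i] * tx[i] + cn * ty[i] * ty[i]
            c01 = (ct - cn) * tx[i] * ty[i]
            c11 = ct * ty[i] * ty[i] + cn * tx[i] * tx[i]
            for side in (-1.0, 1.0):
                rxx = side * w[i] * ux
                ryy = side * w[i] * uy
                # G = [[1,0,-ry],[0,1,rx]]; D += G^T C G
                diag[i, 0, 0] += c00
                diag[i, 0, 1] += c01
                diag[i, 1, 0] += c01
                diag[i, 1, 1] += c11
                g02 = -ryy
                g12 = rxx
                d02 = c00 * g02 + c01 * g12
                d12 = c01 * g02 + c11 * g12
                diag[i, 0, 2] += d02
                diag[i, 1, 2] += d12
                diag[i, 2, 0] += d02
                diag[i, 2, 1] += d12
                diag[i, 2, 2] += g02 * (c00 * g02 + c01 * g12) + g12 * (c01 * g02 + c11 * g12)
        # elements: explicit elastic + muscle forces, implicit damping + axial stiffness
        for e in range(n_el):
            a = ea[e]
            b = a + 1
            uax = math.cos(phi[a])
            uay = math.sin(phi[a])
            ubx = math.cos(phi[b])
            uby = math.sin(phi[b])
            rax = side_a[e] * w[a] * uax
            ray = side_a[e] * w[a] * uay
            rbx = side_b[e] * w[b] * ubx
            rby = side_b[e] * w[b] * uby
            dx = (x[b] + rbx) - (x[a] + rax)
            dy = (y[b] + rby) - (y[a] + ray)
            ell = math.sqrt(dx * dx + dy * dy)
            if ell < 1e-12:
                return 2
            ex = dx / ell
            ey = dy / ell
            sa2 = rax * ey - ray * ex
            sb2 = rbx * ey - rby * ex
            dldt = (-(ex * vx[a] + ey * vy[a] + sa2 * vphi[a])
                    + (ex * vx[b] + ey * vy[b] + sb2 * vphi[b]))
            tension = ke[e] * (ell - L0[e])
            if kind[e] == 0 or kind[e] == 1:
                act = act_d[a] if kind[e] == 0 else act_v[a]
                if act != 0.0:
                    strain = (ell - L0[e]) / (fl_width * L0[e])
                    fl = 1.0 - strain * strain
                    if fl < 0.0:
                        fl = 0.0
                    ush = -dldt
                    if ush > 0.0:
                        if ush >= fv_vmax:
                            fv = 0.0
                        else:
                            fv = (1.0 - ush / fv_vmax) / (1.0 + fv_b * ush / fv_vmax)
                    else:
                        fv = 1.0
                    tension += f_max * act * fl * fv
            coef = ce[e] + dt * ke[e]
            # s_a = (-ex, -ey, -sa2); s_b = (ex, ey, sb2)
            sax = -ex
            say = -ey
            saz = -sa2
            sbx = ex
            sby = ey
            sbz = sb2
            rhs[a, 0] -= tension * sax
            rhs[a, 1] -= tension * say
            rhs[a, 2] -= tension * saz
            rhs[b, 0] -= tension * sbx
            rhs[b, 1] -= tension * sby
            rhs[b, 2] -= tension * sbz
            # diag blocks
            diag[a, 0, 0] += coef * sax * sax
            diag[a, 0, 1] += coef * sax * say
            diag[a, 0, 2] += coef * sax * saz
            diag[a, 1, 0] += coef * say * sax
            diag[a, 1, 1] += coef * say * say
            diag[a, 1, 2] += coef * say * saz
            diag[a, 2, 0] += coef * saz * sax
            diag[a, 2, 1] += coef * saz * say
            diag[a, 2, 2] += coef * saz * saz
            diag[b, 0, 0] += coef * sbx * sbx
            diag[b, 0, 1] += coef * sbx * sby
            diag[b, 0, 2] += coef * sbx * sbz
            diag[b, 1, 0] += coef * sby * sbx
            diag[b, 1, 1] += coef * sby * sby
            diag[b, 1, 2] += coef * sby * sbz
            diag[b, 2, 0] += coef * sbz * sbx
            diag[b, 2, 1] += coef * sbz * sby
            diag[b, 2, 2] += coef * sbz * sbz
            # cross blocks: A[a,b] += coef * s_a s_b^T ; A[b,a] += coef * s_b s_a^T
            upper[a, 0, 0] += coef * sax * sbx
            upper[a, 0, 1] += coef * sax * sby
            upper[a, 0, 2] += coef * sax * sbz
            upper[a, 1, 0] += coef * say * sbx
            upper[a, 1, 1] += coef * say * sby
            upper[a, 1, 2] += coef * say * sbz
            upper[a, 2, 0] += coef * saz * sbx
            upper[a, 2, 1] += coef * saz * sby
            upper[a, 2, 2] += coef * saz * sbz
            lower[a, 0, 0] += coef * sbx * sax
            lower[a, 0, 1] += coef * sbx * say
            lower[a, 0, 2] += coef * sbx * saz
            lower[a, 1, 0] += coef * sby * sax
            lower[a, 1, 1] += coef * sby * say
            lower[a, 1, 2] += coef * sby * saz
            lower[a, 2, 0] += coef * sbz * sax
            lower[a, 2, 1] += coef * sbz * say
            lower[a, 2, 2] += coef * sbz * saz
        status = _solve_block_tridiag_ws(diag, lower, upper, rhs, sol, cp_ws, dp_ws)
        if status != 0:
            return status
        for i in range(n_rod):
            vx[i] = sol[i, 0]
            vy[i] = sol[i, 1]
            vphi[i] = sol[i, 2]
            x[i] += dt * vx[i]
            y[i] += dt * vy[i]
            phi[i] += dt * vphi[i]
    return 0


@njit(cache=True)
def neural_steps(V, W, G, theta, tau, alive, ext, dt, n_steps,
                 stride, S_rec, rec_offset, V_rec=None):
    """Forward-Euler CTRNN steps with optional strided recording of S (and V).

    Records sigma(V+theta)*alive at steps where (global step index)
    % stride == 0, starting the global index at rec_offset. Returns the
    number of records written.
    """
    n = V.shape[0]
    S = np.zeros(n)
    chem = np.zeros(n)
    wrote = 0
    for step in range(n_steps):
        for i in range(n):
            S[i] = alive[i] / (1.0 + math.exp(-(V[i] + theta[i])))
        gstep = rec_offset + step
        if stride > 0 and gstep % stride == 0:
            idx = gstep // stride
            if idx < S_rec.shape[0]:
                for i in range(n):
                    S_rec[idx, i] = S[i]
                if V_rec is not None and idx < V_rec.shape[0]:
                    for i in range(n):
                        V_rec[idx, i] = V[i]
                wrote += 1
        for i in range(n):
            chem[i] = 0.0
            for j in range(n):
                chem[i] += W[i, j] * S[j]
        for i in range(n):
            if alive[i] == 0.0:
                V[i] = 0.0
                continue
            gap = 0.0
            for j in range(n):
                if G[i, j] != 0.0 and alive[j] != 0.0:
                    gap += G[i, j] * (V[j] - V[i])
            V[i] += dt * (-V[i] + chem[i] + gap + ext[i]) / tau[i]
    return wrote


@njit(cache=True)
def embodied_steps(
    V, W, G, theta, tau, alive, ext, dt_n, n_macro,
    Mmap, A, tau_m,
    ME, act_d, act_v,
    x, y, phi, vx, vy, vphi, w,
    ea, side_a, side_b, ke, ce, L0, kind,
    f_max, fl_width, fv_vmax, fv_b, drag_t, drag_n, dt_b, n_sub,
    stride, S_rec, A_rec, mid_rec, rec_offset,
):
    """Coupled neural + muscle + body loop.

    Per macro step (dt_n): record (if due) -> neural Euler step ->
    muscle drive I = Mmap @ S -> muscle leaky-integrator step -> map
    activations onto lateral elements -> n_sub body substeps (dt_b).
    All state arrays update in place. Returns 0, or the body error code.
    """
    n = V.shape[0]
    n_mus = A.shape[0]
    n_seg = act_d.shape[0]
    n_rod = x.shape[0]
    S = np.zeros(n)
    chem = np.zeros(n)
    I = np.zeros(n_mus)
    half = n_mus // 2
    for step in range(n_macro):
        for i in range(n):
            S[i] = alive[i] / (1.0 + math.exp(-(V[i] + theta[i])))
        gstep = rec_offset + step
        if stride > 0 and gstep % stride == 0:
            idx = gstep // stride
            if idx < S_rec.shape[0]:
                for i in range(n):
                    S_rec[idx, i] = S[i]
                for m in range(n_mus):
                    A_rec[idx, m] = A[m]
                for i in range(n_rod):
                    mid_rec[idx, i, 0] = x[i]
                    mid_rec[idx, i, 1] = y[i]
        # neural update
        for i in range(n):
            chem[i] = 0.0
            for j in range(n):
                chem[i] += W[i, j] * S[j]
        for i in range(n):
            if alive[i] == 0.0:
                V[i] = 0.0
                continue
            gap = 0.0
            for j in range(n):
                if G[i, j] != 0.0 and alive[j] != 0.0:
                    gap += G[i, j] * (V[j] - V[i])
            V[i] += dt_n * (-V[i] + chem[i] + gap + ext[i]) / tau[i]
        # muscle drive and activation
        for m in range(n_mus):
            acc = 0.0
            for j in range(n):
                acc += Mmap[m, j] * S[j]
            I[m] = acc
            A[m] += dt_n * (I[m] - A[m]) / tau_m
        # distribute activations onto lateral elements
        for s in range(n_seg):
            ad = 0.0
            av = 0.0
            for m in range(half):
                if ME[s, m] != 0.0:
                    ad += ME[s, m] * A[m]
                    av += ME[s, m] * A[half + m]
            act_d[s] = ad
            act_v[s] = av
        status = body_substeps(
            x, y, phi, vx, vy, vphi, w,
            ea, side_a, side_b, ke, ce, L0, kind,
            act_d, act_v, f_max, fl_width, fv_vmax, fv_b,
            drag_t, drag_n, dt_b, n_sub,
        )
        if status != 0:
            return status
    return 0
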