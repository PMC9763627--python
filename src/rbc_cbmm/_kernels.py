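"""Numba-compiled inner loops for the membrane force evaluation.

These kernels are numerically identical to the vectorized numpy
implementations in :mod:`rbc_cbmm.mechanics` (asserted by the test suite);
they exist purely to keep the per-step cost of the two-cell protocols low on
a single core.
"""

import numpy as np
from numba import njit


@njit(cache=True)
def edge_forces_kernel(x, v, edges, quads, rest_theta, wlc_c, l_max, k_pow,
                       k_bend, eta_t, eta_c, out):
    """Spring (WLC + power-law), bending and viscous forces, fused per edge."""
    ne = edges.shape[0]
    for e in range(ne):
        i = edges[e, 0]
        j = edges[e, 1]
        dx = x[j, 0] - x[i, 0]
        dy = x[j, 1] - x[i, 1]
        dz = x[j, 2] - x[i, 2]
        l = np.sqrt(dx * dx + dy * dy + dz * dz)
        if l < 1e-300:
            l = 1e-300
        ex = dx / l
        ey = dy / l
        ez = dz / l
        # WLC + POW spring tension
        xr = l / l_max[e]
        if xr > 1.0 - 1e-9:
            xr = 1.0 - 1e-9
        omx = 1.0 - xr
        f_wlc = wlc_c[e] * (1.0 / (4.0 * omx * omx) - 0.25 + xr)
        tension = f_wlc - k_pow[e] / (l * l)
        fx = tension * ex
        fy = tension * ey
        fz = tension * ez
        # membrane viscosity
        vx = v[i, 0] - v[j, 0]
        vy = v[i, 1] - v[j, 1]
        vz = v[i, 2] - v[j, 2]
        vdot = vx * ex + vy * ey + vz * ez
        fvx = -eta_t * vx - eta_c * vdot * ex
        fvy = -eta_t * vy - eta_c * vdot * ey
        fvz = -eta_t * vz - eta_c * vdot * ez
        out[i, 0] += fx + fvx
        out[i, 1] += fy + fvy
        out[i, 2] += fz + fvz
        out[j, 0] += -fx - fvx
        out[j, 1] += -fy - fvy
        out[j, 2] += -fz - fvz
        # bending at interior edges
        k2 = quads[e, 2]
        k3 = quads[e, 3]
        if k2 < 0 or k3 < 0:
            continue
        x0x, x0y, x0z = x[i, 0], x[i, 1], x[i, 2]
        x1x, x1y, x1z = x[j, 0], x[j, 1], x[j, 2]
        x2x, x2y, x2z = x[k2, 0], x[k2, 1], x[k2, 2]
        x3x, x3y, x3z = x[k3, 0], x[k3, 1], x[k3, 2]
        # n1 = (x1-x0) x (x2-x0); n2 = (x3-x0) x (x1-x0)
        ax, ay, az = x1x - x0x, x1y - x0y, x1z - x0z
        bx, by, bz = x2x - x0x, x2y - x0y, x2z - x0z
        cx, cy, cz = x3x - x0x, x3y - x0y, x3z - x0z
        n1x = ay * bz - az * by
        n1y = az * bx - ax * bz
        n1z = ax * by - ay * bx
        n2x = cy * az - cz * ay
        n2y = cz * ax - cx * az
        n2z = cx * ay - cy * ax
        n1sq = n1x * n1x + n1y * n1y + n1z * n1z
        n2sq = n2x * n2x + n2y * n2y + n2z * n2z
        if n1sq < 1e-300:
            n1sq = 1e-300
        if n2sq < 1e-300:
            n2sq = 1e-300
        # theta = atan2((n1 x n2).ehat, n1.n2)
        cxx = n1y * n2z - n1z * n2y
        cyy = n1z * n2x - n1x * n2z
        czz = n1x * n2y - n1y * n2x
        s = (cxx * ex + cyy * ey + czz * ez)
        cdot = n1x * n2x + n1y * n2y + n1z * n2z
        theta = np.arctan2(s, cdot)
        dudt = k_bend * np.sin(theta - rest_theta[e])
        # projections (x2-x1).e/|e| etc.
        d12 = ((x2x - x1x) * dx + (x2y - x1y) * dy + (x2z - x1z) * dz) / l
        d02 = ((x2x - x0x) * dx + (x2y - x0y) * dy + (x2z - x0z) * dz) / l
        d13 = ((x3x - x1x) * dx + (x3y - x1y) * dy + (x3z - x1z) * dz) / l
        d03 = ((x3x - x0x) * dx + (x3y - x0y) * dy + (x3z - x0z) * dz) / l
        w1 = dudt / n1sq
        w2 = dudt / n2sq
        # f = dudt * (-dtheta/dx) per the sign convention of the angle
        out[i, 0] += w1 * d12 * n1x + w2 * d13 * n2x
        out[i, 1] += w1 * d12 * n1y + w2 * d13 * n2y
        out[i, 2] += w1 * d12 * n1z + w2 * d13 * n2z
        out[j, 0] += -(w1 * d02 * n1x + w2 * d03 * n2x)
        out[j, 1] += -(w1 * d02 * n1y + w2 * d03 * n2y)
        out[j, 2] += -(w1 * d02 * n1z + w2 * d03 * n2z)
        out[k2, 0] += w1 * l * n1x
        out[k2, 1] += w1 * l * n1y
        out[k2, 2] += w1 * l * n1z
        out[k3, 0] += w2 * l * n2x
        out[k3, 1] += w2 * l * n2y
        out[k3, 2] += w2 * l * n2z


@njit(cache=True)
def area_volume_forces_kernel(x, tris, rest_areas, rest_total_area,
                              rest_volume, ka, kd, k_omega, closed, out):
    """Global/local area penalty and volume penalty forces."""
    m = tris.shape[0]
    # pass 1: totals
    a_tot = 0.0
    vol = 0.0
    for t in range(m):
        ia, ib, ic = tris[t, 0], tris[t, 1], tris[t, 2]
        abx = x[ib, 0] - x[ia, 0]
        aby = x[ib, 1] - x[ia, 1]
        abz = x[ib, 2] - x[ia, 2]
        acx = x[ic, 0] - x[ia, 0]
        acy = x[ic, 1] - x[ia, 1]
        acz = x[ic, 2] - x[ia, 2]
        nx = aby * acz - abz * acy
        ny = abz * acx - abx * acz
        nz = abx * acy - aby * acx
        a_tot += 0.5 * np.sqrt(nx * nx + ny * ny + nz * nz)
        if closed:
            vol += (x[ia, 0] * (x[ib, 1] * x[ic, 2] - x[ib, 2] * x[ic, 1])
                    + x[ia, 1] * (x[ib, 2] * x[ic, 0] - x[ib, 0] * x[ic, 2])
                    + x[ia, 2] * (x[ib, 0] * x[ic, 1] - x[ib, 1] * x[ic, 0])) / 6.0
    ga_coef = ka * (a_tot - rest_total_area) / rest_total_area
    vcoef = 0.0
    if closed:
        vcoef = k_omega * (vol - rest_volume) / rest_volume
    # pass 2: gradients
    for t in range(m):
        ia, ib, ic = tris[t, 0], tris[t, 1], tris[t, 2]
        abx = x[ib, 0] - x[ia, 0]
        aby = x[ib, 1] - x[ia, 1]
        abz = x[ib, 2] - x[ia, 2]
        acx = x[ic, 0] - x[ia, 0]
        acy = x[ic, 1] - x[ia, 1]
        acz = x[ic, 2] - x[ia, 2]
        nx = aby * acz - abz * acy
        ny = abz * acx - abx * acz
        nz = abx * acy - aby * acx
        nn = np.sqrt(nx * nx + ny * ny + nz * nz)
        if nn < 1e-300:
            nn = 1e-300
        nhx, nhy, nhz = nx / nn, ny / nn, nz / nn
        area = 0.5 * nn
        coef = ga_coef + kd * (area - rest_areas[t]) / rest_areas[t]
        # dA/dx_a = 0.5 nhat x (c - b), cyclic
        cbx = x[ic, 0] - x[ib, 0]
        cby = x[ic, 1] - x[ib, 1]
        cbz = x[ic, 2] - x[ib, 2]
        out[ia, 0] += -coef * 0.5 * (nhy * cbz - nhz * cby)
        out[ia, 1] += -coef * 0.5 * (nhz * cbx - nhx * cbz)
        out[ia, 2] += -coef * 0.5 * (nhx * cby - nhy * cbx)
        out[ib, 0] += -coef * 0.5 * (nhy * (-acz) - nhz * (-acy))
        out[ib, 1] += -coef * 0.5 * (nhz * (-acx) - nhx * (-acz))
        out[ib, 2] += -coef * 0.5 * (nhx * (-acy) - nhy * (-acx))
        out[ic, 0] += -coef * 0.5 * (nhy * abz - nhz * aby)
        out[ic, 1] += -coef * 0.5 * (nhz * abx - nhx * abz)
        out[ic, 2] += -coef * 0.5 * (nhx * aby - nhy * abx)
        if closed:
            # dV/dx_a = (b x c)/6, cyclic
            out[ia, 0] += -vcoef / 6.0 * (x[ib, 1] * x[ic, 2] - x[ib, 2] * x[ic, 1])
            out[ia, 1] += -vcoef / 6.0 * (x[ib, 2] * x[ic, 0] - x[ib, 0] * x[ic, 2])
            out[ia, 2] += -vcoef / 6.0 * (x[ib, 0] * x[ic, 1] - x[ib, 1] * x[ic, 0])
            out[ib, 0] += -vcoef / 6.0 * (x[ic, 1] * x[ia, 2] - x[ic, 2] * x[ia, 1])
            out[ib, 1] += -vcoef / 6.0 * (x[ic, 2] * x[ia, 0] - x[ic, 0] * x[ia, 2])
            out[ib, 2] += -vcoef / 6.0 * (x[ic, 0] * x[ia, 1] - x[ic, 1] * x[ia, 0])
            out[ic, 0] += -vcoef / 6.0 * (x[ia, 1] * x[ib, 2] - x[ia, 2] * x[ib, 1])
            out[ic, 1] += -vcoef / 6.0 * (x[ia, 2] * x[ib, 0] - x[ia, 0] * x[ib, 2])
            out[ic, 2] += -vcoef / 6.0 * (x[ia, 0] * x[ib, 1] - x[ia, 1] * x[ib, 0])
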