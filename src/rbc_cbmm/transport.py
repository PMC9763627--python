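"""Surface convection-diffusion of the mobile fibrinogen cross-bridge field.

The normalized mobile-Fg density N lives at mesh vertices and evolves by

    dN/dt = D ∇² N − ∇·(V_drift N) + S_adsorp

solved in the material frame of the moving membrane (mesh vertices are
Lagrangian markers, so only the drift *relative to the surface* convects the
field).  Spatial discretization is a finite-volume scheme on the median-dual
cells: cotangent-weighted surface Laplacian for diffusion and first-order
upwind fluxes across dual edges for the drift.  Fluxes are antisymmetric, so
with the adsorption source off the total amount Σ N_i A_i is conserved to
rounding.

The drift velocity is the phenomenological sliding of adsorbed mFg relative
to its adsorption surface caused by intercellular Couette friction: it
interpolates linearly from half of the neighbouring-surface relative
velocity at zero gap to zero once the gap clears the mFg hydrodynamic size.
The adsorption source exchanges mFg with the bulk plasma on exposed surface
regions, balancing a constant recruitment flux against a diffusive
bulk-to-surface flux so that the initial equilibrium has zero net exchange.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError, StateError
from .geometry import (ContactMap, cross3, median_dual_areas, norm_rows,
                       scatter_add, vertex_normals)

_logged_substep_warning = False


@dataclass
class TransportParams:
    """Mobile-Fg transport constants (SI)."""

    d_mfg: float = 1e-15          # surface diffusivity [m^2/s]
    delta_fg: float = 45e-9       # mFg hydrodynamic size [m]
    adsorption_on: bool = False
    phi0: float = 0.001           # surface-to-bulk ratio at equilibrium [-]
    n0: float = 1.0               # initial/equilibrium surface density [-]
    nb_fg: float | None = None    # bulk density [-]; defaults to n0/phi0

    def __post_init__(self):
        if self.d_mfg < 0:
            raise ConfigurationError("d_mfg must be non-negative")
        if self.delta_fg <= 0:
            raise ConfigurationError("delta_fg must be positive")
        if self.adsorption_on:
            if self.phi0 <= 0:
                raise ConfigurationError("phi0 must be positive")
            if self.nb_fg is None:
                self.nb_fg = self.n0 / self.phi0
            elif abs(self.phi0 - self.n0 / self.nb_fg) > 1e-9 * self.phi0:
                raise ConfigurationError(
                    "phi0 inconsistent with n0 / nb_fg")


def cotan_weights(mesh, positions: np.ndarray,
                  clamp_negative: bool = True) -> np.ndarray:
    """Per-edge cotangent weights (cot a + cot b)/2 of the two opposite angles.

    Negative weights (obtuse configurations) are clamped to zero by default
    so the explicit diffusion operator satisfies the maximum principle.
    """
    quads = mesh.edge_quads
    w = np.zeros(len(quads))
    for slot in (2, 3):
        has = quads[:, slot] >= 0
        o = positions[quads[has, slot]]
        u = positions[quads[has, 0]] - o
        v = positions[quads[has, 1]] - o
        sin = norm_rows(cross3(u, v))
        cos = np.einsum("ij,ij->i", u, v)
        w[has] += 0.5 * cos / np.maximum(sin, 1e-300)
    if clamp_negative:
        np.maximum(w, 0.0, out=w)
    return w


def drift_velocity(body, contact: ContactMap, params: TransportParams,
                   r_glyco: float, normals: np.ndarray | None = None,
                   ) -> np.ndarray:
    """Friction-induced tangential drift of adsorbed mFg [m/s].

    V_drift = 0.5 (V_neighbor − V_surface) (δ_Fg − δ_gap)/δ_Fg for
    δ_gap < δ_Fg, zero otherwise, projected onto the local tangent plane.
    δ_gap = r_sep − 2 r_glyco (clamped at 0 for the weight).
    """
    if contact is None:
        raise StateError("drift_velocity requires a current contact map")
    n = len(body.positions)
    out = np.zeros((n, 3))
    has = (contact.tri_index >= 0) & np.isfinite(contact.r_vts)
    dgap = contact.r_vts - 2.0 * r_glyco
    active = has & (dgap < params.delta_fg)
    if not active.any():
        return out
    w = np.flatnonzero(active)
    weight = (params.delta_fg - np.maximum(dgap[w], 0.0)) / params.delta_fg
    weight = np.clip(weight, 0.0, 1.0)
    v_rel = contact.v_neighbor[w] - body.velocities[w]
    v = 0.5 * weight[:, None] * v_rel
    nrm = (vertex_normals(body.mesh, body.positions)
           if normals is None else normals)[w]
    v -= np.einsum("ij,ij->i", v, nrm)[:, None] * nrm
    out[w] = v
    return out


def adsorption_source(n_density: np.ndarray, contact: ContactMap | None,
                      params: TransportParams) -> np.ndarray:
    """Net bulk-to-surface mFg exchange rate S_adsorp [1/s] per vertex.

    S = J_constant + J_diffus on exposed surface (r_sep ≥ δ_Fg, including
    vertices with no pairing contact at all); zero in the tight gap.
    J_constant = D N0 (φ0 − 1) / (φ0 (1.4 δ_Fg)²) and
    J_diffus = −D (N φ0 − N0) / (φ0 (1.4 δ_Fg)²), so S vanishes identically
    at N = N0.
    """
    if not params.adsorption_on:
        return np.zeros_like(n_density)
    if params.phi0 <= 0:
        raise ConfigurationError("phi0 must be positive")
    layer = (1.4 * params.delta_fg) ** 2
    j_const = (params.d_mfg * params.n0 * (params.phi0 - 1.0)
               / (params.phi0 * layer))
    j_diff = -(params.d_mfg * (n_density * params.phi0 - params.n0)
               / (params.phi0 * layer))
    s = j_const + j_diff
    if contact is not None:
        tight = ((contact.tri_index >= 0)
                 & (contact.r_vts < params.delta_fg))
        s = np.where(tight, 0.0, s)
    return s


def transport_step(body, drift: np.ndarray, source: np.ndarray, dt: float,
                   params: TransportParams) -> np.ndarray:
    """Advance the mobile-Fg density one step; returns the updated field.

    Finite-volume update of the amount N_i A_i on median-dual control
    volumes; internally sub-steps to respect the explicit diffusion/CFL
    positivity bound.  The body's ``mfg_density`` is updated in place.
    """
    global _logged_substep_warning
    if dt <= 0:
        raise ConfigurationError("dt must be positive")
    mesh = body.mesh
    x = body.positions
    n_field = body.mfg_density.astype(float, copy=True)
    areas = median_dual_areas(mesh, x)
    w_cot = cotan_weights(mesh, x)
    i, j = mesh.edges[:, 0], mesh.edges[:, 1]
    evec = x[j] - x[i]
    elen = np.maximum(norm_rows(evec), 1e-300)
    ehat = evec / elen[:, None]

    d_coef = params.d_mfg * w_cot                       # [m^2/s] per edge
    conv = np.zeros(len(i))
    if drift is not None:
        v_edge = 0.5 * np.einsum("ij,ij->i", drift[i] + drift[j], ehat)
        conv = v_edge * w_cot * elen                    # dual-edge flux rate

    # positivity bound: amount_i must stay >= 0 under explicit outflow
    out_coef = np.zeros(len(areas))
    scatter_add(out_coef, i, d_coef + np.maximum(conv, 0.0))
    scatter_add(out_coef, j, d_coef + np.maximum(-conv, 0.0))
    with np.errstate(divide="ignore"):
        dt_bound = 0.9 * np.min(np.where(out_coef > 0,
                                         areas / np.maximum(out_coef, 1e-300),
                                         np.inf))
    n_sub = max(1, int(np.ceil(dt / dt_bound))) if np.isfinite(dt_bound) else 1
    if n_sub > 1 and not _logged_substep_warning:
        _logged_substep_warning = True
    sub_dt = dt / n_sub

    src_amt = source * areas if source is not None else 0.0
    for _ in range(n_sub):
        diff_flux = d_coef * (n_field[j] - n_field[i])  # amount/s, i<-j positive
        upwind = np.where(conv > 0, n_field[i], n_field[j])
        conv_flux = conv * upwind                        # amount/s, i->j positive
        rate = np.zeros(len(areas))
        scatter_add(rate, i, diff_flux - conv_flux)
        scatter_add(rate, j, -diff_flux + conv_flux)
        amount = n_field * areas + sub_dt * (rate + src_amt)
        n_field = amount / areas
    if (n_field < 0).any():
        # upwinding should prevent this; clamp defensively
        n_field = np.maximum(n_field, 0.0)
    body.mfg_density = n_field
    return n_field


def average_gap_density(bodies, contacts) -> float:
    """Area-weighted mean gap bridge density N_ave over in-contact vertices.

    For each cell's in-contact vertices the gap density is its own N plus
    the pairing surface's N interpolated at the nearest point; the average
    weights by median-dual area over both cells.  Returns NaN when there is
    no contact.
    """
    total_w = 0.0
    total = 0.0
    pairs = [(bodies[0], bodies[1], contacts[0]),
             (bodies[1], bodies[0], contacts[1])]
    for src, tgt, cm in pairs:
        if cm is None:
            continue
        w = np.flatnonzero(cm.within_cutoff & (cm.tri_index >= 0))
        if not w.size:
            continue
        tri = tgt.mesh.triangles[cm.tri_index[w]]
        n_loc = (src.mfg_density[w]
                 + np.einsum("nk,nk->n", cm.bary[w], tgt.mfg_density[tri]))
        a = median_dual_areas(src.mesh, src.positions)[w]
        total += float((n_loc * a).sum())
        total_w += float(a.sum())
    if total_w == 0.0:
        return float("nan")
    return total / total_w
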