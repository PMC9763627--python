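"""Cross-bridge adhesion and intercellular friction forces.

Adhesion between the two cells is a Morse-type potential evaluated at mesh
vertices, with the affinity composed of three cross-bridge populations:

* specific receptor-bound bridges (iFgRB), acting along the vertex-to-vertex
  (VTV) direction;
* immobile non-specific bridges (iFgB), acting along the vertex-to-surface
  (VTS) normal-distance direction;
* mobile non-specific bridges (mFgB), also VTS, scaled by the local mobile
  fibrinogen density summed over both surfaces.

Intercellular friction assumes a Couette flow profile of the gap plasma
between the sliding surfaces, reduced by the glycocalyx height on each cell,
and opposes the tangential relative surface velocity.

Both interactions are evaluated per vertex with the median-dual area as the
local interaction area, and the reaction is distributed to the pairing
surface (barycentrically onto the nearest element for VTS, onto the partner
vertex for VTV) so that the pair conserves linear momentum exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError, StateError
from .geometry import ContactMap, median_dual_areas, scatter_add, vertex_normals


@dataclass
class AdhesionParams:
    """Cross-bridge affinities, Morse constants and friction constants (SI)."""

    gamma_ifgr: float = 0.0       # specific-bridge affinity [J/m^2] (VTV)
    gamma_ifg: float = 0.0        # immobile non-specific affinity [J/m^2] (VTS)
    gamma_mfg: float = 0.0        # mobile non-specific affinity per unit density [J/m^2]
    beta: float = 0.05e9          # Morse spatial decay [1/m]
    r0: float = 20e-9             # zero-force separation [m]
    r_cutoff: float = 100e-9      # interaction cutoff [m]
    r_glyco: float = 5e-9         # glycocalyx height [m]
    mu_gap: float = 3.6e-3        # intercellular gap plasma viscosity [Pa s]
    eps_gap: float = 1e-9         # lower clamp on the Couette gap [m]
    scheme: str = "vts"           # bookkeeping: dominant scheme of the run

    def __post_init__(self):
        if min(self.gamma_ifgr, self.gamma_ifg, self.gamma_mfg) < 0:
            raise ConfigurationError("affinities must be non-negative")
        if not (0 < self.r0 < self.r_cutoff):
            raise ConfigurationError("need 0 < r0 < r_cutoff")
        if self.beta <= 0:
            raise ConfigurationError("beta must be positive")
        if self.mu_gap < 0 or self.r_glyco < 0 or self.eps_gap <= 0:
            raise ConfigurationError("invalid friction constants")


@dataclass
class PathophysParams:
    """Multipliers mapping plasma fibrinogen status onto the baseline model.

    ``n_star`` scales the equilibrium surface density of adsorbed mobile Fg,
    ``gamma_star`` scales the per-density mobile affinity; both equal 1 for
    the healthy lower-limit reference.
    """

    n_star: float = 1.0
    gamma_star: float = 1.0
    n_b_rbc1: float = 1.0         # baseline surface density on RBC1 [-]
    n_b_rbc2: float = 1.0
    gamma_mfg_b: float = 0.25e-6  # baseline mobile affinity [J/m^2]

    def __post_init__(self):
        if self.n_star <= 0 or self.gamma_star <= 0:
            raise ConfigurationError("n_star and gamma_star must be positive")


def total_affinity(params: AdhesionParams, n1, n2):
    """Total adhesion affinity Γ_affin = Γ_iFgR + Γ_iFg + (N1+N2)·Γ_mFg.

    ``n1``/``n2`` are the mobile-Fg densities contributed by the two
    surfaces (scalars or arrays).  With Γ_mFg = 0 this reduces to the
    uniform affinity model (UAM).
    """
    n1 = np.asarray(n1, dtype=float)
    n2 = np.asarray(n2, dtype=float)
    if (n1 < 0).any() or (n2 < 0).any():
        raise StateError("negative mobile-Fg density")
    out = params.gamma_ifgr + params.gamma_ifg + (n1 + n2) * params.gamma_mfg
    return float(out) if out.ndim == 0 else out


def pathophys_affinity(p: PathophysParams, gamma_ifg: float,
                       ) -> tuple[float, float]:
    """Initial affinity and starting gap density for a pathophysiology case.

    Γ_affin = Γ_iFg + N*·(N_b,1 + N_b,2)·Γ*·Γ_mFg,b.  The second return
    value N_ave,t0 = N*·(N_b,1 + N_b,2) is the equilibrium gap density used
    to initialize the per-surface fields (N_ave,t0 / 2 on each cell).
    """
    nave_t0 = p.n_star * (p.n_b_rbc1 + p.n_b_rbc2)
    gamma = gamma_ifg + nave_t0 * p.gamma_star * p.gamma_mfg_b
    return float(gamma), float(nave_t0)


def morse_energy(rsep, gamma, beta, r0, rcutoff, area):
    """Morse-type interaction energy at a vertex [J].

    U = Γ [e^{2β(r0−r)} − 2 e^{β(r0−r)}] A_i for r ≤ r_cutoff, else 0;
    the well depth at r = r0 is Γ·A_i.
    """
    rsep = np.asarray(rsep, dtype=float)
    d = beta * (r0 - rsep)
    u = gamma * (np.exp(2.0 * d) - 2.0 * np.exp(d)) * area
    out = np.where(rsep <= rcutoff, u, 0.0)
    return float(out) if out.ndim == 0 else out


def morse_force_magnitude(rsep, gamma, beta, r0, rcutoff, area):
    """Signed Morse force magnitude along the approach direction [N].

    F = Γ A_i [2β e^{β(r0−r)} − 2β e^{2β(r0−r)}] (= −dU/dr); positive values
    attract (force toward the pairing surface), negative repel.  Zero beyond
    the cutoff.
    """
    rsep = np.asarray(rsep, dtype=float)
    d = beta * (r0 - rsep)
    f = gamma * area * 2.0 * beta * (np.exp(d) - np.exp(2.0 * d))
    out = np.where(rsep <= rcutoff, f, 0.0)
    return float(out) if out.ndim == 0 else out


def _one_sided_adhesion(src_body, tgt_body, contact: ContactMap,
                        params: AdhesionParams, src_areas: np.ndarray):
    """Adhesion force on source vertices + reaction on the target surface."""
    n_src = len(src_body.positions)
    n_tgt = len(tgt_body.positions)
    f_src = np.zeros((n_src, 3))
    f_tgt = np.zeros((n_tgt, 3))

    # --- VTS terms (immobile + mobile non-specific) ----------------------
    if params.gamma_ifg > 0 or params.gamma_mfg > 0:
        ws = np.flatnonzero((contact.tri_index >= 0)
                            & (contact.r_vts <= params.r_cutoff))
        if ws.size:
            tri = tgt_body.mesh.triangles[contact.tri_index[ws]]
            bary = contact.bary[ws]
            n_loc = (src_body.mfg_density[ws]
                     + np.einsum("nk,nk->n", bary, tgt_body.mfg_density[tri]))
            gamma = params.gamma_ifg + n_loc * params.gamma_mfg
            mag = morse_force_magnitude(contact.r_vts[ws], gamma, params.beta,
                                        params.r0, params.r_cutoff,
                                        src_areas[ws])
            fvec = mag[:, None] * contact.e_vts[ws]
            f_src[ws] += fvec
            for k in range(3):
                scatter_add(f_tgt, tri[:, k], -bary[:, k, None] * fvec)

    # --- VTV term (specific bridges) --------------------------------------
    if params.gamma_ifgr > 0:
        wv = np.flatnonzero((contact.vtv_index >= 0)
                            & (contact.r_vtv <= params.r_cutoff))
        if wv.size:
            mag = morse_force_magnitude(contact.r_vtv[wv], params.gamma_ifgr,
                                        params.beta, params.r0,
                                        params.r_cutoff, src_areas[wv])
            fvec = mag[:, None] * contact.e_vtv[wv]
            f_src[wv] += fvec
            scatter_add(f_tgt, contact.vtv_index[wv], -fvec)

    return f_src, f_tgt


def adhesion_forces(body_a, body_b, contact_ab: ContactMap,
                    params: AdhesionParams,
                    contact_ba: ContactMap | None = None,
                    areas_a: np.ndarray | None = None,
                    areas_b: np.ndarray | None = None):
    """Cross-bridge adhesion forces on both bodies [N].

    With both contact maps the interaction is symmetrized: each one-sided
    evaluation (source-vertex force + momentum-conserving reaction on the
    pairing surface) is averaged with the roles swapped, so both cells'
    vertices carry the per-vertex Morse force and the pair conserves
    momentum exactly.  With only ``contact_ab`` the one-sided force plus
    reaction is returned.
    """
    if contact_ab is None:
        raise StateError("adhesion_forces requires a current contact map")
    if areas_a is None:
        areas_a = median_dual_areas(body_a.mesh, body_a.positions)
    if areas_b is None:
        areas_b = median_dual_areas(body_b.mesh, body_b.positions)
    fa, fb = _one_sided_adhesion(body_a, body_b, contact_ab, params, areas_a)
    if contact_ba is None:
        return fa, fb
    fb2, fa2 = _one_sided_adhesion(body_b, body_a, contact_ba, params, areas_b)
    return 0.5 * (fa + fa2), 0.5 * (fb + fb2)


def _one_sided_friction(src_body, tgt_body, contact: ContactMap,
                        params: AdhesionParams, src_areas: np.ndarray,
                        src_normals: np.ndarray):
    n_src = len(src_body.positions)
    n_tgt = len(tgt_body.positions)
    f_src = np.zeros((n_src, 3))
    f_tgt = np.zeros((n_tgt, 3))
    if params.mu_gap <= 0:
        return f_src, f_tgt
    w = np.flatnonzero((contact.tri_index >= 0)
                       & (contact.r_vts <= params.r_cutoff))
    if not w.size:
        return f_src, f_tgt
    tri = tgt_body.mesh.triangles[contact.tri_index[w]]
    bary = contact.bary[w]
    v_nb = np.einsum("nk,nkj->nj", bary, tgt_body.velocities[tri])
    v_rel = src_body.velocities[w] - v_nb
    nrm = src_normals[w]
    v_tan = v_rel - np.einsum("ij,ij->i", v_rel, nrm)[:, None] * nrm
    gap = np.maximum(contact.r_vts[w] - 2.0 * params.r_glyco, params.eps_gap)
    fvec = -(params.mu_gap * src_areas[w] / gap)[:, None] * v_tan
    f_src[w] += fvec
    for k in range(3):
        scatter_add(f_tgt, tri[:, k], -bary[:, k, None] * fvec)
    return f_src, f_tgt


def friction_forces(body_a, body_b, contact_ab: ContactMap,
                    params: AdhesionParams,
                    contact_ba: ContactMap | None = None,
                    areas_a: np.ndarray | None = None,
                    areas_b: np.ndarray | None = None,
                    normals_a: np.ndarray | None = None,
                    normals_b: np.ndarray | None = None):
    """Intercellular Couette friction forces on both bodies [N].

    Per interacting vertex (within the adhesion cutoff) the tangential
    relative velocity v_ij − (v_ij·n̂)n̂ is opposed by the Couette shear
    stress μ_gap |v_t| / (r_sep − 2 r_glyco), converted to a nodal force by
    the median-dual area; the gap denominator is clamped below at
    ``eps_gap``.  Symmetrized like :func:`adhesion_forces`.
    """
    if contact_ab is None:
        raise StateError("friction_forces requires a current contact map")
    if areas_a is None:
        areas_a = median_dual_areas(body_a.mesh, body_a.positions)
    if normals_a is None:
        normals_a = vertex_normals(body_a.mesh, body_a.positions)
    fa, fb = _one_sided_friction(body_a, body_b, contact_ab, params,
                                 areas_a, normals_a)
    if contact_ba is None:
        return fa, fb
    if areas_b is None:
        areas_b = median_dual_areas(body_b.mesh, body_b.positions)
    if normals_b is None:
        normals_b = vertex_normals(body_b.mesh, body_b.positions)
    fb2, fa2 = _one_sided_friction(body_b, body_a, contact_ba, params,
                                   areas_b, normals_b)
    return 0.5 * (fa + fa2), 0.5 * (fb + fb2)
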