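"""Canonical desk-scale study runs of the published protocol conditions.

These helpers bundle the parameter sets of the formation groups, the
disaggregation comparisons and the pathophysiology cases with the package's
scaled-down numerical conditions (coarse mesh, resolution-scaled interaction
reach, shortened windows).  The same functions back the acceptance script
and the protocol-level tests, so every headline number is produced by one
code path.
"""

from __future__ import annotations

from .adhesion import AdhesionParams, PathophysParams, pathophys_affinity
from .mechanics import MembraneParams
from .protocols import (
    ProtocolConfig,
    Trajectory,
    formation_rate,
    resolution_scaled,
    resolution_scaled_transport,
    run_doublet_formation,
    run_ot_disaggregation,
)
from .geometry import build_discocyte_mesh
from .transport import TransportParams

# friction-optimized interaction constants shared by every baseline run
FRICTION_OPTIMIZED = dict(beta=0.05e9, r0=20e-9, r_cutoff=100e-9,
                          r_glyco=5e-9, mu_gap=3.6e-3)

# desk-scale defaults: coarse mesh and shortened windows (full-resolution
# reference conditions are ~5000 vertices and 40 s formation windows)
N_VERTICES = 642
FORMATION_WINDOW = 24.0
DISAGG_WINDOW = 40.0


def _scaled(params: AdhesionParams, n_vertices: int,
            transport: TransportParams | None = None):
    mesh = build_discocyte_mesh(n_vertices)
    adh = resolution_scaled(params, mesh)
    if transport is None:
        return adh, None
    return adh, resolution_scaled_transport(transport, mesh)


def formation_case(gamma_affin_uj: float, scheme: str = "mobile",
                   n_vertices: int = N_VERTICES,
                   duration: float = FORMATION_WINDOW,
                   seed: int | None = None) -> Trajectory:
    """One doublet-formation run at total affinity ``gamma_affin_uj`` uJ/m².

    ``scheme`` selects the cross-bridge population carrying the affinity:
    ``"mobile"`` (mFgB on VTS with unit starting densities, the migrating
    cross-bridge case), ``"immobile"`` (iFgB on VTS, uniform affinity) or
    ``"specific"`` (iFgRB on VTV).
    """
    gamma = gamma_affin_uj * 1e-6
    if scheme == "mobile":
        adh = AdhesionParams(gamma_mfg=gamma / 2.0, **FRICTION_OPTIMIZED)
        nave0 = 2.0
        transport = TransportParams(d_mfg=1e-15)
    elif scheme == "immobile":
        adh = AdhesionParams(gamma_ifg=gamma, **FRICTION_OPTIMIZED)
        nave0 = 0.0
        transport = None
    elif scheme == "specific":
        # VTV keeps the physical reach: the cutoff-to-receptor-spacing ratio
        # is the modeled physics (sparse receptors cannot recruit), so the
        # zipper-motivated reach scaling must not apply here.
        adh = AdhesionParams(gamma_ifgr=gamma, **FRICTION_OPTIMIZED)
        cfg = ProtocolConfig(protocol="formation", duration=duration,
                             n_vertices=n_vertices, snapshot_interval=0.25,
                             nave0=0.0, rng_seed=seed)
        return run_doublet_formation(cfg, MembraneParams(), adh, None)
    else:
        raise ValueError(f"unknown scheme {scheme!r}")
    adh, transport = _scaled(adh, n_vertices, transport)
    cfg = ProtocolConfig(protocol="formation", duration=duration,
                         n_vertices=n_vertices, snapshot_interval=0.25,
                         nave0=nave0, rng_seed=seed)
    return run_doublet_formation(cfg, MembraneParams(), adh, transport)


def formation_rate_case(gamma_affin_uj: float, **kw) -> float:
    """Average overlap-growth rate [m/s] for one formation run."""
    return formation_rate(formation_case(gamma_affin_uj, **kw))


def disaggregation_case(kind: str, n_vertices: int = N_VERTICES,
                        duration: float = DISAGG_WINDOW,
                        escape_threshold: float | None = None,
                        seed: int | None = None,
                        equilibration: float = 1.5) -> Trajectory:
    """One optical-tweezers disaggregation run.

    Kinds: ``"uam"`` (uniform affinity 1.5 uJ/m², no mobile bridges),
    ``"cbmm_low_d"`` / ``"cbmm_high_d"`` (mobile bridges at diffusivity
    1e-15 / 1.8e-11 m²/s, initial affinity 1.5 uJ/m²), and the
    pathophysiology cases ``"healthy_lower"``, ``"healthy_median"``,
    ``"healthy_upper"``, ``"sle_median"``.
    """
    patho = {
        "healthy_lower": (1.0, 1.0),
        "healthy_median": (1.25, 1.0),
        "healthy_upper": (1.5, 1.0),
        "sle_median": (1.5, 2.0),
    }
    transport = None
    if kind == "uam":
        adh = AdhesionParams(gamma_ifg=1.5e-6, **FRICTION_OPTIMIZED)
        nave0 = 0.0
    elif kind in ("cbmm_low_d", "cbmm_high_d"):
        adh = AdhesionParams(gamma_ifg=1e-6, gamma_mfg=0.25e-6,
                             **FRICTION_OPTIMIZED)
        nave0 = 2.0
        d = 1e-15 if kind == "cbmm_low_d" else 1.8e-11
        transport = TransportParams(d_mfg=d)
    elif kind in patho:
        n_star, g_star = patho[kind]
        pp = PathophysParams(n_star=n_star, gamma_star=g_star,
                             gamma_mfg_b=0.25e-6)
        _, nave0 = pathophys_affinity(pp, 1e-6)
        adh = AdhesionParams(gamma_ifg=1e-6, gamma_mfg=0.25e-6 * g_star,
                             **FRICTION_OPTIMIZED)
        transport = TransportParams(d_mfg=1e-15, adsorption_on=True,
                                    phi0=0.001, n0=nave0 / 2.0)
    else:
        raise ValueError(f"unknown disaggregation kind {kind!r}")
    adh, transport = _scaled(adh, n_vertices, transport)
    cfg = ProtocolConfig(protocol="disaggregation", duration=duration,
                         n_vertices=n_vertices, snapshot_interval=0.1,
                         pulling_rate=0.15e-6, nave0=nave0,
                         escape_threshold=escape_threshold,
                         equilibration=equilibration, rng_seed=seed,
                         initial_offset_fraction=0.3)
    return run_ot_disaggregation(cfg, MembraneParams(), adh, transport)
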