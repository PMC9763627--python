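"""Doublet formation and optical-tweezers disaggregation protocols.

Two in-silico experiments drive the model:

* **formation** — two discocytes are initialized near point contact
  (face-to-face, laterally offset) at the zero-force separation and evolve
  under adhesion + intercellular friction with no external load.  The
  readout is the growth of the silhouette overlap and adhesive contact area.

* **disaggregation** — an equilibrated doublet with a prescribed crescent
  overlap is pulled apart by displacing a distal vertex patch on each cell
  at a fixed rate in opposite directions along the sliding axis (a kinematic
  optical-trap constraint).  The trap tension F_OT is the constraint
  reaction force; the run ends at complete separation or at a configured
  escape threshold.

Trajectories carry the trap tension, axial adhesion force, contact area,
overlap length and average gap bridge density against time and applied
displacement.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .adhesion import AdhesionParams, adhesion_forces, friction_forces
from .errors import ConfigurationError, StateError
from .geometry import (
    ContactTracker,
    build_discocyte_mesh,
    contact_query,
    mean_vertex_spacing,
    median_dual_areas,
    vertex_normals,
)
from .mechanics import MembraneParams, RBCBody, integrate_step, stable_dt
from .transport import (
    TransportParams,
    adsorption_source,
    average_gap_density,
    drift_velocity,
    transport_step,
)


@dataclass
class ProtocolConfig:
    """Settings of one protocol run (SI units)."""

    protocol: str = "formation"           # "formation" | "disaggregation"
    duration: float = 16.0                # simulated physical time [s]
    dt: float | None = None               # mechanics step; None -> stable_dt
    pulling_rate: float = 0.15e-6         # per trap, opposite directions [m/s]
    trap_patch_fraction: float = 0.02     # distal cap area fraction per cell
    escape_threshold: float | None = None # stop when F_OT exceeds this [N]
    initial_offset_fraction: float | None = None  # x offset / cell diameter
    initial_tilt_deg: float | None = None  # relative tilt of the second cell
    initial_gap: float | None = None      # starting min separation [m]
    snapshot_interval: float = 0.05       # trajectory sampling interval [s]
    equilibration: float = 1.0            # pre-pull relaxation [s]
    n_vertices: int = 642
    cell_diameter: float = 7.8e-6
    transport_stride: int = 5             # mechanics steps per transport step
    contact_reassign_every: int = 24
    nave0: float = 2.0                    # starting gap density N_ave,t0
    rng_seed: int | None = None           # optional initial perturbation seed
    perturbation: float = 0.0             # vertex noise amplitude [m]

    def __post_init__(self):
        if self.protocol not in ("formation", "disaggregation"):
            raise ConfigurationError(f"unknown protocol {self.protocol!r}")
        if self.duration <= 0:
            raise ConfigurationError("duration must be positive")
        if self.pulling_rate < 0:
            raise ConfigurationError("pulling_rate must be non-negative")


@dataclass
class Trajectory:
    """Time series of a protocol run plus run metadata."""

    data: pd.DataFrame
    meta: dict = field(default_factory=dict)

    def __len__(self):
        return len(self.data)

    def to_csv(self, path):
        self.data.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, meta=None):
        return cls(pd.read_csv(path), meta or {})


# mean adhesion-vertex spacing of the reference-resolution (~5000 vertex)
# discocyte; coarser meshes scale the interaction reach relative to this
REFERENCE_SPACING = 183e-9


def resolution_scaled(params: AdhesionParams, mesh) -> AdhesionParams:
    """Scaled-down adhesion constants for a coarse mesh.

    Contact growth proceeds by a zipping front: a vertex just outside the
    contact line must lie within the Morse cutoff to be captured, so the
    interaction reach must track the vertex spacing.  For meshes coarser
    than the reference resolution, ``r_cutoff`` and the Morse decay length
    1/β are stretched by the spacing ratio.  The affinity (adhesion energy
    per area), the zero-force separation and the friction constants are
    left untouched, so the energetics and the Couette gap physics are
    preserved; only the reach is coarsened.  At reference resolution this
    is the identity.
    """
    from dataclasses import replace

    rv = mean_vertex_spacing(mesh)
    s = rv / REFERENCE_SPACING
    if s <= 1.0:
        return params
    return replace(params, r_cutoff=params.r_cutoff * s, beta=params.beta / s)


def resolution_scaled_transport(params: TransportParams, mesh,
                                ) -> TransportParams:
    """Scaled-down transport constants for a coarse mesh.

    Stretching the Morse reach (see :func:`resolution_scaled`) dilates the
    separation distribution inside the contact, so the gap-law length that
    demarcates in-gap from exposed surface — the mobile-Fg hydrodynamic
    size δ_Fg entering the drift weight and the adsorption switch — must
    stretch by the same factor to keep the fraction of the contact subject
    to friction drift at its reference-resolution value.  Diffusivity and
    equilibrium densities are untouched.
    """
    from dataclasses import replace

    rv = mean_vertex_spacing(mesh)
    s = rv / REFERENCE_SPACING
    if s <= 1.0:
        return params
    return replace(params, delta_fg=params.delta_fg * s)


# ---------------------------------------------------------------------------
# doublet assembly
# ---------------------------------------------------------------------------

def doublet_shift(mesh, offset_x: float, gap: float,
                  tilt_deg: float = 0.0) -> np.ndarray:
    """Translation placing a (possibly tilted) copy of ``mesh`` at x offset
    with minimum inter-surface separation ``gap`` above the original."""
    vb = _tilted_vertices(mesh, tilt_deg)

    class _Probe:
        def __init__(self, pos):
            self.mesh = mesh
            self.positions = pos
            self.velocities = np.zeros_like(pos)

    base = mesh.vertices
    thickness = base[:, 2].max() - base[:, 2].min()
    z = thickness + gap
    a = _Probe(base)
    big = 10.0 * (thickness + abs(offset_x))
    for _ in range(10):
        b = _Probe(vb + np.array([offset_x, 0.0, z]))
        d1 = contact_query(a, b, big, "vts").r_vts.min()
        d2 = contact_query(b, a, big, "vts").r_vts.min()
        d = min(d1, d2)
        if abs(d - gap) < 0.005 * gap:
            break
        z += (gap - d)
    return np.array([offset_x, 0.0, z])


def _tilted_vertices(mesh, tilt_deg: float) -> np.ndarray:
    if not tilt_deg:
        return mesh.vertices
    th = np.radians(tilt_deg)
    rot = np.array([[np.cos(th), 0.0, np.sin(th)],
                    [0.0, 1.0, 0.0],
                    [-np.sin(th), 0.0, np.cos(th)]])
    return mesh.vertices @ rot.T


def make_doublet(config: ProtocolConfig, membrane: MembraneParams,
                 adhesion: AdhesionParams) -> tuple[RBCBody, RBCBody]:
    """Build the two-cell starting state of a protocol.

    Both cells share one discocyte mesh (stress-free reference); the second
    is placed above the first at an x offset with minimum separation equal
    to the zero-force distance (or ``initial_gap``).  For the formation
    protocol the second cell is tilted by default (25 degrees about the y
    axis) so the two faces meet in a near point contact that can close by
    face-on-face zipping, the configuration from which spontaneous sliding
    growth proceeds; the disaggregation protocol starts from an untilted
    crescent overlap.  Each surface starts with the uniform mobile-Fg
    density N_ave,t0 / 2.
    """
    mesh = build_discocyte_mesh(config.n_vertices, config.cell_diameter)
    frac = config.initial_offset_fraction
    tilt = config.initial_tilt_deg
    if frac is None:
        frac = 0.85 if config.protocol == "formation" else 0.5
    if tilt is None:
        tilt = 25.0 if config.protocol == "formation" else 0.0
    gap = config.initial_gap if config.initial_gap is not None else adhesion.r0
    shift = doublet_shift(mesh, frac * config.cell_diameter, gap, tilt)
    n0 = config.nave0 / 2.0
    body_a = RBCBody(mesh, membrane, mfg_density=np.full(mesh.n_vertices, n0))
    body_b = RBCBody(mesh, membrane,
                     positions=_tilted_vertices(mesh, tilt) + shift,
                     mfg_density=np.full(mesh.n_vertices, n0))
    if config.perturbation > 0 and config.rng_seed is not None:
        rng = np.random.default_rng(config.rng_seed)
        for b in (body_a, body_b):
            b.positions = b.positions + rng.normal(
                scale=config.perturbation, size=b.positions.shape)
    return body_a, body_b


def _trap_patches(bodies, fraction: float):
    """Distal vertex patches along the x (sliding) axis, ~``fraction`` of the
    cell area each; cell A's patch at its far −x end, cell B's at +x."""
    out = []
    for body, sign in zip(bodies, (-1.0, 1.0)):
        areas = median_dual_areas(body.mesh, body.positions)
        order = np.argsort(sign * body.positions[:, 0])[::-1]
        target = fraction * areas.sum()
        acc = np.cumsum(areas[order])
        k = max(1, int(np.searchsorted(acc, target) + 1))
        out.append(np.sort(order[:k]))
    return out


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def contact_area(bodies, contacts) -> float:
    """Adhesive contact area: Σ A_i over in-cutoff vertices, averaged over
    the two cells [m²]."""
    vals = []
    for body, cm in zip(bodies, contacts):
        if cm is None:
            vals.append(0.0)
            continue
        w = cm.within_cutoff & (cm.tri_index >= 0)
        if not w.any():
            vals.append(0.0)
            continue
        a = median_dual_areas(body.mesh, body.positions)
        vals.append(float(a[w].sum()))
    return float(np.mean(vals))


def overlap_length(bodies) -> float:
    """Projected overlap of the two cell silhouettes along the sliding axis."""
    ax = bodies[0].positions[:, 0]
    bx = bodies[1].positions[:, 0]
    return max(0.0, float(min(ax.max(), bx.max()) - max(ax.min(), bx.min())))


def formation_rate(traj: Trajectory) -> float:
    """Average overlap-growth rate up to 80% of the final overlap [m/s].

    Final overlap is the maximum recorded value; the rate is the overlap
    growth from the start to the 80% point divided by the time to reach it
    (linearly interpolated).  Returns 0 (meta flag ``no_growth``) when the
    overlap never grows.
    """
    t = traj.data["time"].to_numpy()
    o = traj.data["overlap"].to_numpy()
    o0 = o[0]
    of = o.max()
    if of <= o0 * (1 + 1e-9) or of <= 0:
        traj.meta["no_growth"] = True
        return 0.0
    target = o0 + 0.8 * (of - o0)
    k = int(np.argmax(o >= target))
    if k == 0:
        traj.meta["no_growth"] = True
        return 0.0
    # linear interpolation inside the crossing interval
    t80 = t[k - 1] + (t[k] - t[k - 1]) * (target - o[k - 1]) / (o[k] - o[k - 1])
    if t80 <= t[0]:
        traj.meta["no_growth"] = True
        return 0.0
    return float((target - o0) / (t80 - t[0]))


@dataclass
class StageInfo:
    peak_force: float
    peak_displacement: float
    boundary_index: int
    has_stage_two: bool
    single_stage: bool


def stage_segmentation(traj: Trajectory, smooth_window: int | None = None,
                       ) -> StageInfo:
    """Split a disaggregation force-displacement curve at its smoothed peak.

    Stage I is the rising branch up to the (smoothed) global maximum of the
    trap tension, stage II the declining branch after it.  A curve that is
    still rising at the end of the record (escape while in stage I) reports
    ``has_stage_two=False``; a monotone curve reports ``single_stage=True``.
    """
    f = traj.data["f_ot"].to_numpy()
    d = traj.data["displacement"].to_numpy()
    if len(f) < 3:
        raise StateError("trajectory too short for stage segmentation")
    if smooth_window is None:
        smooth_window = max(3, len(f) // 25)
    kernel = np.ones(smooth_window) / smooth_window
    fs = np.convolve(f, kernel, mode="same")
    k = int(np.argmax(fs))
    peak = float(fs[k])
    # stage II exists if the smoothed curve later drops well below the peak
    tail_min = float(fs[k:].min()) if k < len(fs) else peak
    has2 = bool(k < len(fs) - 2 and tail_min < 0.9 * peak)
    single = bool(k >= len(fs) - 2)
    return StageInfo(peak_force=peak, peak_displacement=float(d[k]),
                     boundary_index=k, has_stage_two=has2, single_stage=single)


# ---------------------------------------------------------------------------
# main loop
# ---------------------------------------------------------------------------

def _run(bodies, config: ProtocolConfig, adhesion: AdhesionParams,
         transport: TransportParams | None, pulling: bool,
         snapshot_hook=None) -> Trajectory:
    body_a, body_b = bodies
    if config.dt is not None:
        dt = config.dt
    else:
        dt = stable_dt(bodies)
        # intercellular friction at the clamped gap adds damping on contact
        # vertices; keep the explicit step below that bound as well
        ai_max = float(median_dual_areas(body_a.mesh,
                                         body_a.positions).max())
        c_fric = adhesion.mu_gap * ai_max / adhesion.eps_gap
        if c_fric > 0:
            dt = min(dt, 0.8 * body_a.vertex_mass / c_fric)
    bound = stable_dt(bodies, safety=1.0)
    if dt > bound:
        raise ConfigurationError(
            f"dt={dt:g} exceeds the stability bound {bound:g}")
    n_steps = int(round(config.duration / dt))
    record_every = max(1, int(round(config.snapshot_interval / dt)))
    stride = max(1, config.transport_stride)

    tracker_ab = ContactTracker(adhesion.r_cutoff, "vts",
                                config.contact_reassign_every)
    tracker_ba = ContactTracker(adhesion.r_cutoff, "vts",
                                config.contact_reassign_every)

    constraints = None
    patches = None
    if pulling:
        patches = _trap_patches(bodies, config.trap_patch_fraction)
        v_a = np.array([-config.pulling_rate, 0.0, 0.0])
        v_b = np.array([+config.pulling_rate, 0.0, 0.0])
        constraints = [(patches[0], v_a), (patches[1], v_b)]
        # seed the imposed velocity to avoid a startup reaction spike
        body_a.velocities[patches[0]] = v_a
        body_b.velocities[patches[1]] = v_b

    transport_on = transport is not None and (
        adhesion.gamma_mfg > 0 or (transport.adsorption_on))

    rows = []
    meta = {"dt": dt, "n_steps": n_steps, "escaped": False,
            "separated": False, "max_volume_drift": 0.0,
            "max_area_drift": 0.0}
    fot_acc = 0.0
    fagg_acc = 0.0
    acc_n = 0
    rest_vol = body_a.mesh.rest_total_volume
    rest_area = body_a.mesh.rest_total_area
    empty_since = None

    # initial state row (t = 0, no forces applied yet)
    sep0 = abs(body_b.positions[:, 0].mean() - body_a.positions[:, 0].mean())
    cm0_ab = tracker_ab.query(body_a, body_b)
    cm0_ba = tracker_ba.query(body_b, body_a)
    rows.append({
        "time": 0.0,
        "displacement": 0.0,
        "f_ot": 0.0,
        "f_agg_x": 0.0,
        "contact_area": contact_area(bodies, (cm0_ab, cm0_ba)),
        "overlap": overlap_length(bodies),
        "n_ave": average_gap_density(bodies, (cm0_ab, cm0_ba)),
    })

    for step in range(n_steps):
        t = step * dt
        cm_ab = tracker_ab.query(body_a, body_b)
        cm_ba = tracker_ba.query(body_b, body_a)
        areas_a = median_dual_areas(body_a.mesh, body_a.positions)
        areas_b = median_dual_areas(body_b.mesh, body_b.positions)
        normals_a = vertex_normals(body_a.mesh, body_a.positions)
        normals_b = vertex_normals(body_b.mesh, body_b.positions)

        fa_adh, fb_adh = adhesion_forces(body_a, body_b, cm_ab, adhesion,
                                         cm_ba, areas_a, areas_b)
        fa_fr, fb_fr = friction_forces(body_a, body_b, cm_ab, adhesion, cm_ba,
                                       areas_a, areas_b, normals_a, normals_b)

        if transport_on and step % stride == 0:
            for body, cm, nrm in ((body_a, cm_ab, normals_a),
                                  (body_b, cm_ba, normals_b)):
                drift = drift_velocity(body, cm, transport, adhesion.r_glyco,
                                       normals=nrm)
                src = adsorption_source(body.mfg_density, cm, transport)
                transport_step(body, drift, src, dt * stride, transport)

        reactions = integrate_step(
            [body_a, body_b], [fa_adh + fa_fr, fb_adh + fb_fr], dt,
            constraints)

        if pulling:
            ra = reactions[0][0]      # x component on cell A's patch
            rb = reactions[1][0]
            fot_acc += 0.5 * (abs(ra) + abs(rb))
        fagg_acc += abs(float(fa_adh[:, 0].sum()))
        acc_n += 1

        if (step + 1) % record_every == 0 or step == n_steps - 1:
            contacts = (cm_ab, cm_ba)
            area_c = contact_area(bodies, contacts)
            nave = average_gap_density(bodies, contacts)
            disp = 2.0 * config.pulling_rate * (t + dt) if pulling else \
                abs(sep0 - abs(body_b.positions[:, 0].mean()
                               - body_a.positions[:, 0].mean()))
            vol_drift = max(
                abs(body_a.current_volume() - rest_vol) / rest_vol,
                abs(body_b.current_volume() - rest_vol) / rest_vol)
            area_drift = max(
                abs(body_a.current_area() - rest_area) / rest_area,
                abs(body_b.current_area() - rest_area) / rest_area)
            meta["max_volume_drift"] = max(meta["max_volume_drift"], vol_drift)
            meta["max_area_drift"] = max(meta["max_area_drift"], area_drift)
            f_ot = fot_acc / acc_n if pulling else 0.0
            rows.append({
                "time": t + dt,
                "displacement": disp,
                "f_ot": f_ot,
                "f_agg_x": fagg_acc / acc_n,
                "contact_area": area_c,
                "overlap": overlap_length(bodies),
                "n_ave": nave,
            })
            fot_acc = fagg_acc = 0.0
            acc_n = 0
            if snapshot_hook is not None:
                snapshot_hook(t + dt, bodies, contacts)
            n_contact = cm_ab.n_interacting + cm_ba.n_interacting
            if pulling and n_contact == 0:
                if empty_since is None:
                    empty_since = t
                elif t - empty_since > 3 * config.snapshot_interval:
                    meta["separated"] = True
                    break
            else:
                empty_since = None
            if (pulling and config.escape_threshold is not None
                    and f_ot >= config.escape_threshold):
                meta["escaped"] = True
                meta["escape_displacement"] = disp
                break

    return Trajectory(pd.DataFrame(rows), meta)


def run_doublet_formation(config: ProtocolConfig, membrane: MembraneParams,
                          adhesion: AdhesionParams,
                          transport: TransportParams | None = None,
                          snapshot_hook=None) -> Trajectory:
    """Spontaneous doublet formation from near point contact (no load)."""
    bodies = make_doublet(config, membrane, adhesion)
    traj = _run(list(bodies), config, adhesion, transport, pulling=False,
                snapshot_hook=snapshot_hook)
    traj.meta["protocol"] = "formation"
    traj.meta["bodies"] = bodies
    return traj


def run_ot_disaggregation(config: ProtocolConfig, membrane: MembraneParams,
                          adhesion: AdhesionParams,
                          transport: TransportParams | None = None,
                          bodies=None, snapshot_hook=None) -> Trajectory:
    """Forced doublet disaggregation under the kinematic trap constraint.

    Unless ``bodies`` (e.g. from a formation run) is given, a crescent
    doublet at 50% diameter overlap is assembled and relaxed for
    ``config.equilibration`` seconds before pulling starts.
    """
    if bodies is None:
        bodies = list(make_doublet(config, membrane, adhesion))
        if config.equilibration > 0:
            eq_cfg = ProtocolConfig(
                protocol="disaggregation", duration=config.equilibration,
                dt=config.dt, pulling_rate=0.0,
                snapshot_interval=config.snapshot_interval,
                n_vertices=config.n_vertices,
                cell_diameter=config.cell_diameter,
                transport_stride=config.transport_stride,
                contact_reassign_every=config.contact_reassign_every,
                nave0=config.nave0)
            _run(bodies, eq_cfg, adhesion, transport, pulling=False)
    traj = _run(bodies, config, adhesion, transport, pulling=True,
                snapshot_hook=snapshot_hook)
    traj.meta["protocol"] = "disaggregation"
    traj.meta["bodies"] = tuple(bodies)
    return traj
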