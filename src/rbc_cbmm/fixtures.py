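"""Deterministic small geometries for unit tests and PDE oracles."""

from __future__ import annotations

import numpy as np

from .errors import ConfigurationError
from .geometry import TriSurfaceMesh, build_discocyte_mesh, unit_sphere_mesh


def flat_patch(nx: int = 20, ny: int = 20, spacing: float = 100e-9,
               ) -> TriSurfaceMesh:
    """Open planar triangulated sheet in the z=0 plane.

    Equilateral-ish right-triangle lattice with known analytic areas:
    (nx-1)*(ny-1) cells of area spacing^2, two triangles each.
    """
    if nx < 2 or ny < 2:
        raise ConfigurationError("patch needs at least 2x2 vertices")
    xs = np.arange(nx) * spacing
    ys = np.arange(ny) * spacing
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    verts = np.column_stack([gx.ravel(), gy.ravel(), np.zeros(nx * ny)])
    tris = []
    for i in range(nx - 1):
        for j in range(ny - 1):
            v00 = i * ny + j
            v10 = (i + 1) * ny + j
            v01 = i * ny + j + 1
            v11 = (i + 1) * ny + j + 1
            tris.append([v00, v10, v11])
            tris.append([v00, v11, v01])
    return TriSurfaceMesh(verts, np.asarray(tris), closed=False)


def equilateral_patch(n_side: int = 12, spacing: float = 100e-9,
                      ) -> TriSurfaceMesh:
    """Open patch of equilateral triangles (hexagonal lattice sheet)."""
    verts = []
    index = {}
    for j in range(n_side):
        for i in range(n_side):
            index[(i, j)] = len(verts)
            verts.append([(i + 0.5 * (j % 2)) * spacing,
                          j * spacing * np.sqrt(3) / 2, 0.0])
    tris = []
    for j in range(n_side - 1):
        for i in range(n_side - 1):
            a = index[(i, j)]
            b = index[(i + 1, j)]
            c = index[(i, j + 1)]
            d = index[(i + 1, j + 1)]
            if j % 2 == 0:
                tris.append([a, b, c])
                tris.append([b, d, c])
            else:
                tris.append([a, b, d])
                tris.append([a, d, c])
    return TriSurfaceMesh(np.asarray(verts), np.asarray(tris), closed=False)


def sphere_pair(radius: float = 1e-6, gap: float = 20e-9, n: int = 200):
    """Two concentric-axis sphere meshes separated by ``gap`` at the poles.

    Returns (mesh, shift_vector): the second body is the same mesh translated
    by ``shift_vector`` along +z, giving minimum surface separation ~``gap``
    (up to faceting of the discretized spheres).
    """
    mesh = unit_sphere_mesh(n)
    verts = mesh.vertices * radius
    scaled = TriSurfaceMesh(verts, mesh.triangles)
    shift = np.array([0.0, 0.0, 2.0 * radius + gap])
    return scaled, shift


def coarse_discocyte_pair(n: int = 300, cell_diameter: float = 7.8e-6,
                          gap: float = 20e-9, overlap_offset: float | None = None):
    """Two coarse discocyte meshes stacked face-to-face at the given gap.

    Returns (mesh, shift_vector) where the second cell is offset by
    ``overlap_offset`` along x (default: 90% of the diameter, a near point
    contact) and raised along z until the minimum inter-surface distance is
    approximately ``gap``.
    """
    from .protocols import doublet_shift  # local import to avoid cycle
    mesh = build_discocyte_mesh(n, cell_diameter)
    if overlap_offset is None:
        overlap_offset = 0.9 * cell_diameter
    shift = doublet_shift(mesh, overlap_offset, gap)
    return mesh, shift


def make_fixture(kind: str, **params):
    """Dispatch by name: flat_patch, equilateral_patch, sphere_pair,
    coarse_discocyte_pair."""
    table = {
        "flat_patch": flat_patch,
        "equilateral_patch": equilateral_patch,
        "sphere_pair": sphere_pair,
        "coarse_discocyte_pair": coarse_discocyte_pair,
    }
    if kind not in table:
        raise ConfigurationError(f"unknown fixture kind {kind!r}")
    return table[kind](**params)
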