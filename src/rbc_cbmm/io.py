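"""Trajectory, mesh-snapshot and run-manifest writers.

Snapshots are legacy-VTK ASCII PolyData (one file per cell) carrying the
per-vertex scalar fields (mobile-Fg density, VTS separation) and vector
fields (velocity, adhesion force); they open in ParaView and other standard
viewers.  Trajectories are plain CSV with a fixed header contract; run
manifests are JSON echoes of every resolved parameter in SI units.
"""

from __future__ import annotations

import json
import pathlib

import numpy as np
import pandas as pd

from .errors import CbmmError
from .protocols import Trajectory

TRAJECTORY_COLUMNS = ["time", "displacement", "f_ot", "f_agg_x",
                      "contact_area", "overlap", "n_ave"]


def write_trajectory(traj: Trajectory, path) -> None:
    missing = [c for c in TRAJECTORY_COLUMNS if c not in traj.data.columns]
    if missing:
        raise CbmmError(f"trajectory missing columns {missing}")
    traj.data.to_csv(path, index=False, columns=TRAJECTORY_COLUMNS)


def read_trajectory(path) -> Trajectory:
    df = pd.read_csv(path)
    missing = [c for c in TRAJECTORY_COLUMNS if c not in df.columns]
    if missing:
        raise CbmmError(f"trajectory file missing columns {missing}")
    return Trajectory(df)


def write_snapshot(bodies, path, scalar_fields=None, vector_fields=None,
                   ) -> list[str]:
    """Write one legacy-VTK ASCII PolyData file per body.

    ``scalar_fields``/``vector_fields`` are dicts mapping field name to a
    list with one per-vertex array per body.  The mobile-Fg density is
    always written as scalar field ``n_mfg``; velocities as ``velocity``.
    Returns the written file paths.
    """
    path = pathlib.Path(path)
    scalar_fields = dict(scalar_fields or {})
    vector_fields = dict(vector_fields or {})
    scalar_fields.setdefault("n_mfg", [b.mfg_density for b in bodies])
    vector_fields.setdefault("velocity", [b.velocities for b in bodies])
    written = []
    for k, body in enumerate(bodies):
        fp = path.with_name(f"{path.stem}_body{k}.vtk")
        with open(fp, "w") as fh:
            fh.write("# vtk DataFile Version 3.0\n")
            fh.write("rbc-cbmm snapshot\nASCII\nDATASET POLYDATA\n")
            pos = body.positions
            fh.write(f"POINTS {len(pos)} double\n")
            np.savetxt(fh, pos, fmt="%.9e")
            tris = body.mesh.triangles
            fh.write(f"POLYGONS {len(tris)} {4 * len(tris)}\n")
            np.savetxt(fh, np.column_stack(
                [np.full(len(tris), 3), tris]), fmt="%d")
            fh.write(f"POINT_DATA {len(pos)}\n")
            for name, arrays in scalar_fields.items():
                fh.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
                np.savetxt(fh, np.asarray(arrays[k]), fmt="%.9e")
            for name, arrays in vector_fields.items():
                fh.write(f"VECTORS {name} double\n")
                np.savetxt(fh, np.asarray(arrays[k]), fmt="%.9e")
        written.append(str(fp))
    return written


def read_snapshot_points(path) -> np.ndarray:
    """Read back the POINTS block of a legacy-VTK snapshot (round-trip aid)."""
    with open(path) as fh:
        lines = fh.readlines()
    for k, line in enumerate(lines):
        if line.startswith("POINTS"):
            n = int(line.split()[1])
            data = " ".join(lines[k + 1:k + 1 + n])
            return np.fromstring(data, sep=" ").reshape(n, 3)
    raise CbmmError(f"no POINTS block in {path}")


def write_manifest(config, path, seed=None, extra=None) -> None:
    """JSON manifest echoing every resolved parameter in SI units."""
    from . import __version__
    doc = {"package_version": __version__, "seed": seed}
    doc.update(config.manifest())
    if extra:
        doc.update(extra)
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=2, default=_json_default)
        fh.write("\n")


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return str(obj)
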