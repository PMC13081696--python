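"""File I/O: surfaces (PLY, FreeSurfer), source spaces, sensor layouts,
per-vertex overlays and summaries."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .arrays import Sensor, SensorArray, tangential_axes
from .geometry import SourceSpace, SurfaceMesh


# -- surfaces --------------------------------------------------------------

def write_surface(mesh: SurfaceMesh, path) -> None:
    """Write a surface as binary PLY or FreeSurfer geometry (by extension)."""
    path = Path(path)
    if path.suffix == ".ply":
        mesh.as_trimesh().export(path, file_type="ply", encoding="binary")
    else:
        import nibabel.freesurfer.io as fsio

        # FreeSurfer stores millimeters
        fsio.write_geometry(str(path), mesh.vertices * 1000.0, mesh.faces)


def read_surface(path) -> SurfaceMesh:
    path = Path(path)
    if path.suffix == ".ply":
        import trimesh

        tm = trimesh.load(path, file_type="ply", process=False)
        return SurfaceMesh(vertices=np.asarray(tm.vertices), faces=np.asarray(tm.faces))
    import nibabel.freesurfer.io as fsio

    verts, faces = fsio.read_geometry(str(path))
    return SurfaceMesh(vertices=np.asarray(verts) / 1000.0, faces=np.asarray(faces))


# -- source spaces ---------------------------------------------------------

def write_source_space(space: SourceSpace, path) -> None:
    """JSON sidecar with positions, normals, vertex ids and region."""
    payload = dict(region=space.region,
                   positions=space.positions.tolist(),
                   normals=space.normals.tolist(),
                   vertex_ids=space.vertex_ids.tolist())
    Path(path).write_text(json.dumps(payload))


def read_source_space(path, parent_mesh: SurfaceMesh | None = None) -> SourceSpace:
    d = json.loads(Path(path).read_text())
    return SourceSpace(positions=np.asarray(d["positions"]),
                       normals=np.asarray(d["normals"]),
                       region=d["region"], parent_mesh=parent_mesh,
                       vertex_ids=np.asarray(d["vertex_ids"]))


# -- sensor layouts --------------------------------------------------------

def write_layout(array: SensorArray, path) -> None:
    """TSV layout: id, position, axis triad, sensor type."""
    lines = ["id\tx\ty\tz\trx\try\trz\tt1x\tt1y\tt1z\tt2x\tt2y\tt2z\ttype"]
    for s in array.sensors:
        row = [s.id, *s.position, *s.radial_axis, *s.tan1_axis, *s.tan2_axis,
               s.sensor_type]
        lines.append("\t".join(f"{v:.9g}" if isinstance(v, float) else str(v)
                               for v in row))
    Path(path).write_text("\n".join(lines) + "\n")


def read_layout(path, channel_mode: str = "single_axis",
                name: str = "") -> SensorArray:
    """Read a TSV layout; tolerates position-only files (axes derived by
    taking the radial direction from the head-centred position)."""
    lines = [ln for ln in Path(path).read_text().splitlines() if ln.strip()]
    header = lines[0].split("\t")
    sensors = []
    for ln in lines[1:]:
        parts = ln.split("\t")
        rec = dict(zip(header, parts))
        pos = np.array([float(rec["x"]), float(rec["y"]), float(rec["z"])])
        if "rx" in rec:
            radial = np.array([float(rec["rx"]), float(rec["ry"]), float(rec["rz"])])
            tan1 = np.array([float(rec["t1x"]), float(rec["t1y"]), float(rec["t1z"])])
            tan2 = np.array([float(rec["t2x"]), float(rec["t2y"]), float(rec["t2z"])])
        else:
            radial = pos / np.linalg.norm(pos)
            tan1, tan2 = tangential_axes(radial)
        sensors.append(Sensor(id=int(rec["id"]), position=pos, radial_axis=radial,
                              tan1_axis=tan1, tan2_axis=tan2,
                              sensor_type=rec.get("type", "opm")))
    return SensorArray(sensors=sensors, channel_mode=channel_mode,
                       name=name or Path(path).stem)


# -- overlays --------------------------------------------------------------

def write_overlay(values, path, vertex_ids=None) -> None:
    """Per-vertex scalar overlay: FreeSurfer curv (.curv) or CSV."""
    values = np.asarray(values, float)
    path = Path(path)
    if path.suffix == ".curv":
        import nibabel.freesurfer.io as fsio

        fsio.write_morph_data(str(path), values)
    else:
        ids = np.arange(len(values)) if vertex_ids is None else np.asarray(vertex_ids)
        lines = ["vertex_id,value"] + [f"{i},{v:.12g}" for i, v in zip(ids, values)]
        path.write_text("\n".join(lines) + "\n")


def read_overlay(path) -> np.ndarray:
    path = Path(path)
    if path.suffix == ".curv":
        import nibabel.freesurfer.io as fsio

        return np.asarray(fsio.read_morph_data(str(path)))
    rows = Path(path).read_text().splitlines()[1:]
    return np.array([float(r.split(",")[1]) for r in rows if r.strip()])
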