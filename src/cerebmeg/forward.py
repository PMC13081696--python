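"""Forward model: magnetic field of a current dipole in a spherical conductor.

The external field of a current dipole inside a spherically symmetric
conductor has the well-known closed form (Sarvas): it is independent of the
conductivity profile and of the conductor radius, and a radially oriented
dipole produces no external field at all ("radial silence").  All array
metrics in this package consume only the resulting gain matrix, so lead
fields computed with a realistic boundary-element model can be imported and
fed through the identical downstream code.

Units are SI throughout: positions in meters, dipole moments in A·m, fields
in tesla, gains in T/(A·m).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .geometry import SourceSpace, SurfaceMesh

MU0_OVER_4PI = 1e-7  # T·m/A


# --------------------------------------------------------------------------
# Dipole field (Sarvas formula)
# --------------------------------------------------------------------------

def dipole_field_sphere(dipole_position, dipole_moment, field_point, sphere_center):
    """Magnetic field (T) of a current dipole in a spherically symmetric conductor.

    ``field_point`` must be strictly outside the sphere through the dipole;
    the dipole must not sit at the conductor center (the formula's local
    radial direction is then undefined).
    """
    r0 = np.asarray(dipole_position, float) - np.asarray(sphere_center, float)
    r = np.asarray(field_point, float) - np.asarray(sphere_center, float)
    q = np.asarray(dipole_moment, float)
    if np.linalg.norm(r0) < 1e-12:
        raise ValueError("dipole at sphere center: field direction undefined")
    if np.linalg.norm(r) <= np.linalg.norm(r0):
        raise ValueError("field point must be strictly outside the sphere "
                         "through the dipole position")
    return _sarvas(r0[None, :], q[None, :], r)[0]


def _sarvas(r0: np.ndarray, q: np.ndarray, r: np.ndarray) -> np.ndarray:
    """Vectorized Sarvas formula.

    r0: (n, 3) dipole positions relative to the conductor center.
    q:  (n, 3) dipole moments (A·m).
    r:  (3,)   field point relative to the center.
    Returns (n, 3) fields in tesla.
    """
    a_vec = r[None, :] - r0                      # (n, 3)
    a = np.linalg.norm(a_vec, axis=1)            # (n,)
    rn = np.linalg.norm(r)
    r0_dot_r = r0 @ r                            # (n,)
    F = a * (rn * a + rn ** 2 - r0_dot_r)        # (n,)
    # grad F with respect to r
    gF = ((a ** 2 / rn + a_vec @ r / a + 2.0 * a + 2.0 * rn)[:, None] * r[None, :]
          - (a + 2.0 * rn + (a_vec @ r) / a)[:, None] * r0)
    q_x_r0 = np.cross(q, r0)                     # (n, 3)
    # a radial dipole is exactly silent; suppress round-off in the cross
    # product when moment and position are numerically parallel
    scale = np.linalg.norm(q, axis=1) * np.linalg.norm(r0, axis=1)
    parallel = np.linalg.norm(q_x_r0, axis=1) <= 1e-12 * scale
    q_x_r0[parallel] = 0.0
    B = MU0_OVER_4PI / (F ** 2)[:, None] * (
        F[:, None] * q_x_r0 - (q_x_r0 @ r)[:, None] * gF)
    return B


# --------------------------------------------------------------------------
# Channels
# --------------------------------------------------------------------------

@dataclass
class Channel:
    """One measurement channel: integration points, weights, pickup orientation."""

    kind: str                       # "magnetometer" | "axial_gradiometer"
    integration_points: np.ndarray  # (k, 3) meters
    integration_weights: np.ndarray # (k,)
    orientation: np.ndarray         # unit 3-vector
    parent_sensor_id: int = 0
    axis_label: str = "radial"      # radial | tan1 | tan2
    baseline: Optional[float] = None

    def __post_init__(self) -> None:
        self.integration_points = np.atleast_2d(np.asarray(self.integration_points, float))
        self.integration_weights = np.atleast_1d(np.asarray(self.integration_weights, float))
        self.orientation = np.asarray(self.orientation, float)
        if abs(np.linalg.norm(self.orientation) - 1.0) > 1e-9:
            raise ValueError("channel orientation must be unit length")
        if len(self.integration_points) != len(self.integration_weights):
            raise ValueError("one weight per integration point required")
        s = self.integration_weights.sum()
        if self.kind == "magnetometer" and abs(s - 1.0) > 1e-9:
            raise ValueError("magnetometer weights must sum to 1")
        if self.kind == "axial_gradiometer" and abs(s) > 1e-9:
            raise ValueError("gradiometer weights must sum to 0")


def channel_gain(channel: Channel, dipole_position, dipole_orientation,
                 sphere_center) -> float:
    """Gain (T per A·m) of one channel for a unit dipole along ``dipole_orientation``."""
    r0 = np.asarray(dipole_position, float)
    q = np.asarray(dipole_orientation, float)
    total = 0.0
    for p, w in zip(channel.integration_points, channel.integration_weights):
        b = dipole_field_sphere(r0, q, p, sphere_center)
        total += w * float(b @ channel.orientation)
    return total


# --------------------------------------------------------------------------
# Lead fields
# --------------------------------------------------------------------------

@dataclass
class LeadField:
    """Dense channel x source gain matrix in T/(A·m)."""

    gain: np.ndarray
    channel_meta: list
    source_meta: Optional[SourceSpace] = None
    model_tag: str = "sphere"

    def __post_init__(self) -> None:
        self.gain = np.asarray(self.gain, dtype=float)
        if self.gain.ndim != 2:
            raise ValueError("gain must be 2-D (channels x sources)")
        if self.channel_meta is not None and len(self.channel_meta) != self.gain.shape[0]:
            raise ValueError("channel metadata length must match gain rows")
        if self.source_meta is not None and len(self.source_meta) != self.gain.shape[1]:
            raise ValueError("source metadata length must match gain columns")
        if not np.all(np.isfinite(self.gain)):
            raise ValueError("gain entries must be finite")

    @property
    def n_channels(self) -> int:
        return self.gain.shape[0]

    @property
    def n_sources(self) -> int:
        return self.gain.shape[1]


def assemble_leadfield(array, space: SourceSpace, sphere_center) -> LeadField:
    """Assemble the gain matrix for a sensor array over a source space.

    Channel ordering is the array's canonical ordering (sensor id, then
    radial/tan1/tan2); source ordering follows the space's vertex_ids order.
    Every source must lie strictly inside the sphere through the innermost
    integration point.
    """
    channels = array.channels() if hasattr(array, "channels") else list(array)
    if not channels:
        raise ValueError("empty sensor array")
    if len(space) == 0:
        raise ValueError("empty source space")
    center = np.asarray(sphere_center, float)
    src_r = np.linalg.norm(space.positions - center, axis=1)
    min_point_r = min(np.linalg.norm(c.integration_points - center, axis=1).min()
                      for c in channels)
    if np.any(src_r >= min_point_r):
        raise ValueError("source outside conductor (beyond an integration point)")

    # Gather unique integration points so each Sarvas evaluation is shared.
    gain = np.zeros((len(channels), len(space)))
    r0 = space.positions - center
    q = space.normals
    point_cache: dict[tuple, np.ndarray] = {}
    for ci, ch in enumerate(channels):
        row = np.zeros(len(space))
        for p, w in zip(ch.integration_points, ch.integration_weights):
            key = tuple(np.round(p, 12))
            if key not in point_cache:
                point_cache[key] = _sarvas(r0, q, np.asarray(p, float) - center)
            row += w * (point_cache[key] @ ch.orientation)
        gain[ci] = row
    return LeadField(gain=gain, channel_meta=channels, source_meta=space,
                     model_tag="sphere")


# --------------------------------------------------------------------------
# Near-boundary exclusion
# --------------------------------------------------------------------------

def _point_triangle_distances(points: np.ndarray, tri: np.ndarray) -> np.ndarray:
    """Exact min distance from each point to a set of triangles.

    points: (n, 3); tri: (m, 3, 3).  Returns (n,).  Chunked over triangles
    to bound memory.
    """
    n = len(points)
    best = np.full(n, np.inf)
    chunk = max(1, int(2e6 // max(n, 1)))
    for start in range(0, len(tri), chunk):
        t = tri[start:start + chunk]              # (c, 3, 3)
        a, b, c = t[:, 0], t[:, 1], t[:, 2]
        ab = b - a
        ac = c - a
        p = points[:, None, :]                    # (n, 1, 3)
        ap = p - a[None, :, :]
        d1 = np.einsum("cj,ncj->nc", ab, ap)
        d2 = np.einsum("cj,ncj->nc", ac, ap)
        bp = p - b[None, :, :]
        d3 = np.einsum("cj,ncj->nc", ab, bp)
        d4 = np.einsum("cj,ncj->nc", ac, bp)
        cp = p - c[None, :, :]
        d5 = np.einsum("cj,ncj->nc", ab, cp)
        d6 = np.einsum("cj,ncj->nc", ac, cp)

        va = d3 * d6 - d5 * d4
        vb = d5 * d2 - d1 * d6
        vc = d1 * d4 - d3 * d2
        denom = va + vb + vc
        with np.errstate(divide="ignore", invalid="ignore"):
            v = np.clip(np.where(denom != 0, vb / denom, 0.0), 0, 1)
            w = np.clip(np.where(denom != 0, vc / denom, 0.0), 0, 1)
        # region tests (Ericson, Real-Time Collision Detection)
        closest = a[None] + v[..., None] * ab[None] + w[..., None] * ac[None]
        # vertex regions
        closest = np.where(((d1 <= 0) & (d2 <= 0))[..., None], a[None], closest)
        closest = np.where(((d3 >= 0) & (d4 <= d3))[..., None], b[None], closest)
        closest = np.where(((d6 >= 0) & (d5 <= d6))[..., None], c[None], closest)
        # edge AB
        vab = np.clip(np.where(d1 - d3 != 0, d1 / (d1 - d3), 0.0), 0, 1)
        on_ab = (vc <= 0) & (d1 >= 0) & (d3 <= 0)
        closest = np.where(on_ab[..., None], a[None] + vab[..., None] * ab[None], closest)
        # edge AC
        vac = np.clip(np.where(d2 - d6 != 0, d2 / (d2 - d6), 0.0), 0, 1)
        on_ac = (vb <= 0) & (d2 >= 0) & (d6 <= 0)
        closest = np.where(on_ac[..., None], a[None] + vac[..., None] * ac[None], closest)
        # edge BC
        num = d4 - d3
        den = (d4 - d3) + (d5 - d6)
        vbc = np.clip(np.where(den != 0, num / den, 0.0), 0, 1)
        on_bc = (va <= 0) & (d4 - d3 >= 0) & (d5 - d6 >= 0)
        closest = np.where(on_bc[..., None], b[None] + vbc[..., None] * (c - b)[None], closest)
        d = np.linalg.norm(p - closest, axis=2).min(axis=1)
        best = np.minimum(best, d)
    return best


def distance_to_mesh(points, mesh: SurfaceMesh) -> np.ndarray:
    """Exact Euclidean distance from points to the nearest mesh triangle."""
    points = np.atleast_2d(np.asarray(points, float))
    return _point_triangle_distances(points, mesh.vertices[mesh.faces])


def exclude_near_boundary(space: SourceSpace, boundary: SurfaceMesh,
                          min_distance: float = 0.003) -> SourceSpace:
    """Drop sources closer than ``min_distance`` to the boundary surface.

    The default 3 mm guards against numerical forward-model error blowing up
    for sources nearly touching the conductor boundary.  Ordering of the
    surviving sources is preserved.
    """
    import warnings

    if not boundary.is_closed:
        raise ValueError("boundary surface must be closed")
    d = distance_to_mesh(space.positions, boundary)
    keep = d >= min_distance
    if not keep.any():
        warnings.warn("near-boundary exclusion removed every source", stacklevel=2)
    return space.subset(np.flatnonzero(keep))


# --------------------------------------------------------------------------
# Import / export
# --------------------------------------------------------------------------

_UNIT_PREFIX = {"": 1.0, "f": 1e-15, "p": 1e-12, "n": 1e-9, "u": 1e-6, "m": 1e-3}


def _parse_gain_unit(unit: str) -> float:
    """Scale factor converting a gain in ``unit`` to internal T/(A·m)."""
    u = unit.replace(" ", "").replace("·", ".").replace("*", ".")
    try:
        num, den = u.split("/")
    except ValueError as err:
        raise ValueError(f"cannot parse gain unit {unit!r}") from err
    den = den.strip("()")
    if not num.endswith("T") or not den.endswith(("A.m", "Am")):
        raise ValueError(f"cannot parse gain unit {unit!r}")
    num_scale = _UNIT_PREFIX.get(num[:-1])
    den_prefix = den.split("A")[0]
    den_scale = _UNIT_PREFIX.get(den_prefix)
    if num_scale is None or den_scale is None:
        raise ValueError(f"cannot parse gain unit {unit!r}")
    return num_scale / den_scale


def export_leadfield(lf: LeadField, path) -> None:
    """Write a lead field as HDF5 (gain + channel/source tables + unit attrs)."""
    import h5py

    path = Path(path)
    with h5py.File(path, "w") as f:
        f.create_dataset("gain", data=lf.gain)
        f.attrs["units"] = "T/(A·m)"
        f.attrs["model_tag"] = lf.model_tag
        ch = f.create_group("channels")
        ch.create_dataset("kind", data=np.array([c.kind for c in lf.channel_meta], dtype="S"))
        ch.create_dataset("axis_label",
                          data=np.array([c.axis_label for c in lf.channel_meta], dtype="S"))
        ch.create_dataset("parent_sensor_id",
                          data=np.array([c.parent_sensor_id for c in lf.channel_meta]))
        if lf.source_meta is not None:
            src = f.create_group("sources")
            src.create_dataset("positions", data=lf.source_meta.positions)
            src.create_dataset("normals", data=lf.source_meta.normals)
            src.create_dataset("vertex_ids", data=lf.source_meta.vertex_ids)
            src.attrs["region"] = lf.source_meta.region


def import_leadfield(path, channel_meta=None, source_meta=None) -> LeadField:
    """Read a lead field from HDF5 or a dense matrix (.npy/.txt) + JSON sidecar.

    The container must declare its gain unit; values are rescaled to the
    internal T/(A·m).  Shape mismatches against supplied metadata raise.
    """
    import h5py

    path = Path(path)
    if path.suffix in (".h5", ".hdf5", ".hdf"):
        try:
            with h5py.File(path, "r") as f:
                gain = np.asarray(f["gain"])
                unit = f.attrs.get("units", "T/(A·m)")
                tag = f.attrs.get("model_tag", "imported")
                if source_meta is None and "sources" in f:
                    src = f["sources"]
                    source_meta = SourceSpace(
                        positions=np.asarray(src["positions"]),
                        normals=np.asarray(src["normals"]),
                        region=str(src.attrs.get("region", "imported")),
                        vertex_ids=np.asarray(src["vertex_ids"]))
        except OSError as err:
            raise ValueError(f"unreadable lead-field container {path}: {err}") from err
        del tag  # imported containers are re-tagged below
    else:
        if path.suffix == ".npy":
            try:
                gain = np.load(path)
            except (ValueError, EOFError, OSError) as err:
                raise ValueError(f"unreadable lead-field matrix {path}: {err}") from err
        else:
            gain = np.loadtxt(path)
        sidecar = path.with_suffix(".json")
        meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
        unit = meta.get("units", "T/(A·m)")
    gain = np.atleast_2d(gain) * _parse_gain_unit(str(unit))
    if channel_meta is not None and len(channel_meta) != gain.shape[0]:
        raise ValueError("channel metadata does not match stored gain rows")
    if source_meta is not None and len(source_meta) != gain.shape[1]:
        raise ValueError("source metadata does not match stored gain columns")
    return LeadField(gain=gain, channel_meta=channel_meta, source_meta=source_meta,
                     model_tag="imported")
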