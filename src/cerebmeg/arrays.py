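"""Sensor arrays: helmet layouts, scalp projection, triaxial expansion and
uniform layouts of arbitrary sensor count.

Uniform layouts follow the eigen-embedding strategy used for on-scalp array
design: a dense candidate mesh is built over the coverage region, a Laplace
basis with Dirichlet boundary condition is computed on it, each basis
function is given uniform variance, and farthest-point sampling in that
embedding yields quasi-uniformly spaced sensor positions for any requested
count.  Because the sampling is greedy, layouts are nested: the first k
sensors of a (k+1)-sensor layout form the k-sensor layout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import dijkstra as _csgraph_dijkstra
from scipy.sparse.linalg import eigsh
from scipy.spatial import Delaunay

from .forward import Channel
from .geometry import SurfaceMesh

#: physical sensor element lengths (m), used for the overlap flag
PHYSICAL_LENGTH = {"squid_mag": 0.028, "squid_axial_grad": 0.028, "opm": 0.017}

#: default standoff from the scalp per sensor type (m)
DEFAULT_STANDOFF = {"squid_mag": 0.022, "squid_axial_grad": 0.022, "opm": 0.005}

DEFAULT_SQUID_LOOP_EDGE = 0.021   # 4-point square pickup loop edge (m)
DEFAULT_GRAD_BASELINE = 0.050     # axial gradiometer baseline (m)


# --------------------------------------------------------------------------
# Sensors and arrays
# --------------------------------------------------------------------------

def tangential_axes(radial: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic orthonormal tangential axes completing a radial axis.

    tan1 = normalize(z_hat x radial); if radial is (anti)parallel to z within
    1e-6, x_hat replaces z_hat.  tan2 = radial x tan1 (right-handed triad).
    """
    radial = np.asarray(radial, float)
    ref = np.array([0.0, 0.0, 1.0])
    t1 = np.cross(ref, radial)
    if np.linalg.norm(t1) < 1e-6:
        t1 = np.cross(np.array([1.0, 0.0, 0.0]), radial)
    t1 /= np.linalg.norm(t1)
    t2 = np.cross(radial, t1)
    return t1, t2


@dataclass
class Sensor:
    id: int
    position: np.ndarray
    radial_axis: np.ndarray
    tan1_axis: np.ndarray
    tan2_axis: np.ndarray
    sensor_type: str  # squid_mag | squid_axial_grad | opm

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, float)
        for name in ("radial_axis", "tan1_axis", "tan2_axis"):
            setattr(self, name, np.asarray(getattr(self, name), float))
        triad = np.stack([self.radial_axis, self.tan1_axis, self.tan2_axis])
        if not np.allclose(triad @ triad.T, np.eye(3), atol=1e-9):
            raise ValueError("sensor axes must form an orthonormal triad")
        if np.dot(np.cross(self.radial_axis, self.tan1_axis), self.tan2_axis) < 0:
            raise ValueError("sensor triad must be right-handed")
        if self.sensor_type not in PHYSICAL_LENGTH:
            raise ValueError(f"unknown sensor_type {self.sensor_type!r}")

    @property
    def physical_length(self) -> float:
        return PHYSICAL_LENGTH[self.sensor_type]


@dataclass
class SensorArray:
    sensors: list
    channel_mode: str = "single_axis"  # single_axis | triaxial
    name: str = ""
    squid_loop_edge: float = DEFAULT_SQUID_LOOP_EDGE
    gradiometer_baseline: float = DEFAULT_GRAD_BASELINE

    def __post_init__(self) -> None:
        ids = [s.id for s in self.sensors]
        if len(set(ids)) != len(ids):
            raise ValueError("sensor ids must be unique")
        if self.channel_mode not in ("single_axis", "triaxial"):
            raise ValueError("channel_mode must be single_axis or triaxial")
        if self.channel_mode == "triaxial" and any(
                s.sensor_type != "opm" for s in self.sensors):
            raise ValueError("triaxial mode is defined only for opm sensors")

    @property
    def n_sensors(self) -> int:
        return len(self.sensors)

    @property
    def n_channels(self) -> int:
        return self.n_sensors * (3 if self.channel_mode == "triaxial" else 1)

    @property
    def positions(self) -> np.ndarray:
        return np.array([s.position for s in self.sensors])

    def subset(self, k: int) -> "SensorArray":
        """First k sensors (nested layouts for FPS-generated arrays)."""
        return SensorArray(sensors=self.sensors[:k], channel_mode=self.channel_mode,
                           name=f"{self.name}[:{k}]",
                           squid_loop_edge=self.squid_loop_edge,
                           gradiometer_baseline=self.gradiometer_baseline)

    def channels(self) -> list:
        """Canonical channel list: sensors in order, axes radial/tan1/tan2."""
        out = []
        for s in sorted(self.sensors, key=lambda s: s.id):
            if s.sensor_type == "squid_mag":
                e = self.squid_loop_edge / 2.0
                pts = [s.position + dx * s.tan1_axis + dy * s.tan2_axis
                       for dx in (-e, e) for dy in (-e, e)]
                out.append(Channel(kind="magnetometer", integration_points=np.array(pts),
                                   integration_weights=np.full(4, 0.25),
                                   orientation=s.radial_axis,
                                   parent_sensor_id=s.id, axis_label="radial"))
            elif s.sensor_type == "squid_axial_grad":
                b = self.gradiometer_baseline
                pts = np.array([s.position, s.position + b * s.radial_axis])
                out.append(Channel(kind="axial_gradiometer", integration_points=pts,
                                   integration_weights=np.array([1.0, -1.0]),
                                   orientation=s.radial_axis, baseline=b,
                                   parent_sensor_id=s.id, axis_label="radial"))
            else:  # opm: point magnetometer at the sensitive element
                axes = [("radial", s.radial_axis)]
                if self.channel_mode == "triaxial":
                    axes += [("tan1", s.tan1_axis), ("tan2", s.tan2_axis)]
                for label, ax in axes:
                    out.append(Channel(kind="magnetometer",
                                       integration_points=s.position[None, :],
                                       integration_weights=np.array([1.0]),
                                       orientation=ax,
                                       parent_sensor_id=s.id, axis_label=label))
        return out


def expand_triaxial(array: SensorArray) -> list:
    """Channel list of the triaxial expansion (3 channels per OPM sensor)."""
    if any(s.sensor_type != "opm" for s in array.sensors):
        raise ValueError("triaxial expansion requires opm sensors")
    tri = SensorArray(sensors=array.sensors, channel_mode="triaxial",
                      name=array.name + "_triaxial")
    return tri.channels()


# --------------------------------------------------------------------------
# Scalp projection
# --------------------------------------------------------------------------

def _closest_on_mesh(points: np.ndarray, scalp: SurfaceMesh):
    """Closest surface points and face indices (brute force over faces)."""
    from trimesh.proximity import closest_point_naive

    tm = scalp.as_trimesh()
    closest, _, tri_id = closest_point_naive(tm, points)
    return np.asarray(closest), np.asarray(tri_id), tm


def project_to_scalp(positions, scalp: SurfaceMesh, standoff: float = 0.005,
                     sensor_type: str = "opm") -> list:
    """Project points onto the scalp and stand them off along the local normal.

    Each output sensor sits at (nearest scalp point) + standoff * outward
    face normal, with its radial axis along that normal.  Projections that
    land on an open-boundary edge keep the normal of the nearest face.
    """
    positions = np.atleast_2d(np.asarray(positions, float))
    closest, tri_id, tm = _closest_on_mesh(positions, scalp)
    # the offset from a point to its closest surface point lies in the
    # normal cone at that point, so (position - closest) is the exact
    # outward direction there; it also makes re-projection idempotent.
    # Points already on the surface fall back to the face normal.
    offsets = positions - closest
    off_norm = np.linalg.norm(offsets, axis=1)
    face_n = np.asarray(tm.face_normals)[tri_id]
    normals = np.where(off_norm[:, None] > 1e-9,
                       offsets / np.where(off_norm[:, None] > 0, off_norm[:, None], 1.0),
                       face_n)
    # ensure outward orientation (positive along centroid -> point direction)
    centroid = scalp.vertices.mean(axis=0)
    outward = closest - centroid
    flip = np.einsum("ij,ij->i", normals, outward) < 0
    normals[flip] *= -1.0
    sensors = []
    for i, (c, n) in enumerate(zip(closest, normals)):
        t1, t2 = tangential_axes(n)
        sensors.append(Sensor(id=i, position=c + standoff * n, radial_axis=n,
                              tan1_axis=t1, tan2_axis=t2, sensor_type=sensor_type))
    return sensors


# --------------------------------------------------------------------------
# Candidate mesh + Laplace embedding
# --------------------------------------------------------------------------

@dataclass
class CandidateMesh:
    mesh: SurfaceMesh
    embedding: Optional[np.ndarray] = None  # (n_vertices, n_basis)
    scalp: Optional[SurfaceMesh] = None
    standoff: float = 0.0


def _stereographic(points: np.ndarray, center_dir: np.ndarray) -> np.ndarray:
    """Stereographic projection of directions from the antipode of the cap center."""
    u = points / np.linalg.norm(points, axis=1, keepdims=True)
    c = center_dir / np.linalg.norm(center_dir)
    t1, t2 = tangential_axes(c)
    z = u @ c
    if np.any(z <= -1 + 1e-9):
        raise ValueError("point at the projection pole; cap too large")
    return np.stack([(u @ t1) / (1 + z), (u @ t2) / (1 + z)], axis=1)


def build_candidate_mesh(seed_positions, scalp: SurfaceMesh,
                         target_vertices: int = 5821,
                         standoff: float = 0.005) -> CandidateMesh:
    """Dense candidate sensor mesh over the coverage cap.

    The seed positions (e.g. a helmet layout) are triangulated by planar
    Delaunay after stereographic projection about the cap center, then
    midpoint-subdivided until the vertex count reaches ``target_vertices``;
    subdivided vertices are re-projected to the standoff surface above the
    scalp.
    """
    pts = np.atleast_2d(np.asarray(seed_positions, float))
    if len(pts) < 4:
        raise ValueError("need at least 4 positions")
    center_dir = pts.mean(axis=0)
    if np.linalg.norm(center_dir) < 1e-12:
        raise ValueError("degenerate seed positions (no cap direction)")
    try:
        plane = _stereographic(pts, center_dir)
        tri = Delaunay(plane)
    except Exception as err:
        raise ValueError(f"cannot triangulate candidate positions: {err}") from err
    if tri.simplices.size == 0:
        raise ValueError("coplanar/degenerate seed positions")
    # snap seeds to the standoff surface so all candidate vertices share it
    seeds = np.array([s.position for s in project_to_scalp(pts, scalp, standoff)])
    mesh = SurfaceMesh(vertices=seeds, faces=tri.simplices)
    while mesh.n_vertices < target_vertices:
        mesh = _midpoint_subdivide(mesh, scalp, standoff)
    return CandidateMesh(mesh=mesh, scalp=scalp, standoff=standoff)


def _midpoint_subdivide(mesh: SurfaceMesh, scalp: SurfaceMesh,
                        standoff: float) -> SurfaceMesh:
    """One round of 1-to-4 midpoint subdivision; new vertices re-projected."""
    edges = mesh.edges()
    edge_index = {tuple(e): i for i, e in enumerate(edges)}
    mids = 0.5 * (mesh.vertices[edges[:, 0]] + mesh.vertices[edges[:, 1]])
    projected = np.array([s.position for s in project_to_scalp(mids, scalp, standoff)])
    n0 = mesh.n_vertices
    new_faces = []
    for a, b, c in mesh.faces:
        mab = n0 + edge_index[tuple(sorted((a, b)))]
        mbc = n0 + edge_index[tuple(sorted((b, c)))]
        mca = n0 + edge_index[tuple(sorted((c, a)))]
        new_faces += [[a, mab, mca], [b, mbc, mab], [c, mca, mbc], [mab, mbc, mca]]
    return SurfaceMesh(vertices=np.vstack([mesh.vertices, projected]),
                       faces=np.asarray(new_faces))


# -- Laplacian ------------------------------------------------------------

def cotangent_laplacian(mesh: SurfaceMesh) -> tuple[sp.csr_matrix, sp.csr_matrix]:
    """FEM cotangent stiffness matrix and lumped (barycentric) mass matrix."""
    v = mesh.vertices
    f = mesh.faces
    n = mesh.n_vertices
    rows, cols, vals = [], [], []
    mass = np.zeros(n)
    areas = mesh.face_areas()
    for k in range(3):
        i = f[:, k]
        j = f[:, (k + 1) % 3]
        o = f[:, (k + 2) % 3]
        e1 = v[i] - v[o]
        e2 = v[j] - v[o]
        cot = np.einsum("ij,ij->i", e1, e2) / np.linalg.norm(np.cross(e1, e2), axis=1)
        w = 0.5 * cot
        rows += [i, j, i, j]
        cols += [j, i, i, j]
        vals += [-w, -w, w, w]
        np.add.at(mass, f[:, k], areas / 3.0)
    K = sp.csr_matrix((np.concatenate(vals),
                       (np.concatenate(rows), np.concatenate(cols))), shape=(n, n))
    M = sp.diags(mass).tocsr()
    return K, M


def dirichlet_eigenbasis(stiffness: sp.spmatrix, mass: sp.spmatrix,
                         interior: np.ndarray, n_basis: int
                         ) -> tuple[np.ndarray, np.ndarray]:
    """Lowest generalized eigenpairs K x = lam M x restricted to interior nodes.

    Returns (eigenvalues ascending, eigenvectors as columns) on the interior
    set; each eigenvector is scaled to unit variance over interior nodes and
    sign-fixed so its largest-magnitude entry is positive.
    """
    interior = np.asarray(interior)
    if interior.dtype == bool:
        interior = np.flatnonzero(interior)
    ni = len(interior)
    if n_basis >= ni:
        raise ValueError("n_basis must be smaller than the interior vertex count")
    Kii = stiffness.tocsr()[interior][:, interior]
    Mii = mass.tocsr()[interior][:, interior]
    # connectivity check of the interior (Dirichlet problem must be connected)
    from scipy.sparse.csgraph import connected_components

    ncomp, _ = connected_components(abs(Kii) > 0, directed=False)
    if ncomp > 1:
        raise ValueError("interior vertex set is disconnected")
    vals, vecs = eigsh(Kii, k=n_basis, M=Mii, sigma=0, which="LM")
    order = np.argsort(vals)
    vals, vecs = vals[order], vecs[:, order]
    for k in range(vecs.shape[1]):
        v = vecs[:, k]
        v *= np.sqrt(ni) / np.linalg.norm(v)
        if v[np.argmax(np.abs(v))] < 0:
            v *= -1.0
        vecs[:, k] = v
    return vals, vecs


def laplace_embedding(candidate: CandidateMesh, n_basis: int = 100) -> CandidateMesh:
    """Dirichlet Laplace eigen-embedding of the candidate mesh.

    Rows are per-vertex coordinates (zero on the boundary, where the
    Dirichlet condition pins the basis); each column has unit variance over
    the interior vertices, giving every basis function equal weight in the
    sampling metric.
    """
    mesh = candidate.mesh
    if mesh.is_closed:
        raise ValueError("candidate mesh must have a boundary for the Dirichlet condition")
    K, _ = cotangent_laplacian(mesh)
    interior = ~mesh.boundary_vertex_flags
    # identity mass: the embedding weights every vertex equally, so the
    # basis functions are plainly orthogonal over the interior vertex set
    _, vecs = dirichlet_eigenbasis(K, sp.identity(mesh.n_vertices).tocsr(),
                                   interior, n_basis)
    emb = np.zeros((mesh.n_vertices, n_basis))
    emb[interior] = vecs
    return CandidateMesh(mesh=mesh, embedding=emb, scalp=candidate.scalp,
                         standoff=candidate.standoff)


# --------------------------------------------------------------------------
# Farthest-point sampling
# --------------------------------------------------------------------------

def farthest_point_sample(embedding: np.ndarray, k: int,
                          start_index: int = 0,
                          candidates: Optional[np.ndarray] = None) -> np.ndarray:
    """Greedy maximin selection of k rows in embedding Euclidean distance.

    Returns indices in selection order (first entry is ``start_index``);
    ties break toward the lowest index, so the output is fully deterministic
    and prefixes are nested.
    """
    X = np.asarray(embedding, float)
    if candidates is None:
        candidates = np.arange(len(X))
    candidates = np.asarray(candidates)
    if not 1 <= k <= len(candidates):
        raise ValueError("k must be in [1, number of candidate vertices]")
    if start_index not in set(candidates.tolist()):
        raise ValueError("start_index must be a candidate vertex")
    Xc = X[candidates]
    sel = [int(np.flatnonzero(candidates == start_index)[0])]
    mind = np.linalg.norm(Xc - Xc[sel[0]], axis=1)
    for _ in range(k - 1):
        nxt = int(np.argmax(mind))
        sel.append(nxt)
        mind = np.minimum(mind, np.linalg.norm(Xc - Xc[nxt], axis=1))
    return candidates[np.asarray(sel)]


def default_fps_start(candidate: CandidateMesh) -> int:
    """Deterministic FPS start: interior vertex farthest (graph distance)
    from the boundary; ties break toward the lowest vertex id."""
    mesh = candidate.mesh
    edges = mesh.edges()
    w = np.linalg.norm(mesh.vertices[edges[:, 0]] - mesh.vertices[edges[:, 1]], axis=1)
    n = mesh.n_vertices
    g = sp.coo_matrix((w, (edges[:, 0], edges[:, 1])), shape=(n, n))
    g = g + g.T
    sources = np.flatnonzero(mesh.boundary_vertex_flags)
    if not sources.size:
        raise ValueError("candidate mesh has no boundary")
    d = _csgraph_dijkstra(g, directed=False, indices=sources).min(axis=0)
    d[mesh.boundary_vertex_flags] = -np.inf
    return int(np.argmax(d))


def make_uniform_array(scalp: SurfaceMesh, helmet_seed_positions, k: int,
                       sensor_type: str = "opm", channel_mode: str = "single_axis",
                       standoff: Optional[float] = None, n_basis: int = 100,
                       target_vertices: int = 5821) -> SensorArray:
    """Quasi-uniform k-sensor layout on the coverage cap of a helmet layout.

    Pipeline: candidate mesh -> Dirichlet Laplace embedding -> farthest-point
    sampling -> scalp projection at the sensor type's standoff.
    """
    if standoff is None:
        standoff = DEFAULT_STANDOFF[sensor_type]
    cand = build_candidate_mesh(helmet_seed_positions, scalp,
                                target_vertices=target_vertices, standoff=standoff)
    cand = laplace_embedding(cand, n_basis=n_basis)
    interior = np.flatnonzero(~cand.mesh.boundary_vertex_flags)
    idx = farthest_point_sample(cand.embedding, k,
                                start_index=default_fps_start(cand),
                                candidates=interior)
    sensors = project_to_scalp(cand.mesh.vertices[idx], scalp, standoff,
                               sensor_type=sensor_type)
    return SensorArray(sensors=sensors, channel_mode=channel_mode,
                       name=f"uniform_{sensor_type}_{k}")


def mean_neighbor_distance(array: SensorArray) -> tuple[float, bool]:
    """Mean nearest-neighbor sensor distance and the overlap flag.

    The flag is raised when the mean spacing drops below the physical sensor
    element length, i.e. when neighboring sensors of that type would
    physically overlap and the array could not be built as modelled.
    """
    pos = array.positions
    if len(pos) < 2:
        raise ValueError("neighbor distance undefined for a single sensor")
    d = np.linalg.norm(pos[:, None, :] - pos[None, :, :], axis=2)
    np.fill_diagonal(d, np.inf)
    mean_nn = float(d.min(axis=1).mean())
    length = max(s.physical_length for s in array.sensors)
    return mean_nn, mean_nn < length


# --------------------------------------------------------------------------
# Helmet-like fixture layouts
# --------------------------------------------------------------------------

def helmet_layout(scalp: SurfaceMesh, n_sensors: int = 102,
                  standoff: float = 0.022, sensor_type: str = "squid_mag",
                  extent_deg: float = 115.0, channel_mode: str = "single_axis",
                  name: str = "") -> SensorArray:
    """Procedural quasi-uniform helmet covering the head down past the inion.

    Points follow a Fibonacci spiral over a spherical cap about +z with the
    given angular extent (default 115 degrees, reaching below the posterior
    head to mimic whole-head MEG coverage), then are projected to the scalp
    with the requested standoff.  This is a synthetic stand-in for
    proprietary vendor helmet geometries.
    """
    golden = np.pi * (3.0 - np.sqrt(5.0))
    i = np.arange(n_sensors)
    zmin = np.cos(np.deg2rad(extent_deg))
    z = 1.0 - (1.0 - zmin) * (i + 0.5) / n_sensors
    theta = golden * i
    rho = np.sqrt(1.0 - z ** 2)
    dirs = np.stack([rho * np.cos(theta), rho * np.sin(theta), z], axis=1)
    r_scalp = np.linalg.norm(scalp.vertices, axis=1).mean()
    sensors = project_to_scalp(dirs * (r_scalp + 0.05), scalp, standoff,
                               sensor_type=sensor_type)
    return SensorArray(sensors=sensors, channel_mode=channel_mode,
                       name=name or f"helmet_{sensor_type}_{n_sensors}")
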