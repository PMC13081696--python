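"""Synthetic head and source-surface geometry.

The analyses in this package only need geometry with the right *structure*:
a scalp to carry sensors, an inner conductor boundary for the near-boundary
source exclusion rule, a superficial gently-folded "cortex-like" source
surface and a deep, highly-folded, posterior-inferior "cerebellum-like"
surface.  Everything here is generated deterministically from a seed; no
anatomical data are used.

Folding is modelled as a band-limited radial perturbation of a spherical
cap.  The two knobs that matter downstream are the fold amplitude and the
fold spatial frequency: higher frequency produces stronger disorder of the
dipole orientations, which is the property that drives field cancellation
of deep, convoluted sources.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import trimesh


# --------------------------------------------------------------------------
# Core containers
# --------------------------------------------------------------------------

@dataclass
class SurfaceMesh:
    """Triangulated surface with vertices in meters (head-centred origin).

    ``boundary_vertex_flags`` marks vertices on an open-boundary rim; it is
    empty (all False) for closed surfaces.
    """

    vertices: np.ndarray
    faces: np.ndarray
    boundary_vertex_flags: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.faces = np.asarray(self.faces, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise ValueError("vertices must be (n, 3)")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise ValueError("faces must be (m, 3)")
        if self.faces.size and (self.faces.min() < 0 or self.faces.max() >= len(self.vertices)):
            raise ValueError("face indices out of range")
        areas = self.face_areas()
        if np.any(areas <= 0.0):
            raise ValueError("mesh contains degenerate (zero-area) triangles")
        if self.boundary_vertex_flags is None:
            self.boundary_vertex_flags = self._compute_boundary_flags()
        else:
            self.boundary_vertex_flags = np.asarray(self.boundary_vertex_flags, dtype=bool)

    # -- basic queries ----------------------------------------------------

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def face_areas(self) -> np.ndarray:
        v = self.vertices[self.faces]
        return 0.5 * np.linalg.norm(np.cross(v[:, 1] - v[:, 0], v[:, 2] - v[:, 0]), axis=1)

    def area(self) -> float:
        return float(self.face_areas().sum())

    def edges(self) -> np.ndarray:
        """Unique undirected edges, (n_edges, 2), sorted pairs."""
        e = np.concatenate([self.faces[:, [0, 1]], self.faces[:, [1, 2]], self.faces[:, [2, 0]]])
        e = np.sort(e, axis=1)
        return np.unique(e, axis=0)

    def _boundary_edges(self) -> np.ndarray:
        e = np.concatenate([self.faces[:, [0, 1]], self.faces[:, [1, 2]], self.faces[:, [2, 0]]])
        e = np.sort(e, axis=1)
        uniq, counts = np.unique(e, axis=0, return_counts=True)
        return uniq[counts == 1]

    def _compute_boundary_flags(self) -> np.ndarray:
        flags = np.zeros(self.n_vertices, dtype=bool)
        be = self._boundary_edges()
        if be.size:
            flags[np.unique(be)] = True
        return flags

    @property
    def is_closed(self) -> bool:
        return not bool(self.boundary_vertex_flags.any())

    def euler_characteristic(self) -> int:
        return self.n_vertices - len(self.edges()) + self.n_faces

    def boundary_loop_count(self) -> int:
        """Number of connected open-boundary loops."""
        be = self._boundary_edges()
        if not be.size:
            return 0
        import scipy.sparse as sp
        from scipy.sparse.csgraph import connected_components

        n = self.n_vertices
        adj = sp.coo_matrix((np.ones(len(be)), (be[:, 0], be[:, 1])), shape=(n, n))
        ncomp, labels = connected_components(adj + adj.T, directed=False)
        return len(np.unique(labels[self.boundary_vertex_flags]))

    def as_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(vertices=self.vertices, faces=self.faces, process=False)

    def vertex_normals(self) -> np.ndarray:
        """Area-weighted outward vertex normals (unit length)."""
        v = self.vertices[self.faces]
        fn = np.cross(v[:, 1] - v[:, 0], v[:, 2] - v[:, 0])  # area-weighted
        out = np.zeros_like(self.vertices)
        for k in range(3):
            np.add.at(out, self.faces[:, k], fn)
        return out / np.linalg.norm(out, axis=1, keepdims=True)


@dataclass
class SourceSpace:
    """Dipoles on a surface: positions (m), unit normals, region label."""

    positions: np.ndarray
    normals: np.ndarray
    region: str
    parent_mesh: Optional[SurfaceMesh] = None
    vertex_ids: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.normals = np.asarray(self.normals, dtype=float)
        if self.positions.shape != self.normals.shape:
            raise ValueError("positions and normals must have the same shape")
        norms = np.linalg.norm(self.normals, axis=1)
        if self.normals.size and np.any(np.abs(norms - 1.0) > 1e-9):
            raise ValueError("source normals must be unit length within 1e-9")
        if self.vertex_ids is None:
            self.vertex_ids = np.arange(len(self.positions))
        else:
            self.vertex_ids = np.asarray(self.vertex_ids, dtype=np.int64)

    def __len__(self) -> int:
        return len(self.positions)

    def subset(self, index: np.ndarray) -> "SourceSpace":
        return SourceSpace(
            positions=self.positions[index],
            normals=self.normals[index],
            region=self.region,
            parent_mesh=self.parent_mesh,
            vertex_ids=self.vertex_ids[index],
        )


def concatenate_spaces(spaces: list[SourceSpace], region: str = "whole") -> SourceSpace:
    """Column-concatenation of source spaces (e.g. cortex + cerebellum)."""
    return SourceSpace(
        positions=np.concatenate([s.positions for s in spaces]),
        normals=np.concatenate([s.normals for s in spaces]),
        region=region,
        vertex_ids=np.arange(sum(len(s) for s in spaces)),
    )


# --------------------------------------------------------------------------
# Generators
# --------------------------------------------------------------------------

def make_sphere_mesh(radius: float, subdivision_level: int) -> SurfaceMesh:
    """Closed icosphere of given radius; 10 * 4**level + 2 vertices."""
    if radius <= 0:
        raise ValueError("radius must be positive")
    if subdivision_level < 0:
        raise ValueError("subdivision_level must be >= 0")
    ico = trimesh.creation.icosphere(subdivisions=subdivision_level, radius=radius)
    return SurfaceMesh(vertices=np.asarray(ico.vertices), faces=np.asarray(ico.faces))


def _cap_submesh(unit_sphere: SurfaceMesh, center_direction: np.ndarray,
                 half_angle: float) -> tuple[np.ndarray, np.ndarray]:
    """Select the spherical-cap submesh of a unit icosphere.

    Returns (unit vertex directions, remapped faces).
    """
    c = np.asarray(center_direction, dtype=float)
    c = c / np.linalg.norm(c)
    u = unit_sphere.vertices / np.linalg.norm(unit_sphere.vertices, axis=1, keepdims=True)
    keep = u @ c >= np.cos(half_angle)
    face_keep = keep[unit_sphere.faces].all(axis=1)
    faces = unit_sphere.faces[face_keep]
    used = np.unique(faces)
    remap = -np.ones(len(u), dtype=np.int64)
    remap[used] = np.arange(len(used))
    return u[used], remap[faces]


def _fold_pattern(u: np.ndarray, fold_frequency: int, seed: int,
                  n_modes: int = 6) -> tuple[np.ndarray, np.ndarray]:
    """Band-limited pattern on the unit sphere and its surface gradient.

    Sum of ``n_modes`` plane-wave sinusoids sin(f * d_i . u + phi_i) with
    seeded random directions d_i and phases; normalised by n_modes so the
    pattern is bounded by 1.  Returns (pattern, tangential gradient) with
    the gradient taken on the unit sphere.
    """
    rng = np.random.default_rng(seed)
    d = rng.normal(size=(n_modes, 3))
    d /= np.linalg.norm(d, axis=1, keepdims=True)
    phi = rng.uniform(0, 2 * np.pi, size=n_modes)
    arg = fold_frequency * (u @ d.T) + phi  # (n_vert, n_modes)
    pattern = np.sin(arg).sum(axis=1) / n_modes
    # d/du of sin(f d.u + phi) is f cos(.) d; project onto tangent plane
    coef = fold_frequency * np.cos(arg) / n_modes  # (n_vert, n_modes)
    grad = coef @ d  # ambient gradient
    grad -= (np.sum(grad * u, axis=1, keepdims=True)) * u
    return pattern, grad


def make_folded_surface(base_radius: float, fold_amplitude: float, fold_frequency: int,
                        angular_extent: float, center_direction, seed: int,
                        region: str = "cortex",
                        subdivision_level: int = 4) -> tuple[SurfaceMesh, SourceSpace]:
    """Folded spherical-cap source surface with outward dipole normals.

    The cap is a radial graph r(u) = R + a * p(u) over the unit sphere, with
    p a seeded band-limited pattern of spatial frequency ``fold_frequency``.
    Normals are the exact normals of that continuous surface,
    n ∝ u - ∇p * a / r, so the unperturbed limit is exactly radial.
    """
    if angular_extent <= 0:
        raise ValueError("angular_extent must be positive (empty cap)")
    if fold_amplitude < 0 or (fold_amplitude > 0 and fold_amplitude >= base_radius / 4):
        raise ValueError("fold_amplitude must satisfy 0 <= a < base_radius / 4")
    if fold_frequency < 1:
        raise ValueError("fold_frequency must be >= 1")
    unit = make_sphere_mesh(1.0, subdivision_level)
    u, faces = _cap_submesh(unit, center_direction, angular_extent)
    if fold_amplitude > 0:
        pattern, grad = _fold_pattern(u, fold_frequency, seed)
    else:
        pattern = np.zeros(len(u))
        grad = np.zeros_like(u)
    r = base_radius + fold_amplitude * pattern
    vertices = u * r[:, None]
    normals = u - (fold_amplitude / r)[:, None] * grad
    normals /= np.linalg.norm(normals, axis=1, keepdims=True)
    mesh = SurfaceMesh(vertices=vertices, faces=faces)
    space = SourceSpace(positions=vertices, normals=normals, region=region,
                        parent_mesh=mesh, vertex_ids=np.arange(len(vertices)))
    return mesh, space


@dataclass
class FixtureConfig:
    """Defaults approximate an adult head scale (scalp radius 9 cm)."""

    scalp_radius: float = 0.09
    inner_radius: float = 0.083
    scalp_subdivision: int = 4
    cortex_radius: float = 0.072
    cortex_extent: float = np.deg2rad(80.0)
    cortex_fold_frequency: int = 10
    cortex_fold_amplitude: float = 0.006
    cerebellum_radius: float = 0.055
    cerebellum_extent: float = np.deg2rad(55.0)
    cerebellum_fold_frequency: int = 24
    cerebellum_fold_amplitude: float = 0.004
    source_subdivision: int = 4
    # posterior-inferior direction for the cerebellum-like cap
    cerebellum_direction: tuple = (0.0, -1.0, -1.0)
    cortex_direction: tuple = (0.0, 0.0, 1.0)


@dataclass
class GeometryFixture:
    scalp: SurfaceMesh
    inner_boundary: SurfaceMesh
    cortex_space: SourceSpace
    cerebellum_space: SourceSpace
    sphere_center: np.ndarray
    seed: int

    def __post_init__(self) -> None:
        self.sphere_center = np.asarray(self.sphere_center, dtype=float)
        # containment: every source strictly inside the inner boundary.
        # The fixture inner boundary is a sphere mesh, so a radius test
        # against its inscribed radius is exact enough (and conservative).
        r_in = np.linalg.norm(self.inner_boundary.vertices - self.sphere_center, axis=1).min()
        for sp in (self.cortex_space, self.cerebellum_space):
            rad = np.linalg.norm(sp.positions - self.sphere_center, axis=1)
            if np.any(rad >= r_in):
                raise ValueError(f"{sp.region} sources not strictly inside inner boundary")
        d_ctx = self._mean_scalp_distance(self.cortex_space)
        d_cb = self._mean_scalp_distance(self.cerebellum_space)
        if not d_cb > d_ctx:
            raise ValueError("cerebellar sources must be deeper on average than cortical")

    def _mean_scalp_distance(self, space: SourceSpace) -> float:
        r_scalp = np.linalg.norm(self.scalp.vertices - self.sphere_center, axis=1).mean()
        rad = np.linalg.norm(space.positions - self.sphere_center, axis=1)
        return float((r_scalp - rad).mean())


def make_head_fixture(config: FixtureConfig | None = None, seed: int = 0) -> GeometryFixture:
    """Build the default synthetic head: scalp, inner boundary, two source caps."""
    cfg = config or FixtureConfig()
    if not (cfg.scalp_radius > cfg.inner_radius > cfg.cortex_radius
            and cfg.inner_radius > cfg.cerebellum_radius):
        raise ValueError("radii must satisfy scalp > inner_boundary > source surfaces")
    # independent child seeds for the two folded surfaces
    s_ctx, s_cb = (int(s.generate_state(1)[0] % (2 ** 31))
                   for s in np.random.SeedSequence(seed).spawn(2))
    scalp = make_sphere_mesh(cfg.scalp_radius, cfg.scalp_subdivision)
    inner = make_sphere_mesh(cfg.inner_radius, cfg.scalp_subdivision)
    _, cortex = make_folded_surface(
        cfg.cortex_radius, cfg.cortex_fold_amplitude, cfg.cortex_fold_frequency,
        cfg.cortex_extent, cfg.cortex_direction, seed=s_ctx, region="cortex",
        subdivision_level=cfg.source_subdivision)
    _, cerebellum = make_folded_surface(
        cfg.cerebellum_radius, cfg.cerebellum_fold_amplitude, cfg.cerebellum_fold_frequency,
        cfg.cerebellum_extent, cfg.cerebellum_direction, seed=s_cb, region="cerebellum",
        subdivision_level=cfg.source_subdivision)
    return GeometryFixture(scalp=scalp, inner_boundary=inner, cortex_space=cortex,
                           cerebellum_space=cerebellum,
                           sphere_center=np.zeros(3), seed=seed)
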