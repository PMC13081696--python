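"""Subspace-angle correlation between cortical and cerebellar lead fields.

Whether a sensor array can distinguish cerebellar from cortical activity is
a question about the angle between the column spaces of the two regions'
gain matrices.  Principal angles are computed with the SVD-based
Björck–Golub procedure: orthonormal bases U_A, U_B from SVDs truncated at
numerical rank, then the singular values of U_A^T U_B are the cosines of
the principal angles — equivalently the canonical correlations between the
two sets of topographies.  A mean cosine near 1 means the regions produce
nearly indistinguishable field patterns.

Comparisons run on geodesic surface patches (10 mm radius, 15 mm seed
spacing by default) rather than single dipoles, since an angle between a
one-dimensional topography and a whole region's subspace is dominated by
the subspace dimension rather than by geometry.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import dijkstra

from .forward import LeadField
from .geometry import SourceSpace


@dataclass
class Patch:
    seed: int
    members: np.ndarray
    geodesic_radius: float

    def __post_init__(self) -> None:
        self.members = np.asarray(self.members, dtype=np.int64)
        if self.seed not in self.members:
            raise ValueError("patch seed must be one of its members")


@dataclass
class SubspaceResult:
    cosines: np.ndarray
    rank_a: int
    rank_b: int

    def __post_init__(self) -> None:
        self.cosines = np.asarray(self.cosines, float)
        if len(self.cosines) != min(self.rank_a, self.rank_b):
            raise ValueError("number of cosines must equal min(rank_a, rank_b)")
        if np.any(self.cosines < 0) or np.any(self.cosines > 1):
            raise ValueError("cosines must lie in [0, 1]")
        if np.any(np.diff(self.cosines) > 1e-12):
            raise ValueError("cosines must be sorted descending")


@dataclass
class CorrelationMap:
    values: np.ndarray
    location_ids: np.ndarray
    location_type: str          # "cerebellar_patch_seeds" | "cortical_vertices"
    seed_spacing: float
    patch_radius: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, float)
        if self.values.size and (self.values.min() < 0 or self.values.max() > 1):
            raise ValueError("correlation values must lie in [0, 1]")

    def mean(self) -> float:
        return float(np.nanmean(self.values))


# --------------------------------------------------------------------------
# Geodesic patches
# --------------------------------------------------------------------------

def _mesh_graph(space: SourceSpace) -> sp.csr_matrix:
    mesh = space.parent_mesh
    if mesh is None:
        raise ValueError("source space has no parent mesh for geodesics")
    edges = mesh.edges()
    w = np.linalg.norm(mesh.vertices[edges[:, 0]] - mesh.vertices[edges[:, 1]], axis=1)
    n = mesh.n_vertices
    g = sp.coo_matrix((w, (edges[:, 0], edges[:, 1])), shape=(n, n))
    return (g + g.T).tocsr()


def geodesic_patches(space: SourceSpace, radius: float = 0.010,
                     spacing: float = 0.015) -> list:
    """Overlapping Dijkstra-ball patches with greedily spaced seeds.

    Seeds are chosen in ascending vertex-id order subject to all pairwise
    seed geodesic distances being >= spacing; by maximality of the greedy
    set, every vertex then lies within ``spacing`` of some seed.  Members
    are all vertices with geodesic distance <= radius from the seed, on the
    edge-length-weighted mesh graph.
    """
    if radius <= 0:
        raise ValueError("patch radius must be positive")
    g = _mesh_graph(space)
    ids = np.asarray(space.vertex_ids)
    reach = max(radius, spacing)
    min_to_seed = np.full(g.shape[0], np.inf)
    seeds = []
    members = {}
    for v in np.sort(ids):
        if min_to_seed[v] < spacing:
            continue
        d = dijkstra(g, directed=False, indices=v, limit=reach * 1.0000001)
        seeds.append(int(v))
        members[int(v)] = np.flatnonzero(d <= radius)
        min_to_seed = np.minimum(min_to_seed, d)
    return [Patch(seed=s, members=members[s], geodesic_radius=radius) for s in seeds]


# --------------------------------------------------------------------------
# Principal angles
# --------------------------------------------------------------------------

def _orthonormal_basis(gain: np.ndarray) -> np.ndarray:
    u, s, _ = np.linalg.svd(gain, full_matrices=False)
    if s.size == 0 or s[0] == 0:
        raise ValueError("zero matrix has no subspace")
    tol = max(gain.shape) * np.finfo(float).eps * s[0]
    rank = int((s > tol).sum())
    return u[:, :rank]


def principal_angle_cosines(gain_a: np.ndarray, gain_b: np.ndarray) -> SubspaceResult:
    """Cosines of the principal angles between the column spaces of two gains.

    SVD-based (Björck–Golub): cosines are the singular values of
    U_A^T U_B, where U_A and U_B are rank-truncated orthonormal bases;
    values are clipped to [0, 1] against round-off.
    """
    gain_a = np.asarray(gain_a, float)
    gain_b = np.asarray(gain_b, float)
    if gain_a.shape[0] != gain_b.shape[0]:
        raise ValueError("gain matrices must share the channel dimension")
    ua = _orthonormal_basis(gain_a)
    ub = _orthonormal_basis(gain_b)
    c = np.linalg.svd(ua.T @ ub, compute_uv=False)
    return SubspaceResult(cosines=np.clip(c, 0.0, 1.0),
                          rank_a=ua.shape[1], rank_b=ub.shape[1])


def mean_subspace_correlation(result: SubspaceResult) -> float:
    """Arithmetic mean of all principal-angle cosines (single scalar summary)."""
    if result.cosines.size == 0:
        raise ValueError("empty cosine set")
    return float(result.cosines.mean())


def high_correlation_fraction(results: Sequence[SubspaceResult],
                              threshold: float = 0.5) -> np.ndarray:
    """Percent of principal-angle cosines above threshold, per result."""
    if not results:
        raise ValueError("empty result list")
    return np.array([100.0 * float((r.cosines > threshold).sum()) / len(r.cosines)
                     for r in results])


# --------------------------------------------------------------------------
# Maps
# --------------------------------------------------------------------------

def patch_to_patch_map(L_cortex: LeadField, cortical_patch: Patch,
                       L_cerebellum: LeadField,
                       cerebellar_patches: Sequence[Patch],
                       seed_spacing: float = 0.015) -> CorrelationMap:
    """One fixed cortical patch versus equal-size cerebellar patches.

    For each cerebellar patch the mean principal-angle cosine against the
    cortical patch is recorded at that patch's seed.
    """
    ga = L_cortex.gain[:, cortical_patch.members]
    values, seeds = [], []
    for p in cerebellar_patches:
        res = principal_angle_cosines(ga, L_cerebellum.gain[:, p.members])
        values.append(mean_subspace_correlation(res))
        seeds.append(p.seed)
    return CorrelationMap(values=np.array(values), location_ids=np.array(seeds),
                          location_type="cerebellar_patch_seeds",
                          seed_spacing=seed_spacing,
                          patch_radius=cortical_patch.geodesic_radius)


def patch_to_whole_map(L_cortex: LeadField, cortical_patches: Sequence[Patch],
                       L_cerebellum: LeadField,
                       seed_spacing: float = 0.015
                       ) -> tuple[CorrelationMap, np.ndarray, list]:
    """Every cortical patch versus the full cerebellar lead field.

    Returns (per-vertex map, per-patch values, per-patch SubspaceResult).
    The per-vertex map averages the values of all patches containing each
    vertex; vertices in no patch get NaN.
    """
    ub = _orthonormal_basis(L_cerebellum.gain)
    patch_values = np.empty(len(cortical_patches))
    results = []
    for i, p in enumerate(cortical_patches):
        ua = _orthonormal_basis(L_cortex.gain[:, p.members])
        c = np.clip(np.linalg.svd(ua.T @ ub, compute_uv=False), 0.0, 1.0)
        res = SubspaceResult(cosines=c, rank_a=ua.shape[1], rank_b=ub.shape[1])
        results.append(res)
        patch_values[i] = mean_subspace_correlation(res)
    n_vert = L_cortex.n_sources
    acc = np.zeros(n_vert)
    cnt = np.zeros(n_vert)
    for val, p in zip(patch_values, cortical_patches):
        acc[p.members] += val
        cnt[p.members] += 1
    with np.errstate(invalid="ignore"):
        per_vertex = np.where(cnt > 0, acc / np.maximum(cnt, 1), np.nan)
    vmap = CorrelationMap(values=per_vertex[~np.isnan(per_vertex)],
                          location_ids=np.flatnonzero(cnt > 0),
                          location_type="cortical_vertices",
                          seed_spacing=seed_spacing,
                          patch_radius=cortical_patches[0].geodesic_radius
                          if cortical_patches else 0.0)
    return vmap, patch_values, results
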