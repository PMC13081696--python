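"""Independent numerical oracles used by the test suite.

These deliberately avoid the code paths they check: the magnetic field
oracle integrates the boundary potential of a homogeneous conductor
sphere (solved numerically as a Neumann problem in spherical harmonics)
over a Gauss-Legendre surface quadrature; principal angles are taken
from orthogonal-projector products; shortest paths from networkx.
"""

import numpy as np
from numpy.polynomial.legendre import leggauss

MU0_OVER_4PI = 1e-7


def _legendre_tables(x, lmax):
    """P_l(x) and P_l^1(x) (Condon-Shortley) for l=0..lmax, vectorized."""
    P = np.zeros((lmax + 1, len(x)))
    P1 = np.zeros((lmax + 1, len(x)))
    P[0] = 1.0
    if lmax >= 1:
        P[1] = x
        P1[1] = -np.sqrt(np.clip(1 - x ** 2, 0, None))
    for l in range(2, lmax + 1):
        P[l] = ((2 * l - 1) * x * P[l - 1] - (l - 1) * P[l - 2]) / l
        P1[l] = ((2 * l - 1) * x * P1[l - 1] - l * P1[l - 2]) / (l - 1)
    return P, P1


def surface_potential(r0, q, surf_points, R, sigma, lmax=80):
    """Potential on a homogeneous conductor sphere for an interior dipole,
    by numeric harmonic solution of the Neumann problem (dipole-aligned
    frame, azimuthal orders 0 and 1 only)."""
    r0 = np.asarray(r0, float)
    q = np.asarray(q, float)
    b = np.linalg.norm(r0)
    ez = r0 / b if b > 1e-15 else np.array([0.0, 0.0, 1.0])
    tmp = np.array([1.0, 0.0, 0.0]) if abs(ez[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    ex = tmp - (tmp @ ez) * ez
    ex /= np.linalg.norm(ex)
    ey = np.cross(ez, ex)
    x = np.clip((surf_points @ ez) / R, -1, 1)
    phi = np.arctan2(surf_points @ ey, surf_points @ ex)
    # projection quadrature grid (local frame)
    ng = lmax + 20
    xg, wg = leggauss(ng)
    nphi = 2 * lmax + 21
    phig = 2 * np.pi * np.arange(nphi) / nphi
    ctg = np.repeat(xg, nphi)
    phg = np.tile(phig, ng)
    stg = np.sqrt(1 - ctg ** 2)
    Pg = R * np.stack([stg * np.cos(phg), stg * np.sin(phg), ctg], axis=1)
    wq = np.repeat(wg, nphi) * (2 * np.pi / nphi) * R ** 2
    r0l = np.array([0.0, 0.0, b])
    ql = np.array([q @ ex, q @ ey, q @ ez])
    d = Pg - r0l
    dn = np.linalg.norm(d, axis=1)
    grad = (ql[None, :] / dn[:, None] ** 3
            - 3 * (d @ ql)[:, None] * d / dn[:, None] ** 5) / (4 * np.pi * sigma)
    g = np.einsum("ij,ij->i", grad, Pg) / R
    PgL, Pg1 = _legendre_tables(ctg, lmax)
    PtL, Pt1 = _legendre_tables(x, lmax)
    cg, sg = np.cos(phg), np.sin(phg)
    ctp, stp = np.cos(phi), np.sin(phi)
    Vh = np.zeros(len(surf_points))
    for l in range(1, lmax + 1):
        n0 = np.sqrt((2 * l + 1) / (4 * np.pi))
        n1 = np.sqrt(2.0) * np.sqrt((2 * l + 1) / (4 * np.pi) / (l * (l + 1)))
        for Yg, Yt in ((n0 * PgL[l], n0 * PtL[l]),
                       (n1 * Pg1[l] * cg, n1 * Pt1[l] * ctp),
                       (n1 * Pg1[l] * sg, n1 * Pt1[l] * stp)):
            glm = np.sum(wq * g * Yg) / R ** 2   # <g, Y> over solid angle
            Vh += (-glm / (l * R ** (l - 1))) * R ** l * Yt
    dts = surf_points - r0
    dtn = np.linalg.norm(dts, axis=1)
    Vinf = (dts @ q) / (4 * np.pi * sigma * dtn ** 3)
    return Vinf + Vh


def geselowitz_field(r0, q, field_points, R=0.083, sigma=0.3, lmax=80):
    """B outside a homogeneous conductor sphere: primary dipole term plus the
    single-layer surface integral of the boundary potential."""
    r0 = np.asarray(r0, float)
    q = np.asarray(q, float)
    field_points = np.atleast_2d(np.asarray(field_points, float))
    ng = lmax + 20
    nphi = 2 * lmax + 21
    xg, wg = leggauss(ng)
    phig = 2 * np.pi * np.arange(nphi) / nphi
    ct = np.repeat(xg, nphi)
    ph = np.tile(phig, ng)
    st = np.sqrt(1 - ct ** 2)
    P = R * np.stack([st * np.cos(ph), st * np.sin(ph), ct], axis=1)
    w = np.repeat(wg, nphi) * (2 * np.pi / nphi) * R ** 2
    V = surface_potential(r0, q, P, R, sigma, lmax=lmax)
    n_hat = P / R
    out = []
    for r in field_points:
        dd = r[None, :] - P
        ddn = np.linalg.norm(dd, axis=1)
        Bp = MU0_OVER_4PI * np.cross(q, r - r0) / np.linalg.norm(r - r0) ** 3
        Bs = -MU0_OVER_4PI * sigma * np.sum(
            (w * V)[:, None] * np.cross(n_hat, dd) / ddn[:, None] ** 3, axis=0)
        out.append(Bp + Bs)
    return np.array(out)




def projector_angle_cosines(A, B):
    """Principal-angle cosines via eigenvalues of the projector product.

    cos^2(theta_i) are the nonzero eigenvalues of P_A P_B restricted to
    range(A); uses QR for the projectors, nothing shared with the SVD path.
    """
    qa, _ = np.linalg.qr(A)
    qb, _ = np.linalg.qr(B)
    # ranks via pivoted magnitudes of the diagonal of R are unreliable for
    # random full-rank tests; the fixtures always supply full-rank matrices
    Pa = qa @ qa.T
    Pb = qb @ qb.T
    evals = np.linalg.eigvalsh(Pa @ Pb @ Pa)
    r = min(A.shape[1], B.shape[1])
    cos2 = np.sort(evals)[::-1][:r]
    return np.sqrt(np.clip(cos2, 0.0, 1.0))


def fps_bruteforce_best(points, k):
    """Exhaustive maximin subset search: the k-subset maximizing the minimum
    pairwise distance.  Only usable for tiny problems."""
    from itertools import combinations

    pts = np.asarray(points, float)
    best_val, best_sub = -1.0, None
    for sub in combinations(range(len(pts)), k):
        p = pts[list(sub)]
        d = np.linalg.norm(p[:, None] - p[None, :], axis=2)
        val = d[np.triu_indices(k, 1)].min()
        if val > best_val:
            best_val, best_sub = val, sub
    return best_val, best_sub


def dijkstra_ball_networkx(mesh, seed, radius):
    """Geodesic ball membership via networkx single-source Dijkstra."""
    import networkx as nx

    g = nx.Graph()
    for (i, j) in mesh.edges():
        w = float(np.linalg.norm(mesh.vertices[i] - mesh.vertices[j]))
        g.add_edge(int(i), int(j), weight=w)
    dist = nx.single_source_dijkstra_path_length(g, int(seed), cutoff=radius,
                                                 weight="weight")
    return np.array(sorted(dist.keys()))
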