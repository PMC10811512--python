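"""3D geometry primitives: minimum-volume enclosing ellipsoid and alpha shape.

These back the morphometric indices; they are kept dependency-light
(numpy/scipy only) and deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import Delaunay


@dataclass
class Ellipsoid:
    center: np.ndarray
    radii: np.ndarray  # semi-axes, sorted descending
    rotation: np.ndarray  # rows are the axis directions

    @property
    def volume(self) -> float:
        return float(4.0 / 3.0 * np.pi * np.prod(self.radii))

    def contains(self, points: np.ndarray, tol: float = 1e-7) -> np.ndarray:
        local = (np.atleast_2d(points) - self.center) @ self.rotation.T
        return ((local / self.radii) ** 2).sum(axis=1) <= 1.0 + tol


def min_volume_ellipsoid(points: np.ndarray, tol: float = 1e-7, max_iter: int = 10000) -> Ellipsoid:
    """Minimum-volume enclosing ellipsoid by the Khachiyan coordinate-ascent
    iteration with Wolfe–Atwood away steps.

    Requires at least d+1 affinely independent points; raises for
    coplanar/collinear inputs (jitter the points to regularize if needed).
    """
    P = np.atleast_2d(np.asarray(points, dtype=float))
    n, d = P.shape
    if n < d + 1:
        raise ValueError(f"need at least {d + 1} points, got {n}")
    if np.linalg.matrix_rank(P - P.mean(axis=0), tol=1e-10) < d:
        raise ValueError(
            "points are affinely degenerate (coplanar/collinear); "
            "add a small jitter to regularize"
        )
    Q = np.column_stack([P, np.ones(n)]).T  # (d+1, n)
    u = np.full(n, 1.0 / n)
    dd = d + 1.0
    for _ in range(max_iter):
        X = (Q * u) @ Q.T
        M = np.einsum("ij,ji->i", Q.T, np.linalg.solve(X, Q))
        j_plus = int(np.argmax(M))
        support = u > 1e-12
        j_minus = int(np.flatnonzero(support)[np.argmin(M[support])])
        eps_plus = M[j_plus] / dd - 1.0
        eps_minus = 1.0 - M[j_minus] / dd
        # ε-primality bounds the relative containment error of the ellipsoid
        if max(eps_plus, eps_minus) < tol:
            break
        if eps_plus >= eps_minus:
            j = j_plus
            step = (M[j] - dd) / (dd * (M[j] - 1.0))
        else:  # away step: shrink the weight of an interior support point
            j = j_minus
            step = max(
                (M[j] - dd) / (dd * (M[j] - 1.0)), -u[j] / (1.0 - u[j])
            )
        u = (1.0 - step) * u
        u[j] += step
    c = P.T @ u
    A = np.linalg.inv(P.T @ np.diag(u) @ P - np.outer(c, c)) / d
    eigval, eigvec = np.linalg.eigh(A)
    radii = 1.0 / np.sqrt(eigval)  # ascending eigval → descending radii
    order = np.argsort(-radii)
    ell = Ellipsoid(center=c, radii=radii[order], rotation=eigvec[:, order].T)
    # guarantee containment: inflate by the residual support-point excess
    local = (P - ell.center) @ ell.rotation.T
    qmax = float(((local / ell.radii) ** 2).sum(axis=1).max())
    if qmax > 1.0:
        ell.radii = ell.radii * np.sqrt(qmax)
    return ell


@dataclass
class AlphaSurface:
    """Alpha-shape surface mesh of a 3D point set.

    ``vertices``/``faces`` describe the boundary triangles of the alpha
    complex (tetrahedra with circumradius ≤ alpha); ``volume`` is the summed
    tetrahedron volume of the complex, ``area`` the total boundary triangle
    area, ``weighted_center`` the area-weighted centroid of the boundary
    triangles.
    """

    vertices: np.ndarray
    faces: np.ndarray
    volume: float
    area: float
    weighted_center: np.ndarray
    alpha: float

    @property
    def triangles(self) -> np.ndarray:
        return self.vertices[self.faces]

    def face_areas(self) -> np.ndarray:
        tri = self.triangles
        return 0.5 * np.linalg.norm(
            np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0]), axis=1
        )

    def sample_surface(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Draw n points area-uniformly on the boundary mesh."""
        areas = self.face_areas()
        idx = rng.choice(len(areas), size=n, p=areas / areas.sum())
        tri = self.triangles[idx]
        r1 = np.sqrt(rng.uniform(size=n))[:, None]
        r2 = rng.uniform(size=n)[:, None]
        return (
            (1 - r1) * tri[:, 0]
            + r1 * (1 - r2) * tri[:, 1]
            + r1 * r2 * tri[:, 2]
        )

    def to_trimesh(self):
        """Optional trimesh view (trimesh is not a hard dependency)."""
        import trimesh

        return trimesh.Trimesh(self.vertices, self.faces, process=False)


def _circumradii(points: np.ndarray, tets: np.ndarray) -> np.ndarray:
    """Circumradius of each tetrahedron (vectorized)."""
    a, b, c, d = (points[tets[:, i]] for i in range(4))
    # solve for circumcenter: rows 2(b-a), 2(c-a), 2(d-a); rhs |b|²-|a|² ...
    A = 2.0 * np.stack([b - a, c - a, d - a], axis=1)
    rhs = np.stack(
        [
            (b**2).sum(1) - (a**2).sum(1),
            (c**2).sum(1) - (a**2).sum(1),
            (d**2).sum(1) - (a**2).sum(1),
        ],
        axis=1,
    )
    radii = np.full(len(tets), np.inf)
    det = np.linalg.det(A)
    ok = np.abs(det) > 1e-12
    centers = np.linalg.solve(A[ok], rhs[ok][..., None])[..., 0]
    radii[ok] = np.linalg.norm(centers - a[ok], axis=1)
    return radii


def _tet_volumes(points: np.ndarray, tets: np.ndarray) -> np.ndarray:
    a, b, c, d = (points[tets[:, i]] for i in range(4))
    return np.abs(np.einsum("ij,ij->i", np.cross(b - a, c - a), d - a)) / 6.0


def alpha_shape(points: np.ndarray, alpha: float) -> AlphaSurface:
    """Alpha shape of a 3D point set via the Delaunay alpha complex.

    Keeps tetrahedra with circumradius ≤ alpha; the boundary consists of
    faces that belong to exactly one kept tetrahedron.  Raises when the
    kept complex is empty or splits into multiple connected components
    (alpha too small for a single closed surface).
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if len(pts) < 4:
        raise ValueError("need at least 4 points")
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    tri = Delaunay(pts)
    tets = tri.simplices
    keep = _circumradii(pts, tets) <= alpha
    kept = tets[keep]
    if len(kept) == 0:
        raise ValueError("alpha too small: empty alpha complex (0 components)")

    faces = np.concatenate(
        [kept[:, [0, 1, 2]], kept[:, [0, 1, 3]], kept[:, [0, 2, 3]], kept[:, [1, 2, 3]]]
    )
    key = np.sort(faces, axis=1)
    uniq, inverse, counts = np.unique(
        key, axis=0, return_inverse=True, return_counts=True
    )
    boundary = uniq[counts == 1]

    n_comp = _component_count(kept, key, inverse, counts)
    if n_comp != 1:
        raise ValueError(
            f"alpha complex has {n_comp} connected components; increase alpha"
        )

    tri_pts = pts[boundary]
    areas = 0.5 * np.linalg.norm(
        np.cross(tri_pts[:, 1] - tri_pts[:, 0], tri_pts[:, 2] - tri_pts[:, 0]), axis=1
    )
    centroids = tri_pts.mean(axis=1)
    center = (areas[:, None] * centroids).sum(axis=0) / areas.sum()
    return AlphaSurface(
        vertices=pts,
        faces=boundary,
        volume=float(_tet_volumes(pts, kept).sum()),
        area=float(areas.sum()),
        weighted_center=center,
        alpha=alpha,
    )


def _component_count(kept, face_key, inverse, counts) -> int:
    """Connected components of kept tetrahedra under shared-face adjacency."""
    from scipy.sparse import coo_matrix
    from scipy.sparse.csgraph import connected_components

    n = len(kept)
    tet_of_face = np.tile(np.arange(n), 4)
    order = np.argsort(inverse, kind="stable")
    inv_sorted = inverse[order]
    tets_sorted = tet_of_face[order]
    # faces shared by two tets are consecutive in the sorted order
    shared = np.nonzero(inv_sorted[:-1] == inv_sorted[1:])[0]
    rows = tets_sorted[shared]
    cols = tets_sorted[shared + 1]
    adj = coo_matrix(
        (np.ones(len(rows)), (rows, cols)), shape=(n, n)
    )
    n_comp, _ = connected_components(adj, directed=False)
    return n_comp


def auto_alpha(points: np.ndarray, margin: float = 1.05, coverage: float = 0.99) -> float:
    """Smallest alpha (times ``margin``) giving a single connected alpha
    complex that covers at least ``coverage`` of the points.

    Surface-sampled clouds have near-cospherical Delaunay tetrahedra whose
    circumradii concentrate near the local curvature radius, so a fixed
    small alpha can yield an empty or fragmented complex; this picks the
    connectivity threshold from the circumradius distribution instead.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    tri = Delaunay(pts)
    tets = tri.simplices
    radii = _circumradii(pts, tets)
    finite = np.unique(radii[np.isfinite(radii)])
    if finite.size == 0:
        raise ValueError("no finite circumradius; degenerate point set")
    lo, hi = 0, len(finite) - 1
    if not _connected_and_covering(pts, tets, radii, finite[hi], coverage):
        raise ValueError("no alpha yields a single covering component")
    while lo < hi:
        mid = (lo + hi) // 2
        if _connected_and_covering(pts, tets, radii, finite[mid], coverage):
            hi = mid
        else:
            lo = mid + 1
    return float(finite[hi] * margin)


def _connected_and_covering(pts, tets, radii, alpha, coverage) -> bool:
    kept = tets[radii <= alpha]
    if len(kept) == 0:
        return False
    used = np.unique(kept)
    if len(used) < coverage * len(pts):
        return False
    faces = np.concatenate(
        [kept[:, [0, 1, 2]], kept[:, [0, 1, 3]], kept[:, [0, 2, 3]], kept[:, [1, 2, 3]]]
    )
    key = np.sort(faces, axis=1)
    _, inverse, counts = np.unique(key, axis=0, return_inverse=True, return_counts=True)
    return _component_count(kept, key, inverse, counts) == 1


def nn_distances(points: np.ndarray, k: int = 1) -> np.ndarray:
    """k-th nearest-neighbor distance for each point (k=1: first neighbor)."""
    from scipy.spatial import cKDTree

    pts = np.atleast_2d(points)
    d, _ = cKDTree(pts).query(pts, k=k + 1)
    return d[:, k]
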