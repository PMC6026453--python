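"""Triangle-mesh ingestion and geometric primitives for egg digitisation.

This module owns the raw geometric object of the pipeline -- a closed,
consistently oriented triangle surface of an eggshell exterior -- together
with the operations the digitiser needs: PLY read/write, enclosed and
convex-hull volumes, principal-axes alignment, pole orientation (pointed
end toward +x) and ray/surface queries.

Meshes are stored as plain ``(vertices, faces)`` arrays; :mod:`trimesh` is
used for format parsing and topology checks, while the ray-casting and
closest-point kernels are implemented here as vectorised NumPy routines
(exhaustive over triangles -- the eggshell meshes are ~10,000 triangles,
for which brute force is both fast and robust).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import trimesh as _tm
from scipy.spatial import ConvexHull, QhullError


class MeshError(ValueError):
    """Invalid mesh or mesh operation."""


class OpenMeshError(MeshError):
    """Mesh is not closed/edge-manifold where a closed mesh is required."""


class DegenerateMeshError(MeshError):
    """Mesh geometry is degenerate (flat, zero area, ...)."""


class RayMissError(MeshError):
    """A surface ray query found no intersection."""


@dataclass
class TriMesh:
    """A triangulated surface: ``vertices`` (n, 3) float64, ``faces`` (m, 3) int."""

    vertices: np.ndarray
    faces: np.ndarray
    name: str = ""

    def __post_init__(self) -> None:
        self.vertices = np.ascontiguousarray(self.vertices, dtype=np.float64)
        self.faces = np.ascontiguousarray(self.faces, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise MeshError("vertices must be an (n, 3) array")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise MeshError("faces must be an (m, 3) array of vertex triples")
        if not np.isfinite(self.vertices).all():
            raise MeshError("non-finite vertex coordinates")
        if len(self.faces):
            if self.faces.min() < 0 or self.faces.max() >= len(self.vertices):
                raise MeshError("face indices out of range")
            if (np.diff(np.sort(self.faces, axis=1), axis=1) == 0).any():
                raise MeshError("face with repeated vertex indices")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def copy(self) -> "TriMesh":
        return TriMesh(self.vertices.copy(), self.faces.copy(), self.name)

    def triangles(self) -> np.ndarray:
        """(m, 3, 3) array of triangle vertex coordinates."""
        return self.vertices[self.faces]

    def to_trimesh(self) -> _tm.Trimesh:
        return _tm.Trimesh(self.vertices, self.faces, process=False, validate=False)

    def is_closed(self) -> bool:
        return bool(self.to_trimesh().is_watertight)


@dataclass
class RigidTransform:
    """Proper rigid motion ``x -> rotation @ x + translation``."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=np.float64)
        self.translation = np.asarray(self.translation, dtype=np.float64)
        R = self.rotation
        if R.shape != (3, 3) or self.translation.shape != (3,):
            raise ValueError("rotation must be 3x3 and translation a 3-vector")
        if np.abs(R @ R.T - np.eye(3)).max() > 1e-10:
            raise ValueError("rotation is not orthonormal")
        if abs(np.linalg.det(R) - 1.0) > 1e-10:
            raise ValueError("rotation must have determinant +1 (no reflections)")

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points, dtype=np.float64) @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return the transform equivalent to applying ``other`` then ``self``."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )


# ---------------------------------------------------------------------------
# PLY I/O
# ---------------------------------------------------------------------------

def read_mesh(path: str | os.PathLike) -> TriMesh:
    """Read a triangle mesh from an ASCII or binary little-endian PLY file.

    Non-triangular faces are fan-triangulated by the parser. Closedness is
    *not* enforced here; operations that require a closed mesh raise
    :class:`OpenMeshError` themselves.
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    try:
        loaded = _tm.load(path, file_type="ply", process=False)
    except Exception as exc:  # malformed header / payload
        raise MeshError(f"could not parse PLY file {path!r}: {exc}") from exc
    if not isinstance(loaded, _tm.Trimesh) or len(loaded.faces) == 0:
        raise MeshError(f"{path!r} does not contain a triangle mesh")
    name = os.path.splitext(os.path.basename(path))[0]
    return TriMesh(np.asarray(loaded.vertices, dtype=np.float64),
                   np.asarray(loaded.faces), name=name)


def write_mesh(mesh: TriMesh, path: str | os.PathLike, mode: str = "ascii") -> None:
    """Write a PLY file. ``mode='ascii'`` round-trips float64 coordinates
    bit-identically (17 significant digits); ``mode='binary'`` writes
    binary little-endian float64."""
    if mode not in ("ascii", "binary"):
        raise ValueError("mode must be 'ascii' or 'binary'")
    if mesh.n_vertices == 0 or mesh.n_faces == 0:
        raise MeshError("refusing to write an empty mesh")
    fmt = "ascii" if mode == "ascii" else "binary_little_endian"
    header = (
        "ply\n"
        f"format {fmt} 1.0\n"
        "comment written by eggmorph\n"
        f"element vertex {mesh.n_vertices}\n"
        "property double x\n"
        "property double y\n"
        "property double z\n"
        f"element face {mesh.n_faces}\n"
        "property list uchar int vertex_indices\n"
        "end_header\n"
    )
    with open(path, "wb") as fh:
        fh.write(header.encode("ascii"))
        if mode == "ascii":
            lines = [
                f"{x:.17g} {y:.17g} {z:.17g}" for x, y, z in mesh.vertices
            ]
            lines += [f"3 {a} {b} {c}" for a, b, c in mesh.faces]
            fh.write(("\n".join(lines) + "\n").encode("ascii"))
        else:
            fh.write(mesh.vertices.astype("<f8").tobytes())
            face_dtype = np.dtype([("n", "u1"), ("idx", "<i4", (3,))])
            rec = np.empty(mesh.n_faces, dtype=face_dtype)
            rec["n"] = 3
            rec["idx"] = mesh.faces
            fh.write(rec.tobytes())


# ---------------------------------------------------------------------------
# Volumes
# ---------------------------------------------------------------------------

def enclosed_volume(mesh: TriMesh) -> float:
    """Volume enclosed by a closed, outward-oriented mesh (divergence theorem
    over signed tetrahedra spanned by the origin and each face)."""
    tm = mesh.to_trimesh()
    if not tm.is_watertight:
        raise OpenMeshError("enclosed_volume requires a closed (watertight) mesh")
    tri = mesh.triangles()
    vol = float(np.einsum("ij,ij->", tri[:, 0], np.cross(tri[:, 1], tri[:, 2]))) / 6.0
    if vol <= 0:
        raise MeshError("signed volume is non-positive: inconsistent (inward) face "
                        "orientation")
    return vol


def convex_hull_volume(points: np.ndarray) -> float:
    """Volume of the convex hull of a 3D point set (>= 4 non-coplanar points)."""
    pts = np.asarray(points, dtype=np.float64)
    if pts.ndim != 2 or pts.shape[1] != 3 or len(pts) < 4:
        raise MeshError("convex hull needs at least 4 three-dimensional points")
    try:
        hull = ConvexHull(pts)
    except QhullError as exc:
        raise DegenerateMeshError(f"degenerate (coplanar?) point set: {exc}") from exc
    return float(hull.volume)


# ---------------------------------------------------------------------------
# Principal-axes alignment and pole orientation
# ---------------------------------------------------------------------------

def _surface_centroid_and_covariance(mesh: TriMesh) -> tuple[np.ndarray, np.ndarray]:
    tri = mesh.triangles()
    cross = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
    areas = 0.5 * np.linalg.norm(cross, axis=1)
    total = areas.sum()
    if total <= 0:
        raise DegenerateMeshError("mesh has zero surface area")
    w = areas / total
    centroids = tri.mean(axis=1)
    c = w @ centroids
    d = centroids - c
    cov = (w[:, None] * d).T @ d
    return c, cov


def _fix_eigenvector_ties(evals: np.ndarray, evecs: np.ndarray,
                          rel_tol: float = 1e-9) -> np.ndarray:
    """Within groups of (numerically) equal eigenvalues the eigenbasis is
    arbitrary; rotate each tied block to the basis closest to the coordinate
    axes so the alignment is deterministic (e.g. for spheres)."""
    n = len(evals)
    scale = max(evals.max(), 1e-300)
    groups: list[list[int]] = [[0]]
    for i in range(1, n):
        if abs(evals[i] - evals[i - 1]) < rel_tol * scale:
            groups[-1].append(i)
        else:
            groups.append([i])
    out = evecs.copy()
    for g in groups:
        if len(g) == 1:
            continue
        V = evecs[:, g]                      # 3 x k block
        E = np.eye(n)[:, g]
        U, _, Vt = np.linalg.svd(V.T @ E)
        out[:, g] = V @ (U @ Vt)             # orthogonal Procrustes to axes
    return out


def principal_axes_align(mesh: TriMesh) -> tuple[TriMesh, RigidTransform]:
    """Centre the mesh at its area-weighted surface centroid and rotate its
    principal axes onto the coordinate axes, longest dimension on x.

    The axes are the eigenvectors of the area-weighted covariance of face
    centroids. The rotation is proper (det +1). The residual sign freedom
    per axis is resolved intrinsically -- each axis is oriented so the
    area-weighted third moment of the surface along it is positive -- which
    makes the canonical frame a function of the surface alone, hence
    equivariant under rigid motions of the input. Axes whose third moment
    vanishes (symmetric surfaces) fall back to the proper sign combination
    closest to the identity.
    """
    c, cov = _surface_centroid_and_covariance(mesh)
    evals, evecs = np.linalg.eigh(cov)       # ascending
    evals, evecs = evals[::-1], evecs[:, ::-1]
    if evals[0] <= 0 or evals[2] < 1e-10 * evals[0]:
        raise DegenerateMeshError("flat or degenerate mesh: principal axes undefined")
    evecs = _fix_eigenvector_ties(evals, evecs)
    R = evecs.T
    det_sign = np.sign(np.linalg.det(R))

    tri = mesh.triangles()
    cross = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
    w = 0.5 * np.linalg.norm(cross, axis=1)
    w /= w.sum()
    proj = (tri.mean(axis=1) - c) @ R.T
    m3 = w @ proj ** 3                       # per-axis skewness (length^3)
    m3_rel = m3 / np.maximum(evals, 1e-300) ** 1.5
    determined = np.abs(m3_rel) > 1e-8
    want = np.sign(m3_rel)

    # among proper sign combinations, prefer the intrinsically determined
    # orientation; indeterminate axes break ties toward the identity
    best_key, best_R = None, None
    for s in np.array([[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1],
                       [-1, -1, -1], [-1, 1, 1], [1, -1, 1], [1, 1, -1]],
                      dtype=float):
        if s.prod() * det_sign < 0:          # keeps det(R) = +1
            continue
        mismatch = float(np.abs(m3_rel)[determined & (s != want)].sum()) \
            if determined.any() else 0.0
        cand = s[:, None] * R
        key = (mismatch, -np.trace(cand))
        if best_key is None or key < best_key:
            best_key, best_R = key, cand
    R = best_R
    transform = RigidTransform(R, -R @ c)
    aligned = TriMesh(transform.apply(mesh.vertices), mesh.faces.copy(), mesh.name)
    return aligned, transform


#: proper 180-degree rotation about z used to exchange the poles
_FLIP_Z = np.diag([-1.0, -1.0, 1.0])


def orient_poles(mesh: TriMesh, rel_tol: float = 1e-9) -> tuple[TriMesh, bool]:
    """Ensure the pointed pole lies toward +x.

    The mesh (already principal-axes aligned) is split at the plane x = 0;
    the half whose vertex subset has the smaller convex-hull volume is the
    pointed one. If it sits at -x the mesh is rotated 180 degrees about z
    (a proper rotation, so handedness is preserved). Ties within ``rel_tol``
    (relative) are broken by not flipping.
    """
    v = mesh.vertices
    vol_pos = convex_hull_volume(v[v[:, 0] >= 0])
    vol_neg = convex_hull_volume(v[v[:, 0] <= 0])
    flipped = (vol_pos - vol_neg) > rel_tol * max(vol_pos, vol_neg)
    if flipped:
        mesh = TriMesh(v @ _FLIP_Z.T, mesh.faces.copy(), mesh.name)
    return (mesh.copy() if not flipped else mesh), bool(flipped)


# ---------------------------------------------------------------------------
# Ray casting and closest-point queries (vectorised, exhaustive)
# ---------------------------------------------------------------------------

def _ray_hits(mesh: TriMesh, origin: np.ndarray, direction: np.ndarray,
              eps: float) -> np.ndarray:
    """Moller-Trumbore over all triangles; returns sorted positive ray
    parameters of the intersections."""
    tri = mesh.triangles()
    v0, e1, e2 = tri[:, 0], tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0]
    pvec = np.cross(direction, e2)
    det = np.einsum("ij,ij->i", e1, pvec)
    ok = np.abs(det) > eps
    inv_det = np.zeros_like(det)
    inv_det[ok] = 1.0 / det[ok]
    tvec = origin - v0
    u = np.einsum("ij,ij->i", tvec, pvec) * inv_det
    qvec = np.cross(tvec, e1)
    v = (qvec @ direction) * inv_det
    t = np.einsum("ij,ij->i", e2, qvec) * inv_det
    bary_eps = 1e-12
    ok &= (u >= -bary_eps) & (v >= -bary_eps) & (u + v <= 1 + bary_eps) & (t > eps)
    return np.sort(t[ok])


def ray_surface_intersection(mesh: TriMesh, origin, direction) -> np.ndarray:
    """Outermost intersection of the ray ``origin + t * direction`` (t > 0)
    with the mesh surface. Taking the largest positive t makes near-tangent
    double hits stable. Raises :class:`RayMissError` if nothing is hit."""
    origin = np.asarray(origin, dtype=np.float64)
    direction = np.asarray(direction, dtype=np.float64)
    norm = np.linalg.norm(direction)
    if norm == 0:
        raise ValueError("direction must be a non-zero vector")
    direction = direction / norm
    scale = float(np.abs(mesh.vertices).max()) or 1.0
    eps = 1e-14 * scale
    ts = _ray_hits(mesh, origin, direction, eps)
    if len(ts) == 0:
        # deterministic retry for rays that graze a vertex or edge exactly
        basis = np.eye(3)
        perp = basis[np.argmin(np.abs(direction))]
        perp = perp - (perp @ direction) * direction
        perp /= np.linalg.norm(perp)
        for mag in (1e-10, 1e-8):
            for sgn in (1.0, -1.0):
                d2 = direction + sgn * mag * perp
                d2 /= np.linalg.norm(d2)
                ts = _ray_hits(mesh, origin, d2, eps)
                if len(ts):
                    return origin + ts[-1] * d2
        raise RayMissError("ray does not intersect the mesh surface")
    return origin + ts[-1] * direction


def _closest_on_triangles(pts: np.ndarray, tri: np.ndarray
                          ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-query nearest point over a candidate triangle set.

    ``pts``: (q, 3); ``tri``: (q, k, 3, 3). Returns (closest (q, 3),
    distance (q,), argmin index into k). Ericson's barycentric region test,
    fully vectorised.
    """
    a, b, c = tri[:, :, 0], tri[:, :, 1], tri[:, :, 2]
    ab, ac = b - a, c - a
    p = pts[:, None, :]
    ap, bp, cp = p - a, p - b, p - c
    d1 = np.einsum("qfj,qfj->qf", ab, ap)
    d2 = np.einsum("qfj,qfj->qf", ac, ap)
    d3 = np.einsum("qfj,qfj->qf", ab, bp)
    d4 = np.einsum("qfj,qfj->qf", ac, bp)
    d5 = np.einsum("qfj,qfj->qf", ab, cp)
    d6 = np.einsum("qfj,qfj->qf", ac, cp)
    va = d3 * d6 - d5 * d4
    vb = d5 * d2 - d1 * d6
    vc = d1 * d4 - d3 * d2
    denom = va + vb + vc
    with np.errstate(divide="ignore", invalid="ignore"):
        v = np.nan_to_num(vb / denom)
        w = np.nan_to_num(vc / denom)
        t_ab = np.clip(np.nan_to_num(d1 / (d1 - d3)), 0.0, 1.0)
        t_ac = np.clip(np.nan_to_num(d2 / (d2 - d6)), 0.0, 1.0)
        t_bc = np.clip(np.nan_to_num((d4 - d3) / ((d4 - d3) + (d5 - d6))),
                       0.0, 1.0)
    bary = np.stack([1.0 - v - w, v, w], axis=-1)   # interior projection
    in_a = (d1 <= 0) & (d2 <= 0)
    in_b = (d3 >= 0) & (d4 <= d3)
    in_c = (d6 >= 0) & (d5 <= d6)
    on_ab = (~in_a) & (~in_b) & (vc <= 0) & (d1 >= 0) & (d3 <= 0)
    on_ac = (~in_a) & (~in_c) & (vb <= 0) & (d2 >= 0) & (d6 <= 0)
    on_bc = (~in_b) & (~in_c) & (va <= 0) & ((d4 - d3) >= 0) & ((d5 - d6) >= 0)
    zero = np.zeros_like(t_ab)
    bary[on_ab] = np.stack([1 - t_ab, t_ab, zero], axis=-1)[on_ab]
    bary[on_ac] = np.stack([1 - t_ac, zero, t_ac], axis=-1)[on_ac]
    bary[on_bc] = np.stack([zero, 1 - t_bc, t_bc], axis=-1)[on_bc]
    bary[in_a] = [1.0, 0.0, 0.0]
    bary[in_b] = [0.0, 1.0, 0.0]
    bary[in_c] = [0.0, 0.0, 1.0]
    cand = np.einsum("qfk,qfkj->qfj", bary, tri)
    dist2 = ((cand - p) ** 2).sum(-1)
    j = np.argmin(dist2, axis=1)
    rows = np.arange(len(j))
    return cand[rows, j], np.sqrt(dist2[rows, j]), j


def _proximity_cache(mesh: TriMesh):
    """KD-tree over face centroids plus the largest centroid-to-vertex
    radius, cached on the mesh object."""
    cache = getattr(mesh, "_prox_cache", None)
    if cache is None or cache[0] is not mesh.vertices:
        from scipy.spatial import cKDTree
        tri = mesh.triangles()
        centroids = tri.mean(axis=1)
        h = np.linalg.norm(tri - centroids[:, None, :], axis=2).max()
        cache = (mesh.vertices, cKDTree(centroids), float(h))
        mesh._prox_cache = cache
    return cache


def closest_points_on_surface(mesh: TriMesh, points: np.ndarray
                              ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Nearest point on the triangulated surface for each query point.

    Returns ``(closest, distances, face_index)``. Candidate triangles are
    preselected by a KD-tree over face centroids; any query whose best
    candidate distance cannot be certified optimal (within the largest
    face radius) falls back to an exhaustive scan, so the result is exact.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=np.float64))
    tri = mesh.triangles()
    m = len(tri)
    k = min(48, m)
    _, tree, h_max = _proximity_cache(mesh)
    cdist, cidx = tree.query(pts, k=k)
    if k == 1:
        cdist, cidx = cdist[:, None], cidx[:, None]
    out, dist, jloc = _closest_on_triangles(pts, tri[cidx])
    fidx = cidx[np.arange(len(pts)), jloc]
    if k < m:
        # optimality certificate: any face not among the candidates has its
        # centroid farther than the k-th distance, hence its surface at
        # least (k-th distance - h_max) away
        unsure = dist > cdist[:, -1] - h_max
        if unsure.any():
            sub = pts[unsure]
            best = (np.empty((len(sub), 3)), np.full(len(sub), np.inf),
                    np.empty(len(sub), dtype=np.int64))
            block = max(1, int(2e6 / m))
            for s in range(0, len(sub), block):
                t_all = np.broadcast_to(tri, (len(sub[s:s + block]), m, 3, 3))
                o, d, j = _closest_on_triangles(sub[s:s + block], t_all)
                best[0][s:s + block] = o
                best[1][s:s + block] = d
                best[2][s:s + block] = j
            out[unsure], dist[unsure], fidx[unsure] = best
    return out, dist, fidx


def face_normals(mesh: TriMesh) -> np.ndarray:
    """Unit outward normals per face (assumes consistent winding)."""
    tri = mesh.triangles()
    n = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
    lens = np.linalg.norm(n, axis=1, keepdims=True)
    lens[lens == 0] = 1.0
    return n / lens


def validation_report(mesh: TriMesh) -> dict:
    """JSON-able summary used by the CLI logs: counts, closedness, volume."""
    tm = mesh.to_trimesh()
    closed = bool(tm.is_watertight)
    report = {
        "name": mesh.name,
        "n_vertices": mesh.n_vertices,
        "n_faces": mesh.n_faces,
        "closed": closed,
        "winding_consistent": bool(tm.is_winding_consistent),
        "euler_characteristic": int(tm.euler_number),
        "volume": None,
    }
    if closed:
        try:
            report["volume"] = enclosed_volume(mesh)
        except MeshError:
            report["volume"] = None
    return report
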