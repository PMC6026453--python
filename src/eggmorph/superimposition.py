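"""Generalised Procrustes analysis with sliding semilandmarks.

Configurations are centred, scaled to unit centroid size and rotated (no
reflections) to a consensus that is re-estimated iteratively. When sliding
is enabled, each specimen's semilandmarks are displaced within local
tangent planes by the closed-form least-squares step that minimises the
thin-plate-spline bending energy of its deviation from the consensus
(anchors never move); slid points are re-projected onto the specimen's
surface mesh when meshes are available, so landmarks stay on the shell.

Tangent planes come from the mesh normal at each landmark when meshes are
supplied; otherwise the surface normal is approximated by the radial
direction from the configuration centroid, which is well defined for
star-shaped surfaces such as eggs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import mesh_core
from .mesh_core import TriMesh
from .tps_core import BendingEnergyMatrix, bending_energy_matrix


class SuperimpositionError(ValueError):
    """Degenerate configuration or failed alignment."""


def _center(X: np.ndarray) -> np.ndarray:
    return X - X.mean(axis=0)


def centroid_size(X: np.ndarray) -> float:
    return float(np.linalg.norm(_center(np.asarray(X, dtype=np.float64))))


def _unit(X: np.ndarray) -> np.ndarray:
    Xc = _center(np.asarray(X, dtype=np.float64))
    cs = np.linalg.norm(Xc)
    if cs == 0:
        raise SuperimpositionError("zero centroid size")
    return Xc / cs


def _optimal_rotation(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Rotation R (det +1) minimising ||A R - B||_F for centred A, B."""
    U, _, Vt = np.linalg.svd(A.T @ B)
    D = np.eye(3)
    D[2, 2] = np.sign(np.linalg.det(U @ Vt))
    return U @ D @ Vt


def opa(moving: np.ndarray, fixed: np.ndarray) -> tuple[np.ndarray, float]:
    """Ordinary Procrustes: centre both, scale to unit centroid size, rotate
    ``moving`` onto ``fixed`` (reflections disallowed). Returns the aligned
    moving configuration and the Procrustes distance
    sqrt(sum of squared coordinate differences)."""
    A, B = _unit(moving), _unit(fixed)
    if A.shape != B.shape:
        raise SuperimpositionError("configurations must have equal dimensions")
    aligned = A @ _optimal_rotation(A, B)
    return aligned, float(np.linalg.norm(aligned - B))


def procrustes_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Procrustes distance between two configurations (the distance part
    of :func:`opa`)."""
    return opa(a, b)[1]


@dataclass
class SlidingConfig:
    """Semilandmark sliding options.

    ``indices``: row indices allowed to slide (default: all but the first
    six anchors). ``passes``: maximum sliding passes per GPA iteration.
    ``energy_tol``: stop passes early when the relative drop in summed
    bending energy falls below this. ``project``: re-project slid points to
    the specimen mesh surface (only possible when meshes are supplied).
    ``max_slide_iterations``: sliding is applied during at most this many
    GPA iterations (or until the summed energy plateaus between
    iterations); afterwards the landmarks freeze and the plain Procrustes
    iteration polishes to convergence. Unbounded sliding lets
    semilandmarks crawl indefinitely at ever-smaller energy gains, which
    stalls the consensus without changing the shape solution.
    """

    indices: np.ndarray | None = None
    passes: int = 3
    energy_tol: float = 1e-6
    project: bool = True
    max_slide_iterations: int = 10

    def resolve_indices(self, p: int) -> np.ndarray:
        if self.indices is None:
            return np.arange(6, p)
        idx = np.asarray(self.indices, dtype=np.int64)
        if len(idx) and (idx.min() < 0 or idx.max() >= p):
            raise SuperimpositionError("sliding indices out of range")
        return idx


@dataclass
class AlignmentResult:
    """Output of GPA: aligned unit-size configurations and their consensus."""

    aligned: np.ndarray            # (n, p, 3)
    consensus: np.ndarray          # (p, 3), arithmetic mean of aligned
    centroid_sizes: np.ndarray     # (n,) sizes of the input configurations
    iterations: int
    converged: bool

    @property
    def n_specimens(self) -> int:
        return self.aligned.shape[0]

    @property
    def n_landmarks(self) -> int:
        return self.aligned.shape[1]

    def flattened(self) -> np.ndarray:
        """(n, 3p) row-per-specimen matrix of aligned coordinates."""
        return self.aligned.reshape(self.n_specimens, -1)


def _tangent_frames(normals: np.ndarray) -> np.ndarray:
    """(q, 3, 2) orthonormal tangent bases perpendicular to unit normals."""
    n = normals / np.linalg.norm(normals, axis=1, keepdims=True)
    helper = np.eye(3)[np.argmin(np.abs(n), axis=1)]
    t1 = np.cross(n, helper)
    t1 /= np.linalg.norm(t1, axis=1, keepdims=True)
    t2 = np.cross(n, t1)
    return np.stack([t1, t2], axis=-1)


def _slide_one(x: np.ndarray, consensus: np.ndarray, idx: np.ndarray,
               normals: np.ndarray, bemat: BendingEnergyMatrix) -> np.ndarray:
    """Closed-form tangent-plane sliding step for one specimen."""
    B = bemat.matrix
    U = _tangent_frames(normals)                       # (q, 3, 2)
    q = len(idx)
    Bss = B[np.ix_(idx, idx)]
    G = np.einsum("kda,ldb->kalb", U, U)
    M = (Bss[:, None, :, None] * G).reshape(2 * q, 2 * q)
    r = x - consensus
    Br = B @ r
    rhs = -np.einsum("kda,kd->ka", U, Br[idx]).reshape(2 * q)
    # tiny ridge keeps the system well-posed; the ridge solution still
    # never increases the bending energy (it minimises energy + penalty)
    M[np.diag_indices_from(M)] += 1e-10 * max(np.abs(np.diagonal(M)).max(), 1e-300)
    c = np.linalg.solve(M, rhs).reshape(q, 2)
    out = x.copy()
    out[idx] += np.einsum("kda,ka->kd", U, c)
    return out


def _normals_for(x: np.ndarray, idx: np.ndarray, mesh: TriMesh | None,
                 transform) -> np.ndarray:
    """Unit surface normals at the sliding landmarks, in the aligned frame."""
    if mesh is None:
        pts = x[idx]
        norms = np.linalg.norm(pts, axis=1, keepdims=True)
        if (norms == 0).any():
            raise SuperimpositionError("landmark at configuration centroid: "
                                       "radial normal undefined")
        return pts / norms
    c, s, R = transform
    raw_pts = s * (x[idx] @ R.T) + c
    _, _, fidx = mesh_core.closest_points_on_surface(mesh, raw_pts)
    return mesh_core.face_normals(mesh)[fidx] @ R


def slide_semilandmarks(shapes: np.ndarray, consensus: np.ndarray,
                        sliding_indices: np.ndarray,
                        meshes: list[TriMesh] | None = None,
                        transforms: list | None = None,
                        project: bool = True,
                        bemat: BendingEnergyMatrix | None = None) -> np.ndarray:
    """One sliding pass over all specimens against the current consensus.

    Each semilandmark moves within its tangent plane by the least-squares
    displacement minimising trace(d' B d), B the bending-energy matrix of
    the consensus. Anchors (rows outside ``sliding_indices``) never move.
    With meshes (and the per-specimen similarity ``transforms`` mapping
    aligned frame -> mesh frame), slid points are re-projected to the
    nearest surface point.
    """
    shapes = np.asarray(shapes, dtype=np.float64)
    idx = np.asarray(sliding_indices, dtype=np.int64)
    if bemat is None:
        bemat = bending_energy_matrix(consensus)
    if meshes is not None and transforms is None:
        transforms = [(np.zeros(3), 1.0, np.eye(3))] * len(shapes)
    out = np.empty_like(shapes)
    for i, x in enumerate(shapes):
        mesh = meshes[i] if meshes is not None else None
        tr = transforms[i] if transforms is not None else None
        normals = _normals_for(x, idx, mesh, tr)
        slid = _slide_one(x, consensus, idx, normals, bemat)
        if project and mesh is not None:
            c, s, R = tr
            raw_pts = s * (slid[idx] @ R.T) + c
            proj, _, _ = mesh_core.closest_points_on_surface(mesh, raw_pts)
            slid[idx] = ((proj - c) / s) @ R
        out[i] = slid
    return out


def _align_all(raw: list[np.ndarray], reference: np.ndarray):
    """OPA-align every configuration to the (unit-size) reference."""
    X, transforms = [], []
    for r_ in raw:
        c = r_.mean(axis=0)
        centred = r_ - c
        s = np.linalg.norm(centred)
        if s == 0:
            raise SuperimpositionError("zero centroid size")
        A = centred / s
        R = _optimal_rotation(A, reference)
        X.append(A @ R)
        transforms.append((c, s, R))
    return X, transforms


def gpa(shapes, sliding: SlidingConfig | None = None,
        meshes: list[TriMesh] | None = None,
        max_iter: int = 100, tol: float = 1e-8) -> AlignmentResult:
    """Generalised Procrustes superimposition, optionally with semilandmark
    sliding, iterated until the root-mean-square change of the consensus
    falls below ``tol`` (or ``max_iter`` iterations)."""
    raw = [np.array(s, dtype=np.float64) for s in shapes]
    n = len(raw)
    if n < 2:
        raise SuperimpositionError("GPA needs at least two configurations")
    p = raw[0].shape[0]
    if any(r_.shape != (p, 3) for r_ in raw):
        raise SuperimpositionError("all configurations must be (p, 3) with equal p")
    if meshes is not None and len(meshes) != n:
        raise SuperimpositionError("need one mesh per configuration")
    csizes = np.array([centroid_size(r_) for r_ in raw])
    idx = sliding.resolve_indices(p) if sliding is not None else None

    cons = _unit(raw[0])
    converged = False
    X = transforms = None
    slide_energy_prev = None
    sliding_active = sliding is not None and len(idx) > 0
    for it in range(1, max_iter + 1):
        X, transforms = _align_all(raw, cons)
        cons_new = _unit(np.mean(X, axis=0))
        if sliding_active and it <= sliding.max_slide_iterations:
            bemat = bending_energy_matrix(cons_new)
            prev_e = None
            arr = np.stack(X)
            for _ in range(max(1, sliding.passes)):
                arr = slide_semilandmarks(
                    arr, cons_new, idx, meshes=meshes,
                    transforms=transforms, project=sliding.project,
                    bemat=bemat)
                e = sum(bemat.energy(a - cons_new) for a in arr)
                if prev_e is not None and \
                        prev_e - e <= sliding.energy_tol * max(prev_e, 1e-300):
                    break
                prev_e = e
            # write slid landmarks back to the specimen frames, then re-fit
            raw = [s * (a @ R.T) + c
                   for a, (c, s, R) in zip(arr, transforms)]
            X, transforms = _align_all(raw, cons_new)
            cons_new = _unit(np.mean(X, axis=0))
            if slide_energy_prev is not None and \
                    slide_energy_prev - e <= \
                    sliding.energy_tol * max(slide_energy_prev, 1e-300):
                sliding_active = False      # energy plateau: freeze landmarks
            slide_energy_prev = e
        delta = np.sqrt(np.mean((cons_new - cons) ** 2))
        cons = cons_new
        if delta < tol:
            converged = True
            break
    aligned = np.stack(X)
    return AlignmentResult(aligned=aligned,
                           consensus=aligned.mean(axis=0),
                           centroid_sizes=csizes,
                           iterations=it, converged=converged)
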