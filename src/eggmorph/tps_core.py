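"""Three-dimensional thin-plate spline interpolation and bending energy.

The 3D TPS uses the biharmonic kernel U(r) = r. A fitted spline maps

    f(x) = c + A x + sum_i w_i U(|x - s_i|)

with the side conditions 1' w = 0 and S' w = 0 (S the source landmarks),
which make affine displacements cost zero bending energy. The bending
energy of a displacement field d (p x 3) relative to a reference
configuration is trace(d' B d) where B is the bending-energy matrix of
that reference: the upper-left p x p block of the inverse of the bordered
kernel system. These are the ingredients of template-to-specimen warping,
semilandmark sliding and PC-extreme surface visualisation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist, pdist

from .mesh_core import TriMesh


class TPSError(ValueError):
    """Singular or ill-posed thin-plate spline system."""


def _kernel(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """U(r) = r between every pair of rows of a and b."""
    return cdist(a, b)


def _check_source(source: np.ndarray) -> np.ndarray:
    src = np.asarray(source, dtype=np.float64)
    if src.ndim != 2 or src.shape[1] != 3 or len(src) < 5:
        raise TPSError("source must be a (p, 3) array with p >= 5")
    size = float(np.linalg.norm(src - src.mean(0)))
    if pdist(src).min() < 1e-9 * max(size, 1e-300):
        raise TPSError("coincident source landmarks (separation below 1e-9 of "
                       "configuration size)")
    return src


def _bordered_system(src: np.ndarray) -> np.ndarray:
    p = len(src)
    K = _kernel(src, src)
    P = np.hstack([np.ones((p, 1)), src])
    L = np.zeros((p + 4, p + 4))
    L[:p, :p] = K
    L[:p, p:] = P
    L[p:, :p] = P.T
    return L


@dataclass
class TPSModel:
    """A fitted 3D thin-plate spline ``f(x) = affine([1, x]) + kernel part``."""

    source: np.ndarray          # (p, 3)
    affine: np.ndarray          # (4, 3): row 0 constant, rows 1..3 linear map
    weights: np.ndarray         # (p, 3) non-affine kernel weights

    def warp(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=np.float64))
        U = _kernel(pts, self.source)
        out = self.affine[0] + pts @ self.affine[1:] + U @ self.weights
        return out

    def side_condition_residual(self) -> float:
        """Max abs residual of the orthogonality side conditions."""
        p = len(self.source)
        P = np.hstack([np.ones((p, 1)), self.source])
        return float(np.abs(P.T @ self.weights).max())


def tps_fit(source: np.ndarray, target: np.ndarray) -> TPSModel:
    """Fit the interpolating TPS taking each source landmark exactly to its
    target (within numerical tolerance)."""
    src = _check_source(source)
    tgt = np.asarray(target, dtype=np.float64)
    if tgt.shape != src.shape:
        raise TPSError("target must have the same shape as source")
    L = _bordered_system(src)
    rhs = np.vstack([tgt, np.zeros((4, 3))])
    try:
        sol = np.linalg.solve(L, rhs)
    except np.linalg.LinAlgError as exc:
        raise TPSError(f"singular TPS system: {exc}") from exc
    p = len(src)
    return TPSModel(source=src, affine=sol[p:], weights=sol[:p])


@dataclass
class BendingEnergyMatrix:
    """Quadratic form of TPS bending energy for a reference configuration."""

    matrix: np.ndarray          # (p, p), symmetric PSD
    reference: np.ndarray       # (p, 3)

    def energy(self, displacement: np.ndarray) -> float:
        """trace(d' B d) of a (p, 3) displacement field."""
        d = np.asarray(displacement, dtype=np.float64)
        return float(np.einsum("ik,ij,jk->", d, self.matrix, d))


def bending_energy_matrix(reference: np.ndarray) -> BendingEnergyMatrix:
    """Bending-energy matrix B of a reference configuration.

    B is the upper-left p x p block of the inverse of the bordered kernel
    system, negated: in 3D the kernel U(r) = r is conditionally *negative*
    definite, so the positive-semidefinite energy form is the negation of
    the raw block. B 1 = 0 and B X_ref = 0, so affine displacement fields
    have zero energy.
    """
    ref = _check_source(reference)
    L = _bordered_system(ref)
    try:
        Linv = np.linalg.inv(L)
    except np.linalg.LinAlgError as exc:
        raise TPSError(f"singular bending-energy system: {exc}") from exc
    p = len(ref)
    B = -Linv[:p, :p]
    return BendingEnergyMatrix(matrix=(B + B.T) / 2.0, reference=ref)


def warp_mesh(mesh: TriMesh, source_lms: np.ndarray,
              target_lms: np.ndarray) -> TriMesh:
    """Warp mesh vertices by the TPS taking source landmarks to target
    landmarks; face topology is unchanged."""
    model = tps_fit(source_lms, target_lms)
    return TriMesh(model.warp(mesh.vertices), mesh.faces.copy(), mesh.name)
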