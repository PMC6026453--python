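"""Semi-automated landmark digitisation of egg surface meshes.

Each egg receives 206 ordered 3D landmarks: six fixed anchors at the
axis-surface intersections of the aligned, pole-oriented mesh (pointed
pole on +x, blunt pole on -x, then the equator at +y, -y, +z, -z) and 200
sliding surface semilandmarks. The semilandmarks are defined once on a
reference specimen -- rays cast from the centroid along a spherical
Fibonacci lattice, giving a deterministic, near-uniform template -- and
transferred to every other specimen by a 6-anchor thin-plate-spline warp
followed by projection onto the target surface. Index j on every specimen
therefore descends from template point j, which is the positional-homology
claim of the method. The whole routine is deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist

from . import mesh_core
from .mesh_core import TriMesh, RayMissError
from .tps_core import tps_fit

#: fixed anchor casting directions, in role order:
#: 1 pointed pole (+x), 2 blunt pole (-x), 3..6 equator (+y, -y, +z, -z)
ANCHOR_DIRECTIONS = np.array([
    [1.0, 0.0, 0.0], [-1.0, 0.0, 0.0],
    [0.0, 1.0, 0.0], [0.0, -1.0, 0.0],
    [0.0, 0.0, 1.0], [0.0, 0.0, -1.0],
])

N_ANCHORS = 6
GOLDEN_ANGLE = np.pi * (3.0 - np.sqrt(5.0))


class DigitizerError(ValueError):
    """Digitisation failure (template separation, off-surface landmarks...)."""


def centroid_size(coords: np.ndarray) -> float:
    """Square root of summed squared deviations from the landmark centroid."""
    c = np.asarray(coords, dtype=np.float64)
    return float(np.linalg.norm(c - c.mean(0)))


@dataclass
class LandmarkSet:
    """One specimen's ordered landmark configuration (anchors first)."""

    specimen_id: str
    coords: np.ndarray          # (6 + n_semi, 3)
    n_anchors: int = N_ANCHORS

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=np.float64)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise DigitizerError("coords must be an (n, 3) array")
        if len(self.coords) < self.n_anchors:
            raise DigitizerError("fewer coordinates than anchors")
        if not np.isfinite(self.coords).all():
            raise DigitizerError("non-finite landmark coordinates")

    @property
    def n_landmarks(self) -> int:
        return len(self.coords)

    @property
    def anchors(self) -> np.ndarray:
        return self.coords[:self.n_anchors]

    @property
    def semilandmarks(self) -> np.ndarray:
        return self.coords[self.n_anchors:]

    @property
    def roles(self) -> list[str]:
        return ["anchor"] * self.n_anchors + \
            ["semi"] * (self.n_landmarks - self.n_anchors)


@dataclass
class Template:
    """Reference-specimen landmark template transferred to all other eggs."""

    reference_id: str
    anchors: np.ndarray         # (6, 3)
    semilandmarks: np.ndarray   # (n_semi, 3)

    @property
    def coords(self) -> np.ndarray:
        return np.vstack([self.anchors, self.semilandmarks])


def place_anchors(mesh: TriMesh) -> np.ndarray:
    """Six axis-surface intersections of an aligned, pole-oriented mesh,
    cast from the origin along +x, -x, +y, -y, +z, -z (role order)."""
    return np.array([
        mesh_core.ray_surface_intersection(mesh, np.zeros(3), d)
        for d in ANCHOR_DIRECTIONS
    ])


def _fibonacci_directions(n: int, phase: float = 0.0) -> np.ndarray:
    """Near-uniform unit directions: spherical Fibonacci lattice with the
    lattice axis along x (the egg's long axis)."""
    i = np.arange(n)
    x = 1.0 - (2.0 * i + 1.0) / n
    r = np.sqrt(np.clip(1.0 - x * x, 0.0, None))
    theta = i * GOLDEN_ANGLE + phase
    return np.stack([x, r * np.cos(theta), r * np.sin(theta)], axis=1)


def build_template(reference: TriMesh, n_semi: int = 200,
                   reference_id: str | None = None) -> Template:
    """Template from an aligned, pole-oriented reference mesh.

    Semilandmarks are the outermost ray-surface intersections along a
    spherical Fibonacci lattice of ``n_semi`` directions. If the minimum
    pairwise separation guard fails, the lattice is rotated by one golden
    angle and re-cast (up to 10 times).
    """
    if n_semi < 4:
        raise DigitizerError("need at least 4 semilandmarks")
    anchors = place_anchors(reference)
    size = centroid_size(reference.vertices)
    for attempt in range(10):
        dirs = _fibonacci_directions(n_semi, phase=attempt * GOLDEN_ANGLE)
        semis = np.array([
            mesh_core.ray_surface_intersection(reference, np.zeros(3), d)
            for d in dirs
        ])
        if pdist(semis).min() >= 1e-9 * size:
            return Template(reference_id=reference_id or reference.name,
                            anchors=anchors, semilandmarks=semis)
    raise DigitizerError("could not achieve minimum semilandmark separation "
                         "after 10 lattice rotations")


def fit_template(template: Template, target: TriMesh,
                 specimen_id: str | None = None) -> LandmarkSet:
    """Transfer the template to an aligned, pole-oriented target mesh.

    A TPS is fitted from the template's six anchors to the target's six
    anchors (at p = 6 this warp is affine-dominated and acts as the
    orientation/scaling step); the 200 semilandmarks are warped by it and
    then projected to the nearest point of the target surface, guaranteeing
    on-surface landmarks.
    """
    anchors_t = place_anchors(target)
    model = tps_fit(template.anchors, anchors_t)
    warped = model.warp(template.semilandmarks)
    projected, _, _ = mesh_core.closest_points_on_surface(target, warped)
    coords = np.vstack([anchors_t, projected])
    lms = LandmarkSet(specimen_id=specimen_id or target.name, coords=coords)
    _check_on_surface(lms, target)
    return lms


def _check_on_surface(lms: LandmarkSet, mesh: TriMesh) -> None:
    _, dists, _ = mesh_core.closest_points_on_surface(mesh, lms.coords)
    tol = 1e-6 * centroid_size(lms.coords)
    if dists.max() > tol:
        raise DigitizerError(
            f"{(dists > tol).sum()} landmarks lie off the surface "
            f"(max deviation {dists.max():.3g} > tolerance {tol:.3g})")


def digitize_specimen(mesh: TriMesh, template: Template,
                      specimen_id: str | None = None) -> LandmarkSet:
    """End-to-end digitisation of a raw closed mesh: principal-axes
    alignment, pole orientation, anchor placement and template fitting."""
    if not mesh.is_closed():
        raise mesh_core.OpenMeshError(
            f"digitisation requires a closed mesh ({mesh.name!r} is open)")
    aligned, _ = mesh_core.principal_axes_align(mesh)
    oriented, _ = mesh_core.orient_poles(aligned)
    return fit_template(template, oriented,
                        specimen_id=specimen_id or mesh.name)


def template_from_specimen(mesh: TriMesh, n_semi: int = 200) -> Template:
    """Build the template from a raw reference mesh (align + orient first)."""
    if not mesh.is_closed():
        raise mesh_core.OpenMeshError(
            f"template reference must be a closed mesh ({mesh.name!r} is open)")
    aligned, _ = mesh_core.principal_axes_align(mesh)
    oriented, _ = mesh_core.orient_poles(aligned)
    return build_template(oriented, n_semi=n_semi, reference_id=mesh.name)


# ---------------------------------------------------------------------------
# Landmark CSV dialect
# ---------------------------------------------------------------------------

def write_landmarks(landmark_sets: list[LandmarkSet], path,
                    header_comment: str | None = None) -> None:
    """Write landmark sets to CSV (specimen_id, landmark_index 1-based,
    role, x, y, z). An optional provenance comment line starts with '#'."""
    frames = []
    for lms in landmark_sets:
        frames.append(pd.DataFrame({
            "specimen_id": lms.specimen_id,
            "landmark_index": np.arange(1, lms.n_landmarks + 1),
            "role": lms.roles,
            "x": lms.coords[:, 0],
            "y": lms.coords[:, 1],
            "z": lms.coords[:, 2],
        }))
    table = pd.concat(frames, ignore_index=True)
    with open(path, "w", newline="") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        table.to_csv(fh, index=False, float_format="%.17g")


def read_landmarks(path) -> list[LandmarkSet]:
    """Read the landmark CSV dialect back into LandmarkSet objects,
    preserving file order of specimens."""
    table = pd.read_csv(path, comment="#")
    required = {"specimen_id", "landmark_index", "role", "x", "y", "z"}
    if not required.issubset(table.columns):
        raise DigitizerError(f"landmark CSV missing columns "
                             f"{sorted(required - set(table.columns))}")
    out = []
    for sid in table["specimen_id"].unique():
        sub = table[table["specimen_id"] == sid].sort_values("landmark_index")
        n_anchors = int((sub["role"] == "anchor").sum())
        out.append(LandmarkSet(specimen_id=str(sid),
                               coords=sub[["x", "y", "z"]].to_numpy(),
                               n_anchors=n_anchors or N_ANCHORS))
    return out
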