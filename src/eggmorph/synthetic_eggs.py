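"""Parametric egg meshes and hierarchically structured populations.

Eggs are modelled as surfaces of revolution about the x-axis with the
profile

    rho(t) = (W/2) * sqrt(1 - t^2) * (1 - a*t) / m(a),   t in [-1, 1]

where ``L`` is pole-to-pole length (x spans [-L/2, L/2]), ``W`` the maximum
breadth, and ``a`` in [0, 0.9) a taper parameter: a = 0 gives an ellipsoid
of revolution, increasing a makes the +x pole progressively more pointed
and shifts the widest section toward the blunt (-x) end. The normaliser
m(a) = max_t sqrt(1-t^2)(1-a*t) keeps the true maximum breadth exactly W.
Radial symmetry can be broken with an elliptical cross-section term
``rho * (1 + eps * cos 2phi)`` and measurement noise emulated with
isotropic vertex jitter.

Populations mirror a museum-clutch sampling design: species have mean
parameters, and clutch- and egg-level Gaussian effects act on
(log elongation, taper) so every generated shape stays a valid egg.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .mesh_core import TriMesh


@dataclass(frozen=True)
class EggParams:
    """Ground-truth shape parameters of one egg (lengths in mm)."""

    length: float
    width: float
    taper: float = 0.0
    radial_pert: float = 0.0
    vertex_noise: float = 0.0

    def __post_init__(self) -> None:
        if not self.length > 0:
            raise ValueError("length must be positive")
        if not (0 < self.width <= self.length):
            raise ValueError("width must satisfy 0 < W <= L")
        if not (0 <= self.taper < 0.9):
            raise ValueError("taper must lie in [0, 0.9)")
        if self.radial_pert < 0 or self.vertex_noise < 0:
            raise ValueError("perturbation amplitudes must be >= 0")

    @property
    def elongation(self) -> float:
        return self.length / self.width


def _profile_shape(t: np.ndarray, a: float) -> np.ndarray:
    return np.sqrt(np.clip(1.0 - t * t, 0.0, None)) * (1.0 - a * t)


def _profile_max(a: float) -> float:
    """max_t sqrt(1-t^2)(1-a*t), located at t <= 0 for a >= 0."""
    if a == 0.0:
        return 1.0
    res = minimize_scalar(lambda t: -_profile_shape(np.asarray(t), a),
                          bounds=(-1.0, 0.0), method="bounded",
                          options={"xatol": 1e-13})
    return float(_profile_shape(np.asarray(res.x), a))


def egg_profile(t, params: EggParams):
    """Radius of the egg's surface of revolution at axial position t in [-1, 1]."""
    t_arr = np.asarray(t, dtype=np.float64)
    if np.any(np.abs(t_arr) > 1.0):
        raise ValueError("t must lie in [-1, 1]")
    rho = (params.width / 2.0) * _profile_shape(t_arr, params.taper) \
        / _profile_max(params.taper)
    return rho if np.ndim(t) else float(rho)


def make_egg_mesh(params: EggParams, n_axial: int = 70, n_azimuthal: int = 72,
                  seed: int | None = None, name: str = "") -> TriMesh:
    """Closed, outward-oriented triangulated egg surface.

    ``n_axial`` axial segments (n_axial - 1 interior vertex rings) and
    ``n_azimuthal`` azimuthal steps give 2 * n_azimuthal * (n_axial - 1)
    triangles; the defaults (70, 72) give 9,936, matching the ~10,000
    triangles of a typical micro-CT eggshell export. Pole caps are triangle
    fans so the surface is watertight.
    """
    if n_axial < 8 or n_azimuthal < 8:
        raise ValueError("resolution too low: need n_axial >= 8, n_azimuthal >= 8")
    L, eps = params.length, params.radial_pert
    t = -1.0 + 2.0 * np.arange(1, n_axial) / n_axial        # interior stations
    rho = egg_profile(t, params)
    phi = 2.0 * np.pi * np.arange(n_azimuthal) / n_azimuthal
    rr = rho[:, None] * (1.0 + eps * np.cos(2.0 * phi))[None, :]
    x = np.broadcast_to((L / 2.0) * t[:, None], rr.shape)
    ring_verts = np.stack([x, rr * np.cos(phi)[None, :],
                           rr * np.sin(phi)[None, :]], axis=-1).reshape(-1, 3)
    verts = np.vstack([[[-L / 2.0, 0.0, 0.0]], ring_verts, [[L / 2.0, 0.0, 0.0]]])

    nv = len(verts)
    n_rings = n_axial - 1
    ring = lambda k, j: 1 + k * n_azimuthal + (j % n_azimuthal)
    faces = []
    for j in range(n_azimuthal):               # blunt cap at -x
        faces.append((0, ring(0, j), ring(0, j + 1)))
    for k in range(n_rings - 1):               # quad strips
        for j in range(n_azimuthal):
            a, b = ring(k, j), ring(k, j + 1)
            c, d = ring(k + 1, j), ring(k + 1, j + 1)
            faces.append((a, c, d))
            faces.append((a, d, b))
    for j in range(n_azimuthal):               # pointed cap at +x
        faces.append((nv - 1, ring(n_rings - 1, j + 1), ring(n_rings - 1, j)))
    faces = np.asarray(faces, dtype=np.int64)

    if params.vertex_noise > 0:
        rng = np.random.default_rng(seed)
        verts = verts + rng.normal(0.0, params.vertex_noise, size=verts.shape)

    # guarantee outward orientation (signed volume > 0)
    tri = verts[faces]
    vol = np.einsum("ij,ij->", tri[:, 0], np.cross(tri[:, 1], tri[:, 2])) / 6.0
    if vol < 0:
        faces = faces[:, [0, 2, 1]]
    return TriMesh(verts, faces, name=name)


@dataclass
class PopulationSpec:
    """Generative design of a species -> clutch -> egg hierarchy.

    ``species`` maps species name to its mean :class:`EggParams`;
    ``clutch_sizes`` maps species name to the list of eggs per clutch
    (one entry per clutch). ``sigma_clutch`` / ``sigma_egg`` are the
    standard deviations of Gaussian random effects on
    (log elongation, taper) at the clutch and egg level.
    """

    species: dict[str, EggParams]
    clutch_sizes: dict[str, list[int]]
    clutch_names: dict[str, list[str]] | None = None
    sigma_clutch: tuple[float, float] = (0.0, 0.0)
    sigma_egg: tuple[float, float] = (0.0, 0.0)
    seed: int = 0
    n_axial: int = 70
    n_azimuthal: int = 72

    def __post_init__(self) -> None:
        if set(self.species) != set(self.clutch_sizes):
            raise ValueError("species and clutch_sizes must list the same species")
        for sp, sizes in self.clutch_sizes.items():
            if len(sizes) == 0 or any(s < 1 for s in sizes):
                raise ValueError(f"clutch sizes for {sp!r} must all be >= 1")
        if any(s < 0 for s in self.sigma_clutch + self.sigma_egg):
            raise ValueError("random-effect standard deviations must be >= 0")
        if self.clutch_names is not None:
            for sp, names in self.clutch_names.items():
                if len(names) != len(self.clutch_sizes[sp]):
                    raise ValueError(f"clutch_names for {sp!r} has wrong length")

    @property
    def n_specimens(self) -> int:
        return sum(sum(sizes) for sizes in self.clutch_sizes.values())


def _perturbed_params(base: EggParams, d_log_e: float, d_taper: float) -> EggParams:
    elongation = max(np.exp(np.log(base.elongation) + d_log_e), 1.0)
    taper = float(np.clip(base.taper + d_taper, 0.0, 0.899))
    return replace(base, width=base.length / elongation, taper=taper)


def make_population(spec: PopulationSpec) -> tuple[list[TriMesh], pd.DataFrame]:
    """Generate one mesh per egg plus a manifest of ground-truth parameters.

    The manifest has columns specimen_id, species, clutch, true_L, true_W,
    true_a and matches the returned mesh list row for row. All randomness
    (random effects and vertex jitter) derives from ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    sc, se = spec.sigma_clutch, spec.sigma_egg
    meshes: list[TriMesh] = []
    rows = []
    for sp_name in spec.species:
        base = spec.species[sp_name]
        sizes = spec.clutch_sizes[sp_name]
        names = (spec.clutch_names or {}).get(
            sp_name, [f"{sp_name}_C{i + 1}" for i in range(len(sizes))])
        for clutch_name, size in zip(names, sizes):
            cl_eff = rng.normal(0.0, 1.0, 2) * sc
            for egg_i in range(size):
                egg_eff = rng.normal(0.0, 1.0, 2) * se
                params = _perturbed_params(base, cl_eff[0] + egg_eff[0],
                                           cl_eff[1] + egg_eff[1])
                sid = f"{sp_name}_{clutch_name}_{egg_i + 1}"
                mesh_seed = int(rng.integers(0, 2 ** 31 - 1))
                meshes.append(make_egg_mesh(params, spec.n_axial, spec.n_azimuthal,
                                            seed=mesh_seed, name=sid))
                rows.append({"specimen_id": sid, "species": sp_name,
                             "clutch": clutch_name, "true_L": params.length,
                             "true_W": params.width, "true_a": params.taper})
    return meshes, pd.DataFrame(rows)


def study_population(seed: int = 0, n_axial: int = 70, n_azimuthal: int = 72,
                      sigma_clutch: tuple[float, float] = (0.05, 0.05),
                      sigma_egg: tuple[float, float] = (0.03, 0.03),
                      vertex_noise: float = 0.02,
                      radial_pert: float = 0.01) -> PopulationSpec:
    """The study's sampling design: 4 passerine species x 4 clutches, museum
    clutch sizes (with one damaged egg excluded from the 7-egg finch clutch),
    55 specimens in total. Mean lengths/breadths are species-typical values
    in mm; tapers give mildly pointed eggs.
    """
    def params(L, W, a):
        return EggParams(L, W, a, radial_pert=radial_pert,
                         vertex_noise=vertex_noise)

    species = {
        "grey_shrike_thrush": params(27.0, 19.5, 0.20),
        "red_browed_finch": params(16.0, 12.0, 0.12),
        "spiny_cheeked_honeyeater": params(24.0, 17.0, 0.18),
        "superb_fairy_wren": params(16.0, 12.5, 0.15),
    }
    clutch_sizes = {
        "grey_shrike_thrush": [3, 3, 2, 3],
        "red_browed_finch": [5, 6, 5, 5],     # E10376 had 7, one excluded
        "spiny_cheeked_honeyeater": [2, 2, 2, 3],
        "superb_fairy_wren": [3, 4, 4, 3],
    }
    clutch_names = {
        "grey_shrike_thrush": ["E14331", "E14518", "E15293", "E06328"],
        "red_browed_finch": ["E06238", "E10376", "E14319", "E14515"],
        "spiny_cheeked_honeyeater": ["E14372", "E05185", "E06303", "E06324"],
        "superb_fairy_wren": ["E10499", "E12643", "E13865", "E14555"],
    }
    return PopulationSpec(species=species, clutch_sizes=clutch_sizes,
                          clutch_names=clutch_names, sigma_clutch=sigma_clutch,
                          sigma_egg=sigma_egg, seed=seed,
                          n_axial=n_axial, n_azimuthal=n_azimuthal)
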