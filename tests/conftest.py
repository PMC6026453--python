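import numpy as np
import pytest
import trimesh

import eggmorph as em


def make_sphere(radius: float = 1.0, subdivisions: int = 3) -> em.TriMesh:
    s = trimesh.creation.icosphere(subdivisions=subdivisions, radius=radius)
    return em.TriMesh(np.asarray(s.vertices), np.asarray(s.faces),
                      name="sphere")


def make_ellipsoid(semi_axes=(2.0, 1.0, 0.8), subdivisions: int = 3) -> em.TriMesh:
    s = trimesh.creation.icosphere(subdivisions=subdivisions)
    return em.TriMesh(np.asarray(s.vertices) * np.asarray(semi_axes),
                      np.asarray(s.faces), name="ellipsoid")


def random_rotation(rng) -> np.ndarray:
    A = rng.normal(size=(3, 3))
    Q, R = np.linalg.qr(A)
    Q *= np.sign(np.diagonal(R))
    if np.linalg.det(Q) < 0:
        Q[:, [0, 1]] = Q[:, [1, 0]]
    return Q


@pytest.fixture(scope="session")
def sphere():
    return make_sphere(subdivisions=4)


@pytest.fixture(scope="session")
def ellipsoid():
    return make_ellipsoid(subdivisions=4)


@pytest.fixture(scope="session")
def study_lowres():
    """The 55-egg museum design at reduced mesh resolution (fast tests)."""
    spec = em.study_population(seed=7, n_axial=24, n_azimuthal=24)
    meshes, manifest = em.make_population(spec)
    return spec, meshes, manifest


@pytest.fixture(scope="session")
def digitized_population(study_lowres):
    spec, meshes, manifest = study_lowres
    template = em.template_from_specimen(meshes[0], n_semi=200)
    lms = [em.digitize_specimen(m, template) for m in meshes]
    return manifest, template, lms


@pytest.fixture(scope="session")
def aligned_population(digitized_population):
    manifest, template, lms = digitized_population
    result = em.gpa([l.coords for l in lms], sliding=em.SlidingConfig())
    return manifest, lms, result
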