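# Methods

This note documents the models, algorithms and numerical choices behind
`eggmorph`, in the order the pipeline applies them.

## Mesh model and canonical frame

An egg is a closed, edge-manifold, outward-oriented triangle mesh of the
eggshell exterior (PLY, ASCII or binary little-endian; non-triangular
faces are fan-triangulated on read). Enclosed volume is the divergence-
theorem sum of signed tetrahedra; a non-positive signed volume is treated
as an orientation error rather than silently negated.

Every specimen is first moved to a canonical frame:

1. **Centring** at the area-weighted mean of face centroids (the surface
   centroid). A vertex mean would be biased by uneven tessellation; the
   volume centroid would need a watertight integral for no practical
   gain. This choice is a convention, not a claim about the data — all
   downstream statistics are Procrustes-invariant to it.
2. **Principal axes** from the area-weighted covariance of face
   centroids, eigenvalues descending so the longest dimension lies on x.
   Eigenvalue ties (relative gap < 1e-9) are resolved by rotating the
   tied eigenspace as close to the coordinate axes as possible.
3. **Axis signs.** A principal frame is defined only up to per-axis sign
   flips. Signs are fixed intrinsically: each axis is oriented so the
   area-weighted third moment (skewness) of the surface along it is
   positive; axes whose skewness is numerically zero (symmetric
   surfaces, |relative moment| < 1e-8) fall back to the proper rotation
   closest to the identity. The intrinsic rule makes digitisation
   equivariant under rigid motions of the input mesh for generic
   surfaces; for exactly symmetric surfaces no intrinsic azimuth exists
   and only the surface itself (not its tessellation) is reproducible.
4. **Pole orientation.** The egg is split at x = 0 and the convex-hull
   volumes of the two vertex subsets are compared; the smaller (pointed)
   half goes to +x, via a proper 180° rotation about z so handedness is
   preserved. Using the raw vertex subsets without the plane-intersection
   ring slightly underestimates both half volumes; the comparison is
   unaffected in practice. Ties (relative difference < 1e-9) do not flip.

Ray–surface intersection (Möller–Trumbore) and point–triangle closest
point (barycentric region test) are exhaustive vectorised kernels; the
closest-point query preselects candidates with a KD-tree over face
centroids and falls back to a full scan whenever the candidate optimum
cannot be certified within the largest face radius, so results are exact.
At the ~10,000-triangle resolution of typical micro-CT exports both are
milliseconds per call.

## Digitisation (206 landmarks)

Six **anchors** are the intersections of the coordinate half-axes with
the surface, cast from the origin: pointed pole (+x), blunt pole (−x),
equator at +y, −y, +z, −z. Rays that graze a vertex or edge exactly are
retried with a deterministic 1e-10 perturbation.

200 **semilandmarks** are defined once, on a reference specimen, as the
outermost surface intersections of rays along a spherical Fibonacci
lattice (axis along x). The lattice is deterministic, gives an exact
count, and is near-uniform (nearest-neighbour spacing CV ≈ 2.5% on a
sphere); "equally spaced" has no unique meaning on an irregular surface,
and this construction is well defined for any surface star-shaped about
its centroid — eggs are. If the minimum-separation guard
(1e-9 × centroid size) fails, the lattice is rotated by one golden angle
and re-cast (at most 10 times).

The template is transferred to each specimen by a TPS fitted on the six
anchor pairs (at p = 6 this warp is affine-dominated and acts as the
orientation/scaling step), followed by projection of each warped
semilandmark to the nearest surface point. Projection guarantees
on-surface landmarks (tolerance 1e-6 × centroid size); index j on every
specimen descends from template point j, which is the positional-homology
claim of dense semilandmark methods. The whole digitiser is
deterministic.

## Thin-plate splines and bending energy

The 3D TPS uses the biharmonic kernel U(r) = r and the bordered system
solved densely (p = 206 is small; minimum source separation
1e-9 × configuration size guards against singular kernels). In 3D this
kernel is conditionally *negative* definite, so the positive-semidefinite
bending-energy matrix is the **negated** upper-left p × p block of the
inverse bordered matrix — with the raw block, "minimising" bending energy
would drift toward negative pseudo-energies. B annihilates affine fields
(B·1 = 0, B·X_ref = 0) and its eigenvalues are ≥ −1e-10 numerically.

## Superimposition and sliding

GPA centres each configuration, scales it to unit centroid size
(shape-only analysis: size is removed, per the standard Kendall
definition) and rotates it to the consensus with the SVD solution,
reflections disallowed. The loop `align → new consensus → slide →
re-align` repeats until the RMS change of the consensus drops below 1e-8
(at most 100 iterations; the `converged` flag records which).

Sliding displaces each semilandmark within its tangent plane by the
closed-form least-squares step minimising `tr(dᵀ B d)` with B from the
current consensus, all 200 semilandmarks of a specimen jointly (a
400-unknown symmetric solve; a relative ridge of 1e-10 keeps it
well-posed and cannot increase the energy). Anchors never move. Tangent
planes come from the specimen mesh normal at the landmark when meshes are
supplied — in which case slid points are re-projected to the surface,
keeping landmarks on the shell — and otherwise from the radial direction
out of the configuration centroid, which is exact for spheres and a good
approximation for any star-shaped surface. At most 3 sliding passes per
GPA iteration, stopping early when the relative energy drop falls below
1e-6.

Sliding participates in at most `max_slide_iterations = 10` GPA
iterations (or until the summed energy plateaus between iterations);
afterwards the landmarks freeze and the plain Procrustes iteration
polishes to convergence. Unbounded interleaving lets semilandmarks crawl
along the surface at ever-smaller energy gains, which stalls the
consensus criterion without materially changing the solution; ten
iterations are well past the plateau in every configuration we generate.

## Shape statistics

**PCA** is the SVD of the mean-centred flattened aligned coordinates
(covariance PCA — the coordinates share units, so correlation scaling
would be wrong). Components are kept down to machine-noise eigenvalues
and capped at min(n − 1, 3p − 7). Signs are fixed so PC1 correlates
positively with per-specimen elongation and PC2 with asymmetry, both
computable from the anchor rows of the aligned coordinates; this removes
the arbitrary sign flip between runs.

**Elongation** is pole-to-pole length over y-axis breadth. **Asymmetry**
uses the trigonometric construction: h = mean distance from the pointed
pole to the two y-axis landmarks (the hypotenuse), w = half-breadth,
offset d = sqrt(h² − w²), normalised A = d / length, so A = 0.5 means the
equatorial plane halves the polar axis. The triangle inequality
guarantees h ≥ w for real landmark configurations; h < w (possible only
with corrupted input) raises.

**Distance-based ANOVA.** Sequential model comparison on the flattened
aligned coordinates (intercept → +species → +species:clutch), with
SS_term = RSS_reduced − RSS_full summed over coordinate columns —
algebraically the Procrustes-distance decomposition. Degrees of freedom:
s − 1, c − s, n − c. F_species = MS_species / MS_clutch (clutches are the
replication level for species differences; this matches the printed
structure of nested shape ANOVAs in the field), F_clutch =
MS_clutch / MS_residual. Because any orthonormal rotation of the columns
preserves every RSS, the response is first rotated to at most n columns
(thin SVD), which makes permutations cheap at 3p ≫ n with no change to
any statistic.

**RRPP.** For each term, the residuals of its reduced model are permuted
(`nperm` times, seeded, same permutation indices for all terms of an
iteration) and the F recomputed on the reconstructed response;
p = (1 + #{F* ≥ F_obs}) / (nperm + 1), so the observed arrangement counts
as one permutation and p ∈ (0, 1]. The effect size Z is the standard
score of log F_obs within the log-F permutation distribution (observed
included). Z conventions differ between software versions; it is
reported for completeness and nothing downstream depends on it.

**Disparity.** Procrustes variance PV_g = mean squared distance of group
members from their group mean, computed both directly and as the trace of
the group covariance (divisor n_g, matching "mean squared distance");
the two paths are asserted equal at 1e-10. The pairwise test permutes
specimens' residual vectors (deviations from their own group mean) among
groups and recomputes PVs; since only squared residual norms enter, the
permutation is run on those norms, vectorised. p-values use the same
(1 + count)/(nperm + 1) convention.

**Scalar ANOVA** (used to compare mean clutch disparity among species) is
the classical one-way decomposition with the parametric F p-value.

## Synthetic eggs

Profile of revolution ρ(t) = (W/2)·sqrt(1 − t²)·(1 − a·t)/m(a) on
t ∈ [−1, 1], x = (L/2)t. The taper a ∈ [0, 0.9) leaves an ellipsoid at
a = 0, sharpens the +x pole and shifts the widest section toward the
blunt end as a grows; m(a) = max_t sqrt(1 − t²)(1 − a·t) (1-D bounded
maximisation, xatol 1e-13) keeps the true maximum breadth exactly W.
Radial symmetry is broken with ρ·(1 + ε·cos 2φ) (elliptical
cross-section, the minimal symmetry break); measurement noise is
isotropic Gaussian vertex jitter σ_v. Meshes are built from n_axial − 1
vertex rings plus two pole vertices with triangle-fan caps (default
70 × 72 ≈ 9,900 triangles, matching typical micro-CT exports), and are
watertight with Euler characteristic 2 by construction; orientation is
verified by the signed volume.

Populations draw clutch- and egg-level Gaussian effects on
(log elongation, taper) — on that scale so elongation stays ≥ 1 and
shapes stay valid — and derive W = L/E with L held at the species mean.
The built-in `study_population` reproduces the museum sampling design:
4 passerine species × 4 clutches with clutch sizes (3,3,2,3), (5,6,5,5),
(2,2,2,3), (3,4,4,3) — one damaged egg excluded from the 7-egg finch
clutch — totalling 55 specimens. Mean lengths/breadths (27 × 19.5,
16 × 12, 24 × 17, 16 × 12.5 mm) are species-typical values; tapers
0.12–0.20 give mildly pointed passerine eggs; default random-effect SDs
(0.05, 0.05) at clutch level and (0.03, 0.03) at egg level, ε = 0.01,
σ_v = 0.02 mm, were chosen once as biologically plausible magnitudes
(clutch effects a few percent of elongation, jitter well below voxel
size).

What the generator does **not** emulate: real eggs are not exact surfaces
of revolution with a single taper parameter — creases, local dents,
pigment-correlated thickenings and segmentation artefacts are absent, and
the radial-symmetry break is a single harmonic. Passing tests therefore
demonstrate that the pipeline recovers known geometry and that the
statistics are calibrated under the generative model, not that any
biological conclusion transfers to real shells.

## Test and calibration problem sizes

The suite runs the full 55-egg design at 24 × 24 mesh resolution
(~1,100 triangles) and the acceptance script at 40 × 40 (~3,100
triangles); the degrees-of-freedom structure, landmark counts and all
algebraic identities are resolution-independent, and parameter-recovery
tolerances (elongation within 1%, monotone asymmetry) hold already at
these sizes. Statistical calibration uses 200 null replicates of the
nested ANOVA at nperm = 199 (rejection counts checked against the exact
binomial 95% interval at α = 0.05) and 50 replicates each for the
disparity test's null calibration and its power under a 4× dispersion
ratio at n = 20 per group. All simulations are seeded; results are exactly
reproducible.

## Known limitations

- Surfaces must be star-shaped about their centroid for the ray-cast
  template (true for eggs; not for arbitrary shapes).
- For exactly radially symmetric meshes the azimuthal frame — hence the
  exact tessellation-level landmark placement — is not intrinsically
  defined; only generic (asymmetric or noisy) surfaces digitise
  pose-equivariantly to machine precision.
- The 6-anchor TPS transfer is affine-dominated; strongly non-affine
  shape differences are absorbed by the projection and sliding steps.
- Procrustes variance uses divisor n_g and is therefore biased low in
  very small clutches; the permutation tests are calibrated for the
  statistic as defined.
- No allometry, bilateral-symmetry decomposition or phylogenetic
  comparative layer; the package quantifies shape, it does not explain
  it.
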