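"""Shape-space statistics for Procrustes-aligned egg landmarks.

Covers the analysis layer of the pipeline: PCA of the aligned coordinates
(the morphospace), the classical elongation and asymmetry ratios computed
from the anchor landmarks, distance-based Procrustes ANOVA -- one-way and
nested (shape ~ species/clutch) -- with residual-randomisation permutation
(RRPP) p-values, morphological disparity as Procrustes variance with its
pairwise permutation test, a scalar one-way ANOVA helper and the
PC-vs-ratio correlations.

The distance-based ANOVA partitions the total sum of squared Procrustes
distances by sequential model comparison on the flattened coordinates
(RSS_reduced - RSS_full summed over coordinate columns), which is
algebraically identical to the Procrustes-distance decomposition. In the
nested design the species F-ratio is tested over the clutch mean square,
the clutch term over the residual mean square.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as _sps

from .digitizer import LandmarkSet
from .superimposition import AlignmentResult


class ShapeStatsError(ValueError):
    """Invalid input to a shape-statistics routine."""


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _as_matrix(shapes) -> np.ndarray:
    """Accept (n, p, 3) landmark stacks or (n, D) matrices; return (n, D)."""
    if isinstance(shapes, AlignmentResult):
        return shapes.flattened()
    arr = np.asarray(shapes, dtype=np.float64)
    if arr.ndim == 3:
        return arr.reshape(arr.shape[0], -1)
    if arr.ndim == 2:
        return arr
    raise ShapeStatsError("shapes must be (n, p, 3) or (n, D)")


def _codes(labels) -> tuple[np.ndarray, list]:
    labels = np.asarray(labels)
    uniq, codes = np.unique(labels, return_inverse=True)
    return codes, list(uniq)


def _hat(design: np.ndarray) -> np.ndarray:
    """Orthogonal projector onto the column space of the design matrix."""
    Q, R = np.linalg.qr(design)
    keep = np.abs(np.diagonal(R)) > 1e-12 * max(np.abs(np.diagonal(R)).max(), 1e-300)
    Q = Q[:, keep]
    return Q @ Q.T


def _dummies(codes: np.ndarray) -> np.ndarray:
    return np.eye(codes.max() + 1)[codes]


def _reduce_columns(Y: np.ndarray) -> np.ndarray:
    """Rotate Y to at most n informative columns. Any orthonormal
    right-rotation preserves every model RSS, so this loses nothing for
    the ANOVA while making permutations cheap for 3p >> n."""
    n, D = Y.shape
    if D <= n:
        return Y
    U, s, _ = np.linalg.svd(Y, full_matrices=False)
    return U * s


# ---------------------------------------------------------------------------
# PCA morphospace
# ---------------------------------------------------------------------------

@dataclass
class PCAResult:
    """Principal components of the aligned shape coordinates."""

    eigenvalues: np.ndarray        # descending, length k
    percent_variance: np.ndarray   # sums to 100 over the k retained axes
    scores: np.ndarray             # (n, k)
    loadings: np.ndarray           # (3p, k), orthonormal columns
    mean: np.ndarray               # (3p,) centring vector

    @property
    def n_components(self) -> int:
        return len(self.eigenvalues)


def _elongation_from_rows(aligned: np.ndarray) -> np.ndarray:
    d_poles = np.linalg.norm(aligned[:, 0] - aligned[:, 1], axis=1)
    d_width = np.linalg.norm(aligned[:, 2] - aligned[:, 3], axis=1)
    return d_poles / d_width


def _asymmetry_from_rows(aligned: np.ndarray) -> np.ndarray:
    h = 0.5 * (np.linalg.norm(aligned[:, 2] - aligned[:, 0], axis=1)
               + np.linalg.norm(aligned[:, 3] - aligned[:, 0], axis=1))
    w = 0.5 * np.linalg.norm(aligned[:, 2] - aligned[:, 3], axis=1)
    L = np.linalg.norm(aligned[:, 0] - aligned[:, 1], axis=1)
    d2 = h * h - w * w
    return np.sqrt(np.clip(d2, 0.0, None)) / L


def pca(alignment: AlignmentResult) -> PCAResult:
    """Covariance PCA of the mean-centred flattened aligned coordinates.

    Sign convention: PC1 is flipped, if needed, so its scores correlate
    positively with elongation, and PC2 so its scores correlate positively
    with asymmetry (signs are otherwise arbitrary).
    """
    if alignment.n_specimens < 3:
        raise ShapeStatsError("PCA needs at least 3 specimens")
    Y = alignment.flattened()
    n = len(Y)
    mean = Y.mean(axis=0)
    Yc = Y - mean
    U, s, Vt = np.linalg.svd(Yc, full_matrices=False)
    eig = s ** 2 / (n - 1)
    total = eig.sum()
    keep = eig > max(eig[0], 1e-300) * 1e-15
    eig, U, s, Vt = eig[keep], U[:, keep], s[keep], Vt[keep]
    scores = U * s
    loadings = Vt.T
    # deterministic orientation: PC1 follows elongation, PC2 asymmetry
    ratios = [_elongation_from_rows(alignment.aligned),
              _asymmetry_from_rows(alignment.aligned)]
    for j, ref in enumerate(ratios):
        if j >= scores.shape[1]:
            break
        if np.std(ref) > 0 and np.std(scores[:, j]) > 0:
            r = np.corrcoef(scores[:, j], ref)[0, 1]
            if r < 0:
                scores[:, j] *= -1.0
                loadings[:, j] *= -1.0
    return PCAResult(eigenvalues=eig,
                     percent_variance=100.0 * eig / total,
                     scores=scores, loadings=loadings, mean=mean)


# ---------------------------------------------------------------------------
# Elongation and asymmetry ratios
# ---------------------------------------------------------------------------

@dataclass
class ShapeRatios:
    """Classical linear shape descriptors of one egg."""

    length: float
    width: float
    elongation: float
    asymmetry: float


def _coords_of(lms) -> np.ndarray:
    if isinstance(lms, LandmarkSet):
        return lms.coords
    arr = np.asarray(lms, dtype=np.float64)
    if arr.ndim != 2 or arr.shape[1] != 3 or len(arr) < 4:
        raise ShapeStatsError("need a LandmarkSet or an (n>=4, 3) array")
    return arr


def elongation(lms) -> float:
    """Length / width: pole-to-pole distance over the y-axis breadth
    (anchor pairs 1-2 and 3-4)."""
    c = _coords_of(lms)
    width = np.linalg.norm(c[2] - c[3])
    if width == 0:
        raise ShapeStatsError("zero egg width")
    return float(np.linalg.norm(c[0] - c[1]) / width)


def asymmetry(lms) -> float:
    """Normalised distance from the pointed pole to the crossing of the
    polar and equatorial axes.

    With h the mean distance from the pointed pole (landmark 1) to the two
    y-axis landmarks, and w the half-breadth, the pole-to-equator offset is
    d = sqrt(h^2 - w^2); asymmetry is d / length. A value of 0.5 means the
    equator halves the polar axis (symmetric ends)."""
    c = _coords_of(lms)
    h = 0.5 * (np.linalg.norm(c[2] - c[0]) + np.linalg.norm(c[3] - c[0]))
    w = 0.5 * np.linalg.norm(c[2] - c[3])
    if h < w:
        raise ShapeStatsError("impossible landmark geometry: hypotenuse "
                              "shorter than half-breadth")
    L = np.linalg.norm(c[0] - c[1])
    if L == 0:
        raise ShapeStatsError("zero egg length")
    return float(np.sqrt(h * h - w * w) / L)


def shape_ratios(lms) -> ShapeRatios:
    c = _coords_of(lms)
    return ShapeRatios(length=float(np.linalg.norm(c[0] - c[1])),
                       width=float(np.linalg.norm(c[2] - c[3])),
                       elongation=elongation(lms), asymmetry=asymmetry(lms))


# ---------------------------------------------------------------------------
# Distance-based Procrustes ANOVA with RRPP
# ---------------------------------------------------------------------------

@dataclass
class AnovaTable:
    """df / SS / MS / R^2 / F / Z / p rows of a distance-based ANOVA."""

    rows: pd.DataFrame
    permutations: int
    seed: int | None
    degenerate: bool = False

    def term(self, name: str) -> pd.Series:
        return self.rows.loc[name]

    def to_dict(self) -> dict:
        out = {"permutations": self.permutations, "seed": self.seed,
               "degenerate": self.degenerate, "terms": {}}
        for name, row in self.rows.iterrows():
            out["terms"][name] = {
                k: (None if pd.isna(v) else float(v)) for k, v in row.items()}
            out["terms"][name]["Df"] = int(row["Df"])
        return out


def _rss(H: np.ndarray, Y: np.ndarray) -> float:
    R = Y - H @ Y
    return float(np.einsum("ij,ij->", R, R))


def _zscore(obs: float, perm: np.ndarray) -> float:
    vals = np.concatenate([[obs], perm])
    vals = vals[vals > 0]
    if len(vals) < 3:
        return float("nan")
    logs = np.log(vals)
    sd = logs.std(ddof=1)
    if sd == 0:
        return float("nan")
    return float((np.log(obs) - logs.mean()) / sd)


def nested_danova(shapes, species, clutch, nperm: int = 1000,
                  seed: int | None = None) -> AnovaTable:
    """Nested distance-based Procrustes ANOVA, shape ~ species/clutch.

    Sequential sums of squares (intercept -> +species -> +species:clutch);
    F_species = MS_species / MS_clutch (the nested error stratum),
    F_clutch = MS_clutch / MS_residual. P-values by RRPP: residuals of each
    term's reduced model are permuted ``nperm`` times and
    p = (1 + #{F* >= F_obs}) / (nperm + 1). Z is the effect size on the
    log-F permutation distribution (observed case included).
    """
    Y = _reduce_columns(_as_matrix(shapes))
    n = len(Y)
    sp_codes, sp_levels = _codes(species)
    # clutch labels are nested: identify clutches by (species, clutch) pairs
    cl_pairs = list(zip(np.asarray(species), np.asarray(clutch)))
    cl_codes, cl_levels = _codes([f"{s}::{c}" for s, c in cl_pairs])
    # validate nesting: a clutch label must not span species
    by_label: dict = {}
    for s, c in cl_pairs:
        by_label.setdefault(c, set()).add(s)
    for label, sps in by_label.items():
        if len(sps) > 1:
            raise ShapeStatsError(f"clutch label {label!r} occurs in several "
                                  f"species: {sorted(map(str, sps))}")
    n_sp, n_cl = len(sp_levels), len(cl_levels)
    if n_sp < 2:
        raise ShapeStatsError("need at least two species")
    if n <= n_cl:
        raise ShapeStatsError("need more specimens than clutches")
    df = {"species": n_sp - 1, "clutch": n_cl - n_sp, "resid": n - n_cl}
    if df["clutch"] < 1:
        raise ShapeStatsError("nested design needs clutches within species")

    H0 = np.full((n, n), 1.0 / n)
    H1 = _hat(_dummies(sp_codes))
    H2 = _hat(_dummies(cl_codes))
    rss0, rss1, rss2 = _rss(H0, Y), _rss(H1, Y), _rss(H2, Y)
    ss = {"species": rss0 - rss1, "clutch": rss1 - rss2, "resid": rss2,
          "total": rss0}
    degenerate = ss["total"] <= 1e-30

    def f_stats(y):
        r0, r1, r2 = _rss(H0, y), _rss(H1, y), _rss(H2, y)
        ms_sp = (r0 - r1) / df["species"]
        ms_cl = (r1 - r2) / df["clutch"]
        ms_re = r2 / df["resid"]
        f_sp = ms_sp / ms_cl if ms_cl > 0 else np.nan
        f_cl = ms_cl / ms_re if ms_re > 0 else np.nan
        return f_sp, f_cl

    f_sp_obs, f_cl_obs = f_stats(Y)
    rng = np.random.default_rng(seed)
    f_sp_perm = np.empty(nperm)
    f_cl_perm = np.empty(nperm)
    fit0, res0 = H0 @ Y, Y - H0 @ Y
    fit1, res1 = H1 @ Y, Y - H1 @ Y
    for b in range(nperm):
        perm = rng.permutation(n)
        f_sp_perm[b] = f_stats(fit0 + res0[perm])[0]
        f_cl_perm[b] = f_stats(fit1 + res1[perm])[1]

    def pval(obs, perm):
        if not np.isfinite(obs):
            return np.nan
        return (1 + np.sum(perm >= obs)) / (nperm + 1)

    ms = {k: ss[k] / df[k] for k in ("species", "clutch", "resid")}
    total = ss["total"] if ss["total"] > 0 else np.nan
    rows = pd.DataFrame(
        {
            "Df": [df["species"], df["clutch"], df["resid"], n - 1],
            "SS": [ss["species"], ss["clutch"], ss["resid"], ss["total"]],
            "MS": [ms["species"], ms["clutch"], ms["resid"], np.nan],
            "R2": [ss["species"] / total, ss["clutch"] / total,
                   ss["resid"] / total, np.nan],
            "F": [f_sp_obs, f_cl_obs, np.nan, np.nan],
            "Z": [_zscore(f_sp_obs, f_sp_perm), _zscore(f_cl_obs, f_cl_perm),
                  np.nan, np.nan],
            "p": [pval(f_sp_obs, f_sp_perm), pval(f_cl_obs, f_cl_perm),
                  np.nan, np.nan],
        },
        index=["species", "species:clutch", "Residuals", "Total"],
    )
    return AnovaTable(rows=rows, permutations=nperm, seed=seed,
                      degenerate=degenerate)


def oneway_danova(shapes, groups, nperm: int = 1000,
                  seed: int | None = None) -> AnovaTable:
    """One-way distance-based Procrustes ANOVA (F = MS_group / MS_residual,
    RRPP over intercept-model residuals)."""
    Y = _reduce_columns(_as_matrix(shapes))
    n = len(Y)
    codes, levels = _codes(groups)
    g = len(levels)
    if g < 2:
        raise ShapeStatsError("need at least two groups")
    if n <= g:
        raise ShapeStatsError("need more specimens than groups")
    df1, df2 = g - 1, n - g
    H0 = np.full((n, n), 1.0 / n)
    H1 = _hat(_dummies(codes))
    rss0, rss1 = _rss(H0, Y), _rss(H1, Y)
    ss_g, ss_r, ss_t = rss0 - rss1, rss1, rss0
    degenerate = ss_t <= 1e-30

    def f_stat(y):
        r0, r1 = _rss(H0, y), _rss(H1, y)
        msr = r1 / df2
        return ((r0 - r1) / df1) / msr if msr > 0 else np.nan

    f_obs = f_stat(Y)
    rng = np.random.default_rng(seed)
    fit0, res0 = H0 @ Y, Y - H0 @ Y
    f_perm = np.array([f_stat(fit0 + res0[rng.permutation(n)])
                       for _ in range(nperm)])
    if np.isfinite(f_obs):
        p = (1 + np.sum(f_perm >= f_obs)) / (nperm + 1)
    else:
        p = np.nan
    total = ss_t if ss_t > 0 else np.nan
    rows = pd.DataFrame(
        {
            "Df": [df1, df2, n - 1],
            "SS": [ss_g, ss_r, ss_t],
            "MS": [ss_g / df1, ss_r / df2, np.nan],
            "R2": [ss_g / total, ss_r / total, np.nan],
            "F": [f_obs, np.nan, np.nan],
            "Z": [_zscore(f_obs, f_perm) if np.isfinite(f_obs) else np.nan,
                  np.nan, np.nan],
            "p": [p, np.nan, np.nan],
        },
        index=["groups", "Residuals", "Total"],
    )
    return AnovaTable(rows=rows, permutations=nperm, seed=seed,
                      degenerate=degenerate)


# ---------------------------------------------------------------------------
# Morphological disparity (Procrustes variance)
# ---------------------------------------------------------------------------

@dataclass
class DisparityResult:
    """Per-group Procrustes variance and its pairwise permutation test."""

    groups: list
    variances: np.ndarray           # (g,)
    differences: np.ndarray         # (g, g) |PV_i - PV_j|, zero diagonal
    p_values: np.ndarray | None     # (g, g) or None if no test run
    permutations: int | None
    seed: int | None

    def to_dict(self) -> dict:
        out = {"groups": [str(g) for g in self.groups],
               "procrustes_variance": {str(g): float(v) for g, v
                                       in zip(self.groups, self.variances)},
               "abs_differences": self.differences.tolist(),
               "permutations": self.permutations, "seed": self.seed}
        if self.p_values is not None:
            out["p_values"] = self.p_values.tolist()
        return out


def _group_pv(Y: np.ndarray) -> float:
    """Mean squared distance of rows from their mean."""
    R = Y - Y.mean(axis=0)
    return float(np.einsum("ij,ij->", R, R)) / len(Y)


def _group_pv_trace(Y: np.ndarray) -> float:
    """Sum of the diagonal of the group covariance matrix (divisor n)."""
    R = Y - Y.mean(axis=0)
    cov = R.T @ R / len(Y)
    return float(np.trace(cov))


def disparity(shapes, groups) -> DisparityResult:
    """Procrustes variance per group: the mean squared (Procrustes)
    distance of each specimen from its group mean shape, equal to the
    trace of the group covariance matrix (divisor n_g). Both formulations
    are computed and must agree."""
    Y = _as_matrix(shapes)
    codes, levels = _codes(groups)
    pvs = np.empty(len(levels))
    for gi in range(len(levels)):
        sub = Y[codes == gi]
        if len(sub) == 0:
            raise ShapeStatsError(f"empty group {levels[gi]!r}")
        a, b = _group_pv(sub), _group_pv_trace(sub)
        if abs(a - b) > 1e-10 * max(a, b, 1e-300):
            raise ShapeStatsError("internal inconsistency between the "
                                  "distance and covariance-trace forms")
        pvs[gi] = a
    diff = np.abs(pvs[:, None] - pvs[None, :])
    return DisparityResult(groups=levels, variances=pvs, differences=diff,
                           p_values=None, permutations=None, seed=None)


def pairwise_disparity_test(shapes, groups, nperm: int = 1000,
                            seed: int | None = None) -> DisparityResult:
    """Permutation test of pairwise absolute differences in Procrustes
    variance: specimens' residual vectors (deviations from their own group
    mean) are randomised among groups and the PVs recomputed;
    p = (1 + #{|dPV*| >= |dPV_obs|}) / (nperm + 1)."""
    Y = _as_matrix(shapes)
    codes, levels = _codes(groups)
    g = len(levels)
    if g < 2:
        raise ShapeStatsError("need at least two groups")
    base = disparity(Y, groups)
    # squared residual norms carry all the information the PV needs
    sqnorm = np.empty(len(Y))
    for gi in range(g):
        mask = codes == gi
        R = Y[mask] - Y[mask].mean(axis=0)
        sqnorm[mask] = (R ** 2).sum(axis=1)
    rng = np.random.default_rng(seed)
    counts = np.zeros((g, g))
    obs = base.differences
    sizes = np.bincount(codes, minlength=g).astype(float)
    for _ in range(nperm):
        perm = sqnorm[rng.permutation(len(Y))]
        pv_star = np.bincount(codes, weights=perm, minlength=g) / sizes
        diff_star = np.abs(pv_star[:, None] - pv_star[None, :])
        counts += diff_star >= obs - 1e-300
    pvals = (1.0 + counts) / (nperm + 1.0)
    np.fill_diagonal(pvals, 1.0)
    return DisparityResult(groups=levels, variances=base.variances,
                           differences=obs, p_values=pvals,
                           permutations=nperm, seed=seed)


# ---------------------------------------------------------------------------
# Scalar ANOVA and correlations
# ---------------------------------------------------------------------------

@dataclass
class ScalarAnova:
    F: float
    df1: int
    df2: int
    p: float
    degenerate: bool = False


def scalar_anova(values, groups) -> ScalarAnova:
    """Classical one-way ANOVA with the parametric F p-value (used e.g. to
    compare mean clutch disparity among species)."""
    vals = np.asarray(values, dtype=np.float64)
    codes, levels = _codes(groups)
    if len(levels) < 2:
        raise ShapeStatsError("need at least two groups")
    samples = [vals[codes == gi] for gi in range(len(levels))]
    df1, df2 = len(levels) - 1, len(vals) - len(levels)
    if df2 < 1:
        raise ShapeStatsError("not enough residual degrees of freedom")
    grand = vals.mean()
    ss_b = sum(len(s) * (s.mean() - grand) ** 2 for s in samples)
    ss_w = sum(((s - s.mean()) ** 2).sum() for s in samples)
    if ss_w <= 0:
        return ScalarAnova(F=np.nan, df1=df1, df2=df2, p=np.nan,
                           degenerate=True)
    F = (ss_b / df1) / (ss_w / df2)
    p = float(_sps.f.sf(F, df1, df2))
    return ScalarAnova(F=float(F), df1=df1, df2=df2, p=p)


def correlate_scores_with_ratios(pca_result: PCAResult,
                                 ratios: list[ShapeRatios]
                                 ) -> tuple[float, float]:
    """Pearson correlations (r_PC1-elongation, r_PC2-asymmetry) for
    specimens in matching order."""
    if len(ratios) != len(pca_result.scores):
        raise ShapeStatsError("ratio list does not match score rows")
    e = np.array([r.elongation for r in ratios])
    a = np.array([r.asymmetry for r in ratios])
    out = []
    for j, v in enumerate((e, a)):
        if j >= pca_result.scores.shape[1]:
            out.append(float("nan"))
            continue
        s = pca_result.scores[:, j]
        if np.std(s) == 0 or np.std(v) == 0:
            raise ShapeStatsError("zero variance in scores or ratios")
        out.append(float(np.corrcoef(s, v)[0, 1]))
    return out[0], out[1]
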