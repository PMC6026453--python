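import numpy as np
import pytest
from scipy import stats as sps

import eggmorph as em
from eggmorph.shape_stats import ShapeStatsError

from conftest import make_ellipsoid


def study_design_labels():
    """Species and clutch label vectors of the 55-specimen museum design."""
    sizes = {"A": [3, 3, 2, 3], "B": [5, 6, 5, 5],
             "C": [2, 2, 2, 3], "D": [3, 4, 4, 3]}
    species, clutch = [], []
    for sp, cs in sizes.items():
        for ci, n in enumerate(cs):
            species += [sp] * n
            clutch += [f"{sp}{ci}"] * n
    return np.array(species), np.array(clutch)


def nested_anova_oracle(y, species, clutch):
    """Textbook nested ANOVA by explicit group means on a scalar response."""
    y = np.asarray(y, dtype=float)
    grand = y.mean()
    ss_sp = ss_cl = ss_re = 0.0
    for sp in np.unique(species):
        ysp = y[species == sp]
        ss_sp += len(ysp) * (ysp.mean() - grand) ** 2
        for cl in np.unique(clutch[species == sp]):
            ycl = y[(species == sp) & (clutch == cl)]
            ss_cl += len(ycl) * (ycl.mean() - ysp.mean()) ** 2
            ss_re += ((ycl - ycl.mean()) ** 2).sum()
    return ss_sp, ss_cl, ss_re


@pytest.fixture(scope="module")
def alignment():
    rng = np.random.default_rng(30)
    base = rng.normal(size=(20, 3))
    shapes = [base + 0.05 * rng.normal(size=base.shape) for _ in range(12)]
    return em.gpa(shapes)


class TestPca:

    def test_percent_variance_sums_to_100(self, alignment):
        res = em.pca(alignment)
        assert res.percent_variance.sum() == pytest.approx(100.0, abs=1e-8)
        assert np.all(np.diff(res.eigenvalues) <= 1e-12)
        assert np.all(res.eigenvalues >= 0)

    def test_reconstruction_with_all_components(self, alignment):
        res = em.pca(alignment)
        Y = alignment.flattened()
        recon = res.mean + res.scores @ res.loadings.T
        assert np.abs(recon - Y).max() < 1e-8

    def test_component_count_bound(self, alignment):
        res = em.pca(alignment)
        n, p = alignment.n_specimens, alignment.n_landmarks
        assert res.n_components <= min(n - 1, 3 * p - 7)

    def test_needs_three_specimens(self):
        rng = np.random.default_rng(0)
        two = em.gpa([rng.normal(size=(8, 3)) for _ in range(2)])
        with pytest.raises(ShapeStatsError):
            em.pca(two)


class TestRatios:
    def test_sphere_elongation_is_one(self, sphere):
        from eggmorph.digitizer import place_anchors
        oriented, _ = em.orient_poles(sphere)
        anchors = place_anchors(oriented)
        assert em.elongation(anchors) == pytest.approx(1.0, abs=1e-2)

    def test_ellipsoid_elongation(self):
        from eggmorph.digitizer import place_anchors
        ell = make_ellipsoid((2.0, 1.0, 0.8), subdivisions=4)
        assert em.elongation(place_anchors(ell)) == pytest.approx(2.0,
                                                                  abs=1e-2)

    def test_generator_ground_truth_elongation(self):
        mesh = em.make_egg_mesh(em.EggParams(40, 28, 0.0),
                                n_axial=40, n_azimuthal=40)
        template = em.template_from_specimen(mesh, n_semi=40)
        lms = em.digitize_specimen(mesh, template)
        assert em.elongation(lms) == pytest.approx(40 / 28, rel=1e-2)

    def test_symmetric_ellipsoid_asymmetry_is_half(self):
        from eggmorph.digitizer import place_anchors
        ell = make_ellipsoid((2.0, 1.0, 0.8), subdivisions=4)
        assert em.asymmetry(place_anchors(ell)) == pytest.approx(0.5,
                                                                 abs=1e-3)

    def test_hand_built_configuration(self):
        # h = sqrt(20), w = 2, d = 4, L = 6 -> A = 2/3
        lms = np.array([[-3, 0, 0], [3, 0, 0], [1, 2, 0], [1, -2, 0],
                        [0, 0, 1], [0, 0, -1]], dtype=float)
        assert em.asymmetry(lms) == pytest.approx(2.0 / 3.0, abs=1e-12)

    def test_degenerate_colinear_pole_gives_zero(self):
        # the triangle inequality forces h >= w for any real points; at the
        # boundary (pole on the equator segment) the offset d collapses to 0
        lms = np.array([[0, 0, 0], [4, 0, 0], [0, 1.0, 0], [0, -1.0, 0],
                        [0, 0, 1], [0, 0, -1]], dtype=float)
        assert em.asymmetry(lms) == 0.0


class TestNestedDanova:
    def test_study_design_degrees_of_freedom(self):
        species, clutch = study_design_labels()
        rng = np.random.default_rng(40)
        Y = rng.normal(size=(55, 12))
        table = em.nested_danova(Y, species, clutch, nperm=99, seed=1)
        assert table.term("species")["Df"] == 3
        assert table.term("species:clutch")["Df"] == 12
        assert table.term("Residuals")["Df"] == 39
        assert table.term("Total")["Df"] == 54

    def test_bookkeeping_identities(self):
        species, clutch = study_design_labels()
        rng = np.random.default_rng(41)
        Y = rng.normal(size=(55, 9))
        t = em.nested_danova(Y, species, clutch, nperm=49, seed=2).rows
        assert t["Df"][:3].sum() == t.loc["Total", "Df"]
        assert t["SS"][:3].sum() == pytest.approx(t.loc["Total", "SS"],
                                                  rel=1e-10)
        assert t["R2"][:3].sum() == pytest.approx(1.0, abs=1e-10)

    def test_matches_scalar_nested_oracle(self):
        species, clutch = study_design_labels()
        rng = np.random.default_rng(42)
        y = rng.normal(size=55) + (species == "B") * 0.5
        table = em.nested_danova(y[:, None], species, clutch,
                                 nperm=9, seed=0)
        ss_sp, ss_cl, ss_re = nested_anova_oracle(y, species, clutch)
        assert table.term("species")["SS"] == pytest.approx(ss_sp, abs=1e-10)
        assert table.term("species:clutch")["SS"] == pytest.approx(ss_cl,
                                                                   abs=1e-10)
        assert table.term("Residuals")["SS"] == pytest.approx(ss_re,
                                                              abs=1e-10)
        f_sp = (ss_sp / 3) / (ss_cl / 12)
        f_cl = (ss_cl / 12) / (ss_re / 39)
        assert table.term("species")["F"] == pytest.approx(f_sp, rel=1e-10)
        assert table.term("species:clutch")["F"] == pytest.approx(f_cl,
                                                                  rel=1e-10)

    def test_same_seed_same_pvalues(self):
        species, clutch = study_design_labels()
        rng = np.random.default_rng(43)
        Y = rng.normal(size=(55, 6))
        t1 = em.nested_danova(Y, species, clutch, nperm=99, seed=5)
        t2 = em.nested_danova(Y, species, clutch, nperm=99, seed=5)
        assert t1.rows["p"].equals(t2.rows["p"])

    def test_clutch_label_spanning_species_rejected(self):
        species = np.array(["A"] * 4 + ["B"] * 4)
        clutch = np.array(["c1", "c1", "c2", "c2"] * 2)
        with pytest.raises(ShapeStatsError):
            em.nested_danova(np.random.default_rng(0).normal(size=(8, 3)),
                             species, clutch, nperm=9)


class TestOnewayDanova:
    def test_study_species_degrees_of_freedom(self):
        species, _ = study_design_labels()
        rng = np.random.default_rng(50)
        Y = rng.normal(size=(55, 12))
        table = em.oneway_danova(Y, species, nperm=99, seed=1)
        assert table.term("groups")["Df"] == 3
        assert table.term("Residuals")["Df"] == 51

    def test_identical_shapes_flagged_degenerate(self):
        Y = np.ones((12, 6))
        groups = np.repeat(["a", "b", "c"], 4)
        table = em.oneway_danova(Y, groups, nperm=9, seed=0)
        assert table.degenerate
        assert np.isnan(table.term("groups")["F"])

    def test_matches_scalar_oneway_oracle(self):
        rng = np.random.default_rng(51)
        y = rng.normal(size=30)
        groups = np.repeat(["a", "b", "c"], 10)
        table = em.oneway_danova(y[:, None], groups, nperm=9, seed=0)
        F, _ = sps.f_oneway(*(y[groups == g] for g in "abc"))
        assert table.term("groups")["F"] == pytest.approx(F, rel=1e-10)


class TestDisparity:
    def test_identical_shapes_have_zero_variance(self):
        Y = np.tile(np.arange(6.0), (8, 1))
        groups = np.repeat(["a", "b"], 4)
        res = em.disparity(Y, groups)
        assert np.allclose(res.variances, 0.0)

    def test_dual_formula_agreement_on_random_groups(self):
        # the distance-based and covariance-trace paths are checked
        # against each other inside disparity(); a mismatch raises
        rng = np.random.default_rng(60)
        Y = rng.normal(size=(40, 18))
        groups = rng.choice(["a", "b", "c"], size=40)
        res = em.disparity(Y, groups)
        assert np.all(res.variances > 0)
        assert np.allclose(res.differences, res.differences.T)
        assert np.allclose(np.diag(res.differences), 0.0)

    def test_quadratic_scaling_of_residuals(self):
        rng = np.random.default_rng(61)
        Y = rng.normal(size=(20, 9))
        groups = np.repeat(["a", "b"], 10)
        base = em.disparity(Y, groups)
        Y2 = np.empty_like(Y)
        for g in ("a", "b"):
            sub = Y[groups == g]
            Y2[groups == g] = sub.mean(0) + 2.0 * (sub - sub.mean(0))
        scaled = em.disparity(Y2, groups)
        assert np.allclose(scaled.variances, 4.0 * base.variances, rtol=1e-10)

    def test_pairwise_test_output_structure(self):
        rng = np.random.default_rng(62)
        Y = rng.normal(size=(30, 12))
        groups = np.repeat(["a", "b", "c"], 10)
        res = em.pairwise_disparity_test(Y, groups, nperm=199, seed=3)
        assert np.allclose(res.differences, res.differences.T)
        assert np.allclose(np.diag(res.differences), 0.0)
        off = ~np.eye(3, dtype=bool)
        assert np.all(res.p_values[off] > 0) and np.all(res.p_values[off] <= 1)


class TestScalarAnova:
    def test_hand_computed_three_groups(self):
        values = [1, 2, 2, 3, 3, 4]
        groups = ["a", "a", "b", "b", "c", "c"]
        res = em.scalar_anova(values, groups)
        # SS_between = 4, SS_within = 1.5, df = (2, 3) -> F = 4
        assert res.F == pytest.approx(4.0, abs=1e-12)
        assert (res.df1, res.df2) == (2, 3)
        assert res.p == pytest.approx(float(sps.f.sf(4.0, 2, 3)), abs=1e-12)

    def test_equal_group_means_give_small_f(self):
        rng = np.random.default_rng(70)
        base = rng.normal(size=10)
        values = np.concatenate([base, base + 1e-12, base - 1e-12])
        groups = np.repeat(["a", "b", "c"], 10)
        res = em.scalar_anova(values, groups)
        assert res.F == pytest.approx(0.0, abs=1e-6)

    def test_matches_scipy(self):
        rng = np.random.default_rng(71)
        values = rng.normal(size=24)
        groups = np.repeat(["a", "b", "c", "d"], 6)
        res = em.scalar_anova(values, groups)
        F, p = sps.f_oneway(*(values[groups == g] for g in "abcd"))
        assert res.F == pytest.approx(float(F), rel=1e-10)
        assert res.p == pytest.approx(float(p), rel=1e-10)


class TestCorrelations:
    def test_perfectly_linear_pair(self):
        rng = np.random.default_rng(80)
        base = rng.normal(size=(20, 3))
        shapes = [base + 0.05 * rng.normal(size=base.shape)
                  for _ in range(10)]
        res = em.pca(em.gpa(shapes))
        # ratios built as exact linear functions of the scores
        ratios = [em.ShapeRatios(length=1, width=1,
                                 elongation=2.0 * res.scores[i, 0] + 5.0,
                                 asymmetry=-3.0 * res.scores[i, 1] + 1.0)
                  for i in range(10)]
        r1, r2 = em.correlate_scores_with_ratios(res, ratios)
        assert r1 == pytest.approx(1.0, abs=1e-10)
        assert r2 == pytest.approx(-1.0, abs=1e-10)

    def test_matches_direct_formula(self):
        rng = np.random.default_rng(81)
        base = rng.normal(size=(15, 3))
        shapes = [base + 0.05 * rng.normal(size=base.shape)
                  for _ in range(8)]
        res = em.pca(em.gpa(shapes))
        e = rng.normal(size=8) + 2
        a = rng.normal(size=8) * 0.1 + 0.5
        ratios = [em.ShapeRatios(1, 1, e[i], a[i]) for i in range(8)]
        r1, r2 = em.correlate_scores_with_ratios(res, ratios)
        s1, s2 = res.scores[:, 0], res.scores[:, 1]
        direct1 = np.cov(s1, e)[0, 1] / (s1.std(ddof=1) * e.std(ddof=1))
        direct2 = np.cov(s2, a)[0, 1] / (s2.std(ddof=1) * a.std(ddof=1))
        assert r1 == pytest.approx(direct1, abs=1e-12)
        assert r2 == pytest.approx(direct2, abs=1e-12)
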