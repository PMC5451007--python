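"""Geometric morphometrics: GPA, allometry, PCA, CVA, distances, ellipses."""

import numpy as np
import pytest
from scipy.stats import chi2

from flightdiff import morpho, synthdata
from flightdiff.morpho import LandmarkSet


def lms_from_coords(coords, groups=None):
    coords = np.asarray(coords, float)
    n = coords.shape[0]
    g = (
        np.array(groups, dtype=object)
        if groups is not None
        else np.array(["g"] * n, dtype=object)
    )
    return LandmarkSet(
        specimens=np.array([f"s{i}" for i in range(n)], dtype=object),
        groups=g,
        coords=coords,
    )


def random_similarity(coords, rng):
    """Random rotation + scale + translation (no reflection) per specimen."""
    out = np.empty_like(coords)
    for i in range(coords.shape[0]):
        th = rng.uniform(0, 2 * np.pi)
        R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        s = rng.uniform(0.5, 2.0)
        out[i] = coords[i] @ R.T * s + rng.uniform(-5, 5, 2)
    return out


class TestCentroidSize:
    def test_two_point_configuration(self):
        cfg = np.zeros((12, 2))
        cfg[1] = [2.0, 0.0]
        # centroid size is dominated by the two stated points plus the
        # ten copies at the origin: compute directly against the formula
        c = cfg - cfg.mean(axis=0)
        assert morpho.centroid_size(cfg) == pytest.approx(
            np.sqrt((c**2).sum())
        )

    def test_unit_square_corners(self):
        """Four unit-square corners (triplicated to 12 points): CS = √6."""
        sq = np.array([[0, 0], [1, 0], [1, 1], [0, 1]], float)
        cfg = np.vstack([sq, sq, sq])
        # 12 points, each 0.5 squared distance from centroid -> sqrt(6)
        assert morpho.centroid_size(cfg) == pytest.approx(np.sqrt(6.0))

    def test_homogeneity_under_scaling(self):
        rng = np.random.default_rng(1)
        cfg = rng.normal(size=(12, 2))
        assert morpho.centroid_size(3.5 * cfg) == pytest.approx(
            3.5 * morpho.centroid_size(cfg)
        )

    def test_degenerate_configuration_is_zero(self):
        assert morpho.centroid_size(np.ones((12, 2))) == 0.0


class TestGeneralizedProcrustes:
    def test_similarity_copies_align_exactly(self):
        rng = np.random.default_rng(2)
        base = synthdata.DEFAULT_BASE_SHAPE
        coords = random_similarity(np.tile(base, (8, 1, 1)), rng)
        aligned = morpho.generalized_procrustes(lms_from_coords(coords))
        flat = aligned.procrustes_coords.reshape(8, -1)
        assert np.linalg.norm(flat - flat[0], axis=1).max() < 1e-8

    def test_pairwise_symmetry(self):
        rng = np.random.default_rng(3)
        coords = rng.normal(size=(2, 12, 2))
        a1 = morpho.generalized_procrustes(lms_from_coords(coords))
        a2 = morpho.generalized_procrustes(lms_from_coords(coords[::-1]))
        d1 = np.linalg.norm(
            a1.procrustes_coords[0] - a1.procrustes_coords[1]
        )
        d2 = np.linalg.norm(
            a2.procrustes_coords[0] - a2.procrustes_coords[1]
        )
        assert d1 == pytest.approx(d2, abs=1e-12)

    def test_aligned_configurations_are_centered(self):
        rng = np.random.default_rng(4)
        aligned = morpho.generalized_procrustes(
            lms_from_coords(rng.normal(size=(6, 12, 2)))
        )
        assert np.abs(
            aligned.procrustes_coords.mean(axis=1)
        ).max() < 1e-9
        assert np.sqrt((aligned.mean_shape**2).sum()) == pytest.approx(1.0)

    def test_zero_noise_group_means_match_generators(self):
        eff = np.zeros(24)
        eff[0] = 0.05
        lms, truth = synthdata.sim_landmarks(
            {"a": 10, "b": 10},
            shape_effects={"a": eff, "b": -eff},
            noise_sd=0.0,
            seed=5,
        )
        # compare on the pre-shape sphere (tangent projection deliberately
        # displaces configurations by O(distance²) off the sphere)
        aligned = morpho.generalized_procrustes(lms, tangent_projection=False)
        # group means should equal the generating shapes up to similarity:
        # align generated group-mean shapes against recovered ones
        for lab in ("a", "b"):
            target = (truth.base_shape.reshape(24) + truth.shape_effects[lab])
            got = aligned.procrustes_coords[aligned.groups == lab].mean(axis=0)
            both = morpho.generalized_procrustes(
                lms_from_coords(np.stack([target.reshape(12, 2), got])),
                tangent_projection=False,
            )
            d = np.linalg.norm(
                both.procrustes_coords[0] - both.procrustes_coords[1]
            )
            assert d < 1e-6

    def test_rotation_never_reflects(self):
        rng = np.random.default_rng(6)
        base = synthdata.DEFAULT_BASE_SHAPE
        coords = random_similarity(np.tile(base, (5, 1, 1)), rng)
        coords[2] = coords[2][:, ::-1]  # a reflected specimen stays reflected
        aligned = morpho.generalized_procrustes(lms_from_coords(coords))
        flat = aligned.procrustes_coords.reshape(5, -1)
        d = np.linalg.norm(flat - flat[0], axis=1)
        assert d[[1, 3, 4]].max() < 1e-8
        assert d[2] > 0.05


class TestAllometry:
    def test_no_covariance_means_no_prediction(self):
        lms, _ = synthdata.sim_landmarks({"a": 30}, noise_sd=0.01, seed=7)
        res = morpho.allometry_correction(morpho.generalized_procrustes(lms))
        assert res.percent_predicted < 0.1

    def test_allometric_direction_recovered(self):
        """Generator allometric vector of norm 0.05: direction cosine > 0.99.

        Superimposition removes translation, rotation, and size by
        construction, so only the component of the allometric vector in the
        tangent space of the shape manifold is recoverable; the truth
        vector is therefore drawn in that tangent space.
        """
        rng = np.random.default_rng(8)
        base = synthdata.DEFAULT_BASE_SHAPE
        v = rng.normal(size=24)
        # project out translations, the rotation generator, and the radial
        # (size) direction at the base shape
        null = np.zeros((4, 24))
        null[0, 0::2] = 1.0                         # x translation
        null[1, 1::2] = 1.0                         # y translation
        null[2] = np.stack([-base[:, 1], base[:, 0]], 1).reshape(24)  # rotation
        null[3] = base.reshape(24)                  # scale
        for b0 in null:
            v -= (v @ b0) / (b0 @ b0) * b0
        v /= np.linalg.norm(v)
        lms, truth = synthdata.sim_landmarks(
            {"a": 40}, allometric_vector=0.05 * v, noise_sd=0.005, seed=9
        )
        aligned = morpho.generalized_procrustes(lms)
        res = morpho.allometry_correction(aligned)
        cos = _best_similarity_cosine(0.05 * v, res.regression_vector)
        assert cos > 0.99

    def test_residuals_uncorrelated_with_size(self):
        lms, _ = synthdata.sim_landmarks({"a": 15, "b": 15}, noise_sd=0.01, seed=10)
        res = morpho.allometry_correction(morpho.generalized_procrustes(lms))
        cs = res.centroid_size - res.centroid_size.mean()
        cov = cs @ res.residual_coords / len(cs)
        assert np.abs(cov).max() < 1e-9

    def test_constant_size_degenerates_gracefully(self, caplog):
        lms, _ = synthdata.sim_landmarks(
            {"a": 8}, cs_range=(25.0, 25.0), noise_sd=0.0, seed=11
        )
        aligned = morpho.generalized_procrustes(lms)
        with caplog.at_level("WARNING"):
            res = morpho.allometry_correction(aligned)
        assert res.percent_predicted == 0.0
        assert np.allclose(res.regression_vector, 0.0)


def _best_similarity_cosine(truth_vec, est_vec):
    """Cosine between 24-vectors, allowing the rotation freedom of GPA."""
    t = truth_vec.reshape(12, 2)
    e = est_vec.reshape(12, 2)
    r = morpho._rotation_onto(t, e)
    t = (t @ r).reshape(24)
    e = est_vec
    return float(t @ e / (np.linalg.norm(t) * np.linalg.norm(e)))


class TestShapePca:
    def test_eigenvalue_sum_matches_total_variance(self):
        lms, _ = synthdata.sim_landmarks({"a": 20}, noise_sd=0.01, seed=12)
        res = morpho.allometry_correction(morpho.generalized_procrustes(lms))
        r = morpho.shape_pca(res)
        X = res.residual_coords - res.residual_coords.mean(axis=0)
        assert r.eigenvalues.sum() == pytest.approx(
            (X**2).sum() / (len(X) - 1), rel=1e-9
        )

    def test_rank_bounded_by_twenty(self):
        lms, _ = synthdata.sim_landmarks({"a": 60}, noise_sd=0.01, seed=13)
        res = morpho.allometry_correction(morpho.generalized_procrustes(lms))
        r = morpho.shape_pca(res)
        nonzero = (r.eigenvalues > 1e-12 * r.eigenvalues.max()).sum()
        assert nonzero <= 20

    def test_pc1_tracks_group_difference_at_low_noise(self):
        rng = np.random.default_rng(14)
        v = rng.normal(size=24)
        v = v / np.linalg.norm(v) * 0.05
        lms, _ = synthdata.sim_landmarks(
            {"a": 25, "b": 25},
            shape_effects={"a": v, "b": -v},
            noise_sd=0.005,
            seed=15,
        )
        res = morpho.allometry_correction(morpho.generalized_procrustes(lms))
        r = morpho.shape_pca(res)
        diff = (
            res.residual_coords[res.groups == "a"].mean(axis=0)
            - res.residual_coords[res.groups == "b"].mean(axis=0)
        )
        cos = abs(r.components[0] @ diff) / np.linalg.norm(diff)
        assert cos > 0.95


class TestCanonicalVariates:
    def test_matches_fisher_discriminant_at_two_groups(self):
        """CV1 equals the independently solved W⁻¹(m₁−m₂) direction."""
        lms, _ = synthdata.sim_landmarks(
            {"a": 30, "b": 30},
            shape_effects={"a": np.r_[0.03, np.zeros(23)],
                           "b": np.r_[-0.03, np.zeros(23)]},
            noise_sd=0.01,
            seed=16,
        )
        res = morpho.allometry_correction(morpho.generalized_procrustes(lms))
        cva = morpho.canonical_variates(res)
        # independent direct solve in the same rank-guarded subspace
        X = res.residual_coords - res.residual_coords.mean(axis=0)
        U, s, Vt = np.linalg.svd(X, full_matrices=False)
        P = Vt[s**2 > 1e-12 * (s**2).max()].T
        Z = X @ P
        za, zb = Z[res.groups == "a"], Z[res.groups == "b"]
        W = ((za - za.mean(0)).T @ (za - za.mean(0))
             + (zb - zb.mean(0)).T @ (zb - zb.mean(0))) / (len(Z) - 2)
        w_dir = np.linalg.solve(W, za.mean(0) - zb.mean(0))
        fisher_scores = Z @ w_dir
        cv1 = cva.cv_scores[:, 0]
        cos = abs(np.corrcoef(fisher_scores, cv1)[0, 1])
        assert cos > 0.9999
        assert cva.cv_scores.shape[1] == 1

    def test_identical_group_means_give_null_eigenvalues(self):
        """Duplicating one point cloud under two labels nulls every axis."""
        rng = np.random.default_rng(17)
        cloud = rng.normal(size=(12, 12, 2)) * 0.01 + synthdata.DEFAULT_BASE_SHAPE
        coords = np.concatenate([cloud, cloud])
        lms = lms_from_coords(coords, groups=["a"] * 12 + ["b"] * 12)
        res = morpho.allometry_correction(morpho.generalized_procrustes(lms))
        cva = morpho.canonical_variates(res)
        assert cva.eigenvalues.max() < 1e-9

    def test_axis_count_bounded_by_groups(self):
        lms, _ = synthdata.sim_landmarks(
            {"a": 10, "b": 10, "c": 10, "d": 10}, noise_sd=0.01, seed=18
        )
        res = morpho.allometry_correction(morpho.generalized_procrustes(lms))
        cva = morpho.canonical_variates(res)
        assert cva.cv_scores.shape[1] <= 3
        assert cva.percent_among_variance.sum() == pytest.approx(100.0, abs=1e-6)

    def test_unit_pooled_within_variance(self):
        lms, _ = synthdata.sim_landmarks(
            {"a": 20, "b": 20},
            shape_effects={"a": np.r_[0.02, np.zeros(23)],
                           "b": np.r_[-0.02, np.zeros(23)]},
            noise_sd=0.01,
            seed=19,
        )
        res = morpho.allometry_correction(morpho.generalized_procrustes(lms))
        cva = morpho.canonical_variates(res)
        sc = cva.cv_scores[:, 0]
        a, b = sc[res.groups == "a"], sc[res.groups == "b"]
        pooled = (
            ((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()
        ) / (len(sc) - 2)
        assert pooled == pytest.approx(1.0, rel=1e-9)

    def test_small_group_rejected_by_name(self):
        lms, _ = synthdata.sim_landmarks({"a": 5, "tiny": 1}, seed=20)
        res = morpho.allometry_correction(morpho.generalized_procrustes(lms))
        with pytest.raises(ValueError, match="tiny"):
            morpho.canonical_variates(res)


class TestProcrustesDistances:
    def test_matrix_structure_and_null_pvalue(self):
        rng = np.random.default_rng(21)
        coords = rng.normal(size=(30, 12, 2)) * 0.01 + synthdata.DEFAULT_BASE_SHAPE
        lms = lms_from_coords(coords, groups=["a", "b", "c"] * 10)
        aligned = morpho.generalized_procrustes(lms)
        dist, pval = morpho.procrustes_distances(
            aligned, permutations=400, seed=22
        )
        assert np.allclose(dist.to_numpy(), dist.to_numpy().T)
        assert np.allclose(np.diag(dist.to_numpy()), 0.0)
        assert (pval.to_numpy()[~np.eye(3, dtype=bool)] > 0.05).all()

    def test_separated_groups_are_significant(self):
        """Group offset 3× the noise sd: p < 0.05 in nearly every replicate."""
        hits = 0
        reps = 25
        for s in range(reps):
            eff = np.zeros(24)
            eff[3] = 0.03
            lms, _ = synthdata.sim_landmarks(
                {"a": 20, "b": 20},
                shape_effects={"a": eff, "b": -eff},
                noise_sd=0.01 * 2,  # per-coordinate sd; offset 3x the sd
                seed=100 + s,
            )
            aligned = morpho.generalized_procrustes(lms)
            _, pval = morpho.procrustes_distances(
                aligned, permutations=300, seed=200 + s
            )
            hits += pval.loc["a", "b"] < 0.05
        assert hits >= int(np.ceil(0.95 * reps))


class TestMeanEllipse:
    def test_isotropic_closed_form(self):
        """Isotropic sample covariance: circle of radius sqrt(5.991 σ²/n)."""
        a = 2.0
        pts = np.array([[a, 0], [-a, 0], [0, a], [0, -a]], float)
        e = morpho.mean_confidence_ellipse(pts)
        sigma2 = np.cov(pts, rowvar=False)[0, 0]
        expected = np.sqrt(chi2.ppf(0.95, 2) * sigma2 / 4)
        assert e.semi_axes == pytest.approx([expected, expected], rel=1e-9)

    def test_identical_points_are_degenerate(self):
        pts = np.ones((5, 2))
        e = morpho.mean_confidence_ellipse(pts)
        assert np.allclose(e.semi_axes, 0.0)

    def test_coverage_of_true_mean(self):
        """The 95% mean ellipse covers the true mean in ≈95% of replicates.

        The chi-square scaling is asymptotic (it ignores covariance
        estimation error, which a Hotelling-T² region would absorb), so the
        check runs at n=200 where the nominal level holds to within 2%.
        """
        rng = np.random.default_rng(23)
        n, reps = 200, 2000
        cov = np.array([[2.0, 0.7], [0.7, 1.0]])
        chol = np.linalg.cholesky(cov)
        covered = 0
        q = chi2.ppf(0.95, 2)
        for _ in range(reps):
            pts = rng.normal(size=(n, 2)) @ chol.T
            c = np.cov(pts, rowvar=False) / n
            m = pts.mean(axis=0)
            covered += float(m @ np.linalg.solve(c, m)) <= q
        assert abs(covered / reps - 0.95) < 0.02

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            morpho.mean_confidence_ellipse(np.zeros((2, 2)))


class TestSimilarityInvariance:
    def test_downstream_statistics_invariant_to_similarity_transforms(self):
        """Rotating/scaling/translating raw landmarks changes nothing."""
        eff = np.zeros(24)
        eff[5] = 0.04
        lms, _ = synthdata.sim_landmarks(
            {"a": 12, "b": 12},
            shape_effects={"a": eff, "b": -eff},
            noise_sd=0.01,
            seed=24,
        )
        # per-specimen rotation/translation plus one common scale: a common
        # scale multiplies every centroid size, which the allometry
        # regression absorbs; per-specimen scale would genuinely change the
        # size covariate and is exercised separately by the generator tests
        rng = np.random.default_rng(25)
        coords2 = np.empty_like(lms.coords)
        for i in range(lms.coords.shape[0]):
            th = rng.uniform(0, 2 * np.pi)
            R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
            coords2[i] = lms.coords[i] @ R.T * 1.7 + rng.uniform(-5, 5, 2)
        lms2 = lms_from_coords(coords2, groups=lms.groups)
        out = []
        for cur in (lms, lms2):
            aligned = morpho.generalized_procrustes(cur)
            res = morpho.allometry_correction(aligned)
            pca = morpho.shape_pca(res)
            cva = morpho.canonical_variates(res)
            dist, _ = morpho.procrustes_distances(aligned, permutations=100, seed=1)
            out.append((pca.eigenvalues, cva.eigenvalues, dist.loc["a", "b"]))
        assert np.allclose(out[0][0], out[1][0], atol=1e-8)
        assert np.allclose(out[0][1], out[1][1], atol=1e-6)
        assert out[0][2] == pytest.approx(out[1][2], abs=1e-8)
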