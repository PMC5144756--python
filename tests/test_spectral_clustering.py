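"""Nystrom embedding, k-means, fiber probabilities, outlier rejection,
and atlas construction."""

import numpy as np
import pytest
from sklearn.cluster import SpectralClustering
from sklearn.metrics import adjusted_rand_score

from tractatlas.fiber_geometry import (DistanceConfig,
                                       pairwise_distance_matrix,
                                       reflect_points, stack_resampled)
from tractatlas.spectral_clustering import (ClusterConfig, build_atlas,
                                            embed_fibers,
                                            fiber_probabilities,
                                            fit_embedding_basis,
                                            kmeans_embed, reject_outliers)
from tractatlas.synthdata import (BundleSpec, CohortSpec,
                                  default_bundle_specs, make_bundle,
                                  make_cohort, make_subject)


def _three_bundle_stack(n_per_bundle=100, n_points=15):
    """300 fibers from 3 well-separated straight bundles + labels."""
    specs = [BundleSpec("straight", 80.0, (c, 0.0, 0.0), n_fibers=n_per_bundle,
                        dispersion=2.0)
             for c in (-60.0, 0.0, 60.0)]
    fibers, labels = [], []
    for b, s in enumerate(specs):
        tract, lab = make_bundle(s, seed=b + 1, label=b)
        fibers.extend(tract.fibers)
        labels.extend(lab)
    return stack_resampled(fibers, n_points), np.asarray(labels)


class TestEmbeddingBasis:
    def test_full_sample_matches_dense_spectral_clustering(self):
        """With m = N the Nystrom pipeline must reproduce dense normalized
        spectral clustering (independent route: scikit-learn on the same
        precomputed affinity), ARI = 1.0 on a 3-bundle toy."""
        fibers, truth = _three_bundle_stack()
        cfg = ClusterConfig(k=3, nystrom_m=fibers.shape[0],
                            fibers_per_subject=1000, sigma_cluster=30.0,
                            n_eigenvectors=3, bilateral=False, seed=0)
        basis = fit_embedding_basis(fibers, cfg)
        emb = embed_fibers(basis, fibers)
        labels, _ = kmeans_embed(emb, 3, seed=0)

        D = pairwise_distance_matrix(fibers, fibers,
                                     DistanceConfig(n_points=15))
        A = np.exp(-(D ** 2) / 30.0 ** 2)
        sc = SpectralClustering(n_clusters=3, affinity="precomputed",
                                random_state=0, assign_labels="kmeans")
        dense_labels = sc.fit_predict(A)
        assert adjusted_rand_score(labels, dense_labels) == 1.0
        assert adjusted_rand_score(labels, truth) == 1.0

    def test_eigvals_nonincreasing_and_bounded(self):
        fibers, _ = _three_bundle_stack(40)
        cfg = ClusterConfig(k=3, nystrom_m=60, fibers_per_subject=1000,
                            n_eigenvectors=10, bilateral=False, seed=1)
        basis = fit_embedding_basis(fibers, cfg)
        assert np.all(np.diff(basis.eigvals) <= 1e-12)
        assert np.all(basis.eigvals <= basis.eigvals[0] + 1e-12)

    def test_two_bundles_linearly_separable_in_2d(self, two_bundles):
        tract, labels = two_bundles
        fibers = stack_resampled(tract, 15)
        cfg = ClusterConfig(k=2, nystrom_m=30, fibers_per_subject=1000,
                            n_eigenvectors=2, bilateral=False, seed=2)
        basis = fit_embedding_basis(fibers, cfg)
        emb = embed_fibers(basis, fibers)
        from sklearn.svm import LinearSVC
        clf = LinearSVC().fit(emb.coords, labels)
        assert clf.score(emb.coords, labels) == 1.0

    def test_sample_too_large_rejected(self):
        fibers, _ = _three_bundle_stack(5)
        cfg = ClusterConfig(k=2, nystrom_m=100, fibers_per_subject=10,
                            n_eigenvectors=5)
        with pytest.raises(ValueError):
            fit_embedding_basis(fibers, cfg)


class TestOutOfSampleExtension:
    def _basis(self, bilateral=False):
        fibers, _ = _three_bundle_stack(60)
        cfg = ClusterConfig(k=3, nystrom_m=90, fibers_per_subject=1000,
                            n_eigenvectors=5, bilateral=bilateral, seed=3)
        return fit_embedding_basis(fibers, cfg), fibers

    def test_sample_fiber_reproduces_fitted_coordinate(self):
        basis, _ = self._basis()
        emb = embed_fibers(basis, basis.sample_fibers)
        np.testing.assert_allclose(emb.coords,
                                   basis.sample_affinity_eigvecs, atol=1e-6)

    def test_mirror_gets_identical_coords_when_bilateral(self):
        basis, fibers = self._basis(bilateral=True)
        emb = embed_fibers(basis, fibers[:10])
        emb_m = embed_fibers(basis, reflect_points(fibers[:10]))
        np.testing.assert_allclose(emb_m.coords, emb.coords, atol=1e-6)

    def test_far_fiber_flagged_at_origin(self):
        basis, _ = self._basis()
        far = np.zeros((1, 15, 3))
        far[0, :, 0] = np.linspace(0, 80, 15)
        far[0, :, 1] = 5000.0  # >> 10 sigma from every sample
        emb = embed_fibers(basis, far)
        assert emb.low_affinity[0]
        assert np.linalg.norm(emb.coords[0]) < 1e-3


class TestKMeans:
    def test_separated_blobs_recovered(self):
        rng = np.random.default_rng(4)
        centers = np.array([[0.0, 0], [50.0, 0], [0, 50.0]])
        X = np.concatenate([c + rng.normal(scale=0.5, size=(40, 2))
                            for c in centers])
        truth = np.repeat([0, 1, 2], 40)
        from tractatlas.spectral_clustering import FiberEmbedding
        emb = FiberEmbedding(coords=X,
                             low_affinity=np.zeros(120, dtype=bool))
        labels, _ = kmeans_embed(emb, 3, seed=0)
        assert adjusted_rand_score(labels, truth) == 1.0

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(5)
        from tractatlas.spectral_clustering import FiberEmbedding
        emb = FiberEmbedding(coords=rng.normal(size=(50, 4)),
                             low_affinity=np.zeros(50, dtype=bool))
        a, _ = kmeans_embed(emb, 4, seed=7)
        b, _ = kmeans_embed(emb, 4, seed=7)
        np.testing.assert_array_equal(a, b)

    def test_k1_centroid_is_mean(self):
        from tractatlas.spectral_clustering import FiberEmbedding
        X = np.arange(12.0).reshape(6, 2)
        emb = FiberEmbedding(coords=X, low_affinity=np.zeros(6, dtype=bool))
        labels, cents = kmeans_embed(emb, 1, seed=0)
        assert set(labels) == {0}
        np.testing.assert_allclose(cents[0], X.mean(axis=0))


class TestFiberProbabilities:
    def test_identical_fibers_probability_one(self):
        f = np.tile(np.linspace(0, 80, 15)[None, :, None], (6, 1, 3))
        labels = np.zeros(6, dtype=int)
        subjects = np.array(["a", "a", "b", "b", "c", "c"])
        p, flagged = fiber_probabilities(f, labels, subjects, sigma=30.0,
                                         bilateral=False)
        np.testing.assert_allclose(p, 1.0)
        assert not flagged.any()

    def test_displaced_fiber_has_minimum_probability(self):
        rng = np.random.default_rng(6)
        base = np.linspace(0, 80, 15)[:, None] * np.array([[0, 1.0, 0]])
        fibers = np.stack([base + rng.normal(scale=1.0, size=(15, 3))
                           for _ in range(12)])
        fibers[4] += np.array([150.0, 0.0, 0.0])  # 5 sigma at sigma=30
        labels = np.zeros(12, dtype=int)
        subjects = np.array([f"s{i % 4}" for i in range(12)])
        p, _ = fiber_probabilities(fibers, labels, subjects, sigma=30.0,
                                   bilateral=False)
        assert p.argmin() == 4
        assert p[4] < p[np.arange(12) != 4].min()

    def test_single_subject_cluster_flagged_zero(self):
        f = np.tile(np.linspace(0, 80, 15)[None, :, None], (4, 1, 3))
        labels = np.zeros(4, dtype=int)
        subjects = np.array(["only"] * 4)
        p, flagged = fiber_probabilities(f, labels, subjects, sigma=30.0,
                                         leave_one_out="subject",
                                         bilateral=False)
        np.testing.assert_allclose(p, 0.0)
        assert flagged.all()


class TestRejectOutliers:
    def test_equal_probabilities_keep_everything(self):
        labels = np.zeros(10, dtype=int)
        keep, stats = reject_outliers(labels, np.full(10, 0.7), 2.0)
        assert keep.all()
        assert stats[0] == (pytest.approx(0.7), pytest.approx(0.0))

    def test_planted_low_probability_rejected(self):
        probs = np.array([0.9] * 19 + [0.1])
        labels = np.zeros(20, dtype=int)
        keep, stats = reject_outliers(labels, probs, 2.0)
        # mean 0.86, sd 0.1744 -> cutoff 0.511: only the 0.1 fiber is below
        assert keep.sum() == 19
        assert not keep[19]
        mu, sd = stats[0]
        assert mu == pytest.approx(0.86)
        assert sd == pytest.approx(np.std(probs))

    def test_infinite_threshold_keeps_all(self):
        probs = np.array([0.9, 0.1, 0.5])
        keep, _ = reject_outliers(np.zeros(3, dtype=int), probs, np.inf)
        assert keep.all()


def _atlas_cohort(seed=7, n_fibers=25, outlier_fraction=0.05):
    spec = CohortSpec(n_subjects=5, outlier_fraction=outlier_fraction,
                      seed=seed, bundles=default_bundle_specs(n_fibers))
    subjects, labels, _ = make_cohort(spec)
    for s in subjects:
        s.frame = "atlas"
    return subjects, labels


ATLAS_CFG = ClusterConfig(k=6, nystrom_m=400, fibers_per_subject=400,
                          min_fiber_length=40.0, n_eigenvectors=10, seed=3)


@pytest.fixture(scope="module")
def atlas_and_truth():
    subjects, labels = _atlas_cohort()
    atlas = build_atlas(subjects, ATLAS_CFG)
    sid_to_lab = {s.subject_id: l for s, l in zip(subjects, labels)}
    gt = np.array([sid_to_lab[sid][i] for sid, i in
                   zip(atlas.training_subjects,
                       atlas.training_fiber_indices)])
    return subjects, labels, atlas, gt


class TestBuildAtlas:
    def test_kept_fiber_ari_against_planted_bundles(self, atlas_and_truth):
        _, _, atlas, gt = atlas_and_truth
        real = gt >= 0
        ari = adjusted_rand_score(gt[real], atlas.training_labels[real])
        assert ari >= 0.95

    def test_most_planted_outliers_rejected(self, atlas_and_truth):
        subjects, labels, atlas, gt = atlas_and_truth
        planted = sum(int((l == -1).sum()) for l in labels)
        kept_outliers = int((gt == -1).sum())
        assert 1.0 - kept_outliers / planted >= 0.80

    def test_rejection_bounded_by_planted_fraction(self, atlas_and_truth):
        subjects, labels, atlas, gt = atlas_and_truth
        total = sum(len(l) for l in labels)
        rejected_frac = 1.0 - gt.shape[0] / total
        planted_frac = sum(int((l == -1).sum()) for l in labels) / total
        assert rejected_frac <= planted_frac + 0.05

    def test_every_cluster_present_in_every_subject(self, atlas_and_truth):
        _, _, atlas, _ = atlas_and_truth
        assert atlas.subject_presence.all()

    def test_default_config_records_study_parameters(self):
        cfg = ClusterConfig()
        assert cfg.k == 800
        assert cfg.nystrom_m == 2500
        assert cfg.fibers_per_subject == 10000
        assert cfg.min_fiber_length == 60.0
        assert cfg.outlier_rounds == 2
        assert cfg.outlier_threshold_sd == 2.0

    def test_same_seed_bitwise_identical_atlas(self):
        subjects, _ = _atlas_cohort(seed=42, n_fibers=10,
                                    outlier_fraction=0.0)
        cfg = ClusterConfig(k=6, nystrom_m=200, fibers_per_subject=200,
                            min_fiber_length=40.0, n_eigenvectors=8,
                            outlier_rounds=1, seed=9)
        a = build_atlas(subjects, cfg)
        b = build_atlas(subjects, cfg)
        np.testing.assert_array_equal(a.training_labels, b.training_labels)
        np.testing.assert_array_equal(a.centroids, b.centroids)

    def test_too_few_fibers_rejected(self):
        subjects, _ = _atlas_cohort(n_fibers=2, outlier_fraction=0.0)
        cfg = ClusterConfig(k=6, nystrom_m=400, fibers_per_subject=400,
                            min_fiber_length=40.0)
        with pytest.raises(ValueError):
            build_atlas(subjects, cfg)


class TestBilateralSymmetry:
    def test_mirror_twins_share_cluster(self):
        """Clustering a mirror-symmetric brain puts each fiber and its
        mirror in the same cluster for >=99% of fibers."""
        tract, labels = make_subject(default_bundle_specs(n_fibers=20),
                                     bilateral=True, seed=17)
        fibers = stack_resampled(tract, 15)
        cfg = ClusterConfig(k=6, nystrom_m=120, fibers_per_subject=1000,
                            n_eigenvectors=8, bilateral=True, seed=4)
        basis = fit_embedding_basis(fibers, cfg)
        emb = embed_fibers(basis, fibers)
        got, _ = kmeans_embed(emb, 6, seed=4)
        # fibers are laid out bundle-by-bundle: right copy then mirror copy
        agree = 0
        n = 0
        for b in range(6):
            idx = np.flatnonzero(labels == b)
            right, left = idx[:20], idx[20:]
            agree += int((got[right] == got[left]).sum())
            n += 20
        assert agree / n >= 0.99

    def test_sigma_sweep_keeps_separated_bundles_apart(self, two_bundles):
        tract, truth = two_bundles
        fibers = stack_resampled(tract, 15)
        reference = None
        for sigma in (15.0, 30.0):
            cfg = ClusterConfig(k=2, nystrom_m=60, fibers_per_subject=1000,
                                sigma_cluster=sigma, n_eigenvectors=2,
                                bilateral=False, seed=5)
            basis = fit_embedding_basis(fibers, cfg)
            emb = embed_fibers(basis, fibers)
            labels, _ = kmeans_embed(emb, 2, seed=5)
            assert adjusted_rand_score(labels, truth) == 1.0
            if reference is not None:
                assert adjusted_rand_score(labels, reference) == 1.0
            reference = labels
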