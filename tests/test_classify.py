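"""Dataset assembly, splitting rules and the SVM classification protocol."""

import numpy as np
import pytest

from ffsoct import (
    FeatureVector,
    LabeledFeatureSet,
    ReconVolume,
    assemble_dataset,
    cross_validate,
    feature_set_from_vectors,
    fit_classifier,
    project_pca,
    split_cscan,
)
from ffsoct.classify import cv_splits


def _vol(ny=8, nz=6, nx=5, source="scan"):
    rng = np.random.default_rng(abs(hash(source)) % 2**31)
    return ReconVolume(
        intensity=rng.uniform(0, 1, (nz, nx, ny)),
        depth_axis=np.arange(nz) * 3.0,
        medium_index=1.38,
        source=source,
    )


def _blob_features(n_per_class, centers, seed=0, animals=("A", "B", "C"), spread=0.3):
    """Gaussian blob feature vectors, one parent per consecutive pair."""
    rng = np.random.default_rng(seed)
    vectors = []
    for ci, (label, center) in enumerate(centers.items()):
        for i in range(n_per_class):
            f = rng.normal(center, spread)
            vectors.append(
                FeatureVector(
                    glcm_contrast=f[0],
                    glcm_correlation=f[1],
                    attenuation_mu=f[2],
                    sample_id=f"{label}-{i // 2:03d}/h{i % 2}",
                    animal_id=animals[(i // 2) % len(animals)],
                    class_label=label,
                )
            )
    return vectors


CENTERS = {
    "homogeneous": (1.0, 0.8, 2.5),
    "white_matter": (0.7, 0.9, 6.0),
    "striped": (2.5, 0.5, 2.5),
}


class TestSplitCscan:
    def test_halving_doubles_sample_count(self):
        vols = [_vol(source=f"s{i}") for i in range(53)]
        halves = [h for v in vols for h in split_cscan(v)]
        assert len(halves) == 106

    def test_floor_ceil_split_161(self):
        a, b = split_cscan(_vol(ny=161))
        assert a.intensity.shape[2] == 80
        assert b.intensity.shape[2] == 81

    def test_reassembly(self):
        v = _vol(ny=9)
        a, b = split_cscan(v)
        np.testing.assert_array_equal(
            np.concatenate([a.intensity, b.intensity], axis=2), v.intensity
        )
        assert a.source == "scan/h0" and b.source == "scan/h1"

    def test_too_narrow(self):
        with pytest.raises(ValueError):
            split_cscan(_vol(ny=1))


class TestAssembleDataset:
    def test_holdout_animals_disjoint(self):
        vectors = _blob_features(12, CENTERS)
        split = assemble_dataset(vectors, holdout_animals={"C"})
        assert set(split.train.animal_ids) & set(split.test.animal_ids) == set()

    def test_class_counts_conserved(self):
        vectors = _blob_features(12, CENTERS)
        split = assemble_dataset(vectors, holdout_animals={"B"})
        for label in CENTERS:
            n_train = np.sum(split.train.labels == label)
            n_test = np.sum(split.test.labels == label)
            assert n_train + n_test == 12

    def test_study_shaped_cohort_106_70_36(self):
        # 44 + 24 + 38 = 106 samples over three animals, one held out
        rng = np.random.default_rng(1)
        vectors = []
        plan = {
            "homogeneous": {"A": 16, "B": 14, "C": 14},
            "white_matter": {"A": 8, "B": 8, "C": 8},
            "striped": {"A": 12, "B": 12, "C": 14},
        }
        for label, per_animal in plan.items():
            i = 0
            for animal, count in per_animal.items():
                for _ in range(count // 2):
                    for h in (0, 1):
                        f = rng.normal(CENTERS[label], 0.3)
                        vectors.append(FeatureVector(
                            glcm_contrast=f[0], glcm_correlation=f[1],
                            attenuation_mu=f[2],
                            sample_id=f"{label}-{i:03d}/h{h}",
                            animal_id=animal, class_label=label))
                    i += 1
        assert len(vectors) == 106
        split = assemble_dataset(vectors, holdout_animals={"C"})
        assert split.train.n_samples == 70
        assert split.test.features.shape[0] == 36

    def test_siblings_share_animal_and_group(self):
        vectors = _blob_features(8, CENTERS)
        data = feature_set_from_vectors(vectors)
        for g in np.unique(data.group_ids):
            idx = data.group_ids == g
            assert len(set(data.animal_ids[idx])) == 1

    def test_missing_class_in_train_rejected(self):
        vectors = _blob_features(4, CENTERS, animals=("A", "B"))
        only_c = [v for v in vectors if v.class_label != "striped"] + [
            FeatureVector(
                glcm_contrast=2.5, glcm_correlation=0.5, attenuation_mu=2.5,
                sample_id="striped-000/h0", animal_id="Z", class_label="striped",
            ),
            FeatureVector(
                glcm_contrast=2.4, glcm_correlation=0.5, attenuation_mu=2.4,
                sample_id="striped-000/h1", animal_id="Z", class_label="striped",
            ),
        ]
        with pytest.raises(ValueError, match="absent from the training set"):
            assemble_dataset(only_c, holdout_animals={"Z"})


class TestClassifier:
    def test_separable_blobs_train_perfectly(self):
        vectors = _blob_features(12, CENTERS, spread=0.05)
        data = feature_set_from_vectors(vectors)
        model = fit_classifier(data, seed=0)
        assert np.mean(model.predict(data.features) == data.labels) == 1.0

    def test_sample_order_invariance(self):
        vectors = _blob_features(12, CENTERS, spread=0.1)
        data = feature_set_from_vectors(vectors)
        model = fit_classifier(data, seed=0)
        rng = np.random.default_rng(3)
        perm = rng.permutation(data.n_samples)
        shuffled = data.subset(perm)
        model2 = fit_classifier(shuffled, seed=0)
        np.testing.assert_array_equal(
            model.predict(data.features), model2.predict(data.features)
        )

    def test_zero_variance_feature_named(self):
        vectors = _blob_features(6, CENTERS)
        data = feature_set_from_vectors(vectors)
        data.features[:, 1] = 0.5
        with pytest.raises(ValueError, match="glcm_correlation"):
            fit_classifier(data)

    def test_no_leakage_from_test_set(self):
        vectors = _blob_features(12, CENTERS)
        split = assemble_dataset(vectors, holdout_animals={"C"})
        m1 = fit_classifier(split.train, seed=0)
        m2 = fit_classifier(split.train, seed=0)  # refit without ever seeing test
        for a, b in zip(
            m1.named_steps["svm"].estimators_, m2.named_steps["svm"].estimators_
        ):
            np.testing.assert_array_equal(a.coef_, b.coef_)
        np.testing.assert_allclose(
            m1.named_steps["scale"].mean_,
            split.train.features.mean(axis=0),
        )


class TestCrossValidation:
    def test_perfectly_separable_scores_100(self):
        vectors = _blob_features(12, CENTERS, spread=0.02)
        data = feature_set_from_vectors(vectors)
        mean, sd = cross_validate(data, k=5, seed=0)
        assert mean == 100.0 and sd == 0.0

    def test_deterministic_per_seed(self):
        vectors = _blob_features(12, CENTERS, spread=0.8)
        data = feature_set_from_vectors(vectors)
        assert cross_validate(data, 5, seed=3) == cross_validate(data, 5, seed=3)

    def test_siblings_never_straddle_folds(self):
        vectors = _blob_features(12, CENTERS)
        data = feature_set_from_vectors(vectors)
        for _, test_idx in cv_splits(data, 5, seed=1):
            groups_in_fold = data.group_ids[test_idx]
            for g in np.unique(groups_in_fold):
                members = np.nonzero(data.group_ids == g)[0]
                assert set(members) <= set(test_idx)

    def test_k_below_two_rejected(self):
        vectors = _blob_features(6, CENTERS)
        with pytest.raises(ValueError):
            cross_validate(feature_set_from_vectors(vectors), k=1)

    def test_monotone_effect_size_trend(self):
        # widening class separation must not lower mean CV accuracy
        means = []
        for sep in (0.0, 1.0, 3.0):
            accs = []
            for seed in range(20):
                centers = {
                    "a": (0.0, 0.0, 0.0),
                    "b": (sep, 0.0, 0.0),
                    "c": (0.0, sep, 0.0),
                }
                vectors = _blob_features(8, centers, seed=seed, spread=1.0)
                data = feature_set_from_vectors(vectors)
                accs.append(cross_validate(data, 4, seed=seed)[0])
            means.append(np.mean(accs))
        assert means[0] <= means[1] + 1e-9 <= means[2] + 1e-9


class TestPCA:
    def test_recovers_2d_uncorrelated_data(self):
        rng = np.random.default_rng(0)
        X = np.column_stack([rng.normal(0, 3, 40), rng.normal(0, 1, 40)])
        data = LabeledFeatureSet(
            features=X, labels=np.array([0, 1] * 20), animal_ids=np.arange(40)
        )
        coords, ev = project_pca(data)
        Xs = (X - X.mean(axis=0)) / X.std(axis=0, ddof=0)
        # 2D full-rank input: projection preserves the standardized geometry
        # up to rotation/sign, so all pairwise distances match
        d_in = np.linalg.norm(Xs[:, None, :] - Xs[None, :, :], axis=-1)
        d_out = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=-1)
        np.testing.assert_allclose(d_out, d_in, rtol=1e-8, atol=1e-8)

    def test_explained_fractions_valid(self):
        rng = np.random.default_rng(1)
        data = LabeledFeatureSet(
            features=rng.normal(0, 1, (30, 3)),
            labels=np.array([0, 1] * 15),
            animal_ids=np.arange(30),
        )
        _, ev = project_pca(data)
        assert 0 <= ev[1] <= ev[0] <= 1
        assert ev[0] + ev[1] <= 1 + 1e-12

    def test_top_component_matches_eigendecomposition(self):
        rng = np.random.default_rng(2)
        X = rng.normal(0, 1, (10, 3)) @ np.diag([3.0, 1.0, 0.3])
        data = LabeledFeatureSet(
            features=X, labels=np.array([0, 1] * 5), animal_ids=np.arange(10)
        )
        _, ev = project_pca(data)
        Xs = (X - X.mean(axis=0)) / X.std(axis=0, ddof=0)
        w = np.linalg.eigvalsh(np.cov(Xs, rowvar=False))[::-1]
        assert ev[0] == pytest.approx(w[0] / w.sum(), rel=1e-9)

    def test_rank_deficient_rejected(self):
        X = np.tile(np.arange(6.0)[:, None], (1, 3))  # rank 1
        data = LabeledFeatureSet(
            features=X, labels=np.array([0, 1] * 3), animal_ids=np.arange(6)
        )
        with pytest.raises(ValueError, match="rank"):
            project_pca(data)
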