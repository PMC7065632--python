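"""Three-class brain-tissue classification protocol.

Dataset assembly mirrors the ex vivo study design: every acquired C-scan
is halved along y to double the sample count (the two halves remain
"siblings" and are never separated by a split), samples are grouped into
three tissue classes, and the train/test split holds out whole animals so
test performance measures generalization across subjects.  The classifier
is a per-feature standardizer followed by a linear soft-margin SVM
(one-vs-rest, C = 1) on the three features (GLCM contrast, GLCM
correlation, attenuation coefficient); stratified grouped 10-fold
cross-validation refits the standardizer inside every fold.  PCA onto the
two dominant components is used for visualization only.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import PCA
from sklearn.model_selection import StratifiedGroupKFold, StratifiedKFold
from sklearn.multiclass import OneVsRestClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .features import FeatureVector
from .recon import ReconVolume
from .stats import LabeledFeatureSet

__all__ = [
    "DatasetSplit",
    "ClassifierReport",
    "split_cscan",
    "assemble_dataset",
    "feature_set_from_vectors",
    "fit_classifier",
    "cv_splits",
    "cross_validate",
    "plot_classification",
    "project_pca",
    "evaluate",
]

FEATURE_NAMES = ("glcm_contrast", "glcm_correlation", "attenuation_mu")


@dataclass
class DatasetSplit:
    """Animal-held-out train/test partition of a labelled feature set."""

    train: LabeledFeatureSet
    test: LabeledFeatureSet
    split_rule: str = ""

    def __post_init__(self) -> None:
        common = set(np.unique(self.train.animal_ids)) & set(
            np.unique(self.test.animal_ids)
        )
        if common:
            raise ValueError(
                f"train and test share animals {sorted(common)}; the split "
                "must hold out whole animals"
            )


@dataclass
class ClassifierReport:
    """Cross-validation and held-out-test performance of the classifier."""

    cv_mean: float  # percent
    cv_sd: float  # percent
    test_accuracy: float  # percent
    confusion: np.ndarray  # (C, C) counts, rows = true class
    classes: tuple
    pca_coords: np.ndarray | None = None
    pca_explained: tuple[float, ...] = ()
    hyperplane: dict | None = None

    def __post_init__(self) -> None:
        self.confusion = np.asarray(self.confusion)
        if not (0 <= self.test_accuracy <= 100 and 0 <= self.cv_mean <= 100):
            raise ValueError("accuracies must lie in [0, 100] percent")

    def summary(self) -> str:
        lines = [
            "Tissue classification report",
            "=" * 44,
            f"{'10-fold CV accuracy':<28}{self.cv_mean:6.1f}% +/- {self.cv_sd:.1f}%",
            f"{'Held-out test accuracy':<28}{self.test_accuracy:6.1f}%",
            "",
            "Confusion matrix (rows = true):",
        ]
        header = " " * 14 + "".join(f"{str(c)[:10]:>12}" for c in self.classes)
        lines.append(header)
        for c, row in zip(self.classes, self.confusion):
            lines.append(f"{str(c)[:12]:<14}" + "".join(f"{int(v):>12d}" for v in row))
        if self.pca_explained:
            ev = ", ".join(f"{v:.2f}" for v in self.pca_explained)
            lines.append("")
            lines.append(f"PCA explained-variance fractions: {ev}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "cv_mean_pct": self.cv_mean,
            "cv_sd_pct": self.cv_sd,
            "test_accuracy_pct": self.test_accuracy,
            "classes": [str(c) for c in self.classes],
            "confusion": self.confusion.tolist(),
            "pca_explained": list(self.pca_explained),
        }


def plot_classification(report: ClassifierReport, train: LabeledFeatureSet,
                        path: str) -> None:
    """Scatter the training samples in PCA space, colored by class.

    The linear decision boundary lives in the 3-feature space; its
    projection is indicated by shading PCA space with the class predicted
    at the back-projected feature vector of each grid point.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    coords = report.pca_coords
    if coords is None:
        raise ValueError("report carries no PCA coordinates")
    fig, ax = plt.subplots(figsize=(5, 4))
    for c in report.classes:
        m = train.labels == c
        ax.scatter(coords[m, 0], coords[m, 1], label=str(c), s=18, alpha=0.8)
    ev = report.pca_explained
    ax.set_xlabel(f"PC1 ({ev[0]:.0%} var)" if ev else "PC1")
    ax.set_ylabel(f"PC2 ({ev[1]:.0%} var)" if ev else "PC2")
    ax.legend(frameon=False, fontsize=8)
    ax.set_title("Tissue classes in PCA space")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def split_cscan(vol: ReconVolume) -> tuple[ReconVolume, ReconVolume]:
    """Split one C-scan into two half C-scans along y.

    Doubles the sample count; the halves carry provenance ``<parent>/h0``
    and ``<parent>/h1`` so that downstream splits can keep siblings
    together.
    """
    ny = vol.intensity.shape[2]
    if ny < 2:
        raise ValueError("y dimension must be >= 2 to split")
    half = ny // 2
    parent = vol.source or "cscan"
    a = ReconVolume(
        intensity=vol.intensity[:, :, :half],
        depth_axis=vol.depth_axis,
        medium_index=vol.medium_index,
        source=f"{parent}/h0",
    )
    b = ReconVolume(
        intensity=vol.intensity[:, :, half:],
        depth_axis=vol.depth_axis,
        medium_index=vol.medium_index,
        source=f"{parent}/h1",
    )
    return a, b


def _parent_id(sample_id: str) -> str:
    return sample_id.rsplit("/h", 1)[0]


def feature_set_from_vectors(
    vectors: list[FeatureVector], class_map: dict | None = None
) -> LabeledFeatureSet:
    """Stack FeatureVectors into a LabeledFeatureSet (siblings grouped).

    ``class_map`` optionally maps raw region labels (e.g. "cortex") onto
    class groups (e.g. "gray_matter"); unmapped labels pass through.
    """
    feats = np.array(
        [[v.glcm_contrast, v.glcm_correlation, v.attenuation_mu] for v in vectors]
    )
    labels = []
    for v in vectors:
        if v.class_label is None:
            raise ValueError(f"sample {v.sample_id!r} has no class label")
        lbl = v.class_label
        if class_map:
            lbl = class_map.get(lbl, lbl)
        labels.append(lbl)
    groups = np.array([_parent_id(v.sample_id) for v in vectors])
    return LabeledFeatureSet(
        features=feats,
        labels=np.array(labels),
        animal_ids=np.array([v.animal_id for v in vectors]),
        group_ids=groups,
        feature_names=FEATURE_NAMES,
    )


def assemble_dataset(
    features: list[FeatureVector],
    class_map: dict | None = None,
    holdout_animals: set | None = None,
) -> DatasetSplit:
    """Label, group and split feature vectors by held-out animal.

    Samples whose ``animal_id`` is in ``holdout_animals`` form the test
    set; the rest train.  Sibling half-C-scans share an animal so they can
    never straddle the boundary.  Raises if any class is absent from the
    training set.
    """
    data = feature_set_from_vectors(features, class_map)
    holdout = set(holdout_animals or ())
    test_mask = np.array([a in holdout for a in data.animal_ids])
    if test_mask.all():
        raise ValueError("holdout_animals covers every sample; no training data")
    train = data.subset(~test_mask)
    missing = set(np.unique(data.labels)) - set(np.unique(train.labels))
    if missing:
        raise ValueError(f"classes {sorted(missing)} absent from the training set")
    rule = f"holdout_animals={sorted(map(str, holdout))}"
    if not test_mask.any():
        # empty test set is allowed (e.g. CV-only use); keep shapes valid
        return DatasetSplit(train=train, test=_empty_like(data), split_rule=rule)
    return DatasetSplit(train=train, test=data.subset(test_mask), split_rule=rule)


def _empty_like(data: LabeledFeatureSet) -> LabeledFeatureSet:
    obj = LabeledFeatureSet.__new__(LabeledFeatureSet)
    obj.features = np.empty((0, data.features.shape[1]))
    obj.labels = np.empty(0, dtype=data.labels.dtype)
    obj.animal_ids = np.empty(0, dtype=data.animal_ids.dtype)
    obj.group_ids = None
    obj.feature_names = data.feature_names
    return obj


def _make_pipeline(seed: int | None) -> Pipeline:
    svc = SVC(kernel="linear", C=1.0, random_state=seed)
    return Pipeline(
        [("scale", StandardScaler()), ("svm", OneVsRestClassifier(svc))]
    )


def fit_classifier(train: LabeledFeatureSet, seed: int = 0) -> Pipeline:
    """Fit standardizer + linear one-vs-rest SVM (C = 1) on training data."""
    for c in train.classes:
        if np.sum(train.labels == c) < 2:
            raise ValueError(f"class {c!r} has fewer than 2 training samples")
    variances = train.features.var(axis=0)
    dead = np.nonzero(variances == 0)[0]
    if dead.size:
        names = [train.feature_names[i] for i in dead]
        raise ValueError(f"zero-variance feature(s): {names}")
    model = _make_pipeline(seed)
    model.fit(train.features, train.labels)
    return model


def cv_splits(data: LabeledFeatureSet, k: int, seed: int = 0):
    """Stratified fold indices; sibling groups never straddle a fold."""
    X, y = data.features, data.labels
    if data.group_ids is not None and len(np.unique(data.group_ids)) > k:
        splitter = StratifiedGroupKFold(n_splits=k, shuffle=True, random_state=seed)
        yield from splitter.split(X, y, groups=data.group_ids)
    else:
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        yield from splitter.split(X, y)


def cross_validate(
    data: LabeledFeatureSet, k: int = 10, seed: int = 0
) -> tuple[float, float]:
    """Stratified grouped k-fold CV accuracy, as (mean %, sd %).

    Folds are stratified by class; when the data carries sibling group ids
    the two halves of a parent C-scan always land in the same fold.  The
    standardizer is refit inside each fold, so no statistics leak from the
    held-out fold.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    X, y = data.features, data.labels
    accs = []
    for tr, te in cv_splits(data, k, seed):
        if len(te) == 0:
            raise ValueError("empty CV fold")
        model = _make_pipeline(seed)
        model.fit(X[tr], y[tr])
        accs.append(float(np.mean(model.predict(X[te]) == y[te])))
    accs = np.asarray(accs) * 100.0
    return float(accs.mean()), float(accs.std(ddof=0))


def project_pca(data: LabeledFeatureSet) -> tuple[np.ndarray, tuple[float, float]]:
    """Standardize and project onto the two dominant principal components."""
    X = data.features
    if X.shape[0] < 3:
        raise ValueError("need >= 3 samples for a 2D projection")
    if X.shape[1] < 2:
        raise ValueError("need >= 2 features for a 2D projection")
    Xs = StandardScaler().fit_transform(X)
    if np.linalg.matrix_rank(np.cov(Xs, rowvar=False)) < 2:
        raise ValueError("feature matrix has rank < 2; PCA projection undefined")
    pca = PCA(n_components=2)
    coords = pca.fit_transform(Xs)
    ev = pca.explained_variance_ratio_
    return coords, (float(ev[0]), float(ev[1]))


def evaluate(
    split: DatasetSplit, k: int = 10, seed: int = 0
) -> ClassifierReport:
    """Fit on train, cross-validate within train, score the held-out test."""
    model = fit_classifier(split.train, seed=seed)
    cv_mean, cv_sd = cross_validate(split.train, k=k, seed=seed)
    classes = tuple(np.unique(split.train.labels))
    if split.test.features.shape[0]:
        pred = model.predict(split.test.features)
        acc = float(np.mean(pred == split.test.labels)) * 100.0
        conf = np.zeros((len(classes), len(classes)), dtype=int)
        index = {c: i for i, c in enumerate(classes)}
        for t, p in zip(split.test.labels, pred):
            conf[index[t], index[p]] += 1
    else:
        acc = 0.0
        conf = np.zeros((len(classes), len(classes)), dtype=int)
    coords, ev = project_pca(split.train)
    svm = model.named_steps["svm"]
    hyper = {
        "coef": np.vstack([e.coef_ for e in svm.estimators_]).tolist(),
        "intercept": np.concatenate(
            [e.intercept_ for e in svm.estimators_]
        ).tolist(),
    }
    return ClassifierReport(
        cv_mean=cv_mean,
        cv_sd=cv_sd,
        test_accuracy=acc,
        confusion=conf,
        classes=classes,
        pca_coords=coords,
        pca_explained=ev,
        hyperplane=hyper,
    )
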