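"""Statistical instruments: rank tests, class separability, repeatability.

Class separability of labelled feature clusters is measured as the ratio
J = S_B / S_W of between- to within-class scatter,

    S_W = sum_i sum_{x in D_i} (x - mu_i)(x - mu_i)^T
    S_B = sum_i N_i (mu_i - mu)(mu_i - mu)^T

(scalar features divide directly; vector features use the trace ratio).
A larger J means the class clusters sit further apart relative to their
internal spread.  Group differences on single features are tested with
the two-sided Mann-Whitney U test, and scan-to-scan repeatability of
reconstructed images with the structural similarity index (SSIM).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps
from skimage.metrics import structural_similarity

__all__ = [
    "LabeledFeatureSet",
    "SeparabilityResult",
    "mann_whitney_u",
    "separability_J",
    "ssim",
]


@dataclass
class LabeledFeatureSet:
    """Feature matrix with class labels and per-sample animal identity.

    ``features`` is (n_samples, n_features) (a 1D array is treated as a
    single feature); ``group_ids`` optionally tags samples that must stay
    together in any split (e.g. the two halves of one parent C-scan).
    """

    features: np.ndarray
    labels: np.ndarray
    animal_ids: np.ndarray
    group_ids: np.ndarray | None = None
    feature_names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.features = np.atleast_2d(np.asarray(self.features, dtype=float))
        if self.features.shape[0] == 1 and len(np.asarray(self.labels)) > 1:
            self.features = self.features.T
        self.labels = np.asarray(self.labels)
        self.animal_ids = np.asarray(self.animal_ids)
        n = self.features.shape[0]
        if len(self.labels) != n or len(self.animal_ids) != n:
            raise ValueError("features, labels and animal_ids must have equal length")
        if self.group_ids is not None:
            self.group_ids = np.asarray(self.group_ids)
            if len(self.group_ids) != n:
                raise ValueError("group_ids length mismatch")
        classes = np.unique(self.labels)
        if len(classes) < 2:
            raise ValueError("need at least 2 classes")
        if not self.feature_names:
            self.feature_names = tuple(
                f"f{i}" for i in range(self.features.shape[1])
            )

    @property
    def n_samples(self) -> int:
        return self.features.shape[0]

    @property
    def classes(self) -> np.ndarray:
        return np.unique(self.labels)

    def feature_column(self, feature: int | str) -> np.ndarray:
        if isinstance(feature, str):
            feature = self.feature_names.index(feature)
        return self.features[:, feature]

    def subset(self, mask: np.ndarray) -> "LabeledFeatureSet":
        return LabeledFeatureSet(
            features=self.features[mask],
            labels=self.labels[mask],
            animal_ids=self.animal_ids[mask],
            group_ids=None if self.group_ids is None else self.group_ids[mask],
            feature_names=self.feature_names,
        )


@dataclass(frozen=True)
class SeparabilityResult:
    """Scatter-matrix separability: J = S_B / S_W (trace ratio for vectors)."""

    J: float
    S_W: np.ndarray | float
    S_B: np.ndarray | float


def mann_whitney_u(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test; returns (U of x, p).

    The exact null distribution is enumerated when the pooled sample is
    small (n_x + n_y <= 12) and tie-free; otherwise the normal
    approximation with tie and continuity corrections is used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < len(pooled)
    if x.size + y.size <= 12 and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = sps.mannwhitneyu(
        x, y, alternative="two-sided", method=method, use_continuity=True
    )
    return float(res.statistic), float(res.pvalue)


def separability_J(
    data: LabeledFeatureSet, feature: int | str | None = None
) -> SeparabilityResult:
    """Between- to within-class scatter ratio of one feature (or all).

    With ``feature`` given, x is scalar and J = S_B / S_W directly; with
    ``feature=None`` the full scatter matrices are formed and J is the
    trace ratio trace(S_B)/trace(S_W).  A degenerate within-class scatter
    of zero yields J = +inf (perfectly separated point classes) and a
    fully degenerate S_W = S_B = 0 raises.
    """
    if feature is not None:
        X = data.feature_column(feature)[:, None]
    else:
        X = data.features
    labels = data.labels
    classes = np.unique(labels)
    for c in classes:
        if np.sum(labels == c) < 2:
            raise ValueError(f"class {c!r} has fewer than 2 samples")
    mu = X.mean(axis=0)
    p = X.shape[1]
    S_W = np.zeros((p, p))
    S_B = np.zeros((p, p))
    for c in classes:
        Xc = X[labels == c]
        mu_c = Xc.mean(axis=0)
        d = Xc - mu_c
        S_W += d.T @ d
        dm = (mu_c - mu)[:, None]
        S_B += Xc.shape[0] * (dm @ dm.T)
    tw, tb = float(np.trace(S_W)), float(np.trace(S_B))
    if tw == 0 and tb == 0:
        raise ValueError("all samples identical: separability undefined")
    J = float("inf") if tw == 0 else tb / tw
    if p == 1:
        return SeparabilityResult(J=J, S_W=tw, S_B=tb)
    return SeparabilityResult(J=J, S_W=S_W, S_B=S_B)


def ssim(a: np.ndarray, b: np.ndarray) -> float:
    """Mean structural similarity of two images, in [-1, 1].

    Gaussian-weighted 11x11 local windows (sigma = 1.5) with stabilizers
    K1 = 0.01, K2 = 0.03 on the joint dynamic range of the pair; identical
    images score 1.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"image shapes differ: {a.shape} vs {b.shape}")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("images must be finite")
    lo = min(a.min(), b.min())
    hi = max(a.max(), b.max())
    data_range = hi - lo
    if data_range == 0:
        return 1.0
    win = min(11, min(a.shape))
    if win % 2 == 0:
        win -= 1
    if win < 3:
        raise ValueError("images too small for SSIM (need >= 3 pixels per side)")
    return float(
        structural_similarity(
            a,
            b,
            gaussian_weights=True,
            sigma=1.5,
            win_size=win,
            use_sample_covariance=False,
            K1=0.01,
            K2=0.03,
            data_range=data_range,
        )
    )
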