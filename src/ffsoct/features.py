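"""Texture and attenuation features for tissue discrimination.

The texture pathway collapses a volume by maximum intensity projection
along y, max-pools the (depth x transverse) image onto a coarse 25 x 5
grid to concentrate sparse bright features, quantizes to a small number of
gray levels and computes symmetric normalized gray-level co-occurrence
matrices (GLCM) at distance 1 along 0/45/90/135 degrees.  The four
Haralick-style properties (contrast, energy, correlation, homogeneity)
are averaged over the four directions to damp rotational variance.

The optical pathway fits the exponential decay of the depth profile:
mean linear intensity per depth bin, ordinary least squares of its log
against depth, attenuation coefficient mu = -slope in mm^-1.  Myelinated
white matter scatters more strongly and shows markedly higher mu than
gray matter.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps
from skimage.feature import graycomatrix

from .recon import ReconVolume, max_intensity_projection

__all__ = [
    "GLCMProperties",
    "AttenuationEstimate",
    "FeatureVector",
    "FeatureConfig",
    "max_pool",
    "quantize_gray",
    "glcm",
    "glcm_properties",
    "estimate_attenuation",
    "build_feature_vector",
    "GLCM_ANGLES_DEG",
]

GLCM_ANGLES_DEG = (0, 45, 90, 135)
_ANGLE_RAD = {0: 0.0, 45: np.pi / 4, 90: np.pi / 2, 135: 3 * np.pi / 4}


@dataclass(frozen=True)
class GLCMProperties:
    """Direction-averaged co-occurrence properties."""

    contrast: float
    energy: float
    correlation: float
    homogeneity: float


@dataclass(frozen=True)
class AttenuationEstimate:
    """Single-exponential intensity-decay fit I(z) ~ exp(-mu*z)."""

    mu: float  # mm^-1
    fit_window: tuple[float, float]  # um
    r_squared: float


@dataclass
class FeatureVector:
    """The per-sample classification features with provenance."""

    glcm_contrast: float
    glcm_correlation: float
    attenuation_mu: float
    sample_id: str
    animal_id: str
    class_label: str | None = None
    glcm_energy: float = np.nan
    glcm_homogeneity: float = np.nan
    attenuation_r2: float = np.nan

    def __post_init__(self) -> None:
        for name in ("glcm_contrast", "glcm_correlation", "attenuation_mu"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"feature {name} is not finite")


@dataclass
class FeatureConfig:
    """Knobs of the feature-extraction flow.

    The pooled grid is 25 cells along depth by 5 across the transverse
    axis; 8 gray levels keep the co-occurrence matrix well populated for a
    125-pixel pooled image.  ``depth_range_um`` restricts the texture MIP
    to the usable depth of field; ``fit_window_um`` is the attenuation fit
    interval, skipping the first 10% of the 400 um depth of field where
    surface artifacts dominate.
    """

    pool_grid: tuple[int, int] = (25, 5)
    levels: int = 8
    distance: int = 1
    depth_range_um: tuple[float, float] = (0.0, 450.0)
    fit_window_um: tuple[float, float] = (40.0, 380.0)
    floor_from_um: float | None = 500.0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["schema_version"] = 1
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "FeatureConfig":
        d = {k: v for k, v in d.items() if k != "schema_version"}
        for key in ("pool_grid", "depth_range_um", "fit_window_um"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


def max_pool(image: np.ndarray, grid: tuple[int, int] = (25, 5)) -> np.ndarray:
    """Max-pool an image onto a (rows, cols) grid of near-equal tiles."""
    image = np.asarray(image)
    rows, cols = grid
    if rows < 1 or cols < 1:
        raise ValueError("grid dimensions must be >= 1")
    if rows > image.shape[0] or cols > image.shape[1]:
        raise ValueError(
            f"grid {grid} larger than image {image.shape}"
        )
    r_edges = np.linspace(0, image.shape[0], rows + 1).round().astype(int)
    c_edges = np.linspace(0, image.shape[1], cols + 1).round().astype(int)
    out = np.empty((rows, cols), dtype=image.dtype)
    for i in range(rows):
        for j in range(cols):
            tile = image[r_edges[i]:r_edges[i + 1], c_edges[j]:c_edges[j + 1]]
            out[i, j] = tile.max()
    return out


def quantize_gray(image: np.ndarray, levels: int = 8) -> np.ndarray:
    """Min-max quantize to integers 0..levels-1 (constant image -> 0).

    The binning is floor((x - min)/(max - min) * levels) clipped to
    levels-1, so a value exactly halfway lands in the upper bin.
    """
    image = np.asarray(image, dtype=float)
    if levels < 2:
        raise ValueError("levels must be >= 2")
    if not np.all(np.isfinite(image)):
        raise ValueError("image contains non-finite pixels")
    lo, hi = image.min(), image.max()
    if hi == lo:
        return np.zeros(image.shape, dtype=np.uint8)
    q = np.floor((image - lo) / (hi - lo) * levels).astype(int)
    return np.clip(q, 0, levels - 1).astype(np.uint8)


def glcm(
    image: np.ndarray,
    distance: int = 1,
    angle: int = 0,
    levels: int = 8,
) -> np.ndarray:
    """Symmetric, normalized gray-level co-occurrence matrix.

    ``angle`` is in degrees, one of 0, 45, 90, 135; at distance d the pixel
    offsets are (0, d), (d, d), (-d, 0), (d, -d) in (row, col).  Since the
    matrix is symmetric (pairs counted in both directions) each diagonal
    direction and its reverse are equivalent; entries sum to 1.
    """
    image = np.asarray(image)
    if angle not in _ANGLE_RAD:
        raise ValueError("angle must be one of 0, 45, 90, 135 degrees")
    if distance < 1:
        raise ValueError("distance must be >= 1")
    if image.shape[0] <= distance and image.shape[1] <= distance:
        raise ValueError("image smaller than the co-occurrence offset")
    if image.min() < 0 or image.max() >= levels:
        raise ValueError("image values must lie in [0, levels)")
    mat = graycomatrix(
        image.astype(np.uint8),
        distances=[distance],
        angles=[_ANGLE_RAD[angle]],
        levels=levels,
        symmetric=True,
        normed=True,
    )[:, :, 0, 0]
    return mat


def glcm_properties(matrices: list[np.ndarray] | np.ndarray) -> GLCMProperties:
    """Average contrast/energy/correlation/homogeneity over directions.

    Per normalized matrix P:
      contrast    = sum_ij P(i,j) (i-j)^2
      energy      = sum_ij P(i,j)^2
      homogeneity = sum_ij P(i,j) / (1 + |i-j|)
      correlation = sum_ij (i-mu_i)(j-mu_j) P(i,j) / (sigma_i sigma_j)
    with marginal means/SDs of P; a constant image (zero marginal SD) gets
    correlation 0 by convention.
    """
    matrices = [np.asarray(m, dtype=float) for m in matrices]
    props = np.zeros((len(matrices), 4))
    for idx, P in enumerate(matrices):
        if P.ndim != 2 or P.shape[0] != P.shape[1]:
            raise ValueError("each GLCM must be a square matrix")
        if not np.isclose(P.sum(), 1.0, atol=1e-8):
            raise ValueError("GLCM is not normalized (entries must sum to 1)")
        L = P.shape[0]
        i, j = np.meshgrid(np.arange(L), np.arange(L), indexing="ij")
        contrast = float((P * (i - j) ** 2).sum())
        energy = float((P**2).sum())
        homogeneity = float((P / (1.0 + np.abs(i - j))).sum())
        pi = P.sum(axis=1)
        pj = P.sum(axis=0)
        mi = float((np.arange(L) * pi).sum())
        mj = float((np.arange(L) * pj).sum())
        si = float(np.sqrt(((np.arange(L) - mi) ** 2 * pi).sum()))
        sj = float(np.sqrt(((np.arange(L) - mj) ** 2 * pj).sum()))
        if si > 0 and sj > 0:
            correlation = float(((i - mi) * (j - mj) * P).sum() / (si * sj))
        else:
            correlation = 0.0
        props[idx] = (contrast, energy, correlation, homogeneity)
    mean = props.mean(axis=0)
    return GLCMProperties(
        contrast=float(mean[0]),
        energy=float(mean[1]),
        correlation=float(mean[2]),
        homogeneity=float(mean[3]),
    )


def estimate_attenuation(
    vol: ReconVolume,
    fit_window: tuple[float, float] = (40.0, 380.0),
    floor_from_um: float | None = None,
) -> AttenuationEstimate:
    """Attenuation coefficient from the axial intensity-decay slope.

    The mean backscattered power (squared reconstructed magnitude) over
    (x, y) is computed per depth bin; an ordinary least-squares line is
    fitted to its natural log against depth over ``fit_window`` (um).  The
    single-exponential decay model I(z) ~ exp(-mu*z) on the sample
    intensity appears as exp(-2*mu*z) in the power profile, so
    mu = -slope/2, reported in mm^-1.  Fitting in the power domain makes
    the detection noise exactly additive per bin, which is what lets the
    noise floor be subtracted without bias.

    ``floor_from_um`` optionally enables noise-floor subtraction: the mean
    power of all bins deeper than this depth (which must lie beyond the
    structure of interest) is taken as the additive background of the
    detector and subtracted before the log fit.  Without it the flat floor
    biases the slope of strongly attenuating samples towards zero.
    """
    lo, hi = fit_window
    mask = (vol.depth_axis >= lo) & (vol.depth_axis <= hi)
    if mask.sum() < 5:
        raise ValueError(
            f"fit window {fit_window} um contains {int(mask.sum())} depth bins; need >= 5"
        )
    z_mm = vol.depth_axis[mask] * 1e-3
    power = np.square(vol.intensity)
    mean_p = power[mask].mean(axis=(1, 2))
    if floor_from_um is not None:
        deep = vol.depth_axis > floor_from_um
        if not np.any(deep):
            raise ValueError(
                f"no depth bins beyond floor_from_um={floor_from_um} um"
            )
        mean_p = mean_p - power[deep].mean()
    if np.any(mean_p <= 0):
        raise ValueError("nonpositive mean intensity in fit window; log undefined")
    fit = sps.linregress(z_mm, np.log(mean_p))
    return AttenuationEstimate(
        mu=float(-fit.slope / 2.0),
        fit_window=(float(lo), float(hi)),
        r_squared=float(fit.rvalue**2),
    )


def texture_image(vol: ReconVolume, cfg: FeatureConfig) -> np.ndarray:
    """The depth-limited (z, x) MIP image feeding the GLCM flow."""
    lo, hi = cfg.depth_range_um
    keep = np.nonzero((vol.depth_axis >= lo) & (vol.depth_axis <= hi))[0]
    if keep.size == 0:
        raise ValueError("depth_range_um selects no depth bins")
    sub = ReconVolume(
        intensity=vol.intensity[keep],
        depth_axis=vol.depth_axis[keep],
        medium_index=vol.medium_index,
        source=vol.source,
    )
    return max_intensity_projection(sub, axis="y")


def build_feature_vector(
    vol: ReconVolume,
    cfg: FeatureConfig | None = None,
    sample_id: str = "",
    animal_id: str = "",
    class_label: str | None = None,
) -> FeatureVector:
    """Run the full flow MIP -> max-pool -> quantize -> GLCM + attenuation."""
    if cfg is None:
        cfg = FeatureConfig()
    mip = texture_image(vol, cfg)
    pooled = max_pool(mip, cfg.pool_grid)
    quant = quantize_gray(pooled, cfg.levels)
    mats = [glcm(quant, cfg.distance, a, cfg.levels) for a in GLCM_ANGLES_DEG]
    props = glcm_properties(mats)
    att = estimate_attenuation(vol, cfg.fit_window_um, cfg.floor_from_um)
    return FeatureVector(
        glcm_contrast=props.contrast,
        glcm_correlation=props.correlation,
        attenuation_mu=att.mu,
        sample_id=sample_id or vol.source,
        animal_id=animal_id,
        class_label=class_label,
        glcm_energy=props.energy,
        glcm_homogeneity=props.homogeneity,
        attenuation_r2=att.r_squared,
    )
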