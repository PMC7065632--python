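"""Fourier-domain depth reconstruction of swept-source interference stacks.

Depth is encoded in the fringe frequency of each pixel's intensity trace
across the wavelength sweep.  Reconstruction per pixel: remove the DC
(sweep-mean) background, resample the uniformly-stepped-in-wavelength trace
onto a uniform wavenumber grid k = 2*pi*n/lambda, apply a window, Fourier
transform, and keep the positive-frequency magnitudes.  A fringe
cos(2*k*z) lands in bin j at depth z_j = pi*j / (N_fft * dk), equivalently
z_j ~= j * lambda_c^2 / (2 * n * dlambda_total * pad); the maximum
unambiguous depth is lambda_c^2 / (4 * n * lambda_step).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline

from .phantom import SweepStack

__all__ = [
    "ReconConfig",
    "ReconVolume",
    "reconstruct_volume",
    "max_intensity_projection",
    "extract_bscan",
]


@dataclass
class ReconConfig:
    """Reconstruction options.

    window
        Spectral window applied before the FFT ("hann" or "none"); Hann is
        the default to suppress sidelobes that would leak texture into the
        co-occurrence features.
    dc_removal
        "mean_subtract" removes the per-pixel sweep mean (the reference and
        self-term background); "none" keeps it.
    zero_pad_factor
        Integer >= 1; pads the spectrum, refining the depth sampling.
    medium_index
        Refractive index used for the wavenumber axis and depth calibration.
    k_resample
        "cubic" resamples the uniform-wavelength samples onto a uniform
        wavenumber grid (same endpoints); "none" pretends the lambda grid is
        already uniform in k (only sensible for toy sweeps).
    crop_depth_um
        Drop leading depth bins shallower than this (e.g. surface residue
        on the probe facet); the depth axis keeps absolute depths.
    """

    window: str = "hann"
    dc_removal: str = "mean_subtract"
    zero_pad_factor: int = 2
    medium_index: float = 1.33
    k_resample: str = "cubic"
    crop_depth_um: float = 0.0

    def __post_init__(self) -> None:
        if self.window not in ("hann", "none"):
            raise ValueError("window must be 'hann' or 'none'")
        if self.dc_removal not in ("mean_subtract", "none"):
            raise ValueError("dc_removal must be 'mean_subtract' or 'none'")
        if self.k_resample not in ("cubic", "none"):
            raise ValueError("k_resample must be 'cubic' or 'none'")
        if int(self.zero_pad_factor) != self.zero_pad_factor or self.zero_pad_factor < 1:
            raise ValueError("zero_pad_factor must be an integer >= 1")
        if self.medium_index < 1:
            raise ValueError("medium_index must be >= 1")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["schema_version"] = 1
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ReconConfig":
        return cls(**{k: v for k, v in d.items() if k != "schema_version"})


@dataclass
class ReconVolume:
    """Depth-resolved linear-magnitude volume (z, x, y).

    ``depth_axis`` gives the physical depth (um, in the medium) of every
    z bin; it starts at zero unless a leading crop was applied.  Magnitude
    (not log) is stored so that downstream attenuation fitting sees linear
    intensity; log scaling is a display/feature-time concern.
    """

    intensity: np.ndarray
    depth_axis: np.ndarray
    medium_index: float
    source: str = ""

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity)
        self.depth_axis = np.asarray(self.depth_axis, dtype=float)
        if self.intensity.ndim != 3:
            raise ValueError("intensity must be 3D (z, x, y)")
        if len(self.depth_axis) != self.intensity.shape[0]:
            raise ValueError("depth_axis length must equal the z dimension")
        if np.any(np.diff(self.depth_axis) <= 0):
            raise ValueError("depth_axis must be strictly increasing")
        if np.any(self.intensity < 0):
            raise ValueError("intensity must be >= 0")

    @property
    def depth_bin_um(self) -> float:
        return float(self.depth_axis[1] - self.depth_axis[0])


def reconstruct_volume(stack: SweepStack, cfg: ReconConfig | None = None) -> ReconVolume:
    """Reconstruct a depth-calibrated volume from a raw sweep stack."""
    if cfg is None:
        cfg = ReconConfig()
    frames = np.asarray(stack.frames, dtype=float)
    n_frames = frames.shape[0]
    if n_frames < 2:
        raise ValueError("need at least 2 frames to reconstruct depth")
    lambdas_um = np.asarray(stack.sweep.wavelengths_nm, dtype=float) * 1e-3
    if np.any(np.diff(lambdas_um) <= 0):
        raise ValueError("wavelength axis must be strictly increasing")

    sig = frames.reshape(n_frames, -1)
    if cfg.dc_removal == "mean_subtract":
        sig = sig - sig.mean(axis=0, keepdims=True)

    k = 2.0 * np.pi * cfg.medium_index / lambdas_um  # decreasing in lambda
    if cfg.k_resample == "cubic":
        # flip to increasing k, then resample onto a uniform grid with the
        # same endpoints (uniform-in-lambda stepping is nonuniform in k)
        k_inc = k[::-1]
        sig_inc = sig[::-1]
        k_uniform = np.linspace(k_inc[0], k_inc[-1], n_frames)
        sig = CubicSpline(k_inc, sig_inc, axis=0)(k_uniform)
        dk = (k_inc[-1] - k_inc[0]) / (n_frames - 1)
    else:
        # treat samples as uniform in k with the true endpoints
        dk = abs(k[-1] - k[0]) / (n_frames - 1)

    if cfg.window == "hann":
        sig = sig * np.hanning(n_frames)[:, None]

    n_fft = n_frames * int(cfg.zero_pad_factor)
    spec = np.fft.rfft(sig, n=n_fft, axis=0)
    mag = np.abs(spec)
    # fringe cos(2*k*z) has frequency z/pi cycles per unit k
    depth_axis = np.pi * np.arange(mag.shape[0]) / (n_fft * dk)

    if cfg.crop_depth_um > 0:
        keep = depth_axis >= cfg.crop_depth_um
        if not np.any(keep):
            raise ValueError("crop_depth_um removes every depth bin")
        mag = mag[keep]
        depth_axis = depth_axis[keep]

    nz = mag.shape[0]
    vol = mag.reshape(nz, frames.shape[1], frames.shape[2])
    return ReconVolume(
        intensity=vol,
        depth_axis=depth_axis,
        medium_index=cfg.medium_index,
        source=stack.provenance,
    )


_AXES = {"z": 0, "x": 1, "y": 2}


def max_intensity_projection(
    vol: ReconVolume,
    axis: str = "y",
    frame_range: tuple[int, int] | None = None,
) -> np.ndarray:
    """Maximum intensity projection along one axis over a frame range.

    ``frame_range`` is a half-open (start, stop) index interval along the
    projection axis; ``None`` projects over the full extent.  Projecting
    along y collapses a volume into the (z, x) image used for texture
    feature extraction.
    """
    if axis not in _AXES:
        raise ValueError("axis must be one of 'z', 'x', 'y'")
    ax = _AXES[axis]
    n = vol.intensity.shape[ax]
    if frame_range is None:
        frame_range = (0, n)
    start, stop = frame_range
    if not (0 <= start < stop <= n):
        raise ValueError(f"frame_range {frame_range} invalid for axis of size {n}")
    sl = [slice(None)] * 3
    sl[ax] = slice(start, stop)
    return vol.intensity[tuple(sl)].max(axis=ax)


def extract_bscan(vol: ReconVolume, y_index: int) -> np.ndarray:
    """The (z, x) cross-sectional slice at one y position."""
    ny = vol.intensity.shape[2]
    if not 0 <= y_index < ny:
        raise IndexError(f"y_index {y_index} out of range [0, {ny})")
    return vol.intensity[:, :, y_index]
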