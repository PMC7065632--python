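"""Phantom scenes and full-field swept-source interference simulation.

A scene is a set of discrete backscatterers embedded in a homogeneous
medium.  For every wavelength of a tunable-laser sweep the camera records
the interference of the reference field (the distal endoscope-facet
reflection of a common-path interferometer) with the field backscattered
from every reflector:

    I_img(x, y; lambda) = | E_ref + sum_i E_i(x, y) |^2
    E_i(x, y) = sqrt(I_samp_i(x, y)) * exp(i * 2 * k * z_i),   k = 2*pi*n/lambda

which expands into the reference term, the sample self-terms, the
reference-sample fringes 2*sqrt(I_ref*I_samp_i)*cos(2k(z_i - z_ref)) and all
sample-sample cross fringes.  I_samp_i is the single-scattering round-trip
(Beer-Lambert) intensity reflectivity_i * exp(-2*mu*z_i), spread over the
camera via a Gaussian transverse point-spread function.

Three synthetic tissue classes emulate the qualitative ex vivo signatures
of rat brain regions: a homogeneous speckle field (cortex/hippocampus-like),
a strongly attenuating homogeneous field (corpus-callosum-like white matter)
and a field with dark axially-oriented stripes (striatum/thalamus-like).
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import sparse

__all__ = [
    "Scatterer",
    "PhantomScene",
    "SweepConfig",
    "NoiseConfig",
    "SweepStack",
    "AliasingError",
    "make_bead_phantom",
    "make_tissue_scene",
    "simulate_sweep",
    "TISSUE_CLASSES",
    "BEAD_INDEX",
    "GEL_INDEX",
]

#: Refractive indices of the bead-phantom constituents: borosilicate-type
#: high-index glass beads suspended in aqueous agarose gel.
BEAD_INDEX = 1.95
GEL_INDEX = 1.33

TISSUE_CLASSES = ("homogeneous", "white_matter", "striped")


class AliasingError(ValueError):
    """Scene extends beyond the maximum unambiguous (aliasing) depth."""


@dataclass(frozen=True)
class Scatterer:
    """A point backscatterer.

    Positions are object-space micrometres; ``z`` is optical depth below the
    reference surface.  ``reflectivity`` is the dimensionless backscattered
    intensity fraction at the reflector itself (before attenuation).
    """

    x: float
    y: float
    z: float
    reflectivity: float

    def __post_init__(self) -> None:
        if self.z < 0:
            raise ValueError(f"scatterer depth must be >= 0, got {self.z}")
        if not 0 < self.reflectivity <= 1:
            raise ValueError(
                f"reflectivity must lie in (0, 1], got {self.reflectivity}"
            )


@dataclass
class PhantomScene:
    """A collection of scatterers in a homogeneous attenuating medium.

    Parameters
    ----------
    scatterers
        Point reflectors inside ``bounds``.
    medium_index
        Refractive index n of the embedding medium (>= 1).
    attenuation_mu
        Bulk intensity attenuation coefficient in mm^-1 (Beer-Lambert,
        round trip applied as exp(-2*mu*z)).
    bounds
        (x, y, z) extents in micrometres; scatterers live in
        [0, bx] x [0, by] x [0, bz].
    class_label
        Optional tissue-class tag.
    """

    scatterers: list[Scatterer]
    medium_index: float = GEL_INDEX
    attenuation_mu: float = 0.0
    bounds: tuple[float, float, float] = (450.0, 450.0, 450.0)
    class_label: str | None = None
    scene_id: str | None = None

    def __post_init__(self) -> None:
        if self.medium_index < 1:
            raise ValueError("medium_index must be >= 1")
        if self.attenuation_mu < 0:
            raise ValueError("attenuation_mu must be >= 0")
        bx, by, bz = self.bounds
        for s in self.scatterers:
            if not (0 <= s.x <= bx and 0 <= s.y <= by and 0 <= s.z <= bz):
                raise ValueError(
                    f"scatterer at ({s.x}, {s.y}, {s.z}) outside bounds {self.bounds}"
                )

    @property
    def depth_extent(self) -> float:
        """Largest scatterer depth (um); 0 for an empty scene."""
        if not self.scatterers:
            return 0.0
        return max(s.z for s in self.scatterers)

    def to_dict(self) -> dict:
        return {
            "schema_version": 1,
            "medium_index": self.medium_index,
            "attenuation_mu": self.attenuation_mu,
            "bounds": list(self.bounds),
            "class_label": self.class_label,
            "scene_id": self.scene_id,
            "scatterers": [
                [s.x, s.y, s.z, s.reflectivity] for s in self.scatterers
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PhantomScene":
        return cls(
            scatterers=[Scatterer(*row) for row in d["scatterers"]],
            medium_index=d["medium_index"],
            attenuation_mu=d["attenuation_mu"],
            bounds=tuple(d["bounds"]),
            class_label=d.get("class_label"),
            scene_id=d.get("scene_id"),
        )


@dataclass
class SweepConfig:
    """Wavelength-sweep and camera geometry.

    Defaults follow the instrument: a tunable laser stepped uniformly from
    1260 to 1345 nm.  The full-resolution step of 0.042 nm yields 2024
    frames; the scaled-down default below keeps the same span with 256
    frames for desk-scale simulation.  ``pixel_pitch`` is the object-space
    sampling of the camera (um/pixel); ``counts_scale`` converts the
    dimensionless interference intensity to camera counts.
    """

    lambda_start: float = 1260.0
    lambda_end: float = 1345.0
    lambda_step: float = 85.0 / 255.0
    n_pixels_x: int = 64
    n_pixels_y: int = 64
    pixel_pitch: float = 7.0
    reference_reflectivity: float = 0.2
    reference_depth: float = 0.0
    counts_scale: float = 20000.0
    psf_sigma: float = 4.0

    def __post_init__(self) -> None:
        if not self.lambda_start < self.lambda_end:
            raise ValueError("lambda_start must be < lambda_end")
        if self.lambda_step <= 0:
            raise ValueError("lambda_step must be > 0")
        if self.n_frames < 2:
            raise ValueError("sweep must contain at least 2 frames")

    @property
    def n_frames(self) -> int:
        return int(math.floor(
            (self.lambda_end - self.lambda_start) / self.lambda_step + 1e-9
        )) + 1

    @property
    def wavelengths_nm(self) -> np.ndarray:
        return self.lambda_start + self.lambda_step * np.arange(self.n_frames)

    @property
    def lambda_center(self) -> float:
        return 0.5 * (self.lambda_start + self.lambda_end)

    def aliasing_depth_um(self, medium_index: float) -> float:
        """Maximum unambiguous depth lambda_c^2 / (4 n dlambda), in um."""
        lc_nm = self.lambda_center
        return lc_nm**2 / (4.0 * medium_index * self.lambda_step) * 1e-3

    @classmethod
    def full_scale(cls, **overrides) -> "SweepConfig":
        """The instrument-scale sweep: 0.042 nm step (2024 frames), 320x256."""
        base = dict(lambda_step=0.042, n_pixels_x=320, n_pixels_y=256,
                    pixel_pitch=450.0 / 320.0)
        base.update(overrides)
        return cls(**base)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["schema_version"] = 1
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SweepConfig":
        d = {k: v for k, v in d.items() if k != "schema_version"}
        return cls(**d)


@dataclass
class NoiseConfig:
    """Camera/acquisition noise model.

    Noise is applied after the interference physics, in fixed order:
    Poisson shot noise on the counts, additive Gaussian read noise, then
    clipping and quantization to ``bit_depth`` bits.  ``motion_blur_sd``
    adds a random rigid jitter of the whole sample per frame (um), the
    dominant degradation of in vivo acquisition where cerebrospinal-fluid
    pulsation and respiration move the tissue between frames.
    """

    shot_noise: bool = True
    read_noise_sd: float = 2.0
    bit_depth: int = 16
    motion_blur_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.read_noise_sd < 0:
            raise ValueError("read_noise_sd must be >= 0")
        if not 8 <= self.bit_depth <= 16:
            raise ValueError("bit_depth must lie in [8, 16]")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["schema_version"] = 1
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "NoiseConfig":
        return cls(**{k: v for k, v in d.items() if k != "schema_version"})


@dataclass
class SweepStack:
    """Raw interference frames, one per wavelength: (wavelength, x, y)."""

    frames: np.ndarray
    sweep: SweepConfig
    provenance: str = ""

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError("frames must be 3D (wavelength, x, y)")
        if self.frames.shape[0] != self.sweep.n_frames:
            raise ValueError(
                f"frame count {self.frames.shape[0]} does not match sweep "
                f"config ({self.sweep.n_frames})"
            )
        if np.any(self.frames < 0):
            raise ValueError("camera counts must be >= 0")


# ---------------------------------------------------------------------------
# scene generators


def fresnel_reflectivity(n1: float, n2: float) -> float:
    """Normal-incidence Fresnel intensity reflectance between two media."""
    return ((n1 - n2) / (n1 + n2)) ** 2


def make_bead_phantom(
    n_beads: int,
    bead_diameter: float = 55.0,
    depth_range: tuple[float, float] = (30.0, 300.0),
    bounds: tuple[float, float, float] = (450.0, 450.0, 450.0),
    seed: int = 0,
    bead_index: float = BEAD_INDEX,
    medium_index: float = GEL_INDEX,
) -> PhantomScene:
    """Glass-bead calibration phantom: high-index beads in agarose gel.

    Each 55 um bead is reduced to a single point reflector at its upper
    surface (the bead body extends one diameter below), with reflectivity
    given by the Fresnel contrast between bead and gel.  Reflector depths
    are placed uniformly at random inside ``depth_range``.
    """
    if n_beads < 0:
        raise ValueError("n_beads must be >= 0")
    zlo, zhi = depth_range
    bx, by, bz = bounds
    if zlo < 0 or zhi > bz or zlo >= zhi:
        raise ValueError(f"depth_range {depth_range} outside bounds {bounds}")
    rng = np.random.default_rng(seed)
    refl = fresnel_reflectivity(bead_index, medium_index)
    scatterers = []
    for _ in range(n_beads):
        x = rng.uniform(0, bx)
        y = rng.uniform(0, by)
        z = rng.uniform(zlo, zhi)
        scatterers.append(Scatterer(x=x, y=y, z=z, reflectivity=refl))
    return PhantomScene(
        scatterers=scatterers,
        medium_index=medium_index,
        attenuation_mu=0.1,  # weakly scattering gel
        bounds=bounds,
        class_label="bead_phantom",
    )


@dataclass
class TissueParams:
    """Effect-size knobs for the synthetic tissue classes.

    ``density`` is scatterers per 1e5 um^3.  Attenuation is drawn uniformly
    from ``mu_range`` (mm^-1): gray matter-like classes default to the
    ex vivo low range 1-4, white matter to the high range 4-8.  Stripes are
    axially oriented low-reflectivity bands across x with the given width /
    spacing (um); scatterers inside a band keep ``1 - stripe_suppression``
    of their reflectivity.
    """

    density: float = 3.5
    mu_range: tuple[float, float] = (1.0, 4.0)
    stripe_width: float = 100.0
    stripe_spacing: float = 100.0
    stripe_suppression: float = 0.8
    reflectivity_mean: float = 0.001


_DEFAULT_MU = {
    "homogeneous": (1.0, 4.0),
    "white_matter": (4.0, 8.0),
    "striped": (1.0, 4.0),
}


def make_tissue_scene(
    class_name: str,
    params: TissueParams | None = None,
    seed: int = 0,
    bounds: tuple[float, float, float] = (450.0, 450.0, 400.0),
    medium_index: float = 1.38,
) -> PhantomScene:
    """Synthesize a scene with one of the three tissue-class signatures.

    ``homogeneous`` emulates cortex/hippocampus: spatially uniform random
    scatterers with low attenuation.  ``white_matter`` emulates the corpus
    callosum: the same uniform texture but attenuation drawn from the high
    ex vivo range.  ``striped`` emulates striatum/thalamus: a homogeneous
    field overlaid with dark stripes running along the axial (z) direction.
    """
    if class_name not in TISSUE_CLASSES:
        raise ValueError(
            f"unknown tissue class {class_name!r}; expected one of {TISSUE_CLASSES}"
        )
    if params is None:
        params = TissueParams(mu_range=_DEFAULT_MU[class_name])
    if not 0 <= params.stripe_suppression < 1:
        raise ValueError("stripe_suppression must lie in [0, 1)")
    ss_field, ss_stripe = np.random.SeedSequence(seed).spawn(2)
    rng = np.random.default_rng(ss_field)
    bx, by, bz = bounds
    volume = bx * by * bz
    n = rng.poisson(params.density * volume / 1e5)
    xs = rng.uniform(0, bx, n)
    ys = rng.uniform(0, by, n)
    zs = rng.uniform(0, bz, n)
    # exponential reflectivity spread gives speckle-like amplitude variation
    refl = np.clip(rng.exponential(params.reflectivity_mean, n), 1e-9, 1.0)
    mu = rng.uniform(*params.mu_range)
    if class_name == "striped":
        # separate substream: with zero suppression the field is identical
        # to the homogeneous class at the same seed and mu range
        period = params.stripe_width + params.stripe_spacing
        phase = np.random.default_rng(ss_stripe).uniform(0, period)
        in_stripe = ((xs + phase) % period) < params.stripe_width
        refl = np.where(in_stripe, refl * (1.0 - params.stripe_suppression), refl)
        refl = np.clip(refl, 1e-9, 1.0)
    scatterers = [
        Scatterer(x=float(x), y=float(y), z=float(z), reflectivity=float(r))
        for x, y, z, r in zip(xs, ys, zs, refl)
    ]
    return PhantomScene(
        scatterers=scatterers,
        medium_index=medium_index,
        attenuation_mu=mu,
        bounds=bounds,
        class_label=class_name,
    )


# ---------------------------------------------------------------------------
# forward simulation


def _sample_amplitudes(
    scene: PhantomScene, sweep: SweepConfig
) -> tuple[sparse.csr_array, np.ndarray]:
    """Per-scatterer amplitude images sqrt(I_samp_i(x, y)), flattened.

    Returns (amps, depths): amps is a sparse (n_scatterers, n_pixels)
    matrix with the Gaussian transverse point-spread applied to the
    *intensity* and the round-trip Beer-Lambert decay folded in; each
    scatterer only touches pixels within 4 sigma, which keeps dense-speckle
    scenes tractable.  depths is (n_scatterers,) um.
    """
    nx, ny = sweep.n_pixels_x, sweep.n_pixels_y
    px = (np.arange(nx) + 0.5) * sweep.pixel_pitch
    py = (np.arange(ny) + 0.5) * sweep.pixel_pitch
    mu_per_um = scene.attenuation_mu * 1e-3
    n_sc = len(scene.scatterers)
    depths = np.empty(n_sc)
    sig2 = 2.0 * sweep.psf_sigma**2
    support = 4.0 * sweep.psf_sigma
    rows: list[np.ndarray] = []
    cols: list[np.ndarray] = []
    vals: list[np.ndarray] = []
    for i, s in enumerate(scene.scatterers):
        depths[i] = s.z
        peak = s.reflectivity * math.exp(-2.0 * mu_per_um * s.z)
        ix = np.nonzero(np.abs(px - s.x) <= support)[0]
        iy = np.nonzero(np.abs(py - s.y) <= support)[0]
        if ix.size == 0 or iy.size == 0:
            continue
        gx = np.exp(-((px[ix] - s.x) ** 2) / sig2)
        gy = np.exp(-((py[iy] - s.y) ** 2) / sig2)
        tile = np.sqrt(peak * np.outer(gx, gy)).ravel()
        flat = (ix[:, None] * ny + iy[None, :]).ravel()
        rows.append(np.full(flat.size, i))
        cols.append(flat)
        vals.append(tile)
    if rows:
        amps = sparse.csr_array(
            (
                np.concatenate(vals),
                (np.concatenate(rows), np.concatenate(cols)),
            ),
            shape=(n_sc, nx * ny),
        )
    else:
        amps = sparse.csr_array((n_sc, nx * ny))
    return amps, depths


def simulate_sweep(
    scene: PhantomScene,
    sweep: SweepConfig | None = None,
    noise: NoiseConfig | None = None,
) -> SweepStack:
    """Simulate the raw interference stack for one wavelength sweep.

    For every wavelength the complex field at each camera pixel is the sum
    of the reference field and all scatterer fields with round-trip phase
    exp(i*2*k*z), k = 2*pi*n/lambda evaluated at the true wavelength of the
    frame; the camera records counts_scale * |field|^2, so all reference-
    sample and sample-sample interference terms are present.  If ``noise``
    is given, shot noise, read noise and quantization are applied in that
    order (seeded, bit-reproducible); ``noise=None`` returns noise-free
    float counts.

    Raises
    ------
    AliasingError
        If the scene extends beyond the maximum unambiguous depth
        lambda_c^2 / (4 n dlambda) for this sweep.
    """
    if sweep is None:
        sweep = SweepConfig()
    z_alias = sweep.aliasing_depth_um(scene.medium_index)
    if scene.depth_extent >= z_alias:
        raise AliasingError(
            f"scene depth {scene.depth_extent:.1f} um reaches beyond the "
            f"aliasing depth {z_alias:.1f} um for step {sweep.lambda_step} nm"
        )
    lambdas_um = sweep.wavelengths_nm * 1e-3
    k = 2.0 * np.pi * scene.medium_index / lambdas_um  # rad/um, per frame
    nx, ny = sweep.n_pixels_x, sweep.n_pixels_y
    n_pix = nx * ny
    ref_amp = math.sqrt(sweep.reference_reflectivity)
    ref_field = ref_amp * np.exp(2j * k * sweep.reference_depth)

    amps, depths = _sample_amplitudes(scene, sweep)

    motion_sd = noise.motion_blur_sd if noise is not None else 0.0
    rng_shot, rng_read, rng_motion = _noise_rngs(noise)

    if len(scene.scatterers) == 0:
        frames = np.broadcast_to(
            (np.abs(ref_field) ** 2)[:, None], (sweep.n_frames, n_pix)
        ).copy()
    else:
        phases = np.exp(2j * np.outer(k, depths))  # (n_frames, n_sc)
        # sparse (n_pix, n_sc) @ dense (n_sc, n_frames): O(nnz * n_frames)
        sample_field = (amps.T @ phases.T).T  # (n_frames, n_pix)
        if motion_sd > 0:
            # rigid per-frame jitter: a common axial shift enters the phase,
            # the transverse shift rolls the sample field by whole pixels
            sample_img = sample_field.reshape(sweep.n_frames, nx, ny)
            for j in range(sweep.n_frames):
                dz, dx, dy = rng_motion.normal(0.0, motion_sd, 3)
                sx = int(round(dx / sweep.pixel_pitch))
                sy = int(round(dy / sweep.pixel_pitch))
                fr = sample_img[j]
                if sx or sy:
                    fr = np.roll(fr, (sx, sy), axis=(0, 1))
                sample_img[j] = fr * np.exp(2j * k[j] * dz)
            sample_field = sample_img.reshape(sweep.n_frames, n_pix)
        frames = np.abs(sample_field + ref_field[:, None]) ** 2
    frames *= sweep.counts_scale
    frames = frames.reshape(sweep.n_frames, nx, ny)

    if noise is not None:
        if noise.shot_noise:
            frames = rng_shot.poisson(frames).astype(float)
        if noise.read_noise_sd > 0:
            frames = frames + rng_read.normal(0.0, noise.read_noise_sd, frames.shape)
        top = 2**noise.bit_depth - 1
        frames = np.clip(np.rint(frames), 0, top)

    prov = scene.scene_id or (scene.class_label or "scene")
    return SweepStack(frames=frames, sweep=sweep, provenance=prov)


def _noise_rngs(noise: NoiseConfig | None):
    if noise is None:
        return None, None, None
    ss = np.random.SeedSequence(noise.seed)
    return tuple(np.random.default_rng(c) for c in ss.spawn(3))
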