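import numpy as np
import pytest

from ffsoct import PhantomScene, Scatterer, SweepConfig, ReconConfig


@pytest.fixture
def toy_sweep():
    """Small fast sweep: 32 frames, 16x16 pixels, full wavelength span."""
    return SweepConfig(
        lambda_step=85.0 / 31.0,
        n_pixels_x=16,
        n_pixels_y=16,
        pixel_pitch=28.0,
    )


@pytest.fixture
def single_reflector_scene():
    return PhantomScene(
        scatterers=[Scatterer(x=225.0, y=225.0, z=150.0, reflectivity=0.01)],
        medium_index=1.33,
        attenuation_mu=0.0,
    )


@pytest.fixture
def recon_cfg():
    return ReconConfig(medium_index=1.33)


def make_volume(intensity, depth_step=5.0, n=1.38, source="test"):
    """Helper: wrap an array into a ReconVolume with a uniform depth axis."""
    from ffsoct import ReconVolume

    intensity = np.asarray(intensity, dtype=float)
    depth = np.arange(intensity.shape[0]) * depth_step
    return ReconVolume(
        intensity=intensity, depth_axis=depth, medium_index=n, source=source
    )
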