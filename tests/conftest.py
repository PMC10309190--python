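import numpy as np
import pytest

from phagoflux.profiles import KineticProfile
from phagoflux.simulate import ParticleSpec, SceneConfig, generate_timelapse


@pytest.fixture
def single_particle_scene():
    """Factory: one stationary 1.5 um particle in a small frame."""

    def make(profile=None, n_frames=30, noise=0.05, seed=1, engulfment_frame=3,
             **scene_kwargs):
        profile = profile or KineticProfile(60, 90, 150, 210, e_max=2.5)
        cfg = SceneConfig(
            particles=[
                ParticleSpec(
                    center_um=(6.4, 6.4),
                    radius_um=1.5,
                    engulfment_frame=engulfment_frame,
                    profiles={"reporter": profile},
                )
            ],
            n_frames=n_frames,
            image_shape=(128, 128),
            noise_sd_frac=noise,
            **scene_kwargs,
        )
        stack, truth = generate_timelapse(cfg, seed)
        return stack, truth, cfg

    return make


def disk_image(radius_um, pixel_size, shape=(128, 128), center_px=None, high=1000.0, low=10.0):
    """Analytic disk rendered by pixel-center membership."""
    h, w = shape
    cy, cx = center_px or (h // 2, w // 2)
    yy, xx = np.mgrid[0:h, 0:w]
    d = np.hypot(yy - cy, xx - cx) * pixel_size
    img = np.full(shape, low)
    img[d <= radius_um] = high
    return img
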