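import numpy as np
import pytest

from petpatterns.synthetic import PhantomConfig, SphereRegion, generate_phantom
from petpatterns.volume import SuvVolume


@pytest.fixture
def sphere_phantom():
    """Noiseless single-sphere phantom (radius 12 mm, peak 8.0, background 1.0)."""
    config = PhantomConfig(
        grid_shape=(32, 32, 32),
        voxel_spacing_mm=(3.0, 3.0, 3.0),
        background_suv=1.0,
        background_noise_sd=0.0,
        lesions=[SphereRegion((46.0, 46.0, 46.0), 12.0, 8.0)],
        liver_region=SphereRegion((20.0, 70.0, 46.0), 10.0, 2.2),
        mediastinum_region=SphereRegion((70.0, 20.0, 46.0), 8.0, 1.5),
    )
    volume, masks, summaries = generate_phantom(config)
    seed_point = tuple(np.argwhere(masks["lesion_0"])[0])
    return volume, masks, summaries, seed_point


def make_volume(values, spacing=(2.0, 2.0, 2.0)):
    return SuvVolume(np.asarray(values, dtype=float), spacing)


def random_phantom(rng, grid=24, spacing=3.0, n_lesions=None):
    """A noiseless multi-sphere phantom with all peaks above the SUV4.0 floor."""
    extent = (grid - 1) * spacing
    n_lesions = n_lesions or int(rng.integers(1, 4))
    lesions = []
    tries = 0
    while len(lesions) < n_lesions and tries < 200:
        tries += 1
        radius = float(rng.uniform(6.0, 12.0))
        center = tuple(rng.uniform(radius + spacing, extent - radius - spacing, 3))
        peak = float(rng.uniform(4.6, 15.0))
        if all(
            np.linalg.norm(np.subtract(center, l.center_mm)) > radius + l.radius_mm + spacing
            for l in lesions
        ):
            lesions.append(SphereRegion(center, radius, peak))
    config = PhantomConfig(
        grid_shape=(grid,) * 3,
        voxel_spacing_mm=(spacing,) * 3,
        background_suv=1.0,
        background_noise_sd=0.0,
        lesions=lesions,
        seed=int(rng.integers(2**31)),
    )
    return generate_phantom(config)
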