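import numpy as np
import pytest

from npk3d import SceneSpec, SpectralCube, apply_transform, make_plant_cloud, render_views
from npk3d.registration import invert_transform


def make_textured_image(seed: int = 0, n: int = 256) -> np.ndarray:
    """Anisotropic synthetic texture (oriented Gabor blobs) on [0, 255].

    A smooth isotropic random field has a rotationally featureless FFT
    magnitude, so rotation/scale registration tests need oriented structure.
    """
    rng = np.random.default_rng(seed)
    yy, xx = np.mgrid[0:n, 0:n]
    img = np.zeros((n, n))
    for _ in range(60):
        cx, cy = rng.uniform(0, n, 2)
        th = rng.uniform(0, np.pi)
        freq = rng.uniform(0.05, 0.25)
        s = rng.uniform(5, 15)
        u = (xx - cx) * np.cos(th) + (yy - cy) * np.sin(th)
        v = -(xx - cx) * np.sin(th) + (yy - cy) * np.cos(th)
        img += rng.uniform(0.3, 1.0) * np.exp(-(u**2 + (2 * v) ** 2) / (2 * s**2)) * np.cos(
            2 * np.pi * freq * u
        )
    img -= img.min()
    return img * (255.0 / img.max())


def warp_by_inverse(fixed: np.ndarray, t) -> np.ndarray:
    """Create a moving image such that ``apply_transform(moving, t)`` ≈ fixed,
    using the same interpolation as apply_transform itself."""
    ti = invert_transform(t, fixed.shape)
    cube = SpectralCube(bands=fixed[None], wavelengths_nm=[550.0])
    return apply_transform(cube, ti, fixed.shape).bands[0]


@pytest.fixture(scope="session")
def textured_image() -> np.ndarray:
    return make_textured_image()


@pytest.fixture(scope="session")
def fast_scene():
    """Small noise-free turntable scene shared by unit tests (reduced density)."""
    spec = SceneSpec(depth_noise_mm=0.0, point_density=3e5, seed=11)
    cloud = make_plant_cloud(spec)
    views = render_views(cloud, spec)
    return spec, cloud, views
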