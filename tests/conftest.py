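import numpy as np
import pytest

from implantquant import (
    SceneConfig,
    ROIMask,
    generate_cells,
    make_roi_mask,
    render_scene,
)


@pytest.fixture(scope="session")
def small_scene_config():
    """A compact default-style scene used across modules (fast to render)."""
    return SceneConfig(
        image_size_px=(384, 384),
        pixel_size_um=2.0,
        roi_shape={"kind": "disk", "radius_um": 320.0},
        seed=11,
    )


@pytest.fixture(scope="session")
def small_scene(small_scene_config):
    roi = make_roi_mask(small_scene_config)
    truth = generate_cells(small_scene_config, roi)
    image = render_scene(truth, small_scene_config)
    return small_scene_config, roi, truth, image


@pytest.fixture(scope="session")
def default_scene():
    """The generator's default study-condition scene with ground truth."""
    cfg = SceneConfig(seed=5)
    roi = make_roi_mask(cfg)
    truth = generate_cells(cfg, roi)
    image = render_scene(truth, cfg)
    return cfg, roi, truth, image


def disk_roi(radius_um=250.0, pixel_size_um=1.0, pad_px=30):
    n = int(2 * radius_um / pixel_size_um) + 2 * pad_px
    yy, xx = np.mgrid[0:n, 0:n]
    c = n / 2
    x = (xx + 0.5 - c) * pixel_size_um
    y = (yy + 0.5 - c) * pixel_size_um
    return ROIMask(x**2 + y**2 <= radius_um**2, pixel_size_um)


def random_blob_roi(seed, size=260, pixel_size_um=2.0):
    """Irregular but simply connected test masks for geometry properties."""
    from scipy import ndimage as ndi
    from skimage import measure

    rng = np.random.default_rng(seed)
    noise = ndi.gaussian_filter(rng.standard_normal((size, size)), 18)
    mask = noise > np.quantile(noise, 0.72)
    lab = measure.label(mask)
    assert lab.max() > 0
    mask = lab == (np.argmax(np.bincount(lab.ravel())[1:]) + 1)
    mask = ndi.binary_fill_holes(mask)
    return ROIMask(mask, pixel_size_um)
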