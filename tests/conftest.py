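import numpy as np
import pytest

from ecmbridge import SceneConfig


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def viability_config():
    """Full-depth single-cluster viability stack at assay conditions:
    500 cells in a 200-um cluster, sections every 10 um."""
    return SceneConfig(image_shape=(21, 144, 144), pixel_size_xy=1.5,
                       z_step=10.0, cells_per_cluster=500, seed=7)


@pytest.fixture
def bridge_config():
    """Compact two-cluster bridge layout (900-um spacing at 2.5 um/px)."""
    return SceneConfig(image_shape=(3, 160, 480), pixel_size_xy=2.5,
                       z_step=25.0, fiber_density=0.5,
                       artefact_spots=[(30, 70, 6), (130, 410, 6)], seed=5)


def stripe_image(theta_deg: float, shape=(128, 128), period_px=12.0,
                 amplitude=80.0, offset=100.0) -> np.ndarray:
    """Sinusoidal stripe phantom whose ridges run along ``theta_deg``
    (degrees CCW from +x, y axis pointing down in the raster)."""
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]].astype(float)
    th = np.deg2rad(theta_deg)
    phase = xx * np.sin(th) + yy * np.cos(th)
    return offset + amplitude * np.sin(2.0 * np.pi * phase / period_px)


def draw_rod(canvas: np.ndarray, center_yx, theta_deg: float,
             length_px: float, peak: float = 200.0) -> None:
    """Stamp one anti-aliased rod at an axial angle (y axis down)."""
    from skimage.draw import line_aa

    th = np.deg2rad(theta_deg)
    dy, dx = -np.sin(th) * length_px / 2, np.cos(th) * length_px / 2
    r0 = int(round(center_yx[0] - dy))
    c0 = int(round(center_yx[1] - dx))
    r1 = int(round(center_yx[0] + dy))
    c1 = int(round(center_yx[1] + dx))
    rr, cc, val = line_aa(r0, c0, r1, c1)
    keep = (rr >= 0) & (rr < canvas.shape[0]) & (cc >= 0) & (cc < canvas.shape[1])
    np.maximum.at(canvas, (rr[keep], cc[keep]), val[keep] * peak)
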