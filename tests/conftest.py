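import numpy as np
import pytest

import fiberalign as fa


def make_grating(angle_deg, shape=(128, 128), period=8.0):
    """Sinusoidal grating with stripes oriented at ``angle_deg`` in the
    package's y-up, counterclockwise-from-columns convention."""
    H, W = shape
    r, c = np.mgrid[0:H, 0:W]
    x, y = c.astype(float), -(r.astype(float))
    th = np.deg2rad(angle_deg)
    phase = (-x * np.sin(th) + y * np.cos(th)) * 2 * np.pi / period
    return 100.0 + 50.0 * np.cos(phase)


def fft_peak_orientation(img):
    """Independent orientation oracle: dominant peak of the 2D Fourier power
    spectrum; the wave vector is normal to the stripes."""
    F = np.fft.fftshift(np.abs(np.fft.fft2(img - img.mean())) ** 2)
    H, W = img.shape
    ky, kx = np.unravel_index(np.argmax(F), F.shape)
    gy, gx = -(ky - H // 2), kx - W // 2  # y-up
    return (np.degrees(np.arctan2(gy, gx)) + 90.0) % 180.0


def axial_diff(a, b):
    d = np.abs(np.asarray(a) - np.asarray(b)) % 180.0
    return np.minimum(d, 180.0 - d)


@pytest.fixture(scope="session")
def default_image():
    """One default confluent micrograph with moderate alignment."""
    spec = fa.SyntheticSpec(seed=42, kappa=2.0, mu=0.0)
    img, gt = fa.render_image(spec)
    return spec, img, gt


@pytest.fixture(scope="session")
def single_fiber_image():
    """A noiseless horizontal fiber through the image centre."""
    spec = fa.SyntheticSpec(
        width=96, height=96, n_cells=1, fibers_per_cell=1, mu=0.0, kappa=1e6,
        noise_sd=0.0, background_level=10.0, fiber_length_px=(40.0, 0.0),
        seed=7,
    )
    img, gt = fa.render_image(spec)
    return spec, img, gt
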