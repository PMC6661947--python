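import numpy as np
import pytest

from topodrive import fields


@pytest.fixture(scope="session")
def uniform30():
    """Uniform 30-degree field over a 200 x 200 µm extent."""
    return fields.make_uniform(30.0, (200.0, 200.0), 2.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def render_ellipse(psi_deg, major_um=40.0, minor_um=20.0, pixel_size=0.5,
                   size_um=80.0):
    """Noiseless filled ellipse raster centered in the frame (test helper)."""
    n = int(round(size_um / pixel_size))
    c = (n - 1) / 2.0
    Y, X = np.mgrid[:n, :n]
    t = np.deg2rad(psi_deg)
    dx, dy = X - c, Y - c
    u = dx * np.cos(t) + dy * np.sin(t)
    v = -dx * np.sin(t) + dy * np.cos(t)
    a = 0.5 * major_um / pixel_size
    b = 0.5 * minor_um / pixel_size
    return ((u / a) ** 2 + (v / b) ** 2 <= 1.0).astype(float)
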