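import numpy as np
import pytest

from starphase.segmentation import BinaryMask


def rasterize_disk(radius_px: float, pad: int = 4, pixel_size: float = 1.0) -> BinaryMask:
    """Binary mask of a disk centered on a pixel grid."""
    n = int(np.ceil(2 * radius_px)) + 2 * pad + 1
    c = n // 2
    rr, cc = np.mgrid[0:n, 0:n]
    return BinaryMask((rr - c) ** 2 + (cc - c) ** 2 <= radius_px**2, pixel_size=pixel_size)


def rasterize_ellipse(a: float, b: float, pad: int = 4) -> BinaryMask:
    """Axis-aligned filled ellipse, semi-axis ``a`` along columns, ``b`` along rows."""
    nr = int(np.ceil(2 * b)) + 2 * pad + 1
    nc = int(np.ceil(2 * a)) + 2 * pad + 1
    cr, cc0 = nr // 2, nc // 2
    rr, cc = np.mgrid[0:nr, 0:nc]
    return BinaryMask(((cc - cc0) / a) ** 2 + ((rr - cr) / b) ** 2 <= 1.0, pixel_size=1.0)


@pytest.fixture
def disk_mask():
    return rasterize_disk


@pytest.fixture
def ellipse_mask():
    return rasterize_ellipse
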