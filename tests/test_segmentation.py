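"""Segmentation: Otsu thresholding, the strict sub-6-px^2 noise filter and
moment-based best-fit-ellipse measurements against an eigen-decomposition
oracle."""

import numpy as np
import pytest

from starphase.errors import NoContrastError
from starphase.segmentation import BinaryMask, label_and_measure, segment_image


def two_disk_frame(background=10.0, amplitude=100.0):
    frame = np.full((64, 64), background)
    rr, cc = np.mgrid[0:64, 0:64]
    frame[(rr - 16) ** 2 + (cc - 16) ** 2 <= 36] = background + amplitude
    frame[(rr - 45) ** 2 + (cc - 45) ** 2 <= 64] = background + amplitude
    return frame


def test_two_disk_fixture_segments_two_components():
    mask = segment_image(two_disk_frame())
    regions = label_and_measure(mask)
    assert regions.n_regions == 2


def test_constant_frame_raises_no_contrast():
    with pytest.raises(NoContrastError):
        segment_image(np.full((32, 32), 7.0))


def test_size_filter_is_strict():
    """Area 4 px^2 removed, area 6 px^2 kept: 'smaller than 6' is strict."""
    frame = np.zeros((20, 20))
    frame[2:4, 2:4] = 100.0  # 4 px^2
    frame[10:12, 10:13] = 100.0  # 6 px^2
    mask = segment_image(frame, min_area=6)
    regions = label_and_measure(mask)
    assert regions.n_regions == 1
    assert regions.records["area"].iloc[0] == 6


def test_filter_monotonicity():
    """Raising min_area never increases the region count."""
    rng = np.random.default_rng(3)
    frame = np.where(rng.random((64, 64)) < 0.35, 100.0, 0.0)
    counts = [
        label_and_measure(segment_image(frame, min_area=a)).n_regions
        for a in (1, 2, 4, 6, 10)
    ]
    assert all(c1 >= c2 for c1, c2 in zip(counts, counts[1:]))


def test_mask_idempotence():
    """Segmenting an already binary image reproduces its foreground."""
    rng = np.random.default_rng(5)
    fg = rng.random((48, 48)) < 0.3
    mask1 = segment_image(np.where(fg, 80.0, 0.0), min_area=1)
    assert np.array_equal(mask1.mask, fg)


def test_disk_aspect_ratio_is_one(disk_mask):
    regions = label_and_measure(disk_mask(20))
    assert regions.n_regions == 1
    assert regions.records["aspect_ratio"].iloc[0] == pytest.approx(1.0, rel=0.02)


def test_ellipse_axes_and_orientation(ellipse_mask):
    """Axis-aligned ellipse with semi-axes (40, 10): AR ~ 4, orientation 0.

    The measured value is compared exactly against the brute-force moment
    oracle on the same raster; the comparison with the continuous-ellipse
    value 4.0 carries the ~2% bias binarization introduces at this size.
    """
    regions = label_and_measure(ellipse_mask(40, 10))
    rec = regions.records.iloc[0]
    coords = np.argwhere(regions.labels == 1).astype(float)
    major, minor, _ = moment_oracle(coords)
    assert rec["aspect_ratio"] == pytest.approx(major / minor, rel=1e-9)
    assert rec["aspect_ratio"] == pytest.approx(4.0, rel=0.025)
    assert abs(rec["orientation"]) < 0.05
    assert rec["major_axis"] == pytest.approx(80.0, rel=0.02)


def test_empty_mask_yields_zero_regions():
    regions = label_and_measure(BinaryMask(np.zeros((16, 16), dtype=bool)))
    assert regions.n_regions == 0
    assert regions.records.empty


def moment_oracle(coords: np.ndarray):
    """Direct eigen-decomposition of the 2x2 second-central-moment matrix."""
    c = coords - coords.mean(axis=0)
    cov = c.T @ c / len(coords)
    eigvals, eigvecs = np.linalg.eigh(cov)
    major = 4.0 * np.sqrt(eigvals[-1])
    minor = 4.0 * np.sqrt(eigvals[0])
    vy, vx = eigvecs[:, -1]  # coords are (row, col) = (y, x)
    orientation = np.arctan2(vy, vx)
    if orientation <= -np.pi / 2:
        orientation += np.pi
    elif orientation > np.pi / 2:
        orientation -= np.pi
    return major, minor, orientation


def test_moment_ellipse_matches_eigendecomposition_oracle():
    """Axes agree with the independent oracle to 1e-9 relative on small masks."""
    rng = np.random.default_rng(11)
    checked = 0
    for _ in range(30):
        mask = rng.random((32, 32)) < 0.4
        regions = label_and_measure(BinaryMask(mask))
        for _, rec in regions.records.iterrows():
            coords = np.argwhere(regions.labels == rec["label"])
            if len(coords) < 3:
                continue
            major, minor, _ = moment_oracle(coords.astype(float))
            assert rec["major_axis"] == pytest.approx(major, rel=1e-9, abs=1e-9)
            assert rec["minor_axis"] == pytest.approx(minor, rel=1e-9, abs=1e-9)
            checked += 1
    assert checked > 50


def test_orientation_matches_oracle_on_tilted_ellipse():
    rr, cc = np.mgrid[0:64, 0:64]
    x, y = cc - 32.0, rr - 32.0
    th = 0.5
    u = x * np.cos(th) + y * np.sin(th)
    v = -x * np.sin(th) + y * np.cos(th)
    mask = (u / 25) ** 2 + (v / 8) ** 2 <= 1
    regions = label_and_measure(BinaryMask(mask))
    coords = np.argwhere(regions.labels == 1).astype(float)
    major, minor, orient = moment_oracle(coords)
    rec = regions.records.iloc[0]
    assert rec["orientation"] == pytest.approx(orient, abs=1e-9)
    assert rec["major_axis"] == pytest.approx(major, rel=1e-9)
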