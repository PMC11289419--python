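"""Generators: determinism, ground-truth closure through segmentation, the
radius law, two-channel composition, fusion geometry and FRAP traces."""

import numpy as np
import pytest

from starphase.errors import GeometryError, PlacementError
from starphase.frap import normalize_recovery
from starphase.segmentation import label_and_measure, segment_image
from starphase.synthetic import (
    BleedMatrix,
    FieldSpec,
    generate_droplet_field,
    generate_frap_series,
    generate_fusion_series,
    generate_two_channel_field,
)


def test_equal_seeds_are_bit_identical():
    spec = FieldSpec(n_droplets=8, seed=123)
    s1, t1 = generate_droplet_field(spec)
    s2, t2 = generate_droplet_field(spec)
    assert np.array_equal(s1.data, s2.data)
    assert t1.records.equals(t2.records)


def test_noiseless_field_segmentation_closure():
    """Noiseless spherical field: segmentation recovers every droplet with
    sub-pixel centroid accuracy."""
    spec = FieldSpec(n_droplets=10, noise_sigma=0.0, psf_sigma=0.0, seed=1)
    stack, truth = generate_droplet_field(spec)
    mask = segment_image(stack.frame(), pixel_size=spec.pixel_size)
    regions = label_and_measure(mask)
    assert regions.n_regions == truth.true_count == 10
    found = regions.records[["centroid_row", "centroid_col"]].to_numpy()
    for _, rec in truth.records.iterrows():
        d = np.hypot(found[:, 0] - rec["row"], found[:, 1] - rec["col"]).min()
        assert d < 1.0


def test_radius_law_sample_mean():
    """Sampled radii match the closed-form lognormal mean within 3 SE."""
    mu, sigma = np.log(2.0), 0.3
    rng = np.random.default_rng(99)
    radii = rng.lognormal(mu, sigma, 10_000)
    true_mean = np.exp(mu + sigma**2 / 2)
    true_sd = true_mean * np.sqrt(np.exp(sigma**2) - 1.0)
    assert abs(radii.mean() - true_mean) < 3 * true_sd / np.sqrt(10_000)


def test_placement_error_when_droplets_cannot_fit():
    spec = FieldSpec(image_shape=(48, 48), n_droplets=4,
                     radius_law=(np.log(20.0), 0.01), pixel_size=1.0, seed=0)
    with pytest.raises(PlacementError):
        generate_droplet_field(spec)


def test_network_morphology_produces_connected_aggregates():
    spec = FieldSpec(n_droplets=12, morphology="network", network_walk_steps=6,
                     noise_sigma=0.0, psf_sigma=0.0, seed=4)
    stack, truth = generate_droplet_field(spec)
    mask = segment_image(stack.frame(), pixel_size=spec.pixel_size)
    regions = label_and_measure(mask)
    # chained disks overlap, so fewer components than droplets
    assert 0 < regions.n_regions < truth.true_count


@pytest.mark.parametrize("mixing, allowed", [(0.0, {0.0, 1.0}), (1.0, {0.5})])
def test_two_channel_composition_limits(mixing, allowed):
    spec = FieldSpec(n_droplets=12, seed=2)
    _, truth = generate_two_channel_field(spec, mixing=mixing)
    assert set(truth.records["composition"]) <= allowed


def test_two_channel_mixing_domain_error():
    with pytest.raises(ValueError):
        generate_two_channel_field(FieldSpec(seed=0), mixing=1.5)


def test_pure_species_identity_bleed_angles():
    """m=0, identity bleed, no noise: in-droplet angles are exactly 0 or pi/2."""
    spec = FieldSpec(n_droplets=10, noise_sigma=0.0, psf_sigma=0.0,
                     background_level=0.0, seed=6)
    stack, _ = generate_two_channel_field(spec, mixing=0.0, bleed=BleedMatrix.identity())
    fitc, cy3 = stack.frame(0, "FITC"), stack.frame(0, "Cy3")
    inside = (fitc > 0) | (cy3 > 0)
    theta = np.arctan2(fitc[inside], cy3[inside])
    assert set(np.unique(theta)) <= {0.0, np.pi / 2}


def test_fusion_first_frame_aspect_ratio():
    A = 0.6
    stack = generate_fusion_series(A=A, tau=120.0, duration=120.0)
    regions = label_and_measure(segment_image(stack.frame(0), pixel_size=stack.pixel_size))
    assert regions.records["aspect_ratio"].iloc[0] == pytest.approx(1 + A, rel=0.02)


def test_fusion_frames_conserve_area():
    stack = generate_fusion_series(A=0.6, tau=120.0, duration=240.0)
    areas = []
    for t in range(stack.n_frames):
        regions = label_and_measure(segment_image(stack.frame(t), pixel_size=stack.pixel_size))
        areas.append(regions.records["area"].iloc[0])
    assert np.ptp(areas) / np.mean(areas) < 0.02


def test_fusion_geometry_error():
    with pytest.raises(GeometryError):
        generate_fusion_series(A=1.0, tau=100.0, area=5000.0, image_shape=(64, 64))


def test_frap_no_bleach_recovery_is_unity():
    trace = generate_frap_series(bleach_depth=0.0)
    curve = normalize_recovery(trace)
    assert np.allclose(curve.recovery, 1.0)


def test_frap_photobleach_cancels_in_normalization():
    """Global exp(-lambda t) decay on both ROIs leaves the normalized
    recovery unchanged to 1e-9."""
    kw = dict(bleach_depth=0.7, recovery_amplitude=0.3, tau_rec=40.0, seed=5)
    r0 = normalize_recovery(generate_frap_series(photobleach_lambda=0.0, **kw)).recovery
    r1 = normalize_recovery(generate_frap_series(photobleach_lambda=0.01, **kw)).recovery
    assert np.max(np.abs(r0 - r1)) <= 1e-9


def test_frap_no_recovery_is_flat_at_bleach_depth():
    trace = generate_frap_series(bleach_depth=0.8, recovery_amplitude=0.0)
    curve = normalize_recovery(trace)
    post = curve.recovery[trace.bleach_frame_index:]
    assert np.allclose(post, 1.0 - 0.8)
    assert np.allclose(curve.recovery[: trace.bleach_frame_index], 1.0)


def test_frap_default_cadence():
    """Defaults mirror the acquisition protocol: 6 pre-bleach frames and 60
    post-bleach frames at 5-second intervals."""
    trace = generate_frap_series()
    assert len(trace.frame_times) == 66
    assert np.allclose(np.diff(trace.frame_times), 5.0)
    assert trace.bleach_frame_index == 6
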