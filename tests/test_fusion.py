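"""Aspect-ratio relaxation fitting and the inverse capillary velocity."""

import numpy as np
import pytest

from starphase.fusion import (
    AspectRatioSeries,
    aspect_ratio_series,
    fit_relaxation,
    inverse_capillary_velocity,
)
from starphase.segmentation import BinaryMask
from starphase.synthetic import generate_fusion_series


def analytic_series(A, tau, dt=15.0, span=600.0, ell=np.nan):
    t = np.arange(0.0, span + dt / 2, dt)
    return AspectRatioSeries(t, 1.0 + A * np.exp(-t / tau), characteristic_length=ell)


def test_circular_stack_aspect_ratio_near_one(disk_mask):
    from starphase.io import ImageStack

    frame = np.where(disk_mask(20, pad=8).mask, 100.0, 5.0)
    stack = ImageStack(np.stack([frame] * 5)[:, None], pixel_size=0.5,
                       frame_times=np.arange(5.0))
    series = aspect_ratio_series(stack)
    assert np.allclose(series.aspect_ratio, 1.0, rtol=0.02)


def test_generator_measurement_closure():
    """Noiseless rendered fusion series reproduces 1 + 0.6 exp(-t/120)
    frame by frame within 2%."""
    stack = generate_fusion_series(A=0.6, tau=120.0, dt=15.0, duration=600.0)
    series = aspect_ratio_series(stack)
    truth = 1.0 + 0.6 * np.exp(-series.times / 120.0)
    assert np.allclose(series.aspect_ratio, truth, rtol=0.02)


def test_generator_fit_round_trip():
    stack = generate_fusion_series(A=0.6, tau=120.0, dt=15.0, duration=600.0)
    fit = fit_relaxation(aspect_ratio_series(stack))
    assert fit.converged
    assert fit.A == pytest.approx(0.6, rel=0.01)
    assert fit.tau == pytest.approx(120.0, rel=0.01)


def test_characteristic_length_equivalent_diameter():
    """Final-frame disk of area 100*pi px^2 at 0.5 um/px: ell = 10 um."""
    from starphase.io import ImageStack

    rr, cc = np.mgrid[0:64, 0:64]
    frame = np.where((rr - 32) ** 2 + (cc - 32) ** 2 <= 100, 100.0, 5.0)
    stack = ImageStack(np.stack([frame] * 4)[:, None], pixel_size=0.5,
                       frame_times=np.arange(4.0))
    series = aspect_ratio_series(stack)
    area_px = np.pi * 100
    assert series.characteristic_length == pytest.approx(
        2 * np.sqrt(area_px / np.pi) * 0.5, rel=0.02
    )
    assert series.characteristic_length == pytest.approx(10.0, rel=0.02)


def test_fit_round_trip_noiseless():
    fit = fit_relaxation(analytic_series(0.6, 120.0))
    assert fit.converged
    assert fit.A == pytest.approx(0.6, rel=1e-3)
    assert fit.tau == pytest.approx(120.0, rel=1e-3)
    assert fit.residual_rms < 1e-3


def test_fit_recovers_observed_relaxation_constant():
    """The slowly fusing condensate example: tau = 172 min recovered to
    0.5% from a noiseless series with A = 0.5 sampled every 15 min."""
    fit = fit_relaxation(analytic_series(0.5, 172.0, dt=15.0, span=600.0))
    assert fit.converged
    assert fit.tau == pytest.approx(172.0, rel=5e-3)


def test_constant_series_is_unidentifiable():
    t = np.arange(0.0, 100.0, 10.0)
    fit = fit_relaxation(AspectRatioSeries(t, np.ones_like(t)))
    assert not fit.converged
    assert fit.A == 0.0


def test_fitted_model_monotone_to_one():
    fit = fit_relaxation(analytic_series(0.4, 90.0))
    t = np.linspace(0, 1000, 200)
    model = 1 + fit.A * np.exp(-t / fit.tau)
    assert model[0] == pytest.approx(1 + fit.A)
    assert np.all(np.diff(model) < 0)
    assert model[-1] == pytest.approx(1.0, abs=1e-4)


def test_time_unit_equivariance():
    s_min = analytic_series(0.5, 120.0)
    s_scaled = AspectRatioSeries(s_min.times * 60.0, s_min.aspect_ratio)
    f1, f2 = fit_relaxation(s_min), fit_relaxation(s_scaled)
    assert f2.tau == pytest.approx(60.0 * f1.tau, rel=1e-6)
    icv1 = inverse_capillary_velocity([(f1.tau, 2.0)])
    icv2 = inverse_capillary_velocity([(f2.tau, 2.0)])
    assert icv2.eta_over_gamma == pytest.approx(60.0 * icv1.eta_over_gamma, rel=1e-6)


def test_icv_single_pair_is_ratio():
    est = inverse_capillary_velocity([(100.0, 2.0)])
    assert est.eta_over_gamma == pytest.approx(50.0)


def test_icv_noiseless_regression_round_trip():
    k = 57.81
    pairs = [(k * ell, ell) for ell in (1.0, 2.0, 3.0, 4.0, 5.0)]
    est = inverse_capillary_velocity(pairs)
    assert est.eta_over_gamma == pytest.approx(k, abs=1e-12)
    assert est.residual_rms == pytest.approx(0.0, abs=1e-12)


def test_icv_noise_robustness_monte_carlo():
    """Zero-mean noise on tau: the pooled slope stays within its standard
    error of the true value."""
    rng = np.random.default_rng(8)
    k, ells = 57.81, np.array([1.0, 2.0, 3.0, 4.0, 5.0])
    estimates = []
    for _ in range(200):
        taus = k * ells + rng.normal(0, 5.0, ells.shape)
        estimates.append(inverse_capillary_velocity(list(zip(taus, ells))).eta_over_gamma)
    estimates = np.asarray(estimates)
    assert abs(estimates.mean() - k) < 3 * estimates.std(ddof=1) / np.sqrt(len(estimates))


def test_icv_all_zero_lengths_error():
    with pytest.raises(ValueError):
        inverse_capillary_velocity([(10.0, 0.0)])
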