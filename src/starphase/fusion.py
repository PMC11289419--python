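"""Coalescence kinetics: aspect-ratio relaxation and inverse capillary velocity.

When two viscous droplets fuse, surface tension drives the dumbbell-shaped
intermediate back toward a sphere. Tracking the best-fit-ellipse aspect
ratio AR of the fusing pair over time and fitting

    AR(t) = 1 + A * exp(-t / tau)

yields the relaxation constant tau. In the capillary-relaxation model
tau scales with the characteristic droplet length ell as
tau = (eta/gamma) * ell, so regressing tau against ell through the origin
estimates the inverse capillary velocity eta/gamma — the
viscosity-to-surface-tension ratio of the condensate material.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .errors import StarphaseError
from .io import ImageStack
from .segmentation import DEFAULT_MIN_AREA, label_and_measure, segment_image

__all__ = [
    "AspectRatioSeries",
    "FusionFit",
    "ICVEstimate",
    "aspect_ratio_series",
    "fit_relaxation",
    "inverse_capillary_velocity",
]


@dataclass
class AspectRatioSeries:
    """Aspect ratio of one tracked fusion event over time.

    ``characteristic_length`` is the equivalent-circle diameter (um) of the
    fused droplet in the final retained frame — the length scale entering
    the capillary-velocity regression.
    """

    times: np.ndarray  # minutes
    aspect_ratio: np.ndarray
    event_id: str = "0"
    characteristic_length: float = float("nan")  # um

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.aspect_ratio = np.asarray(self.aspect_ratio, dtype=float)
        if self.times.shape != self.aspect_ratio.shape:
            raise ValueError("times and aspect_ratio must align")
        if len(self.times) > 1 and np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.aspect_ratio < 1.0 - 1e-9):
            raise ValueError("aspect ratios must be >= 1")


@dataclass
class FusionFit:
    A: float
    tau: float  # minutes
    residual_rms: float
    converged: bool
    reason: str = ""


@dataclass
class ICVEstimate:
    eta_over_gamma: float  # min / um
    n_events: int
    residual_rms: float


def aspect_ratio_series(
    stack: ImageStack,
    min_area: int = DEFAULT_MIN_AREA,
    event_id: str = "0",
    channel: int = 0,
) -> AspectRatioSeries:
    """Track the largest condensate in each frame of a cropped fusion stack.

    Each frame is Otsu-segmented; the largest labeled region gives the
    best-fit-ellipse aspect ratio. Frames with no region above ``min_area``
    are dropped with a warning; an all-dropped stack is an error. The
    stack is assumed to be a manually cropped single fusion event, so no
    multi-object tracking is attempted.
    """
    times, ars = [], []
    ell = float("nan")
    for t in range(stack.n_frames):
        frame = stack.frame(t, channel)
        try:
            mask = segment_image(frame, pixel_size=stack.pixel_size, min_area=min_area)
        except StarphaseError:
            warnings.warn(f"frame {t}: segmentation failed, frame dropped", stacklevel=2)
            continue
        regions = label_and_measure(mask)
        if regions.n_regions == 0:
            warnings.warn(f"frame {t}: no region above min_area, frame dropped", stacklevel=2)
            continue
        largest = regions.records.loc[regions.records["area"].idxmax()]
        times.append(stack.frame_times[t])
        ars.append(max(float(largest["aspect_ratio"]), 1.0))
        ell = 2.0 * np.sqrt(float(largest["area"]) / np.pi) * stack.pixel_size
    if not times:
        raise StarphaseError("no usable frames: every frame lacked a region above min_area")
    return AspectRatioSeries(
        times=np.asarray(times),
        aspect_ratio=np.asarray(ars),
        event_id=event_id,
        characteristic_length=ell,
    )


def fit_relaxation(series: AspectRatioSeries) -> FusionFit:
    """Fit AR(t) = 1 + A exp(-t/tau) by constrained nonlinear least squares.

    Time is measured from the first frame. Initialization: A0 = AR(0) - 1;
    tau0 = the first time at which AR - 1 falls below A0/e, falling back to
    half the series span. A series indistinguishable from AR = 1 has an
    unidentifiable tau and is reported unconverged with A = 0.
    """
    if len(series.times) < 4:
        raise ValueError("need at least 4 frames to fit the relaxation model")
    t = series.times - series.times[0]
    ar = series.aspect_ratio
    a0 = max(ar[0] - 1.0, 0.0)
    if np.max(ar - 1.0) < 1e-9:
        return FusionFit(A=0.0, tau=float("nan"), residual_rms=0.0, converged=False,
                         reason="aspect ratio constant at 1; tau unidentifiable")
    below = np.flatnonzero(ar - 1.0 < a0 / np.e)
    tau0 = float(t[below[0]]) if len(below) and t[below[0]] > 0 else 0.5 * float(t[-1])

    def model(tt, A, tau):
        return 1.0 + A * np.exp(-tt / tau)

    try:
        popt, _ = curve_fit(
            model, t, ar,
            p0=[max(a0, 1e-6), max(tau0, 1e-6)],
            bounds=([0.0, 1e-12], [np.inf, np.inf]),
            maxfev=10000,
        )
    except RuntimeError as exc:
        return FusionFit(A=float("nan"), tau=float("nan"), residual_rms=float("nan"),
                         converged=False, reason=f"least squares failed: {exc}")
    resid = ar - model(t, *popt)
    return FusionFit(
        A=float(popt[0]),
        tau=float(popt[1]),
        residual_rms=float(np.sqrt(np.mean(resid**2))),
        converged=True,
    )


def inverse_capillary_velocity(fits: list[tuple[float, float]]) -> ICVEstimate:
    """Estimate eta/gamma from (tau, ell) pairs.

    Fits tau = (eta/gamma) * ell by least squares through the origin:
    eta/gamma = sum(tau*ell) / sum(ell^2). The origin is forced because
    tau -> 0 as ell -> 0 in the capillary-relaxation model. A single pair
    reduces to the ratio tau/ell.
    """
    if not fits:
        raise ValueError("at least one (tau, ell) pair required")
    tau = np.asarray([f[0] for f in fits], dtype=float)
    ell = np.asarray([f[1] for f in fits], dtype=float)
    if np.any(ell < 0) or np.any(tau < 0):
        raise ValueError("tau and ell must be nonnegative")
    denom = float(np.sum(ell**2))
    if denom == 0:
        raise ValueError("all characteristic lengths are zero")
    slope = float(np.sum(tau * ell) / denom)
    resid = tau - slope * ell
    return ICVEstimate(
        eta_over_gamma=slope,
        n_events=len(fits),
        residual_rms=float(np.sqrt(np.mean(resid**2))),
    )
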