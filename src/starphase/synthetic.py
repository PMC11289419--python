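"""Seeded generators of ground-truthed synthetic fluorescence microscopy data.

The raw micrographs behind the condensate measurements are not public, so
every imaging stage in this package is exercised on synthetic fields whose
statistical structure matches what those stages assume:

* **Droplet fields** — disk-shaped condensates (or chained "network"
  aggregates) of lognormally distributed radius, rendered as uniform disks
  over a constant background, blurred by a Gaussian PSF and corrupted by
  additive Gaussian read noise. Every droplet is recorded in a
  :class:`GroundTruth` table.
* **Two-channel fields** — two condensate species with per-droplet
  composition ``f`` imaged through a 2x2 spectral bleed-through matrix into
  FITC and Cy3 detection channels, emulating fluorogenic-aptamer imaging
  where each aptamer is detected in both channels.
* **Fusion time-lapse** — a single relaxing dumbbell coarse-grained as a
  constant-area ellipse whose aspect ratio follows ``1 + A exp(-t/tau)``.
* **FRAP series** — bleached/reference ROI mean-intensity traces with a
  single-exponential recovery and optional global observational
  photobleaching ``exp(-lambda t)`` applied to both ROIs.

All generators are deterministic given their seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import GeometryError, PlacementError
from .frap import FrapTrace
from .io import ImageStack

__all__ = [
    "FieldSpec",
    "GroundTruth",
    "BleedMatrix",
    "generate_droplet_field",
    "generate_two_channel_field",
    "generate_fusion_series",
    "generate_frap_series",
]

_MAX_PLACEMENT_TRIES = 2000


@dataclass
class FieldSpec:
    """Parameters of a synthetic condensate field.

    ``radius_law`` is the (mu, sigma) of a lognormal in um: radii are
    ``exp(N(mu, sigma^2))``. ``morphology`` selects isolated spherical
    droplets (rejection-sampled so they never touch) or network aggregates
    built by chaining overlapping disks along a random walk of at most
    ``network_walk_steps`` steps.
    """

    image_shape: tuple[int, int] = (256, 256)
    pixel_size: float = 0.5  # um/px
    n_droplets: int = 20
    radius_law: tuple[float, float] = (math.log(2.0), 0.3)  # lognormal, um
    morphology: Literal["spherical", "network"] = "spherical"
    network_walk_steps: int = 8
    background_level: float = 10.0
    droplet_amplitude: float = 100.0
    psf_sigma: float = 1.0  # px
    noise_sigma: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if self.n_droplets < 0:
            raise ValueError("n_droplets must be nonnegative")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be nonnegative")
        if self.psf_sigma < 0:
            raise ValueError("psf_sigma must be nonnegative")
        if self.morphology not in ("spherical", "network"):
            raise ValueError(f"unknown morphology {self.morphology!r}")


@dataclass
class GroundTruth:
    """Per-droplet records of a generated field.

    ``records`` has one row per droplet: center (``row``, ``col`` in px),
    ``radius_um``, ``composition`` f in [0, 1] (fraction of species A; 1.0
    for single-species fields) and per-channel brightness.
    """

    records: pd.DataFrame
    channel_names: list[str] = field(default_factory=lambda: ["ch0"])

    @property
    def true_count(self) -> int:
        return len(self.records)

    def to_csv(self, path: str | Path) -> None:
        self.records.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "GroundTruth":
        df = pd.read_csv(path)
        channels = [c[len("brightness_"):] for c in df.columns if c.startswith("brightness_")]
        return cls(df, channel_names=channels or ["ch0"])


class BleedMatrix:
    """2x2 nonnegative gain matrix mapping species emission to channels.

    Row order is detection channels ``(FITC, Cy3)``; column order is species
    ``(A, B)``. The diagonal must be positive: each species is detected at
    least in its own primary channel.
    """

    def __init__(self, matrix: np.ndarray | list[list[float]]) -> None:
        m = np.asarray(matrix, dtype=float)
        if m.shape != (2, 2):
            raise ValueError("bleed matrix must be 2x2")
        if np.any(m < 0):
            raise ValueError("bleed gains must be nonnegative")
        if m[0, 0] <= 0 or m[1, 1] <= 0:
            raise ValueError("diagonal gains must be positive")
        self.matrix = m

    @classmethod
    def identity(cls) -> "BleedMatrix":
        return cls(np.eye(2))

    def __array__(self, dtype=None, copy=None) -> np.ndarray:
        return np.asarray(self.matrix, dtype=dtype)


def _sample_radii(rng: np.random.Generator, spec: FieldSpec) -> np.ndarray:
    mu, sigma = spec.radius_law
    return rng.lognormal(mean=mu, sigma=sigma, size=spec.n_droplets)


def _place_spherical(
    rng: np.random.Generator, spec: FieldSpec, radii_px: np.ndarray
) -> np.ndarray:
    """Uniform non-overlapping centers, droplets fully inside the frame."""
    rows, cols = spec.image_shape
    margin_extra = 2.0 + 2.0 * spec.psf_sigma  # keep blurred disks separable
    centers: list[tuple[float, float]] = []
    for i, r in enumerate(radii_px):
        margin = r + margin_extra
        if 2 * margin >= min(rows, cols):
            raise PlacementError(
                f"droplet radius {r:.1f} px does not fit in {spec.image_shape} (spec={spec})"
            )
        for _ in range(_MAX_PLACEMENT_TRIES):
            cr = rng.uniform(margin, rows - margin)
            cc = rng.uniform(margin, cols - margin)
            ok = all(
                math.hypot(cr - pr, cc - pc) > r + radii_px[j] + margin_extra
                for j, (pr, pc) in enumerate(centers)
            )
            if ok:
                centers.append((cr, cc))
                break
        else:
            raise PlacementError(
                f"could not place droplet {i} without overlap after "
                f"{_MAX_PLACEMENT_TRIES} tries (spec={spec})"
            )
    return np.asarray(centers, dtype=float).reshape(-1, 2)


def _place_network(
    rng: np.random.Generator, spec: FieldSpec, radii_px: np.ndarray
) -> np.ndarray:
    """Chain overlapping disks along random walks of bounded length."""
    rows, cols = spec.image_shape
    centers: list[tuple[float, float]] = []
    i = 0
    while i < spec.n_droplets:
        r0 = radii_px[i]
        cr = rng.uniform(r0, rows - r0)
        cc = rng.uniform(r0, cols - r0)
        centers.append((cr, cc))
        i += 1
        steps = 1
        while i < spec.n_droplets and steps < max(1, spec.network_walk_steps):
            r = radii_px[i]
            # step by less than the sum of radii so consecutive disks fuse
            d = 0.8 * (radii_px[i - 1] + r)
            ang = rng.uniform(0.0, 2.0 * math.pi)
            cr = float(np.clip(cr + d * math.sin(ang), r, rows - r))
            cc = float(np.clip(cc + d * math.cos(ang), r, cols - r))
            centers.append((cr, cc))
            i += 1
            steps += 1
    return np.asarray(centers, dtype=float).reshape(-1, 2)


def _paint_disks(
    shape: tuple[int, int],
    centers: np.ndarray,
    radii_px: np.ndarray,
    amplitudes: np.ndarray,
) -> np.ndarray:
    """Rasterize uniform disks; overlaps take the maximum, not the sum."""
    canvas = np.zeros(shape, dtype=float)
    for (cr, cc), r, amp in zip(centers, radii_px, amplitudes):
        r0 = max(int(math.floor(cr - r)) - 1, 0)
        r1 = min(int(math.ceil(cr + r)) + 2, shape[0])
        c0 = max(int(math.floor(cc - r)) - 1, 0)
        c1 = min(int(math.ceil(cc + r)) + 2, shape[1])
        rr, cc_ = np.ogrid[r0:r1, c0:c1]
        inside = (rr - cr) ** 2 + (cc_ - cc) ** 2 <= r**2
        patch = canvas[r0:r1, c0:c1]
        np.maximum(patch, inside * amp, out=patch)
    return canvas


def _finish_image(
    rng: np.random.Generator, spec: FieldSpec, foreground: np.ndarray
) -> np.ndarray:
    img = spec.background_level + foreground
    if spec.psf_sigma > 0:
        img = ndimage.gaussian_filter(img, sigma=spec.psf_sigma)
    if spec.noise_sigma > 0:
        img = img + rng.normal(0.0, spec.noise_sigma, size=img.shape)
    return np.clip(img, 0.0, None)


def generate_droplet_field(spec: FieldSpec) -> tuple[ImageStack, GroundTruth]:
    """Render one single-channel field of stained condensates.

    Returns the image as a one-frame, one-channel :class:`ImageStack` and
    the :class:`GroundTruth` listing every droplet.
    """
    rng = np.random.default_rng(spec.seed)
    radii_um = _sample_radii(rng, spec)
    radii_px = radii_um / spec.pixel_size
    if spec.morphology == "spherical":
        centers = _place_spherical(rng, spec, radii_px)
    else:
        centers = _place_network(rng, spec, radii_px)
    amplitudes = np.full(spec.n_droplets, spec.droplet_amplitude)
    foreground = _paint_disks(spec.image_shape, centers, radii_px, amplitudes)
    img = _finish_image(rng, spec, foreground)
    stack = ImageStack(
        img[None, None],
        pixel_size=spec.pixel_size,
        frame_times=np.array([0.0]),
        channel_names=["SYBR"],
    )
    records = pd.DataFrame(
        {
            "row": centers[:, 0] if len(centers) else np.array([]),
            "col": centers[:, 1] if len(centers) else np.array([]),
            "radius_um": radii_um,
            "composition": np.ones(spec.n_droplets),
            "brightness_SYBR": amplitudes,
        }
    )
    return stack, GroundTruth(records, channel_names=["SYBR"])


def generate_two_channel_field(
    spec: FieldSpec,
    mixing: float,
    bleed: BleedMatrix | None = None,
) -> tuple[ImageStack, GroundTruth]:
    """Render a two-species field imaged in FITC and Cy3 channels.

    ``mixing`` m in [0, 1] interpolates the per-droplet composition
    ``f`` (fraction of species A) between fully demixed droplets
    (m=0: f is exactly 0 or 1) and fully mixed droplets (m=1: f = 0.5).
    Droplet channel brightness is ``bleed @ (f, 1-f)`` scaled by the
    droplet amplitude, so spectral overlap between the two fluorophores is
    part of the model, as it is for real fluorogenic aptamers.
    """
    if not 0.0 <= mixing <= 1.0:
        raise ValueError(f"mixing must be in [0, 1], got {mixing}")
    bleed = bleed if bleed is not None else BleedMatrix.identity()
    rng = np.random.default_rng(spec.seed)
    radii_um = _sample_radii(rng, spec)
    radii_px = radii_um / spec.pixel_size
    if spec.morphology == "spherical":
        centers = _place_spherical(rng, spec, radii_px)
    else:
        centers = _place_network(rng, spec, radii_px)
    # two populations of equal expected number
    pure = rng.integers(0, 2, size=spec.n_droplets).astype(float)
    f = (1.0 - mixing) * pure + mixing * 0.5
    emission = np.stack([f, 1.0 - f])  # 2 x n, rows = species (A, B)
    channel_amp = spec.droplet_amplitude * (bleed.matrix @ emission)  # 2 x n
    channels = []
    for ch in range(2):
        fg = _paint_disks(spec.image_shape, centers, radii_px, channel_amp[ch])
        channels.append(_finish_image(rng, spec, fg))
    img = np.stack(channels)[None]  # 1 x 2 x H x W
    stack = ImageStack(
        img,
        pixel_size=spec.pixel_size,
        frame_times=np.array([0.0]),
        channel_names=["FITC", "Cy3"],
    )
    records = pd.DataFrame(
        {
            "row": centers[:, 0] if len(centers) else np.array([]),
            "col": centers[:, 1] if len(centers) else np.array([]),
            "radius_um": radii_um,
            "composition": f,
            "brightness_FITC": channel_amp[0],
            "brightness_Cy3": channel_amp[1],
        }
    )
    return stack, GroundTruth(records, channel_names=["FITC", "Cy3"])


def generate_fusion_series(
    A: float,
    tau: float,
    area: float = 900.0,
    dt: float = 15.0,
    duration: float = 240.0,
    noise_sigma: float = 0.0,
    seed: int = 0,
    image_shape: tuple[int, int] = (256, 256),
    pixel_size: float = 0.5,
    background_level: float = 10.0,
    amplitude: float = 100.0,
    psf_sigma: float = 0.0,
) -> ImageStack:
    """Render a coalescing condensate as a relaxing constant-area ellipse.

    Each frame at time ``t`` (minutes) is an axis-aligned filled ellipse of
    fixed area ``area`` (um^2) whose major/minor axis ratio equals
    ``1 + A exp(-t/tau)`` — the coarse-grained shape of a fusing droplet
    pair relaxing to a sphere under surface tension. Frames are sampled
    every ``dt`` minutes (default 15, the experimental cadence) over
    ``duration`` minutes.
    """
    if A < 0:
        raise ValueError("A must be nonnegative")
    if tau <= 0:
        raise ValueError("tau must be positive")
    rng = np.random.default_rng(seed)
    times = np.arange(0.0, duration + 0.5 * dt, dt)
    area_px = area / pixel_size**2
    rows, cols = image_shape
    ar_max = 1.0 + A
    a_max = math.sqrt(area_px * ar_max / math.pi)
    if 2 * a_max + 4 >= min(rows, cols):
        raise GeometryError(
            f"ellipse with area {area} um^2 and initial aspect ratio {ar_max}"
            f" does not fit in image_shape {image_shape}"
        )
    cr, cc = (rows - 1) / 2.0, (cols - 1) / 2.0
    rr, cc_grid = np.mgrid[0:rows, 0:cols]
    frames = []
    for t in times:
        ar = 1.0 + A * math.exp(-t / tau)
        b = math.sqrt(area_px / (math.pi * ar))  # semi-minor, px
        a = ar * b  # semi-major, px (along columns)
        inside = ((cc_grid - cc) / a) ** 2 + ((rr - cr) / b) ** 2 <= 1.0
        img = background_level + amplitude * inside
        if psf_sigma > 0:
            img = ndimage.gaussian_filter(img, sigma=psf_sigma)
        if noise_sigma > 0:
            img = img + rng.normal(0.0, noise_sigma, size=img.shape)
        frames.append(np.clip(img, 0.0, None))
    return ImageStack(
        np.stack(frames)[:, None],
        pixel_size=pixel_size,
        frame_times=times,
        channel_names=["FITC"],
    )


def generate_frap_series(
    pre_frames: int = 6,
    post_frames: int = 60,
    dt: float = 5.0,
    bleach_depth: float = 0.8,
    recovery_amplitude: float = 0.0,
    tau_rec: float = 60.0,
    photobleach_lambda: float = 0.0,
    seed: int = 0,
    noise_sigma: float = 0.0,
    baseline: float = 100.0,
) -> FrapTrace:
    """Simulate bleached/reference ROI mean-intensity traces.

    Defaults follow the experimental cadence: 6 frames every 5 s before the
    bleach, then 60 frames every 5 s (5 min) after. At the bleach the
    bleached-ROI intensity drops by ``bleach_depth`` (fraction of baseline)
    and recovers as a single exponential of amplitude ``recovery_amplitude``
    and time constant ``tau_rec`` (seconds). ``photobleach_lambda`` applies
    a global observational-photobleaching factor ``exp(-lambda t)`` to both
    ROIs; the downstream double-ratio normalization cancels it exactly.
    """
    if not 0.0 <= bleach_depth <= 1.0:
        raise ValueError("bleach_depth must be in [0, 1]")
    if recovery_amplitude < 0:
        raise ValueError("recovery_amplitude must be nonnegative")
    if tau_rec <= 0:
        raise ValueError("tau_rec must be positive")
    if photobleach_lambda < 0:
        raise ValueError("photobleach_lambda must be nonnegative")
    rng = np.random.default_rng(seed)
    n = pre_frames + post_frames
    times = np.arange(n, dtype=float) * dt
    t_bleach = times[pre_frames] if pre_frames < n else times[-1]
    i_bleach = np.full(n, baseline)
    post = times >= t_bleach
    rec = recovery_amplitude * (1.0 - np.exp(-(times[post] - t_bleach) / tau_rec))
    i_bleach[post] = baseline * np.clip(1.0 - bleach_depth + rec, 0.0, None)
    i_unbleach = np.full(n, baseline)
    decay = np.exp(-photobleach_lambda * times)
    i_bleach = i_bleach * decay
    i_unbleach = i_unbleach * decay
    if noise_sigma > 0:
        i_bleach = np.clip(i_bleach + rng.normal(0, noise_sigma, n), 0, None)
        i_unbleach = np.clip(i_unbleach + rng.normal(0, noise_sigma, n), 0, None)
    return FrapTrace(
        frame_times=times,
        i_bleach=i_bleach,
        i_unbleach=i_unbleach,
        bleach_frame_index=pre_frames,
    )
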