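"""Two-channel demixing analysis via intensity-ratio angle histograms.

Fluorogenic aptamers with overlapping emission spectra are detected in both
the FITC and the Cy3 channel, so colocalization cannot be judged from a
single channel. Instead, each condensate pixel is mapped to the angle

    theta = arctan2(I_FITC, I_Cy3)  in [0, pi/2],

which depends only on the intensity *ratio*: a pixel dominated by the
Cy3-bright species sits near 0, one dominated by the FITC-bright species
near pi/2, and a pixel containing both sits in between. Histogramming
theta over all condensate pixels gives one peak per spectrally distinct
pixel population. Condensates assembled together are demixed when their
histogram peaks coincide with the peaks of individually assembled control
samples; a single intermediate peak indicates mixing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

from .errors import EmptyRoiError
from .segmentation import BinaryMask

__all__ = ["AngleHistogram", "DemixingReport", "compute_angle_histogram", "compare_histograms"]

DEFAULT_N_BINS = 90  # ~1 degree per bin over [0, pi/2]
DEFAULT_SMOOTH_WINDOW = 5  # bins, moving average before peak picking
DEFAULT_PROMINENCE_FRAC = 0.05  # of the smoothed maximum
DEFAULT_PEAK_TOL = 0.05  # rad, peak-matching tolerance


@dataclass
class AngleHistogram:
    """Histogram of per-pixel FITC/Cy3 angles with detected peaks."""

    bin_edges: np.ndarray  # n_bins + 1 edges over [0, pi/2]
    counts: np.ndarray
    n_pixels: int
    n_excluded: int  # pixels where both channels were zero
    peaks: list[float]  # peak angles, rad
    prominences: list[float]


@dataclass
class DemixingReport:
    """Outcome of comparing a co-assembled sample against controls."""

    control_peaks: list[float]
    mixed_peaks: list[float]
    peak_distances: list[float]  # each mixed peak's distance to nearest control peak
    verdict: str  # demixed | mixed | indeterminate
    reason: str = ""


def _detect_peaks(
    counts: np.ndarray,
    bin_edges: np.ndarray,
    smooth_window: int,
    prominence_frac: float,
) -> tuple[list[float], list[float]]:
    if counts.sum() == 0:
        return [], []
    kernel = np.ones(smooth_window) / smooth_window
    smoothed = np.convolve(counts.astype(float), kernel, mode="same")
    # zero-pad so maxima at the domain boundaries are still local maxima
    padded = np.concatenate(([0.0], smoothed, [0.0]))
    floor = prominence_frac * padded.max()
    idx, props = find_peaks(padded, prominence=floor)
    centers = 0.5 * (bin_edges[:-1] + bin_edges[1:])
    angles = [float(centers[i - 1]) for i in idx]
    return angles, [float(p) for p in props["prominences"]]


def compute_angle_histogram(
    fitc: np.ndarray,
    cy3: np.ndarray,
    roi: BinaryMask | np.ndarray | None = None,
    n_bins: int = DEFAULT_N_BINS,
    smooth_window: int = DEFAULT_SMOOTH_WINDOW,
    prominence_frac: float = DEFAULT_PROMINENCE_FRAC,
) -> AngleHistogram:
    """Histogram per-pixel angles theta = arctan2(I_FITC, I_Cy3) over a ROI.

    The two frames must be co-registered and of identical shape. ``roi``
    restricts the statistic to condensate pixels (typically the segmented
    foreground of the channel-sum image); ``None`` uses every pixel.
    Pixels where both channels read exactly zero have no defined angle and
    are excluded (their count is reported). The two-argument arctangent
    keeps zero-denominator pixels well defined: (I_FITC>0, 0) maps to
    pi/2 and (0, I_Cy3>0) to 0.
    """
    fitc = np.asarray(fitc, dtype=float)
    cy3 = np.asarray(cy3, dtype=float)
    if fitc.shape != cy3.shape:
        raise ValueError("channel frames must share a shape")
    if roi is None:
        sel = np.ones(fitc.shape, dtype=bool)
    else:
        sel = roi.mask if isinstance(roi, BinaryMask) else np.asarray(roi, dtype=bool)
        if sel.shape != fitc.shape:
            raise ValueError("ROI must match the frame shape")
    if not sel.any():
        raise EmptyRoiError("empty ROI: no pixels to histogram")
    f = fitc[sel]
    c = cy3[sel]
    defined = (f > 0) | (c > 0)
    n_excluded = int((~defined).sum())
    theta = np.arctan2(f[defined], c[defined])
    edges = np.linspace(0.0, np.pi / 2, n_bins + 1)
    counts, _ = np.histogram(theta, bins=edges)
    peaks, proms = _detect_peaks(counts, edges, smooth_window, prominence_frac)
    return AngleHistogram(
        bin_edges=edges,
        counts=counts,
        n_pixels=int(defined.sum()),
        n_excluded=n_excluded,
        peaks=peaks,
        prominences=proms,
    )


def _pool_control_peaks(controls: list[AngleHistogram], tol: float) -> list[float]:
    """Union of control peaks, merging peaks closer than ``tol``."""
    all_peaks = sorted(p for h in controls for p in h.peaks)
    pooled: list[list[float]] = []
    for p in all_peaks:
        if pooled and p - pooled[-1][-1] <= tol:
            pooled[-1].append(p)
        else:
            pooled.append([p])
    return [float(np.mean(group)) for group in pooled]


def compare_histograms(
    controls: list[AngleHistogram],
    mixed: AngleHistogram,
    tol: float = DEFAULT_PEAK_TOL,
) -> DemixingReport:
    """Classify a co-assembled sample against individually assembled controls.

    verdict ``demixed``: every peak of the co-assembled histogram lies
    within ``tol`` of a pooled control peak and the peak counts agree —
    the species occupy the same distinct pixel populations whether
    assembled separately or together. verdict ``mixed``: the co-assembled
    histogram shows a single peak strictly between the control peaks,
    farther than ``tol`` from all of them — the species share pixels.
    Anything else is ``indeterminate``.
    """
    if not controls:
        raise ValueError("at least one control histogram required")
    control_peaks = _pool_control_peaks(controls, tol)
    mixed_peaks = sorted(mixed.peaks)
    distances = [
        min(abs(m - c) for c in control_peaks) if control_peaks else np.inf
        for m in mixed_peaks
    ]
    if not mixed_peaks:
        return DemixingReport(
            control_peaks, mixed_peaks, distances, "indeterminate",
            reason="no peaks detected in the co-assembled histogram",
        )
    if not control_peaks:
        return DemixingReport(
            control_peaks, mixed_peaks, distances, "indeterminate",
            reason="no peaks detected in any control histogram",
        )
    all_match = all(d <= tol for d in distances)
    if all_match and len(mixed_peaks) == len(control_peaks):
        return DemixingReport(
            control_peaks, mixed_peaks, distances, "demixed",
            reason="co-assembled peaks align one-to-one with control peaks",
        )
    if (
        len(mixed_peaks) == 1
        and len(control_peaks) >= 2
        and min(control_peaks) < mixed_peaks[0] < max(control_peaks)
        and distances[0] > tol
    ):
        return DemixingReport(
            control_peaks, mixed_peaks, distances, "mixed",
            reason="single intermediate peak between the control peaks",
        )
    return DemixingReport(
        control_peaks, mixed_peaks, distances, "indeterminate",
        reason="peak pattern matches neither the demixed nor the mixed signature",
    )
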