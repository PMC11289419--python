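"""FRAP trace normalization and replicate aggregation.

Recovery in the bleached region of interest is normalized by a double
ratio: each ROI's mean-intensity series is divided by its own maximum over
all time points, and the bleached-ROI ratio is divided by the reference
(unbleached) ROI ratio,

    recovery_t = (I_bleach,t / I_bleach,max) / (I_unbleach,t / I_unbleach,max).

Because any global multiplicative intensity change (observational
photobleaching, lamp drift) enters both ROIs identically, it cancels in the
double ratio; an unperturbed trace normalizes to exactly 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import AlignmentError, DegenerateTraceError

__all__ = [
    "FrapTrace",
    "RecoveryCurve",
    "normalize_recovery",
    "aggregate_recovery",
    "load_trace_csv",
]


@dataclass
class FrapTrace:
    """Mean-intensity series of a bleached and an unbleached reference ROI."""

    frame_times: np.ndarray
    i_bleach: np.ndarray
    i_unbleach: np.ndarray
    bleach_frame_index: int

    def __post_init__(self) -> None:
        self.frame_times = np.asarray(self.frame_times, dtype=float)
        self.i_bleach = np.asarray(self.i_bleach, dtype=float)
        self.i_unbleach = np.asarray(self.i_unbleach, dtype=float)
        n = len(self.frame_times)
        if len(self.i_bleach) != n or len(self.i_unbleach) != n:
            raise ValueError("trace series must share one length")
        if np.any(self.i_bleach < 0) or np.any(self.i_unbleach < 0):
            raise ValueError("intensities must be nonnegative")
        if not 0 <= self.bleach_frame_index < n:
            raise ValueError("bleach_frame_index outside the series")


@dataclass
class RecoveryCurve:
    """Normalized recovery per frame; NaN marks frames where the reference
    ROI read zero and the ratio is undefined."""

    frame_times: np.ndarray
    recovery: np.ndarray
    replicate_id: str = "0"
    undefined_frames: list[int] = field(default_factory=list)


def normalize_recovery(trace: FrapTrace, replicate_id: str = "0") -> RecoveryCurve:
    """Apply the double-ratio normalization to one trace.

    The per-ROI maxima are taken over the full series, pre-bleach frames
    included. A zero maximum in either ROI makes the whole trace degenerate;
    a zero reference intensity at an individual frame flags only that frame.
    """
    b_max = float(trace.i_bleach.max(initial=0.0))
    u_max = float(trace.i_unbleach.max(initial=0.0))
    if b_max <= 0 or u_max <= 0:
        raise DegenerateTraceError(
            "degenerate trace: a ROI series maximum is zero, normalization undefined"
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        recovery = (trace.i_bleach / b_max) / (trace.i_unbleach / u_max)
    undefined = np.flatnonzero(trace.i_unbleach == 0.0)
    recovery[undefined] = np.nan
    return RecoveryCurve(
        frame_times=trace.frame_times.copy(),
        recovery=recovery,
        replicate_id=replicate_id,
        undefined_frames=[int(i) for i in undefined],
    )


def aggregate_recovery(curves: list[RecoveryCurve]) -> pd.DataFrame:
    """Per-frame mean and standard error across replicate curves.

    Returns a frame with columns ``time``, ``mean``, ``stderr`` and ``n``.
    With a single replicate the standard error is reported as NaN. All
    curves must share the same time grid.
    """
    if not curves:
        raise ValueError("no curves to aggregate")
    t0 = curves[0].frame_times
    for c in curves[1:]:
        if len(c.frame_times) != len(t0) or not np.allclose(c.frame_times, t0):
            raise AlignmentError("replicate curves do not share a time grid")
    mat = np.vstack([c.recovery for c in curves])
    mean = np.nanmean(mat, axis=0)
    n = len(curves)
    if n > 1:
        stderr = np.nanstd(mat, axis=0, ddof=1) / np.sqrt(n)
    else:
        stderr = np.full_like(mean, np.nan)
    return pd.DataFrame({"time": t0, "mean": mean, "stderr": stderr, "n": n})


def load_trace_csv(path: str | Path, bleach_frame_index: int | None = None) -> FrapTrace:
    """Read a trace CSV with columns ``time``, ``i_bleach``, ``i_unbleach``.

    If ``bleach_frame_index`` is not given it is inferred as the frame of
    the largest single-step drop in the bleached-ROI series.
    """
    df = pd.read_csv(path)
    required = {"time", "i_bleach", "i_unbleach"}
    if not required.issubset(df.columns):
        raise ValueError(f"trace CSV needs columns {sorted(required)}")
    if bleach_frame_index is None:
        drops = np.diff(df["i_bleach"].to_numpy())
        bleach_frame_index = int(np.argmin(drops)) + 1 if len(drops) else 0
    return FrapTrace(
        frame_times=df["time"].to_numpy(float),
        i_bleach=df["i_bleach"].to_numpy(float),
        i_unbleach=df["i_unbleach"].to_numpy(float),
        bleach_frame_index=bleach_frame_index,
    )
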