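"""ROI fluorescence time-course analysis and per-frame vessel summaries.

The wash-in of intracameral fluorescein into the episcleral vasculature is
summarized by the total intensity within a circular region of interest per
frame, plotted against time, and fitted with the saturating exponential

    total(t) = B + I_inf * (1 - exp(-(t - t0)/tau)) * 1[t >= t0].

The "optimal imaging time" is operationalized as the time at which the fitted
curve reaches 95% of its plateau, t0 + tau * ln 20; the 95% criterion is
carried in the fit result so reports are explicit about it.  Intensities are
arbitrary units (au) and are never renormalized.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from skimage.draw import polygon as _sk_polygon

from .frame import FrameImage
from .ridge import VesselSegment, compute_borders

__all__ = [
    "CircularROI",
    "WashinFit",
    "TimeCourse",
    "EmptyROIError",
    "InvalidSeriesError",
    "InsufficientDataError",
    "PLATEAU_FRACTION",
    "roi_total_intensity",
    "build_timecourse",
    "fit_washin",
    "frame_vessel_summary",
]

#: Fraction of the fitted plateau defining the optimal imaging time.
PLATEAU_FRACTION = 0.95

#: t(95%) = t0 + tau * ln 20.
_LN20 = math.log(1.0 / (1.0 - PLATEAU_FRACTION))


class EmptyROIError(ValueError):
    """ROI contains no pixel centers of the frame."""


class InvalidSeriesError(ValueError):
    """Frame times are not strictly increasing."""


class InsufficientDataError(ValueError):
    """Too few samples to attempt a wash-in fit."""


@dataclass
class CircularROI:
    """Circular region of interest in pixel coordinates.

    Membership is the strict Euclidean test on pixel centers; boundary pixels
    at distance exactly equal to the radius are included.
    """

    center_px: tuple
    radius_px: float
    description: str = ""

    def __post_init__(self) -> None:
        if not self.radius_px > 0:
            raise ValueError("radius_px must be > 0")

    def mask(self, shape: tuple) -> np.ndarray:
        h, w = shape
        cx, cy = self.center_px
        yy, xx = np.mgrid[0:h, 0:w]
        return (xx - cx) ** 2 + (yy - cy) ** 2 <= self.radius_px ** 2


@dataclass
class WashinFit:
    baseline_au: float
    plateau_au: float
    tau_s: float
    t0_s: float
    rmse_au: float
    converged: bool
    degenerate: bool = False
    plateau_fraction: float = PLATEAU_FRACTION

    @property
    def optimal_time_s(self) -> float:
        if self.degenerate:
            return self.t0_s
        return self.t0_s + self.tau_s * _LN20


@dataclass
class TimeCourse:
    """ROI total intensity vs time, with optional wash-in fit."""

    samples: list                 # list of (time_s, total_au)
    roi: CircularROI | None = None
    fit: WashinFit | None = None

    def __post_init__(self) -> None:
        t = np.array([s[0] for s in self.samples], dtype=float)
        if t.size >= 2 and np.any(np.diff(t) <= 0):
            raise InvalidSeriesError("times must be strictly increasing")
        if any(s[1] < 0 for s in self.samples):
            raise ValueError("total_au must be >= 0")

    @property
    def times_s(self) -> np.ndarray:
        return np.array([s[0] for s in self.samples], dtype=float)

    @property
    def totals_au(self) -> np.ndarray:
        return np.array([s[1] for s in self.samples], dtype=float)

    @property
    def optimal_time_s(self) -> float | None:
        return None if self.fit is None else self.fit.optimal_time_s


def roi_total_intensity(frame: FrameImage, roi: CircularROI) -> float:
    """Sum of pixel intensities whose centers lie within the ROI circle."""
    m = roi.mask(frame.shape)
    if not m.any():
        raise EmptyROIError(
            f"ROI at {roi.center_px} r={roi.radius_px} contains no pixel of a "
            f"{frame.shape} frame")
    return float(frame.pixels[m].sum())


def build_timecourse(frames: list[tuple[float, FrameImage]],
                     roi: CircularROI) -> TimeCourse:
    """One ROI total per frame, order preserved; times must strictly increase."""
    if len(frames) < 2:
        raise InvalidSeriesError("need at least 2 frames")
    times = np.array([t for t, _ in frames], dtype=float)
    if np.any(np.diff(times) <= 0):
        raise InvalidSeriesError("frame times must be strictly increasing")
    samples = [(float(t), roi_total_intensity(f, roi)) for t, f in frames]
    return TimeCourse(samples, roi=roi)


def _washin_model(params: np.ndarray, t: np.ndarray) -> np.ndarray:
    b, i_inf, tau, t0 = params
    rise = np.where(t >= t0, 1.0 - np.exp(-(t - t0) / np.maximum(tau, 1e-12)), 0.0)
    return b + i_inf * rise


def fit_washin(tc: TimeCourse) -> TimeCourse:
    """Nonlinear least-squares fit of the saturating wash-in model.

    Initialization: I_inf0 = max - min of the totals, tau0 = one third of the
    time span, t00 = time of the first sample exceeding min + 5% of the
    range; the solver is bounded.  A non-converged fit returns the course
    with ``fit.converged = False`` rather than raising; a constant series is
    flagged degenerate with I_inf ~ 0 and optimal time = t0.
    """
    t = tc.times_s
    y = tc.totals_au
    if t.size < 5:
        raise InsufficientDataError(f"need >= 5 samples, got {t.size}")
    rng_y = float(y.max() - y.min())
    span = float(t[-1] - t[0])
    if rng_y == 0.0:
        tc.fit = WashinFit(baseline_au=float(y[0]), plateau_au=0.0, tau_s=1.0,
                           t0_s=float(t[0]), rmse_au=0.0, converged=True,
                           degenerate=True)
        return tc
    above = t[y > y.min() + 0.05 * rng_y]
    t00 = float(above[0]) if above.size else float(t[0])
    x0 = np.array([float(y.min()), rng_y, span / 3.0, t00])
    # t0 earlier than one sampling interval before the first frame is not
    # identifiable (no pre-onset samples), so it is bounded there; the bound
    # moves with the time axis, preserving shift equivariance.
    dt = float(np.median(np.diff(t)))
    lb = np.array([0.0, 0.0, 1e-6, float(t[0]) - dt])
    ub = np.array([float(y.max()), 10.0 * rng_y, 10.0 * span, float(t[-1])])
    x0 = np.clip(x0, lb, ub)
    try:
        res = least_squares(lambda p: _washin_model(p, t) - y, x0,
                            bounds=(lb, ub), method="trf")
        ok = res.success and np.all(np.isfinite(res.x))
    except Exception:
        tc.fit = None
        return tc
    if not ok:
        tc.fit = WashinFit(*x0, rmse_au=float("nan"), converged=False)
        return tc
    b, i_inf, tau, t0 = (float(v) for v in res.x)
    rmse = float(np.sqrt(np.mean((_washin_model(res.x, t) - y) ** 2)))
    tc.fit = WashinFit(baseline_au=b, plateau_au=i_inf, tau_s=tau, t0_s=t0,
                       rmse_au=rmse, converged=True,
                       degenerate=(i_inf <= 1e-9 * max(1.0, rng_y)))
    return tc


def _lumen_mask(segment: VesselSegment, shape: tuple, pitch_um: float) -> np.ndarray:
    """Boolean mask of pixels inside the segment's border polygon."""
    if segment.border is None:
        compute_borders(segment, pitch_um)
    left, right = segment.border
    poly = np.vstack([left, right[::-1]])          # (x, y) ring
    rr, cc = _sk_polygon(poly[:, 1], poly[:, 0], shape=shape)
    m = np.zeros(shape, dtype=bool)
    m[rr, cc] = True
    return m


def frame_vessel_summary(frame: FrameImage,
                         segments: list[VesselSegment]) -> pd.DataFrame:
    """Per-segment table: diameter statistics, mean midline response, and
    total intraluminal intensity (sum over pixels within the border polygon).

    Returns a header-only table when no segments are given.
    """
    cols = ["segment_id", "n_points", "median_diameter_um", "mean_diameter_um",
            "min_diameter_um", "max_diameter_um", "mean_response",
            "total_intraluminal_au"]
    rows = []
    for sid, seg in enumerate(segments):
        d = seg.diameters_um
        d = d[np.isfinite(d)]
        mask = _lumen_mask(seg, frame.shape, frame.pitch_um)
        rows.append({
            "segment_id": sid,
            "n_points": len(seg.points),
            "median_diameter_um": float(np.median(d)) if d.size else np.nan,
            "mean_diameter_um": float(np.mean(d)) if d.size else np.nan,
            "min_diameter_um": float(np.min(d)) if d.size else np.nan,
            "max_diameter_um": float(np.max(d)) if d.size else np.nan,
            "mean_response": float(np.mean([p.response for p in seg.points])),
            "total_intraluminal_au": float(frame.pixels[mask].sum()),
        })
    return pd.DataFrame(rows, columns=cols)
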