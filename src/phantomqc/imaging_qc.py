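"""Stability and photobleaching QC for fluorescence-imager time series.

The per-frame intensity statistic is the mean of the k brightest pixels
in a fixed region of interest (k = 21 by default), the series is
normalized to its first frame, and stability is summarized by the
sample standard deviation, a linear drift fit, and the fraction of
points inside a tolerance band.  Bleaching series are fitted with an
exponential-plus-offset decay.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import curve_fit


@dataclass
class ImageSeries:
    """Stack of fluorescence frames with acquisition timing.

    frames: (n, h, w) nonnegative intensities; timestamps_s strictly
    increasing, seconds from series start.
    """

    frames: np.ndarray
    timestamps_s: np.ndarray
    exposure_ms: float = 200.0
    pause_ms: float = 600.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        self.timestamps_s = np.asarray(self.timestamps_s, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[0] < 1:
            raise ValueError("frames must be a (n, h, w) stack with n >= 1")
        if self.timestamps_s.shape[0] != self.frames.shape[0]:
            raise ValueError("one timestamp per frame required")
        if np.any(np.diff(self.timestamps_s) <= 0):
            raise ValueError("timestamps must be strictly increasing")
        if np.any(self.frames < 0):
            raise ValueError("frame intensities must be nonnegative")


@dataclass
class ROISpec:
    """Rectangular region of interest and the order statistic k.

    ``x0, y0`` is the top-left pixel, ``width/height`` the extent.  If
    the region holds fewer than k pixels, k is clipped (with a warning
    flag on the result).
    """

    x0: int
    y0: int
    width: int
    height: int
    k: int = 21

    def __post_init__(self) -> None:
        if self.width < 1 or self.height < 1:
            raise ValueError("ROI must contain at least one pixel")
        if self.k < 1:
            raise ValueError("k must be >= 1")

    def slice(self) -> Tuple[slice, slice]:
        return slice(self.y0, self.y0 + self.height), slice(self.x0, self.x0 + self.width)


@dataclass
class StabilityReport:
    normalized: np.ndarray
    std_percent: Optional[float]
    drift_percent_per_frame: Optional[float]
    drift_percent_per_min: Optional[float]
    in_band_fraction: Optional[float]
    band_halfwidth: float
    metrics_available: bool
    note: str = ""


@dataclass
class BleachFit:
    total_drop_percent: float
    rate: float
    offset: float
    amplitude: float
    converged: bool


def roi_intensity(frame: np.ndarray, roi: ROISpec) -> float:
    """Mean of the k brightest pixels inside the ROI.

    The statistic depends on pixel values only through their order
    statistics, so it is invariant to any permutation of pixels within
    the region; ties at the k-th value do not affect the mean.
    """
    frame = np.asarray(frame)
    sy, sx = roi.slice()
    if (
        roi.x0 < 0
        or roi.y0 < 0
        or roi.y0 + roi.height > frame.shape[0]
        or roi.x0 + roi.width > frame.shape[1]
    ):
        raise ValueError("ROI extends outside the frame")
    region = frame[sy, sx].ravel()
    if region.size == 0:
        raise ValueError("empty ROI")
    k = min(roi.k, region.size)
    top = np.partition(region, region.size - k)[region.size - k :]
    return float(top.mean())


def series_intensity(series: ImageSeries, roi: ROISpec) -> np.ndarray:
    """Per-frame ROI intensity over the whole stack (fixed ROI)."""
    return np.array([roi_intensity(f, roi) for f in series.frames])


def normalize_series(intensities: Sequence[float]) -> np.ndarray:
    """Divide a series by its first value (first element becomes 1)."""
    x = np.asarray(intensities, dtype=float)
    if x.size == 0:
        raise ValueError("empty series")
    if x[0] <= 0:
        raise ValueError("first value must be > 0 to normalize")
    return x / x[0]


def stability_metrics(
    normalized: Sequence[float],
    band_halfwidth: float = 0.02,
    timestamps_s: Optional[Sequence[float]] = None,
) -> StabilityReport:
    """Stability summary of a first-frame-normalized series.

    Reports the percent sample (n-1) standard deviation, an ordinary
    least-squares linear drift (per frame, and per minute when
    timestamps are given), and the fraction of points with
    |x - 1| <= band_halfwidth.  With fewer than 3 points the metrics
    are flagged unavailable.
    """
    x = np.asarray(normalized, dtype=float)
    if x.size < 3:
        return StabilityReport(
            normalized=x,
            std_percent=None,
            drift_percent_per_frame=None,
            drift_percent_per_min=None,
            in_band_fraction=None,
            band_halfwidth=band_halfwidth,
            metrics_available=False,
            note="fewer than 3 points",
        )
    std_percent = float(np.std(x, ddof=1) * 100.0)
    frames = np.arange(x.size, dtype=float)
    slope = np.polyfit(frames, x, 1)[0]
    drift_frame = float(slope * 100.0)
    drift_min = None
    if timestamps_s is not None:
        t_min = np.asarray(timestamps_s, dtype=float) / 60.0
        drift_min = float(np.polyfit(t_min, x, 1)[0] * 100.0)
    in_band = float(np.mean(np.abs(x - 1.0) <= band_halfwidth))
    return StabilityReport(
        normalized=x,
        std_percent=std_percent,
        drift_percent_per_frame=drift_frame,
        drift_percent_per_min=drift_min,
        in_band_fraction=in_band,
        band_halfwidth=band_halfwidth,
        metrics_available=True,
    )


def fit_bleaching(
    intensities: Sequence[float], timestamps: Optional[Sequence[float]] = None
) -> BleachFit:
    """Fit an exponential-with-offset bleaching model.

    I(t) = A exp(-k t) + B by least squares; the total relative drop is
    100 * (I_fit(t0) - I_fit(t_end)) / I_fit(t0).  If the fit does not
    converge the raw first-versus-last drop is reported with
    ``converged=False``.  ``timestamps`` defaults to the frame index.
    """
    y = np.asarray(intensities, dtype=float)
    if y.size < 5:
        raise ValueError("bleaching fit needs at least 5 points")
    t = (
        np.arange(y.size, dtype=float)
        if timestamps is None
        else np.asarray(timestamps, dtype=float)
    )
    t = t - t[0]
    span = t[-1] if t[-1] > 0 else 1.0

    def model(tt, a, k, b):
        return a * np.exp(-k * tt) + b

    a0 = max(y[0] - y[-1], 1e-12 * max(abs(y[0]), 1.0))
    p0 = (a0, 1.0 / span, y[-1])
    try:
        popt, _ = curve_fit(
            model,
            t,
            y,
            p0=p0,
            bounds=([-np.inf, 0.0, -np.inf], [np.inf, np.inf, np.inf]),
            maxfev=20000,
        )
        a, k, b = (float(v) for v in popt)
        i_start = model(t[0], a, k, b)
        i_end = model(t[-1], a, k, b)
        if i_start <= 0:
            raise RuntimeError("non-physical fit")
        # amplitude indistinguishable from zero -> no bleaching, rate moot
        if abs(a) <= 1e-9 * max(abs(b), 1e-300):
            return BleachFit(0.0, 0.0, b, 0.0, True)
        drop = 100.0 * (i_start - i_end) / i_start
        return BleachFit(drop, k, b, a, True)
    except (RuntimeError, ValueError):
        drop = 100.0 * (y[0] - y[-1]) / y[0] if y[0] > 0 else float("nan")
        return BleachFit(drop, float("nan"), float("nan"), float("nan"), False)
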