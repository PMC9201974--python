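"""Spectral analysis for NIR dye characterization.

Covers straight-line background subtraction of extinction spectra,
sub-sample peak localization, long-pass band intensity, detection of
the concentration where fluorescence departs from linearity
(inner-filter/reabsorption saturation), and equivalent-concentration
lookup against a calibration curve of another dye.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np


@dataclass
class Spectrum:
    """Wavelength-value curve (extinction, absorbance or fluorescence)."""

    wavelength_nm: np.ndarray
    values: np.ndarray
    kind: str = "fluorescence"  # fluorescence | absorbance | extinction
    excitation_nm: Optional[float] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.wavelength_nm = np.asarray(self.wavelength_nm, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.wavelength_nm.shape != self.values.shape:
            raise ValueError("wavelengths and values must have equal length")
        if np.any(np.diff(self.wavelength_nm) <= 0):
            raise ValueError("wavelengths must be strictly increasing")
        if self.kind == "fluorescence" and self.excitation_nm is None:
            self.excitation_nm = 740.0


@dataclass
class ConcentrationSeries:
    """Dye-concentration response: intensity (or spectrum) per concentration."""

    concentrations: np.ndarray
    intensities: np.ndarray
    unit: str = "ug/g"
    spectra: Optional[List[Spectrum]] = None

    def __post_init__(self) -> None:
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.concentrations.shape != self.intensities.shape:
            raise ValueError("one intensity per concentration required")
        if np.any(np.diff(self.concentrations) <= 0):
            raise ValueError("concentrations must be strictly increasing")


@dataclass
class LinearityResult:
    slope: float
    onset: Optional[float]
    rel_threshold: float
    deviations: np.ndarray
    monotone: bool
    unit: str = "ug/g"


@dataclass
class PeakResult:
    wavelength_nm: float
    at_boundary: bool


@dataclass
class BackgroundFit:
    slope: float
    intercept: float
    corrected: Spectrum
    anchor_warning: bool = False


def fit_linear_background(
    spectrum: Spectrum,
    anchor_windows: Sequence[Tuple[float, float]],
    clip_negative: bool = False,
) -> BackgroundFit:
    """Subtract a straight-line background anchored outside the dye band.

    A least-squares line is fitted through the samples falling in the
    anchor windows (>= 2 non-overlapping windows, each with >= 2
    samples) and subtracted.  If any window's mean residual from the
    line exceeds 3 sigma of the anchor residuals, the line model is
    suspect (anchors probably sit on the dye band) and
    ``anchor_warning`` is set.
    """
    if len(anchor_windows) < 2:
        raise ValueError("need at least 2 anchor windows")
    windows = sorted((float(a), float(b)) for a, b in anchor_windows)
    for (a1, b1), (a2, b2) in zip(windows, windows[1:]):
        if b1 > a2:
            raise ValueError("anchor windows must not overlap")
    wl = spectrum.wavelength_nm
    vals = spectrum.values
    masks = []
    for lo, hi in windows:
        if hi <= lo:
            raise ValueError("anchor window bounds must satisfy lo < hi")
        m = (wl >= lo) & (wl <= hi)
        if m.sum() < 2:
            raise ValueError(f"anchor window ({lo}, {hi}) holds < 2 samples")
        masks.append(m)
    anchor = np.logical_or.reduce(masks)

    slope, intercept = np.polyfit(wl[anchor], vals[anchor], 1)
    line = slope * wl + intercept
    # the line-model check must not let an offending window inflate its
    # own tolerance: pool the residual scatter after centring each
    # window, then compare the window mean offsets against it
    window_means = []
    centred = []
    for m in masks:
        r = vals[m] - line[m]
        window_means.append(r.mean())
        centred.append(r - r.mean())
    sigma = np.concatenate(centred).std(ddof=1)
    warning = bool(sigma > 0 and any(abs(mu) > 3.0 * sigma for mu in window_means))
    corrected_vals = vals - line
    if clip_negative:
        corrected_vals = np.clip(corrected_vals, 0.0, None)
    corrected = Spectrum(
        wavelength_nm=wl.copy(),
        values=corrected_vals,
        kind=spectrum.kind,
        excitation_nm=spectrum.excitation_nm,
        meta={**spectrum.meta, "background": {"slope": float(slope), "intercept": float(intercept)}},
    )
    return BackgroundFit(float(slope), float(intercept), corrected, warning)


def peak_wavelength(spectrum: Spectrum) -> PeakResult:
    """Sub-sample peak position via parabolic interpolation.

    Fits a parabola through the maximum sample and its two neighbours;
    if the maximum sits on a boundary, the boundary wavelength is
    returned with ``at_boundary=True``.  Ties go to the shortest
    wavelength.
    """
    v = spectrum.values
    wl = spectrum.wavelength_nm
    i = int(np.argmax(v))
    if i == 0 or i == len(v) - 1:
        return PeakResult(float(wl[i]), True)
    y0, y1, y2 = v[i - 1], v[i], v[i + 1]
    denom = y0 - 2.0 * y1 + y2
    if denom >= 0:
        return PeakResult(float(wl[i]), False)
    delta = 0.5 * (y0 - y2) / denom
    step = 0.5 * (wl[i + 1] - wl[i - 1])
    return PeakResult(float(wl[i] + delta * step), False)


def band_intensity(spectrum: Spectrum, cut_on_nm: float) -> float:
    """Trapezoidal integral of the spectrum above a long-pass cut-on.

    The integration starts exactly at the cut-on wavelength (value
    linearly interpolated there), emulating an ideal long-pass filter.
    """
    wl = spectrum.wavelength_nm
    v = spectrum.values
    if cut_on_nm < wl[0] or cut_on_nm > wl[-1]:
        raise ValueError("cut-on wavelength outside the spectral range")
    if cut_on_nm == wl[-1]:
        return 0.0
    v_cut = float(np.interp(cut_on_nm, wl, v))
    sel = wl > cut_on_nm
    xs = np.concatenate(([cut_on_nm], wl[sel]))
    ys = np.concatenate(([v_cut], v[sel]))
    return float(np.trapezoid(ys, xs))


def linearity_onset(
    series: ConcentrationSeries,
    n_ref_points: int = 2,
    rel_threshold: float = 0.05,
) -> LinearityResult:
    """Concentration where the intensity departs from linearity.

    A reference slope is fitted through the origin on the lowest
    ``n_ref_points`` concentrations (zero dye gives zero fluorescence);
    the onset is the smallest concentration whose intensity deviates
    from ``slope * c`` by more than ``rel_threshold`` (relative), or
    None if no point exceeds it.
    """
    c = series.concentrations
    y = series.intensities
    if n_ref_points < 2:
        raise ValueError("n_ref_points must be >= 2")
    if len(c) < n_ref_points + 1:
        raise ValueError("need at least n_ref_points + 1 concentrations")
    cr, yr = c[:n_ref_points], y[:n_ref_points]
    slope = float(np.sum(cr * yr) / np.sum(cr * cr))
    if slope <= 0:
        raise ValueError("reference slope is not positive")
    expected = slope * c
    deviations = np.abs(y - expected) / expected
    exceed = np.nonzero(deviations > rel_threshold)[0]
    onset = float(c[exceed[0]]) if exceed.size else None
    monotone = bool(np.all(np.diff(y) > 0))
    return LinearityResult(
        slope=slope,
        onset=onset,
        rel_threshold=rel_threshold,
        deviations=deviations,
        monotone=monotone,
        unit=series.unit,
    )


def equivalent_concentration(
    query_intensity: float, calibration: ConcentrationSeries
) -> float:
    """Invert a monotone calibration curve at a query intensity.

    Piecewise-linear interpolation of concentration versus intensity;
    the calibration intensities must be strictly increasing and
    extrapolation outside the calibrated range is refused.
    """
    c = calibration.concentrations
    y = calibration.intensities
    if np.any(np.diff(y) <= 0):
        raise ValueError("calibration intensities must be strictly increasing")
    if not y[0] <= query_intensity <= y[-1]:
        raise ValueError("query intensity outside the calibration range")
    return float(np.interp(query_intensity, y, c))
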