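"""Core domain types shared across the package.

Units follow diffuse-optics convention: lengths in cm, times in ps,
optical coefficients in 1/cm, lateral scan positions in mm, wavelengths
in nm.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

#: vacuum speed of light, cm/ps
C0_CM_PER_PS = 0.0299792458


@dataclass(frozen=True)
class OpticalProperties:
    """Bulk optical properties of a homogeneous turbid medium.

    Parameters
    ----------
    mu_a : float
        Absorption coefficient, 1/cm.
    mu_sp : float
        Reduced scattering coefficient ``mu_s * (1 - g)``, 1/cm.
    g : float
        Scattering anisotropy (mean cosine of the single-scattering
        deflection angle), in [0, 1).
    n_in : float
        Refractive index of the medium.  The photon speed inside the
        medium is ``c0 / n_in``.
    n_out : float
        Refractive index of the surroundings.
    """

    mu_a: float
    mu_sp: float
    g: float = 0.0
    n_in: float = 1.54
    n_out: float = 1.0

    def __post_init__(self) -> None:
        if self.mu_a < 0:
            raise ValueError(f"mu_a must be >= 0, got {self.mu_a}")
        if self.mu_sp <= 0:
            raise ValueError(f"mu_sp must be > 0, got {self.mu_sp}")
        if not 0.0 <= self.g < 1.0:
            raise ValueError(f"g must be in [0, 1), got {self.g}")
        if self.n_in < 1.0 or self.n_out < 1.0:
            raise ValueError("refractive indices must be >= 1")
        if not math.isfinite(self.mu_s):
            raise ValueError("mu_s = mu_sp/(1-g) is not finite")

    @property
    def mu_s(self) -> float:
        """Scattering coefficient mu_sp / (1 - g), 1/cm."""
        return self.mu_sp / (1.0 - self.g)

    @property
    def c_medium(self) -> float:
        """Speed of light in the medium, cm/ps."""
        return C0_CM_PER_PS / self.n_in

    def with_mu_a(self, mu_a: float) -> "OpticalProperties":
        return replace(self, mu_a=mu_a)


@dataclass(frozen=True)
class SlabGeometry:
    """Slab sample with pencil-beam source and coaxial disc detector.

    The source is a pencil beam at normal incidence on the entry face
    (origin).  The detector is a disc on the exit face, coaxial with the
    beam, with a given radius and acceptance half-angle (measured
    outside the medium).  ``lateral_radius_cm = None`` means laterally
    unbounded (infinite slab).
    """

    thickness_cm: float
    detector_radius_cm: float = 0.25
    acceptance_deg: float = 90.0
    lateral_radius_cm: Optional[float] = None

    def __post_init__(self) -> None:
        if self.thickness_cm <= 0:
            raise ValueError("thickness must be > 0")
        if self.detector_radius_cm <= 0:
            raise ValueError("detector radius must be > 0")
        if not 0.0 < self.acceptance_deg <= 90.0:
            raise ValueError("acceptance half-angle must be in (0, 90]")
        if self.lateral_radius_cm is not None and self.lateral_radius_cm <= 0:
            raise ValueError("lateral radius must be > 0 or None")


@dataclass(frozen=True)
class RandomStream:
    """Counter-based random stream identifier.

    The same ``(seed, substream)`` pair reproduces the same photon
    trajectories bit for bit, independent of execution order.
    """

    seed: int
    substream: int = 0

    def child(self, k: int) -> "RandomStream":
        """Derive substream ``k`` offsets from this stream."""
        return RandomStream(self.seed, self.substream + k)

    def numpy_rng(self) -> np.random.Generator:
        """A numpy Generator keyed by (seed, substream)."""
        return np.random.default_rng(
            np.random.SeedSequence(entropy=self.seed, spawn_key=(self.substream,))
        )


@dataclass
class DTOF:
    """Distribution of times of flight of photons (a.k.a. TPSF).

    Attributes
    ----------
    bin_edges_ps : ndarray
        Strictly increasing, uniform-width time-bin edges, ps.
    values : ndarray
        Per-bin detected photon weight or counts, >= 0.
    kind : str
        One of ``white``, ``absorbing``, ``measured``, ``synthetic``.
        ``white`` marks a zero-absorption curve to which analytic
        absorption scaling may still be applied.
    """

    bin_edges_ps: np.ndarray
    values: np.ndarray
    kind: str = "measured"
    wavelength_nm: Optional[float] = None
    position_mm: Optional[tuple] = None
    n_photons: Optional[int] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.bin_edges_ps = np.asarray(self.bin_edges_ps, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape[0] != self.bin_edges_ps.shape[0] - 1:
            raise ValueError("len(values) must equal len(bin_edges) - 1")
        widths = np.diff(self.bin_edges_ps)
        if np.any(widths <= 0):
            raise ValueError("bin edges must be strictly increasing")
        if not np.allclose(widths, widths[0], rtol=1e-9):
            raise ValueError("bin widths must be uniform")
        if np.any(self.values < 0):
            raise ValueError("DTOF values must be >= 0")
        if self.kind not in ("white", "absorbing", "measured", "synthetic"):
            raise ValueError(f"unknown DTOF kind {self.kind!r}")

    @property
    def bin_centers_ps(self) -> np.ndarray:
        return 0.5 * (self.bin_edges_ps[:-1] + self.bin_edges_ps[1:])

    @property
    def bin_width_ps(self) -> float:
        return float(self.bin_edges_ps[1] - self.bin_edges_ps[0])

    @property
    def total(self) -> float:
        """Total detected weight (sum of bin values)."""
        return float(self.values.sum())

    @property
    def integral(self) -> float:
        """Time integral, sum(values) * bin width (weight * ps)."""
        return self.total * self.bin_width_ps

    def replace_values(self, values: np.ndarray, kind: Optional[str] = None) -> "DTOF":
        """Copy with new values (and optionally a new kind flag)."""
        return DTOF(
            bin_edges_ps=self.bin_edges_ps.copy(),
            values=np.asarray(values, dtype=float),
            kind=self.kind if kind is None else kind,
            wavelength_nm=self.wavelength_nm,
            position_mm=self.position_mm,
            n_photons=self.n_photons,
            meta=dict(self.meta),
        )

    def rebin(self, factor: int) -> "DTOF":
        """Merge ``factor`` adjacent bins (trailing remainder dropped)."""
        if factor < 1:
            raise ValueError("rebin factor must be >= 1")
        n = (len(self.values) // factor) * factor
        vals = self.values[:n].reshape(-1, factor).sum(axis=1)
        edges = self.bin_edges_ps[: n + 1 : factor]
        return DTOF(
            bin_edges_ps=edges,
            values=vals,
            kind=self.kind,
            wavelength_nm=self.wavelength_nm,
            position_mm=self.position_mm,
            n_photons=self.n_photons,
            meta=dict(self.meta),
        )


@dataclass
class IRF:
    """Instrument response function, normalized to unit area.

    Either parametric (Gaussian of given FWHM, in ps) or a sampled
    curve on a DTOF time axis.  ``IRF.delta()`` gives an ideal
    instrument.
    """

    fwhm_ps: Optional[float] = None
    curve_times_ps: Optional[np.ndarray] = None
    curve_values: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if self.fwhm_ps is None and self.curve_values is None:
            raise ValueError("IRF needs either fwhm_ps or a sampled curve")
        if self.curve_values is not None:
            self.curve_times_ps = np.asarray(self.curve_times_ps, dtype=float)
            self.curve_values = np.asarray(self.curve_values, dtype=float)
            if np.any(self.curve_values < 0):
                raise ValueError("IRF curve must be nonnegative")
            s = self.curve_values.sum()
            if s <= 0:
                raise ValueError("IRF curve must have positive area")
            self.curve_values = self.curve_values / s
        elif self.fwhm_ps is not None and self.fwhm_ps < 0:
            raise ValueError("fwhm_ps must be >= 0")

    @classmethod
    def delta(cls) -> "IRF":
        """Ideal instrument (identity convolution)."""
        return cls(fwhm_ps=0.0)

    @classmethod
    def gaussian(cls, fwhm_ps: float) -> "IRF":
        return cls(fwhm_ps=fwhm_ps)

    def kernel(self, bin_width_ps: float) -> np.ndarray:
        """Discrete unit-sum kernel on a grid of the given bin width.

        The kernel is symmetric about its centre sample; convolving
        with it leaves the time origin of the DTOF unchanged up to the
        instrument blur.
        """
        if self.curve_values is not None:
            return self.curve_values.copy()
        sigma = self.fwhm_ps / (2.0 * math.sqrt(2.0 * math.log(2.0)))
        if sigma < 1e-12 or sigma < 1e-3 * bin_width_ps:
            return np.array([1.0])
        half = max(1, int(math.ceil(4.0 * sigma / bin_width_ps)))
        t = np.arange(-half, half + 1) * bin_width_ps
        k = np.exp(-0.5 * (t / sigma) ** 2)
        return k / k.sum()
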