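"""Lookup-table inversion of DTOFs to optical properties.

The forward model for a measured DTOF is

    model(t; mu_sp, mu_a, A) = A * IRF (*) [ white(t; mu_sp) * exp(-mu_a * cM * t) ]

where ``white`` is a zero-absorption ("white") DTOF taken from a
precomputed lookup table over a grid of reduced scattering values,
absorption is applied analytically (microscopic Beer-Lambert at the
speed of light in the medium), the instrument response is applied by
causal discrete convolution, and A is a free positive amplitude.

Fitting minimizes a Poisson-weighted chi-square on a window spanning
the leading edge (default 80% of peak) to the tail (default 1% of
peak).  The reduced-scattering optimum is refined off-grid by parabolic
interpolation of the chi-square profile through the three best nodes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np
from scipy.optimize import minimize_scalar

from .datatypes import C0_CM_PER_PS, DTOF, IRF, RandomStream, SlabGeometry
from .transport import diffusion_slab_dtof, simulate_white_dtof
from .datatypes import OpticalProperties


@dataclass
class WhiteLUT:
    """Grid of white (zero-absorption) DTOFs indexed by mu_sp.

    All entries share a common time axis.  ``provenance`` records how
    the table was built (geometry, refractive index, photons per entry,
    seed, engine).
    """

    mu_sp_grid: np.ndarray
    dtofs: list  # list[DTOF], white-kind, common bin edges
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.mu_sp_grid = np.asarray(self.mu_sp_grid, dtype=float)
        if len(self.dtofs) != len(self.mu_sp_grid):
            raise ValueError("one DTOF required per grid value")
        if np.any(np.diff(self.mu_sp_grid) <= 0):
            raise ValueError("mu_sp grid must be strictly increasing")
        edges = self.dtofs[0].bin_edges_ps
        for d in self.dtofs:
            if d.kind != "white":
                raise ValueError("LUT entries must be white-kind DTOFs")
            if not np.array_equal(d.bin_edges_ps, edges):
                raise ValueError("LUT entries must share a common time axis")

    @property
    def bin_edges_ps(self) -> np.ndarray:
        return self.dtofs[0].bin_edges_ps

    @property
    def n_in(self) -> float:
        return float(self.provenance.get("n_in", 1.54))

    def rebin(self, factor: int) -> "WhiteLUT":
        return WhiteLUT(
            mu_sp_grid=self.mu_sp_grid.copy(),
            dtofs=[d.rebin(factor) for d in self.dtofs],
            provenance=dict(self.provenance),
        )


@dataclass
class FitConfig:
    """Fit-window and bound settings for :func:`fit_dtof`.

    The window opens on the leading edge where the DTOF last falls at
    or below ``rise_fraction`` of the peak and closes on the trailing
    edge where it first falls to ``tail_fraction`` of the peak.
    """

    rise_fraction: float = 0.80
    tail_fraction: float = 0.01
    mu_a_min: float = 0.0
    mu_a_max: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 < self.tail_fraction < self.rise_fraction <= 1.0:
            raise ValueError("require 0 < tail_fraction < rise_fraction <= 1")
        if self.mu_a_min < 0 or self.mu_a_max <= self.mu_a_min:
            raise ValueError("require 0 <= mu_a_min < mu_a_max")


@dataclass
class FitResult:
    mu_sp: float
    mu_a: float
    amplitude: float
    chi2_reduced: float
    window: Tuple[int, int]
    converged: bool
    grid_index: int = 0
    low_counts: bool = False


def build_lut(
    grid_min: float = 0.1,
    grid_max: float = 20.0,
    grid_step: float = 0.1,
    geom: SlabGeometry = SlabGeometry(thickness_cm=2.0),
    n_photons: int = 100_000,
    bin_width_ps: float = 10.0,
    t_max_ps: float = 6000.0,
    stream: RandomStream = RandomStream(0),
    n_in: float = 1.54,
    n_out: float = 1.0,
    engine: str = "mc",
) -> WhiteLUT:
    """Build a white lookup table over a uniform mu_sp grid.

    ``engine='mc'`` runs the white Monte Carlo per grid node (each node
    on its own RNG substream); ``engine='diffusion'`` evaluates the
    closed-form diffusion transmittance instead — noise-free and fast,
    appropriate when the data to invert come from the same diffusive
    forward family.
    """
    if grid_min <= 0 or grid_step <= 0:
        raise ValueError("grid_min and grid_step must be > 0")
    n = int(round((grid_max - grid_min) / grid_step)) + 1
    grid = grid_min + grid_step * np.arange(n)
    grid = grid[grid <= grid_max + 1e-9]
    if np.any(np.diff(grid) <= 0):
        raise ValueError("grid must be strictly increasing")

    dtofs = []
    for k, mu_sp in enumerate(grid):
        props = OpticalProperties(mu_a=0.0, mu_sp=float(mu_sp), n_in=n_in, n_out=n_out)
        if engine == "mc":
            d = simulate_white_dtof(
                props, geom, n_photons, bin_width_ps, t_max_ps, stream.child(k)
            )
        elif engine == "diffusion":
            d = diffusion_slab_dtof(props, geom, bin_width_ps, t_max_ps)
        else:
            raise ValueError(f"unknown engine {engine!r}")
        dtofs.append(d)

    return WhiteLUT(
        mu_sp_grid=grid,
        dtofs=dtofs,
        provenance={
            "engine": engine,
            "thickness_cm": geom.thickness_cm,
            "detector_radius_cm": geom.detector_radius_cm,
            "n_in": n_in,
            "n_out": n_out,
            "photons_per_entry": n_photons if engine == "mc" else 0,
            "seed": stream.seed,
            "substream": stream.substream,
            "bin_width_ps": bin_width_ps,
            "t_max_ps": t_max_ps,
        },
    )


def apply_absorption(dtof: DTOF, mu_a: float, n_in: Optional[float] = None) -> DTOF:
    """Scale a white DTOF by the microscopic Beer-Lambert factor.

    Multiplies each bin by exp(-mu_a * cM * t_center) with
    cM = c0 / n_in; the result is flagged absorbing so it cannot be
    attenuated twice by accident.
    """
    if dtof.kind != "white":
        raise ValueError("apply_absorption requires a white-kind DTOF")
    if mu_a < 0:
        raise ValueError("mu_a must be >= 0")
    if n_in is None:
        n_in = float(dtof.meta.get("n_in", 1.54))
    c_m = C0_CM_PER_PS / n_in
    factor = np.exp(-mu_a * c_m * dtof.bin_centers_ps)
    out = dtof.replace_values(dtof.values * factor, kind="absorbing")
    out.meta["applied_mu_a"] = mu_a
    return out


def convolve_irf(dtof: DTOF, irf: IRF) -> DTOF:
    """Convolve a DTOF with the instrument response.

    Discrete convolution with the unit-sum IRF kernel on the DTOF bin
    grid; total weight is preserved as long as the blurred curve stays
    within the time axis.  Sets ``meta['irf_truncated']`` when the
    kernel support exceeds the DTOF support.
    """
    kernel = irf.kernel(dtof.bin_width_ps)
    if len(kernel) == 1:
        return dtof.replace_values(dtof.values.copy())
    half = len(kernel) // 2
    full = np.convolve(dtof.values, kernel)
    out_vals = full[half : half + len(dtof.values)]
    out = dtof.replace_values(out_vals)
    if len(kernel) > len(dtof.values):
        out.meta["irf_truncated"] = True
    lost = full[:half].sum() + full[half + len(dtof.values) :].sum()
    if dtof.values.sum() > 0 and lost / dtof.values.sum() > 1e-9:
        out.meta["edge_loss"] = float(lost)
    return out


def select_fit_range(dtof: DTOF, cfg: FitConfig = FitConfig()) -> Tuple[int, int]:
    """Fit window (start, stop) bin indices, inclusive of start, exclusive of stop.

    Opens at the last leading-edge bin at or below
    ``rise_fraction * peak`` (or the peak itself if the curve never
    dips below) and closes after the first trailing-edge bin at or
    below ``tail_fraction * peak`` (or the last bin).
    """
    v = dtof.values
    if not np.any(v > 0):
        raise ValueError("cannot select a fit range on an all-zero DTOF")
    peak_idx = int(np.argmax(v))  # argmax breaks ties to the earliest bin
    peak = v[peak_idx]

    start = peak_idx
    for i in range(peak_idx, -1, -1):
        if v[i] <= cfg.rise_fraction * peak:
            start = i
            break
    else:
        start = 0

    stop = len(v)
    for j in range(peak_idx, len(v)):
        if v[j] <= cfg.tail_fraction * peak:
            stop = j + 1
            break

    if stop - start < 3:
        raise ValueError("fit window is degenerate (fewer than 3 bins)")
    return start, stop


def _chi2_at_node(
    data: np.ndarray,
    weights: np.ndarray,
    entry: DTOF,
    irf: IRF,
    cfg: FitConfig,
    window: Tuple[int, int],
    n_in: float,
):
    """Optimal (chi2, mu_a, amplitude) for one LUT node.

    Amplitude is solved in closed form per mu_a candidate; mu_a is
    optimized by bounded scalar minimization.
    """
    s, e = window
    d = data[s:e]
    w = weights[s:e]

    def chi2_of_mu_a(mu_a):
        m = convolve_irf(apply_absorption(entry, mu_a, n_in), irf).values[s:e]
        denom = np.sum(w * m * m)
        if denom <= 0:
            return np.inf, 0.0
        amp = max(np.sum(w * m * d) / denom, 0.0)
        r = d - amp * m
        return float(np.sum(w * r * r)), amp

    res = minimize_scalar(
        lambda x: chi2_of_mu_a(x)[0],
        bounds=(cfg.mu_a_min, cfg.mu_a_max),
        method="bounded",
        options={"xatol": 1e-6},
    )
    chi2, amp = chi2_of_mu_a(res.x)
    return chi2, float(res.x), amp


def fit_dtof(
    measured: DTOF,
    lut: WhiteLUT,
    irf: IRF = IRF.gaussian(35.0),
    cfg: FitConfig = FitConfig(),
) -> FitResult:
    """Invert a measured DTOF to (mu_sp, mu_a, amplitude).

    Scans the white LUT; at each node the absorption coefficient and a
    free amplitude are fitted by Poisson-weighted least squares
    (weights 1/max(counts, 1)) inside the fit window.  The reported
    mu_sp is refined by parabolic interpolation of the chi-square
    profile across the best node and its neighbours; mu_a and amplitude
    are re-fitted by linear interpolation of the neighbouring node
    solutions at the refined mu_sp.  ``converged`` is False when the
    optimum sits on the grid boundary.
    """
    edges = lut.bin_edges_ps
    if measured.bin_edges_ps.shape != edges.shape or not np.allclose(
        measured.bin_edges_ps, edges
    ):
        # integer rebin of the measurement onto the LUT axis if widths allow
        ratio = lut.dtofs[0].bin_width_ps / measured.bin_width_ps
        if abs(ratio - round(ratio)) < 1e-9 and round(ratio) >= 1:
            measured = measured.rebin(int(round(ratio)))
            if measured.values.shape[0] > lut.dtofs[0].values.shape[0]:
                measured = DTOF(
                    bin_edges_ps=edges,
                    values=measured.values[: len(edges) - 1],
                    kind=measured.kind,
                    meta=dict(measured.meta),
                )
        if measured.bin_edges_ps.shape != edges.shape or not np.allclose(
            measured.bin_edges_ps, edges
        ):
            raise ValueError("measured time axis incompatible with LUT axis")

    data = measured.values
    weights = 1.0 / np.maximum(data, 1.0)
    window = select_fit_range(measured, cfg)
    s, e = window
    low_counts = data[s:e].sum() < 1000

    n_in = lut.n_in
    chi2s = np.full(len(lut.mu_sp_grid), np.inf)
    mu_as = np.zeros(len(lut.mu_sp_grid))
    amps = np.zeros(len(lut.mu_sp_grid))
    for k, entry in enumerate(lut.dtofs):
        chi2s[k], mu_as[k], amps[k] = _chi2_at_node(
            data, weights, entry, irf, cfg, window, n_in
        )

    k0 = int(np.argmin(chi2s))
    converged = 0 < k0 < len(chi2s) - 1

    mu_sp = float(lut.mu_sp_grid[k0])
    mu_a = float(mu_as[k0])
    amp = float(amps[k0])
    if converged:
        # parabolic refinement of the chi2 profile through the 3 best nodes
        x = lut.mu_sp_grid[k0 - 1 : k0 + 2]
        y = chi2s[k0 - 1 : k0 + 2]
        denom = (y[0] - 2.0 * y[1] + y[2])
        if denom > 0:
            delta = 0.5 * (y[0] - y[2]) / denom
            delta = float(np.clip(delta, -1.0, 1.0))
            mu_sp = float(x[1] + delta * (x[1] - x[0]))
            if delta > 0:
                mu_a = float((1 - delta) * mu_as[k0] + delta * mu_as[k0 + 1])
                amp = float((1 - delta) * amps[k0] + delta * amps[k0 + 1])
            else:
                mu_a = float((1 + delta) * mu_as[k0] - delta * mu_as[k0 - 1])
                amp = float((1 + delta) * amps[k0] - delta * amps[k0 - 1])

    dof = max((e - s) - 3, 1)
    return FitResult(
        mu_sp=mu_sp,
        mu_a=mu_a,
        amplitude=amp,
        chi2_reduced=float(chi2s[k0] / dof),
        window=window,
        converged=converged,
        grid_index=k0,
        low_counts=bool(low_counts),
    )
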