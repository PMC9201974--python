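"""Homogeneity mapping of scan-grid DTOF datasets.

A phantom disc is scanned on a regular lateral lattice; at each
position one DTOF is recorded per spectral band (excitation through a
short-pass filter, fluorescence through a long-pass filter).  The maps
produced here are (a) normalized DTOF time-integrals and (b) per-
position inverted optical properties, with edge masking and central-
region deviation statistics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np

from .datatypes import DTOF, IRF
from .inversion import FitConfig, WhiteLUT, fit_dtof


@dataclass
class ScanGrid:
    """Regular-lattice scan of DTOFs over a disc phantom.

    ``data`` maps lattice position (x_mm, y_mm) to a dict of band-name
    -> DTOF.  Positions are multiples of ``step_mm`` relative to the
    outline centre.  Every present position must carry the same bands.
    """

    step_mm: float
    data: Dict[Tuple[float, float], Dict[str, DTOF]]
    outline_center_mm: Tuple[float, float] = (0.0, 0.0)
    outline_radius_mm: float = 40.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.step_mm <= 0:
            raise ValueError("lattice step must be > 0")
        if not self.data:
            raise ValueError("scan grid is empty")
        bands = None
        for pos, per_band in self.data.items():
            b = frozenset(per_band)
            if bands is None:
                bands = b
            elif b != bands:
                raise ValueError(f"position {pos} has bands {set(b)} != {set(bands)}")

    @property
    def bands(self):
        first = next(iter(self.data.values()))
        return sorted(first)

    def lattice(self):
        """Sorted unique x and y coordinates (mm)."""
        xs = sorted({p[0] for p in self.data})
        ys = sorted({p[1] for p in self.data})
        return np.array(xs), np.array(ys)


@dataclass
class PropertyMap:
    """Scalar lattice map aligned to a scan grid.

    ``values`` is (ny, nx) with NaN at invalid cells; ``valid`` marks
    cells holding a value; ``edge_mm`` is the distance from each cell
    to the phantom outline (negative outside).  ``norm_reference``
    records the normalization applied, if any.
    """

    xs_mm: np.ndarray
    ys_mm: np.ndarray
    values: np.ndarray
    valid: np.ndarray
    edge_mm: np.ndarray
    edge_margin_mm: float = 10.0
    norm_reference: Optional[dict] = None

    def central_mask(self, edge_margin_mm: Optional[float] = None) -> np.ndarray:
        margin = self.edge_margin_mm if edge_margin_mm is None else edge_margin_mm
        return self.valid & (self.edge_mm >= margin)


@dataclass
class CentralStats:
    mean: float
    max_rel_deviation: float
    rel_std: float
    extreme_position_mm: Tuple[float, float]
    n_cells: int


def _grid_arrays(scan: ScanGrid):
    xs, ys = scan.lattice()
    nx, ny = len(xs), len(ys)
    ix = {x: i for i, x in enumerate(xs)}
    iy = {y: j for j, y in enumerate(ys)}
    cx, cy = scan.outline_center_mm
    edge = np.full((ny, nx), -np.inf)
    for j, y in enumerate(ys):
        for i, x in enumerate(xs):
            edge[j, i] = scan.outline_radius_mm - math.hypot(x - cx, y - cy)
    return xs, ys, ix, iy, edge


def integral_map(
    scan: ScanGrid, band: str, edge_margin_mm: float = 10.0
) -> PropertyMap:
    """Normalized DTOF time-integral per scan position.

    Each position's DTOF is integrated over time and the map is divided
    by the maximum over the unmasked central region (cells at least
    ``edge_margin_mm`` inside the outline); the normalization reference
    is recorded in ``norm_reference``.
    """
    if band not in scan.bands:
        raise ValueError(f"band {band!r} not present (have {scan.bands})")
    xs, ys, ix, iy, edge = _grid_arrays(scan)
    values = np.full((len(ys), len(xs)), np.nan)
    valid = np.zeros_like(values, dtype=bool)
    for (x, y), per_band in scan.data.items():
        values[iy[y], ix[x]] = per_band[band].integral
        valid[iy[y], ix[x]] = True

    central = valid & (edge >= edge_margin_mm)
    if not central.any():
        raise ValueError("empty central region: edge margin excludes all cells")
    ref = float(np.nanmax(values[central]))
    if ref <= 0:
        raise ValueError("normalization reference is not positive")
    j, i = np.unravel_index(
        np.nanargmax(np.where(central, values, -np.inf)), values.shape
    )
    return PropertyMap(
        xs_mm=np.asarray(xs, dtype=float),
        ys_mm=np.asarray(ys, dtype=float),
        values=values / ref,
        valid=valid,
        edge_mm=edge,
        edge_margin_mm=edge_margin_mm,
        norm_reference={
            "kind": "central_max",
            "value": ref,
            "position_mm": (float(xs[i]), float(ys[j])),
            "band": band,
        },
    )


def property_map(
    scan: ScanGrid,
    lut: WhiteLUT,
    irf: IRF = IRF.gaussian(35.0),
    cfg: FitConfig = FitConfig(),
    band: str = "excitation",
    edge_margin_mm: float = 10.0,
):
    """Per-position inversion of the scan to (mu_a, mu_sp) maps.

    Runs :func:`phantomqc.inversion.fit_dtof` at every position of the
    requested band; non-converged positions are masked.  Returns
    ``(mu_a_map, mu_sp_map, report)`` where the report collects
    per-position warnings.
    """
    if band not in scan.bands:
        raise ValueError(f"band {band!r} not present (have {scan.bands})")
    xs, ys, ix, iy, edge = _grid_arrays(scan)
    shape = (len(ys), len(xs))
    mu_a = np.full(shape, np.nan)
    mu_sp = np.full(shape, np.nan)
    valid = np.zeros(shape, dtype=bool)
    report = {"low_counts": [], "not_converged": []}

    for (x, y), per_band in scan.data.items():
        fit = fit_dtof(per_band[band], lut, irf, cfg)
        if fit.low_counts:
            report["low_counts"].append((x, y))
        if not fit.converged:
            report["not_converged"].append((x, y))
            continue
        mu_a[iy[y], ix[x]] = fit.mu_a
        mu_sp[iy[y], ix[x]] = fit.mu_sp
        valid[iy[y], ix[x]] = True

    def mk(vals):
        return PropertyMap(
            xs_mm=np.asarray(xs, dtype=float),
            ys_mm=np.asarray(ys, dtype=float),
            values=vals,
            valid=valid.copy(),
            edge_mm=edge,
            edge_margin_mm=edge_margin_mm,
        )

    return mk(mu_a), mk(mu_sp), report


def central_stats(pmap: PropertyMap, edge_margin_mm: Optional[float] = None) -> CentralStats:
    """Deviation statistics over the central (edge-masked) region.

    Reports the maximum absolute relative deviation from the central
    mean, the relative standard deviation, and the lattice position of
    the extreme cell.
    """
    margin = pmap.edge_margin_mm if edge_margin_mm is None else edge_margin_mm
    if margin >= pmap.edge_mm.max():
        raise ValueError("edge margin excludes all cells")
    mask = pmap.central_mask(margin)
    if not mask.any():
        raise ValueError("edge margin excludes all cells")
    vals = pmap.values[mask]
    mean = float(vals.mean())
    if mean == 0:
        raise ValueError("central mean is zero")
    rel = (vals - mean) / mean
    k = int(np.argmax(np.abs(rel)))
    jj, ii = np.argwhere(mask)[k]
    rel_std = float(vals.std(ddof=1) / abs(mean)) if len(vals) > 1 else 0.0
    return CentralStats(
        mean=mean,
        max_rel_deviation=float(np.abs(rel).max()),
        rel_std=rel_std,
        extreme_position_mm=(float(pmap.xs_mm[ii]), float(pmap.ys_mm[jj])),
        n_cells=int(mask.sum()),
    )
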