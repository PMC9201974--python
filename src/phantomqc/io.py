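"""File formats: DTOF CSV + YAML sidecar, LUT HDF5, scan manifests,
TIFF stacks, spectra CSV, and report/plot export."""

from __future__ import annotations

import json
import math
from dataclasses import asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .datatypes import DTOF, SlabGeometry
from .imaging_qc import ImageSeries
from .inversion import FitResult, WhiteLUT
from .mapping import PropertyMap, ScanGrid
from .spectra import ConcentrationSeries, Spectrum


# ---------------------------------------------------------------- DTOF CSV

def write_dtof_csv(dtof: DTOF, path) -> Path:
    """Write `time_ps,value` rows (bin left edges) plus a YAML sidecar."""
    path = Path(path)
    df = pd.DataFrame({"time_ps": dtof.bin_edges_ps[:-1], "value": dtof.values})
    df.to_csv(path, index=False)
    sidecar = {
        "kind": dtof.kind,
        "bin_width_ps": dtof.bin_width_ps,
        "wavelength_nm": dtof.wavelength_nm,
        "position_mm": list(dtof.position_mm) if dtof.position_mm else None,
        "n_photons": dtof.n_photons,
        "meta": _plain(dtof.meta),
    }
    path.with_suffix(".yaml").write_text(yaml.safe_dump(sidecar, sort_keys=False))
    return path


def read_dtof_csv(path) -> DTOF:
    path = Path(path)
    df = pd.read_csv(path)
    left = df["time_ps"].to_numpy(dtype=float)
    width = left[1] - left[0] if len(left) > 1 else 1.0
    edges = np.append(left, left[-1] + width)
    kind = "measured"
    wavelength = None
    position = None
    n_photons = None
    meta = {}
    sidecar = path.with_suffix(".yaml")
    if sidecar.exists():
        info = yaml.safe_load(sidecar.read_text()) or {}
        kind = info.get("kind", kind)
        wavelength = info.get("wavelength_nm")
        pos = info.get("position_mm")
        position = tuple(pos) if pos else None
        n_photons = info.get("n_photons")
        meta = info.get("meta") or {}
    return DTOF(
        bin_edges_ps=edges,
        values=df["value"].to_numpy(dtype=float),
        kind=kind,
        wavelength_nm=wavelength,
        position_mm=position,
        n_photons=n_photons,
        meta=meta,
    )


# ---------------------------------------------------------------- LUT HDF5

def save_lut(lut: WhiteLUT, path) -> Path:
    import h5py

    path = Path(path)
    with h5py.File(path, "w") as f:
        f.create_dataset("mu_sp_grid", data=lut.mu_sp_grid)
        f.create_dataset("bin_edges_ps", data=lut.bin_edges_ps)
        f.create_dataset("dtofs", data=np.stack([d.values for d in lut.dtofs]))
        for key, val in lut.provenance.items():
            if val is not None:
                f.attrs[key] = val
    return path


def load_lut(path) -> WhiteLUT:
    import h5py

    with h5py.File(path, "r") as f:
        grid = f["mu_sp_grid"][:]
        edges = f["bin_edges_ps"][:]
        matrix = f["dtofs"][:]
        prov = {k: _h5attr(v) for k, v in f.attrs.items()}
    dtofs = [
        DTOF(bin_edges_ps=edges, values=row, kind="white", meta={"n_in": prov.get("n_in", 1.54)})
        for row in matrix
    ]
    return WhiteLUT(mu_sp_grid=grid, dtofs=dtofs, provenance=prov)


# ------------------------------------------------------------ scan manifest

def write_scan(scan: ScanGrid, directory) -> Path:
    """Write per-position DTOF CSVs plus a YAML manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    entries = []
    for (x, y), per_band in sorted(scan.data.items()):
        for band, dtof in sorted(per_band.items()):
            fname = f"dtof_x{x:+08.2f}_y{y:+08.2f}_{band}.csv"
            write_dtof_csv(dtof, directory / fname)
            entries.append({"x_mm": x, "y_mm": y, "band": band, "file": fname})
    manifest = {
        "step_mm": scan.step_mm,
        "outline_center_mm": list(scan.outline_center_mm),
        "outline_radius_mm": scan.outline_radius_mm,
        "meta": _plain(scan.meta),
        "entries": entries,
    }
    mpath = directory / "manifest.yaml"
    mpath.write_text(yaml.safe_dump(manifest, sort_keys=False))
    return mpath


def read_scan(manifest_path) -> ScanGrid:
    manifest_path = Path(manifest_path)
    manifest = yaml.safe_load(manifest_path.read_text())
    data: dict = {}
    for entry in manifest["entries"]:
        pos = (float(entry["x_mm"]), float(entry["y_mm"]))
        dtof = read_dtof_csv(manifest_path.parent / entry["file"])
        data.setdefault(pos, {})[entry["band"]] = dtof
    return ScanGrid(
        step_mm=float(manifest["step_mm"]),
        data=data,
        outline_center_mm=tuple(manifest["outline_center_mm"]),
        outline_radius_mm=float(manifest["outline_radius_mm"]),
        meta=manifest.get("meta") or {},
    )


# ------------------------------------------------------------- image stacks

def save_image_series(series: ImageSeries, path) -> Path:
    """16-bit multipage TIFF plus a YAML sidecar with timestamps."""
    import tifffile

    path = Path(path)
    stack = np.clip(np.round(series.frames), 0, 65535).astype(np.uint16)
    tifffile.imwrite(path, stack, photometric="minisblack")
    sidecar = {
        "timestamps_s": [float(t) for t in series.timestamps_s],
        "exposure_ms": series.exposure_ms,
        "pause_ms": series.pause_ms,
        "meta": _plain(series.meta),
    }
    path.with_suffix(".yaml").write_text(yaml.safe_dump(sidecar, sort_keys=False))
    return path


def load_image_series(path) -> ImageSeries:
    import tifffile

    path = Path(path)
    frames = tifffile.imread(path).astype(float)
    if frames.ndim == 2:
        frames = frames[None]
    sidecar = path.with_suffix(".yaml")
    if sidecar.exists():
        info = yaml.safe_load(sidecar.read_text()) or {}
        ts = np.asarray(info.get("timestamps_s", np.arange(frames.shape[0])), dtype=float)
        return ImageSeries(
            frames=frames,
            timestamps_s=ts,
            exposure_ms=info.get("exposure_ms", 200.0),
            pause_ms=info.get("pause_ms", 600.0),
            meta=info.get("meta") or {},
        )
    return ImageSeries(frames=frames, timestamps_s=np.arange(frames.shape[0], dtype=float))


# ------------------------------------------------------------------ spectra

def write_spectrum_csv(spectrum: Spectrum, path) -> Path:
    path = Path(path)
    pd.DataFrame(
        {"wavelength_nm": spectrum.wavelength_nm, "value": spectrum.values}
    ).to_csv(path, index=False)
    return path


def read_spectrum_csv(path, kind: str = "fluorescence", excitation_nm: Optional[float] = None) -> Spectrum:
    df = pd.read_csv(path)
    return Spectrum(
        wavelength_nm=df["wavelength_nm"].to_numpy(dtype=float),
        values=df["value"].to_numpy(dtype=float),
        kind=kind,
        excitation_nm=excitation_nm,
    )


def write_concentration_series_csv(series: ConcentrationSeries, path) -> Path:
    path = Path(path)
    pd.DataFrame(
        {"concentration": series.concentrations, "intensity": series.intensities}
    ).to_csv(path, index=False)
    path.with_suffix(".yaml").write_text(yaml.safe_dump({"unit": series.unit}))
    return path


def read_concentration_series_csv(path) -> ConcentrationSeries:
    path = Path(path)
    df = pd.read_csv(path)
    unit = "ug/g"
    sidecar = path.with_suffix(".yaml")
    if sidecar.exists():
        unit = (yaml.safe_load(sidecar.read_text()) or {}).get("unit", unit)
    return ConcentrationSeries(
        concentrations=df["concentration"].to_numpy(dtype=float),
        intensities=df["intensity"].to_numpy(dtype=float),
        unit=unit,
    )


# -------------------------------------------------------------- maps, fits

def write_map_csv(pmap: PropertyMap, path) -> Path:
    path = Path(path)
    df = pd.DataFrame(pmap.values, index=pmap.ys_mm, columns=pmap.xs_mm)
    df.index.name = "y_mm"
    df.to_csv(path)
    return path


def render_map_png(pmap: PropertyMap, path, title: str = "") -> Path:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    path = Path(path)
    fig, ax = plt.subplots(figsize=(5, 4))
    extent = [
        pmap.xs_mm[0],
        pmap.xs_mm[-1],
        pmap.ys_mm[0],
        pmap.ys_mm[-1],
    ]
    im = ax.imshow(pmap.values, origin="lower", extent=extent, cmap="viridis")
    fig.colorbar(im, ax=ax)
    ax.set_xlabel("x (mm)")
    ax.set_ylabel("y (mm)")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path


def write_fit_json(fit: FitResult, path) -> Path:
    path = Path(path)
    payload = asdict(fit)
    payload["window"] = list(payload["window"])
    path.write_text(json.dumps(payload, indent=2))
    return path


def _plain(obj):
    """Recursively convert numpy scalars/arrays for YAML/JSON dumping."""
    if isinstance(obj, dict):
        return {str(k): _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, float) and math.isnan(obj):
        return None
    return obj


def _h5attr(v):
    if isinstance(v, bytes):
        return v.decode()
    if isinstance(v, (np.floating, np.integer)):
        return v.item()
    return v
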