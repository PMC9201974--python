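"""Time-resolved light propagation through a homogeneous turbid slab.

Two forward models are provided:

* a photon-packet Monte Carlo simulator (:func:`simulate_white_dtof` at
  zero absorption — the "white" mode in which absorption is applied
  afterwards analytically — and :func:`simulate_absorbing_dtof` as the
  absorbing validation variant sharing the same trajectories), and
* a closed-form time-domain diffusion solution for the infinite slab
  with extrapolated-boundary image sources
  (:func:`diffusion_slab_dtof`), which serves as a noise-free oracle
  and as a fast generator backend.

Geometry: pencil beam at normal incidence on the entry face, coaxial
disc detector on the exit face.  All times in ps, lengths in cm.
"""

from __future__ import annotations

import math
from typing import Optional

import numpy as np
from scipy.integrate import quad

from ._mc import (
    DETECTED,
    REFLECTED,
    RESIDUAL,
    SIDE_LOSS,
    TRANSMITTED_MISSED,
    run_slab_mc,
)
from .datatypes import C0_CM_PER_PS, DTOF, OpticalProperties, RandomStream, SlabGeometry

_BUCKET_NAMES = {
    DETECTED: "detected",
    TRANSMITTED_MISSED: "transmitted_undetected",
    REFLECTED: "reflected",
    SIDE_LOSS: "side_loss",
    RESIDUAL: "residual",
}


def fresnel_reflectance(n_from: float, n_to: float, incidence_deg: float) -> float:
    """Unpolarized Fresnel reflectance at a planar interface.

    Parameters
    ----------
    n_from, n_to : float
        Refractive indices of the incidence and transmission media.
    incidence_deg : float
        Incidence angle from the surface normal, degrees, in [0, 90].

    Returns
    -------
    float
        Reflectance in [0, 1]; 1.0 beyond the critical angle (total
        internal reflection).
    """
    if not 0.0 <= incidence_deg <= 90.0:
        raise ValueError("incidence angle must be in [0, 90] degrees")
    if n_from == n_to:
        return 0.0
    theta = math.radians(incidence_deg)
    cos_i = math.cos(theta)
    sin_t2 = (n_from / n_to) ** 2 * (1.0 - cos_i**2)
    if sin_t2 >= 1.0:
        return 1.0
    cos_t = math.sqrt(1.0 - sin_t2)
    rs = (n_from * cos_i - n_to * cos_t) / (n_from * cos_i + n_to * cos_t)
    rp = (n_from * cos_t - n_to * cos_i) / (n_from * cos_t + n_to * cos_i)
    return 0.5 * (rs**2 + rp**2)


def boundary_mismatch_factor(n_in: float, n_out: float) -> float:
    """Extrapolation factor A for the refractive-index mismatch.

    Computed from angular moments of the internal Fresnel reflectance
    (Haskell-style effective reflection coefficient), so the diffusion
    boundary condition is consistent with the Monte Carlo boundary
    physics.  A = 1 for matched media.
    """
    if abs(n_in - n_out) < 1e-12:
        return 1.0

    def refl(theta):
        return fresnel_reflectance(n_in, n_out, math.degrees(theta))

    r_phi, _ = quad(lambda t: 2.0 * math.sin(t) * math.cos(t) * refl(t), 0, math.pi / 2)
    r_j, _ = quad(
        lambda t: 3.0 * math.sin(t) * math.cos(t) ** 2 * refl(t), 0, math.pi / 2
    )
    r_eff = (r_phi + r_j) / (2.0 - r_phi + r_j)
    return (1.0 + r_eff) / (1.0 - r_eff)


def _image_source_positions(thickness: float, z0: float, ze: float, n_terms: int):
    """Signed image depths for the transmitted flux at z = thickness.

    Returns (a_m, b_m) arrays: positive and negative image families of
    the extrapolated-boundary dipole expansion.
    """
    period = thickness + 2.0 * ze
    m = np.arange(-n_terms, n_terms + 1)
    a = thickness - 2.0 * m * period - z0
    b = thickness - 2.0 * m * period + 2.0 * ze + z0
    return a, b


def diffusion_slab_dtof(
    props: OpticalProperties,
    geom: SlabGeometry,
    bin_width_ps: float = 10.0,
    t_max_ps: float = 6000.0,
    n_terms: int = 10,
    time_axis_ps: Optional[np.ndarray] = None,
) -> DTOF:
    """Closed-form time-domain diffuse transmittance of a slab.

    Extrapolated-boundary image-source series for a pencil beam onto an
    infinite slab; the returned values are the expected detected weight
    per time bin and launched photon, integrated over the coaxial
    detector disc (``detector_radius_cm = inf`` integrates the full
    exit plane).  Absorption enters only through the factor
    exp(-mu_a * cM * t), evaluated at bin centres so that it factorizes
    exactly from the zero-absorption curve.

    A warning flag ``meta['non_diffusive']`` is set when
    mu_sp * thickness < 5 (series still evaluated).
    """
    if time_axis_ps is not None:
        edges = np.asarray(time_axis_ps, dtype=float)
    else:
        n_bins = int(round(t_max_ps / bin_width_ps))
        edges = np.arange(n_bins + 1) * bin_width_ps
    t = 0.5 * (edges[:-1] + edges[1:])
    widths = np.diff(edges)

    v = props.c_medium  # cm/ps
    D = 1.0 / (3.0 * props.mu_sp)  # cm
    z0 = 1.0 / props.mu_sp
    A = boundary_mismatch_factor(props.n_in, props.n_out)
    ze = 2.0 * A * D

    a, b = _image_source_positions(geom.thickness_cm, z0, ze, n_terms)
    dvt = 4.0 * D * v * t  # cm^2
    series = np.zeros_like(t)
    for am, bm in zip(a, b):
        series += am * np.exp(-(am**2) / dvt) - bm * np.exp(-(bm**2) / dvt)
    flux = 0.5 * series / (np.sqrt(4.0 * math.pi * D * v) * t**1.5)  # 1/ps

    r = geom.detector_radius_cm
    if np.isfinite(r):
        flux = flux * (1.0 - np.exp(-(r**2) / dvt))

    values = np.clip(flux, 0.0, None) * widths
    if props.mu_a > 0:
        values = values * np.exp(-props.mu_a * v * t)

    meta = {
        "model": "diffusion",
        "n_in": props.n_in,
        "n_out": props.n_out,
        "mu_sp": props.mu_sp,
        "mu_a": props.mu_a,
        "thickness_cm": geom.thickness_cm,
        "detector_radius_cm": r,
        "A_factor": A,
        "n_terms": n_terms,
    }
    if props.mu_sp * geom.thickness_cm < 5.0:
        meta["non_diffusive"] = True
    kind = "white" if props.mu_a == 0.0 else "absorbing"
    return DTOF(bin_edges_ps=edges, values=values, kind=kind, meta=meta)


def cw_slab_transmittance(
    props: OpticalProperties, geom: SlabGeometry, n_terms: int = 10
) -> float:
    """Steady-state total diffuse transmittance of the slab.

    Closed-form time integral of the plane-integrated diffusion
    transmittance: T = 1/2 sum_m [sgn(a_m) e^{-mu_eff |a_m|}
    - sgn(b_m) e^{-mu_eff |b_m|}].  Requires mu_a > 0 (the alternating
    image series is conditionally convergent at mu_a = 0).
    """
    if props.mu_a <= 0:
        raise ValueError("steady-state closed form requires mu_a > 0")
    D = 1.0 / (3.0 * props.mu_sp)
    z0 = 1.0 / props.mu_sp
    A = boundary_mismatch_factor(props.n_in, props.n_out)
    ze = 2.0 * A * D
    mu_eff = math.sqrt(props.mu_a / D)
    a, b = _image_source_positions(geom.thickness_cm, z0, ze, n_terms)
    total = 0.5 * float(
        np.sum(np.sign(a) * np.exp(-mu_eff * np.abs(a)))
        - np.sum(np.sign(b) * np.exp(-mu_eff * np.abs(b)))
    )
    return total


def _run_mc(
    props: OpticalProperties,
    geom: SlabGeometry,
    n_photons: int,
    bin_width_ps: float,
    t_max_ps: float,
    stream: RandomStream,
) -> DTOF:
    if n_photons < 1:
        raise ValueError("n_photons must be >= 1")
    if bin_width_ps <= 0:
        raise ValueError("bin_width_ps must be > 0")
    n_bins = int(round(t_max_ps / bin_width_ps))
    lateral = geom.lateral_radius_cm if geom.lateral_radius_cm is not None else -1.0
    det_radius = geom.detector_radius_cm
    if not np.isfinite(det_radius):
        det_radius = 1e12
    cos_accept = math.cos(math.radians(geom.acceptance_deg))

    hist, buckets = run_slab_mc(
        int(n_photons),
        props.mu_s,
        props.g,
        props.mu_a,
        props.n_in,
        props.n_out,
        geom.thickness_cm,
        lateral,
        det_radius,
        cos_accept,
        props.c_medium,
        bin_width_ps,
        n_bins,
        stream.seed,
        stream.substream,
    )

    edges = np.arange(n_bins + 1) * bin_width_ps
    meta = {
        "model": "mc",
        "n_in": props.n_in,
        "n_out": props.n_out,
        "mu_sp": props.mu_sp,
        "mu_a": props.mu_a,
        "g": props.g,
        "thickness_cm": geom.thickness_cm,
        "detector_radius_cm": geom.detector_radius_cm,
        "acceptance_deg": geom.acceptance_deg,
        "seed": stream.seed,
        "substream": stream.substream,
        "buckets": {name: float(buckets[i]) for i, name in _BUCKET_NAMES.items()},
    }
    # late-peak warning: histogram peak in the last 3 bins means t_max
    # is too short to have captured the DTOF maximum
    if hist.sum() > 0 and int(np.argmax(hist)) >= n_bins - 3:
        meta["t_max_too_short"] = True

    kind = "white" if props.mu_a == 0.0 else "absorbing"
    return DTOF(
        bin_edges_ps=edges,
        values=hist,
        kind=kind,
        n_photons=int(n_photons),
        meta=meta,
    )


def simulate_white_dtof(
    props: OpticalProperties,
    geom: SlabGeometry,
    n_photons: int,
    bin_width_ps: float = 10.0,
    t_max_ps: float = 6000.0,
    stream: RandomStream = RandomStream(0),
) -> DTOF:
    """White (zero-absorption) Monte Carlo transmittance DTOF.

    Photon packets are traced with scattering only; absorption must be
    zero and is applied to white DTOFs afterwards via
    :func:`phantomqc.inversion.apply_absorption`.  Detection requires
    exit through the detector disc within the acceptance cone; arrival
    times are binned at the given width (TCSPC-style quantization).
    """
    if props.mu_a != 0.0:
        raise ValueError("white Monte Carlo requires mu_a = 0")
    return _run_mc(props, geom, n_photons, bin_width_ps, t_max_ps, stream)


def simulate_absorbing_dtof(
    props: OpticalProperties,
    geom: SlabGeometry,
    n_photons: int,
    bin_width_ps: float = 10.0,
    t_max_ps: float = 6000.0,
    stream: RandomStream = RandomStream(0),
) -> DTOF:
    """Absorbing-medium Monte Carlo DTOF (validation variant).

    Traces the identical trajectory ensemble as
    :func:`simulate_white_dtof` for the same stream (scattering does
    not depend on mu_a) and attenuates each detected packet by the
    microscopic Beer-Lambert factor exp(-mu_a * cM * t) at its binned
    flight time.  Bin by bin it therefore equals analytic absorption
    scaling of the corresponding white DTOF, up to round-off.
    """
    if props.mu_a <= 0.0:
        raise ValueError("absorbing simulation requires mu_a > 0")
    return _run_mc(props, geom, n_photons, bin_width_ps, t_max_ps, stream)
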