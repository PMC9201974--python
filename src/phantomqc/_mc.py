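"""Numba photon-packet kernel for slab transport.

Counter-based RNG: each photon derives its own xoroshiro128+ state from
(seed, substream, photon index) via splitmix64, so trajectories are
reproducible bit for bit regardless of execution order.

Photons carry unit weight.  Boundary interactions are sampled
probabilistically from the unpolarized Fresnel reflectance, so no
weight splitting or roulette is needed at zero absorption: every photon
ends in exactly one terminal bucket and energy bookkeeping is exact.

Detection quantizes the arrival time to its histogram bin, mirroring
the timing discretization of time-correlated single-photon counting.
Absorption is applied per detected photon as exp(-mu_a * cM * t_bin),
the microscopic Beer-Lambert factor at the binned flight time; this is
what makes analytic absorption scaling of a white histogram exact.
"""

import math

import numpy as np
from numba import njit

_MASK64 = np.uint64(0xFFFFFFFFFFFFFFFF)

# terminal bucket indices
DETECTED = 0
TRANSMITTED_MISSED = 1
REFLECTED = 2
SIDE_LOSS = 3
RESIDUAL = 4
N_BUCKETS = 5


@njit(cache=True, inline="always")
def _splitmix64(x):
    x = (x + np.uint64(0x9E3779B97F4A7C15)) & _MASK64
    z = x
    z = ((z ^ (z >> np.uint64(30))) * np.uint64(0xBF58476D1CE4E5B9)) & _MASK64
    z = ((z ^ (z >> np.uint64(27))) * np.uint64(0x94D049BB133111EB)) & _MASK64
    return (z ^ (z >> np.uint64(31))) & _MASK64


@njit(cache=True, inline="always")
def _rotl(x, k):
    return ((x << np.uint64(k)) | (x >> np.uint64(64 - k))) & _MASK64


@njit(cache=True, inline="always")
def _xoroshiro_next(state):
    s0 = state[0]
    s1 = state[1]
    result = (s0 + s1) & _MASK64
    s1 ^= s0
    state[0] = (_rotl(s0, 55) ^ s1 ^ ((s1 << np.uint64(14)) & _MASK64)) & _MASK64
    state[1] = _rotl(s1, 36)
    return result


@njit(cache=True, inline="always")
def _uniform(state):
    # (0, 1]: never 0, safe for log()
    return (np.float64(_xoroshiro_next(state) >> np.uint64(11)) + 1.0) * (2.0 ** -53)


@njit(cache=True, inline="always")
def _init_state(seed, substream, photon, state):
    h = _splitmix64(np.uint64(seed) ^ np.uint64(0x5DEECE66D))
    h = _splitmix64(h ^ np.uint64(substream))
    h = _splitmix64(h ^ np.uint64(photon))
    state[0] = _splitmix64(h)
    state[1] = _splitmix64(state[0])


@njit(cache=True, inline="always")
def _fresnel_unpolarized(n_from, n_to, cos_i):
    """Unpolarized Fresnel reflectance for incidence cosine cos_i."""
    if n_from == n_to:
        return 0.0
    sin_i2 = 1.0 - cos_i * cos_i
    sin_t2 = (n_from / n_to) * (n_from / n_to) * sin_i2
    if sin_t2 >= 1.0:
        return 1.0  # total internal reflection
    cos_t = math.sqrt(1.0 - sin_t2)
    rs = (n_from * cos_i - n_to * cos_t) / (n_from * cos_i + n_to * cos_t)
    rp = (n_from * cos_t - n_to * cos_i) / (n_from * cos_t + n_to * cos_i)
    return 0.5 * (rs * rs + rp * rp)


@njit(cache=True)
def run_slab_mc(
    n_photons,
    mu_s,
    g,
    mu_a,
    n_in,
    n_out,
    thickness,
    lateral_radius,  # <= 0 means unbounded
    det_radius,
    cos_accept_out,  # cos of acceptance half-angle outside the medium
    c_medium,  # cm/ps
    bin_width,  # ps
    n_bins,
    seed,
    substream,
):
    """Trace photons through the slab; returns (histogram, buckets).

    histogram: detected weight per time bin (weight = Beer-Lambert
    factor at the binned arrival time; unity when mu_a == 0).
    buckets: unit-weight photon counts per terminal fate.
    """
    hist = np.zeros(n_bins, dtype=np.float64)
    buckets = np.zeros(N_BUCKETS, dtype=np.float64)
    state = np.zeros(2, dtype=np.uint64)
    l_max = bin_width * n_bins * c_medium  # max useful path length, cm
    r_spec = _fresnel_unpolarized(n_out, n_in, 1.0)
    bounded = lateral_radius > 0.0

    for i in range(n_photons):
        _init_state(seed, substream, i, state)

        # specular reflection at the entry face
        if _uniform(state) < r_spec:
            buckets[REFLECTED] += 1.0
            continue

        x = 0.0
        y = 0.0
        z = 0.0
        ux = 0.0
        uy = 0.0
        uz = 1.0
        path = 0.0
        alive = True

        while alive:
            step = -math.log(_uniform(state)) / mu_s

            # propagate, handling any boundary hits within this step
            while step > 0.0:
                if uz > 0.0:
                    d_bound = (thickness - z) / uz
                elif uz < 0.0:
                    d_bound = -z / uz
                else:
                    d_bound = 1e30

                if step < d_bound:
                    x += ux * step
                    y += uy * step
                    z += uz * step
                    path += step
                    step = 0.0
                else:
                    x += ux * d_bound
                    y += uy * d_bound
                    z += uz * d_bound
                    path += d_bound
                    step -= d_bound
                    cos_i = abs(uz)
                    if _uniform(state) < _fresnel_unpolarized(n_in, n_out, cos_i):
                        uz = -uz  # internally reflected
                        # clamp to the face to avoid drift
                        z = thickness if z > 0.5 * thickness else 0.0
                    else:
                        # transmitted out of the slab
                        if uz > 0.0:
                            r2 = x * x + y * y
                            if r2 <= det_radius * det_radius:
                                sin_i2 = 1.0 - cos_i * cos_i
                                sin_t2 = (n_in / n_out) * (n_in / n_out) * sin_i2
                                cos_t = math.sqrt(max(0.0, 1.0 - sin_t2))
                                if cos_t >= cos_accept_out - 1e-12:
                                    t = path / c_medium
                                    b = int(t / bin_width)
                                    if b < n_bins:
                                        t_bin = (b + 0.5) * bin_width
                                        w = math.exp(-mu_a * c_medium * t_bin)
                                        hist[b] += w
                                        buckets[DETECTED] += 1.0
                                    else:
                                        buckets[RESIDUAL] += 1.0
                                else:
                                    buckets[TRANSMITTED_MISSED] += 1.0
                            else:
                                buckets[TRANSMITTED_MISSED] += 1.0
                        else:
                            buckets[REFLECTED] += 1.0
                        alive = False
                        break

                if bounded and x * x + y * y > lateral_radius * lateral_radius:
                    buckets[SIDE_LOSS] += 1.0
                    alive = False
                    break
                if path > l_max:
                    buckets[RESIDUAL] += 1.0
                    alive = False
                    break

            if not alive:
                break

            # scatter into a new direction
            if g == 0.0:
                cos_s = 2.0 * _uniform(state) - 1.0
            else:
                tmp = (1.0 - g * g) / (1.0 - g + 2.0 * g * _uniform(state))
                cos_s = (1.0 + g * g - tmp * tmp) / (2.0 * g)
                if cos_s > 1.0:
                    cos_s = 1.0
                elif cos_s < -1.0:
                    cos_s = -1.0
            sin_s = math.sqrt(max(0.0, 1.0 - cos_s * cos_s))
            phi = 2.0 * math.pi * _uniform(state)
            cos_p = math.cos(phi)
            sin_p = math.sin(phi)

            if abs(uz) > 0.99999:
                ux = sin_s * cos_p
                uy = sin_s * sin_p
                uz = cos_s * (1.0 if uz >= 0.0 else -1.0)
            else:
                denom = math.sqrt(1.0 - uz * uz)
                ux_new = sin_s * (ux * uz * cos_p - uy * sin_p) / denom + ux * cos_s
                uy_new = sin_s * (uy * uz * cos_p + ux * sin_p) / denom + uy * cos_s
                uz_new = -sin_s * cos_p * denom + uz * cos_s
                ux = ux_new
                uy = uy_new
                uz = uz_new
            norm = math.sqrt(ux * ux + uy * uy + uz * uz)
            ux /= norm
            uy /= norm
            uz /= norm

    return hist, buckets
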