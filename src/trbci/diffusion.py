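"""Closed-form time-resolved diffuse reflectance of a homogeneous half-space.

Extrapolated-boundary dipole solution for the time-resolved reflectance of a
semi-infinite medium (the flux/dipole form that agrees well with transport
Monte Carlo at source-detector separations of a few centimetres).  Used to
seed and validate the Monte-Carlo engine, and to provide an independent
mean-time-of-flight oracle.
"""

from __future__ import annotations

import numpy as np

from .constants import C_MM_PER_PS
from .montecarlo import Geometry, OpticalLayer


def _boundary_factor(n_rel: float) -> float:
    """A = (1 + r_d)/(1 - r_d) with the Groenhuis internal-reflection fit.

    Exactly 1 for an index-matched boundary.
    """
    if abs(n_rel - 1.0) < 1e-9:
        return 1.0
    r_d = -1.440 / n_rel**2 + 0.710 / n_rel + 0.668 + 0.0636 * n_rel
    return (1.0 + r_d) / (1.0 - r_d)


def homogeneous_tr_reflectance(
    sd_separation_mm: float,
    time_grid_ps: np.ndarray,
    props: OpticalLayer,
    external_refractive_index: float = 1.0,
) -> np.ndarray:
    """Time-resolved reflectance R(rho, t) of a homogeneous half-space.

    Parameters
    ----------
    sd_separation_mm : float
        Radial source-detector distance rho, mm.
    time_grid_ps : array
        Strictly increasing, positive times, ps.
    props : OpticalLayer
        Homogeneous optical properties (mu_a, mu_s_prime, n).
    external_refractive_index : float
        Refractive index above the surface; sets the extrapolated-boundary
        distance via the Groenhuis fit.

    Returns
    -------
    array
        Reflectance per unit area and time (photons mm^-2 ps^-1, arbitrary
        overall scale), nonnegative, -> 0 as t -> 0+.
    """
    t = np.asarray(time_grid_ps, dtype=float)
    if t.ndim != 1 or np.any(t <= 0) or np.any(np.diff(t) <= 0):
        raise ValueError("time grid must be strictly increasing and positive")
    if not props.mu_s_prime > 0:
        raise ValueError("diffusion solution invalid for mu_s_prime = 0")
    v = C_MM_PER_PS / props.refractive_index
    D = 1.0 / (3.0 * props.mu_s_prime)
    z0 = 1.0 / props.mu_s_prime
    A = _boundary_factor(props.refractive_index / external_refractive_index)
    zb = 2.0 * A * D
    rho2 = sd_separation_mm**2
    four_dvt = 4.0 * D * v * t
    with np.errstate(over="ignore", under="ignore"):
        pref = 0.5 * (4.0 * np.pi * D * v) ** -1.5 * v * t**-2.5
        atten = np.exp(-props.mu_a * v * t - rho2 / four_dvt)
        dipole = z0 * np.exp(-(z0**2) / four_dvt) + (z0 + 2 * zb) * np.exp(
            -((z0 + 2 * zb) ** 2) / four_dvt
        )
        curve = pref * atten * dipole
    return np.where(np.isfinite(curve), curve, 0.0)


def annulus_tr_reflectance(
    geometry: Geometry,
    time_grid_ps: np.ndarray,
    props: OpticalLayer,
    n_quad: int = 16,
) -> np.ndarray:
    """Reflectance integrated over the detection annulus (per unit time).

    Gauss-Legendre quadrature of ``R(rho, t) 2 pi rho`` over
    ``separation +- detector_radius``; matches what the Monte-Carlo detector
    actually collects.
    """
    r0 = geometry.source_detector_separation
    half = geometry.detector_radius
    nodes, wts = np.polynomial.legendre.leggauss(n_quad)
    rho = r0 + half * nodes
    out = np.zeros_like(np.asarray(time_grid_ps, dtype=float))
    for r, w in zip(rho, wts):
        out += (
            w
            * half
            * 2.0
            * np.pi
            * r
            * homogeneous_tr_reflectance(
                r, time_grid_ps, props, geometry.external_refractive_index
            )
        )
    return out


def diffusion_mean_tof(
    geometry: Geometry,
    props: OpticalLayer,
    max_time_ps: float,
    n_time: int = 20000,
) -> float:
    """Mean time-of-flight of the annulus-integrated diffusion curve.

    The first moment is evaluated numerically on a dense grid truncated at
    the measurement window, matching the Monte-Carlo detection cutoff.
    """
    t = np.linspace(1e-3, max_time_ps, n_time)
    curve = annulus_tr_reflectance(geometry, t, props)
    norm = np.trapezoid(curve, t)
    if norm <= 0:
        raise ValueError("degenerate diffusion curve")
    return float(np.trapezoid(t * curve, t) / norm)
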