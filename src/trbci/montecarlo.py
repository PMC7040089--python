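"""Layered Monte-Carlo photon transport with per-layer time-resolved pathlengths.

Photons are propagated with isotropic scattering at the reduced scattering
rate (similarity relation) and *no* absorption during flight: absorption is
applied at detection as ``exp(-sum_k mu_a,k * l_k)`` so that a single photon
ensemble serves any absorption values.  Photons are terminated exactly when
their geometric pathlength exceeds ``v * t_max`` for the measurement window —
later arrivals would never be histogrammed, so the truncation is unbiased for
every absorption.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .constants import C_MM_PER_PS, REPETITION_WINDOW_PS


@dataclass(frozen=True)
class OpticalLayer:
    """One slab of the layered head model.

    Parameters
    ----------
    thickness : float
        Slab thickness in mm.  The last layer of a medium may be flagged
        semi-infinite, in which case the thickness only marks its nominal
        extent.
    mu_a : float
        Absorption coefficient, mm^-1 (natural log convention).
    mu_s_prime : float
        Reduced scattering coefficient, mm^-1.
    refractive_index : float
        Refractive index (>= 1).
    """

    thickness: float
    mu_a: float = 0.017
    mu_s_prime: float = 1.0
    refractive_index: float = 1.4
    semi_infinite: bool = False

    def __post_init__(self):
        if not self.semi_infinite and not self.thickness > 0:
            raise ValueError("layer thickness must be positive")
        if self.mu_a < 0:
            raise ValueError("mu_a must be >= 0")
        if not self.mu_s_prime > 0:
            raise ValueError("mu_s_prime must be > 0")
        if self.refractive_index < 1:
            raise ValueError("refractive index must be >= 1")


@dataclass(frozen=True)
class LayeredMedium:
    """Ordered stack of layers, scalp side first.

    ``brain_layer_indices`` are 1-based layer indices whose summed sensitivity
    defines the brain sensitivity factor (default layers 5-10 of the ten
    2-mm-layer head model).
    """

    layers: tuple[OpticalLayer, ...]
    brain_layer_indices: frozenset[int] = frozenset(range(5, 11))
    scalp_layer_indices: frozenset[int] = frozenset({1})

    def __post_init__(self):
        if not self.layers:
            raise ValueError("medium needs at least one layer")
        n = len(self.layers)
        for idx in self.brain_layer_indices | self.scalp_layer_indices:
            if not 1 <= idx <= n:
                raise ValueError(f"layer index {idx} outside 1..{n}")
        ns = {lay.refractive_index for lay in self.layers}
        if len(ns) > 1:
            raise ValueError("all layers must share one refractive index")

    @property
    def n_layers(self) -> int:
        return len(self.layers)

    @property
    def refractive_index(self) -> float:
        return self.layers[0].refractive_index

    @property
    def mu_a(self) -> np.ndarray:
        return np.array([lay.mu_a for lay in self.layers])

    @property
    def mu_s_prime(self) -> np.ndarray:
        return np.array([lay.mu_s_prime for lay in self.layers])

    @property
    def boundaries_mm(self) -> np.ndarray:
        """Depth of each layer interface, starting at 0; bottom of a
        semi-infinite last layer is +inf."""
        z = np.concatenate([[0.0], np.cumsum([lay.thickness for lay in self.layers])])
        if self.layers[-1].semi_infinite:
            z[-1] = np.inf
        return z

    @property
    def brain_mask(self) -> np.ndarray:
        m = np.zeros(self.n_layers, dtype=bool)
        m[[i - 1 for i in self.brain_layer_indices]] = True
        return m

    @property
    def scalp_mask(self) -> np.ndarray:
        m = np.zeros(self.n_layers, dtype=bool)
        m[[i - 1 for i in self.scalp_layer_indices]] = True
        return m

    def content_hash(self) -> str:
        parts = [
            f"{lay.thickness:.6g},{lay.mu_a:.6g},{lay.mu_s_prime:.6g},"
            f"{lay.refractive_index:.6g},{int(lay.semi_infinite)}"
            for lay in self.layers
        ]
        parts.append(",".join(map(str, sorted(self.brain_layer_indices))))
        return hashlib.sha256(";".join(parts).encode()).hexdigest()[:16]


def default_head_medium(
    mu_a: float = 0.017, mu_s_prime: float = 1.0, n_layers: int = 10, thickness: float = 2.0
) -> LayeredMedium:
    """Ten 2-mm layers, bottom layer extended semi-infinite; uniform optics."""
    layers = [
        OpticalLayer(thickness, mu_a, mu_s_prime, semi_infinite=(i == n_layers - 1))
        for i in range(n_layers)
    ]
    return LayeredMedium(tuple(layers))


@dataclass(frozen=True)
class Geometry:
    """Source-detector geometry on the top surface.

    ``detector_radius`` is the half-width of the annulus around the
    source-detector separation within which exiting photons are detected.
    """

    source_detector_separation: float = 30.0
    detector_radius: float = 2.0
    external_refractive_index: float = 1.0

    def __post_init__(self):
        if not self.source_detector_separation > 0:
            raise ValueError("separation must be positive")
        if not self.detector_radius > 0:
            raise ValueError("detector radius must be positive")


@dataclass
class PhotonRecordSet:
    """Detected Monte-Carlo photons with per-layer geometric pathlengths.

    ``weight`` is the survival weight before absorption (all ones here,
    kept for interface completeness); absorption weights for a given set of
    per-layer mu_a come from :meth:`weights_for`.
    """

    arrival_time_ps: np.ndarray          # (N,)
    layer_pathlengths_mm: np.ndarray     # (N, K)
    weight: np.ndarray                   # (N,)
    meta: dict = field(default_factory=dict)

    @property
    def n_detected(self) -> int:
        return self.arrival_time_ps.size

    def weights_for(self, mu_a: np.ndarray) -> np.ndarray:
        """Absorption survival weights exp(-sum_k mu_a[k] * l_k) x base weight."""
        mu_a = np.asarray(mu_a, dtype=float)
        if mu_a.shape != (self.layer_pathlengths_mm.shape[1],):
            raise ValueError("mu_a length must match layer count")
        return self.weight * np.exp(-self.layer_pathlengths_mm @ mu_a)

    def validate(self, refractive_index: float, rtol: float = 1e-9) -> None:
        """Check the pathlength-time identity sum_k l_k = v * t."""
        v = C_MM_PER_PS / refractive_index
        total = self.layer_pathlengths_mm.sum(axis=1)
        if not np.allclose(total, v * self.arrival_time_ps, rtol=rtol, atol=0):
            raise ValueError("pathlength-time identity violated")
        if np.any(self.layer_pathlengths_mm < 0):
            raise ValueError("negative pathlength")


def save_records(records: PhotonRecordSet, path) -> None:
    """Cache a photon ensemble in the repository HDF5 layout."""
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("arrival_time_ps", data=records.arrival_time_ps)
        f.create_dataset("layer_pathlengths_mm", data=records.layer_pathlengths_mm)
        f.create_dataset("weight", data=records.weight)
        for key, value in records.meta.items():
            if value is not None:
                f.attrs[key] = value


def load_records(path) -> PhotonRecordSet:
    import h5py

    with h5py.File(path, "r") as f:
        return PhotonRecordSet(
            arrival_time_ps=f["arrival_time_ps"][()],
            layer_pathlengths_mm=f["layer_pathlengths_mm"][()],
            weight=f["weight"][()],
            meta=dict(f.attrs),
        )


@njit(cache=True)
def _fresnel_reflectance(n_rel, cos_i):
    """Unpolarised Fresnel reflectance, inside (n_rel = n_in/n_out) -> outside."""
    if n_rel == 1.0:
        return 0.0
    sin_i2 = 1.0 - cos_i * cos_i
    sin_t2 = n_rel * n_rel * sin_i2
    if sin_t2 >= 1.0:
        return 1.0  # total internal reflection
    cos_t = np.sqrt(1.0 - sin_t2)
    rs = (n_rel * cos_i - cos_t) / (n_rel * cos_i + cos_t)
    rp = (n_rel * cos_t - cos_i) / (n_rel * cos_t + cos_i)
    return 0.5 * (rs * rs + rp * rp)


@njit(cache=True)
def _mc_kernel(seed, n_photons, mu_s, z_bounds, n_rel, r_min, r_max, max_path,
               out_paths, out_total):
    """Propagate photons; fill per-layer pathlengths of detected ones.

    Returns the number of detected photons.
    """
    np.random.seed(seed)
    n_layers = mu_s.shape[0]
    n_det = 0
    for _ in range(n_photons):
        x = 0.0
        y = 0.0
        z = 0.0
        ux = 0.0
        uy = 0.0
        uz = 1.0
        layer = 0
        total = 0.0
        lpath = np.zeros(n_layers)
        alive = True
        while alive:
            tau = -np.log(np.random.random())
            scattered = False
            while not scattered:
                s_free = tau / mu_s[layer]
                # distance to the layer boundary along the current direction
                if uz > 1e-12:
                    d_bound = (z_bounds[layer + 1] - z) / uz
                elif uz < -1e-12:
                    d_bound = (z_bounds[layer] - z) / uz
                else:
                    d_bound = np.inf
                if s_free < d_bound:
                    # scatter inside the current layer
                    x += ux * s_free
                    y += uy * s_free
                    z += uz * s_free
                    lpath[layer] += s_free
                    total += s_free
                    scattered = True
                else:
                    # advance to the boundary
                    x += ux * d_bound
                    y += uy * d_bound
                    z += uz * d_bound
                    lpath[layer] += d_bound
                    total += d_bound
                    tau -= d_bound * mu_s[layer]
                    if total > max_path:
                        alive = False
                        break
                    if uz < 0.0 and layer == 0:
                        # top surface: Fresnel
                        cos_i = -uz
                        refl = _fresnel_reflectance(n_rel, cos_i)
                        if np.random.random() < refl:
                            uz = -uz
                            z = 0.0
                        else:
                            # photon exits; detect if inside the annulus
                            r = np.sqrt(x * x + y * y)
                            if r_min <= r <= r_max:
                                for k in range(n_layers):
                                    out_paths[n_det, k] = lpath[k]
                                out_total[n_det] = total
                                n_det += 1
                            alive = False
                            break
                    elif uz < 0.0:
                        layer -= 1
                        z = z_bounds[layer + 1]
                    else:
                        layer += 1
                        z = z_bounds[layer]
            if not alive:
                break
            if total > max_path:
                break
            # isotropic scattering
            uz = 2.0 * np.random.random() - 1.0
            phi = 2.0 * np.pi * np.random.random()
            sin_t = np.sqrt(max(0.0, 1.0 - uz * uz))
            ux = sin_t * np.cos(phi)
            uy = sin_t * np.sin(phi)
    return n_det


def run_photon_mc(
    medium: LayeredMedium,
    geometry: Geometry,
    n_photons: int,
    seed: int,
    max_time_ps: float = REPETITION_WINDOW_PS,
) -> PhotonRecordSet:
    """Run the layered Monte-Carlo simulation and return detected photons.

    Scattering is isotropic at rate ``mu_s_prime`` (similarity relation);
    absorption is *not* applied during flight (see module docstring).
    Detection is exit through the top surface within the annulus
    ``separation +- detector_radius``.  Fully reproducible for a fixed seed.
    """
    if n_photons < 1:
        raise ValueError("n_photons must be >= 1")
    if not 0 <= seed < 2**31:
        raise ValueError("seed must fit in a 31-bit unsigned range")
    n = medium.refractive_index
    v = C_MM_PER_PS / n
    max_path = v * max_time_ps
    n_rel = n / geometry.external_refractive_index
    r0 = geometry.source_detector_separation
    r_min = r0 - geometry.detector_radius
    r_max = r0 + geometry.detector_radius
    out_paths = np.zeros((n_photons, medium.n_layers))
    out_total = np.zeros(n_photons)
    z_bounds = medium.boundaries_mm
    # a huge finite stand-in keeps the kernel free of inf arithmetic
    z_bounds = np.where(np.isinf(z_bounds), 1e12, z_bounds)
    n_det = _mc_kernel(
        seed, int(n_photons), medium.mu_s_prime, z_bounds, n_rel,
        r_min, r_max, max_path, out_paths, out_total,
    )
    if n_det == 0:
        raise RuntimeError(
            "no photons detected; increase n_photons or enlarge the detector annulus"
        )
    paths = out_paths[:n_det].copy()
    times = out_total[:n_det] / v
    rec = PhotonRecordSet(
        arrival_time_ps=times,
        layer_pathlengths_mm=paths,
        weight=np.ones(n_det),
        meta={
            "n_launched": int(n_photons),
            "seed": int(seed),
            "medium_hash": medium.content_hash(),
            "separation_mm": r0,
            "detector_radius_mm": geometry.detector_radius,
            "external_n": geometry.external_refractive_index,
            "refractive_index": n,
            "max_time_ps": float(max_time_ps),
        },
    )
    return rec


@dataclass
class DTOFFrame:
    """Binned photon arrival-time histogram (one frame, one channel/wavelength)."""

    counts: np.ndarray
    bin_edges_ps: np.ndarray
    wavelength_nm: float | None = None
    channel: str | None = None
    frame_index: int = 0

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=float)
        self.bin_edges_ps = np.asarray(self.bin_edges_ps, dtype=float)
        if self.counts.size != self.bin_edges_ps.size - 1:
            raise ValueError("len(counts) must equal len(bin_edges) - 1")
        if np.any(np.diff(self.bin_edges_ps) <= 0):
            raise ValueError("bin edges must be increasing")
        if np.any(self.counts < 0):
            raise ValueError("counts must be nonnegative")

    @property
    def bin_centers_ps(self) -> np.ndarray:
        return 0.5 * (self.bin_edges_ps[:-1] + self.bin_edges_ps[1:])


@dataclass
class BinnedDTOF:
    """Expected DTOF with per-bin weighted-mean layer pathlengths.

    The mean pathlengths support first-order absorption perturbations of
    already-binned data (flagged ``first_order``).
    """

    frame: DTOFFrame
    mean_layer_pathlengths_mm: np.ndarray  # (n_bins, K)
    mu_a: np.ndarray                       # baseline absorption used for weights
    n_outside: int = 0
    first_order: bool = True


def bin_photon_records(
    records: PhotonRecordSet,
    bin_edges_ps: np.ndarray,
    mu_a: np.ndarray,
    *,
    warn_empty: bool = True,
) -> BinnedDTOF:
    """Histogram photon records into a DTOF for the given per-layer absorption.

    Expected counts per bin are the summed absorption weights; per-bin mean
    layer pathlengths are weight-averaged.  Photons outside the bin range are
    counted in ``n_outside`` rather than silently dropped.
    """
    bin_edges_ps = np.asarray(bin_edges_ps, dtype=float)
    if np.any(np.diff(bin_edges_ps) <= 0):
        raise ValueError("bin edges must be increasing")
    mu_a = np.asarray(mu_a, dtype=float)
    n_bins = bin_edges_ps.size - 1
    if records.n_detected == 0:
        if warn_empty:
            warnings.warn("empty photon record set; returning all-zero DTOF")
        frame = DTOFFrame(np.zeros(n_bins), bin_edges_ps)
        return BinnedDTOF(frame, np.zeros((n_bins, mu_a.size)), mu_a, 0)
    w = records.weights_for(mu_a)
    t = records.arrival_time_ps
    idx = np.digitize(t, bin_edges_ps) - 1
    inside = (idx >= 0) & (idx < n_bins)
    n_outside = int(np.count_nonzero(~inside))
    counts = np.bincount(idx[inside], weights=w[inside], minlength=n_bins)
    mean_l = np.zeros((n_bins, records.layer_pathlengths_mm.shape[1]))
    for k in range(mean_l.shape[1]):
        wl = np.bincount(
            idx[inside], weights=w[inside] * records.layer_pathlengths_mm[inside, k],
            minlength=n_bins,
        )
        nz = counts > 0
        mean_l[nz, k] = wl[nz] / counts[nz]
    frame = DTOFFrame(counts, bin_edges_ps)
    return BinnedDTOF(frame, mean_l, mu_a, n_outside)


def perturb_dtof(
    baseline: PhotonRecordSet | BinnedDTOF,
    delta_mua_per_layer: np.ndarray,
    *,
    bin_edges_ps: np.ndarray | None = None,
    mu_a: np.ndarray | None = None,
) -> DTOFFrame:
    """Forward-model a DTOF under a per-layer absorption change.

    In per-photon mode (``baseline`` a :class:`PhotonRecordSet`, requires
    ``bin_edges_ps`` and baseline ``mu_a``) every photon weight is multiplied
    by ``exp(-sum_k dmua_k * l_k)`` exactly.  In binned mode the per-bin mean
    pathlengths are used, which is first-order accurate and flagged as such
    on the input object.
    """
    delta = np.asarray(delta_mua_per_layer, dtype=float)
    if not np.all(np.isfinite(delta)):
        raise ValueError("perturbation must be finite")
    if isinstance(baseline, PhotonRecordSet):
        if bin_edges_ps is None or mu_a is None:
            raise ValueError("per-photon mode needs bin_edges_ps and baseline mu_a")
        binned = bin_photon_records(baseline, bin_edges_ps, np.asarray(mu_a) + delta)
        return binned.frame
    if isinstance(baseline, BinnedDTOF):
        factors = np.exp(-baseline.mean_layer_pathlengths_mm @ delta)
        if not np.all(np.isfinite(factors)):
            raise ValueError("perturbation produced non-finite weights")
        counts = baseline.frame.counts * factors
        return DTOFFrame(
            counts, baseline.frame.bin_edges_ps,
            baseline.frame.wavelength_nm, baseline.frame.channel,
            baseline.frame.frame_index,
        )
    raise TypeError("baseline must be PhotonRecordSet or BinnedDTOF")
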