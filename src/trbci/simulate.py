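"""Synthetic study generator.

Emulates the data the time-resolved system records — per-channel,
per-wavelength DTOF time series at 300-ms framing — for a full virtual
cohort: participant profiles with a configurable non-responder fraction,
randomised question order with known truth answers, motor-imagery
hemodynamics confined to the brain layers (boxcar convolved with a
single-gamma HRF), superficial systemic oscillations (cardiac, Mayer),
slow drift, Poisson counting noise, and motion spikes.

The forward model perturbs a Monte-Carlo photon ensemble: per frame, the
brain/scalp concentration changes are mapped to per-wavelength absorption
changes through the extinction matrix, the binned photon ensemble is
reweighted (first order in the per-bin mean pathlengths, accurate to
~(dmu_a x path spread)^2 here), the instrument response is applied, and
integer counts are drawn from a Poisson law.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import scipy.fft

from .constants import N_TIME_BINS, REPETITION_WINDOW_PS, WAVELENGTHS_NM
from .conversion import ExtinctionTable, forward_mua
from .montecarlo import BinnedDTOF, LayeredMedium, PhotonRecordSet, bin_photon_records
from .protocol import ProtocolDesign


# ---------------------------------------------------------------------------
# hemodynamics


def hrf_kernel(
    dt_s: float, peak_s: float = 7.0, shape: float = 6.0, duration_s: float = 32.0
) -> np.ndarray:
    """Unit-area single-gamma hemodynamic response kernel.

    Gamma density with shape ``shape`` and time-to-peak ``peak_s``
    (mode = (shape-1)*scale), sampled at ``dt_s`` and normalised to unit sum
    so that convolving a long boxcar plateaus at the boxcar amplitude.
    """
    theta = peak_s / (shape - 1.0)
    t = np.arange(0.0, duration_s, dt_s)
    k = t ** (shape - 1.0) * np.exp(-t / theta)
    return k / k.sum()


@dataclass
class ParticipantProfile:
    """Amplitudes and noise multipliers of one virtual participant.

    Non-responders (the ~10-15% of people whose imagery elicits no detectable
    hemodynamic response) have both amplitudes fixed to zero.
    """

    id: str
    responder: bool = True
    amp_hbo2: float = 0.5   # uM plateau during imagery
    amp_hb: float = -0.15   # uM, expected negative
    hrf_peak_s: float = 7.0
    noise_scales: dict = field(
        default_factory=lambda: {
            "drift": 1.0, "cardiac": 1.0, "mayer": 1.0,
            "motion_rate": 1.0, "motion_amp": 1.0,
        }
    )

    def __post_init__(self):
        if not self.responder:
            self.amp_hbo2 = 0.0
            self.amp_hb = 0.0
        if self.amp_hbo2 < 0 or self.amp_hb > 0:
            raise ValueError("expected amp_hbo2 >= 0 and amp_hb <= 0")


def hemodynamic_timecourse(
    protocol: ProtocolDesign, truth: str, profile: ParticipantProfile
) -> tuple[np.ndarray, np.ndarray]:
    """Noise-free brain concentration changes (uM) at the frame rate.

    "no" answers are identically zero; "yes" answers are the answer-block
    boxcar convolved with the unit-area gamma kernel, scaled to the profile
    amplitudes.
    """
    if truth not in ("yes", "no"):
        raise ValueError("truth must be 'yes' or 'no'")
    n = protocol.frames_per_run
    dt = protocol.frame_period_s
    if truth == "no" or not profile.responder:
        z = np.zeros(n)
        return z, z.copy()
    box = np.zeros(n)
    for onset in protocol.answer_onsets_s:
        i0 = int(round(onset / dt))
        i1 = i0 + int(round(protocol.answer_s / dt))
        box[i0:i1] = 1.0
    k = hrf_kernel(dt, profile.hrf_peak_s)
    resp = np.convolve(box, k)[:n]
    return profile.amp_hbo2 * resp, profile.amp_hb * resp


# ---------------------------------------------------------------------------
# acquisition / noise configuration


def default_bin_edges() -> np.ndarray:
    return np.linspace(0.0, REPETITION_WINDOW_PS, N_TIME_BINS + 1)


@dataclass
class AcquisitionConfig:
    n_channels: int = 4
    wavelengths_nm: tuple[float, ...] = tuple(float(w) for w in WAVELENGTHS_NM)
    counts_per_frame: float = 1e5
    irf_fwhm_ps: float = 400.0
    n_bins: int = N_TIME_BINS
    window_ps: float = REPETITION_WINDOW_PS

    @property
    def bin_edges_ps(self) -> np.ndarray:
        return np.linspace(0.0, self.window_ps, self.n_bins + 1)


@dataclass
class NoiseConfig:
    """Amplitudes of the emulated noise processes (all switchable).

    Systemic oscillations and drift live in the scalp layer as hemoglobin
    oscillations (uM); motion spikes shift the DTOF time origin and scale its
    amplitude for a few frames.
    """

    systemic: bool = True
    poisson: bool = True
    motion: bool = True
    drift: bool = True
    cardiac_amp_um: float = 0.3
    cardiac_freq_hz: float = 1.1
    mayer_amp_um: float = 0.4
    mayer_freq_hz: float = 0.1
    drift_amp_um: float = 1.0
    drift_rw_step_um: float = 0.02
    motion_rate_hz: float = 0.01
    motion_shift_sd_bins: float = 2.0
    motion_amp_sd: float = 0.1
    motion_duration_s: float = 1.2
    scalp_hb_ratio: float = 0.2  # dHb = ratio x dHbO2 for systemic signals

    @classmethod
    def silent(cls) -> "NoiseConfig":
        return cls(systemic=False, poisson=False, motion=False, drift=False)


# ---------------------------------------------------------------------------
# one run


def _blur_axis1(expected: np.ndarray, bin_edges: np.ndarray, fwhm_ps: float) -> np.ndarray:
    """Gaussian instrument response along the time-bin axis via FFT."""
    if fwhm_ps <= 0:
        return expected
    n_bins = expected.shape[1]
    bin_w = float(np.diff(bin_edges).mean())
    sigma = fwhm_ps / (2.0 * np.sqrt(2.0 * np.log(2.0))) / bin_w
    half = int(np.ceil(4 * sigma))
    i = np.arange(-half, half + 1)
    k = np.exp(-0.5 * (i / sigma) ** 2)
    k /= k.sum()
    nfft = scipy.fft.next_fast_len(n_bins + k.size - 1)
    K = scipy.fft.rfft(k, nfft)
    X = scipy.fft.rfft(expected, nfft, axis=1)
    out = scipy.fft.irfft(X * K[None, :], nfft, axis=1)[:, half : half + n_bins]
    return np.maximum(out, 0.0)


def simulate_run(
    protocol: ProtocolDesign,
    profile: ParticipantProfile,
    truth: str,
    records: PhotonRecordSet | BinnedDTOF,
    medium: LayeredMedium,
    acquisition: AcquisitionConfig,
    noise: NoiseConfig,
    table: ExtinctionTable,
    seed: int,
) -> dict[tuple[int, float], np.ndarray]:
    """Simulate one question run.

    Returns ``{(channel_index, wavelength): counts}`` with counts of shape
    (frames, bins) — integer when Poisson noise is on, expected values
    otherwise.  Fully reproducible for a fixed seed.
    """
    rng = np.random.default_rng(seed)
    edges = acquisition.bin_edges_ps
    if isinstance(records, PhotonRecordSet):
        binned = bin_photon_records(records, edges, medium.mu_a)
    else:
        binned = records
    s0 = binned.frame.counts
    if s0.sum() <= 0:
        raise RuntimeError("baseline photon ensemble is empty")
    lb = binned.mean_layer_pathlengths_mm[:, medium.brain_mask].sum(axis=1)
    ls = binned.mean_layer_pathlengths_mm[:, medium.scalp_mask].sum(axis=1)
    scale = acquisition.counts_per_frame / s0.sum()

    n = protocol.frames_per_run
    dt = protocol.frame_period_s
    t = np.arange(n) * dt
    wavelengths = tuple(acquisition.wavelengths_nm)

    hbo2, hb = hemodynamic_timecourse(protocol, truth, profile)
    brain_mua = forward_mua(hbo2, hb, table, wavelengths)  # (n_wl, frames)

    # motion events are head movements: shared timing across channels
    events = []
    if noise.motion:
        rate = noise.motion_rate_hz * profile.noise_scales.get("motion_rate", 1.0)
        n_events = rng.poisson(rate * protocol.total_run_s)
        for _ in range(n_events):
            f0 = rng.integers(0, n)
            dur = max(1, int(round(rng.exponential(noise.motion_duration_s) / dt)))
            shift = int(round(rng.normal(0.0, noise.motion_shift_sd_bins)))
            if shift == 0:
                shift = int(rng.choice([-1, 1]))
            amp = rng.normal(0.0, noise.motion_amp_sd) * profile.noise_scales.get(
                "motion_amp", 1.0
            )
            events.append((int(f0), min(n, int(f0) + dur), shift, amp))

    out: dict[tuple[int, float], np.ndarray] = {}
    for c in range(acquisition.n_channels):
        # superficial systemic signal, independent phase/jitter per channel
        scalp_hbo2 = np.zeros(n)
        if noise.systemic:
            f_card = noise.cardiac_freq_hz * rng.uniform(0.9, 1.1)
            f_mayer = noise.mayer_freq_hz * rng.uniform(0.8, 1.2)
            scalp_hbo2 += (
                noise.cardiac_amp_um
                * profile.noise_scales.get("cardiac", 1.0)
                * np.sin(2 * np.pi * f_card * t + rng.uniform(0, 2 * np.pi))
            )
            scalp_hbo2 += (
                noise.mayer_amp_um
                * profile.noise_scales.get("mayer", 1.0)
                * np.sin(2 * np.pi * f_mayer * t + rng.uniform(0, 2 * np.pi))
            )
        if noise.drift:
            amp = noise.drift_amp_um * profile.noise_scales.get("drift", 1.0)
            scalp_hbo2 += rng.uniform(-amp, amp) * (t / t[-1])
            scalp_hbo2 += np.cumsum(rng.normal(0.0, noise.drift_rw_step_um, n))
        scalp_mua = forward_mua(scalp_hbo2, noise.scalp_hb_ratio * scalp_hbo2, table, wavelengths)

        for iw, wl in enumerate(wavelengths):
            a = brain_mua[iw]
            b = scalp_mua[iw]
            expected = (scale * s0)[None, :] * np.exp(
                -np.outer(a, lb) - np.outer(b, ls)
            )
            if not np.all(np.isfinite(expected)):
                raise FloatingPointError("expected counts overflowed")
            expected = _blur_axis1(expected, edges, acquisition.irf_fwhm_ps)
            for f0, f1, shift, amp in events:
                seg = expected[f0:f1]
                expected[f0:f1] = np.roll(seg, shift, axis=1) * (1.0 + amp)
            if noise.poisson:
                out[(c, wl)] = rng.poisson(expected).astype(np.uint32)
            else:
                out[(c, wl)] = expected
    return out


# ---------------------------------------------------------------------------
# cohort


@dataclass
class CohortConfig:
    n_participants: int = 18
    n_questions: int = 4
    non_responder_frac: float = 0.12
    yes_per_participant: int = 2
    amp_hbo2_mean_um: float = 0.5
    amp_hbo2_sd_um: float = 0.15
    amp_hbo2_min_um: float = 0.1
    hb_ratio: float = -0.3
    hrf_peak_mean_s: float = 7.0
    hrf_peak_sd_s: float = 0.5


@dataclass
class GroundTruthManifest:
    """Per-run ground truth: answers, seeds, injected amplitudes."""

    entries: list[dict]
    master_seed: int

    def to_json(self) -> str:
        return json.dumps({"master_seed": self.master_seed, "entries": self.entries}, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "GroundTruthManifest":
        d = json.loads(text)
        return cls(d["entries"], d["master_seed"])


def draw_cohort(
    config: CohortConfig, master_seed: int
) -> tuple[list[ParticipantProfile], GroundTruthManifest]:
    """Draw participant profiles and the question/answer manifest.

    Responder status is Bernoulli(1 - non_responder_frac) per participant;
    each participant answers "yes" to ``yes_per_participant`` questions and
    the question order is randomised per participant.
    """
    if config.n_participants < 2:
        raise ValueError("need at least two participants for LOOCV downstream")
    if not 0 <= config.non_responder_frac < 1:
        raise ValueError("non_responder_frac must be in [0, 1)")
    if not 0 <= config.yes_per_participant <= config.n_questions:
        raise ValueError("yes_per_participant out of range")
    rng = np.random.default_rng(master_seed)
    profiles: list[ParticipantProfile] = []
    entries: list[dict] = []
    for i in range(config.n_participants):
        pid = f"P{i + 1:02d}"
        responder = bool(rng.random() >= config.non_responder_frac)
        amp = 0.0
        if responder:
            amp = float(
                np.clip(
                    rng.normal(config.amp_hbo2_mean_um, config.amp_hbo2_sd_um),
                    config.amp_hbo2_min_um,
                    None,
                )
            )
        peak = float(np.clip(rng.normal(config.hrf_peak_mean_s, config.hrf_peak_sd_s), 5.0, 9.0))
        profile = ParticipantProfile(
            id=pid,
            responder=responder,
            amp_hbo2=amp if responder else 0.0,
            amp_hb=config.hb_ratio * amp if responder else 0.0,
            hrf_peak_s=peak,
        )
        profiles.append(profile)
        answers = ["yes"] * config.yes_per_participant + ["no"] * (
            config.n_questions - config.yes_per_participant
        )
        order = rng.permutation(config.n_questions)
        for pos in range(config.n_questions):
            entries.append(
                {
                    "participant": pid,
                    "question_index": pos + 1,
                    "truth": answers[order[pos]],
                    "seed": int(rng.integers(0, 2**31)),
                    "responder": responder,
                    "amp_hbo2_um": profile.amp_hbo2,
                    "amp_hb_um": profile.amp_hb,
                    "hrf_peak_s": profile.hrf_peak_s,
                }
            )
    return profiles, GroundTruthManifest(entries, master_seed)


def iter_cohort_runs(
    profiles: list[ParticipantProfile],
    manifest: GroundTruthManifest,
    protocol: ProtocolDesign,
    records: PhotonRecordSet | BinnedDTOF,
    medium: LayeredMedium,
    acquisition: AcquisitionConfig,
    noise: NoiseConfig,
    table: ExtinctionTable,
):
    """Yield (entry, run_counts) for every run in the manifest, streaming."""
    by_id = {p.id: p for p in profiles}
    edges = acquisition.bin_edges_ps
    if isinstance(records, PhotonRecordSet):
        records = bin_photon_records(records, edges, medium.mu_a)
    for entry in manifest.entries:
        run = simulate_run(
            protocol, by_id[entry["participant"]], entry["truth"], records,
            medium, acquisition, noise, table, entry["seed"],
        )
        yield entry, run


def simulate_cohort(
    config: CohortConfig,
    protocol: ProtocolDesign,
    records: PhotonRecordSet | BinnedDTOF,
    medium: LayeredMedium,
    acquisition: AcquisitionConfig,
    noise: NoiseConfig,
    table: ExtinctionTable,
    master_seed: int,
    out_path: str | Path | None = None,
) -> GroundTruthManifest:
    """Generate a full synthetic study; optionally write the HDF5 dataset."""
    profiles, manifest = draw_cohort(config, master_seed)
    if out_path is not None:
        from .dataio import write_dataset

        runs = iter_cohort_runs(
            profiles, manifest, protocol, records, medium, acquisition, noise, table
        )
        write_dataset(out_path, runs, manifest, protocol, acquisition)
    return manifest
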