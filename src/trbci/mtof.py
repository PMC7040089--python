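"""DTOF moment processing: truncation, mean time-of-flight, baseline referencing.

The mean time-of-flight <t> is the first statistical moment of the photon
arrival-time histogram, computed after truncating each DTOF at a fraction of
its peak on the ascending (default 10%) and descending (default 1%) sides to
suppress noise from near-empty bins.  Changes are expressed relative to the
mean over a baseline period: dt = <t> - <t>_0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .montecarlo import DTOFFrame


def truncate_window(
    frame: DTOFFrame | np.ndarray, rise_frac: float = 0.10, fall_frac: float = 0.01
) -> tuple[int, int]:
    """Inclusive bin-index window [i0, i1] of the truncated DTOF.

    i0 is the first bin at/above ``rise_frac * max`` scanning from the left;
    i1 the last bin at/above ``fall_frac * max`` scanning from the right.
    Thresholds reference the raw peak count; the window always contains the
    peak bin.
    """
    counts = frame.counts if isinstance(frame, DTOFFrame) else np.asarray(frame, dtype=float)
    if counts.ndim != 1:
        raise ValueError("expected a single frame")
    peak = counts.max() if counts.size else 0.0
    if peak <= 0:
        raise ValueError("empty DTOF")
    above_rise = counts >= rise_frac * peak
    above_fall = counts >= fall_frac * peak
    i0 = int(np.argmax(above_rise))
    i1 = int(counts.size - 1 - np.argmax(above_fall[::-1]))
    return i0, i1


def mean_time_of_flight(
    frame: DTOFFrame, window: tuple[int, int] | None = None
) -> float:
    """Count-weighted mean of bin centers inside the truncation window, ps."""
    if window is None:
        window = truncate_window(frame)
    i0, i1 = window
    c = frame.counts[i0 : i1 + 1]
    total = c.sum()
    if total <= 0:
        raise ValueError("zero counts inside window")
    t = frame.bin_centers_ps[i0 : i1 + 1]
    return float((c * t).sum() / total)


def windowed_moments(
    counts_2d: np.ndarray,
    bin_edges_ps: np.ndarray,
    rise_frac: float = 0.10,
    fall_frac: float = 0.01,
    window: tuple[int, int] | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised per-frame truncated <t> for a (frames x bins) array.

    With ``window=None`` the truncation window is recomputed per frame; a
    fixed ``(i0, i1)`` window (e.g. derived once from the baseline-average
    DTOF) is applied to every frame otherwise, which keeps <t> a smooth
    function of the counts.  Returns (t_mean, total_counts, bad) where
    ``bad`` flags frames with no counts in the window (their t_mean is NaN).
    Implemented with cumulative sums so arbitrary per-frame windows cost
    O(frames x bins).
    """
    c = np.asarray(counts_2d, dtype=float)
    if c.ndim != 2:
        raise ValueError("expected (frames, bins)")
    centers = 0.5 * (np.asarray(bin_edges_ps)[:-1] + np.asarray(bin_edges_ps)[1:])
    peaks = c.max(axis=1)
    bad = peaks <= 0
    if window is not None:
        i0 = np.full(c.shape[0], window[0])
        i1 = np.full(c.shape[0], window[1])
    else:
        safe_peaks = np.where(bad, 1.0, peaks)
        above_rise = c >= rise_frac * safe_peaks[:, None]
        above_fall = c >= fall_frac * safe_peaks[:, None]
        i0 = np.argmax(above_rise, axis=1)
        i1 = c.shape[1] - 1 - np.argmax(above_fall[:, ::-1], axis=1)
    cs = np.concatenate([np.zeros((c.shape[0], 1)), np.cumsum(c, axis=1)], axis=1)
    cst = np.concatenate(
        [np.zeros((c.shape[0], 1)), np.cumsum(c * centers[None, :], axis=1)], axis=1
    )
    rows = np.arange(c.shape[0])
    tot = cs[rows, i1 + 1] - cs[rows, i0]
    tot_t = cst[rows, i1 + 1] - cst[rows, i0]
    with np.errstate(invalid="ignore", divide="ignore"):
        t_mean = tot_t / tot
    t_mean = np.where(bad | (tot <= 0), np.nan, t_mean)
    return t_mean, tot, bad | (tot <= 0)


@dataclass
class MTOFSeries:
    """Per-frame <t> and its change relative to the baseline mean."""

    t_mean: np.ndarray
    t_mean_baseline: float
    sampling_period_s: float = 0.3
    channel: str | None = None
    wavelength_nm: float | None = None
    bad_frames: np.ndarray = field(default=None)

    def __post_init__(self):
        if self.bad_frames is None:
            self.bad_frames = ~np.isfinite(self.t_mean)

    @property
    def delta_t(self) -> np.ndarray:
        return self.t_mean - self.t_mean_baseline


def delta_mtof_series(
    frames: list[DTOFFrame] | np.ndarray,
    baseline_frames: int = 100,
    *,
    bin_edges_ps: np.ndarray | None = None,
    rise_frac: float = 0.10,
    fall_frac: float = 0.01,
    sampling_period_s: float = 0.3,
    channel: str | None = None,
    wavelength_nm: float | None = None,
    window_mode: str = "per_frame",
) -> MTOFSeries:
    """Compute the dt = <t> - <t>_0 series for a run.

    <t>_0 is the mean of <t> over the first ``baseline_frames`` frames
    (default 100 = the full 30-s baseline at 0.3-s framing).  Truncation is
    recomputed per frame by default (``window_mode="per_frame"``);
    ``"baseline"`` freezes the window computed from the baseline-average
    DTOF, which removes the discrete jumps the threshold-bin index takes as
    absorption changes.  Frames with no counts are flagged bad, not
    interpolated.
    """
    if isinstance(frames, np.ndarray):
        if bin_edges_ps is None:
            raise ValueError("array input needs bin_edges_ps")
        counts = frames
        edges = np.asarray(bin_edges_ps)
    else:
        if not frames:
            raise ValueError("no frames")
        edges = frames[0].bin_edges_ps
        for f in frames[1:]:
            if not np.array_equal(f.bin_edges_ps, edges):
                raise ValueError("frames must share one bin grid")
        counts = np.stack([f.counts for f in frames])
        channel = channel if channel is not None else frames[0].channel
        wavelength_nm = wavelength_nm if wavelength_nm is not None else frames[0].wavelength_nm
    n_frames = counts.shape[0]
    if not 1 <= baseline_frames <= n_frames:
        raise ValueError("baseline_frames must be in [1, n_frames]")
    if window_mode == "per_frame":
        window = None
    elif window_mode == "baseline":
        window = truncate_window(counts[:baseline_frames].mean(axis=0), rise_frac, fall_frac)
    else:
        raise ValueError("window_mode must be 'per_frame' or 'baseline'")
    t_mean, _, bad = windowed_moments(counts, edges, rise_frac, fall_frac, window)
    base = t_mean[:baseline_frames]
    base = base[np.isfinite(base)]
    if base.size == 0 or bad.all():
        raise ValueError("all baseline frames are bad")
    return MTOFSeries(
        t_mean=t_mean,
        t_mean_baseline=float(base.mean()),
        sampling_period_s=sampling_period_s,
        channel=channel,
        wavelength_nm=wavelength_nm,
        bad_frames=bad,
    )
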