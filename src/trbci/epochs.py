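"""Block-averaged epochs and the four oxyhemoglobin decoding features.

Each question run is reduced to a single 60-s epoch — 15 s pre-task rest,
30 s task, 15 s post-task rest — by averaging across the answer cycles and
across channels, re-zeroed to the mean of the pre-task rest.  From the
oxyhemoglobin epoch four features are extracted:

* ``SM``  — median change during the task (excluding its first 10 s) minus
  the median of the preceding rest (uM);
* ``SS``  — least-squares slope of the first 16 s of the task (uM/s);
* ``CNR`` — mean task-rest difference over the preceding rest SD;
* ``r``   — Pearson correlation with the theoretical activation model
  (task boxcar convolved with the canonical HRF, epoch-extracted the same
  way).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .conversion import HbTimeCourse
from .protocol import ProtocolDesign
from .simulate import hrf_kernel

#: epoch layout in seconds
PRE_REST_S = 15.0
POST_REST_S = 15.0


@dataclass
class Epoch:
    """Cycle- and channel-averaged concentration epoch."""

    values: np.ndarray              # (n_samples,) uM
    sampling_period_s: float
    task_onset_idx: int
    task_offset_idx: int
    n_cycles_used: int
    n_channels_used: int = 1
    species: str = "HbO2"
    dispersion: np.ndarray | None = None  # per-sample SE across averaged units

    @property
    def duration_s(self) -> float:
        return self.values.size * self.sampling_period_s

    @property
    def pre_rest(self) -> np.ndarray:
        return self.values[: self.task_onset_idx]

    @property
    def task(self) -> np.ndarray:
        return self.values[self.task_onset_idx : self.task_offset_idx]


@dataclass
class FeatureVector:
    SM: float
    SS: float
    CNR: float
    r: float

    def as_array(self, subset: tuple[str, ...] = ("SM", "SS", "CNR", "r")) -> np.ndarray:
        return np.array([getattr(self, name) for name in subset])


@dataclass
class QuestionRecord:
    """One question run: features, truth from the manifest, prediction slot."""

    participant: str
    question_index: int
    features: FeatureVector
    truth: str
    predicted: str | None = None


def _epoch_slices(protocol: ProtocolDesign) -> tuple[int, int, int]:
    dt = protocol.frame_period_s
    pre = int(round(PRE_REST_S / dt))
    task = int(round(protocol.answer_s / dt))
    post = int(round(POST_REST_S / dt))
    return pre, task, post


def extract_cycle_epochs(
    values: np.ndarray, protocol: ProtocolDesign, n_cycles: int
) -> np.ndarray:
    """Stack the per-cycle epoch windows [onset - 15 s, onset + 45 s) of a run."""
    if not 1 <= n_cycles <= protocol.n_cycles:
        raise ValueError(f"n_cycles must be in 1..{protocol.n_cycles}")
    dt = protocol.frame_period_s
    pre, task, post = _epoch_slices(protocol)
    length = pre + task + post
    out = []
    for onset_s in protocol.answer_onsets_s[:n_cycles]:
        i_on = int(round(onset_s / dt))
        if i_on - pre < 0:
            raise ValueError("epoch window extends before the run start")
        out.append(values[i_on - pre : i_on - pre + length])
    return np.stack(out)


def average_epochs(
    courses: list[HbTimeCourse] | list[np.ndarray],
    protocol: ProtocolDesign,
    n_cycles: int | None = None,
    species: str = "HbO2",
) -> Epoch:
    """Average the per-cycle, per-channel epochs into one 60-s epoch.

    ``courses`` holds one time course per channel.  The epoch is re-zeroed to
    the mean of its 15-s pre-task rest; ``dispersion`` is the per-sample
    standard error across the averaged cycle x channel units.
    """
    if not courses:
        raise ValueError("no channels supplied")
    if n_cycles is None:
        n_cycles = protocol.n_cycles
    pre, task, post = _epoch_slices(protocol)
    units = []
    for course in courses:
        if isinstance(course, HbTimeCourse):
            values = course.delta_hbo2 if species == "HbO2" else course.delta_hb
        else:
            values = np.asarray(course, dtype=float)
        units.append(extract_cycle_epochs(values, protocol, n_cycles))
    stacked = np.concatenate(units, axis=0)  # (cycles*channels, samples)
    mean = stacked.mean(axis=0)
    mean = mean - mean[:pre].mean()
    if stacked.shape[0] > 1:
        disp = stacked.std(axis=0, ddof=1) / np.sqrt(stacked.shape[0])
    else:
        disp = np.zeros_like(mean)
    return Epoch(
        values=mean,
        sampling_period_s=protocol.frame_period_s,
        task_onset_idx=pre,
        task_offset_idx=pre + task,
        n_cycles_used=n_cycles,
        n_channels_used=len(courses),
        species=species,
        dispersion=disp,
    )


def feature_SM(epoch: Epoch, exclude_first_s: float = 10.0) -> float:
    """Median task change (excluding the first ``exclude_first_s``) minus the
    median of the preceding rest, uM."""
    dt = epoch.sampling_period_s
    skip = int(np.ceil(exclude_first_s / dt))
    task = epoch.values[epoch.task_onset_idx + skip : epoch.task_offset_idx]
    if task.size == 0:
        raise ValueError("task segment shorter than the exclusion window")
    return float(np.median(task) - np.median(epoch.pre_rest))


def feature_SS(epoch: Epoch, slope_window_s: float = 16.0) -> float:
    """Ordinary least-squares slope over the first ``slope_window_s`` of the
    task, uM/s."""
    dt = epoch.sampling_period_s
    n = int(round(slope_window_s / dt))
    if epoch.task_onset_idx + n > epoch.task_offset_idx:
        raise ValueError("slope window longer than the task segment")
    y = epoch.values[epoch.task_onset_idx : epoch.task_onset_idx + n]
    if y.size < 3:
        raise ValueError("need at least 3 samples for a slope")
    t = np.arange(y.size) * dt
    return float(np.polyfit(t, y, 1)[0])


def feature_CNR(epoch: Epoch) -> float:
    """(mean task - mean preceding rest) / SD of the preceding rest."""
    rest = epoch.pre_rest
    sd = rest.std(ddof=1)
    if sd <= 0:
        raise ValueError("degenerate rest period (zero variance)")
    return float((epoch.task.mean() - rest.mean()) / sd)


def model_epoch(
    protocol: ProtocolDesign, n_cycles: int | None = None, hrf_peak_s: float = 7.0
) -> Epoch:
    """Theoretical activation epoch: task boxcar convolved with the canonical
    kernel on the run grid, epoch-extracted identically to the data."""
    dt = protocol.frame_period_s
    n = protocol.frames_per_run
    box = np.zeros(n)
    for onset_s in protocol.answer_onsets_s:
        i0 = int(round(onset_s / dt))
        box[i0 : i0 + int(round(protocol.answer_s / dt))] = 1.0
    model = np.convolve(box, hrf_kernel(dt, hrf_peak_s))[:n]
    return average_epochs([model], protocol, n_cycles, species="model")


def feature_r(epoch: Epoch, model: Epoch) -> float:
    """Pearson correlation between the epoch and the activation model epoch."""
    x = epoch.values
    y = model.values
    if x.size != y.size:
        raise ValueError("epoch and model must share the time grid")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero-variance epoch")
    return float(np.corrcoef(x, y)[0, 1])


def extract_features(
    epoch: Epoch,
    model: Epoch | None = None,
    protocol: ProtocolDesign | None = None,
    slope_window_s: float = 16.0,
) -> FeatureVector:
    """All four features of an oxyhemoglobin epoch."""
    if model is None:
        if protocol is None:
            raise ValueError("need either a model epoch or the protocol")
        model = model_epoch(protocol, epoch.n_cycles_used)
    # degenerate (noise-free, non-responding) epochs: guard the zero-variance
    # denominators with machine epsilon instead of erroring out
    try:
        cnr = feature_CNR(epoch)
    except ValueError:
        rest = epoch.pre_rest
        cnr = float((epoch.task.mean() - rest.mean()) / np.finfo(float).eps)
        cnr = 0.0 if epoch.values.std() == 0 else cnr
    try:
        r = feature_r(epoch, model)
    except ValueError:
        r = 0.0
    return FeatureVector(
        SM=feature_SM(epoch),
        SS=feature_SS(epoch, slope_window_s),
        CNR=cnr,
        r=r,
    )
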