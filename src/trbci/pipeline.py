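"""End-to-end pipeline: simulate -> sensitivity -> process -> features -> decode.

The study runner streams run by run (a full synthetic cohort is ~2.6 GB of
raw DTOF frames, so nothing forces the dataset through disk), keeping only
the per-channel concentration time courses needed for epoching, the cycles
curve and the group-average figures.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np

from . import __version__
from .cleaning import clean_timecourse
from .config import PipelineConfig
from .conversion import (
    AbsorptionChange,
    ExtinctionTable,
    HbTimeCourse,
    delta_mua_from_mtof,
    hb_concentrations,
)
from .decoding import (
    CyclesCurve,
    bootstrap_accuracy_se,
    cycles_curve,
    loocv,
    per_question_accuracy,
    subset_search,
)
from .epochs import Epoch, QuestionRecord, average_epochs, extract_features, model_epoch
from .montecarlo import (
    BinnedDTOF,
    Geometry,
    LayeredMedium,
    OpticalLayer,
    bin_photon_records,
    run_photon_mc,
)
from .mtof import MTOFSeries, truncate_window, windowed_moments
from .sensitivity import (
    MeasurementModel,
    SensitivityFactors,
    compute_measurement_mtsf,
    compute_mtsf,
)
from .simulate import AcquisitionConfig, GroundTruthManifest, draw_cohort, iter_cohort_runs


def build_medium(cfg: PipelineConfig) -> LayeredMedium:
    o = cfg.optics
    layers = tuple(
        OpticalLayer(
            o.layer_thickness_mm, o.mu_a, o.mu_s_prime,
            semi_infinite=(i == o.n_layers - 1),
        )
        for i in range(o.n_layers)
    )
    return LayeredMedium(layers, frozenset(o.brain_layers))


def build_geometry(cfg: PipelineConfig) -> Geometry:
    o = cfg.optics
    return Geometry(o.separation_mm, o.detector_radius_mm, o.external_n)


@dataclass
class SensitivityStage:
    records_binned: BinnedDTOF
    factors: SensitivityFactors          # measurement-matched, used by Eq.-1 inversion
    raw_factors: SensitivityFactors      # raw-ensemble, physics cross-checks
    medium: LayeredMedium


def prepare_sensitivity(cfg: PipelineConfig, records=None) -> SensitivityStage:
    """Run (or reuse) the Monte-Carlo stage and derive both MTSF variants."""
    medium = build_medium(cfg)
    if records is None:
        records = run_photon_mc(
            medium, build_geometry(cfg), cfg.optics.n_photons, cfg.optics.mc_seed
        )
    acq = cfg.acquisition
    measurement = MeasurementModel(
        bin_edges_ps=acq.bin_edges_ps,
        irf_fwhm_ps=acq.irf_fwhm_ps,
        rise_frac=cfg.processing.rise_frac,
        fall_frac=cfg.processing.fall_frac,
        window_mode=cfg.processing.window_mode,
    )
    matched = compute_measurement_mtsf(
        records, medium, measurement, cfg.optics.delta_mua, acq.wavelengths_nm
    )
    raw = compute_mtsf(records, medium, cfg.optics.delta_mua, acq.wavelengths_nm)
    binned = bin_photon_records(records, acq.bin_edges_ps, medium.mu_a)
    return SensitivityStage(binned, matched, raw, medium)


def _interpolate_bad(values: np.ndarray, bad: np.ndarray) -> np.ndarray:
    if not bad.any():
        return values
    out = values.copy()
    good = np.flatnonzero(~bad)
    out[bad] = np.interp(np.flatnonzero(bad), good, values[good])
    return out


def process_run(
    run: dict[tuple[int, float], np.ndarray],
    cfg: PipelineConfig,
    sens: SensitivityFactors,
    table: ExtinctionTable,
) -> list[HbTimeCourse]:
    """Raw DTOF frames -> cleaned per-channel concentration time courses.

    Steps per channel and wavelength: truncated <t> per frame, d<t> against
    the 30-s baseline mean, motion correction, cosine detrending, HRF
    smoothing, then the two-wavelength inversion per channel.
    """
    proc = cfg.processing
    protocol = cfg.protocol
    dt = protocol.frame_period_s
    edges = cfg.acquisition.bin_edges_ps
    baseline_frames = proc.baseline_frames or protocol.baseline_frames
    channels = sorted({c for c, _ in run})
    wavelengths = cfg.acquisition.wavelengths_nm
    courses: list[HbTimeCourse] = []
    for c in channels:
        mua_by_wl: list[AbsorptionChange] = []
        for wl in wavelengths:
            counts = run[(c, wl)]
            if proc.window_mode == "baseline":
                window = truncate_window(
                    counts[:baseline_frames].mean(axis=0), proc.rise_frac, proc.fall_frac
                )
            else:
                window = None
            t_mean, _, bad = windowed_moments(
                counts, edges, proc.rise_frac, proc.fall_frac, window
            )
            t_mean = _interpolate_bad(t_mean, bad)
            base = float(t_mean[:baseline_frames].mean())
            series = MTOFSeries(t_mean, base, dt, str(c), wl, bad)
            cleaned = clean_timecourse(
                series.delta_t,
                dt,
                motion=proc.motion_correction,
                motion_window_s=proc.motion_window_s,
                motion_k=proc.motion_k,
                spline_smoothing=proc.spline_smoothing,
                cutoff_period_s=proc.cutoff_period_s,
                smooth_fwhm_s=proc.smooth_fwhm_s,
                smooth_shape=proc.smooth_shape,
            )
            mua_by_wl.append(
                delta_mua_from_mtof(cleaned.values, sens, wl)
            )
        courses.append(hb_concentrations(mua_by_wl[0], mua_by_wl[1], table))
    return courses


@dataclass
class StudyResult:
    """Everything downstream analyses need, per question run."""

    records: list[QuestionRecord]
    hbo2_courses: list[np.ndarray]       # (n_channels, frames) per record
    hb_courses: list[np.ndarray]
    manifest: GroundTruthManifest
    config_hash: str
    timings_s: dict = field(default_factory=dict)


def _records_for_cycles(
    result: "StudyResult", cfg: PipelineConfig, n_cycles: int
) -> list[QuestionRecord]:
    protocol = cfg.protocol
    model = model_epoch(protocol, n_cycles)
    out = []
    for rec, hbo2 in zip(result.records, result.hbo2_courses):
        epoch = average_epochs(list(hbo2), protocol, n_cycles)
        fv = extract_features(epoch, model, slope_window_s=cfg.processing.slope_window_s)
        out.append(QuestionRecord(rec.participant, rec.question_index, fv, rec.truth))
    return out


def run_study(cfg: PipelineConfig, records=None, manifest_override=None) -> StudyResult:
    """Simulate and process the whole synthetic study, returning features.

    ``records`` may carry a pre-computed photon ensemble (e.g. a shared
    cache); otherwise the Monte-Carlo stage runs with the configured seed.
    """
    timings: dict[str, float] = {}
    t0 = time.perf_counter()
    stage = prepare_sensitivity(cfg, records)
    timings["sensitivity"] = time.perf_counter() - t0
    table = ExtinctionTable.default()
    profiles, manifest = draw_cohort(cfg.cohort, cfg.master_seed)
    if manifest_override is not None:
        profiles, manifest = manifest_override
    protocol = cfg.protocol
    model = model_epoch(protocol)
    out_records: list[QuestionRecord] = []
    hbo2_courses: list[np.ndarray] = []
    hb_courses: list[np.ndarray] = []
    t0 = time.perf_counter()
    for entry, run in iter_cohort_runs(
        profiles, manifest, protocol, stage.records_binned, stage.medium,
        cfg.acquisition, cfg.noise, table,
    ):
        courses = process_run(run, cfg, stage.factors, table)
        hbo2 = np.stack([c.delta_hbo2 for c in courses])
        hb = np.stack([c.delta_hb for c in courses])
        epoch = average_epochs(list(hbo2), protocol)
        fv = extract_features(epoch, model, slope_window_s=cfg.processing.slope_window_s)
        out_records.append(
            QuestionRecord(entry["participant"], entry["question_index"], fv, entry["truth"])
        )
        hbo2_courses.append(hbo2)
        hb_courses.append(hb)
    timings["simulate_process"] = time.perf_counter() - t0
    return StudyResult(
        out_records, hbo2_courses, hb_courses, manifest, cfg.hash(), timings
    )


def decode_study(result: StudyResult, cfg: PipelineConfig) -> dict:
    """Subset search per classifier, cycles curve, per-question accuracies."""
    report: dict = {
        "software_version": __version__,
        "config_hash": result.config_hash,
        "n_records": len(result.records),
        "timings_s": result.timings_s,
        "methods": {},
    }
    t0 = time.perf_counter()
    for method in cfg.decoding.methods:
        search = subset_search(result.records, method)
        best = loocv(result.records, search.best_subset, method)
        entry = {
            "best_subset": list(search.best_subset),
            "accuracy_pct": best.accuracy,
            "sensitivity_pct": best.sensitivity,
            "specificity_pct": best.specificity,
            "confusion": best.confusion,
            "accuracy_se_bootstrap": bootstrap_accuracy_se(
                result.records, best.per_record_predictions
            ),
            "per_question_accuracy_pct": per_question_accuracy(result.records, best),
            "subset_table": {
                "+".join(res.feature_subset): res.accuracy for res in search.results
            },
        }
        report["methods"][method] = entry
    if cfg.decoding.cycles_curve:
        records_by_k = {
            k: _records_for_cycles(result, cfg, k)
            for k in range(1, cfg.protocol.n_cycles + 1)
        }
        curve = cycles_curve(records_by_k, cfg.decoding.primary_method)
        report["cycles_curve"] = {
            "fixed_subset": list(curve.fixed_subset),
            "accuracy_by_k": curve.fixed_subset_accuracy,
            "per_subset": {
                k: {"+".join(s): a for s, a in d.items()}
                for k, d in curve.per_subset.items()
            },
        }
    report["timings_s"]["decode"] = time.perf_counter() - t0
    return report


def class_average_epochs(
    result: StudyResult, cfg: PipelineConfig, by: str = "truth"
) -> dict[str, dict[str, np.ndarray]]:
    """Group-average HbO2/Hb epochs for the yes and no classes.

    ``by`` selects the grouping label: the manifest truth or (when
    predictions have been filled in) the classifier output.
    """
    protocol = cfg.protocol
    groups: dict[str, dict[str, list[np.ndarray]]] = {}
    for rec, hbo2, hb in zip(result.records, result.hbo2_courses, result.hb_courses):
        label = rec.truth if by == "truth" else (rec.predicted or rec.truth)
        g = groups.setdefault(label, {"HbO2": [], "Hb": []})
        g["HbO2"].append(average_epochs(list(hbo2), protocol).values)
        g["Hb"].append(average_epochs(list(hb), protocol, species="Hb").values)
    return {
        label: {
            sp: np.stack(vals).mean(axis=0) for sp, vals in d.items()
        }
        for label, d in groups.items()
    }


def run_default_study(master_seed: int, cfg: PipelineConfig | None = None) -> dict:
    """The headline analysis: default cohort, full pipeline, both classifiers."""
    if cfg is None:
        cfg = PipelineConfig()
    cfg.master_seed = int(master_seed)
    result = run_study(cfg)
    return decode_study(result, cfg)
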