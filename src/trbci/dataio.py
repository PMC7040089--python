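"""File formats: the HDF5 dataset layout, features TSV, results JSON.

HDF5 layout (version 1.0)::

    /                       attrs: layout_version, frame_period_ms,
                            protocol_* fields, manifest (JSON string)
    /time_bin_edges_ps      (n_bins + 1,)
    /participants/<id>/questions/<k>         attrs: truth, question_index, seed
        channels/<c>/wavelengths/<wl>/counts (frames, bins) uint32

Round trips are lossless for counts, edges, attributes and the manifest.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .epochs import FeatureVector, QuestionRecord
from .protocol import ProtocolDesign
from .simulate import AcquisitionConfig, GroundTruthManifest

LAYOUT_VERSION = "1.0"


class SchemaError(RuntimeError):
    pass


def write_dataset(
    path: str | Path,
    runs,
    manifest: GroundTruthManifest,
    protocol: ProtocolDesign,
    acquisition: AcquisitionConfig,
) -> Path:
    """Write a (possibly streamed) iterable of (entry, run_counts) runs."""
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.attrs["layout_version"] = LAYOUT_VERSION
        f.attrs["frame_period_ms"] = protocol.frame_period_ms
        f.attrs["protocol_baseline_s"] = protocol.baseline_s
        f.attrs["protocol_n_cycles"] = protocol.n_cycles
        f.attrs["protocol_answer_s"] = protocol.answer_s
        f.attrs["protocol_rest_s"] = protocol.rest_s
        f.attrs["manifest"] = manifest.to_json()
        f.create_dataset("time_bin_edges_ps", data=acquisition.bin_edges_ps)
        qcount: dict[str, int] = {}
        for entry, run in runs:
            pid = entry["participant"]
            qcount[pid] = qcount.get(pid, 0) + 1
            g = f.create_group(
                f"participants/{pid}/questions/{entry['question_index']}"
            )
            g.attrs["truth"] = entry["truth"]
            g.attrs["question_index"] = entry["question_index"]
            g.attrs["seed"] = entry["seed"]
            for (c, wl), counts in run.items():
                g.create_dataset(
                    f"channels/{c}/wavelengths/{int(wl)}/counts",
                    data=np.asarray(counts),
                    compression="gzip",
                    compression_opts=1,
                )
    manifest_path = path.with_suffix(".manifest.json")
    manifest_path.write_text(manifest.to_json())
    return path


def validate_dataset(path: str | Path) -> None:
    """Raise :class:`SchemaError` naming the first missing piece."""
    with h5py.File(path, "r") as f:
        if "layout_version" not in f.attrs:
            raise SchemaError("missing root attribute 'layout_version'")
        if "time_bin_edges_ps" not in f:
            raise SchemaError("missing dataset '/time_bin_edges_ps'")
        if "manifest" not in f.attrs:
            raise SchemaError("missing root attribute 'manifest'")
        if "participants" not in f:
            raise SchemaError("missing group '/participants'")
        for pid, pg in f["participants"].items():
            if "questions" not in pg:
                raise SchemaError(f"missing '/participants/{pid}/questions'")
            for q, qg in pg["questions"].items():
                for attr in ("truth", "question_index", "seed"):
                    if attr not in qg.attrs:
                        raise SchemaError(
                            f"missing attribute '{attr}' on participants/{pid}/questions/{q}"
                        )
                if "channels" not in qg:
                    raise SchemaError(
                        f"missing 'channels' under participants/{pid}/questions/{q}"
                    )


def read_dataset(path: str | Path):
    """Load the full dataset into memory.

    Returns (runs, manifest, bin_edges_ps, protocol) where runs maps
    (participant, question_index) -> {(channel, wavelength): counts}.
    """
    validate_dataset(path)
    with h5py.File(path, "r") as f:
        edges = f["time_bin_edges_ps"][()]
        manifest = GroundTruthManifest.from_json(f.attrs["manifest"])
        protocol = ProtocolDesign(
            baseline_s=float(f.attrs["protocol_baseline_s"]),
            n_cycles=int(f.attrs["protocol_n_cycles"]),
            answer_s=float(f.attrs["protocol_answer_s"]),
            rest_s=float(f.attrs["protocol_rest_s"]),
            frame_period_ms=float(f.attrs["frame_period_ms"]),
        )
        runs = {}
        for pid, pg in f["participants"].items():
            for q, qg in pg["questions"].items():
                run = {}
                for c, cg in qg["channels"].items():
                    for wl, wg in cg["wavelengths"].items():
                        run[(int(c), float(wl))] = wg["counts"][()]
                runs[(pid, int(q))] = run
    return runs, manifest, edges, protocol


def write_features_tsv(records: list[QuestionRecord], path: str | Path) -> Path:
    """One row per question: participant, order position, features, truth."""
    rows = [
        {
            "participant": r.participant,
            "question_index": r.question_index,
            "SM": r.features.SM,
            "SS": r.features.SS,
            "CNR": r.features.CNR,
            "r": r.features.r,
            "truth": r.truth,
        }
        for r in records
    ]
    path = Path(path)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
    return path


def read_features_tsv(path: str | Path) -> list[QuestionRecord]:
    df = pd.read_csv(path, sep="\t")
    return [
        QuestionRecord(
            participant=str(row.participant),
            question_index=int(row.question_index),
            features=FeatureVector(
                SM=float(row.SM), SS=float(row.SS), CNR=float(row.CNR), r=float(row.r)
            ),
            truth=str(row.truth),
        )
        for row in df.itertuples()
    ]


def write_results_json(report: dict, path: str | Path) -> Path:
    path = Path(path)

    def default(obj):
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, (np.integer,)):
            return int(obj)
        if isinstance(obj, (np.floating,)):
            return float(obj)
        raise TypeError(f"not JSON-serialisable: {type(obj)}")

    path.write_text(json.dumps(report, indent=1, sort_keys=True, default=default))
    return path
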