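"""HDF5 containers (with TSV/JSON mirrors) and run manifests.

Primary container is HDF5, versioned with a ``format_version`` attribute;
every file embeds a :class:`RunManifest` JSON snapshot so any output can be
traced back to the configuration and seeds that produced it. Raw recordings
can additionally be mirrored to a long-format TSV (time, wavelength, voxel,
value) with a JSON sidecar for markers and metadata.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field

import h5py
import numpy as np
import pandas as pd

from . import __version__
from .preprocess import TaskEpoch
from .synthdata import RawRecording, SubjectProfile, TaskSchedule

FORMAT_VERSION = "1"
N_VOXELS = 16


class SchemaError(RuntimeError):
    pass


@dataclass
class RunManifest:
    config: dict = field(default_factory=dict)
    seed: int | None = None
    stage: str = ""
    input_hashes: dict = field(default_factory=dict)
    package_version: str = __version__
    format_version: str = FORMAT_VERSION
    created: float = field(default_factory=time.time)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), sort_keys=True)

    @classmethod
    def from_json(cls, s: str) -> "RunManifest":
        return cls(**json.loads(s))


def file_hash(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


def _check_version(f: h5py.File, path) -> None:
    version = f.attrs.get("format_version")
    if version != FORMAT_VERSION:
        raise SchemaError(
            f"{path}: container format_version {version!r} != expected {FORMAT_VERSION!r}"
        )


# ---------------------------------------------------------------------------
# raw cohorts


def _write_recording_group(g: h5py.Group, rec: RawRecording) -> None:
    g.create_dataset("intensity", data=rec.intensities)
    if rec.ground_truth is not None:
        g.create_dataset("ground_truth_hbo2", data=rec.ground_truth["hbo2"])
        g.create_dataset("ground_truth_hb", data=rec.ground_truth["hb"])
    g.attrs["schedule"] = rec.schedule.to_json()
    g.attrs["profile"] = json.dumps(dataclasses.asdict(rec.profile))
    g.attrs["missing_voxels"] = sorted(rec.missing_voxels)
    g.attrs["fs"] = rec.fs
    g.attrs["detector_max"] = rec.detector_max


def _read_recording_group(g: h5py.Group, path) -> RawRecording:
    intensity = np.asarray(g["intensity"])
    if intensity.ndim != 3 or intensity.shape[0] != 2 or intensity.shape[1] != N_VOXELS:
        raise SchemaError(
            f"{path}: intensity shape {intensity.shape} does not match "
            f"[2, {N_VOXELS}, T] (format_version {FORMAT_VERSION})"
        )
    ground_truth = None
    if "ground_truth_hbo2" in g:
        ground_truth = {
            "hbo2": np.asarray(g["ground_truth_hbo2"]),
            "hb": np.asarray(g["ground_truth_hb"]),
        }
    return RawRecording(
        intensities=intensity,
        fs=float(g.attrs["fs"]),
        schedule=TaskSchedule.from_json(g.attrs["schedule"]),
        profile=SubjectProfile(**json.loads(g.attrs["profile"])),
        missing_voxels=frozenset(int(v) for v in g.attrs["missing_voxels"]),
        detector_max=float(g.attrs["detector_max"]),
        ground_truth=ground_truth,
    )


def write_cohort(recordings: list, path, manifest: RunManifest | None = None) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["format_version"] = FORMAT_VERSION
        f.attrs["manifest"] = (manifest or RunManifest(stage="synth")).to_json()
        subs = f.create_group("subjects")
        for rec in recordings:
            _write_recording_group(subs.create_group(rec.profile.subject_id), rec)


def read_cohort(path) -> list:
    with h5py.File(path, "r") as f:
        _check_version(f, path)
        return [
            _read_recording_group(f["subjects"][k], path)
            for k in sorted(f["subjects"])
        ]


def write_recording(rec: RawRecording, path, manifest: RunManifest | None = None) -> None:
    write_cohort([rec], path, manifest)


def read_recording(path) -> RawRecording:
    recs = read_cohort(path)
    if len(recs) != 1:
        raise SchemaError(f"{path}: expected a single-recording container, found {len(recs)}")
    return recs[0]


# ---------------------------------------------------------------------------
# TSV mirror (long format)


def write_recording_tsv(rec: RawRecording, path) -> None:
    """``<path>`` gets the long-format table, ``<path>.json`` the sidecar."""
    w, v, t = rec.intensities.shape
    frame = pd.DataFrame(
        {
            "time": np.tile(np.arange(t) / rec.fs, w * v),
            "wavelength": np.repeat(np.arange(w), v * t),
            "voxel": np.tile(np.repeat(np.arange(1, v + 1), t), w),
            "value": rec.intensities.reshape(-1),
        }
    )
    frame.to_csv(path, sep="\t", index=False)
    sidecar = {
        "schedule": json.loads(rec.schedule.to_json()),
        "profile": dataclasses.asdict(rec.profile),
        "missing_voxels": sorted(rec.missing_voxels),
        "fs": rec.fs,
        "detector_max": rec.detector_max,
        "format_version": FORMAT_VERSION,
    }
    with open(f"{path}.json", "w") as fh:
        json.dump(sidecar, fh, indent=1)


def read_recording_tsv(path) -> RawRecording:
    with open(f"{path}.json") as fh:
        sidecar = json.load(fh)
    if sidecar.get("format_version") != FORMAT_VERSION:
        raise SchemaError(f"{path}: sidecar format_version mismatch")
    frame = pd.read_csv(path, sep="\t")
    n_w = frame["wavelength"].nunique()
    n_v = frame["voxel"].nunique()
    n_t = frame["time"].nunique()
    if n_v != N_VOXELS:
        raise SchemaError(f"{path}: {n_v} voxels found, schema requires {N_VOXELS}")
    intens = frame["value"].to_numpy().reshape(n_w, n_v, n_t)
    return RawRecording(
        intensities=intens,
        fs=float(sidecar["fs"]),
        schedule=TaskSchedule.from_json(json.dumps(sidecar["schedule"])),
        profile=SubjectProfile(**sidecar["profile"]),
        missing_voxels=frozenset(sidecar["missing_voxels"]),
        detector_max=float(sidecar["detector_max"]),
    )


# ---------------------------------------------------------------------------
# epochs and images


def _epoch_manifest_frame(epochs: list) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "epoch_id": [f"{i:05d}" for i in range(len(epochs))],
            "condition": [e.condition for e in epochs],
            "subject_id": [e.metadata.get("subject_id", "") for e in epochs],
            "duration_s": [e.duration for e in epochs],
            "n_samples": [e.n_samples for e in epochs],
            "n_missing_voxels": [len(e.missing_voxels) for e in epochs],
        }
    )


def write_epochs(epochs: list, path, manifest: RunManifest | None = None) -> None:
    _epoch_manifest_frame(epochs).to_csv(f"{path}.manifest.tsv", sep="\t", index=False)
    with h5py.File(path, "w") as f:
        f.attrs["format_version"] = FORMAT_VERSION
        f.attrs["manifest"] = (manifest or RunManifest(stage="preprocess")).to_json()
        grp = f.create_group("epochs")
        for i, ep in enumerate(epochs):
            g = grp.create_group(f"{i:05d}")
            g.create_dataset("hbo2", data=ep.hbo2)
            g.create_dataset("hb", data=ep.hb)
            g.attrs.update(
                {
                    "condition": ep.condition,
                    "voxels": list(ep.voxels),
                    "missing_voxels": sorted(ep.missing_voxels),
                    "fs": ep.fs,
                    "duration": ep.duration,
                    "baseline_start": ep.baseline_start,
                    "task_start": ep.task_start,
                    "metadata": json.dumps(ep.metadata),
                    "baseline_corrected": ep.baseline_corrected,
                }
            )


def read_epochs(path) -> list:
    out = []
    with h5py.File(path, "r") as f:
        _check_version(f, path)
        for key in sorted(f["epochs"]):
            g = f["epochs"][key]
            out.append(
                TaskEpoch(
                    condition=str(g.attrs["condition"]),
                    hbo2=np.asarray(g["hbo2"]),
                    hb=np.asarray(g["hb"]),
                    voxels=tuple(int(v) for v in g.attrs["voxels"]),
                    missing_voxels=frozenset(int(v) for v in g.attrs["missing_voxels"]),
                    fs=float(g.attrs["fs"]),
                    duration=float(g.attrs["duration"]),
                    baseline_start=float(g.attrs["baseline_start"]),
                    task_start=float(g.attrs["task_start"]),
                    metadata=json.loads(g.attrs["metadata"]),
                    baseline_corrected=bool(g.attrs["baseline_corrected"]),
                )
            )
    return out


def write_images(images, labels, meta, path, manifest: RunManifest | None = None,
                 resize_name: str = "", third: str = "diff") -> None:
    pd.DataFrame(
        {
            "sample_id": np.arange(len(images)),
            "label": np.asarray(labels, dtype=str),
            "subject_id": [m.get("subject_id", "") for m in meta],
        }
    ).to_csv(f"{path}.manifest.tsv", sep="\t", index=False)
    with h5py.File(path, "w") as f:
        f.attrs["format_version"] = FORMAT_VERSION
        f.attrs["manifest"] = (manifest or RunManifest(stage="featurize")).to_json()
        f.attrs["resize"] = resize_name
        f.attrs["third"] = third
        f.attrs["image_shape"] = images.shape[1:]
        f.create_dataset("images", data=images, dtype="f4")
        f.create_dataset("labels", data=np.asarray(labels, dtype="S"))
        f.create_dataset("meta", data=np.asarray([json.dumps(m) for m in meta], dtype="S"))


def read_images(path) -> tuple:
    with h5py.File(path, "r") as f:
        _check_version(f, path)
        images = np.asarray(f["images"], dtype=np.float32)
        labels = np.asarray([s.decode() for s in f["labels"]])
        meta = [json.loads(s.decode()) for s in f["meta"]]
    return images, labels, meta
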