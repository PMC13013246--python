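"""Readers and writers for every on-disk stream of a tracked US recording.

A recording bundle consists of four synchronized streams:

* the 3D ultrasound frame sequence, archived as a single 4D MetaImage with
  PLUS-style per-frame timestamp fields (``Seq_Frame%04d_Timestamp``),
* the ECG trace as a two-column CSV (``t``, ``amplitude``) sampled at
  600 Hz by default,
* the optical tracking stream as a CSV of time-stamped 3x4 pose matrices
  (row-major ``r00..r23``), and
* a YAML metadata map (device settings, probe id, ...).

All timestamps are normalized on load so that the earliest sample across
the streams defines time zero; the US station is assumed to have
pre-synchronized its frame timestamps to the ECG clock.
"""

from __future__ import annotations

import csv
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import SimpleITK as sitk
import yaml

from .geometry import (
    HomogeneousTransform,
    PointCloud,
    TrackingStream,
    VolumeGeometry,
)

__all__ = [
    "UsFrameSequence",
    "EcgTrace",
    "LandmarkSet",
    "RecordingBundle",
    "RecordingLoadError",
    "read_recording",
    "write_recording",
    "validate_recording",
    "read_landmarks",
    "write_landmarks",
    "read_pointcloud",
    "write_pointcloud",
    "read_label_volume",
    "write_label_volume",
    "read_volume",
]

LANDMARK_NAMES = ("apex", "mitral_centre", "aortic_centre")


class RecordingLoadError(RuntimeError):
    """A stream failed to load; the message names the offending stream."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class UsFrameSequence:
    """Ordered 3D US volumes sharing one grid geometry.

    ``volumes[i]`` is an ``(nx, ny, nz)`` array indexed ``[i, j, k]`` in the
    same order as ``geometry.size``.
    """

    timestamps: np.ndarray
    volumes: list[np.ndarray]
    geometry: VolumeGeometry

    def __post_init__(self) -> None:
        ts = np.asarray(self.timestamps, dtype=float)
        if len(ts) != len(self.volumes):
            raise ValueError("timestamps and volumes must have equal length")
        if len(ts) > 1 and np.any(np.diff(ts) <= 0):
            raise ValueError("US frame timestamps must be strictly increasing")
        for v in self.volumes:
            if tuple(v.shape) != self.geometry.size:
                raise ValueError("frame shape does not match sequence geometry")
        self.timestamps = ts

    def __len__(self) -> int:
        return len(self.timestamps)

    def frame_rate(self) -> float:
        """Achieved frame rate: median of inverse inter-frame intervals (Hz)."""
        if len(self) < 2:
            return float("nan")
        return float(np.median(1.0 / np.diff(self.timestamps)))


@dataclass
class EcgTrace:
    """Single-lead ECG samples (arbitrary amplitude units)."""

    timestamps: np.ndarray
    samples: np.ndarray
    sampling_rate: float = 600.0

    def __post_init__(self) -> None:
        ts = np.asarray(self.timestamps, dtype=float)
        amp = np.asarray(self.samples, dtype=float)
        if ts.shape != amp.shape or ts.ndim != 1:
            raise ValueError("ECG timestamps and samples must be equal-length 1-D")
        self.timestamps, self.samples = ts, amp

    def __len__(self) -> int:
        return len(self.timestamps)

    def is_uniform(self, rel_tol: float = 0.01) -> bool:
        if len(self) < 3:
            return True
        dt = np.diff(self.timestamps)
        return bool(np.all(np.abs(dt - np.mean(dt)) <= rel_tol * np.mean(dt)))


@dataclass
class LandmarkSet:
    """Apex, mitral-valve centre and aortic-valve centre in one space (mm)."""

    apex: np.ndarray
    mitral_centre: np.ndarray
    aortic_centre: np.ndarray
    space: str = "ct"

    def __post_init__(self) -> None:
        pts = {}
        for name in LANDMARK_NAMES:
            p = np.asarray(getattr(self, name), dtype=float).reshape(3)
            if not np.all(np.isfinite(p)):
                raise ValueError(f"landmark {name} has non-finite coordinates")
            pts[name] = p
            setattr(self, name, p)
        arr = np.stack(list(pts.values()))
        d = np.linalg.norm(arr[:, None] - arr[None, :], axis=-1)
        if np.any(d[np.triu_indices(3, 1)] < 1e-9):
            raise ValueError("landmarks must be pairwise distinct")

    def as_array(self) -> np.ndarray:
        """(3, 3) array in the fixed order apex, mitral_centre, aortic_centre."""
        return np.stack([self.apex, self.mitral_centre, self.aortic_centre])


@dataclass
class RecordingBundle:
    us: UsFrameSequence
    ecg: EcgTrace
    tracking: TrackingStream
    metadata: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# US sequence (PLUS-style 4D MetaImage)
# ---------------------------------------------------------------------------

def _seq_to_sitk(seq: UsFrameSequence) -> sitk.Image:
    frames = [
        sitk.GetImageFromArray(np.ascontiguousarray(v.transpose(2, 1, 0)))
        for v in seq.volumes
    ]
    g = seq.geometry
    for f in frames:
        f.SetSpacing(tuple(g.spacing))
        f.SetOrigin(tuple(g.origin))
        f.SetDirection(tuple(g.direction.flatten()))
    img = sitk.JoinSeries(frames)
    for i, t in enumerate(seq.timestamps):
        img.SetMetaData(f"Seq_Frame{i:04d}_Timestamp", repr(float(t)))
    return img


def write_us_sequence(path: str | Path, seq: UsFrameSequence) -> None:
    sitk.WriteImage(_seq_to_sitk(seq), str(path))


def read_us_sequence(path: str | Path) -> UsFrameSequence:
    path = Path(path)
    if not path.exists():
        raise RecordingLoadError(f"US sequence file not found: {path}")
    img = sitk.ReadImage(str(path))
    if img.GetDimension() != 4:
        raise RecordingLoadError("US sequence must be a 4D MetaImage")
    arr = sitk.GetArrayFromImage(img)  # (frame, z, y, x)
    n = arr.shape[0]
    sp, org, drn = img.GetSpacing(), img.GetOrigin(), np.asarray(img.GetDirection())
    geom = VolumeGeometry(
        spacing=np.asarray(sp[:3]),
        origin=np.asarray(org[:3]),
        direction=drn.reshape(4, 4)[:3, :3],
        size=(arr.shape[3], arr.shape[2], arr.shape[1]),
    )
    ts = []
    for i in range(n):
        key = f"Seq_Frame{i:04d}_Timestamp"
        if not img.HasMetaDataKey(key):
            raise RecordingLoadError(f"US sequence frame {i} is missing its timestamp field")
        ts.append(float(img.GetMetaData(key)))
    volumes = [np.ascontiguousarray(arr[i].transpose(2, 1, 0)) for i in range(n)]
    ts_arr = np.asarray(ts)
    if np.any(np.diff(ts_arr) <= 0):
        raise RecordingLoadError("US sequence timestamps are not strictly increasing")
    return UsFrameSequence(ts_arr, volumes, geom)


# ---------------------------------------------------------------------------
# ECG and tracking CSV
# ---------------------------------------------------------------------------

def write_ecg(path: str | Path, ecg: EcgTrace) -> None:
    pd.DataFrame({"t": ecg.timestamps, "amplitude": ecg.samples}).to_csv(
        path, index=False
    )


def read_ecg(path: str | Path, sampling_rate: float = 600.0) -> EcgTrace:
    path = Path(path)
    if not path.exists():
        raise RecordingLoadError(f"ECG file not found: {path}")
    df = pd.read_csv(path)
    if not {"t", "amplitude"} <= set(df.columns):
        raise RecordingLoadError("ECG CSV must have columns t,amplitude")
    ts = df["t"].to_numpy(dtype=float)
    if len(ts) > 1 and np.any(np.diff(ts) <= 0):
        raise RecordingLoadError("ECG timestamps are not strictly increasing")
    if len(ts) > 2:
        sampling_rate = 1.0 / float(np.median(np.diff(ts)))
    return EcgTrace(ts, df["amplitude"].to_numpy(dtype=float), sampling_rate)


_TRACK_COLS = [f"r{i}{j}" for i in range(3) for j in range(4)]


def write_tracking(path: str | Path, stream: TrackingStream) -> None:
    rows = []
    for t, pose in zip(stream.timestamps, stream.poses):
        rows.append([t, *pose.matrix[:3].flatten()])
    pd.DataFrame(rows, columns=["t", *_TRACK_COLS]).to_csv(path, index=False)


def read_tracking(path: str | Path) -> TrackingStream:
    path = Path(path)
    if not path.exists():
        raise RecordingLoadError(f"tracking file not found: {path}")
    df = pd.read_csv(path)
    if not {"t", *_TRACK_COLS} <= set(df.columns):
        raise RecordingLoadError("tracking CSV must have columns t,r00..r23")
    ts = df["t"].to_numpy(dtype=float)
    if np.any(np.diff(ts) <= 0):
        raise RecordingLoadError("tracking timestamps are not strictly increasing")
    poses = []
    for _, row in df.iterrows():
        m = np.eye(4)
        m[:3] = row[_TRACK_COLS].to_numpy(dtype=float).reshape(3, 4)
        poses.append(HomogeneousTransform(m, from_space="probe", to_space="tracking"))
    try:
        return TrackingStream(ts, poses)
    except ValueError as exc:
        raise RecordingLoadError(f"tracking stream invalid: {exc}") from exc


# ---------------------------------------------------------------------------
# recording bundle
# ---------------------------------------------------------------------------

def write_recording(out_dir: str | Path, bundle: RecordingBundle) -> dict[str, Path]:
    """Write all streams under ``out_dir``; returns the path map."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "us": out_dir / "us_sequence.mha",
        "ecg": out_dir / "ecg.csv",
        "tracking": out_dir / "tracking.csv",
        "metadata": out_dir / "metadata.yaml",
    }
    write_us_sequence(paths["us"], bundle.us)
    write_ecg(paths["ecg"], bundle.ecg)
    write_tracking(paths["tracking"], bundle.tracking)
    with open(paths["metadata"], "w") as fh:
        yaml.safe_dump(bundle.metadata, fh)
    return paths


def read_recording(in_dir: str | Path) -> RecordingBundle:
    """Load a recording bundle; timestamps are shifted to a shared zero origin."""
    in_dir = Path(in_dir)
    us = read_us_sequence(in_dir / "us_sequence.mha")
    ecg = read_ecg(in_dir / "ecg.csv")
    tracking = read_tracking(in_dir / "tracking.csv")
    meta_path = in_dir / "metadata.yaml"
    metadata = {}
    if meta_path.exists():
        with open(meta_path) as fh:
            metadata = yaml.safe_load(fh) or {}
    t0 = min(us.timestamps[0], ecg.timestamps[0], tracking.timestamps[0])
    us = UsFrameSequence(us.timestamps - t0, us.volumes, us.geometry)
    ecg = EcgTrace(ecg.timestamps - t0, ecg.samples, ecg.sampling_rate)
    tracking = TrackingStream(tracking.timestamps - t0, tracking.poses)
    return RecordingBundle(us, ecg, tracking, metadata)


def validate_recording(bundle: RecordingBundle, min_frame_rate: float = 20.0) -> dict:
    """Report-only validation of a loaded bundle.

    Checks the achieved US frame rate against ``min_frame_rate`` (the study
    floor is 20 Hz, i.e. at most 25 ms trigger-matching error), the ECG
    sampling rate and uniformity, and the temporal overlap of the streams.
    """
    report: dict = {"checks": {}, "passed": True}

    fr = bundle.us.frame_rate()
    report["us_frame_rate_hz"] = fr
    # small tolerance absorbs float round-off of nominally exact frame clocks
    report["checks"]["us_frame_rate"] = bool(
        np.isfinite(fr) and fr >= min_frame_rate * (1.0 - 1e-9)
    )

    if len(bundle.ecg) >= 2:
        report["ecg_rate_hz"] = bundle.ecg.sampling_rate
        report["checks"]["ecg_present"] = True
        report["checks"]["ecg_uniform"] = bundle.ecg.is_uniform()
    else:
        report["ecg_rate_hz"] = float("nan")
        report["checks"]["ecg_present"] = False
        report["checks"]["ecg_uniform"] = False

    if len(bundle.tracking) >= 2 and len(bundle.us) >= 1:
        overlap = (
            bundle.tracking.t_start <= bundle.us.timestamps[0]
            and bundle.tracking.t_end >= bundle.us.timestamps[-1]
        )
    else:
        overlap = False
    report["checks"]["tracking_covers_us"] = bool(overlap)
    report["passed"] = all(report["checks"].values())
    return report


# ---------------------------------------------------------------------------
# landmarks (Slicer-style FCSV)
# ---------------------------------------------------------------------------

def write_landmarks(path: str | Path, lm: LandmarkSet) -> None:
    with open(path, "w", newline="") as fh:
        fh.write("# Markups fiducial file version = 4.11\n")
        fh.write(f"# CoordinateSystem = {lm.space}\n")
        fh.write("# columns = id,x,y,z,ow,ox,oy,oz,vis,sel,lock,label,desc,associatedNodeID\n")
        w = csv.writer(fh)
        for i, name in enumerate(LANDMARK_NAMES):
            p = getattr(lm, name)
            w.writerow([i + 1, p[0], p[1], p[2], 0, 0, 0, 1, 1, 1, 0, name, "", ""])


def read_landmarks(path: str | Path, space: str | None = None) -> LandmarkSet:
    path = Path(path)
    if not path.exists():
        raise RecordingLoadError(f"landmark file not found: {path}")
    file_space = "ct"
    found: dict[str, np.ndarray] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                if "CoordinateSystem" in line:
                    file_space = line.split("=")[-1].strip()
                continue
            parts = line.split(",")
            label = parts[11].strip()
            if label not in LANDMARK_NAMES:
                raise RecordingLoadError(
                    f"unknown landmark name {label!r}; expected one of {LANDMARK_NAMES}"
                )
            found[label] = np.asarray(parts[1:4], dtype=float)
    missing = set(LANDMARK_NAMES) - set(found)
    if missing:
        raise RecordingLoadError(f"landmark file missing: {sorted(missing)}")
    return LandmarkSet(
        found["apex"], found["mitral_centre"], found["aortic_centre"],
        space=space or file_space,
    )


# ---------------------------------------------------------------------------
# point clouds (ASCII PLY) and label volumes
# ---------------------------------------------------------------------------

def write_pointcloud(path: str | Path, cloud: PointCloud) -> None:
    """ASCII PLY vertex cloud; the space tag goes into a comment line."""
    pts = cloud.points
    with open(path, "w") as fh:
        fh.write("ply\nformat ascii 1.0\n")
        fh.write(f"comment space {cloud.space}\n")
        fh.write(f"comment label {cloud.label}\n")
        fh.write(f"element vertex {len(pts)}\n")
        fh.write("property float x\nproperty float y\nproperty float z\n")
        fh.write("end_header\n")
        np.savetxt(fh, pts, fmt="%.6f")


def read_pointcloud(path: str | Path) -> PointCloud:
    path = Path(path)
    space, label = "ct", ""
    n = None
    with open(path) as fh:
        line = fh.readline().strip()
        if line != "ply":
            raise RecordingLoadError(f"{path} is not a PLY file")
        while True:
            line = fh.readline().strip()
            if line == "end_header":
                break
            if line.startswith("comment space"):
                space = line.split(maxsplit=2)[2]
            elif line.startswith("comment label"):
                parts = line.split(maxsplit=2)
                label = parts[2] if len(parts) > 2 else ""
            elif line.startswith("element vertex"):
                n = int(line.split()[-1])
        pts = np.loadtxt(fh, ndmin=2) if n else np.empty((0, 3))
    if n is not None and len(pts) != n:
        raise RecordingLoadError(f"PLY vertex count mismatch in {path}")
    return PointCloud(pts.reshape(-1, 3), space=space, label=label)


def _geometry_from_sitk(img: sitk.Image) -> VolumeGeometry:
    return VolumeGeometry(
        spacing=np.asarray(img.GetSpacing()),
        origin=np.asarray(img.GetOrigin()),
        direction=np.asarray(img.GetDirection()).reshape(3, 3),
        size=tuple(img.GetSize()),
    )


def read_volume(path: str | Path) -> tuple[np.ndarray, VolumeGeometry]:
    """Read a 3D scalar volume (NRRD/NIfTI/MetaImage) as ``arr[i, j, k]``."""
    path = Path(path)
    if not path.exists():
        raise RecordingLoadError(f"volume file not found: {path}")
    img = sitk.ReadImage(str(path))
    if img.GetDimension() != 3:
        raise RecordingLoadError(f"{path} is not a 3D volume")
    arr = sitk.GetArrayFromImage(img).transpose(2, 1, 0)
    return np.ascontiguousarray(arr), _geometry_from_sitk(img)


def write_label_volume(
    path: str | Path, labels: np.ndarray, geom: VolumeGeometry
) -> None:
    img = sitk.GetImageFromArray(
        np.ascontiguousarray(labels.astype(np.uint8).transpose(2, 1, 0))
    )
    img.SetSpacing(tuple(geom.spacing))
    img.SetOrigin(tuple(geom.origin))
    img.SetDirection(tuple(geom.direction.flatten()))
    sitk.WriteImage(img, str(path), useCompression=False)


def label_volume_to_cloud(
    labels: np.ndarray, geom: VolumeGeometry, space: str = "ct", label: str = ""
) -> PointCloud:
    """Physical centres of every labelled (non-zero) voxel."""
    idx = np.argwhere(labels > 0).astype(float)
    if idx.size == 0:
        warnings.warn("label volume is empty; returning empty cloud", stacklevel=2)
        return PointCloud(np.empty((0, 3)), space=space, label=label)
    mm = geom.origin + (geom.spacing * idx) @ geom.direction.T
    return PointCloud(mm, space=space, label=label)


def read_label_volume(
    path: str | Path, space: str = "ct"
) -> tuple[PointCloud, VolumeGeometry]:
    arr, geom = read_volume(path)
    return label_volume_to_cloud(arr, geom, space=space), geom


def write_json_report(path: str | Path, report: dict) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, default=float)
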