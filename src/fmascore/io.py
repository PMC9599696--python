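"""Reading and writing recordings, cohort manifests and reports.

On-disk conventions
-------------------
Time series are CSV (comma separated, ``.`` decimal, UTF-8, mandatory
header, one row per frame); manifests, configs and reports are JSON.
Floats are written with :func:`repr`, i.e. the shortest string that
round-trips exactly, so write -> read is bit-exact.

Skeleton CSV: ``time`` plus 18 joints x ``{x,y,z}`` = 55 columns, meters,
camera frame (x right, y up, z toward camera).  Hand CSV: ``time`` plus
the ten Leap-Motion-style channels (angles in degrees, grab strength in
[0, 1]).  Grasp CSV: ``time,voltage,force`` at 10 Hz.

Manifest JSON schema (paths relative to the manifest file)::

    {"subjects": [
        {"subject_id": "S01",
         "paretic_side": "left",
         "recordings": {"I": {"paretic": ["S01/I_p_1.csv", ...],
                              "less_affected": ["S01/I_h_1.csv", ...]},
                        ...},
         "reference_scores": {"3": 2, ...}}      # optional
    ]}
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .exceptions import FormatError, ValidationError
from .registry import ITEM_IDS, MOTION_KIND, GRASP_TOOLS

#: the 18 tracked joints (camera-facing seated subject)
JOINT_NAMES = (
    "nose", "head", "neck", "mid_hip",
    "shoulder_l", "shoulder_r", "elbow_l", "elbow_r",
    "wrist_l", "wrist_r", "hand_l", "hand_r",
    "hip_l", "hip_r", "knee_l", "knee_r", "ankle_l", "ankle_r",
)

#: hand-tracking channels (degrees except grab_strength)
HAND_CHANNELS = (
    "wrist_pitch", "wrist_yaw", "forearm_rotation",
    "elbow_flexion", "shoulder_flexion",
    "finger1", "finger2", "finger3", "finger4",
    "grab_strength",
)

SIDES = ("paretic", "less_affected")


def _check_times(times: np.ndarray, what: str) -> None:
    if times.ndim != 1 or len(times) == 0:
        raise ValidationError(f"{what}: empty or non-1D timestamp vector")
    if not np.all(np.isfinite(times)):
        raise ValidationError(f"{what}: non-finite timestamps")
    if len(times) > 1 and not np.all(np.diff(times) > 0):
        raise ValidationError(f"{what}: timestamps not strictly increasing")


@dataclass
class SkeletonSequence:
    """Timestamped 18-joint 3D positions for one motion trial, one side."""

    times: np.ndarray                 # (N,) seconds from recording start
    positions: np.ndarray             # (N, 18, 3) meters
    fps: float = 30.0

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        _check_times(self.times, "SkeletonSequence")
        if self.fps <= 0:
            raise ValidationError("SkeletonSequence: fps must be > 0")
        if self.positions.shape != (len(self.times), len(JOINT_NAMES), 3):
            raise ValidationError(
                "SkeletonSequence: positions must be (n_frames, 18, 3), got "
                f"{self.positions.shape}")
        if not np.all(np.isfinite(self.positions)):
            raise ValidationError("SkeletonSequence: non-finite positions")

    def __len__(self) -> int:
        return len(self.times)

    def joint(self, name: str) -> np.ndarray:
        """(N, 3) trajectory of one named joint."""
        try:
            idx = JOINT_NAMES.index(name)
        except ValueError:
            raise ValidationError(f"unknown joint name: {name!r}") from None
        return self.positions[:, idx, :]

    def with_positions(self, positions: np.ndarray) -> "SkeletonSequence":
        return SkeletonSequence(self.times.copy(), positions, self.fps)


@dataclass
class HandSequence:
    """Timestamped wrist/forearm/finger angle and grab-strength channels."""

    times: np.ndarray                 # (N,)
    channels: np.ndarray              # (N, 10) ordered as HAND_CHANNELS
    fps: float = 100.0

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.channels = np.asarray(self.channels, dtype=float)
        _check_times(self.times, "HandSequence")
        if not 0 < self.fps <= 200:
            raise ValidationError("HandSequence: fps must be in (0, 200]")
        if self.channels.shape != (len(self.times), len(HAND_CHANNELS)):
            raise ValidationError(
                "HandSequence: channels must be (n_frames, 10), got "
                f"{self.channels.shape}")
        if not np.all(np.isfinite(self.channels)):
            raise ValidationError("HandSequence: non-finite channel values")
        rho = self.channel("grab_strength")
        if rho.min() < 0 or rho.max() > 1:
            raise ValidationError("HandSequence: grab_strength outside [0, 1]")

    def __len__(self) -> int:
        return len(self.times)

    def channel(self, name: str) -> np.ndarray:
        try:
            idx = HAND_CHANNELS.index(name)
        except ValueError:
            raise ValidationError(f"unknown hand channel: {name!r}") from None
        return self.channels[:, idx]

    def with_channels(self, channels: np.ndarray) -> "HandSequence":
        return HandSequence(self.times.copy(), channels, self.fps)


@dataclass
class GraspRecording:
    """Timestamped voltage/force from one instrumented grip tool."""

    times: np.ndarray
    voltage: np.ndarray               # volts
    force: np.ndarray                 # newtons
    tool_id: str = "hook"
    fps: float = 10.0

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.voltage = np.asarray(self.voltage, dtype=float)
        self.force = np.asarray(self.force, dtype=float)
        _check_times(self.times, "GraspRecording")
        if self.tool_id not in GRASP_TOOLS.values():
            raise ValidationError(f"unknown grasp tool: {self.tool_id!r}")
        if len(self.voltage) != len(self.times) or \
                len(self.force) != len(self.times):
            raise ValidationError("GraspRecording: channel length mismatch")
        if not (np.all(np.isfinite(self.voltage))
                and np.all(np.isfinite(self.force))):
            raise ValidationError("GraspRecording: non-finite values")
        if self.voltage.min() < 0 or self.force.min() < 0:
            raise ValidationError("GraspRecording: negative voltage or force")

    def __len__(self) -> int:
        return len(self.times)


@dataclass
class SubjectRecord:
    """One subject's recordings for every motion task, both sides."""

    subject_id: str
    paretic_side: str                 # "left" | "right"
    #: recordings[motion_code][side] -> list of recording objects
    #: (repetitions in order; motions I, II, III, V are performed twice)
    recordings: dict = field(default_factory=dict)
    reference_scores: dict | None = None   # item_id -> 0/1/2

    def __post_init__(self):
        if self.paretic_side not in ("left", "right"):
            raise ValidationError(
                f"paretic_side must be left/right, got {self.paretic_side!r}")
        if self.reference_scores is not None:
            for item_id, score in self.reference_scores.items():
                if item_id not in ITEM_IDS:
                    raise ValidationError(
                        f"{self.subject_id}: reference score for unknown "
                        f"item {item_id}")
                if score not in (0, 1, 2):
                    raise ValidationError(
                        f"{self.subject_id}: item {item_id} score {score} "
                        "outside {0, 1, 2}")

    @property
    def reference_total(self) -> int:
        if not self.reference_scores:
            raise ValidationError(
                f"{self.subject_id}: no reference scores present")
        return int(sum(self.reference_scores.values()))

    def get(self, motion_code: str, side: str) -> list:
        return self.recordings[motion_code][side]


# ---------------------------------------------------------------------------
# CSV time series

def _fmt(x: float) -> str:
    return repr(float(x))


def _read_table(path) -> tuple[list[str], np.ndarray]:
    with open(path, "r", encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise FormatError(f"{path}: empty file") from None
        try:
            rows = [[float(v) for v in row] for row in reader if row]
        except ValueError as exc:
            raise FormatError(f"{path}: non-numeric cell ({exc})") from None
    data = np.asarray(rows, dtype=float)
    if data.ndim != 2 or data.shape[1] != len(header):
        raise FormatError(f"{path}: ragged rows")
    return header, data


def _write_table(path, header: list[str], columns: list[np.ndarray]) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(header)
        for row in zip(*columns):
            writer.writerow([_fmt(v) for v in row])


def _skeleton_header() -> list[str]:
    cols = ["time"]
    for j in JOINT_NAMES:
        cols += [f"{j}_x", f"{j}_y", f"{j}_z"]
    return cols


def read_skeleton_csv(path, fps: float = 30.0) -> SkeletonSequence:
    header, data = _read_table(path)
    expected = _skeleton_header()
    missing = [c for c in expected if c not in header]
    if missing:
        raise FormatError(f"{path}: missing column {missing[0]!r}")
    order = [header.index(c) for c in expected]
    data = data[:, order]
    times = data[:, 0]
    positions = data[:, 1:].reshape(len(times), len(JOINT_NAMES), 3)
    return SkeletonSequence(times, positions, fps=fps)


def write_skeleton_csv(path, seq: SkeletonSequence) -> None:
    flat = seq.positions.reshape(len(seq), -1)
    _write_table(path, _skeleton_header(),
                 [seq.times] + [flat[:, i] for i in range(flat.shape[1])])


def read_hand_csv(path, fps: float = 100.0) -> HandSequence:
    header, data = _read_table(path)
    expected = ["time", *HAND_CHANNELS]
    missing = [c for c in expected if c not in header]
    if missing:
        raise FormatError(f"{path}: missing column {missing[0]!r}")
    order = [header.index(c) for c in expected]
    data = data[:, order]
    return HandSequence(data[:, 0], data[:, 1:], fps=fps)


def write_hand_csv(path, seq: HandSequence) -> None:
    _write_table(path, ["time", *HAND_CHANNELS],
                 [seq.times] + [seq.channels[:, i]
                                for i in range(len(HAND_CHANNELS))])


def read_grasp_csv(path, tool_id: str, fps: float = 10.0) -> GraspRecording:
    header, data = _read_table(path)
    expected = ["time", "voltage", "force"]
    missing = [c for c in expected if c not in header]
    if missing:
        raise FormatError(f"{path}: missing column {missing[0]!r}")
    order = [header.index(c) for c in expected]
    data = data[:, order]
    return GraspRecording(data[:, 0], data[:, 1], data[:, 2],
                          tool_id=tool_id, fps=fps)


def write_grasp_csv(path, rec: GraspRecording) -> None:
    _write_table(path, ["time", "voltage", "force"],
                 [rec.times, rec.voltage, rec.force])


# ---------------------------------------------------------------------------
# Cohort manifests

_READERS = {
    "skeleton": lambda p, motion: read_skeleton_csv(p),
    "hand": lambda p, motion: read_hand_csv(p),
    "grasp": lambda p, motion: read_grasp_csv(p, GRASP_TOOLS[motion]),
}

_WRITERS = {
    "skeleton": write_skeleton_csv,
    "hand": write_hand_csv,
    "grasp": write_grasp_csv,
}


def read_cohort_manifest(path) -> list[SubjectRecord]:
    """Load a cohort manifest and every recording it references."""
    path = Path(path)
    with open(path, "r", encoding="utf-8") as fh:
        doc = json.load(fh)
    root = path.parent
    subjects = []
    for entry in doc.get("subjects", []):
        sid = entry["subject_id"]
        recordings: dict = {}
        for motion, sides in entry.get("recordings", {}).items():
            if motion not in MOTION_KIND:
                raise FormatError(f"{sid}: unknown motion code {motion!r}")
            kind = MOTION_KIND[motion]
            recordings[motion] = {}
            for side, rel_paths in sides.items():
                if side not in SIDES:
                    raise FormatError(f"{sid}/{motion}: unknown side {side!r}")
                recs = []
                for rel in rel_paths:
                    p = root / rel
                    if not p.exists():
                        raise FormatError(
                            f"{sid}/{motion}/{side}: missing file {rel}")
                    recs.append(_READERS[kind](p, motion))
                recordings[motion][side] = recs
        scores = entry.get("reference_scores")
        if scores is not None:
            scores = {int(k): v for k, v in scores.items()}
        subjects.append(SubjectRecord(sid, entry["paretic_side"],
                                      recordings, scores))
    return subjects


def write_cohort(subjects: list[SubjectRecord], outdir) -> Path:
    """Write every recording as CSV plus a ``manifest.json``; returns the
    manifest path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    doc = {"subjects": []}
    for rec in subjects:
        entry = {"subject_id": rec.subject_id,
                 "paretic_side": rec.paretic_side,
                 "recordings": {}}
        for motion, sides in rec.recordings.items():
            kind = MOTION_KIND[motion]
            entry["recordings"][motion] = {}
            for side, recs in sides.items():
                rels = []
                for i, r in enumerate(recs, start=1):
                    rel = f"{rec.subject_id}/{motion}_{side}_{i}.csv"
                    _WRITERS[kind](outdir / rel, r)
                    rels.append(rel)
                entry["recordings"][motion][side] = rels
        if rec.reference_scores is not None:
            entry["reference_scores"] = {
                str(k): int(v) for k, v in sorted(rec.reference_scores.items())}
        doc["subjects"].append(entry)
    manifest = outdir / "manifest.json"
    with open(manifest, "w", encoding="utf-8") as fh:
        json.dump(doc, fh, indent=1)
    return manifest
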