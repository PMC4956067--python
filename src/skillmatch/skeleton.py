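"""Skeleton motion streams: the 20-joint data model and its file formats.

A depth-sensor pose tracker emits, at a nominal 30 frames per second, the
positions of 20 anatomical landmarks in metres (camera frame), a per-joint
tracking state (Tracked / Inferred / Not Tracked), per-bone orientations as
XYZ Euler angles in degrees, and a timestamp.  This module holds that data in
:class:`SkeletonStream` and reads/writes it in two concrete formats:

* ``.kss`` — a fixed-layout little-endian binary (see :data:`FRAME_DTYPE`),
  with participant metadata and exclusion intervals in a ``<file>.meta.json``
  sidecar so that frames stay fixed-size and seekable;
* JSONL — one frame per line, for debugging and text fixtures.

Coordinate convention (camera 1 frame): X = player's right, Y = up,
Z = away from the camera, metres.  Timestamps are seconds relative to the
first frame.

Exclusion intervals mark spans during which the participant was outside the
capture space.  Frames are never deleted: they are flagged so the rule
matcher skips anchors inside excluded spans and never matches across an
exclusion boundary.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from enum import IntEnum
from pathlib import Path

import numpy as np

from .errors import CorruptFileError, FormatError, ValidationError

N_JOINTS = 20


class JointId(IntEnum):
    """The 20 default tracked joints, with stable codes 0-19 used on disk."""

    HIP_CENTRE = 0
    SPINE = 1
    SHOULDER_CENTRE = 2
    HEAD = 3
    SHOULDER_LEFT = 4
    ELBOW_LEFT = 5
    WRIST_LEFT = 6
    HAND_LEFT = 7
    SHOULDER_RIGHT = 8
    ELBOW_RIGHT = 9
    WRIST_RIGHT = 10
    HAND_RIGHT = 11
    HIP_LEFT = 12
    KNEE_LEFT = 13
    ANKLE_LEFT = 14
    FOOT_LEFT = 15
    HIP_RIGHT = 16
    KNEE_RIGHT = 17
    ANKLE_RIGHT = 18
    FOOT_RIGHT = 19


JOINT_BY_NAME = {j.name.lower(): j for j in JointId}

# Kinematic tree rooted at the hip centre; used for joint-angle conditions.
PARENT: dict[JointId, JointId | None] = {
    JointId.HIP_CENTRE: None,
    JointId.SPINE: JointId.HIP_CENTRE,
    JointId.SHOULDER_CENTRE: JointId.SPINE,
    JointId.HEAD: JointId.SHOULDER_CENTRE,
    JointId.SHOULDER_LEFT: JointId.SHOULDER_CENTRE,
    JointId.ELBOW_LEFT: JointId.SHOULDER_LEFT,
    JointId.WRIST_LEFT: JointId.ELBOW_LEFT,
    JointId.HAND_LEFT: JointId.WRIST_LEFT,
    JointId.SHOULDER_RIGHT: JointId.SHOULDER_CENTRE,
    JointId.ELBOW_RIGHT: JointId.SHOULDER_RIGHT,
    JointId.WRIST_RIGHT: JointId.ELBOW_RIGHT,
    JointId.HAND_RIGHT: JointId.WRIST_RIGHT,
    JointId.HIP_LEFT: JointId.HIP_CENTRE,
    JointId.KNEE_LEFT: JointId.HIP_LEFT,
    JointId.ANKLE_LEFT: JointId.KNEE_LEFT,
    JointId.FOOT_LEFT: JointId.ANKLE_LEFT,
    JointId.HIP_RIGHT: JointId.HIP_CENTRE,
    JointId.KNEE_RIGHT: JointId.HIP_RIGHT,
    JointId.ANKLE_RIGHT: JointId.KNEE_RIGHT,
    JointId.FOOT_RIGHT: JointId.ANKLE_RIGHT,
}

FIRST_CHILD: dict[JointId, JointId | None] = {}
for _j in JointId:
    FIRST_CHILD[_j] = next((c for c in JointId if PARENT[c] == _j), None)


class TrackingState(IntEnum):
    """Per-joint confidence flag returned by the sensor."""

    NOT_TRACKED = 0
    INFERRED = 1
    TRACKED = 2


class FusionSource(IntEnum):
    """Provenance of a fused joint sample (present only on fused streams)."""

    NONE = 0
    CAM1_ONLY = 1
    CAM2_ONLY = 2
    AVERAGED = 3
    FALLBACK_CAM1 = 4


# Little-endian fixed layout: f64 timestamp, 20 x (3xf32 position + validity
# byte), 20 x 3xf32 Euler angles.  8 + 260 + 240 = 508 bytes, already 4-byte
# aligned, so no trailing pad is needed.
FRAME_DTYPE = np.dtype(
    [
        ("t", "<f8"),
        ("joints", [("pos", "<f4", (3,)), ("val", "u1")], (N_JOINTS,)),
        ("orient", "<f4", (N_JOINTS, 3)),
    ]
)
FRAME_BYTES = FRAME_DTYPE.itemsize
assert FRAME_BYTES == 508

MAGIC = b"KSS1"
FORMAT_VERSION = 1
HEADER_BYTES = 16

# Validity byte: base tracking state in the low 2 bits, fusion provenance in
# the next 3 bits.
_STATE_MASK = 0b11
_PROV_SHIFT = 2


@dataclass
class Frame:
    """One sample of the skeleton stream.

    positions : (20, 3) float64 metres; states : (20,) uint8 TrackingState;
    orientations : (20, 3) float32 Euler degrees.
    """

    timestamp: float
    positions: np.ndarray
    states: np.ndarray
    orientations: np.ndarray

    def __post_init__(self):
        # float64 in memory: single frames feed calibration geometry, where
        # float32 quantisation would already dominate the error budget
        self.positions = np.asarray(self.positions, dtype=np.float64)
        self.states = np.asarray(self.states, dtype=np.uint8)
        self.orientations = np.asarray(self.orientations, dtype=np.float32)
        if self.positions.shape != (N_JOINTS, 3):
            raise ValidationError(f"positions must be (20, 3), got {self.positions.shape}")
        if self.states.shape != (N_JOINTS,):
            raise ValidationError(f"states must be (20,), got {self.states.shape}")
        if self.orientations.shape != (N_JOINTS, 3):
            raise ValidationError(f"orientations must be (20, 3), got {self.orientations.shape}")
        tracked = self.states != TrackingState.NOT_TRACKED
        if not np.isfinite(self.positions[tracked]).all():
            raise ValidationError("non-finite position on a joint that is not NOT_TRACKED")

    def position(self, joint: JointId) -> np.ndarray:
        return self.positions[int(joint)]

    def state(self, joint: JointId) -> TrackingState:
        return TrackingState(int(self.states[int(joint)]))


class SkeletonStream:
    """An ordered sequence of skeleton frames plus metadata and exclusions.

    Column-major storage (one array per field across frames) keeps rule
    evaluation vectorisable; :meth:`frame` gives a per-frame view when the
    row-wise picture is more natural (calibration, fusion).
    """

    def __init__(
        self,
        timestamps: np.ndarray,
        positions: np.ndarray,
        states: np.ndarray,
        orientations: np.ndarray,
        *,
        nominal_rate: float = 30.0,
        metadata: dict | None = None,
        exclusions: list[tuple[float, float]] | None = None,
        provenance: np.ndarray | None = None,
    ):
        self.timestamps = np.asarray(timestamps, dtype=np.float64)
        self.positions = np.asarray(positions, dtype=np.float32)
        self.states = np.asarray(states, dtype=np.uint8)
        self.orientations = np.asarray(orientations, dtype=np.float32)
        self.nominal_rate = float(nominal_rate)
        self.metadata = dict(metadata or {})
        self.provenance = None if provenance is None else np.asarray(provenance, dtype=np.uint8)
        self.exclusions = _validate_intervals(list(exclusions or []), merge=True)
        self._validate()
        self._excluded_mask: np.ndarray | None = None
        self._run_ids: np.ndarray | None = None

    def _validate(self) -> None:
        n = len(self.timestamps)
        if self.positions.shape != (n, N_JOINTS, 3):
            raise ValidationError(f"positions must be (n, 20, 3), got {self.positions.shape}")
        if self.states.shape != (n, N_JOINTS):
            raise ValidationError(f"states must be (n, 20), got {self.states.shape}")
        if self.orientations.shape != (n, N_JOINTS, 3):
            raise ValidationError(f"orientations must be (n, 20, 3), got {self.orientations.shape}")
        if self.provenance is not None and self.provenance.shape != (n, N_JOINTS):
            raise ValidationError("provenance must be (n, 20)")
        if n and not (np.diff(self.timestamps) > 0).all():
            raise ValidationError("timestamps must be strictly increasing")
        if self.nominal_rate <= 0:
            raise ValidationError("nominal_rate must be positive")
        tracked = self.states != TrackingState.NOT_TRACKED
        if not np.isfinite(self.positions[tracked]).all():
            raise ValidationError("non-finite position on a joint that is not NOT_TRACKED")
        if n:
            # Keep intervals inside the recorded span; allow the end to reach
            # one frame period past the last timestamp so the final frame can
            # be flagged with a half-open interval.
            limit = float(self.timestamps[-1]) + 1.0 / self.nominal_rate
            self.exclusions = [
                (s, min(e, limit)) for s, e in self.exclusions if s <= self.timestamps[-1]
            ]

    # -- basic accessors ---------------------------------------------------

    @property
    def n_frames(self) -> int:
        return len(self.timestamps)

    @property
    def duration(self) -> float:
        return float(self.timestamps[-1] - self.timestamps[0]) if self.n_frames else 0.0

    def frame(self, i: int) -> Frame:
        return Frame(
            timestamp=float(self.timestamps[i]),
            positions=self.positions[i].copy(),
            states=self.states[i].copy(),
            orientations=self.orientations[i].copy(),
        )

    def frames(self):
        for i in range(self.n_frames):
            yield self.frame(i)

    @classmethod
    def from_frames(
        cls,
        frames: list[Frame],
        *,
        nominal_rate: float = 30.0,
        metadata: dict | None = None,
        exclusions: list[tuple[float, float]] | None = None,
        provenance: np.ndarray | None = None,
    ) -> "SkeletonStream":
        n = len(frames)
        ts = np.array([f.timestamp for f in frames], dtype=np.float64)
        pos = np.stack([f.positions for f in frames]) if n else np.zeros((0, N_JOINTS, 3), np.float32)
        st = np.stack([f.states for f in frames]) if n else np.zeros((0, N_JOINTS), np.uint8)
        ori = np.stack([f.orientations for f in frames]) if n else np.zeros((0, N_JOINTS, 3), np.float32)
        return cls(ts, pos, st, ori, nominal_rate=nominal_rate, metadata=metadata,
                   exclusions=exclusions, provenance=provenance)

    # -- exclusions --------------------------------------------------------

    @property
    def excluded_mask(self) -> np.ndarray:
        """Boolean mask, True where start <= t < end for some exclusion."""
        if self._excluded_mask is None:
            mask = np.zeros(self.n_frames, dtype=bool)
            for s, e in self.exclusions:
                mask |= (self.timestamps >= s) & (self.timestamps < e)
            self._excluded_mask = mask
        return self._excluded_mask

    @property
    def run_ids(self) -> np.ndarray:
        """Integer id of the contiguous non-excluded run each frame belongs
        to; -1 for excluded frames.  The matcher requires anchor and evidence
        to share a run, which forbids matching across an exclusion boundary."""
        if self._run_ids is None:
            mask = self.excluded_mask
            ids = np.full(self.n_frames, -1, dtype=np.int64)
            run = -1
            prev_excluded = True
            for i in range(self.n_frames):
                if mask[i]:
                    prev_excluded = True
                    continue
                if prev_excluded:
                    run += 1
                    prev_excluded = False
                ids[i] = run
            self._run_ids = ids
        return self._run_ids

    def copy(self) -> "SkeletonStream":
        return SkeletonStream(
            self.timestamps.copy(), self.positions.copy(), self.states.copy(),
            self.orientations.copy(), nominal_rate=self.nominal_rate,
            metadata=dict(self.metadata), exclusions=list(self.exclusions),
            provenance=None if self.provenance is None else self.provenance.copy(),
        )

    def __eq__(self, other) -> bool:
        if not isinstance(other, SkeletonStream):
            return NotImplemented
        prov_eq = (self.provenance is None) == (other.provenance is None) and (
            self.provenance is None or np.array_equal(self.provenance, other.provenance)
        )
        return (
            np.array_equal(self.timestamps, other.timestamps)
            and np.array_equal(self.positions, other.positions, equal_nan=True)
            and np.array_equal(self.states, other.states)
            and np.array_equal(self.orientations, other.orientations, equal_nan=True)
            and self.nominal_rate == other.nominal_rate
            and self.metadata == other.metadata
            and self.exclusions == other.exclusions
            and prov_eq
        )

    def __repr__(self) -> str:
        return (f"SkeletonStream(n_frames={self.n_frames}, rate={self.nominal_rate}, "
                f"duration={self.duration:.2f}s, exclusions={len(self.exclusions)})")


def _validate_intervals(intervals: list[tuple[float, float]], *, merge: bool = False):
    """Check [start, end) intervals are well formed and non-overlapping.

    With merge=True, coalesce duplicates/adjacent-identical spans so that
    re-applying the same exclusions is idempotent.
    """
    out: list[tuple[float, float]] = []
    for s, e in intervals:
        s, e = float(s), float(e)
        if not (np.isfinite(s) and np.isfinite(e)) or s < 0 or e <= s:
            raise ValidationError(f"invalid exclusion interval [{s}, {e})")
        out.append((s, e))
    out.sort()
    merged: list[tuple[float, float]] = []
    for s, e in out:
        if merged and s < merged[-1][1]:
            if merge:
                merged[-1] = (merged[-1][0], max(merged[-1][1], e))
                continue
            raise ValidationError(f"overlapping exclusion intervals at [{s}, {e})")
        merged.append((s, e))
    return merged


def apply_exclusions(stream: SkeletonStream, intervals: list[tuple[float, float]]) -> SkeletonStream:
    """Return a copy of *stream* with *intervals* merged into its exclusions.

    Frames are not deleted; they are flagged via the stream's exclusion list.
    Intervals supplied in one call must be non-overlapping; across calls the
    union is taken, so flagging is idempotent and order-independent for
    disjoint intervals.
    """
    _validate_intervals(intervals)  # reject overlapping/inverted input
    new = stream.copy()
    new.exclusions = _validate_intervals(new.exclusions + [(float(s), float(e)) for s, e in intervals],
                                         merge=True)
    new._validate()
    return new


# -- .kss binary I/O -------------------------------------------------------

def _meta_path(path: Path) -> Path:
    return Path(str(path) + ".meta.json")


def write_stream(stream: SkeletonStream, destination) -> None:
    """Write *stream* to *destination* in the ``.kss`` binary layout.

    Byte-identical output for identical input.  Metadata and exclusions go to
    a ``<destination>.meta.json`` sidecar (written only when non-empty).
    """
    path = Path(destination)
    n = stream.n_frames
    arr = np.zeros(n, dtype=FRAME_DTYPE)
    arr["t"] = stream.timestamps
    arr["joints"]["pos"] = stream.positions
    val = stream.states.astype(np.uint8) & _STATE_MASK
    if stream.provenance is not None:
        val = val | (stream.provenance.astype(np.uint8) << _PROV_SHIFT)
    arr["joints"]["val"] = val
    arr["orient"] = stream.orientations
    header = MAGIC + np.array(
        [FORMAT_VERSION, 0], dtype="<u2"
    ).tobytes() + np.array(
        [n, round(stream.nominal_rate * 1000)], dtype="<u4"
    ).tobytes()
    assert len(header) == HEADER_BYTES
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(arr.tobytes())
    if stream.metadata or stream.exclusions:
        sidecar = {
            "metadata": stream.metadata,
            "exclusions": [[s, e] for s, e in stream.exclusions],
            "fused": stream.provenance is not None,
        }
        _meta_path(path).write_text(json.dumps(sidecar, sort_keys=True, indent=2) + "\n")


def read_stream(source) -> SkeletonStream:
    """Read a ``.kss`` file (and its sidecar, if present)."""
    path = Path(source)
    raw = path.read_bytes()
    if len(raw) < HEADER_BYTES:
        raise FormatError(f"{path}: file shorter than the 16-byte header")
    if raw[:4] != MAGIC:
        raise FormatError(f"{path}: bad magic {raw[:4]!r}, expected {MAGIC!r}")
    version = int(np.frombuffer(raw[4:6], dtype="<u2")[0])
    if version != FORMAT_VERSION:
        raise FormatError(f"{path}: unsupported stream format version {version}")
    n, rate_mhz = (int(x) for x in np.frombuffer(raw[8:16], dtype="<u4"))
    body = raw[HEADER_BYTES:]
    if len(body) != n * FRAME_BYTES:
        bad_frame = min(len(body) // FRAME_BYTES, n - 1) if n else 0
        raise CorruptFileError(
            f"{path}: expected {n} frames ({n * FRAME_BYTES} bytes), got "
            f"{len(body)} bytes; file truncated at frame {bad_frame}",
            frame_index=bad_frame,
        )
    arr = np.frombuffer(body, dtype=FRAME_DTYPE)
    val = arr["joints"]["val"]
    states = (val & _STATE_MASK).astype(np.uint8)
    prov = (val >> _PROV_SHIFT).astype(np.uint8)
    metadata: dict = {}
    exclusions: list[tuple[float, float]] = []
    fused = bool(prov.any())
    mp = _meta_path(path)
    if mp.exists():
        sidecar = json.loads(mp.read_text())
        metadata = sidecar.get("metadata", {})
        exclusions = [tuple(x) for x in sidecar.get("exclusions", [])]
        fused = sidecar.get("fused", fused)
    return SkeletonStream(
        arr["t"].copy(),
        arr["joints"]["pos"].copy(),
        states.copy(),
        arr["orient"].copy(),
        nominal_rate=rate_mhz / 1000.0,
        metadata=metadata,
        exclusions=exclusions,
        provenance=prov.copy() if fused else None,
    )


# -- JSONL interchange -----------------------------------------------------

def stream_to_jsonl(stream: SkeletonStream, destination) -> None:
    """One frame per line: timestamp, named joints (pos + state), orientations."""
    names = [j.name.lower() for j in JointId]
    state_names = {int(s): s.name.lower() for s in TrackingState}
    with open(destination, "w") as fh:
        for i in range(stream.n_frames):
            rec = {
                "t": float(stream.timestamps[i]),
                "joints": {
                    names[k]: {
                        "pos": [float(x) for x in stream.positions[i, k]],
                        "state": state_names[int(stream.states[i, k])],
                    }
                    for k in range(N_JOINTS)
                },
                "orientations": {
                    names[k]: [float(x) for x in stream.orientations[i, k]]
                    for k in range(N_JOINTS)
                },
            }
            fh.write(json.dumps(rec) + "\n")


def stream_from_jsonl(source, *, nominal_rate: float = 30.0,
                      metadata: dict | None = None,
                      exclusions: list[tuple[float, float]] | None = None) -> SkeletonStream:
    state_codes = {s.name.lower(): int(s) for s in TrackingState}
    ts, pos, st, ori = [], [], [], []
    with open(source) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            rec = json.loads(line)
            ts.append(rec["t"])
            p = np.zeros((N_JOINTS, 3), np.float32)
            s = np.zeros(N_JOINTS, np.uint8)
            o = np.zeros((N_JOINTS, 3), np.float32)
            for j in JointId:
                jr = rec["joints"][j.name.lower()]
                p[int(j)] = jr["pos"]
                s[int(j)] = state_codes[jr["state"]]
                o[int(j)] = rec["orientations"][j.name.lower()]
            pos.append(p)
            st.append(s)
            ori.append(o)
    n = len(ts)
    return SkeletonStream(
        np.array(ts, np.float64),
        np.stack(pos) if n else np.zeros((0, N_JOINTS, 3), np.float32),
        np.stack(st) if n else np.zeros((0, N_JOINTS), np.uint8),
        np.stack(ori) if n else np.zeros((0, N_JOINTS, 3), np.float32),
        nominal_rate=nominal_rate, metadata=metadata, exclusions=exclusions,
    )


# -- exclusion interval CSV ------------------------------------------------

def read_exclusions_csv(source) -> list[tuple[float, float]]:
    """Read ``start_s,end_s`` rows; returns validated intervals."""
    intervals: list[tuple[float, float]] = []
    with open(source, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or not {"start_s", "end_s"} <= set(reader.fieldnames):
            raise FormatError(f"{source}: exclusions CSV needs columns start_s,end_s")
        for row in reader:
            intervals.append((float(row["start_s"]), float(row["end_s"])))
    return _validate_intervals(intervals)


def write_exclusions_csv(intervals: list[tuple[float, float]], destination) -> None:
    with open(destination, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["start_s", "end_s"])
        for s, e in intervals:
            writer.writerow([s, e])
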