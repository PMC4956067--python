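"""Dual-sensor calibration and per-joint fusion.

Two depth sensors placed on either side of the player view the same body.
The player holds a T-pose (arms horizontally abducted); because both sensors
sit at the same height, their relative pose reduces to a yaw about the
vertical axis plus a translation.  The wrist-to-wrist vector, projected onto
the horizontal (XZ) plane, gives the yaw; aligning the hip centre after
rotation gives the translation.  As a sanity check the 3D wrist span must
agree between the cameras to within 10 cm, otherwise the calibration is
rejected.

Fusion maps camera 2 into camera 1's coordinates and merges joint-by-joint:
valid in both -> coordinate-wise mean; valid in one -> that camera's value;
valid in neither -> camera 1's stored value.  "Valid" means Tracked or
Inferred, with Tracked preferred when the two cameras disagree in state
(averaging only when the states are equal).  Each fused sample carries a
provenance code recording which branch produced it.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import (
    CalibrationRejectedError,
    MissingLandmarkError,
    NoOverlapError,
    ValidationError,
)
from .skeleton import (
    Frame,
    FusionSource,
    JointId,
    SkeletonStream,
    TrackingState,
)

WRIST_SPAN_TOLERANCE_M = 0.10


def _rot_y(yaw_deg: float) -> np.ndarray:
    """Rotation about the vertical (Y) axis.

    In the X-right / Y-up / Z-away convention, R(90 deg) maps (1,0,0) to
    (0,0,-1).
    """
    th = math.radians(yaw_deg)
    c, s = math.cos(th), math.sin(th)
    return np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])


@dataclass
class Calibration:
    """Rigid mapping of camera-2 coordinates into camera 1's frame.

    yaw_deg : rotation of camera 2 about the vertical axis relative to
        camera 1, degrees.  transform applies R(yaw) then the translation.
    translation : metres, aligns camera 2's hip centre with camera 1's after
        rotation.
    wrist_distance_diff_m : |span_cam1 - span_cam2| of the 3D wrist-to-wrist
        distance; the calibration is valid iff this is below 10 cm.
    """

    yaw_deg: float
    translation: np.ndarray
    wrist_distance_diff_m: float

    def __post_init__(self):
        self.translation = np.asarray(self.translation, dtype=np.float64)
        if self.translation.shape != (3,):
            raise ValidationError("translation must be a 3-vector")

    @property
    def valid(self) -> bool:
        return self.wrist_distance_diff_m < WRIST_SPAN_TOLERANCE_M

    @property
    def rotation(self) -> np.ndarray:
        return _rot_y(self.yaw_deg)

    def apply(self, positions: np.ndarray) -> np.ndarray:
        """Map camera-2 positions (..., 3) into camera 1's frame."""
        return positions @ self.rotation.T + self.translation

    def apply_inverse(self, positions: np.ndarray) -> np.ndarray:
        """Map camera-1 positions into camera 2's frame (exact inverse)."""
        return (positions - self.translation) @ self.rotation

    def to_json(self, destination=None) -> str:
        payload = json.dumps(
            {
                "yaw_deg": self.yaw_deg,
                "translation": [float(x) for x in self.translation],
                "wrist_distance_diff_m": self.wrist_distance_diff_m,
                "valid": self.valid,
            },
            sort_keys=True,
            indent=2,
        )
        if destination is not None:
            Path(destination).write_text(payload + "\n")
        return payload

    @classmethod
    def from_json(cls, source) -> "Calibration":
        if isinstance(source, (str, Path)) and Path(source).exists():
            data = json.loads(Path(source).read_text())
        else:
            data = json.loads(source)
        return cls(
            yaw_deg=float(data["yaw_deg"]),
            translation=np.array(data["translation"], dtype=np.float64),
            wrist_distance_diff_m=float(data["wrist_distance_diff_m"]),
        )


def _wrap_deg(angle: float) -> float:
    """Wrap to (-180, 180]."""
    a = (angle + 180.0) % 360.0 - 180.0
    return 180.0 if a == -180.0 else a


def calibrate(tpose_cam1: Frame, tpose_cam2: Frame, *, strict: bool = True) -> Calibration:
    """Estimate the camera-2 -> camera-1 mapping from a T-pose frame pair.

    Both wrists must be Tracked in both frames.  Raises
    :class:`CalibrationRejectedError` when the wrist spans differ by 10 cm or
    more (pass ``strict=False`` to get the invalid Calibration back instead).
    """
    for cam, frame in (("camera 1", tpose_cam1), ("camera 2", tpose_cam2)):
        for wrist in (JointId.WRIST_LEFT, JointId.WRIST_RIGHT):
            if frame.state(wrist) != TrackingState.TRACKED:
                raise MissingLandmarkError(
                    f"{wrist.name.lower()} is not Tracked in {cam}; cannot calibrate"
                )
    w1 = tpose_cam1.position(JointId.WRIST_RIGHT).astype(np.float64) - tpose_cam1.position(
        JointId.WRIST_LEFT
    ).astype(np.float64)
    w2 = tpose_cam2.position(JointId.WRIST_RIGHT).astype(np.float64) - tpose_cam2.position(
        JointId.WRIST_LEFT
    ).astype(np.float64)
    span_diff = abs(float(np.linalg.norm(w1)) - float(np.linalg.norm(w2)))

    # Signed yaw such that R(yaw) aligns camera 2's wrist vector (XZ plane)
    # with camera 1's.  R(yaw) multiplies x+iz by exp(-i*yaw).
    a1 = math.atan2(w1[2], w1[0])
    a2 = math.atan2(w2[2], w2[0])
    yaw_deg = _wrap_deg(math.degrees(a2 - a1))

    rot = _rot_y(yaw_deg)
    hip1 = tpose_cam1.position(JointId.HIP_CENTRE).astype(np.float64)
    hip2 = tpose_cam2.position(JointId.HIP_CENTRE).astype(np.float64)
    translation = hip1 - rot @ hip2

    calib = Calibration(yaw_deg=yaw_deg, translation=translation,
                        wrist_distance_diff_m=span_diff)
    if strict and not calib.valid:
        raise CalibrationRejectedError(
            f"wrist span differs by {span_diff * 100:.1f} cm between cameras "
            f"(must be < {WRIST_SPAN_TOLERANCE_M * 100:.0f} cm)"
        )
    return calib


def transform_frame(frame: Frame, calib: Calibration) -> Frame:
    """Map every joint position of a camera-2 frame into camera 1's frame.

    States, orientations and the timestamp are unchanged.
    """
    if not calib.valid:
        raise ValidationError("refusing to transform with an invalid calibration")
    return Frame(
        timestamp=frame.timestamp,
        positions=calib.apply(frame.positions),
        states=frame.states.copy(),
        orientations=frame.orientations.copy(),
    )


def transform_stream(stream: SkeletonStream, calib: Calibration) -> SkeletonStream:
    if not calib.valid:
        raise ValidationError("refusing to transform with an invalid calibration")
    new = stream.copy()
    new.positions = calib.apply(stream.positions.astype(np.float64)).astype(np.float32)
    return new


def _fusion_valid(states: np.ndarray) -> np.ndarray:
    return states != TrackingState.NOT_TRACKED


def fuse_streams(s1: SkeletonStream, s2: SkeletonStream, calib: Calibration) -> SkeletonStream:
    """Fuse two simultaneously recorded streams into one (camera 1 clock).

    Camera 2 frames are transformed into camera 1's coordinates and paired to
    camera 1 frames by nearest timestamp within half a frame period; unpaired
    camera 1 frames pass through as cam1_only.  Per-joint merge rules are
    described in the module docstring.
    """
    if not calib.valid:
        raise ValidationError("cannot fuse with an invalid calibration")
    if s1.n_frames == 0 or s2.n_frames == 0:
        raise ValidationError("both streams must be nonempty")
    if s1.timestamps[-1] < s2.timestamps[0] or s2.timestamps[-1] < s1.timestamps[0]:
        raise NoOverlapError("the two streams do not overlap in time")

    pos2 = calib.apply(s2.positions.astype(np.float64)).astype(np.float32)
    tol = 1.0 / (2.0 * s1.nominal_rate)
    idx = np.searchsorted(s2.timestamps, s1.timestamps)
    pair = np.full(s1.n_frames, -1, dtype=np.int64)
    for i in range(s1.n_frames):
        best, best_dt = -1, tol
        for j in (idx[i] - 1, idx[i]):
            if 0 <= j < s2.n_frames:
                dt = abs(float(s2.timestamps[j] - s1.timestamps[i]))
                if dt <= best_dt:
                    best, best_dt = j, dt
        pair[i] = best

    out_pos = s1.positions.copy()
    out_states = s1.states.copy()
    prov = np.full((s1.n_frames, 20), int(FusionSource.CAM1_ONLY), dtype=np.uint8)

    paired = pair >= 0
    for i in np.nonzero(paired)[0]:
        j = pair[i]
        st1 = s1.states[i]
        st2 = s2.states[j]
        v1 = _fusion_valid(st1)
        v2 = _fusion_valid(st2)
        both = v1 & v2
        equal_state = st1 == st2
        avg = both & equal_state
        prefer1 = both & ~equal_state & (st1 > st2)
        prefer2 = both & ~equal_state & (st2 > st1)
        only1 = v1 & ~v2
        only2 = v2 & ~v1
        neither = ~v1 & ~v2

        out_pos[i, avg] = (
            (s1.positions[i, avg].astype(np.float64) + pos2[j, avg].astype(np.float64)) / 2.0
        ).astype(np.float32)
        prov[i, avg] = int(FusionSource.AVERAGED)

        sel2 = prefer2 | only2
        out_pos[i, sel2] = pos2[j, sel2]
        out_states[i, sel2] = st2[sel2]
        prov[i, sel2] = int(FusionSource.CAM2_ONLY)

        prov[i, prefer1 | only1] = int(FusionSource.CAM1_ONLY)
        prov[i, neither] = int(FusionSource.FALLBACK_CAM1)

    return SkeletonStream(
        s1.timestamps.copy(),
        out_pos,
        out_states,
        s1.orientations.copy(),
        nominal_rate=s1.nominal_rate,
        metadata={**s1.metadata, "fused": True},
        exclusions=list(s1.exclusions),
        provenance=prov,
    )
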