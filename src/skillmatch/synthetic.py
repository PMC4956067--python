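"""Labelled synthetic skeleton streams for end-to-end testing.

Real recordings of children playing movement-controlled games were never
deposited anywhere this package can reach, so every pipeline stage is
exercised on generated data with known ground truth instead.  The generator
emulates the two study conditions:

* a supervised *FMS condition* — three jumps and twelve sidesteps (six to
  each side), performed cleanly in front of the sensors; and
* a *game-play condition* — several minutes of play containing jumps and
  sidesteps mixed with idle postural sway and tracking dropouts.

A session is a neutral standing pose plus iid Gaussian postural sway, with
event displacement profiles superimposed:

* **jump** — every joint rises and falls with a half-sine of the configured
  amplitude over the event duration (the published rule constrains only net
  displacement and time, so any smooth supra-threshold profile is valid and
  a half-sine exercises the windowing honestly);
* **sidestep** (left = -X, right = +X, matching the rule engine's axis
  convention) — the whole body translates laterally by the amplitude with a
  smoothstep profile while the lead foot steps out early and fast (peak
  excursion >= 1.5x the amplitude, reached within ~0.25 s) before settling;
  the trailing foot simply follows the body, which is what lets the
  published left-lead branch's "right foot trails by 25 cm" clause fire.

Occlusion spans overwrite tracking states (Inferred or Not Tracked) on a few
random joints.  With a second camera enabled, each view is the ground-truth
motion (camera 2 rigidly transformed) plus independent Gaussian noise, so
fusing the two views should beat either one.  Identical seeds give
byte-identical output files.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from .errors import ValidationError
from .fusion import Calibration
from .skeleton import (
    N_JOINTS,
    Frame,
    JointId,
    SkeletonStream,
    TrackingState,
)

EVENT_TYPES = ("jump", "sidestep_left", "sidestep_right")

# Neutral standing pose of a ~1.4 m child, ~2.5 m from the sensor.
# X = player's right, Y = up, Z = away from the camera; metres.
BASE_POSE: dict[JointId, tuple[float, float, float]] = {
    JointId.HIP_CENTRE: (0.00, 0.80, 2.50),
    JointId.SPINE: (0.00, 0.95, 2.50),
    JointId.SHOULDER_CENTRE: (0.00, 1.10, 2.52),
    JointId.HEAD: (0.00, 1.30, 2.52),
    JointId.SHOULDER_LEFT: (-0.16, 1.08, 2.52),
    JointId.ELBOW_LEFT: (-0.20, 0.90, 2.52),
    JointId.WRIST_LEFT: (-0.22, 0.72, 2.50),
    JointId.HAND_LEFT: (-0.23, 0.64, 2.50),
    JointId.SHOULDER_RIGHT: (0.16, 1.08, 2.52),
    JointId.ELBOW_RIGHT: (0.20, 0.90, 2.52),
    JointId.WRIST_RIGHT: (0.22, 0.72, 2.50),
    JointId.HAND_RIGHT: (0.23, 0.64, 2.50),
    JointId.HIP_LEFT: (-0.09, 0.78, 2.50),
    JointId.KNEE_LEFT: (-0.10, 0.45, 2.50),
    JointId.ANKLE_LEFT: (-0.11, 0.08, 2.50),
    JointId.FOOT_LEFT: (-0.11, 0.03, 2.42),
    JointId.HIP_RIGHT: (0.09, 0.78, 2.50),
    JointId.KNEE_RIGHT: (0.10, 0.45, 2.50),
    JointId.ANKLE_RIGHT: (0.11, 0.08, 2.50),
    JointId.FOOT_RIGHT: (0.11, 0.03, 2.42),
}

# Arms straight, shoulders abducted to horizontal.
TPOSE_OVERRIDES: dict[JointId, tuple[float, float, float]] = {
    JointId.ELBOW_LEFT: (-0.42, 1.10, 2.52),
    JointId.WRIST_LEFT: (-0.68, 1.10, 2.52),
    JointId.HAND_LEFT: (-0.78, 1.10, 2.52),
    JointId.ELBOW_RIGHT: (0.42, 1.10, 2.52),
    JointId.WRIST_RIGHT: (0.68, 1.10, 2.52),
    JointId.HAND_RIGHT: (0.78, 1.10, 2.52),
}

# Lead-foot overshoot: the stepping foot's peak excursion relative to the
# body translation (>= 1.5 so a 30 cm body shift carries the foot past the
# published 30-cm-in-0.3-s clause with margin).
LEAD_FOOT_EXTRA = 1.2
LEAD_FOOT_RISE_S = 0.25


def _base_positions() -> np.ndarray:
    pos = np.zeros((N_JOINTS, 3), dtype=np.float64)
    for j, xyz in BASE_POSE.items():
        pos[int(j)] = xyz
    return pos


def _tpose_positions() -> np.ndarray:
    pos = _base_positions()
    for j, xyz in TPOSE_OVERRIDES.items():
        pos[int(j)] = xyz
    return pos


@dataclass
class Event:
    """One scheduled movement: type, onset, duration, amplitude (metres)."""

    type: str
    onset_s: float
    duration_s: float
    amplitude_m: float

    def __post_init__(self):
        if self.type not in EVENT_TYPES:
            raise ValidationError(f"unknown event type {self.type!r}")
        if self.amplitude_m <= 0:
            raise ValidationError("event amplitude must be positive")
        if self.duration_s <= 0 or self.onset_s < 0:
            raise ValidationError("event onset/duration must be nonnegative/positive")

    @property
    def end_s(self) -> float:
        return self.onset_s + self.duration_s


@dataclass
class Camera2Config:
    """Second sensor: its pose relative to camera 1 and per-view noise."""

    yaw_deg: float = 60.0
    translation: tuple[float, float, float] = (0.0, 0.0, 0.0)
    noise_sd_m: float = 0.005

    def calibration(self) -> Calibration:
        return Calibration(
            yaw_deg=self.yaw_deg,
            translation=np.asarray(self.translation, dtype=np.float64),
            wrist_distance_diff_m=0.0,
        )


@dataclass
class SessionConfig:
    """Everything that defines a synthetic recording session."""

    duration_s: float
    events: list[Event] = field(default_factory=list)
    rate: float = 30.0
    sway_sd_m: float = 0.005
    occlusion_rate_per_min: float = 0.0
    occlusion_mean_span_s: float = 0.5
    camera2: Camera2Config | None = None
    seed: int = 0
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.events = sorted(self.events, key=lambda e: e.onset_s)
        for prev, nxt in zip(self.events, self.events[1:]):
            if nxt.onset_s < prev.end_s:
                raise ValidationError(
                    f"events overlap: {prev.type} ending {prev.end_s:.2f}s vs "
                    f"{nxt.type} starting {nxt.onset_s:.2f}s"
                )
        if self.events and self.duration_s <= max(e.end_s for e in self.events):
            raise ValidationError("duration_s must exceed the last event's end")
        if self.duration_s <= 0 or self.rate <= 0:
            raise ValidationError("duration_s and rate must be positive")
        if self.sway_sd_m < 0 or self.occlusion_rate_per_min < 0:
            raise ValidationError("noise parameters must be nonnegative")

    def to_dict(self) -> dict:
        d = asdict(self)
        if self.camera2 is None:
            d.pop("camera2")
        return d

    @classmethod
    def from_dict(cls, data: dict) -> "SessionConfig":
        data = dict(data)
        data["events"] = [Event(**e) for e in data.get("events", [])]
        if data.get("camera2") is not None:
            cam = dict(data["camera2"])
            if "translation" in cam:
                cam["translation"] = tuple(cam["translation"])
            data["camera2"] = Camera2Config(**cam)
        return cls(**data)

    @classmethod
    def from_file(cls, source) -> "SessionConfig":
        return cls.from_dict(yaml.safe_load(Path(source).read_text()))

    def to_file(self, destination) -> None:
        Path(destination).write_text(json.dumps(self.to_dict(), sort_keys=True, indent=2) + "\n")


@dataclass
class TruthEvent:
    type: str
    onset_s: float
    end_s: float


@dataclass
class GroundTruth:
    """The schedule that generated a stream, for scoring detections."""

    events: list[TruthEvent]

    def of_types(self, types) -> list[TruthEvent]:
        return [e for e in self.events if e.type in types]

    def to_csv(self, destination) -> None:
        with open(destination, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["type", "onset_s", "end_s"])
            for e in self.events:
                writer.writerow([e.type, f"{e.onset_s:.6f}", f"{e.end_s:.6f}"])

    @classmethod
    def from_csv(cls, source) -> "GroundTruth":
        events = []
        with open(source, newline="") as fh:
            for row in csv.DictReader(fh):
                events.append(TruthEvent(row["type"], float(row["onset_s"]), float(row["end_s"])))
        return cls(events)


def _smoothstep(u: np.ndarray) -> np.ndarray:
    u = np.clip(u, 0.0, 1.0)
    return u * u * (3.0 - 2.0 * u)


def _lead_foot_bump(tau: np.ndarray, duration: float) -> np.ndarray:
    """Fast out-and-settle excursion: 0 -> 1 within LEAD_FOOT_RISE_S, then
    back to 0 by the end of the event (the foot plants at the body's net
    translation)."""
    rise = min(LEAD_FOOT_RISE_S, 0.5 * duration)
    out = np.zeros_like(tau)
    up = tau < rise
    out[up] = np.sin(0.5 * np.pi * tau[up] / rise) ** 2
    down = (tau >= rise) & (tau <= duration)
    out[down] = np.cos(0.5 * np.pi * (tau[down] - rise) / max(duration - rise, 1e-9)) ** 2
    return out


def _event_offsets(t: np.ndarray, events: list[Event]) -> np.ndarray:
    """Per-frame (n, 20, 3) displacement offsets implied by the schedule."""
    n = len(t)
    off = np.zeros((n, N_JOINTS, 3), dtype=np.float64)
    for ev in events:
        inside = (t >= ev.onset_s) & (t <= ev.end_s)
        if not inside.any():
            continue
        tau = t[inside] - ev.onset_s
        u = tau / ev.duration_s
        if ev.type == "jump":
            dy = ev.amplitude_m * np.sin(np.pi * np.clip(u, 0.0, 1.0))
            off[inside, :, 1] += dy[:, None]
        else:
            direction = -1.0 if ev.type == "sidestep_left" else 1.0
            lead = JointId.FOOT_LEFT if ev.type == "sidestep_left" else JointId.FOOT_RIGHT
            dx = direction * ev.amplitude_m * _smoothstep(u)
            off[inside, :, 0] += dx[:, None]
            extra = direction * ev.amplitude_m * LEAD_FOOT_EXTRA * _lead_foot_bump(tau, ev.duration_s)
            off[inside, int(lead), 0] += extra
        # events translate the body permanently for sidesteps
        if ev.type != "jump":
            after = t > ev.end_s
            direction = -1.0 if ev.type == "sidestep_left" else 1.0
            off[after, :, 0] += direction * ev.amplitude_m
    return off


def _occlusion_spans(config: SessionConfig, rng: np.random.Generator):
    n_spans = rng.poisson(config.occlusion_rate_per_min * config.duration_s / 60.0)
    spans = []
    for _ in range(n_spans):
        onset = rng.uniform(0.0, config.duration_s)
        span = float(np.clip(rng.exponential(config.occlusion_mean_span_s),
                             0.1, 2.0 * config.occlusion_mean_span_s))
        joints = rng.choice(N_JOINTS, size=rng.integers(1, 4), replace=False)
        state = TrackingState.INFERRED if rng.random() < 0.7 else TrackingState.NOT_TRACKED
        spans.append((onset, onset + span, joints, state))
    return spans


def simulate_session(config: SessionConfig):
    """Generate a session per *config*.

    Returns ``(stream, truth)`` for a single-camera session or
    ``((cam1_stream, cam2_stream), truth)`` when ``config.camera2`` is set.
    Identical configs (including the seed) give identical output.
    """
    rng = np.random.default_rng(config.seed)
    n = int(round(config.duration_s * config.rate))
    t = np.arange(n, dtype=np.float64) / config.rate

    truth_pos = _base_positions()[None, :, :] + _event_offsets(t, config.events)
    truth_pos = truth_pos + rng.normal(0.0, config.sway_sd_m, size=truth_pos.shape)

    states = np.full((n, N_JOINTS), int(TrackingState.TRACKED), dtype=np.uint8)
    for onset, end, joints, state in _occlusion_spans(config, rng):
        mask = (t >= onset) & (t < end)
        for j in joints:
            states[mask, j] = int(state)

    orients = np.zeros((n, N_JOINTS, 3), dtype=np.float32)
    truth = GroundTruth([TruthEvent(e.type, e.onset_s, e.end_s) for e in config.events])
    meta = {"condition": config.metadata.get("condition", "synthetic"), **config.metadata}

    if config.camera2 is None:
        stream = SkeletonStream(
            t, truth_pos.astype(np.float32), states, orients,
            nominal_rate=config.rate, metadata={**meta, "camera": 1},
        )
        return stream, truth

    calib = config.camera2.calibration()
    noise_sd = config.camera2.noise_sd_m
    cam1_pos = truth_pos + rng.normal(0.0, noise_sd, size=truth_pos.shape)
    cam2_pos = calib.apply_inverse(truth_pos) + rng.normal(0.0, noise_sd, size=truth_pos.shape)
    s1 = SkeletonStream(
        t, cam1_pos.astype(np.float32), states.copy(), orients,
        nominal_rate=config.rate, metadata={**meta, "camera": 1},
    )
    s2 = SkeletonStream(
        t, cam2_pos.astype(np.float32), states.copy(), orients.copy(),
        nominal_rate=config.rate, metadata={**meta, "camera": 2},
    )
    return (s1, s2), truth


def simulate_tpose(yaw_deg: float = 0.0, translation=(0.0, 0.0, 0.0),
                   noise_sd: float = 0.0, seed: int = 0) -> tuple[Frame, Frame]:
    """A calibration T-pose seen by both cameras.

    Camera 2's view is the rigid transform of camera 1's (yaw about the
    vertical through the configured translation) plus Gaussian noise.
    Requires |yaw_deg| < 90 so the cameras share a frontal view.
    """
    if not abs(yaw_deg) < 90.0:
        raise ValidationError("|yaw_deg| must be < 90")
    rng = np.random.default_rng(seed)
    base = _tpose_positions()
    calib = Calibration(yaw_deg=yaw_deg,
                        translation=np.asarray(translation, dtype=np.float64),
                        wrist_distance_diff_m=0.0)
    p1 = base + rng.normal(0.0, noise_sd, size=base.shape)
    p2 = calib.apply_inverse(base) + rng.normal(0.0, noise_sd, size=base.shape)
    states = np.full(N_JOINTS, int(TrackingState.TRACKED), dtype=np.uint8)
    orients = np.zeros((N_JOINTS, 3), dtype=np.float32)
    f1 = Frame(0.0, p1, states.copy(), orients.copy())
    f2 = Frame(0.0, p2, states.copy(), orients.copy())
    return f1, f2


# -- study-condition presets -------------------------------------------------

#: Default event amplitudes (metres): a modest child jump raises the body
#: ~15 cm; a deliberate sidestep translates the body ~30 cm.
JUMP_AMPLITUDE_M = 0.15
SIDESTEP_AMPLITUDE_M = 0.30
JUMP_DURATION_S = 0.45
SIDESTEP_DURATION_S = 0.60


def fms_condition_config(seed: int = 0, *, jump_amplitude_m: float = JUMP_AMPLITUDE_M,
                         sidestep_amplitude_m: float = SIDESTEP_AMPLITUDE_M,
                         camera2: Camera2Config | None = None) -> SessionConfig:
    """The supervised skills task: three jumps then twelve sidesteps, six to
    each side, well separated, no occlusion."""
    events = [Event("jump", 2.0 + 2.5 * i, JUMP_DURATION_S, jump_amplitude_m) for i in range(3)]
    side = ["sidestep_right", "sidestep_left"] * 6
    events += [
        Event(side[i], 11.0 + 2.5 * i, SIDESTEP_DURATION_S, sidestep_amplitude_m)
        for i in range(12)
    ]
    return SessionConfig(
        duration_s=45.0,
        events=events,
        sway_sd_m=0.005,
        occlusion_rate_per_min=0.0,
        camera2=camera2,
        seed=seed,
        metadata={"condition": "fms"},
    )


def gameplay_condition_config(seed: int = 0, *, duration_s: float = 300.0,
                              n_jumps: int = 20, n_sidesteps: int = 12,
                              occlusion_rate_per_min: float = 2.0) -> SessionConfig:
    """Five minutes of game-play-like motion: randomly interleaved jumps and
    sidesteps (alternating direction to stay in the capture space) with
    tracking dropouts."""
    rng = np.random.default_rng(seed)
    n_events = n_jumps + n_sidesteps
    slot = 2.5
    n_slots = int((duration_s - 4.0) / slot)
    if n_events > n_slots:
        raise ValidationError("too many events for the session duration")
    onsets = 2.0 + slot * np.sort(rng.choice(n_slots, size=n_events, replace=False))
    types = ["jump"] * n_jumps + ["sidestep_right", "sidestep_left"] * (n_sidesteps // 2)
    types += ["sidestep_right"] * (n_sidesteps - 2 * (n_sidesteps // 2))
    rng.shuffle(types)
    # keep sidestep direction alternating so the player drifts, not walks off
    direction = 1
    events = []
    for onset, typ in zip(onsets, types):
        if typ.startswith("sidestep"):
            typ = "sidestep_right" if direction > 0 else "sidestep_left"
            direction = -direction
            events.append(Event(typ, float(onset), SIDESTEP_DURATION_S, SIDESTEP_AMPLITUDE_M))
        else:
            events.append(Event("jump", float(onset), JUMP_DURATION_S, JUMP_AMPLITUDE_M))
    return SessionConfig(
        duration_s=duration_s,
        events=events,
        sway_sd_m=0.005,
        occlusion_rate_per_min=occlusion_rate_per_min,
        occlusion_mean_span_s=0.5,
        seed=seed,
        metadata={"condition": "gameplay"},
    )


# -- scoring -----------------------------------------------------------------

DEFAULT_TYPE_MAP = {"JUMP": ("jump",), "SIDESTEP": ("sidestep_left", "sidestep_right")}


@dataclass
class DetectionScore:
    true_pos: int
    false_pos: int
    false_neg: int
    precision: float
    recall: float
    precision_defined: bool = True


def score_detection(truth: GroundTruth, summary, tolerance_s: float = 0.5,
                    type_map: dict[str, tuple[str, ...]] | None = None
                    ) -> dict[str, DetectionScore]:
    """Greedy one-to-one matching of detections to truth events by onset.

    Each detection claims the nearest unclaimed truth event of the matching
    type within *tolerance_s* of its start.  With no detections at all,
    precision is undefined and reported as 1.0 with ``precision_defined``
    False.
    """
    type_map = DEFAULT_TYPE_MAP if type_map is None else type_map
    scores: dict[str, DetectionScore] = {}
    for rule_name, types in type_map.items():
        detections = sorted(summary.matches.get(rule_name, []), key=lambda m: m.start_s)
        events = sorted(truth.of_types(types), key=lambda e: e.onset_s)
        claimed = [False] * len(events)
        tp = 0
        for det in detections:
            best, best_dt = None, tolerance_s
            for i, ev in enumerate(events):
                if claimed[i]:
                    continue
                dt = abs(det.start_s - ev.onset_s)
                if dt <= best_dt:
                    best, best_dt = i, dt
            if best is not None:
                claimed[best] = True
                tp += 1
        fp = len(detections) - tp
        fn = len(events) - tp
        if detections:
            precision, defined = tp / len(detections), True
        else:
            precision, defined = 1.0, False
        recall = tp / len(events) if events else 1.0
        scores[rule_name] = DetectionScore(tp, fp, fn, precision, recall, defined)
    return scores
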