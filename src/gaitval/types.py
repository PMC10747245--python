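"""Core time-series containers shared across the pipeline.

Coordinate convention: x is the direction of progression, y is up, the
origin sits at the walkway start, and pixel coordinates are metres
multiplied by ``pixel_scale``.  Readers and writers for external formats
(OpenPose JSON uses image coordinates with y pointing down) perform the
conversion so everything in memory obeys this frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: The 12 feature points used for bilateral sagittal lower-limb analysis,
#: in canonical order.  Index into ``PoseSequence.xy`` with
#: ``KEYPOINTS.index(name)`` or the :func:`kp_index` helper.
KEYPOINTS: tuple[str, ...] = (
    "Neck",
    "MidHip",
    "RHip",
    "RKnee",
    "RAnkle",
    "RBigToe",
    "RHeel",
    "LHip",
    "LKnee",
    "LAnkle",
    "LBigToe",
    "LHeel",
)

SIDES: tuple[str, ...] = ("right", "left")
JOINTS: tuple[str, ...] = ("hip", "knee", "ankle")

_KP_INDEX = {name: i for i, name in enumerate(KEYPOINTS)}


def kp_index(name: str) -> int:
    """Column index of a keypoint name in the canonical 12-point order."""
    try:
        return _KP_INDEX[name]
    except KeyError:
        raise KeyError(f"unknown keypoint {name!r}; expected one of {KEYPOINTS}") from None


def kp_side(name: str) -> str:
    """'right', 'left', or 'axial' for a keypoint name."""
    if name.startswith("R"):
        return "right"
    if name.startswith("L"):
        return "left"
    return "axial"


def _check_timestamps(timestamps: np.ndarray) -> None:
    if timestamps.ndim != 1:
        raise ValueError("timestamps must be one-dimensional")
    if len(timestamps) >= 2:
        dt = np.diff(timestamps)
        if np.any(dt <= 0):
            raise ValueError("timestamps must be strictly increasing")
        if np.max(dt) > 1.01 * np.min(dt):
            raise ValueError("sampling interval varies by more than 1%")


@dataclass
class PoseSequence:
    """Time-indexed bilateral keypoint coordinates with confidences.

    Parameters
    ----------
    timestamps : (n,) array, seconds
    xy : (n, 12, 2) array, pixels, canonical keypoint order
    confidence : (n, 12) array in [0, 1]; 0 marks a missing estimate
    imputed : (n, 12) bool array; True where a gap was filled
    side_flags : accumulated per-side quality flags (reason strings)
    unusable_sides : sides invalidated by gaps too long to interpolate
    """

    timestamps: np.ndarray
    xy: np.ndarray
    confidence: np.ndarray
    imputed: np.ndarray = None  # type: ignore[assignment]
    side_flags: dict = field(default_factory=dict)
    unusable_sides: set = field(default_factory=set)

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.xy = np.asarray(self.xy, dtype=float)
        self.confidence = np.asarray(self.confidence, dtype=float)
        n = len(self.timestamps)
        if self.xy.shape != (n, len(KEYPOINTS), 2):
            raise ValueError(f"xy must have shape ({n}, {len(KEYPOINTS)}, 2), got {self.xy.shape}")
        if self.confidence.shape != (n, len(KEYPOINTS)):
            raise ValueError("confidence must have shape (n, 12)")
        if np.any((self.confidence < 0) | (self.confidence > 1)):
            raise ValueError("confidence values must lie in [0, 1]")
        _check_timestamps(self.timestamps)
        if self.imputed is None:
            self.imputed = np.zeros_like(self.confidence, dtype=bool)
        valid = self.confidence > 0
        if not np.all(np.isfinite(self.xy[valid])):
            raise ValueError("coordinates must be finite where confidence > 0")

    @property
    def n_frames(self) -> int:
        return len(self.timestamps)

    @property
    def rate(self) -> float:
        """Nominal sampling rate in Hz."""
        if self.n_frames < 2:
            raise ValueError("rate undefined for sequences shorter than 2 frames")
        return 1.0 / float(np.median(np.diff(self.timestamps)))

    @property
    def valid(self) -> np.ndarray:
        """(n, 12) bool mask of frames usable for angle computation."""
        return self.confidence > 0

    def point(self, name: str) -> np.ndarray:
        """(n, 2) trajectory of one keypoint."""
        return self.xy[:, kp_index(name), :]

    def copy(self) -> "PoseSequence":
        return PoseSequence(
            timestamps=self.timestamps.copy(),
            xy=self.xy.copy(),
            confidence=self.confidence.copy(),
            imputed=self.imputed.copy(),
            side_flags={k: list(v) for k, v in self.side_flags.items()},
            unusable_sides=set(self.unusable_sides),
        )

    def add_side_flag(self, side: str, reason: str) -> None:
        self.side_flags.setdefault(side, []).append(reason)


@dataclass
class JointCenterSequence:
    """Reference joint-centre trajectories (marker-based stand-in).

    Same 12-point vocabulary as :class:`PoseSequence`; confidence is
    implicitly 1 everywhere.
    """

    timestamps: np.ndarray
    xy: np.ndarray

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.xy = np.asarray(self.xy, dtype=float)
        n = len(self.timestamps)
        if self.xy.shape != (n, len(KEYPOINTS), 2):
            raise ValueError(f"xy must have shape ({n}, {len(KEYPOINTS)}, 2), got {self.xy.shape}")
        _check_timestamps(self.timestamps)
        if not np.all(np.isfinite(self.xy)):
            raise ValueError("reference coordinates must be finite")

    n_frames = PoseSequence.n_frames
    rate = PoseSequence.rate
    point = PoseSequence.point

    @property
    def confidence(self) -> np.ndarray:
        return np.ones(self.xy.shape[:2])

    @property
    def valid(self) -> np.ndarray:
        return np.ones(self.xy.shape[:2], dtype=bool)

    def copy(self) -> "JointCenterSequence":
        return JointCenterSequence(self.timestamps.copy(), self.xy.copy())


@dataclass
class ForceSeries:
    """Vertical ground-reaction-force trace for one limb."""

    timestamps: np.ndarray
    fz: np.ndarray
    side: str

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.fz = np.asarray(self.fz, dtype=float)
        if self.side not in SIDES:
            raise ValueError(f"side must be one of {SIDES}, got {self.side!r}")
        if self.fz.shape != self.timestamps.shape:
            raise ValueError("fz and timestamps must have the same shape")
        if not np.all(np.isfinite(self.fz)):
            raise ValueError("fz must be finite")
        _check_timestamps(self.timestamps)

    @property
    def rate(self) -> float:
        if len(self.timestamps) < 2:
            raise ValueError("rate undefined for series shorter than 2 samples")
        return 1.0 / float(np.median(np.diff(self.timestamps)))

    def copy(self) -> "ForceSeries":
        return ForceSeries(self.timestamps.copy(), self.fz.copy(), self.side)


@dataclass
class AngleWaveform:
    """One joint's sagittal angle versus time for one limb.

    Sign convention: hip flexion, knee flexion and ankle dorsiflexion are
    positive.  ``values`` is NaN on frames where ``valid`` is False.
    """

    joint: str
    side: str
    values: np.ndarray
    timestamps: np.ndarray
    valid: np.ndarray
    flagged: np.ndarray
    source: str = "ai"

    def __post_init__(self) -> None:
        if self.joint not in JOINTS:
            raise ValueError(f"joint must be one of {JOINTS}")
        if self.side not in SIDES:
            raise ValueError(f"side must be one of {SIDES}")
        self.values = np.asarray(self.values, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        self.flagged = np.asarray(self.flagged, dtype=bool)


@dataclass
class GaitCycle:
    """One gait cycle (initial contact to next initial contact, one limb).

    ``normalized_angles`` maps joint name to a 101-point array over
    0..100% of the cycle; point 0 is the value at initial contact.
    """

    side: str
    ic_frame: int
    next_ic_frame: int
    toe_off_frame: int
    normalized_angles: dict

    def __post_init__(self) -> None:
        if not (self.ic_frame < self.toe_off_frame < self.next_ic_frame):
            raise ValueError(
                "gait cycle requires ic_frame < toe_off_frame < next_ic_frame, got "
                f"{self.ic_frame}, {self.toe_off_frame}, {self.next_ic_frame}"
            )
        for joint, arr in self.normalized_angles.items():
            if np.asarray(arr).shape != (101,):
                raise ValueError(f"normalized angles for {joint} must have 101 points")

    @property
    def stance_pct(self) -> float:
        """Toe-off expressed as percent of the cycle."""
        return 100.0 * (self.toe_off_frame - self.ic_frame) / (self.next_ic_frame - self.ic_frame)
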