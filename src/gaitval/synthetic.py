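"""Synthetic planar gait trials with known ground truth.

Generates bilateral sagittal joint-angle waveforms, the 12 lower-limb
feature points consistent with those angles via a planar linkage, and
per-limb vertical ground-reaction forces, so the whole downstream
pipeline (filtering, kinematics, event detection, parameter extraction,
agreement statistics) can be exercised against an exact truth.

Angle waveforms are built from windowed raised-cosine (``cos^4``) lobes
plus a single-harmonic hip curve.  The lobes have compact, disjoint
supports, which makes every phase-restricted extremum equal its profile
amplitude exactly — a property a truncated Fourier fit cannot guarantee.
The curves are periodic and C^3 at the lobe edges.

The left limb is the right limb phase-shifted by exactly half a cycle.
The trial timeline opens with a 20%-of-cycle unloaded lead-in on the
right side so every declared initial contact is preceded by a quiet
period, as a force-based event detector requires.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from pydantic import BaseModel, Field, model_validator

from .types import KEYPOINTS, SIDES, ForceSeries, JointCenterSequence, PoseSequence, kp_index

# Template timing (fractions of the gait cycle; initial contact at 0).
# Centres sit on whole percents so a 101-point normalized grid samples
# the peaks exactly when cycle bounds land on frame boundaries.
_HIP_PEAK_PHASE = 0.92  # peak hip flexion in terminal swing
_KNEE_STANCE_LOBE = (0.18, 0.36)  # (centre, width): loading-response flexion wave
_KNEE_SWING_LOBE = (0.75, 0.30)  # swing flexion peak
_ANKLE_DORSI_LOBE = (0.35, 0.44)  # stance dorsiflexion rocker
_ANKLE_PLANTAR_LOBE = (0.68, 0.22)  # push-off plantarflexion

# Right-side phase of the first frame (unloaded lead-in before first IC).
_LEAD_IN_FRACTION = 0.2

# Foot geometry: heel sits behind and below the ankle joint centre,
# expressed as fractions of foot length along/normal to the foot axis.
_HEEL_BACK_FRAC = 0.2
_HEEL_DROP_FRAC = 0.16

# Double-bump vertical GRF: two raised-cosine lobes over normalized
# stance time, first (loading) peak slightly above body weight.
_GRF_LOBES = ((0.25, 0.70, 1.05), (0.75, 0.70, 1.00))  # (centre, width, peak/BW)


class SegmentLengths(BaseModel):
    """Body segment lengths in metres (anthropometric plumbing)."""

    trunk: float = Field(0.50, gt=0)
    thigh: float = Field(0.41, gt=0)
    shank: float = Field(0.42, gt=0)
    foot: float = Field(0.25, gt=0)


class GaitProfile(BaseModel):
    """Parameters of one synthetic gait trial.

    Amplitudes (degrees) default to normative sagittal peaks for
    comfortable adult walking; video and force rates to 120 Hz and
    1200 Hz.  ``noise_sd`` (pixels) and ``dropout_prob_crossing`` control
    the pose-estimation corruption model and default to zero, i.e. the
    pose stream equals the reference stream exactly.
    """

    cycle_duration: float = Field(1.1, gt=0, description="seconds per gait cycle")
    n_cycles: int = Field(5, ge=1)
    sample_rate_video: float = Field(120.0, gt=0)
    sample_rate_force: float = Field(1200.0, gt=0)
    hip_peak_flex: float = Field(30.6, ge=0)
    hip_peak_ext: float = Field(11.4, ge=0)
    knee_stance_peak_flex: float = Field(15.7, ge=0)
    knee_swing_peak_flex: float = Field(59.7, ge=0)
    ankle_peak_dorsi: float = Field(14.1, ge=0)
    ankle_peak_plantar: float = Field(13.9, ge=0)
    stance_fraction: float = Field(0.6, gt=0, lt=1)
    segment_lengths: SegmentLengths = Field(default_factory=SegmentLengths)
    pixel_scale: float = Field(400.0, gt=0, description="pixels per metre")
    speed: float = Field(1.3, gt=0, description="walking speed, m/s")
    body_weight_n: float = Field(585.0, gt=0, description="body weight, newtons")
    noise_sd: float = Field(0.0, ge=0, description="keypoint noise SD, pixels")
    dropout_prob_crossing: float = Field(0.0, ge=0, le=1)
    crossing_threshold_px: float = Field(20.0, gt=0)
    seed: int = 0

    @model_validator(mode="after")
    def _finite_amplitudes(self) -> "GaitProfile":
        amps = [
            self.hip_peak_flex,
            self.hip_peak_ext,
            self.knee_stance_peak_flex,
            self.knee_swing_peak_flex,
            self.ankle_peak_dorsi,
            self.ankle_peak_plantar,
        ]
        if not np.all(np.isfinite(amps)):
            raise ValueError("all angle amplitudes must be finite")
        return self


@dataclass
class GroundTruthTrial:
    """A simulated trial bundled with its exact ground truth."""

    profile: GaitProfile
    pose: PoseSequence
    reference: JointCenterSequence
    grf_right: ForceSeries
    grf_left: ForceSeries
    true_angles: dict  # (side, joint) -> degrees per video frame
    true_events: dict  # side -> force-sample indices of initial contacts


def _lobe(t: np.ndarray, centre: float, width: float) -> np.ndarray:
    """Periodic cos^4 lobe of unit peak with compact support ``width``."""
    d = (np.asarray(t, dtype=float) - centre + 0.5) % 1.0 - 0.5
    out = np.zeros_like(d)
    inside = np.abs(d) < width / 2
    out[inside] = np.cos(np.pi * d[inside] / width) ** 4
    return out


def _templates_periodic(profile: GaitProfile, t: np.ndarray) -> dict:
    """Right-limb joint-angle templates at arbitrary cycle phase ``t``."""
    t = np.asarray(t, dtype=float)
    amp = 0.5 * (profile.hip_peak_flex + profile.hip_peak_ext)
    mid = 0.5 * (profile.hip_peak_flex - profile.hip_peak_ext)
    hip = mid + amp * np.cos(2 * np.pi * (t - _HIP_PEAK_PHASE))
    knee = profile.knee_stance_peak_flex * _lobe(t, *_KNEE_STANCE_LOBE) + (
        profile.knee_swing_peak_flex * _lobe(t, *_KNEE_SWING_LOBE)
    )
    ankle = profile.ankle_peak_dorsi * _lobe(t, *_ANKLE_DORSI_LOBE) - (
        profile.ankle_peak_plantar * _lobe(t, *_ANKLE_PLANTAR_LOBE)
    )
    return {"hip": hip, "knee": knee, "ankle": ankle}


def angle_templates(profile: GaitProfile, t_normalized: np.ndarray) -> dict:
    """Evaluate the joint-angle templates at fractions of the gait cycle.

    Parameters
    ----------
    t_normalized : array of cycle fractions in [0, 1]

    Returns
    -------
    dict mapping 'hip' | 'knee' | 'ankle' to degrees (flexion and
    dorsiflexion positive).  The waveforms are periodic, so t=0 and t=1
    evaluate equal, and their extrema hit the profile amplitudes exactly.
    """
    t = np.asarray(t_normalized, dtype=float)
    if np.any((t < 0) | (t > 1)):
        raise ValueError("t_normalized must lie in [0, 1]")
    return _templates_periodic(profile, t)


def parameter_targets(profile: GaitProfile, grid: int = 100_000) -> dict:
    """Ground-truth values of the 12 gait parameters implied by a profile.

    Evaluated on a dense phase grid with stance = [0, stance_fraction],
    swing = the remainder — the same phase split the force-based pipeline
    recovers.  Peak-extension parameters are magnitudes of the most
    extended (minimum-flexion) value, as reported clinically.
    """
    t = np.arange(grid + 1) / grid
    curves = _templates_periodic(profile, t)
    stance = t <= profile.stance_fraction
    swing = ~stance
    hip, knee, ankle = curves["hip"], curves["knee"], curves["ankle"]
    return {
        "ankle_peak_dorsiflexion": float(np.max(ankle)),
        "ankle_peak_plantarflexion": float(abs(np.min(ankle))),
        "ankle_excursion": float(np.max(ankle) - np.min(ankle)),
        "knee_stance_peak_flexion": float(np.max(knee[stance])),
        "knee_stance_peak_extension": float(abs(np.min(knee[stance]))),
        "knee_stance_excursion": float(np.max(knee[stance]) - np.min(knee[stance])),
        "knee_swing_peak_flexion": float(np.max(knee[swing])),
        "knee_swing_peak_extension": float(abs(np.min(knee[swing]))),
        "knee_swing_excursion": float(np.max(knee[swing]) - np.min(knee[swing])),
        "hip_peak_flexion": float(np.max(hip)),
        "hip_peak_extension": float(abs(np.min(hip))),
        "hip_excursion": float(np.max(hip) - np.min(hip)),
    }


def _side_phase(profile: GaitProfile, t_seconds: np.ndarray, side: str) -> np.ndarray:
    offset = _LEAD_IN_FRACTION + (0.5 if side == "left" else 0.0)
    phase = (np.asarray(t_seconds) / profile.cycle_duration - offset) % 1.0
    # Samples landing exactly on a cycle boundary must read phase 0, not
    # a rounding hair below 1, so declared and detected contacts agree.
    return np.where(phase > 1.0 - 1e-9, 0.0, phase)


def trial_duration(profile: GaitProfile) -> float:
    """Total simulated time covering ``n_cycles`` complete cycles per side."""
    return (profile.n_cycles + 1) * profile.cycle_duration


def true_angle_waveforms(profile: GaitProfile) -> tuple[np.ndarray, dict]:
    """Per-video-frame ground-truth angles for both sides.

    Returns (timestamps, {(side, joint): degrees array}).
    """
    duration = trial_duration(profile)
    n_frames = int(round(duration * profile.sample_rate_video))
    t = np.arange(n_frames) / profile.sample_rate_video
    angles = {}
    for side in SIDES:
        phase = _side_phase(profile, t, side)
        for joint, values in _templates_periodic(profile, phase).items():
            angles[(side, joint)] = values
    return t, angles


def forward_kinematics(profile: GaitProfile, angles: dict | None = None) -> GroundTruthTrial:
    """Emit the 12 feature points realizing the given joint angles.

    The pelvis translates at constant speed along +x with the trunk held
    vertical; each limb is a thigh–shank–foot chain driven by the hip,
    knee and ankle angles.  Re-deriving angles from the emitted landmarks
    with the kinematics module recovers the inputs to float precision.

    ``angles`` maps (side, joint) to degrees per video frame; when None,
    the profile's templates are used.  The pose stream is returned
    noiseless here — apply :func:`corrupt` (or use :func:`make_trial`)
    for the measurement model.
    """
    for name, length in profile.segment_lengths.model_dump().items():
        if length <= 0:
            raise ValueError(f"segment length {name} must be positive")
    t, true_angles = (
        true_angle_waveforms(profile) if angles is None else (None, angles)
    )
    if t is None:
        n_frames = len(next(iter(angles.values())))
        t = np.arange(n_frames) / profile.sample_rate_video
    n_frames = len(t)

    seg = profile.segment_lengths
    hip_y = seg.thigh + seg.shank + _HEEL_DROP_FRAC * seg.foot + 0.01
    midhip = np.column_stack([0.3 + profile.speed * t, np.full(n_frames, hip_y)])
    neck = midhip + np.array([0.0, seg.trunk])

    xy = np.zeros((n_frames, len(KEYPOINTS), 2))
    xy[:, kp_index("MidHip")] = midhip
    xy[:, kp_index("Neck")] = neck

    for side in SIDES:
        prefix = "R" if side == "right" else "L"
        hip = np.radians(true_angles[(side, "hip")])
        knee = np.radians(true_angles[(side, "knee")])
        dorsi = np.radians(true_angles[(side, "ankle")])
        theta_thigh = hip  # absolute segment angle from downward vertical, CCW+
        theta_shank = theta_thigh - knee
        phi_foot = theta_shank + dorsi  # foot axis angle from +x, CCW+

        hip_pt = midhip
        knee_pt = hip_pt + seg.thigh * np.column_stack([np.sin(theta_thigh), -np.cos(theta_thigh)])
        ankle_pt = knee_pt + seg.shank * np.column_stack([np.sin(theta_shank), -np.cos(theta_shank)])
        foot_dir = np.column_stack([np.cos(phi_foot), np.sin(phi_foot)])
        down_n = np.column_stack([np.sin(phi_foot), -np.cos(phi_foot)])
        heel_pt = ankle_pt - _HEEL_BACK_FRAC * seg.foot * foot_dir + _HEEL_DROP_FRAC * seg.foot * down_n
        toe_pt = heel_pt + seg.foot * foot_dir

        xy[:, kp_index(prefix + "Hip")] = hip_pt
        xy[:, kp_index(prefix + "Knee")] = knee_pt
        xy[:, kp_index(prefix + "Ankle")] = ankle_pt
        xy[:, kp_index(prefix + "Heel")] = heel_pt
        xy[:, kp_index(prefix + "BigToe")] = toe_pt

    xy *= profile.pixel_scale
    reference = JointCenterSequence(timestamps=t, xy=xy)
    pose = PoseSequence(
        timestamps=t.copy(),
        xy=xy.copy(),
        confidence=np.ones((n_frames, len(KEYPOINTS))),
    )

    grf_right = synth_grf(profile, "right")
    grf_left = synth_grf(profile, "left")
    return GroundTruthTrial(
        profile=profile,
        pose=pose,
        reference=reference,
        grf_right=grf_right,
        grf_left=grf_left,
        true_angles=true_angles,
        true_events={side: true_event_samples(profile, side) for side in SIDES},
    )


def _grf_stance_shape(u: np.ndarray, body_weight: float) -> np.ndarray:
    """Double-bump force profile over normalized stance time u in [0, 1)."""
    fz = np.zeros_like(u)
    for centre, width, peak in _GRF_LOBES:
        d = u - centre
        inside = np.abs(d) < width / 2
        fz[inside] += peak * body_weight * np.cos(np.pi * d[inside] / width) ** 2
    return fz


def synth_grf(profile: GaitProfile, side: str) -> ForceSeries:
    """Vertical GRF trace for one limb.

    Two raised-cosine bumps over stance with the loading peak slightly
    above body weight, identically 0 N throughout swing, and a step onset
    (~0.2 body weight at first loaded sample) so the trace crosses the
    20 N contact threshold at the declared initial-contact sample.
    """
    duration = trial_duration(profile)
    n = int(round(duration * profile.sample_rate_force))
    t = np.arange(n) / profile.sample_rate_force
    phase = _side_phase(profile, t, side)
    fz = np.zeros(n)
    stance = phase < profile.stance_fraction
    fz[stance] = _grf_stance_shape(phase[stance] / profile.stance_fraction, profile.body_weight_n)
    return ForceSeries(timestamps=t, fz=fz, side=side)


def true_event_samples(profile: GaitProfile, side: str) -> np.ndarray:
    """Force-sample indices of the declared initial contacts for one side.

    Only contacts preceded by an unloaded period within the trace are
    declared (a partial stance at the very start of the recording is not
    an initial contact).
    """
    f = profile.sample_rate_force
    T = profile.cycle_duration
    offset = _LEAD_IN_FRACTION + (0.5 if side == "left" else 0.0)
    n_total = int(round(trial_duration(profile) * f))
    ics = []
    k = 0
    while True:
        t_ic = (offset + k) * T
        sample = int(np.ceil(t_ic * f - 1e-9))
        if sample >= n_total:
            break
        ics.append(sample)
        k += 1
    return np.asarray(ics, dtype=int)


def crossing_frames(pose: PoseSequence, threshold_px: float) -> np.ndarray:
    """Frames where the limbs cross in the image (knees or ankles close)."""
    d_knee = np.linalg.norm(pose.point("RKnee") - pose.point("LKnee"), axis=1)
    d_ankle = np.linalg.norm(pose.point("RAnkle") - pose.point("LAnkle"), axis=1)
    return (d_knee < threshold_px) | (d_ankle < threshold_px)


_LEFT_LIMB_KEYPOINTS = ("LKnee", "LAnkle", "LBigToe", "LHeel")


def corrupt(
    pose: PoseSequence,
    noise_sd: float,
    dropout_prob_crossing: float,
    seed: int,
    crossing_threshold_px: float = 20.0,
) -> PoseSequence:
    """Apply the pose-estimation measurement model.

    Adds i.i.d. Gaussian noise (SD in pixels) to every coordinate and,
    on frames where the limbs cross in the image, zeroes the confidence
    of the left-limb keypoints with the given probability.  The right
    (camera-side) limb is never dropped: with a single laterally placed
    camera, only the far limb is occluded during limb crossing.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    if not 0 <= dropout_prob_crossing <= 1:
        raise ValueError("dropout_prob_crossing must lie in [0, 1]")
    out = pose.copy()
    rng = np.random.default_rng(seed)
    crossing = crossing_frames(pose, crossing_threshold_px)
    if noise_sd > 0:
        out.xy = out.xy + rng.normal(0.0, noise_sd, size=out.xy.shape)
    if dropout_prob_crossing > 0:
        dropped = crossing & (rng.random(pose.n_frames) < dropout_prob_crossing)
        for name in _LEFT_LIMB_KEYPOINTS:
            out.confidence[dropped, kp_index(name)] = 0.0
    return out


def make_trial(profile: GaitProfile) -> GroundTruthTrial:
    """Generate a complete trial: truth, reference stream, corrupted pose.

    With ``noise_sd == 0`` and ``dropout_prob_crossing == 0`` the pose
    coordinates equal the reference coordinates exactly.  The same
    profile (including seed) always reproduces the identical trial.
    """
    trial = forward_kinematics(profile)
    trial.pose = corrupt(
        trial.pose,
        profile.noise_sd,
        profile.dropout_prob_crossing,
        profile.seed,
        profile.crossing_threshold_px,
    )
    return trial
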