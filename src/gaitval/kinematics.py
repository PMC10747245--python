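"""Sagittal hip, knee and ankle angles from planar landmark trajectories.

Axis definitions (proximal point listed first):

* trunk axis: Neck -> MidHip
* thigh axis: Hip -> Knee
* shank axis: Knee -> Ankle
* foot axis:  Heel -> BigToe

Hip flexion is the signed angle between trunk and thigh axes; knee
flexion the signed angle between thigh and shank axes; ankle
dorsiflexion the signed angle between shank and foot axes minus the 90
degree neutral offset (the foot axis is perpendicular to the shank in
neutral standing).  Flexion and dorsiflexion are positive.

Signs are resolved through the walking direction: the orientation of the
image (whether the subject walks left-to-right or right-to-left, or the
whole scene is rotated) is inferred from the mean trunk-up vector and
the net pelvis displacement, which makes every angle invariant to
rotation, translation, scaling and mirroring of the coordinates.
"""

from __future__ import annotations

import numpy as np

from .types import JOINTS, SIDES, AngleWaveform, kp_index

_EPS = 1e-12


def segment_axis(p_from: np.ndarray, p_to: np.ndarray) -> np.ndarray:
    """Unit vector from a proximal to a distal landmark.

    Raises ValueError for coincident points; the vectorized pipeline path
    flags such frames invalid instead.
    """
    d = np.asarray(p_to, dtype=float) - np.asarray(p_from, dtype=float)
    n = np.linalg.norm(d)
    if n < _EPS:
        raise ValueError("coincident points: segment axis undefined")
    return d / n


def angle_between(u: np.ndarray, v: np.ndarray, signed: bool = False) -> float:
    """Angle between two unit vectors in degrees.

    Unsigned form lies in [0, 180]; the signed form in (-180, 180] with
    the sign of the planar cross product u x v (counter-clockwise
    positive).
    """
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    cross = u[0] * v[1] - u[1] * v[0]
    dot = u[0] * v[0] + u[1] * v[1]
    ang = np.degrees(np.arctan2(cross, dot))
    if signed:
        return float(ang) if ang != -180.0 else 180.0
    return float(abs(ang))


def _axes(xy_from: np.ndarray, xy_to: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-frame unit axes and a validity mask (False where degenerate)."""
    d = xy_to - xy_from
    n = np.linalg.norm(d, axis=1)
    ok = n > _EPS
    axes = np.zeros_like(d)
    axes[ok] = d[ok] / n[ok, None]
    return axes, ok


def _signed_angles(u: np.ndarray, v: np.ndarray) -> np.ndarray:
    cross = u[:, 0] * v[:, 1] - u[:, 1] * v[:, 0]
    dot = np.sum(u * v, axis=1)
    return np.degrees(np.arctan2(cross, dot))


def _wrap_deg(a: np.ndarray) -> np.ndarray:
    return (a + 180.0) % 360.0 - 180.0


def progression_sign(seq) -> float:
    """Orientation factor from trunk-up direction and pelvis travel.

    +1 when, with the trunk pointing up, the subject progresses such that
    flexion rotations are counter-clockwise in the coordinate frame
    (e.g. y up, walking toward +x); -1 for the mirrored arrangement.
    Defaults to +1 when the pelvis does not translate.
    """
    midhip = seq.xy[:, kp_index("MidHip"), :]
    neck = seq.xy[:, kp_index("Neck"), :]
    conf = seq.confidence
    ok = (conf[:, kp_index("MidHip")] > 0) & (conf[:, kp_index("Neck")] > 0)
    if not np.any(ok):
        return 1.0
    up = np.mean(neck[ok] - midhip[ok], axis=0)
    valid_idx = np.flatnonzero(ok)
    disp = midhip[valid_idx[-1]] - midhip[valid_idx[0]]
    if np.linalg.norm(disp) < _EPS or np.linalg.norm(up) < _EPS:
        return 1.0
    cross = up[0] * disp[1] - up[1] * disp[0]
    if cross == 0:
        return 1.0
    return -float(np.sign(cross))


def joint_angles(seq, source: str = "ai", orientation: float | None = None) -> dict:
    """Compute the six sagittal angle waveforms from a landmark sequence.

    Accepts a PoseSequence or JointCenterSequence.  Returns a dict
    mapping (side, joint) to :class:`AngleWaveform`.  Frames where any
    required keypoint is missing (confidence 0 and not imputed) or an
    axis is degenerate carry NaN and ``valid=False``; imputed frames
    stay flagged for reporting.
    """
    s = progression_sign(seq) if orientation is None else float(orientation)
    conf = seq.confidence
    imputed = getattr(seq, "imputed", np.zeros_like(conf, dtype=bool))
    valid_kp = conf > 0

    def pt(name: str) -> np.ndarray:
        return seq.xy[:, kp_index(name), :]

    def kp_ok(*names: str) -> np.ndarray:
        m = np.ones(seq.n_frames, dtype=bool)
        for name in names:
            m &= valid_kp[:, kp_index(name)]
        return m

    def kp_imputed(*names: str) -> np.ndarray:
        m = np.zeros(seq.n_frames, dtype=bool)
        for name in names:
            m |= imputed[:, kp_index(name)]
        return m

    trunk, trunk_ok = _axes(pt("Neck"), pt("MidHip"))
    out: dict = {}
    for side in SIDES:
        p = "R" if side == "right" else "L"
        thigh, thigh_ok = _axes(pt(p + "Hip"), pt(p + "Knee"))
        shank, shank_ok = _axes(pt(p + "Knee"), pt(p + "Ankle"))
        foot, foot_ok = _axes(pt(p + "Heel"), pt(p + "BigToe"))

        hip = s * _signed_angles(trunk, thigh)
        knee = -s * _signed_angles(thigh, shank)
        ankle = _wrap_deg(s * _signed_angles(shank, foot) - 90.0)

        specs = {
            "hip": (hip, trunk_ok & thigh_ok & kp_ok("Neck", "MidHip", p + "Hip", p + "Knee"),
                    kp_imputed("Neck", "MidHip", p + "Hip", p + "Knee")),
            "knee": (knee, thigh_ok & shank_ok & kp_ok(p + "Hip", p + "Knee", p + "Ankle"),
                     kp_imputed(p + "Hip", p + "Knee", p + "Ankle")),
            "ankle": (ankle, shank_ok & foot_ok & kp_ok(p + "Knee", p + "Ankle", p + "Heel", p + "BigToe"),
                      kp_imputed(p + "Knee", p + "Ankle", p + "Heel", p + "BigToe")),
        }
        for joint, (values, ok, imp) in specs.items():
            vals = np.where(ok, values, np.nan)
            out[(side, joint)] = AngleWaveform(
                joint=joint,
                side=side,
                values=vals,
                timestamps=seq.timestamps,
                valid=ok,
                flagged=(~ok) | imp,
                source=source,
            )
    return out


#: Plausibility ranges (degrees) per joint used as an optional sanity gate.
SANITY_RANGES = {"hip": (-60.0, 90.0), "knee": (-30.0, 120.0), "ankle": (-60.0, 60.0)}


def out_of_range_count(waveform: AngleWaveform, ranges: dict | None = None) -> int:
    """Number of valid frames outside the joint's plausibility range."""
    lo, hi = (ranges or SANITY_RANGES)[waveform.joint]
    vals = waveform.values[waveform.valid]
    return int(np.sum((vals < lo) | (vals > hi)))


def angles_to_frame(angles: dict) -> "pandas.DataFrame":  # noqa: F821
    """Tidy table of (side, joint, frame, time_s, angle_deg, flagged)."""
    import pandas as pd

    rows = []
    for (side, joint), wf in angles.items():
        rows.append(
            pd.DataFrame(
                {
                    "side": side,
                    "joint": joint,
                    "frame": np.arange(len(wf.values)),
                    "time_s": wf.timestamps,
                    "angle_deg": wf.values,
                    "flagged": wf.flagged,
                    "source": wf.source,
                }
            )
        )
    order = {j: i for i, j in enumerate(JOINTS)}
    df = pd.concat(rows, ignore_index=True)
    return df.sort_values(["side", "joint", "frame"], key=lambda c: c.map(order) if c.name == "joint" else c).reset_index(drop=True)
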