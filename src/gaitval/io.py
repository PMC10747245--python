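"""Readers and writers for the external formats.

* OpenPose-style per-frame JSON (``people[0].pose_keypoints_2d`` as flat
  [x, y, confidence] triplets in BODY-25 index order, one file per
  frame, image coordinates with y down);
* reference joint centres as CSV (frame, time_s, then <name>_x/<name>_y
  per landmark);
* vertical GRF as CSV (sample, time_s, fz_n) per limb;
* a trial manifest JSON recording profile parameters, seed and true
  event indices.

Internally everything uses the y-up walkway frame; the OpenPose reader
and writer flip y against the image height.  CSV dialect: comma
separator, '.' decimal, mandatory header row.
"""

from __future__ import annotations

import json
import re
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .types import KEYPOINTS, ForceSeries, JointCenterSequence, PoseSequence

#: Default mapping from the 12 canonical feature points to BODY-25 indices.
#: User-overridable (e.g. via a small JSON file) for other pose models.
BODY25_KEYPOINT_MAP: dict[str, int] = {
    "Neck": 1,
    "MidHip": 8,
    "RHip": 9,
    "RKnee": 10,
    "RAnkle": 11,
    "LHip": 12,
    "LKnee": 13,
    "LAnkle": 14,
    "LBigToe": 19,
    "LHeel": 21,
    "RBigToe": 22,
    "RHeel": 24,
}

_N_BODY25 = 25
_FRAME_RE = re.compile(r"(\d+)")


def load_keypoint_map(path) -> dict[str, int]:
    """Read a {feature point: model index} override map from JSON."""
    with open(path) as fh:
        raw = json.load(fh)
    missing = [k for k in KEYPOINTS if k not in raw]
    if missing:
        raise ValueError(f"keypoint map is missing entries for {missing}")
    return {k: int(raw[k]) for k in KEYPOINTS}


def _frame_index(path: Path) -> int:
    m = _FRAME_RE.findall(path.stem)
    if not m:
        raise ValueError(f"cannot find a frame index in filename {path.name!r}")
    return int(m[-1])


def write_openpose_dir(
    pose: PoseSequence,
    path,
    image_height_px: float = 720.0,
    keypoint_map: dict[str, int] | None = None,
    prefix: str = "frame",
) -> None:
    """Write one OpenPose-style JSON file per frame.

    Keypoints with confidence 0 are written as the (0, 0, 0) triplet,
    matching the OpenPose missing-point convention, as are BODY-25 slots
    outside the 12-point vocabulary.
    """
    kp_map = keypoint_map or BODY25_KEYPOINT_MAP
    out = Path(path)
    out.mkdir(parents=True, exist_ok=True)
    width = max(6, len(str(pose.n_frames)))
    for i in range(pose.n_frames):
        flat = [0.0] * (3 * _N_BODY25)
        for k, name in enumerate(KEYPOINTS):
            j = kp_map[name]
            if pose.confidence[i, k] > 0:
                flat[3 * j] = float(pose.xy[i, k, 0])
                flat[3 * j + 1] = float(image_height_px - pose.xy[i, k, 1])
                flat[3 * j + 2] = float(pose.confidence[i, k])
        doc = {"version": 1.3, "people": [{"pose_keypoints_2d": flat}]}
        with open(out / f"{prefix}_{i:0{width}d}_keypoints.json", "w") as fh:
            json.dump(doc, fh)


def read_openpose_dir(
    path,
    video_rate: float = 120.0,
    image_height_px: float = 720.0,
    keypoint_map: dict[str, int] | None = None,
) -> PoseSequence:
    """Read a directory of OpenPose per-frame JSON into a PoseSequence.

    Frames are ordered by the numeric index in the filename, so shuffled
    directory listings still yield strictly increasing timestamps.
    Frames with zero detected people become all-dropout frames (counted
    in a warning); more than one person is an error naming the frame,
    since the recording setting is single-subject.
    """
    kp_map = keypoint_map or BODY25_KEYPOINT_MAP
    files = sorted(Path(path).glob("*.json"), key=_frame_index)
    if not files:
        raise FileNotFoundError(f"no JSON frames found in {path}")
    n = len(files)
    xy = np.full((n, len(KEYPOINTS), 2), np.nan)
    conf = np.zeros((n, len(KEYPOINTS)))
    empty_frames = 0
    for i, fp in enumerate(files):
        with open(fp) as fh:
            doc = json.load(fh)
        people = doc.get("people", [])
        if len(people) == 0:
            empty_frames += 1
            continue
        if len(people) > 1:
            raise ValueError(f"frame {fp.name}: {len(people)} people detected, expected one")
        flat = people[0]["pose_keypoints_2d"]
        for k, name in enumerate(KEYPOINTS):
            j = kp_map[name]
            x, y, c = flat[3 * j : 3 * j + 3]
            if c > 0:
                xy[i, k] = (x, image_height_px - y)
                conf[i, k] = c
    if empty_frames:
        warnings.warn(f"{empty_frames} frame(s) contained no detected person", stacklevel=2)
    return PoseSequence(
        timestamps=np.arange(n) / video_rate,
        xy=xy,
        confidence=conf,
    )


def write_reference_csv(reference: JointCenterSequence, path) -> None:
    """Reference joint centres: frame, time_s, then x/y per landmark."""
    data = {"frame": np.arange(reference.n_frames), "time_s": reference.timestamps}
    for k, name in enumerate(KEYPOINTS):
        data[f"{name}_x"] = reference.xy[:, k, 0]
        data[f"{name}_y"] = reference.xy[:, k, 1]
    pd.DataFrame(data).to_csv(path, index=False, float_format="%.17g")


def read_reference_csv(path) -> JointCenterSequence:
    """Read reference joint-centre trajectories written by this package
    (or any CSV with time_s and <name>_x/<name>_y columns).

    Extra columns are ignored; a missing landmark column is an error
    naming it; a non-monotone time column is rejected.
    """
    df = _read_csv_strict(path)
    if "time_s" not in df.columns:
        raise ValueError("reference CSV is missing the 'time_s' column")
    for name in KEYPOINTS:
        for suffix in ("_x", "_y"):
            if name + suffix not in df.columns:
                raise ValueError(f"reference CSV is missing column {name + suffix!r}")
    t = df["time_s"].to_numpy(dtype=float)
    if np.any(np.diff(t) <= 0):
        raise ValueError("reference CSV time column is not strictly increasing")
    xy = np.stack(
        [np.column_stack([df[f"{n}_x"], df[f"{n}_y"]]) for n in KEYPOINTS], axis=1
    ).astype(float)
    return JointCenterSequence(timestamps=t, xy=xy)


def write_grf_csv(grf: ForceSeries, path) -> None:
    """Vertical GRF trace: sample, time_s, fz_n."""
    pd.DataFrame(
        {"sample": np.arange(len(grf.fz)), "time_s": grf.timestamps, "fz_n": grf.fz}
    ).to_csv(path, index=False, float_format="%.17g")


def read_grf_csv(path, side: str) -> ForceSeries:
    """Read a per-limb vertical GRF CSV.

    Negative force samples (unloading artifacts) are preserved, never
    clipped; a malformed file fails loudly rather than yielding a
    garbage series.
    """
    df = _read_csv_strict(path)
    for col in ("time_s", "fz_n"):
        if col not in df.columns:
            raise ValueError(f"GRF CSV is missing the {col!r} column")
    t = df["time_s"].to_numpy(dtype=float)
    if np.any(np.diff(t) <= 0):
        raise ValueError("GRF CSV time column is not strictly increasing")
    return ForceSeries(timestamps=t, fz=df["fz_n"].to_numpy(dtype=float), side=side)


def _read_csv_strict(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise ValueError(
            f"{path}: parsed a single column; wrong delimiter? (comma-separated, header row required)"
        )
    return df


def write_manifest(path, profile, true_events: dict, extra: dict | None = None) -> None:
    """Record the generator parameters and declared events for a trial."""
    doc = {
        "profile": profile.model_dump(),
        "seed": profile.seed,
        "true_initial_contacts_force_samples": {
            side: [int(i) for i in idx] for side, idx in true_events.items()
        },
    }
    if extra:
        doc.update(extra)
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=2, sort_keys=True)


def write_trial(trial, directory, image_height_px: float = 720.0) -> Path:
    """Write a synthetic trial to disk in all external formats.

    Layout: ``openpose/`` with per-frame JSON, ``reference.csv``,
    ``grf_right.csv``, ``grf_left.csv`` and ``manifest.json``.
    """
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    write_openpose_dir(trial.pose, d / "openpose", image_height_px=image_height_px)
    write_reference_csv(trial.reference, d / "reference.csv")
    write_grf_csv(trial.grf_right, d / "grf_right.csv")
    write_grf_csv(trial.grf_left, d / "grf_left.csv")
    write_manifest(d / "manifest.json", trial.profile, trial.true_events)
    return d


def read_trial(directory, image_height_px: float = 720.0):
    """Read back a trial directory written by :func:`write_trial`.

    Returns (pose, reference, grf_right, grf_left, manifest_dict).
    """
    d = Path(directory)
    with open(d / "manifest.json") as fh:
        manifest = json.load(fh)
    video_rate = manifest["profile"]["sample_rate_video"]
    pose = read_openpose_dir(d / "openpose", video_rate=video_rate, image_height_px=image_height_px)
    reference = read_reference_csv(d / "reference.csv")
    grf_r = read_grf_csv(d / "grf_right.csv", "right")
    grf_l = read_grf_csv(d / "grf_left.csv", "left")
    return pose, reference, grf_r, grf_l, manifest
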