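"""Gap handling and zero-lag low-pass filtering of landmark trajectories.

Filtering follows the dominant biomechanics reading of a "fourth-order
zero-lag Butterworth": a 2nd-order design applied forward then backward
(effective 4th order, -6.02 dB at the cutoff).  The alternative reading
(4th-order design applied twice, effective 8th order) is available via
``convention="cascade"``.  Filtering is applied to coordinates before
any angle computation, never to angles.
"""

from __future__ import annotations

import numpy as np
from scipy.signal import butter, filtfilt

from .types import KEYPOINTS, ForceSeries, JointCenterSequence, PoseSequence, kp_side


def _invalid_runs(valid: np.ndarray):
    """(start, stop) pairs of consecutive-invalid index runs (stop exclusive)."""
    runs = []
    n = len(valid)
    i = 0
    while i < n:
        if not valid[i]:
            j = i
            while j < n and not valid[j]:
                j += 1
            runs.append((i, j))
            i = j
        else:
            i += 1
    return runs


def fill_gaps(seq: PoseSequence, max_gap: int = 10) -> PoseSequence:
    """Linearly interpolate short occlusion gaps in a pose sequence.

    Interior runs of confidence-0 frames of length <= ``max_gap`` are
    filled from the flanking valid frames and marked imputed (confidence
    restored to 1 so downstream stages treat them as data, the flag kept
    for reporting).  Longer interior runs mark the affected side
    unusable; leading or trailing gaps are never extrapolated and flag
    the side instead.
    """
    if max_gap < 0:
        raise ValueError("max_gap must be >= 0")
    out = seq.copy()
    n = out.n_frames
    for k, name in enumerate(KEYPOINTS):
        valid = out.confidence[:, k] > 0
        if valid.all():
            continue
        side = kp_side(name)
        affected = ("right", "left") if side == "axial" else (side,)
        for start, stop in _invalid_runs(valid):
            length = stop - start
            if start == 0 or stop == n:
                for s in affected:
                    out.add_side_flag(s, f"{name}: uninterpolatable edge gap of {length} frames")
                continue
            if length > max_gap:
                for s in affected:
                    out.add_side_flag(s, f"{name}: gap of {length} frames exceeds max_gap={max_gap}")
                    out.unusable_sides.add(s)
                continue
            lo, hi = start - 1, stop  # flanking valid frames
            frac = (np.arange(start, stop) - lo) / (hi - lo)
            for c in range(2):
                out.xy[start:stop, k, c] = out.xy[lo, k, c] + frac * (out.xy[hi, k, c] - out.xy[lo, k, c])
            out.confidence[start:stop, k] = 1.0
            out.imputed[start:stop, k] = True
    return out


def _design(cutoff_hz: float, order: int, fs: float, convention: str):
    if convention == "effective":
        design_order = order // 2
        if design_order * 2 != order:
            raise ValueError("effective convention requires an even order")
    elif convention == "cascade":
        design_order = order
    else:
        raise ValueError("convention must be 'effective' or 'cascade'")
    if fs <= 2 * cutoff_hz:
        raise ValueError(f"sample rate {fs} Hz must exceed twice the cutoff {cutoff_hz} Hz")
    return butter(design_order, cutoff_hz, btype="low", fs=fs)


def min_filter_length(cutoff_hz: float = 6.0, order: int = 4, fs: float = 120.0,
                      convention: str = "effective") -> int:
    """Shortest series the zero-lag filter accepts."""
    b, a = _design(cutoff_hz, order, fs, convention)
    return 3 * max(len(a), len(b)) + 1


def _filtfilt(x: np.ndarray, b: np.ndarray, a: np.ndarray) -> np.ndarray:
    padlen = 3 * max(len(a), len(b))
    if x.shape[-1] <= padlen:
        raise ValueError(
            f"series of length {x.shape[-1]} too short for zero-lag filtering; "
            f"minimum length is {padlen + 1}"
        )
    return filtfilt(b, a, x, axis=-1)


def lowpass(seq, cutoff_hz: float = 6.0, order: int = 4, convention: str = "effective"):
    """Zero-lag Butterworth low-pass of a landmark or force sequence.

    ``order`` is the effective order after the forward-backward pass
    (default 4).  Works on PoseSequence, JointCenterSequence and
    ForceSeries; landmark filtering runs over each keypoint coordinate.
    The double pass gives zero net phase and a DC gain of exactly 1.
    """
    fs = seq.rate
    b, a = _design(cutoff_hz, order, fs, convention)
    out = seq.copy()
    if isinstance(seq, (PoseSequence, JointCenterSequence)):
        # Bridge remaining invalid frames so they cannot contaminate the
        # filter; they stay confidence-0 (invalid) downstream.
        valid = out.confidence > 0
        frames = np.arange(out.n_frames)
        for k in range(out.xy.shape[1]):
            vk = valid[:, k]
            if vk.all() or not vk.any():
                continue
            for c in range(2):
                out.xy[~vk, k, c] = np.interp(frames[~vk], frames[vk], out.xy[vk, k, c])
        n_kp = out.xy.shape[1]
        flat = out.xy.reshape(out.n_frames, n_kp * 2).T.copy()  # (24, n)
        finite_rows = np.isfinite(flat).all(axis=1)
        flat[finite_rows] = _filtfilt(flat[finite_rows], b, a)
        out.xy = flat.T.reshape(out.xy.shape)
    elif isinstance(seq, ForceSeries):
        out.fz = _filtfilt(out.fz, b, a)
    else:
        raise TypeError(f"cannot filter object of type {type(seq).__name__}")
    return out


def designed_response(freq_hz, cutoff_hz: float = 6.0, order: int = 4, fs: float = 120.0,
                      convention: str = "effective") -> np.ndarray:
    """Analytic net magnitude response of the zero-lag filter.

    The forward-backward pass applies the designed filter's squared
    magnitude; this is the oracle for attenuation checks.
    """
    from scipy.signal import freqz

    b, a = _design(cutoff_hz, order, fs, convention)
    _, h = freqz(b, a, worN=2 * np.pi * np.atleast_1d(np.asarray(freq_hz, dtype=float)) / fs)
    return np.abs(h) ** 2
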