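"""Gait-cycle segmentation from vertical ground-reaction force.

Ground contact is declared when the vertical force strictly exceeds a
20 N threshold.  Debouncing guards against artifact events: a contact
must be preceded by at least 50 ms below threshold and last at least
100 ms; unloaded gaps shorter than 50 ms inside a contact are treated
as part of it.  A gait cycle runs from one initial contact to the next
on the same limb, and angle waveforms are time-normalized to 101 points
(0..100% of the cycle).  The same force-derived cycle bounds are applied
to both the pose and the reference stream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .types import AngleWaveform, ForceSeries, GaitCycle

log = logging.getLogger(__name__)


@dataclass
class EventList:
    """Paired contact events for one limb, in force-sample indices."""

    side: str
    initial_contacts: np.ndarray
    toe_offs: np.ndarray


def _runs(mask: np.ndarray):
    """(start, stop) pairs of consecutive-True runs, stop exclusive."""
    if not mask.any():
        return []
    d = np.diff(mask.astype(np.int8))
    starts = list(np.flatnonzero(d == 1) + 1)
    stops = list(np.flatnonzero(d == -1) + 1)
    if mask[0]:
        starts.insert(0, 0)
    if mask[-1]:
        stops.append(len(mask))
    return list(zip(starts, stops))


def detect_events(
    grf: ForceSeries,
    threshold_n: float = 20.0,
    min_quiet_s: float = 0.05,
    min_contact_s: float = 0.10,
) -> EventList:
    """Detect initial contacts and toe-offs on one limb's force trace.

    Returns force-sample indices: each initial contact is the first
    sample of a debounced run with fz > threshold; the matching toe-off
    is the first sample after the run where fz stays at or below the
    threshold.  A contact already loaded at the first sample (the trace
    opened mid-stance) and runs shorter than ``min_contact_s`` are
    discarded.
    """
    if threshold_n <= 0:
        raise ValueError("threshold_n must be positive")
    fs = grf.rate
    min_quiet = max(1, int(round(min_quiet_s * fs)))
    min_contact = int(round(min_contact_s * fs))
    above = grf.fz > threshold_n

    runs = _runs(above)
    # Merge contacts separated by sub-debounce unloaded gaps.
    merged: list[list[int]] = []
    for start, stop in runs:
        if merged and start - merged[-1][1] < min_quiet:
            merged[-1][1] = stop
        else:
            merged.append([start, stop])

    ics, tos = [], []
    for start, stop in merged:
        if stop - start < min_contact:
            continue
        # A run must be preceded by an unloaded period.  Runs separated by
        # less than min_quiet were merged above, so any surviving run has a
        # full quiet gap before it — except a contact already loaded at
        # sample 0 (the trace opened mid-stance), which is not an initial
        # contact.  A trace that begins unloaded may contact at any time.
        if start == 0:
            continue
        ics.append(start)
        if stop < len(above):
            tos.append(stop)
        # A contact still loaded at the end of the trace keeps its IC but
        # has no toe-off; it can never close a cycle.
    if not ics:
        log.info("no contact events found on side %s", grf.side)
    return EventList(
        side=grf.side,
        initial_contacts=np.asarray(ics, dtype=int),
        toe_offs=np.asarray(tos, dtype=int),
    )


def to_video_frames(sample_idx, force_rate: float, video_rate: float):
    """Convert force-sample indices to video-frame indices (floor)."""
    ratio = force_rate / video_rate
    if not np.isclose(ratio, round(ratio)) or round(ratio) < 1:
        raise ValueError(
            f"force rate {force_rate} Hz must be a positive integer multiple of video rate {video_rate} Hz"
        )
    idx = np.asarray(sample_idx, dtype=int)
    frames = idx // int(round(ratio))
    return frames if frames.ndim else int(frames)


def normalize_cycle(values: np.ndarray, ic_frame: int, next_ic_frame: int,
                    min_frames: int = 20) -> np.ndarray:
    """Resample one cycle of a per-frame series onto 0..100% (101 points).

    Linear interpolation in frame time; the first point is the value at
    initial contact and the last the value at the next initial contact.
    NaNs covering at most 20% of the cycle's frames are bridged by
    linear interpolation; raises ValueError for shorter cycles or for
    cycles too corrupted to use.
    """
    span = next_ic_frame - ic_frame
    if span < min_frames:
        raise ValueError(f"cycle of {span} frames is shorter than the minimum {min_frames}")
    if next_ic_frame >= len(values):
        raise ValueError("cycle extends past the end of the series")
    seg = np.asarray(values[ic_frame : next_ic_frame + 1], dtype=float)
    bad = ~np.isfinite(seg)
    if bad.any():
        if bad.mean() > 0.20:
            raise ValueError(f"{bad.mean():.0%} of cycle frames are flagged (limit 20%)")
        if bad[0] or bad[-1]:
            raise ValueError("cycle endpoints are flagged; cannot normalize")
        idx = np.arange(len(seg))
        seg[bad] = np.interp(idx[bad], idx[~bad], seg[~bad])
    grid = ic_frame + (span / 100.0) * np.arange(101)
    return np.interp(grid, np.arange(ic_frame, next_ic_frame + 1), seg)


def build_cycles(
    events: EventList,
    angles: dict,
    force_rate: float,
    video_rate: float,
    min_frames: int = 20,
    max_flagged_fraction: float = 0.20,
) -> list[GaitCycle]:
    """Assemble normalized gait cycles for one limb from events + angles.

    ``angles`` maps joint name to an :class:`AngleWaveform` for the
    limb.  Cycles violating event ordering, too short, or with more than
    ``max_flagged_fraction`` flagged frames in any joint are excluded
    with a logged reason.
    """
    side = events.side
    ic_frames = to_video_frames(events.initial_contacts, force_rate, video_rate)
    to_frames = to_video_frames(events.toe_offs, force_rate, video_rate)
    cycles: list[GaitCycle] = []
    for i in range(len(ic_frames) - 1):
        ic, nxt = int(ic_frames[i]), int(ic_frames[i + 1])
        tos = to_frames[(to_frames > ic) & (to_frames < nxt)]
        if len(tos) != 1:
            log.info("side %s cycle at frame %d: no unique toe-off, excluded", side, ic)
            continue
        to = int(tos[0])
        try:
            normalized = {}
            for joint, wf in angles.items():
                flagged_frac = float(np.mean(wf.flagged[ic : nxt + 1]))
                if flagged_frac > max_flagged_fraction:
                    raise ValueError(
                        f"{joint}: {flagged_frac:.0%} of frames flagged (limit {max_flagged_fraction:.0%})"
                    )
                vals = np.where(wf.valid, wf.values, np.nan)
                normalized[joint] = normalize_cycle(vals, ic, nxt, min_frames=min_frames)
            cycles.append(
                GaitCycle(side=side, ic_frame=ic, next_ic_frame=nxt, toe_off_frame=to,
                          normalized_angles=normalized)
            )
        except ValueError as exc:
            log.info("side %s cycle at frame %d excluded: %s", side, ic, exc)
    return cycles


def events_to_frame(events: EventList, force_rate: float, video_rate: float):
    """Tidy events table: (side, event_type, force_sample, video_frame, time_s)."""
    import pandas as pd

    rows = []
    for kind, samples in (("initial_contact", events.initial_contacts), ("toe_off", events.toe_offs)):
        for s in samples:
            rows.append(
                {
                    "side": events.side,
                    "event_type": kind,
                    "force_sample": int(s),
                    "video_frame": int(to_video_frames(int(s), force_rate, video_rate)),
                    "time_s": s / force_rate,
                }
            )
    return pd.DataFrame(rows, columns=["side", "event_type", "force_sample", "video_frame", "time_s"])
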