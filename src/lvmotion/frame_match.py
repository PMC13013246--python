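"""ECG-gated matching of US frames to the CT trigger phase.

The cardiac CT is acquired at a fixed percentage of the R-R interval
(78 % under the study protocol).  To find the US frame that shows the same
cardiac phase, R-peaks are extracted from the ECG by a local-maximum
search, a trigger time is placed at the configured fraction of each R-R
interval, and the US frame with the smallest time offset to each trigger
is selected.  The best of the recorded cycles (smallest offset) defines
the baseline frame used for the US-to-CT registration; at a 20 Hz frame
rate the worst possible offset is half the 50 ms frame interval, 25 ms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

from .stream_io import EcgTrace

__all__ = [
    "CycleMatch",
    "detect_r_peaks",
    "trigger_times",
    "match_frames",
    "select_best_cycle",
]


@dataclass(frozen=True)
class CycleMatch:
    """One cardiac cycle's trigger and its closest US frame."""

    cycle_index: int
    r_start: float
    r_end: float
    trigger_time: float
    matched_frame_index: int
    offset_ms: float
    flagged: bool = False

    def __post_init__(self) -> None:
        if not (self.r_start < self.trigger_time < self.r_end):
            raise ValueError("trigger time must lie inside its R-R interval")
        if self.offset_ms < 0:
            raise ValueError("offset must be non-negative")


def detect_r_peaks(
    ecg: EcgTrace, min_rr: float = 0.3, height_frac: float = 0.5
) -> np.ndarray:
    """R-peak timestamps by local-maximum search.

    A sample is a peak when it is a local maximum above
    ``baseline + height_frac * (max - baseline)`` (baseline = signal
    median) and at least ``min_rr`` seconds from a taller peak.  The
    0.3 s refractory default corresponds to a 200 bpm ceiling.

    Returns an empty array (with no error) for flat or peak-free traces.
    """
    if len(ecg) < 2 or ecg.timestamps[-1] - ecg.timestamps[0] < 2.0:
        raise ValueError("need at least 2 s of ECG signal")
    x = ecg.samples
    baseline = float(np.median(x))
    span = float(np.max(x) - baseline)
    if span <= 0:
        return np.empty(0)
    height = baseline + height_frac * span
    dt = float(np.median(np.diff(ecg.timestamps)))
    distance = max(1, int(round(min_rr / dt)))
    idx, _ = find_peaks(x, height=height, distance=distance)
    return ecg.timestamps[idx]


def trigger_times(r_peaks: np.ndarray, fraction: float = 0.78) -> np.ndarray:
    """CT trigger time per complete R-R interval: ``R_i + fraction * RR_i``."""
    if not 0.0 < fraction < 1.0:
        raise ValueError("trigger fraction must lie in (0, 1)")
    r = np.asarray(r_peaks, dtype=float)
    if len(r) < 2:
        raise ValueError("need at least 2 R-peaks to place triggers")
    return r[:-1] + fraction * np.diff(r)


def match_frames(
    triggers: np.ndarray,
    frame_timestamps: np.ndarray,
    r_peaks: np.ndarray | None = None,
) -> list[CycleMatch]:
    """Closest US frame per trigger; ties go to the earlier frame.

    A match whose offset exceeds one median frame interval is flagged
    (the trigger fell into a gap of the US stream).
    """
    ts = np.asarray(frame_timestamps, dtype=float)
    trig = np.asarray(triggers, dtype=float)
    if len(ts) == 0:
        raise ValueError("no US frames to match against")
    frame_interval = float(np.median(np.diff(ts))) if len(ts) > 1 else np.inf
    if r_peaks is None:
        # reconstruct nominal interval bounds around each trigger
        half = np.diff(trig, prepend=trig[0] - 1.0, append=trig[-1] + 1.0) / 2
        starts = trig - half[:-1]
        ends = trig + half[1:]
    else:
        r = np.asarray(r_peaks, dtype=float)
        starts, ends = r[:-1], r[1:]
    matches = []
    for i, t in enumerate(trig):
        d = np.abs(ts - t)
        j = int(np.argmin(d))  # argmin takes the first == earlier frame on ties
        offset = float(d[j])
        matches.append(
            CycleMatch(
                cycle_index=i,
                r_start=float(starts[i]),
                r_end=float(ends[i]),
                trigger_time=float(t),
                matched_frame_index=j,
                offset_ms=offset * 1e3,
                flagged=offset > frame_interval,
            )
        )
    return matches


def select_best_cycle(matches: list[CycleMatch]) -> CycleMatch:
    """The cycle with the smallest trigger-to-frame offset (earliest on ties)."""
    if not matches:
        raise ValueError("no cycle matches to select from")
    return min(matches, key=lambda m: (m.offset_ms, m.cycle_index))


def match_recording(
    ecg: EcgTrace,
    frame_timestamps: np.ndarray,
    fraction: float = 0.78,
    min_rr: float = 0.3,
    height_frac: float = 0.5,
) -> tuple[list[CycleMatch], CycleMatch]:
    """Full gating chain: peaks -> triggers -> matches -> best cycle."""
    peaks = detect_r_peaks(ecg, min_rr=min_rr, height_frac=height_frac)
    trig = trigger_times(peaks, fraction=fraction)
    matches = match_frames(trig, frame_timestamps, r_peaks=peaks)
    return matches, select_best_cycle(matches)
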