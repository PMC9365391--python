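"""Dual-color roadblock encounter analysis.

A mobile-particle trajectory is paired with a (near-stationary) roadblock
trajectory; every episode where the mobile particle enters a colocalization
radius around the roadblock is classified as reflected, stuck, or
crossover.  Because roadblock fluorophores bleach long before the roadblock
dissociates, the roadblock trace is extended past its last observation with
its mean observed position.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .tracking import Trajectory

__all__ = [
    "DualColorTrack",
    "EncounterEvent",
    "extend_after_bleach",
    "classify_encounters",
    "encounter_fractions",
]

CLASSES = ("reflected", "stuck", "crossover")

#: Default colocalization radius: ~2x the typical localization precision.
DEFAULT_RADIUS_UM = 0.16


@dataclass
class DualColorTrack:
    mobile: Trajectory
    roadblock: Trajectory
    radius_um: float = DEFAULT_RADIUS_UM

    def __post_init__(self) -> None:
        if self.radius_um <= 0:
            raise ValueError("colocalization radius must be positive")
        if abs(self.mobile.frame_interval_s - self.roadblock.frame_interval_s) > 1e-12:
            raise ValueError("trajectories must share a time base")


@dataclass
class EncounterEvent:
    start_s: float
    end_s: float
    approach_side: int  # +1 entered from above, -1 from below
    classification: str
    ends_trace: bool


def extend_after_bleach(roadblock: Trajectory, n_frames: int) -> Trajectory:
    """Extend a roadblock trace to ``n_frames`` with its mean position.

    Requires at least five observed positions; a trace already long enough
    is returned unchanged.
    """
    if len(roadblock) < 5:
        raise ValueError("need at least five observed roadblock positions")
    if n_frames <= len(roadblock):
        return roadblock
    mean_pos = float(np.mean(roadblock.positions_um))
    ext = np.concatenate(
        [roadblock.positions_um, np.full(n_frames - len(roadblock), mean_pos)]
    )
    flags = np.concatenate(
        [roadblock.interpolated, np.ones(n_frames - len(roadblock), dtype=bool)]
    )
    return Trajectory(
        positions_um=ext,
        frame_interval_s=roadblock.frame_interval_s,
        t0_s=roadblock.t0_s,
        source=roadblock.source,
        interpolated=flags,
    )


def classify_encounters(
    track: DualColorTrack, stuck_min_duration_s: float = 2.0
) -> list[EncounterEvent]:
    """Segment and classify colocalization episodes.

    An episode opens when the mobile position enters ``radius_um`` of the
    (extended) roadblock position and closes when it leaves, or at trace
    end.  Classification:

    * crossover — exit side differs from entry side;
    * stuck — residence >= ``stuck_min_duration_s``, or the episode runs to
      the end of the trace (an encounter the particle never escapes);
    * reflected — exit on the entry side before ``stuck_min_duration_s``.
    """
    mobile = track.mobile
    rb = extend_after_bleach(track.roadblock, len(mobile))
    p = float(np.mean(track.roadblock.positions_um))
    if np.std(track.roadblock.positions_um) > track.radius_um:
        raise ValueError("roadblock is mobile beyond the colocalization radius")

    dt = mobile.frame_interval_s
    x = mobile.positions_um
    ref = rb.positions_um[: len(mobile)]
    inside = np.abs(x - ref) < track.radius_um
    side = np.sign(x - ref).astype(int)
    side[side == 0] = 1

    events: list[EncounterEvent] = []
    i = 0
    n = len(mobile)
    while i < n:
        if not inside[i]:
            i += 1
            continue
        start = i
        entry_side = side[i - 1] if i > 0 else side[i]
        while i < n and inside[i]:
            i += 1
        ends_trace = i == n
        duration = (i - start) * dt
        if not ends_trace and side[i] != entry_side:
            cls = "crossover"
        elif ends_trace or duration >= stuck_min_duration_s:
            cls = "stuck"
        else:
            cls = "reflected"
        events.append(
            EncounterEvent(
                start_s=mobile.t0_s + start * dt,
                end_s=mobile.t0_s + min(i, n - 1) * dt,
                approach_side=int(entry_side),
                classification=cls,
                ends_trace=ends_trace,
            )
        )
    return events


def encounter_fractions(events: list[EncounterEvent]) -> dict[str, float]:
    """Per-class event fractions; sums to 1 for a non-empty event list."""
    if not events:
        raise ValueError("no encounter events")
    n = len(events)
    return {c: sum(e.classification == c for e in events) / n for c in CLASSES}
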