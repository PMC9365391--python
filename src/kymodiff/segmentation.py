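"""Windowed instantaneous-diffusion analysis within single trajectories.

A short window (default 0.4 s) slides over the trajectory one frame at a
time; the diffusion coefficient of each window is estimated from its own
MSD sub-curve and thresholded into fast / medium / slow-immobile
categories.  Contiguous runs of slow windows form immobile dwell episodes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .msd import RefinementRules, compute_msd, fit_diffusion_coefficient
from .tracking import Trajectory

__all__ = [
    "SegmentationConfig",
    "StateTrack",
    "instantaneous_diffusion",
    "state_occupancy",
]

CATEGORIES = ("fast", "medium", "slow")


@dataclass(frozen=True)
class SegmentationConfig:
    window_s: float = 0.4
    fast_threshold_um2_s: float = 0.04
    slow_threshold_um2_s: float = 0.01

    def __post_init__(self) -> None:
        if self.window_s <= 0:
            raise ValueError("window must be positive")
        if not self.slow_threshold_um2_s < self.fast_threshold_um2_s:
            raise ValueError("slow threshold must be below fast threshold")


@dataclass
class StateTrack:
    """Per-window instantaneous D with categories and dwell episodes."""

    window_start_s: np.ndarray
    midpoint_frame: np.ndarray
    d_inst_um2_s: np.ndarray
    category: np.ndarray  # str array over CATEGORIES
    interpolated_majority: np.ndarray  # flagged windows
    dwell_durations_s: np.ndarray
    window_s: float
    frame_interval_s: float


def _categorize(d: np.ndarray, cfg: SegmentationConfig) -> np.ndarray:
    cat = np.full(d.size, "medium", dtype=object)
    cat[d > cfg.fast_threshold_um2_s] = "fast"
    cat[d < cfg.slow_threshold_um2_s] = "slow"
    return cat.astype(str)


def instantaneous_diffusion(traj: Trajectory, cfg: SegmentationConfig | None = None) -> StateTrack:
    """Sliding-window instantaneous D, categories and immobile dwells.

    The window must span at least four frame intervals.  Windows where the
    majority of frames were gap-interpolated are flagged.  A dwell episode
    is a maximal run of slow-category window midpoints; its duration is the
    midpoint span plus one window (so a single slow window counts one full
    window of immobility).
    """
    cfg = cfg or SegmentationConfig()
    dt = traj.frame_interval_s
    w = int(round(cfg.window_s / dt)) + 1  # frames per window
    if cfg.window_s < 4 * dt - 1e-12:
        raise ValueError("window must cover at least four frame intervals")
    if len(traj) <= w:
        raise ValueError("trajectory shorter than one window")

    n_win = len(traj) - w + 1
    d_inst = np.empty(n_win)
    interp_major = np.zeros(n_win, dtype=bool)
    no_rules = RefinementRules(max_d_um2_s=None, min_r2=None)
    for i in range(n_win):
        sub = Trajectory(
            positions_um=traj.positions_um[i : i + w],
            frame_interval_s=dt,
        )
        est = fit_diffusion_coefficient(compute_msd(sub), rules=no_rules)
        d_inst[i] = est.d_um2_s
        interp_major[i] = traj.interpolated[i : i + w].mean() > 0.5

    cat = _categorize(d_inst, cfg)
    mid = np.arange(n_win) + w // 2

    # dwell episodes: maximal runs of slow midpoints
    dwells = []
    run = 0
    for c in cat:
        if c == "slow":
            run += 1
        elif run:
            dwells.append(run)
            run = 0
    if run:
        dwells.append(run)
    dwell_durations = np.array([(r - 1) * dt + cfg.window_s for r in dwells])

    return StateTrack(
        window_start_s=traj.t0_s + np.arange(n_win) * dt,
        midpoint_frame=mid,
        d_inst_um2_s=d_inst,
        category=cat,
        interpolated_majority=interp_major,
        dwell_durations_s=dwell_durations,
        window_s=cfg.window_s,
        frame_interval_s=dt,
    )


def state_occupancy(track: StateTrack) -> dict[str, float]:
    """Fraction of windows in each category; fractions sum to 1."""
    n = track.category.size
    if n == 0:
        raise ValueError("empty state track")
    return {c: float(np.mean(track.category == c)) for c in CATEGORIES}
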