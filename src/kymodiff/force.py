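"""Nucleosome counting from force-distance curves.

Two independent counts are produced: discrete unwrapping events detected as
abrupt distance jumps inside the unwrapping force window, and a
compaction-based count from the tether lengthening at 5 pN divided by the
per-nucleosome calibration (~34.6 nm).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

from .simulate import ForceExtensionCurve

__all__ = [
    "UnwrappingStep",
    "StepDetectionResult",
    "detect_unwrapping_steps",
    "count_by_compaction",
    "internucleosome_spacing",
    "length_at_force",
]


@dataclass
class UnwrappingStep:
    force_pn: float
    size_nm: float
    index: int


@dataclass
class StepDetectionResult:
    steps: list[UnwrappingStep]
    tether_broke: bool
    mean_step_nm: float

    @property
    def n_steps(self) -> int:
        return len(self.steps)


def _two_sided_median_diff(y: np.ndarray, half: int) -> np.ndarray:
    """jump[i] = median(y[i+1 .. i+half]) - median(y[i-half+1 .. i])."""
    n = y.size
    out = np.zeros(n)
    for i in range(half - 1, n - half):
        out[i] = np.median(y[i + 1 : i + 1 + half]) - np.median(y[i - half + 1 : i + 1])
    return out


def detect_unwrapping_steps(
    curve: ForceExtensionCurve,
    force_window_pn: tuple[float, float] = (15.0, 30.0),
    min_step_nm: float = 15.0,
    median_half_window: int = 16,
    break_force_pn: float = 1.0,
) -> StepDetectionResult:
    """Detect abrupt distance increases within the unwrapping force window.

    A sliding two-sided median difference is computed over the distance
    signal; local maxima exceeding ``min_step_nm`` are steps, with the step
    size given by the jump of the running medians.  If the force collapses
    to ~0 inside the window (tether break) the analysis is truncated there
    and flagged.
    """
    f = curve.force_pn
    d_nm = curve.distance_um * 1e3
    lo, hi = force_window_pn
    if f.max() < lo:
        raise ValueError("curve does not reach the unwrapping force window")

    # tether-break: force collapse after having exceeded the window floor
    broke = False
    above = np.flatnonzero(f >= lo)
    end = f.size
    if above.size:
        collapse = np.flatnonzero((np.arange(f.size) > above[0]) & (f < break_force_pn))
        if collapse.size:
            end = collapse[0]
            broke = True

    in_win = (f[:end] >= lo) & (f[:end] <= hi)
    jump = np.zeros(end)
    jump_full = _two_sided_median_diff(d_nm[:end], median_half_window)
    jump[in_win] = jump_full[in_win]

    # one peak in the median-difference profile per step; the distance
    # constraint stops a noisy plateau from being counted twice
    peaks, props = find_peaks(jump, height=min_step_nm, distance=median_half_window)
    steps = [
        UnwrappingStep(force_pn=float(f[k]), size_nm=float(jump[k]), index=int(k))
        for k in peaks
    ]
    mean_step = float(np.mean([s.size_nm for s in steps])) if steps else float("nan")
    return StepDetectionResult(steps=steps, tether_broke=broke, mean_step_nm=mean_step)


def length_at_force(curve: ForceExtensionCurve, force_pn: float = 5.0) -> float:
    """Tether distance (um) interpolated at the requested force crossing."""
    f, d = curve.force_pn, curve.distance_um
    if not f.min() <= force_pn <= f.max():
        raise ValueError("requested force outside the curve")
    order = np.argsort(f)
    return float(np.interp(force_pn, f[order], d[order]))


def count_by_compaction(
    length_5pn_before_um: float,
    length_5pn_after_um: float,
    per_nucleosome_nm: float = 34.6,
) -> int:
    """Nucleosome count from the tether lengthening at 5 pN.

    ``round((after - before) * 1000 / per_nucleosome_nm)``; the after
    length (unwrapped) must not be shorter than the before length.
    """
    delta_nm = (length_5pn_after_um - length_5pn_before_um) * 1e3
    if delta_nm < 0:
        raise ValueError("length after unwrapping must be >= length before")
    if per_nucleosome_nm <= 0:
        raise ValueError("per-nucleosome lengthening must be positive")
    return int(round(delta_nm / per_nucleosome_nm))


def internucleosome_spacing(tether_length_um: float, n_nucleosomes: int) -> dict[str, float]:
    """Mean spacing between nucleosomes on a tether.

    Both divisor conventions are reported: ``gaps`` divides by n+1 (the
    number of gaps separating n interior nucleosomes) and ``per_nucleosome``
    divides by n.
    """
    if n_nucleosomes < 1:
        raise ValueError("need at least one nucleosome")
    if tether_length_um <= 0:
        raise ValueError("tether length must be positive")
    return {
        "gaps": tether_length_um / (n_nucleosomes + 1),
        "per_nucleosome": tether_length_um / n_nucleosomes,
    }
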