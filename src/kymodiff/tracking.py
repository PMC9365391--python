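"""Sub-pixel particle tracking on kymographs and localization precision.

A kymograph is a photon-count matrix of shape (n_pixels, n_lines): rows are
positions along the DNA, columns are successive confocal scan lines.  Each
scan line containing a single, spatially isolated particle is fit with a 1D
Gaussian plus constant offset; the fitted centre, converted to physical
units, is the particle position for that line.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "Kymograph",
    "Trajectory",
    "LocalizationModel",
    "localization_precision",
    "track_kymograph",
]


@dataclass
class Kymograph:
    """Photon counts with spatial and temporal calibration.

    counts : (n_pixels, n_lines) non-negative integer array
    pixel_size_um : size of one spatial pixel (um)
    line_time_s : time between successive scan lines (s)
    """

    counts: np.ndarray
    pixel_size_um: float
    line_time_s: float

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValueError("counts must be a 2D (n_pixels, n_lines) matrix")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if self.pixel_size_um <= 0 or self.line_time_s <= 0:
            raise ValueError("pixel size and line time must be positive")

    @property
    def n_pixels(self) -> int:
        return self.counts.shape[0]

    @property
    def n_lines(self) -> int:
        return self.counts.shape[1]


@dataclass
class Trajectory:
    """Uniformly sampled 1D positions of one particle.

    positions_um are physical positions (um); ``times`` is derived from the
    frame interval.  ``interpolated`` flags gap-filled frames.
    """

    positions_um: np.ndarray
    frame_interval_s: float
    t0_s: float = 0.0
    source: str = ""
    interpolated: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.positions_um = np.asarray(self.positions_um, dtype=float)
        if self.positions_um.ndim != 1 or self.positions_um.size < 2:
            raise ValueError("a trajectory needs at least two positions")
        if not np.all(np.isfinite(self.positions_um)):
            raise ValueError("positions must be finite")
        if self.frame_interval_s <= 0:
            raise ValueError("frame interval must be positive")
        if self.interpolated is None:
            self.interpolated = np.zeros(self.positions_um.size, dtype=bool)
        else:
            self.interpolated = np.asarray(self.interpolated, dtype=bool)
            if self.interpolated.size != self.positions_um.size:
                raise ValueError("interpolated flag length mismatch")

    def __len__(self) -> int:
        return self.positions_um.size

    @property
    def times_s(self) -> np.ndarray:
        return self.t0_s + np.arange(len(self)) * self.frame_interval_s

    @property
    def duration_s(self) -> float:
        return (len(self) - 1) * self.frame_interval_s


@dataclass(frozen=True)
class LocalizationModel:
    """Inputs of the centroid-variance localization formula.

    psf_sigma_nm : PSF standard deviation s (nm)
    photons : photons N collected per 5-pixel window per frame
    pixel_nm : pixel size a (nm)
    background : background photons b per 5-pixel window per frame
    """

    psf_sigma_nm: float = 294.0
    photons: float = 12.9
    pixel_nm: float = 100.0
    background: float = 0.8

    def __post_init__(self) -> None:
        if min(self.psf_sigma_nm, self.photons, self.pixel_nm) <= 0:
            raise ValueError("s, N and a must be positive")
        if self.background < 0:
            raise ValueError("background must be non-negative")


def localization_precision(model: LocalizationModel, background_exponent: int = 2) -> float:
    """Predicted localization standard deviation in nm.

    sigma^2 = s^2/N + a^2/(12 N) + 8 pi s^4 b^q / (a^2 N^2)

    The background exponent ``q`` defaults to the standard centroid-variance
    form q=2; it is exposed because typography of the source formula is
    ambiguous.  With the default photon budget the s^2/N term dominates and
    sigma is ~82 nm for negligible background.
    """
    s, n, a, b = model.psf_sigma_nm, model.photons, model.pixel_nm, model.background
    var = s * s / n + a * a / (12.0 * n) + 8.0 * math.pi * s**4 * b**background_exponent / (a * a * n * n)
    return math.sqrt(var)


def _gaussian_line(i: np.ndarray, amp: float, mu: float, sigma: float, offset: float) -> np.ndarray:
    return amp * np.exp(-0.5 * ((i - mu) / sigma) ** 2) + offset


def _fit_line(counts: np.ndarray, sigma_px_guess: float) -> float | None:
    """Fit one scan line, returning the sub-pixel centre or None on failure."""
    idx = np.arange(counts.size, dtype=float)
    total = counts.sum()
    if total <= 0:
        return None
    mu0 = float((idx * counts).sum() / total)
    amp0 = max(float(counts.max()), 1.0)
    p0 = [amp0, mu0, sigma_px_guess, 0.0]
    bounds = (
        [0.0, -1.0, 0.3, 0.0],
        [np.inf, counts.size, counts.size, max(float(counts.max()), 1.0)],
    )
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, _ = curve_fit(
                _gaussian_line, idx, counts.astype(float), p0=p0, bounds=bounds, maxfev=400
            )
    except (RuntimeError, ValueError):
        return None
    mu = float(popt[1])
    if not 0.0 <= mu <= counts.size - 1:
        return None
    return mu


def track_kymograph(
    kymo: Kymograph,
    roi: tuple[int, int] | None = None,
    min_photons: int = 5,
    psf_sigma_um: float = 0.294,
    max_gap: int = 3,
    source: str = "",
) -> list[Trajectory]:
    """Track a single spatially isolated particle inside a pixel ROI.

    Per scan line a Gaussian+offset is least-squares fit over the ROI; lines
    with fewer than ``min_photons`` summed counts (or failed fits) are
    missing.  Runs of up to ``max_gap`` missing lines are filled by linear
    interpolation and flagged; longer gaps split the output into separate
    trajectory segments.  Positions use the pixel-centre convention
    ``x = (index + 0.5) * pixel_size``.

    Returns a list of trajectory segments (usually one).
    """
    lo, hi = roi if roi is not None else (0, kymo.n_pixels)
    if not (0 <= lo < hi <= kymo.n_pixels):
        raise ValueError("roi out of bounds")
    sub = kymo.counts[lo:hi, :]
    sigma_px = psf_sigma_um / kymo.pixel_size_um

    raw = np.full(kymo.n_lines, np.nan)
    for t in range(kymo.n_lines):
        line = sub[:, t]
        if line.sum() < min_photons:
            continue
        mu = _fit_line(line, sigma_px)
        if mu is not None:
            raw[t] = (mu + lo + 0.5) * kymo.pixel_size_um

    valid = np.flatnonzero(np.isfinite(raw))
    if valid.size == 0:
        raise ValueError("no line in the ROI could be tracked")

    # Split where gaps between consecutive valid lines exceed max_gap.
    segments: list[Trajectory] = []
    breaks = np.flatnonzero(np.diff(valid) > max_gap + 1)
    starts = np.concatenate(([0], breaks + 1))
    ends = np.concatenate((breaks, [valid.size - 1]))
    for k, (a, b) in enumerate(zip(starts, ends)):
        first, last = valid[a], valid[b]
        if last - first < 1:
            continue  # a lone line is not a trajectory
        seg_idx = np.arange(first, last + 1)
        seg_valid = valid[(valid >= first) & (valid <= last)]
        pos = np.interp(seg_idx, seg_valid, raw[seg_valid])
        flags = ~np.isin(seg_idx, seg_valid)
        segments.append(
            Trajectory(
                positions_um=pos,
                frame_interval_s=kymo.line_time_s,
                t0_s=first * kymo.line_time_s,
                source=f"{source}:{k}" if source else str(k),
                interpolated=flags,
            )
        )
    if not segments:
        raise ValueError("tracking produced no usable segment")
    return segments
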