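"""Ground-truth generators for every downstream analysis stage.

Four generators are provided:

* :func:`simulate_trajectory` — 1D Brownian motion at a chosen D with
  reflecting walls, point roadblocks (reflect / stick / cross outcomes
  drawn once per encounter episode) and exponential bleaching/unbinding;
* :func:`render_kymograph` — photon-level rendering of a trajectory into a
  confocal-scan count matrix (Poisson signal placed by a Gaussian PSF plus
  Poisson background);
* :func:`simulate_binding_events` — exponential first-binding times whose
  rate scales with DNA length and concentration, plus exponential dwell
  times with right-censoring;
* :func:`simulate_force_extension` — worm-like-chain force-distance curves
  of a nucleosome array with discrete unwrapping steps.

All generators take an integer seed and are bit-reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .tracking import Kymograph, Trajectory

__all__ = [
    "Roadblock",
    "SimConfig",
    "GroundTruth",
    "RoadblockEvent",
    "simulate_trajectory",
    "add_localization_noise",
    "KymographSpec",
    "render_kymograph",
    "BindingEventSet",
    "simulate_binding_events",
    "SyntheticFDConfig",
    "ForceExtensionCurve",
    "simulate_force_extension",
    "wlc_extension_fraction",
]


# ---------------------------------------------------------------------------
# Brownian trajectories with boundaries and roadblocks
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Roadblock:
    """A point obstacle with per-encounter outcome probabilities."""

    position_um: float
    p_reflect: float
    p_stick: float
    p_cross: float

    def __post_init__(self) -> None:
        probs = (self.p_reflect, self.p_stick, self.p_cross)
        if any(p < 0 or p > 1 for p in probs):
            raise ValueError("probabilities must be in [0, 1]")
        if abs(sum(probs) - 1.0) > 1e-9:
            raise ValueError("roadblock probabilities must sum to 1")


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one simulated trajectory."""

    d_true_um2_s: float
    frame_interval_s: float
    n_frames: int
    x0_um: float = 0.0
    boundaries_um: tuple[float, float] | None = None
    roadblocks: tuple[Roadblock, ...] = ()
    bleach_rate_s: float = 0.0
    unbind_rate_s: float = 0.0
    encounter_radius_um: float = 0.082
    stuck_mean_s: float = math.inf
    seed: int = 0

    def __post_init__(self) -> None:
        if not math.isfinite(self.d_true_um2_s) or self.d_true_um2_s < 0:
            raise ValueError("D must be finite and non-negative")
        if self.frame_interval_s <= 0:
            raise ValueError("frame interval must be positive")
        if self.n_frames < 2:
            raise ValueError("need at least two frames")
        for rate in (self.bleach_rate_s, self.unbind_rate_s):
            if not math.isfinite(rate) or rate < 0:
                raise ValueError("rates must be finite and non-negative")
        if self.boundaries_um is not None:
            lo, hi = self.boundaries_um
            if not lo < hi:
                raise ValueError("boundaries must be strictly increasing")
            if not lo <= self.x0_um <= hi:
                raise ValueError("x0 must lie inside the boundaries")
        if self.encounter_radius_um <= 0:
            raise ValueError("encounter radius must be positive")


@dataclass
class RoadblockEvent:
    """One encounter episode: drawn outcome plus its frame extent."""

    roadblock_index: int
    outcome: str  # reflect | stick | cross
    start_frame: int
    end_frame: int | None = None  # None while open / if trace ends inside


@dataclass
class GroundTruth:
    """Simulated trajectory with full knowledge of the generating process."""

    times_s: np.ndarray
    positions_um: np.ndarray
    alive: np.ndarray
    events: list[RoadblockEvent]
    d_true_um2_s: float
    frame_interval_s: float
    interval_length_um: float  # NaN when unbounded
    seed: int

    @property
    def n_alive(self) -> int:
        return int(self.alive.sum())

    def to_trajectory(self, source: str = "truth") -> Trajectory:
        """Observed part of the trajectory (frames before bleach/unbind)."""
        n = self.n_alive
        if n < 2:
            raise ValueError("trajectory died before the second frame")
        return Trajectory(
            positions_um=self.positions_um[:n],
            frame_interval_s=self.frame_interval_s,
            source=source,
        )


def _reflect_into(x: float, lo: float, hi: float) -> float:
    """Elastic reflection of an overshoot into [lo, hi]."""
    span = hi - lo
    y = (x - lo) % (2.0 * span)
    return lo + (y if y <= span else 2.0 * span - y)


def simulate_trajectory(cfg: SimConfig) -> GroundTruth:
    """Discrete-time reflected Brownian motion with roadblock episodes.

    Increments are N(0, 2 D dt).  An encounter episode opens when a step
    lands within ``encounter_radius_um`` of a roadblock; its outcome is
    drawn once from (p_reflect, p_stick, p_cross):

    * reflect — the particle is elastically folded at the roadblock and the
      episode ends once it leaves the encounter radius on the entry side;
    * stick — the particle is pinned at the roadblock for an exponential
      time of mean ``stuck_mean_s`` (infinite by default, i.e. until the
      trace ends);
    * cross — the particle is steered across: it may not retreat past the
      entry-side edge of the encounter zone and the episode ends when it
      exits on the far side.

    The trace is truncated at the minimum of exponential bleaching and
    unbinding times.
    """
    rng = np.random.default_rng(cfg.seed)
    dt = cfg.frame_interval_s
    n = cfg.n_frames
    step_sd = math.sqrt(2.0 * cfg.d_true_um2_s * dt)

    # observable lifetime = min of the two exponential clocks
    t_end = math.inf
    for rate in (cfg.bleach_rate_s, cfg.unbind_rate_s):
        if rate > 0:
            t_end = min(t_end, rng.exponential(1.0 / rate))
    n_alive = n if math.isinf(t_end) else min(n, max(2, int(t_end / dt) + 1))

    steps = rng.normal(0.0, step_sd, size=n - 1) if step_sd > 0 else np.zeros(n - 1)
    positions = np.empty(n)
    positions[0] = cfg.x0_um
    eps = cfg.encounter_radius_um
    events: list[RoadblockEvent] = []

    # per-roadblock episode state
    episode: list[dict | None] = [None] * len(cfg.roadblocks)

    x = cfg.x0_um
    for i in range(1, n):
        x_new = x + steps[i - 1]
        for j, rb in enumerate(cfg.roadblocks):
            p = rb.position_um
            st = episode[j]
            if st is None:
                if abs(x_new - p) < eps:
                    side = math.copysign(1.0, x - p) if x != p else 1.0
                    outcome = rng.choice(
                        ("reflect", "stick", "cross"),
                        p=(rb.p_reflect, rb.p_stick, rb.p_cross),
                    )
                    ev = RoadblockEvent(j, str(outcome), start_frame=i)
                    events.append(ev)
                    st = {"outcome": outcome, "side": side, "event": ev}
                    if outcome == "stick":
                        st["release_t"] = (
                            i * dt + rng.exponential(cfg.stuck_mean_s)
                            if math.isfinite(cfg.stuck_mean_s)
                            else math.inf
                        )
                    episode[j] = st
                else:
                    continue
            side = st["side"]
            outcome = st["outcome"]
            if outcome == "reflect":
                if (x_new - p) * side < 0:
                    x_new = 2.0 * p - x_new
                if (x_new - p) * side >= eps:
                    st["event"].end_frame = i
                    episode[j] = None
            elif outcome == "stick":
                if i * dt < st["release_t"]:
                    x_new = p
                elif abs(x_new - p) >= eps:
                    st["event"].end_frame = i
                    episode[j] = None
            else:  # cross: confined to [entry edge, far side)
                if (x_new - p) * side > eps:
                    over = (x_new - p) * side - eps
                    x_new = p + side * (eps - over)
                if (x_new - p) * side <= -eps:
                    st["event"].end_frame = i
                    episode[j] = None
        if cfg.boundaries_um is not None:
            x_new = _reflect_into(x_new, *cfg.boundaries_um)
        positions[i] = x_new
        x = x_new

    alive = np.arange(n) < n_alive
    interval = (
        cfg.boundaries_um[1] - cfg.boundaries_um[0]
        if cfg.boundaries_um is not None
        else math.nan
    )
    return GroundTruth(
        times_s=np.arange(n) * dt,
        positions_um=positions,
        alive=alive,
        events=events,
        d_true_um2_s=cfg.d_true_um2_s,
        frame_interval_s=dt,
        interval_length_um=interval,
        seed=cfg.seed,
    )


def add_localization_noise(
    traj: Trajectory, sigma_um: float, seed: int | None = None
) -> Trajectory:
    """Return a copy of ``traj`` with i.i.d. Gaussian position noise added,
    emulating finite localization precision."""
    if sigma_um < 0:
        raise ValueError("sigma must be non-negative")
    rng = np.random.default_rng(seed)
    return Trajectory(
        positions_um=traj.positions_um + rng.normal(0.0, sigma_um, len(traj)),
        frame_interval_s=traj.frame_interval_s,
        t0_s=traj.t0_s,
        source=traj.source,
        interpolated=traj.interpolated.copy(),
    )


# ---------------------------------------------------------------------------
# Kymograph rendering
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class KymographSpec:
    """Photophysics of the rendered confocal scan."""

    pixel_size_um: float = 0.1
    psf_sigma_um: float = 0.294
    photons_mean: float = 12.9
    background_mean: float = 0.8  # per 5-pixel window per frame
    n_pixels: int = 64
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pixel_size_um <= 0 or self.psf_sigma_um <= 0 or self.n_pixels <= 0:
            raise ValueError("geometry parameters must be positive")
        if self.photons_mean < 0 or self.background_mean < 0:
            raise ValueError("photon means must be non-negative")


def render_kymograph(gt: GroundTruth, spec: KymographSpec) -> Kymograph:
    """Render the alive part of a trajectory into integer photon counts.

    Per scan line, Poisson(photons_mean) signal photons are placed by
    sampling a Gaussian of width ``psf_sigma_um`` centred on the true
    position and binned into pixels; every pixel independently receives
    Poisson(background_mean / 5) background photons.
    """
    rng = np.random.default_rng(spec.seed)
    n_lines = gt.n_alive
    extent = spec.n_pixels * spec.pixel_size_um
    xs = gt.positions_um[:n_lines]
    if np.any(xs < 0) or np.any(xs >= extent):
        raise ValueError("trajectory leaves the imaged extent")

    counts = rng.poisson(spec.background_mean / 5.0, size=(spec.n_pixels, n_lines))
    for t in range(n_lines):
        n_ph = rng.poisson(spec.photons_mean)
        if n_ph == 0:
            continue
        pos = rng.normal(xs[t], spec.psf_sigma_um, size=n_ph)
        px = np.floor(pos / spec.pixel_size_um).astype(int)
        px = px[(px >= 0) & (px < spec.n_pixels)]
        np.add.at(counts[:, t], px, 1)
    return Kymograph(
        counts=counts.astype(np.uint16),
        pixel_size_um=spec.pixel_size_um,
        line_time_s=gt.frame_interval_s,
    )


# ---------------------------------------------------------------------------
# Binding events
# ---------------------------------------------------------------------------

@dataclass
class BindingEventSet:
    """First-binding times and dwell times for a cohort of molecules."""

    t_first_s: np.ndarray
    first_censored: np.ndarray
    dwell_s: np.ndarray
    dwell_censored: np.ndarray
    concentration_m: float
    dna_length_bp: int

    def __post_init__(self) -> None:
        self.t_first_s = np.asarray(self.t_first_s, dtype=float)
        self.first_censored = np.asarray(self.first_censored, dtype=bool)
        self.dwell_s = np.asarray(self.dwell_s, dtype=float)
        self.dwell_censored = np.asarray(self.dwell_censored, dtype=bool)
        if self.concentration_m <= 0:
            raise ValueError("concentration must be positive")
        if self.dna_length_bp <= 0:
            raise ValueError("DNA length must be positive")


def simulate_binding_events(
    k_on_per_bp: float,
    dna_length_bp: int,
    concentration_m: float,
    mean_lifetime_s: float,
    n_molecules: int,
    observation_window_s: float,
    seed: int = 0,
) -> BindingEventSet:
    """Exponential first-binding and dwell times with right-censoring.

    The pseudo-first-order binding rate is
    ``k_on_per_bp * dna_length_bp * concentration_m`` so that first-binding
    times scale inversely with DNA length at fixed molar concentration.
    """
    if min(k_on_per_bp, concentration_m, mean_lifetime_s, observation_window_s) <= 0:
        raise ValueError("rates, lifetime and window must be positive")
    if dna_length_bp <= 0 or n_molecules <= 0:
        raise ValueError("counts must be positive")
    rng = np.random.default_rng(seed)
    rate = k_on_per_bp * dna_length_bp * concentration_m
    t_first = rng.exponential(1.0 / rate, size=n_molecules)
    first_cens = t_first > observation_window_s
    t_first = np.minimum(t_first, observation_window_s)
    dwell = rng.exponential(mean_lifetime_s, size=n_molecules)
    remaining = np.maximum(observation_window_s - t_first, 0.0)
    dwell_cens = first_cens | (dwell > remaining)
    dwell = np.minimum(dwell, remaining)
    return BindingEventSet(
        t_first_s=t_first,
        first_censored=first_cens,
        dwell_s=dwell,
        dwell_censored=dwell_cens,
        concentration_m=concentration_m,
        dna_length_bp=dna_length_bp,
    )


# ---------------------------------------------------------------------------
# Force-extension curves
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SyntheticFDConfig:
    """Nucleosome-array force-extension generator parameters.

    ``step_size_nm`` is the contour length released by one unwrapping event
    in the 15-30 pN regime; ``lengthening_at_5pn_nm`` is the total
    extension deficit one wrapped nucleosome causes at 5 pN (the compaction
    calibration).  The deficit in excess of the high-force step is released
    smoothly between 15 and 5 pN, mimicking gradual outer-turn unpeeling.
    """

    n_nucleosomes: int = 0
    step_size_nm: float = 25.0
    unwrap_force_range_pn: tuple[float, float] = (15.0, 30.0)
    naked_contour_length_um: float = 16.5
    persistence_length_nm: float = 50.0
    lengthening_at_5pn_nm: float = 34.6
    noise_sd_nm: float = 2.0
    min_force_separation_pn: float = 0.3
    force_min_pn: float = 0.5
    force_max_pn: float = 35.0
    n_samples: int = 3500
    kbt_pn_nm: float = 4.1143
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_nucleosomes < 0:
            raise ValueError("n_nucleosomes must be non-negative")
        lo, hi = self.unwrap_force_range_pn
        if lo <= 0 or hi <= lo:
            raise ValueError("unwrap force range must be positive with min < max")
        if self.force_min_pn <= 0 or self.force_max_pn <= self.force_min_pn:
            raise ValueError("force ramp must be positive with min < max")


@dataclass
class ForceExtensionCurve:
    """A monotone force ramp with the measured tether distance."""

    force_pn: np.ndarray
    distance_um: np.ndarray
    clamp_forces_pn: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        self.force_pn = np.asarray(self.force_pn, dtype=float)
        self.distance_um = np.asarray(self.distance_um, dtype=float)
        if self.force_pn.size != self.distance_um.size:
            raise ValueError("force and distance must be paired")
        if not (np.all(np.isfinite(self.force_pn)) and np.all(np.isfinite(self.distance_um))):
            raise ValueError("samples must be finite")


def wlc_extension_fraction(force_pn, persistence_nm: float = 50.0, kbt: float = 4.1143):
    """Relative extension x/L of a worm-like chain at the given force(s),
    from the Marko-Siggia interpolation
    ``F P / kT = 1/(4(1-z)^2) - 1/4 + z``."""
    scalar = np.isscalar(force_pn)
    forces = np.atleast_1d(np.asarray(force_pn, dtype=float))
    if np.any(forces <= 0):
        raise ValueError("force must be positive")
    out = np.empty_like(forces)
    for i, f in enumerate(forces):
        rhs = f * persistence_nm / kbt

        def g(z, rhs=rhs):
            return 1.0 / (4.0 * (1.0 - z) ** 2) - 0.25 + z - rhs

        out[i] = brentq(g, 0.0, 1.0 - 1e-9)
    return float(out[0]) if scalar else out


def _draw_spaced_uniform(rng, n, lo, hi, min_sep):
    """Uniform order statistics conditioned on a minimum pairwise
    separation, via the exact gap-shift construction: sorted uniforms on the
    interval shrunk by (n-1)*min_sep, then spread back out."""
    if n == 0:
        return np.array([])
    slack = (hi - lo) - (n - 1) * min_sep
    if slack <= 0:
        raise ValueError("force range too narrow for the requested separation")
    u = np.sort(rng.uniform(0.0, slack, size=n))
    return lo + u + np.arange(n) * min_sep


def simulate_force_extension(cfg: SyntheticFDConfig) -> ForceExtensionCurve:
    """Synthesize a nucleosome-array unwrapping force-distance curve.

    The tether follows a Marko-Siggia worm-like chain whose contour length
    grows by ``step_size_nm`` at each of ``n_nucleosomes`` unwrapping
    forces drawn uniformly (with a minimum separation, for detector
    identifiability) from ``unwrap_force_range_pn``.  Each still-wrapped
    nucleosome additionally withholds ``lengthening_at_5pn_nm - z(5pN) *
    step_size_nm`` of extension, released linearly between 5 pN and the
    low edge of the unwrapping window, so that the extension deficit per
    wrapped nucleosome at 5 pN equals exactly ``lengthening_at_5pn_nm``.
    """
    rng = np.random.default_rng(cfg.seed)
    f_lo, f_hi = cfg.unwrap_force_range_pn
    unwrap_f = _draw_spaced_uniform(
        rng, cfg.n_nucleosomes, f_lo, f_hi, cfg.min_force_separation_pn
    )

    forces = np.linspace(cfg.force_min_pn, cfg.force_max_pn, cfg.n_samples)
    z = wlc_extension_fraction(forces, cfg.persistence_length_nm, cfg.kbt_pn_nm)
    z5 = wlc_extension_fraction(5.0, cfg.persistence_length_nm, cfg.kbt_pn_nm)

    n_wrapped = np.searchsorted(unwrap_f, forces, side="left")
    n_wrapped = cfg.n_nucleosomes - n_wrapped  # still wrapped at each force

    contour_um = (
        cfg.naked_contour_length_um
        - n_wrapped * cfg.step_size_nm * 1e-3
    )
    extra_nm = max(cfg.lengthening_at_5pn_nm - z5 * cfg.step_size_nm, 0.0)
    # gradual release of the sub-15pN deficit: full at <=5 pN, gone at f_lo
    ramp = np.clip((f_lo - forces) / (f_lo - 5.0), 0.0, 1.0)
    deficit_um = n_wrapped * extra_nm * 1e-3 * ramp

    distance = z * contour_um - deficit_um
    distance = distance + rng.normal(0.0, cfg.noise_sd_nm * 1e-3, size=distance.size)
    return ForceExtensionCurve(force_pn=forces, distance_um=distance)
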