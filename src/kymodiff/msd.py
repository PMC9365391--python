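"""Mean-squared-displacement curves and diffusion-coefficient estimation.

The per-trace estimator reproduces a specific analysis ledger:

* time-averaged MSD with overlapping windows,
  ``MSD(n) = sum_i (X_{i+n} - X_i)^2 / (N - n)`` for lags 1..N-1;
* adaptive linear fit of the initial portion: among candidate windows of
  3..N-1 lags whose slope has p < 0.05, the one with the highest Pearson
  r^2 is chosen (near-ties within 1e-9 broken toward more points); if none
  qualifies the first 25% of lags is fit;
* D = slope / 2 (1D Brownian motion, MSD = 2 D t); negative slopes are
  clamped to D = 0;
* per-condition refinement: traces with D above an outlier cutoff or fit
  r^2 below a threshold are flagged as rejected;
* ensemble summary: median D over accepted traces, uncertainty of the
  median SEM * sqrt(pi/2), mobile fraction against a fixed threshold with a
  percentile-bootstrap confidence interval.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.optimize import curve_fit

from .tracking import Trajectory

__all__ = [
    "MSDCurve",
    "RefinementRules",
    "DiffusionEstimate",
    "AnomalousFit",
    "PlateauFit",
    "EnsembleStats",
    "compute_msd",
    "mean_msd",
    "fit_diffusion_coefficient",
    "fit_anomalous",
    "fit_plateau",
    "ensemble_stats",
]


@dataclass
class MSDCurve:
    """Time-averaged MSD per lag; lag n covers 1..N-1 frames."""

    lag_times_s: np.ndarray
    values_um2: np.ndarray
    n_pairs: np.ndarray
    frame_interval_s: float

    def __post_init__(self) -> None:
        self.lag_times_s = np.asarray(self.lag_times_s, dtype=float)
        self.values_um2 = np.asarray(self.values_um2, dtype=float)
        self.n_pairs = np.asarray(self.n_pairs, dtype=int)
        if not (self.lag_times_s.size == self.values_um2.size == self.n_pairs.size):
            raise ValueError("lag/value/count length mismatch")
        if np.any(self.values_um2 < 0):
            raise ValueError("MSD values must be non-negative")

    @property
    def n_lags(self) -> int:
        return self.lag_times_s.size


def compute_msd(traj: Trajectory) -> MSDCurve:
    """Exact time-averaged MSD with overlapping windows for all lags."""
    x = traj.positions_um
    n = x.size
    if n < 2:
        raise ValueError("need at least two frames")
    lags = np.arange(1, n)
    values = np.empty(n - 1)
    for k in lags:
        d = x[k:] - x[:-k]
        values[k - 1] = np.mean(d * d)
    return MSDCurve(
        lag_times_s=lags * traj.frame_interval_s,
        values_um2=values,
        n_pairs=n - lags,
        frame_interval_s=traj.frame_interval_s,
    )


def mean_msd(curves: list[MSDCurve]) -> MSDCurve:
    """Average MSD curves sharing one frame interval (truncated to the
    shortest curve); per-lag pair counts are summed."""
    if not curves:
        raise ValueError("no curves to average")
    dt = curves[0].frame_interval_s
    if any(abs(c.frame_interval_s - dt) > 1e-12 for c in curves):
        raise ValueError("curves must share a frame interval")
    m = min(c.n_lags for c in curves)
    vals = np.mean([c.values_um2[:m] for c in curves], axis=0)
    pairs = np.sum([c.n_pairs[:m] for c in curves], axis=0)
    return MSDCurve(curves[0].lag_times_s[:m], vals, pairs, dt)


@dataclass(frozen=True)
class RefinementRules:
    """Per-condition trace-refinement criteria.

    ``max_d_um2_s`` is the outlier cutoff (0.14 for remodeler-scale data,
    5 for fast small-domain data); ``min_r2`` is the fit-quality threshold.
    Either may be None to disable that criterion.
    """

    max_d_um2_s: float | None = 0.14
    min_r2: float | None = 0.8


@dataclass
class DiffusionEstimate:
    d_um2_s: float
    n_points_fit: int
    r2: float
    p_value: float
    method: str  # adaptive | first-quarter-fallback | clamped-zero
    rejected: bool = False
    reason: str = ""
    source: str = ""


def _window_scan(t: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Slope, r^2 and slope p-value of the linear fit over the first k lags,
    vectorised for every k in 3..len(t) via prefix sums."""
    n = t.size
    ks = np.arange(3, n + 1)
    st, sy = np.cumsum(t), np.cumsum(y)
    stt, sty, syy = np.cumsum(t * t), np.cumsum(t * y), np.cumsum(y * y)
    k = ks.astype(float)
    i = ks - 1
    sxx = stt[i] - st[i] ** 2 / k
    sxy = sty[i] - st[i] * sy[i] / k
    syy_c = syy[i] - sy[i] ** 2 / k
    with np.errstate(divide="ignore", invalid="ignore"):
        slope = sxy / sxx
        r2 = np.where(syy_c > 0, sxy**2 / (sxx * syy_c), np.nan)
        tstat = np.sqrt(np.clip(r2, 0, 1 - 1e-15) * (k - 2) / (1 - np.clip(r2, 0, 1 - 1e-15)))
        pval = 2.0 * stats.t.sf(tstat, df=k - 2)
    return slope, r2, pval


def fit_diffusion_coefficient(
    msd: MSDCurve,
    rules: RefinementRules | None = None,
    source: str = "",
) -> DiffusionEstimate:
    """Adaptive linear fit of the initial MSD portion; D = slope/2."""
    t, y = msd.lag_times_s, msd.values_um2
    if t.size < 3:
        raise ValueError("need at least three lags")
    rules = rules if rules is not None else RefinementRules()

    if np.allclose(y, 0.0):
        return DiffusionEstimate(0.0, t.size, 1.0, 0.0, "clamped-zero", source=source)

    slope_k, r2_k, p_k = _window_scan(t, y)
    ok = np.isfinite(p_k) & (p_k < 0.05) & np.isfinite(r2_k)
    if np.any(ok):
        cand = np.flatnonzero(ok)
        best_r2 = np.max(r2_k[cand])
        # highest r2 wins; near-ties resolved toward the longer window
        idx = cand[r2_k[cand] >= best_r2 - 1e-9][-1]
        k = idx + 3
        method = "adaptive"
    else:
        k = max(2, int(np.ceil(0.25 * t.size)))
        method = "first-quarter-fallback"

    res = stats.linregress(t[:k], y[:k])
    slope = res.slope
    r2 = res.rvalue**2
    pval = res.pvalue if np.isfinite(res.pvalue) else float("nan")

    if slope < 0:
        d = 0.0
        method = "clamped-zero"
    else:
        d = slope / 2.0

    est = DiffusionEstimate(d, k, r2, pval, method, source=source)
    if rules.max_d_um2_s is not None and d > rules.max_d_um2_s:
        est.rejected = True
        est.reason = "outlier-cutoff"
    elif rules.min_r2 is not None and r2 < rules.min_r2:
        est.rejected = True
        est.reason = "low-r2"
    return est


@dataclass
class AnomalousFit:
    """Power-law fit MSD = D * t^alpha over an initial window."""

    d_um2_s_alpha: float
    alpha: float
    window_s: float
    alpha_ci95: tuple[float, float]
    n_points: int
    method: str


def fit_anomalous(
    msd: MSDCurve, window_s: float = 2.0, method: str = "power"
) -> AnomalousFit:
    """Fit MSD = D * t^alpha over lags <= ``window_s``.

    ``method="power"`` (default) is a nonlinear least-squares fit in linear
    space; on saturating curves its absolute residuals weight the plateau
    and it tracks the visible curvature, which is how such fits are usually
    shown over MSD curves.  ``method="loglog"`` regresses log MSD on log t
    (zero-MSD lags excluded); the two agree on clean power-law data but the
    log-log variant underweights the plateau of confined curves.  The 95%
    CI on alpha uses the parameter standard error and Student's t.
    """
    mask = msd.lag_times_s <= window_s
    if method == "loglog":
        mask &= msd.values_um2 > 0
    t, y = msd.lag_times_s[mask], msd.values_um2[mask]
    if t.size < 4:
        raise ValueError("need at least four usable lags inside the window")
    if method == "loglog":
        res = stats.linregress(np.log(t), np.log(y))
        alpha, d0, se = res.slope, float(np.exp(res.intercept)), res.stderr
    elif method == "power":
        p0 = [max(y[-1], 1e-12) / t[-1], 1.0]
        popt, pcov = curve_fit(
            lambda tt, d, a: d * np.power(tt, a), t, y, p0=p0, maxfev=10000
        )
        d0, alpha = float(popt[0]), float(popt[1])
        se = float(np.sqrt(pcov[1, 1]))
    else:
        raise ValueError("method must be 'power' or 'loglog'")
    half = stats.t.ppf(0.975, t.size - 2) * se
    return AnomalousFit(
        d_um2_s_alpha=d0,
        alpha=alpha,
        window_s=window_s,
        alpha_ci95=(alpha - half, alpha + half),
        n_points=t.size,
        method=method,
    )


@dataclass
class PlateauFit:
    """Saturating-exponential fit MSD(t) = A (1 - exp(-t/tau))."""

    msd_limit_um2: float
    confinement_length_um: float
    tau_s: float
    r2: float
    saturating: bool


def fit_plateau(msd: MSDCurve) -> PlateauFit:
    """Fit a saturating exponential to a (mean) MSD curve.

    The plateau A is the MSD limit and sqrt(A) the confinement length.  A
    curve that does not saturate inside the observed lag range (fitted tau
    beyond half the maximal lag, or runaway amplitude) is flagged with
    ``saturating=False`` and NaN plateau values.
    """
    t, y = msd.lag_times_s, msd.values_um2
    if t.size < 4:
        raise ValueError("need at least four lags")
    t_max, y_max = t[-1], float(np.max(y))
    if y_max <= 0:
        return PlateauFit(np.nan, np.nan, np.nan, 0.0, False)

    def f(tt, a, tau):
        return a * (1.0 - np.exp(-tt / tau))

    try:
        popt, _ = curve_fit(
            f, t, y, p0=[y_max, max(t[1], t_max / 10.0)],
            bounds=([0.0, t[0] / 10.0], [np.inf, np.inf]), maxfev=2000,
        )
    except RuntimeError:
        return PlateauFit(np.nan, np.nan, np.nan, 0.0, False)
    a, tau = popt
    resid = y - f(t, a, tau)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 0.0
    if tau > 0.5 * t_max or a > 2.0 * y_max:
        return PlateauFit(np.nan, np.nan, tau, r2, False)
    return PlateauFit(a, float(np.sqrt(a)), tau, r2, True)


@dataclass
class EnsembleStats:
    median_d_um2_s: float
    median_uncertainty: float  # SEM * sqrt(pi/2)
    mobile_fraction: float
    mobile_fraction_ci95: tuple[float, float]
    median_ci95: tuple[float, float]
    n_pre: int
    n_post: int
    mobility_threshold: float
    n_boot: int


def ensemble_stats(
    estimates: list[DiffusionEstimate],
    mobility_threshold: float = 0.007,
    n_boot: int = 5000,
    seed: int | None = None,
) -> EnsembleStats:
    """Ensemble summary over accepted (non-rejected) per-trace estimates."""
    d_all = np.array([e.d_um2_s for e in estimates])
    d = np.array([e.d_um2_s for e in estimates if not e.rejected])
    if d.size == 0:
        raise ValueError("no estimate survived refinement")
    sem = d.std(ddof=1) / np.sqrt(d.size) if d.size > 1 else 0.0
    mobile = d >= mobility_threshold

    rng = np.random.default_rng(seed)
    idx = rng.integers(0, d.size, size=(n_boot, d.size))
    boot_frac = mobile[idx].mean(axis=1)
    boot_med = np.median(d[idx], axis=1)
    return EnsembleStats(
        median_d_um2_s=float(np.median(d)),
        median_uncertainty=float(sem * np.sqrt(np.pi / 2.0)),
        mobile_fraction=float(mobile.mean()),
        mobile_fraction_ci95=(
            float(np.percentile(boot_frac, 2.5)),
            float(np.percentile(boot_frac, 97.5)),
        ),
        median_ci95=(
            float(np.percentile(boot_med, 2.5)),
            float(np.percentile(boot_med, 97.5)),
        ),
        n_pre=d_all.size,
        n_post=d.size,
        mobility_threshold=mobility_threshold,
        n_boot=n_boot,
    )
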