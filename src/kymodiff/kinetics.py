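"""On-rate and bound-lifetime estimation from single-molecule event streams.

The on-rate comes from first-arrival times after injection: with
pseudo-first-order kinetics the arrival times are exponential, the rate is
the exponential MLE 1/mean, and the second-order constant is rate divided
by concentration.  Bound lifetimes come from dwell-time survival curves
(Kaplan-Meier under right-censoring) fit to a single exponential.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from lifelines import KaplanMeierFitter
from scipy import stats
from scipy.optimize import curve_fit

from .simulate import BindingEventSet

__all__ = [
    "KineticsResult",
    "SurvivalFit",
    "estimate_kbind",
    "fit_survival",
    "photobleach_correction",
]


@dataclass
class KineticsResult:
    k_bind_m1s1: float
    k_bind_se: float
    k_bind_per_bp_m1s1: float
    pseudo_first_order_rate_s1: float
    mean_t_first_s: float
    n_events: int


def estimate_kbind(events: BindingEventSet) -> KineticsResult:
    """Second-order on-rate from uncensored first-binding times.

    The exponential MLE of the pseudo-first-order rate is 1/mean(t_first);
    its relative standard error is 1/sqrt(n).  ``k_bind`` is the rate
    divided by the molar concentration, and a per-basepair normalization is
    returned alongside.
    """
    t = events.t_first_s[~events.first_censored]
    if t.size < 10:
        raise ValueError("need at least ten uncensored first-binding times")
    mean_t = float(np.mean(t))
    rate = 1.0 / mean_t
    k_bind = rate / events.concentration_m
    return KineticsResult(
        k_bind_m1s1=k_bind,
        k_bind_se=k_bind / np.sqrt(t.size),
        k_bind_per_bp_m1s1=k_bind / events.dna_length_bp,
        pseudo_first_order_rate_s1=rate,
        mean_t_first_s=mean_t,
        n_events=int(t.size),
    )


@dataclass
class SurvivalFit:
    tau_s: float  # time constant of the exponential decay fit to 1-CDF
    half_life_s: float
    tau_mle_s: float  # censoring-aware exponential MLE
    log_survival_r2: float
    flagged: bool
    flag_reason: str
    n_events: int
    n_censored: int


def fit_survival(
    dwell_s: np.ndarray,
    censored: np.ndarray | None = None,
    min_r2: float = 0.95,
) -> SurvivalFit:
    """Exponential fit to the dwell-time survival curve (1 - CDF).

    Censored observations enter through the Kaplan-Meier estimator; the
    survival curve is fit to ``exp(-t/tau)`` by nonlinear least squares and
    the half-life is ``tau * ln 2``.  The censoring-aware exponential MLE
    (total observation time / number of events) is reported alongside.
    Departures from single-exponential decay are flagged when the
    log-survival linearity r^2 falls below ``min_r2``.
    """
    dwell = np.asarray(dwell_s, dtype=float)
    if dwell.size < 10:
        raise ValueError("need at least ten dwell times")
    cens = (
        np.zeros(dwell.size, dtype=bool)
        if censored is None
        else np.asarray(censored, dtype=bool)
    )
    observed = ~cens
    if not observed.any():
        return SurvivalFit(
            tau_s=float("inf"),
            half_life_s=float("inf"),
            tau_mle_s=float("inf"),
            log_survival_r2=float("nan"),
            flagged=True,
            flag_reason="all-censored",
            n_events=0,
            n_censored=int(cens.sum()),
        )
    tau_mle = float(dwell.sum() / observed.sum())

    km = KaplanMeierFitter()
    km.fit(dwell, event_observed=observed)
    surv = km.survival_function_.iloc[:, 0]
    t = surv.index.to_numpy(dtype=float)
    s = surv.to_numpy(dtype=float)
    keep = t > 0
    t, s = t[keep], s[keep]

    try:
        popt, _ = curve_fit(
            lambda tt, tau: np.exp(-tt / tau), t, s, p0=[tau_mle], maxfev=5000
        )
        tau = float(popt[0])
    except RuntimeError:
        tau = float("inf")

    pos = s > 0
    lin = stats.linregress(t[pos], np.log(s[pos]))
    r2 = lin.rvalue**2
    flagged = (not np.isfinite(tau)) or tau <= 0 or r2 < min_r2
    reason = "" if not flagged else ("non-decaying" if not np.isfinite(tau) else "non-exponential")
    return SurvivalFit(
        tau_s=tau,
        half_life_s=tau * np.log(2.0),
        tau_mle_s=tau_mle,
        log_survival_r2=float(r2),
        flagged=flagged,
        flag_reason=reason,
        n_events=int(observed.sum()),
        n_censored=int(cens.sum()),
    )


def photobleach_correction(
    rates_by_power: list[tuple[float, float]],
) -> tuple[float, float]:
    """Intrinsic off-rate by extrapolating apparent rates to zero power.

    Takes (laser_power, apparent_off_rate) pairs, fits a line and returns
    ``(intrinsic_rate, slope)``.  A negative intercept is clamped to zero
    with a warning.
    """
    if len(rates_by_power) < 2:
        raise ValueError("need at least two laser-power levels")
    power = np.array([p for p, _ in rates_by_power], dtype=float)
    rate = np.array([r for _, r in rates_by_power], dtype=float)
    if np.ptp(power) == 0:
        # constant power: no extrapolation possible beyond the mean rate
        return float(np.mean(rate)), 0.0
    res = stats.linregress(power, rate)
    intercept = float(res.intercept)
    if intercept < 0:
        warnings.warn("extrapolated intrinsic off-rate was negative; clamped to 0")
        intercept = 0.0
    return intercept, float(res.slope)
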