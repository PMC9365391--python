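import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from kymodiff.msd import (
    MSDCurve,
    RefinementRules,
    compute_msd,
    ensemble_stats,
    fit_anomalous,
    fit_diffusion_coefficient,
    fit_plateau,
    mean_msd,
)
from kymodiff.simulate import SimConfig, simulate_trajectory
from kymodiff.tracking import Trajectory


def brute_force_msd(x):
    """Independent double-loop oracle for the time-averaged MSD."""
    n = len(x)
    out = []
    for lag in range(1, n):
        acc = 0.0
        for i in range(n - lag):
            acc += (x[i + lag] - x[i]) ** 2
        out.append(acc / (n - lag))
    return np.array(out)


def _curve(values, dt=0.05):
    values = np.asarray(values, dtype=float)
    n = values.size
    return MSDCurve(
        lag_times_s=np.arange(1, n + 1) * dt,
        values_um2=values,
        n_pairs=np.arange(n, 0, -1),
        frame_interval_s=dt,
    )


class TestComputeMsd:
    def test_constant_trajectory_is_zero(self):
        tr = Trajectory(np.full(20, 3.3), 0.05)
        assert np.all(compute_msd(tr).values_um2 == 0.0)

    def test_hand_computed_ramp(self):
        tr = Trajectory(np.array([0.0, 1.0, 2.0, 3.0]), 1.0)
        np.testing.assert_allclose(compute_msd(tr).values_um2, [1.0, 4.0, 9.0])

    def test_pair_counts(self):
        tr = Trajectory(np.arange(6, dtype=float), 1.0)
        np.testing.assert_array_equal(compute_msd(tr).n_pairs, [5, 4, 3, 2, 1])

    @given(st.integers(min_value=2, max_value=50), st.integers(min_value=0, max_value=2**32 - 1))
    @settings(max_examples=80, deadline=None)
    def test_matches_brute_force_oracle(self, n, seed):
        x = np.random.default_rng(seed).normal(size=n)
        tr = Trajectory(x, 0.05)
        np.testing.assert_allclose(compute_msd(tr).values_um2, brute_force_msd(x), rtol=1e-12)

    def test_brownian_expectation(self):
        # ensemble mean of msd(n) ~ 2 D n dt
        d, dt = 0.01, 0.05
        curves = [
            compute_msd(
                simulate_trajectory(
                    SimConfig(d_true_um2_s=d, frame_interval_s=dt, n_frames=200, seed=s)
                ).to_trajectory()
            )
            for s in range(200)
        ]
        mm = mean_msd(curves)
        expected = 2 * d * mm.lag_times_s[:10]
        np.testing.assert_allclose(mm.values_um2[:10], expected, rtol=0.12)


class TestFitDiffusion:
    def test_exact_linear_curve(self):
        dt = 0.05
        t = np.arange(1, 40) * dt
        est = fit_diffusion_coefficient(_curve(2 * 0.01 * t))
        assert est.d_um2_s == pytest.approx(0.01, rel=1e-9)
        assert est.r2 == pytest.approx(1.0)
        assert not est.rejected

    def test_negative_slope_clamped(self):
        est = fit_diffusion_coefficient(_curve(np.linspace(1.0, 0.1, 30)))
        assert est.d_um2_s == 0.0
        assert est.method == "clamped-zero"

    def test_all_zero_curve(self):
        est = fit_diffusion_coefficient(_curve(np.zeros(30)))
        assert est.d_um2_s == 0.0

    def test_outlier_cutoff_rejection(self):
        t = np.arange(1, 30) * 0.05
        est = fit_diffusion_coefficient(_curve(2 * 0.5 * t))  # D = 0.5 > 0.14
        assert est.rejected and est.reason == "outlier-cutoff"
        est5 = fit_diffusion_coefficient(
            _curve(2 * 0.5 * t), rules=RefinementRules(max_d_um2_s=5.0, min_r2=0.8)
        )
        assert not est5.rejected

    def test_offset_and_flip_invariance(self):
        gt = simulate_trajectory(SimConfig(d_true_um2_s=0.02, frame_interval_s=0.05, n_frames=300, seed=5))
        tr = gt.to_trajectory()
        d0 = fit_diffusion_coefficient(compute_msd(tr)).d_um2_s
        shifted = Trajectory(tr.positions_um + 7.7, 0.05)
        flipped = Trajectory(-tr.positions_um, 0.05)
        assert fit_diffusion_coefficient(compute_msd(shifted)).d_um2_s == pytest.approx(d0, rel=1e-12)
        assert fit_diffusion_coefficient(compute_msd(flipped)).d_um2_s == pytest.approx(d0, rel=1e-12)

    def test_recovery_at_atp_condition(self, atp_condition_estimates):
        stats = ensemble_stats(atp_condition_estimates, seed=1)
        lo, hi = stats.median_ci95
        assert lo <= 0.024 <= hi

    @pytest.mark.parametrize("d_true", [0.001, 0.0059, 0.035, 0.21, 1.5])
    def test_recovery_across_log_grid(self, d_true):
        from conftest import make_noisy_estimates

        ests = make_noisy_estimates(
            d_true, n_traces=100, rules=RefinementRules(max_d_um2_s=None, min_r2=None),
            seed0=int(1e4 * d_true) + 13,
        )
        med = np.median([e.d_um2_s for e in ests])
        assert med == pytest.approx(d_true, rel=0.2)

    def test_bias_shrinks_with_trace_length(self):
        from conftest import make_noisy_estimates

        rules = RefinementRules(max_d_um2_s=None, min_r2=None)
        errs = []
        for n_frames in (150, 1200):
            ests = make_noisy_estimates(0.024, n_traces=60, n_frames=n_frames, rules=rules, seed0=99)
            errs.append(abs(np.median([e.d_um2_s for e in ests]) - 0.024))
        assert errs[1] < errs[0]

    def test_outlier_share_below_three_percent(self, atp_condition_estimates):
        n_cut = sum(e.reason == "outlier-cutoff" for e in atp_condition_estimates)
        assert n_cut / len(atp_condition_estimates) < 0.03


class TestFitAnomalous:
    def test_pure_linear_gives_alpha_one(self):
        t = np.arange(1, 50) * 0.05
        af = fit_anomalous(_curve(0.3 * t))
        assert af.alpha == pytest.approx(1.0, abs=1e-6)

    def test_ballistic_gives_alpha_two(self):
        t = np.arange(1, 50) * 0.05
        af = fit_anomalous(_curve(0.3 * t**2))
        assert af.alpha == pytest.approx(2.0, abs=1e-6)

    def test_loglog_agrees_on_clean_power_law(self):
        t = np.arange(1, 50) * 0.05
        curve = _curve(0.1 * t**0.6)
        assert fit_anomalous(curve).alpha == pytest.approx(
            fit_anomalous(curve, method="loglog").alpha, abs=1e-6
        )

    def test_confined_is_subdiffusive(self):
        curves = [
            compute_msd(
                simulate_trajectory(
                    SimConfig(
                        d_true_um2_s=0.024, frame_interval_s=0.05, n_frames=600,
                        x0_um=0.17, boundaries_um=(0.0, 0.35), seed=400 + s,
                    )
                ).to_trajectory()
            )
            for s in range(40)
        ]
        af = fit_anomalous(mean_msd(curves))
        assert af.alpha < 0.6

    def test_window_restriction(self):
        t = np.arange(1, 100) * 0.05
        af = fit_anomalous(_curve(0.3 * t), window_s=1.0)
        assert af.n_points == 20

    def test_too_few_lags(self):
        with pytest.raises(ValueError):
            fit_anomalous(_curve(np.array([0.1, 0.2, 0.3])), window_s=0.1)


class TestFitPlateau:
    def test_exact_saturating_exponential(self):
        t = np.arange(1, 200) * 0.05
        pf = fit_plateau(_curve(0.054 * (1 - np.exp(-t / 0.8))))
        assert pf.saturating
        assert pf.msd_limit_um2 == pytest.approx(0.054, rel=1e-6)
        assert pf.confinement_length_um == pytest.approx(0.2324, abs=5e-4)

    def test_linear_curve_flagged(self):
        t = np.arange(1, 200) * 0.05
        pf = fit_plateau(_curve(0.01 * t))
        assert not pf.saturating
        assert np.isnan(pf.msd_limit_um2)

    def test_reflected_interval_plateau(self):
        L = 0.35
        curves = [
            compute_msd(
                simulate_trajectory(
                    SimConfig(
                        d_true_um2_s=0.024, frame_interval_s=0.05, n_frames=600,
                        x0_um=L / 2, boundaries_um=(0.0, L), seed=800 + s,
                    )
                ).to_trajectory()
            )
            for s in range(60)
        ]
        pf = fit_plateau(mean_msd(curves))
        assert pf.saturating
        assert pf.msd_limit_um2 == pytest.approx(L**2 / 6, rel=0.15)


class TestEnsembleStats:
    def test_all_zero(self):
        ests = [fit_diffusion_coefficient(_curve(np.zeros(20))) for _ in range(5)]
        stats = ensemble_stats(ests, seed=0)
        assert stats.median_d_um2_s == 0.0
        assert stats.mobile_fraction == 0.0

    def test_median_uncertainty_formula(self, atp_condition_estimates):
        d = np.array([e.d_um2_s for e in atp_condition_estimates if not e.rejected])
        stats = ensemble_stats(atp_condition_estimates, seed=0)
        sem = d.std(ddof=1) / np.sqrt(d.size)
        assert stats.median_uncertainty == pytest.approx(sem * np.sqrt(np.pi / 2), rel=1e-12)

    def test_immobile_reference(self, immobile_condition_estimates):
        stats = ensemble_stats(immobile_condition_estimates, seed=2)
        assert stats.median_d_um2_s == pytest.approx(0.0003, abs=3e-4)
        assert stats.mobile_fraction <= 0.05

    def test_bootstrap_ci_covers_true_fraction(self):
        # known Bernoulli(0.7) mixture of clearly-mobile / clearly-immobile D values
        cover = 0
        runs = 40
        for s in range(runs):
            rng = np.random.default_rng(s)
            mobile = rng.random(80) < 0.7
            ests = [
                fit_diffusion_coefficient(_curve(2 * (0.05 if m else 0.001) * np.arange(1, 20) * 0.05))
                for m in mobile
            ]
            stats = ensemble_stats(ests, n_boot=1000, seed=s)
            lo, hi = stats.mobile_fraction_ci95
            cover += lo <= 0.7 <= hi
        assert cover / runs >= 0.85

    def test_empty_after_refinement_errors(self):
        t = np.arange(1, 20) * 0.05
        est = fit_diffusion_coefficient(_curve(2 * 0.5 * t))  # rejected outlier
        with pytest.raises(ValueError):
            ensemble_stats([est])

    def test_rejected_counted_pre_not_post(self, atp_condition_estimates):
        stats = ensemble_stats(atp_condition_estimates, seed=0)
        assert stats.n_post <= stats.n_pre == len(atp_condition_estimates)


class TestMeanMsd:
    def test_mismatched_frame_interval_rejected(self):
        a = _curve(np.arange(1, 10.0), dt=0.05)
        b = _curve(np.arange(1, 10.0), dt=0.02)
        with pytest.raises(ValueError):
            mean_msd([a, b])

    def test_average_of_identical_curves(self):
        a = _curve(np.arange(1, 10.0))
        mm = mean_msd([a, a, a])
        np.testing.assert_allclose(mm.values_um2, a.values_um2)
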