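import numpy as np
import pytest

from kymodiff.msd import RefinementRules, compute_msd, fit_diffusion_coefficient
from kymodiff.simulate import SimConfig, add_localization_noise, simulate_trajectory


def make_noisy_estimates(d_true, n_traces=100, n_frames=600, dt=0.05, noise_um=0.082,
                         rules=None, seed0=0):
    """Simulate -> add localization noise -> per-trace diffusion estimates."""
    ests = []
    for k in range(n_traces):
        gt = simulate_trajectory(
            SimConfig(d_true_um2_s=d_true, frame_interval_s=dt, n_frames=n_frames, seed=seed0 + k)
        )
        tr = add_localization_noise(gt.to_trajectory(), noise_um, seed=seed0 + 100_000 + k)
        ests.append(fit_diffusion_coefficient(compute_msd(tr), rules=rules))
    return ests


@pytest.fixture(scope="session")
def atp_condition_estimates():
    """100 trajectories at the remodeler-with-nucleotide ground truth
    (D=0.024 um^2/s, 600 frames, 50 ms, 82 nm noise)."""
    return make_noisy_estimates(0.024, rules=RefinementRules())


@pytest.fixture(scope="session")
def immobile_condition_estimates():
    """100 trajectories at the immobile-reference ground truth (D=0.0003)."""
    return make_noisy_estimates(
        0.0003, rules=RefinementRules(max_d_um2_s=None, min_r2=None), seed0=7_000
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
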