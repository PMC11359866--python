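import numpy as np
import pytest

from uwbfall import MotionProfile, RadarParams, synthesize_pulses


@pytest.fixture(scope="session")
def params() -> RadarParams:
    return RadarParams()


@pytest.fixture(scope="session")
def wide_params() -> RadarParams:
    """A longer range gate so a 1 m/s target can run for the full 5 s."""
    return RadarParams(max_range=8.0, n_range_bins=256)


def constant_velocity_profile(r0: float, v: float) -> MotionProfile:
    return MotionProfile(
        class_id=None,
        range_trajectory=lambda t: r0 + v * np.asarray(t, dtype=float),
        rcs_envelope=lambda t: np.ones_like(np.asarray(t, dtype=float)),
    )


@pytest.fixture(scope="session")
def moving_target_pulses(wide_params):
    """Noise- and clutter-free echo of a 1 m/s approaching scatterer."""
    prof = constant_velocity_profile(6.5, -1.0)
    return synthesize_pulses(
        prof, wide_params, clutter_amp=0.0, noise_sigma=0.0, rng_seed=0
    )
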