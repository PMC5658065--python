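import numpy as np
import pytest

from dualtrace.profiles import IntensityProfile
from dualtrace.simulate import CategoricalOffset, SimulationConfig, generate_movie


def gaussian_trace(
    amplitude: float,
    center_frames: float,
    sigma_frames: float,
    n_frames: int = 30,
    frame_interval_s: float = 2.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> IntensityProfile:
    """A sampled temporal Gaussian with optional white noise."""
    t = np.arange(n_frames) * frame_interval_s
    v = amplitude * np.exp(
        -((t - center_frames * frame_interval_s) ** 2)
        / (2.0 * (sigma_frames * frame_interval_s) ** 2)
    )
    if noise_sd > 0:
        v = v + np.random.default_rng(seed).normal(0.0, noise_sd, n_frames)
    return IntensityProfile(t, v, frame_interval_s)


def benchmark_config(seed: int = 1, **overrides) -> SimulationConfig:
    """The planted-event recovery benchmark movie: 64x64 px, 150 frames at
    2 s/frame, 30 paired events with temporal sigma 2-5 frames, amplitudes
    above the 40% relative-intensity threshold, SNR >= 5, and peak offsets
    inside the correlation criterion's acceptance region."""
    defaults = dict(
        seed=seed,
        delta_t_spec=CategoricalOffset(
            before_range_pct=(-28.0, -12.0), after_range_pct=(12.0, 28.0)
        ),
    )
    defaults.update(overrides)
    return SimulationConfig(**defaults)


@pytest.fixture(scope="session")
def benchmark_movie():
    return generate_movie(benchmark_config(seed=1))


@pytest.fixture(scope="session")
def benchmark_results(benchmark_movie):
    from dualtrace.model import TwoChannelEventModel

    return TwoChannelEventModel.from_movie(benchmark_movie).fit()
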