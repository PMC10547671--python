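import numpy as np
import pytest

from ctmaxtools import RampParams, ScenarioConfig, SensorLog


def linear_trace(
    sensor_id: str = "s1",
    t0: float = 18.0,
    rate_per_min: float = 0.2,
    duration: float = 1200.0,
    step: float = 10.0,
    offset: float = 0.0,
) -> SensorLog:
    """Noiseless linear ramp T(t) = t0 + rate * t / 60 + offset."""
    times = np.arange(0.0, duration + step / 2, step)
    return SensorLog(sensor_id, times, t0 + rate_per_min * times / 60.0 + offset)


@pytest.fixture
def linear_logs():
    """Three linear traces offset by -0.1, 0, +0.1 degrees C."""
    return [
        linear_trace(f"s{i + 1}", offset=off) for i, off in enumerate((-0.1, 0.0, 0.1))
    ]


@pytest.fixture
def tiny_config():
    """Small, fast scenario: 2 replicates, 2 days, no exclusions."""
    return ScenarioConfig(
        n_replicates=2, n_days=2, exclusion_prob=0.0, seed=7
    )


@pytest.fixture
def default_ramp():
    return RampParams()


def random_piecewise_trace(rng: np.random.Generator) -> SensorLog:
    """Random piecewise-linear temperature trace for oracle comparisons."""
    n = rng.integers(5, 40)
    times = np.cumsum(rng.uniform(1.0, 30.0, size=n))
    times = np.concatenate(([0.0], times))
    temps = 18.0 + np.cumsum(rng.uniform(-0.2, 0.5, size=n + 1))
    return SensorLog("sx", times, temps)


def dense_window_mean(log: SensorLog, a: float, b: float, step: float = 0.01) -> float:
    """Brute-force mean of the interpolated trace over [a, b] on a dense grid."""
    if b - a < step:
        return float(np.interp(b, log.times, log.temps))
    grid = np.arange(a, b, step)
    grid = np.append(grid, b)
    vals = np.interp(grid, log.times, log.temps)
    return float(np.trapezoid(vals, grid) / (b - a))
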