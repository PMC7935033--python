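import numpy as np
import pytest

from spikecircuit import (RasterSpec, BurstSpec, CorrelationSpec, TraceSpec,
                          generate_raster, generate_trace)


@pytest.fixture(scope="session")
def poisson_raster():
    """20 independent 5-Hz Poisson sources, 300 s."""
    return generate_raster(RasterSpec(n_sources=20, duration=300.0,
                                      base_rate=5.0, seed=42))


@pytest.fixture(scope="session")
def correlated_raster():
    """Two planted groups of 10 sources sharing 90% of a mother train."""
    spec = RasterSpec(
        n_sources=20, duration=300.0, base_rate=4.0,
        correlation_spec=CorrelationSpec(
            group_of_source=tuple([0] * 10 + [1] * 10),
            sharing_prob=0.9, jitter=0.001),
        seed=7)
    return generate_raster(spec)


@pytest.fixture(scope="session")
def planted_trace():
    """One channel, 100 spikes at 10x noise SD, >=50 ms apart."""
    rng = np.random.default_rng(3)
    times = np.cumsum(rng.uniform(0.05, 0.15, size=100)) + 0.5
    spec = TraceSpec(true_spike_times=(tuple(times),), duration=14.0,
                     sampling_rate=20_000.0, noise_sd=5e-6,
                     amplitude=50e-6, seed=3)
    return generate_trace(spec)
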