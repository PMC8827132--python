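import numpy as np
import pytest

from gatedphasor import (
    DecayModel,
    GateConfig,
    LaserConfig,
    SimulationParams,
    simulate_gate_stack,
)

FREQ_HZ = 20e6
PERIOD_NS = 50.0


@pytest.fixture
def laser() -> LaserConfig:
    return LaserConfig(period_ns=PERIOD_NS)


@pytest.fixture
def gates_140() -> GateConfig:
    return GateConfig(width_ns=13.1, step_ns=PERIOD_NS / 140, num_gates=140)


@pytest.fixture
def stack_factory(laser):
    """Factory for small synthetic single-exponential gate stacks."""

    def make(
        tau_ns: float,
        seed: int,
        shape=(16, 16),
        gates: GateConfig | None = None,
        brightness: float = 0.8,
        frames_per_gate: int = 255,
        **kwargs,
    ):
        if gates is None:
            gates = GateConfig(width_ns=13.1, step_ns=PERIOD_NS / 140, num_gates=140)
        params = SimulationParams(
            laser=laser,
            gates=gates,
            decay=DecayModel.single(tau_ns),
            shape=shape,
            brightness=brightness,
            frames_per_gate=frames_per_gate,
            seed=seed,
            **kwargs,
        )
        return simulate_gate_stack(params)

    return make


def mean_phasor_with_se(img):
    """Mean (g, s) of valid per-pixel phasors with the covariance of the mean."""
    g = img.g[img.valid]
    s = img.s[img.valid]
    cov = np.cov(g, s) / g.size
    return float(g.mean()), float(s.mean()), cov
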