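import numpy as np
import pytest

from combatmet.data import BreathSeries, CombatProtocol, segment_phases
from combatmet.simulate import SimConfig, gen_cohort


@pytest.fixture(scope="session")
def protocol() -> CombatProtocol:
    return CombatProtocol()


@pytest.fixture(scope="session")
def sim_cfg() -> SimConfig:
    return SimConfig(seed=11)


@pytest.fixture(scope="session")
def small_cohort():
    """Four-subject crossover cohort shared across pipeline tests."""
    return gen_cohort(SimConfig(seed=11, n_subjects=4))


def make_flat_series(protocol: CombatProtocol, vo2: float = 300.0, dt: float = 1.0) -> BreathSeries:
    """Constant-VO2 series covering baseline through recovery at dt spacing."""
    t0 = protocol.baseline_window[0]
    t1 = protocol.recovery_window[1]
    t = np.arange(t0, t1 + dt / 2, dt)
    return segment_phases(BreathSeries(t, np.full(t.size, vo2)), protocol)


@pytest.fixture()
def flat_series(protocol):
    return make_flat_series(protocol)
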