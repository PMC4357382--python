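import numpy as np
import pytest

from capswitch.engine import SimConfig, Trajectory
from capswitch.network import (RATE_NAMES, RateSet, SPECIES,
                               build_growth_capsulation_network)
from capswitch.sweeps import default_init_config, default_rates


@pytest.fixture(scope="session")
def rates():
    return default_rates()


@pytest.fixture(scope="session")
def init_cfg():
    return default_init_config()


@pytest.fixture(scope="session")
def network(rates):
    return build_growth_capsulation_network(rates)


def birth_death_rates(a: float, b: float) -> RateSet:
    """UXP-only birth-death chain: production @a, first-order drain @b."""
    zeros = {n: 0.0 for n in RATE_NAMES}
    zeros["k_uxp_prod"] = a
    zeros["k_pyrg_drain"] = b
    return RateSet.from_dict(zeros)


def make_ca_trajectory(times, ca_values, t_end, rates=None, seed=0):
    """Hand-built piecewise-constant trajectory with a prescribed CA series."""
    times = np.asarray(times, dtype=float)
    counts = np.zeros((len(times), len(SPECIES)), dtype=np.int64)
    counts[:, SPECIES.index("CA")] = np.asarray(ca_values, dtype=np.int64)
    cfg = SimConfig(t_end=float(t_end), burn_in=float(times[0]), seed=seed,
                    record_mode="event")
    if rates is None:
        rates = birth_death_rates(1.0, 1.0)
    from capswitch.network import SpeciesState
    init = SpeciesState(counts[0].copy())
    return Trajectory(times=times, counts=counts, config=cfg, rates=rates,
                      initial_state=init)
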