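import numpy as np
import pytest

from sandswim import SwimConfig, WaveSpec, simulate


@pytest.fixture(scope="session")
def uniform_traj():
    """Default uniform-body run: A/lambda = 0.2, f = 2 Hz, horizontal,
    3 steady cycles after a quarter-cycle discard."""
    return simulate(SwimConfig())


@pytest.fixture(scope="session")
def tapered_traj():
    return simulate(SwimConfig(plan="tapered"))


@pytest.fixture(scope="session")
def uniform_traj_2f():
    """Same run at doubled frequency (for exact frequency-scaling checks)."""
    return simulate(SwimConfig(wave=WaveSpec(frequency=4.0)))


@pytest.fixture(scope="session")
def small_bed():
    """Shared settled mini-bed (softened stiffness, deterministic seed)."""
    from sandswim.dem import prepare_bed

    return prepare_bed(dims=(0.065, 0.032, 0.038), seed=1, stiffness_scale=0.25)


@pytest.fixture(scope="session")
def drag_runs(small_bed):
    """Steady rod drag at reference conditions plus speed/depth variations."""
    from sandswim.dem import drag_rod

    rod = (0.024, 0.008, 0.008)
    kw = dict(rod_size=rod, travel_widths=3.5, discard_widths=1.5)
    return {
        "broadside": drag_rod(small_bed, np.pi / 2, speed=0.25, depth=0.015, **kw),
        "broadside_slow": drag_rod(small_bed, np.pi / 2, speed=0.12, depth=0.015, **kw),
        "shallow": drag_rod(small_bed, np.pi / 2, speed=0.25, depth=0.009, **kw),
        "deep": drag_rod(small_bed, np.pi / 2, speed=0.25, depth=0.021, **kw),
        "axial": drag_rod(small_bed, 0.0, speed=0.25, depth=0.015, **kw),
    }


@pytest.fixture(scope="session")
def oscillation_runs(small_bed):
    """Oscillating-rod records at large/small amplitude and doubled frequency."""
    from sandswim.dem import oscillate_rod

    large, m_large = oscillate_rod(small_bed, amplitude=0.018, frequency=3.0,
                                   depth=0.015, n_cycles=2.85)
    small, m_small = oscillate_rod(small_bed, amplitude=0.005, frequency=3.0,
                                   depth=0.015, n_cycles=2.85)
    _, m_large_2f = oscillate_rod(small_bed, amplitude=0.018, frequency=6.0,
                                  depth=0.015, n_cycles=2.85)
    return {
        "large": (large, m_large),
        "small": (small, m_small),
        "large_2f": (None, m_large_2f),
    }
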