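import numpy as np
import pytest

from spckinetics import popsim


@pytest.fixture
def fixed_cycle_params():
    """Reference cycle with abbreviated G1: 0.5/4/3/0.5 h, 8-h cycle."""
    return popsim.CellCycleParams(
        t_g1=0.5, t_s=4.0, t_g2=3.0, t_m=0.5, entry_rate=0.0, n_cells=200
    )


@pytest.fixture
def big_population(fixed_cycle_params):
    """Large stationary snapshot for occupancy checks."""
    params = fixed_cycle_params.replace(n_cells=100_000)
    return params, popsim.init_population(params, seed=11)


def single_cell_population(params, phase, phase_age):
    """Hand-built one-cell population for boundary-crossing tests."""
    pop = popsim.init_population(params.replace(n_cells=1), seed=0)
    pop.phase[0] = phase
    pop.phase_age[0] = phase_age
    pop.schedule[0] = params.durations
    return pop
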