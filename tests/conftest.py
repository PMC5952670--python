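import numpy as np
import pytest

import hyperkinetics as hk


@pytest.fixture(scope="session")
def two_pulse_schedule():
    return hk.default_two_pulse_schedule()


@pytest.fixture(scope="session")
def single_500_schedule():
    return hk.single_pulse_schedule()


@pytest.fixture(scope="session")
def cytosol_noiseless_experiment(two_pulse_schedule):
    preset = hk.compartment_preset("cytosol").without_noise()
    return hk.simulate_experiment(preset, None, two_pulse_schedule,
                                  n_cells=1, cell_cv=0.0, seed=0)


@pytest.fixture()
def toy_trace():
    """Small hand-built dual-channel trace."""
    t = np.arange(6) * 20.0
    return hk.AcquisitionTrace(
        cell_id="c0",
        time_s=t,
        f420=np.array([100.0, 100, 100, 50, 50, 80]),
        f490=np.array([150.0, 150, 150, 300, 300, 200]),
        metadata={"experiment_id": "e0", "cell_line": "A549"},
    )
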