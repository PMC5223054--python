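import numpy as np
import pytest

import oscmem as om


@pytest.fixture(scope="session")
def sensors16():
    return om.make_sensor_space(16)


@pytest.fixture(scope="session")
def model24(sensors16):
    """Coarse (24 mm) source model on the 16-channel montage."""
    return om.build_leadfield(sensors16, grid_spacing=0.024)


@pytest.fixture(scope="session")
def small_subject(sensors16, model24):
    """One simulated subject at reduced size, with the default effects."""
    counts = {c: 16 for c in om.CELLS}
    return om.simulate_subject(
        sensors16, model24, om.default_effects(), counts,
        seed=11, srate=250.0, n_noise_dipoles=16, subject_id="sub-test")


@pytest.fixture(scope="session")
def small_cells(small_subject):
    """Smoothed first-level cell averages for the small subject (2-10 Hz)."""
    power = om.morlet_power(small_subject, np.arange(2.0, 10.5, 1.0))
    z = om.zscore_power(power)
    cells = om.average_cells(z, small_subject.cell_labels)
    return {c: om.smooth_tf(m) for c, m in cells.items()}
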