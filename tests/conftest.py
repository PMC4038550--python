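import numpy as np
import pytest

import darkbench as db


@pytest.fixture(scope="session")
def catalogue():
    return db.builtin_scenarios()


@pytest.fixture(scope="session")
def small_spec():
    """A quarter-size field for fast rendering tests."""
    return db.FieldSpec(width_px=256, height_px=256, n_cells_target=20)


@pytest.fixture(scope="session")
def quiet_camera():
    """Noise-free, unbinned camera: exact pixel arithmetic."""
    return db.CameraModel(shot_noise=False, read_noise_sd=0.0, binning=1)


@pytest.fixture(scope="session")
def rendered_field(catalogue, small_spec):
    """One default-noise field of 20 EV cells with its ground truth."""
    geoms = db.place_cells(small_spec, 20, seed=101)
    pop = db.simulate_population(catalogue["pGFPamy@OD5"], len(geoms), seed=102)
    img = db.render_field(pop.total_values, geoms, small_spec,
                          db.CameraModel(), seed=103)
    return img


def gamma_sample(rng, mean, sd, n):
    """Independent gamma oracle used by deconvolution tests."""
    return rng.gamma((mean / sd) ** 2, sd ** 2 / mean, n)
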