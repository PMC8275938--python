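import numpy as np
import pytest

from headcrit import PulseSpec, synth_pulse


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def haversine_pulse():
    """A smooth mid-severity pulse with all channel groups populated."""
    rec, truth = synth_pulse(PulseSpec(shape="haversine", peak_lin=120.0,
                                       peak_rot_acc=6000.0, peak_rot_vel=45.0,
                                       duration=0.030, dt=2e-4, seed=7))
    return rec, truth


def random_exceedance_field(seed, n_elements=50, timesteps=10):
    """A synthetic element field with seeded random CSDM/DDM targets."""
    from headcrit import FieldSpec, synth_element_field

    r = np.random.default_rng(seed)
    k25 = int(r.integers(0, n_elements + 1))
    k15 = int(r.integers(k25, n_elements + 1))
    kddm = int(r.integers(0, n_elements + 1))
    spec = FieldSpec(
        n_elements=n_elements,
        volume_law="equal",
        target_csdm={0.15: k15 / n_elements, 0.25: k25 / n_elements},
        target_ddm=kddm / n_elements,
        timesteps=timesteps,
        seed=seed,
    )
    return synth_element_field(spec)
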