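import numpy as np
import pytest

from ringpol import (
    ideal_instrument,
    make_diagonal_depolarizer,
    make_linear_diattenuator,
    make_linear_retarder,
)


@pytest.fixture(scope="session")
def instrument():
    return ideal_instrument()


@pytest.fixture()
def rng():
    return np.random.default_rng(20240)


def random_lu_chipman_product(rng, with_rotation=False):
    """A random physically valid depolarizer @ retarder @ diattenuator
    product together with its construction parameters."""
    a, b = rng.uniform(0.7, 1.0, 2)
    c = rng.uniform(0.7, 1.0)
    delta = rng.uniform(2.0, 170.0)
    axis = rng.uniform(0.0, 180.0)
    r = rng.uniform(0.5, 1.0)
    d_axis = rng.uniform(0.0, 180.0)
    psi = rng.uniform(-20.0, 20.0) if with_rotation else 0.0
    from ringpol import make_rotator

    M = (
        make_diagonal_depolarizer(a, b, c)
        @ make_linear_retarder(delta, axis)
        @ make_rotator(psi)
        @ make_linear_diattenuator(1.0, r, d_axis)
    )
    truth = {
        "a": a, "b": b, "c": c, "delta": delta, "axis": axis,
        "psi": psi, "D": (1 - r) / (1 + r), "d_axis": d_axis,
    }
    return M, truth
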