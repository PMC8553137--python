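import numpy as np
import pytest

from conesens import mouse_cone_parameters, solve_dark_state
from conesens.cascade import simulate_cascade
from conesens.photoresponse import simulate_response


@pytest.fixture(scope="session")
def table10():
    """The packaged best-fit mouse-cone parameter set."""
    return mouse_cone_parameters()


@pytest.fixture(scope="session")
def dark(table10):
    return solve_dark_state(table10)


@pytest.fixture(scope="session")
def response_940(table10):
    """Half-maximal-flash response at the best-fit parameters."""
    return simulate_response(table10, 940)


@pytest.fixture(scope="session")
def cascade_940(table10):
    return simulate_cascade(table10, 940)


@pytest.fixture(scope="session")
def gsa_draws():
    """10^4 uniform draws over the sensitivity-analysis ranges (seeded)."""
    from conesens.parameters import gsa_ranges

    r = gsa_ranges()
    lo, hi = (np.asarray(b) for b in r.bounds())
    rng = np.random.default_rng(20260926)
    X = lo + (hi - lo) * rng.random((10_000, len(r.names)))
    return r, {n: X[:, j] for j, n in enumerate(r.names)}
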