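import numpy as np
import pytest

import tmcgm


@pytest.fixture(scope="session")
def bundled():
    """The three bundled hospitalization-rate series keyed by disease code."""
    return {c: tmcgm.load_hospitalization_rates(c) for c in ("DD", "HD", "CD")}


@pytest.fixture(scope="session")
def noiseless_series():
    """Exact grey series with known parameters (a=-0.2, b=1, x1=1, n=8)."""
    return tmcgm.generate_grey_series(
        tmcgm.SyntheticSpec(a_true=-0.2, b_true=1.0, x1=1.0, n=8)
    )


@pytest.fixture(scope="session")
def near_exact_series():
    """Grey series in the small-|a| regime where the closed-form
    restoration's discretization bias (O(a³) per step) is below 1e-9."""
    return tmcgm.generate_grey_series(
        tmcgm.SyntheticSpec(a_true=-1e-4, b_true=1.0, x1=1.0, n=12)
    )


@pytest.fixture(scope="session")
def hd_fit(bundled):
    return tmcgm.fit_gm11(bundled["HD"])


@pytest.fixture(scope="session")
def hd_context(hd_fit):
    part = tmcgm.partition_states(hd_fit.residuals[1:], 3)
    trans = tmcgm.estimate_transitions(part.labels, 3)
    return tmcgm.CorrectionContext(part, trans, np.full(3, 0.5))
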