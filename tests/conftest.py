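import numpy as np
import pytest

import wingflow as wf


@pytest.fixture(scope="session")
def default_corrugated():
    return wf.make_corrugated(4.0, wf.CorrugationSpec())


@pytest.fixture(scope="session")
def ellipse_section():
    return wf.make_ellipse(4.0, 0.125)


@pytest.fixture(scope="session")
def plate_section():
    return wf.make_flat_plate(4.0, 0.0125)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260923)
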