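import numpy as np
import pytest

from mesowin.connectivity import MidlineAxis


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def vertical_midline():
    """Vertical midline between columns for a 24x24 image (mirror col -> 23-col)."""
    return MidlineAxis(bregma=(0.0, 11.5), lambda_pt=(23.0, 11.5))


def midline_of(truth: dict) -> MidlineAxis:
    return MidlineAxis(
        bregma=tuple(truth["midline"]["bregma"]),
        lambda_pt=tuple(truth["midline"]["lambda"]),
    )
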