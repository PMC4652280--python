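import numpy as np
import pandas as pd
import pytest

from macscreen.panel_io import MISSING, P1, P2, GenotypePanel


def make_panel(calls, chroms=None, positions=None, strain_prefix="S"):
    """Build a panel from a nested list of call codes."""
    calls = np.asarray(calls, dtype=np.int8)
    n, m = calls.shape
    markers = pd.DataFrame(
        {
            "marker_id": [f"mk{j + 1}" for j in range(m)],
            "chromosome": chroms if chroms is not None else ["I"] * m,
            "position": positions if positions is not None else [(j + 1) * 100 for j in range(m)],
        }
    )
    return GenotypePanel(
        strain_ids=[f"{strain_prefix}{i + 1}" for i in range(n)],
        markers=markers,
        calls=calls,
    )


@pytest.fixture
def toy_panel():
    """4 strains x 5 markers, mixed frequencies, one missing call."""
    return make_panel(
        [
            [P1, P1, P2, P2, P1],
            [P1, P2, P2, P2, P1],
            [P2, P2, P2, P1, MISSING],
            [P1, P2, P2, P1, P1],
        ]
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20150904)
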