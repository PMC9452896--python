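import numpy as np
import pandas as pd
import pytest

from mirpair.io import MirCountMatrix


@pytest.fixture
def paired_sheet():
    """3 subjects x 2 compartments x 3 treatments — the study layout."""
    rows = [
        (f"S{s}_{c}_{t}", f"S{s}", c, t)
        for t in ("CTL", "CLFS", "IHFS")
        for c in ("MB", "EV")
        for s in (1, 2, 3)
    ]
    return pd.DataFrame(
        rows, columns=["sample_id", "subject", "compartment", "treatment"]
    ).set_index("sample_id")


@pytest.fixture
def small_matrix(paired_sheet):
    rng = np.random.default_rng(0)
    counts = pd.DataFrame(
        rng.poisson(50, size=(30, len(paired_sheet))),
        index=pd.Index([f"miR-{i}" for i in range(30)], name="mir_id"),
        columns=paired_sheet.index,
    )
    return MirCountMatrix(counts, paired_sheet)
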