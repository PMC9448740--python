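import numpy as np
import pandas as pd
import pytest

from ramandx.containers import META_COLUMNS, BasisLibrary, SpectrumSet
from ramandx.synthetic import default_axis, make_basis_library


@pytest.fixture(scope="session")
def axis():
    """Coarse (2 cm^-1) acquisition axis used throughout the tests."""
    return default_axis(2.0)


@pytest.fixture(scope="session")
def library(axis):
    """A 31-chemical reference library on the coarse axis."""
    return make_basis_library(n=31, axis=axis, seed=7)


def make_meta(n, biopsy="b1", patient="p1"):
    return pd.DataFrame(
        {
            "patient_id": [patient] * n,
            "biopsy_id": [biopsy] * n,
            "timepoint": ["pre"] * n,
            "slice_index": [0] * n,
            "region_index": [0] * n,
            "grid_row": list(range(n)),
            "grid_col": [0] * n,
        },
        columns=META_COLUMNS,
    )


@pytest.fixture
def small_set(axis):
    """Three synthetic Gaussian-band spectra on the shared axis."""
    rng = np.random.default_rng(0)
    y = np.vstack(
        [
            10.0 * np.exp(-0.5 * ((axis - c) / 12.0) ** 2) + 1.0
            for c in (700.0, 1003.0, 1450.0)
        ]
    )
    y += rng.uniform(0.0, 0.01, size=y.shape)
    return SpectrumSet(axis, y, make_meta(3))
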