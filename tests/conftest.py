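import numpy as np
import pandas as pd
import pytest

from udpharm.design import default_dose_ranges, glp_design, scale_doses
from udpharm.herbfx import expand_poly_terms

HERBS = ("ZR", "GCR", "LAR", "CR", "FF", "PR")


@pytest.fixture(scope="session")
def ud_dose_matrix():
    """The canonical 7-run, 6-herb uniform-design dose matrix."""
    table = glp_design(7, 6, generators=[1, 2, 3, 4, 5, 6])
    return scale_doses(table, default_dose_ranges(), HERBS)


@pytest.fixture(scope="session")
def ud_terms(ud_dose_matrix):
    """Standardized polynomial term matrix of the canonical design."""
    X = expand_poly_terms(ud_dose_matrix, standardize_doses=True)
    out = {}
    for c in X.columns:
        col = X[c].to_numpy(float)
        sd = col.std(ddof=1)
        out[c] = (col - col.mean()) / sd if sd > 0 else col * 0
    return pd.DataFrame(out, index=X.index)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
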