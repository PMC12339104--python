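import numpy as np
import pandas as pd
import pytest

from segnav.connectivity import ZConnectivity
from segnav.parcellation import make_parcellation


@pytest.fixture
def two_block_parcellation():
    return make_parcellation([2, 2], ["A", "B"])


def random_z_connectivity(rng, n_parcels, subject_id="s0", neg_fraction=0.3):
    """Symmetric z matrix with a mix of positive and negative edges;
    validity mask derived from the sign (diagonal excluded)."""
    z = rng.normal(0.3, 0.4, size=(n_parcels, n_parcels))
    z = (z + z.T) / 2.0
    flip = rng.random((n_parcels, n_parcels)) < neg_fraction
    flip = flip & flip.T
    z[flip] = -np.abs(z[flip])
    np.fill_diagonal(z, 0.0)
    off = ~np.eye(n_parcels, dtype=bool)
    return ZConnectivity(subject_id, z, off & (z >= 0))


@pytest.fixture
def phenotype_frame():
    return pd.DataFrame(
        {
            "subject_id": ["S0", "S1"],
            "insulin": [10.0, 7.5],
            "glucose": [5.6, 4.9],
            "waist": [94.0, 80.0],
            "height": [176.0, 163.0],
            "triglycerides": [1.4, 0.9],
            "systolic": [131.0, 118.0],
            "hdl": [1.2, 1.7],
            "sex": ["M", "F"],
            "age": [63.0, 58.0],
            "education": [12.0, 16.0],
            "bmi": [27.0, 23.5],
            "apoe_carrier": [True, False],
        }
    )
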