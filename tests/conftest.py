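import numpy as np
import pandas as pd
import pytest
from rdkit import RDLogger

RDLogger.DisableLog("rdApp.*")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture()
def small_well_table():
    """One plate: three DMSO controls and two test wells, two features.

    For feature fa the controls are [1, 2, 3] (median 2, MAD 1); for fb they
    are [10, 20, 30] (median 20, MAD 10).
    """
    return pd.DataFrame({
        "plate_id": "P001",
        "well": ["A01", "A02", "A03", "B01", "B02"],
        "compound_id": ["DMSO", "DMSO", "DMSO", "cpd_a", "cpd_b"],
        "concentration_um": [0.0, 0.0, 0.0, 10.0, 10.0],
        "role": ["control"] * 3 + ["test"] * 2,
        "dmso_percent": 0.1,
        "fa": [1.0, 2.0, 3.0, 5.0, 2.0],
        "fb": [10.0, 20.0, 30.0, 20.0, 50.0],
    })


@pytest.fixture(scope="session")
def funnel_fixture():
    from darkprofiler.synthdata import toy_funnel_records
    return toy_funnel_records()


@pytest.fixture(scope="session")
def toy_sdf(tmp_path_factory):
    """Toy SDF (with one corrupt record) written to disk, plus ground truth."""
    from darkprofiler.synthdata import generate_toy_sdf
    text, truth = generate_toy_sdf(seed=3, include_corrupt=True)
    path = tmp_path_factory.mktemp("sdf") / "toy.sdf"
    path.write_text(text)
    return path, truth
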