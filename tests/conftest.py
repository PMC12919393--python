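import numpy as np
import pandas as pd
import pytest

from soilpte import core, pmf, synthetic
from soilpte.core import ELEMENTS


@pytest.fixture(scope="session")
def refs():
    return core.load_reference_tables()


def _tiny_df():
    rows = []
    rng = np.random.default_rng(0)
    for i, lu in enumerate(("CM", "AG", "RS")):
        row = {
            "sample_id": f"S{i + 1:03d}", "land_use": lu,
            "x": 1000.0 * (i + 1), "y": 2000.0 * (i + 1),
            "depth_class": "0-20cm", "pH": 5.5 + 0.3 * i, "EC_uScm": 200.0 + i,
            "C_pct": 0.5, "N_pct": 0.05, "OM_pct": 1.0 + 0.1 * i,
            "CEC_cmolkg": 10.0, "texture": "sandy_loam",
        }
        for el in ELEMENTS:
            row[el] = float(rng.uniform(1.0, 100.0))
            row[f"{el}_below_mdl"] = bool(i == 0 and el == "Hg")
        rows.append(row)
    return pd.DataFrame(rows)


@pytest.fixture()
def tiny_dataset():
    """Three samples, three land uses, with one censoring flag set."""
    return core.SoilDataset(_tiny_df(), {"Hg": 0.005})


@pytest.fixture(scope="session")
def noiseless_k2(refs):
    """Noise-free rank-2 survey (60 samples) with ground truth."""
    spec = synthetic.make_default_sourcespec(2, seed=1, noise_cv=0.0)
    ds, truth = synthetic.synthesize_dataset(spec, 12, mdl=refs.mdl, seed=1)
    U = pmf.build_uncertainty_matrix(ds, 0.1, refs.mdl)
    return ds, truth, U


@pytest.fixture(scope="session")
def noiseless_k4(refs):
    """Noise-free four-source survey at the full study size (120 samples)."""
    spec = synthetic.make_default_sourcespec(4, seed=1, noise_cv=0.0)
    ds, truth = synthetic.synthesize_dataset(spec, 24, mdl=refs.mdl, seed=1)
    U = pmf.build_uncertainty_matrix(ds, 0.1, refs.mdl)
    return ds, truth, U


@pytest.fixture(scope="session")
def noisy_k4(refs):
    """Four-source survey with 10% multiplicative noise (120 samples)."""
    spec = synthetic.make_default_sourcespec(4, seed=1, noise_cv=0.1)
    ds, truth = synthetic.synthesize_dataset(spec, 24, mdl=refs.mdl, seed=1)
    U = pmf.build_uncertainty_matrix(ds, 0.1, refs.mdl)
    return ds, truth, U


@pytest.fixture(scope="session")
def base_solution_k4(noisy_k4):
    ds, truth, U = noisy_k4
    return pmf.fit_pmf(ds.concentrations(), U, 4, n_starts=5, seed=3)
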