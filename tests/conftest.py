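import numpy as np
import pandas as pd
import pytest

from bbbperm.synthetic_data import (
    SyntheticSpec,
    classification_arrays,
    fixture_compounds,
    generate_descriptor_dataset,
)


@pytest.fixture(scope="session")
def fixtures_by_name():
    return {c.name: c for c in fixture_compounds()}


@pytest.fixture(scope="session")
def table3_rows():
    """The two published worked-example descriptor rows (printed values)."""
    return {
        "sucrose": {
            "MW": 342.12, "aLogP": -4.3105, "tPSA": 189.53, "fPSA3": 0.072136,
            "rotBonds": 5, "BCUTS": 11.9962, "hBondAcceptors": 11,
        },
        "midazolam": {
            "MW": 325.08, "aLogP": 0.4073, "tPSA": 27.96, "fPSA3": 0.033577,
            "rotBonds": 1, "BCUTS": 11.9974, "hBondAcceptors": 3,
        },
    }


@pytest.fixture(scope="session")
def synthetic_default():
    """Default synthetic descriptor dataset plus its classification subset."""
    spec = SyntheticSpec(seed=11)
    X, logps, labels = generate_descriptor_dataset(spec)
    Xc, y = classification_arrays(X, labels)
    return spec, X, logps, labels, Xc, y


@pytest.fixture()
def tiny_csv(tmp_path):
    path = tmp_path / "compounds.csv"
    path.write_text(
        "id,name,smiles,logps\n"
        "c1,ethanol,CCO,-0.5\n"
        "c2,sucrose,OC[C@H]1O[C@@](CO)(O[C@@H]2O[C@H](CO)[C@@H](O)[C@H](O)[C@H]2O)[C@@H](O)[C@@H]1O,-3.8\n"
        "c3,benzene,c1ccccc1,-2.5\n"
    )
    return path


def make_planted_frame(n, rng, sep_attr="sig", noise=0.0):
    """One perfectly (or nearly) separating attribute among distractors."""
    y = (rng.random(n) < 0.5).astype(int)
    X = pd.DataFrame(
        {
            sep_attr: np.where(y == 1, rng.uniform(1, 2, n), rng.uniform(-2, -1, n)),
            "noise_a": rng.normal(size=n),
            "noise_b": rng.uniform(0, 100, n),
        }
    )
    if noise > 0:
        flip = rng.random(n) < noise
        y = np.where(flip, 1 - y, y)
    return X, y
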