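import numpy as np
import pytest

from photoreact.synth import GeneratorConfig, gen_molecules, gen_spectra, simulate


@pytest.fixture(scope="session")
def small_fixture():
    """300 seeded synthetic molecules with spectra, labels and outcomes."""
    cfg = GeneratorConfig(n_molecules=300, seed=7)
    mols, spectra, truth, labels, tox = simulate(cfg)
    return {
        "cfg": cfg,
        "mols": mols,
        "spectra": spectra,
        "truth": truth,
        "labels": labels,
        "tox": tox,
    }


@pytest.fixture(scope="session")
def fixture_smiles(small_fixture):
    return [m.smiles for m in small_fixture["mols"]]


@pytest.fixture(scope="session")
def separable_xy():
    """Synthetic separable binary problem: 2 informative columns out of 12."""
    rng = np.random.default_rng(0)
    n = 240
    y = np.array(["POS", "NEG"])[rng.integers(0, 2, n)]
    X = rng.normal(size=(n, 12))
    X[:, 3] += np.where(y == "POS", 3.0, -3.0)
    X[:, 7] += np.where(y == "POS", -2.5, 2.5)
    return X, y
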