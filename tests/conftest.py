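import numpy as np
import pytest

# Diverse, valid SMILES covering chains, rings, aromatics, heteroatoms,
# halogens, charges and multi-fragment salts — the shared test fixture set.
FIXTURE_SMILES = [
    "C", "CC", "CCC", "CCCC", "CCCCCC", "CO", "CCO", "OCC", "CCN", "CC(C)C",
    "CC(C)(C)C", "C=C", "C#C", "C#N", "CC=O", "CC(=O)O", "CC(=O)OC",
    "CC(=O)N", "CCOCC", "CCSCC", "CS", "O", "N", "OO", "C1CC1", "C1CCC1",
    "C1CCCCC1", "C1CCOC1", "C1CCNC1", "c1ccccc1", "Cc1ccccc1",
    "Oc1ccccc1", "Nc1ccccc1", "Clc1ccccc1", "c1ccc2ccccc2c1",
    "c1ccncc1", "c1ccoc1", "c1ccsc1", "c1cc[nH]c1", "CCCl", "ClCCCl",
    "ClC(Cl)Cl", "FC(F)F", "BrCC", "ICC", "CC(Cl)CC", "OC(=O)c1ccccc1",
    "COc1ccccc1", "CC(N)C(=O)O", "NCCO", "OCC(O)CO", "C(=O)O",
    "CC(=O)[O-]", "[NH4+]", "CC(=O)[O-].[Na+]", "O=S(=O)(O)O",
    "OP(=O)(O)O", "CSC", "CN(C)C", "CCOC(=O)C", "Cn1cccc1",
]


@pytest.fixture(scope="session")
def fixture_smiles():
    return FIXTURE_SMILES


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def tiny_params():
    """Small deterministic model used across tests (fast forwards)."""
    from rbgnn import init_params
    return init_params(T=2, d=8, seed=5)
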