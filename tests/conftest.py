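import pytest

from qlqsar.compound_set import load_builtin_dataset
from qlqsar.ql_descriptors import build_matrix, default_config


@pytest.fixture(scope="session")
def builtin_set():
    return load_builtin_dataset()


@pytest.fixture(scope="session")
def config():
    return default_config()


@pytest.fixture(scope="session")
def builtin_matrix(builtin_set, config):
    return build_matrix(builtin_set, config)


#: Small molecules (<= 12 heavy atoms) for brute-force descriptor oracles.
TOY_SMILES = [
    "C",                      # methane
    "CN(C)C",                 # trimethylamine
    "c1ccccc1",               # benzene
    "c1ccncc1",               # pyridine
    "c1ccc2ccccc2c1",         # naphthalene
    "NC(N)=N",                # guanidine
    "c1cc[nH]c1",             # pyrrole
    "c1cnc[nH]1",             # imidazole
    "CC(=O)NC(N)=N",          # acetylguanidine
    "O=C1C=CNC(=O)N1",        # uracil
    "C=CCN",                  # allylamine
    "CC(C)(C)O",              # tert-butanol
]


@pytest.fixture(scope="session")
def toy_smiles():
    return list(TOY_SMILES)
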