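import numpy as np
import pytest

import tspopet as tp


@pytest.fixture(scope="session")
def records():
    """Packaged ligand table as a name-keyed dict."""
    return {r.name: r for r in tp.builtin_ligands()}


@pytest.fixture(scope="session")
def constants():
    return tp.PhysiologicalConstants()


@pytest.fixture(scope="session")
def input_fn():
    return tp.synth_input()


@pytest.fixture(scope="session")
def schedule():
    return tp.default_schedule()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


SECOND_GEN = ["18F-PBR111", "11C-PBR28", "11C-DPA713"]
PK11195 = "11C-(R)-PK11195"
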