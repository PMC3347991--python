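import numpy as np
import pytest

from mirkit.catalog import load_builtin_catalog
from mirkit.folding import EnergyParams, fold_mfe


@pytest.fixture(scope="session")
def catalog_records():
    return load_builtin_catalog()


@pytest.fixture(scope="session")
def params():
    return EnergyParams.default()


@pytest.fixture(scope="session", autouse=True)
def _warm_fold_kernel():
    # trigger jit compilation once so per-test timings stay meaningful
    fold_mfe("GGGGAAAACCCC")


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def random_rna(rng, length: int) -> str:
    return "".join(rng.choice(list("ACGU"), size=length))
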