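import numpy as np
import pytest

from epmkit.data_io import ClinicalTable, ExpressionMatrix
from epmkit.network import build_network
from epmkit.synthetic_data import CohortParams, generate_study

# small, fast generative settings used by unit tests (the full default
# conditions are exercised in test_acceptance.py)
SMALL_PARAMS = CohortParams(
    n_genes=300,
    n_edges=800,
    n_tumor_per_subtype=30,
    n_normal=20,
    module_n_edges=15,
    n_de_genes=6,
)


@pytest.fixture(scope="session")
def small_study():
    return generate_study(SMALL_PARAMS, seed=11)


@pytest.fixture(scope="session")
def default_study():
    return generate_study(CohortParams(), seed=1)


@pytest.fixture()
def toy_expression():
    return ExpressionMatrix(
        gene_ids=["A", "B", "C"],
        sample_ids=["s1", "s2"],
        values=np.array([[5.0, 1.0], [1.0, 2.0], [3.0, 4.0]]),
        cohort=["tumor", "normal"],
    )


@pytest.fixture()
def toy_network():
    return build_network([("A", "B"), ("A", "C"), ("B", "C")])


def make_clinical(time, event, prefix="s"):
    ids = [f"{prefix}{i}" for i in range(len(time))]
    return ClinicalTable(ids, np.asarray(time, float), np.asarray(event, int))
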