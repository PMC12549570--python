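import pytest

from rfpep.germline import load_germline_set
from rfpep.simulate import CohortDesign, simulate_experiment


@pytest.fixture(scope="session")
def v_genes():
    return load_germline_set("v_genes")


@pytest.fixture(scope="session")
def j_genes():
    return load_germline_set("j_genes")


@pytest.fixture(scope="session")
def constants():
    return load_germline_set("constant_regions")


@pytest.fixture(scope="session")
def germlines(v_genes, j_genes, constants):
    return v_genes + j_genes + constants


@pytest.fixture(scope="session")
def sim_default():
    """One full-size synthetic cohort shared by read-only tests."""
    return simulate_experiment(CohortDesign(seed=7))


@pytest.fixture(scope="session")
def small_design():
    return CohortDesign(
        group_sizes={"RFposCCPpos_RA": 8, "RFnegCCPpos_RA": 4,
                     "RFnegCCPneg_RA": 6, "RFneg_control": 8,
                     "RFpos_control": 4},
        n_background_peptides=40, n_ig_peptides=40, n_upregulated=10,
        n_also_rfneg=3, n_discriminative=4, n_cdr_variants=5, seed=3)
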