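import pandas as pd
import pytest

from bcrlin import SimConfig, simulate_expression, simulate_repertoire


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    return SimConfig(n_cells_per_sample=100, n_samples_tumor=2, n_samples_blood=2, seed=11)


@pytest.fixture(scope="session")
def small_sim(small_config):
    return simulate_repertoire(small_config)


@pytest.fixture(scope="session")
def small_expression(small_config):
    return simulate_expression(small_config)


@pytest.fixture(scope="session")
def medium_config() -> SimConfig:
    # >= 2000 cells so binomial CI checks on planted fractions are meaningful
    return SimConfig(n_cells_per_sample=500, n_samples_tumor=2, n_samples_blood=2, seed=7)


@pytest.fixture(scope="session")
def medium_sim(medium_config):
    return simulate_repertoire(medium_config)


def make_igh_contig(cell_id="CELL1", umi=10, productive=True, sequence="ACGT",
                    locus="IGH", **overrides) -> dict:
    row = {
        "cell_id": cell_id,
        "sample_id": "TNBC1",
        "compartment": "tumor",
        "locus": locus,
        "productive": productive,
        "v_call": "IGHV1-2*01",
        "d_call": "IGHD1-1",
        "j_call": "IGHJ4",
        "junction": "TGTGCGAGAGATTACTGG",
        "junction_aa": "CARDYW",
        "c_call": "IGHM",
        "duplicate_count": umi,
        "v_mut_count": 0,
        "j_mut_count": 0,
        "vj_aligned_length": 300,
        "sequence": sequence,
    }
    row.update(overrides)
    return row


def contig_table(rows) -> pd.DataFrame:
    return pd.DataFrame([make_igh_contig(**r) if isinstance(r, dict) else r for r in rows])
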