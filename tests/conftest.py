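import pytest

from gdmetl import qc
from gdmetl.etl import EtlEngine, run_etl
from gdmetl.synth import SynthParams, generate


@pytest.fixture(scope="session")
def small_dataset():
    return generate(SynthParams(n_patients=60, seed=5))


@pytest.fixture(scope="session")
def small_etl(small_dataset):
    """(dataset, database, engine) for a 60-patient synthetic run."""
    engine = EtlEngine()
    db = run_etl(small_dataset, engine=engine)
    return small_dataset, db, engine


@pytest.fixture(scope="session")
def concept_code_by_id(small_etl):
    _, db, _ = small_etl
    return db["concepts"].set_index("id")["concept_code"]
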