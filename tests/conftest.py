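import numpy as np
import pytest

from asca.evaluate import run_scenario
from asca.msa import default_scoring
from asca.seqio import AMINO_ACIDS, SequenceRecord


@pytest.fixture(scope="session")
def scoring():
    return default_scoring()


@pytest.fixture(scope="session")
def default_run(tmp_path_factory):
    """One full simulate-and-analyse run of the default family scenario."""
    out = tmp_path_factory.mktemp("scenario")
    family, result = run_scenario(seed=11, out_dir=out)
    return family, result


def random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(AMINO_ACIDS), size=length))


def random_record(rng: np.random.Generator, rid: str, length: int) -> SequenceRecord:
    return SequenceRecord(id=rid, residues=random_protein(rng, length))
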