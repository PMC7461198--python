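import numpy as np
import pytest

from disphred import CAPPED_TERMINI, get_scale, parse_sequence

#: the capped Lys-rich model peptide used throughout the charge tests
MODEL_PEPTIDE = "AKAAKAKAAKAKAAKA"

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


@pytest.fixture(scope="session")
def ph_scale():
    return get_scale("ph_default")


@pytest.fixture(scope="session")
def kd_scale():
    return get_scale("kyte_doolittle")


@pytest.fixture(scope="session")
def guy_scale():
    return get_scale("guy")


@pytest.fixture()
def capped_peptide():
    rec = parse_sequence("Ac-AKAAKAKAAKAKAAKA-NH2", id="model_peptide")
    assert rec.termini == CAPPED_TERMINI
    return rec


def random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(AMINO_ACIDS), size=length))
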