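import numpy as np
import pytest

from passdesign.io import Alignment
from passdesign.msa import NON_THERMOPHILIC, THERMOPHILIC, LabeledFamily


@pytest.fixture
def planted_family() -> LabeledFamily:
    """Tiny hand-countable family: thermophilic members carry T at query
    position 3, non-thermophilic carry E; everything else constant."""
    ids = ["QUERY", "T1", "T2", "T3", "T4", "M1", "M2", "M3", "M4"]
    #        pos:   123456
    seqs = [
        "ACEDGH",        # query
        "ACTDGH", "ACTDGH", "ACTDGH", "ACEDGH",   # thermo: T,T,T,E at pos 3
        "ACEDGH", "ACEDGH", "ACEDGH", "ACEDGH",   # meso: all E
    ]
    labels = {f"T{i}": THERMOPHILIC for i in range(1, 5)}
    labels |= {f"M{i}": NON_THERMOPHILIC for i in range(1, 5)}
    return LabeledFamily(
        alignment=Alignment(ids=ids, sequences=seqs),
        labels=labels,
        query_id="QUERY",
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
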